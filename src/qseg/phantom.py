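"""Synthetic dMRI phantoms: digital anatomy plus tensor forward simulation.

A phantom is a nested set of smooth geometric regions — an ellipsoidal
"brain" with a cortical ribbon, a white-matter interior, a ventricle cavity,
deep nuclei blobs, and a cerebellar lobule — each carrying a diffusion
tensor built from class eigenvalues and an orientation rule.  Acquisitions
are simulated with the single-tensor signal model

    S = S0 * exp(-b * g^T D g)

corrupted by Rician noise, emulating magnitude MRI.  Every step is
deterministic given its seed, so train/test phantoms are reproducible and
distinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError, SpecificationError
from .qspace import AcquisitionScheme, generate_directions

__all__ = [
    "TissueClassSpec",
    "PhantomVolume",
    "DWIVolume",
    "default_class_specs",
    "default_scheme",
    "build_phantom",
    "tensor_signal",
    "simulate_acquisition",
    "fractional_anisotropy",
]

DEFAULT_SNR = 25.0
DEFAULT_BVAL = 1000.0


@dataclass(frozen=True)
class TissueClassSpec:
    """Diffusion properties of one tissue class.

    eigenvalues are the tensor diffusivities in mm^2/s, descending
    (lambda1 >= lambda2 >= lambda3 > 0).  ``orientation`` assigns the
    principal eigenvector per voxel: ``constant`` (fixed
    ``orientation_vector``), ``radial`` (outward from the brain center), or
    ``tangential`` (perpendicular to the radial direction).
    """

    label_id: int
    eigenvalues: tuple
    orientation: str = "constant"
    orientation_vector: tuple = (0.0, 0.0, 1.0)
    s0_mean: float = 1.0
    s0_cv: float = 0.02

    def __post_init__(self):
        ev = tuple(float(v) for v in self.eigenvalues)
        if len(ev) != 3 or any(v <= 0 for v in ev):
            raise SpecificationError(
                f"class {self.label_id}: eigenvalues must be 3 positive values"
            )
        if not ev[0] >= ev[1] >= ev[2]:
            raise SpecificationError(
                f"class {self.label_id}: eigenvalues must be descending, got {ev}"
            )
        if self.orientation not in ("constant", "radial", "tangential"):
            raise SpecificationError(
                f"class {self.label_id}: unknown orientation rule {self.orientation!r}"
            )
        object.__setattr__(self, "eigenvalues", ev)


@dataclass
class PhantomVolume:
    """Ground-truth anatomy: labels, per-voxel tensors, S0, and brain mask."""

    labels: np.ndarray        # (W, H, D) int
    tensor_field: np.ndarray  # (W, H, D, 3, 3) float, mm^2/s
    s0: np.ndarray            # (W, H, D) float
    mask: np.ndarray          # (W, H, D) bool
    spacing: float = 1.0      # mm, isotropic

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class DWIVolume:
    """A simulated 4D acquisition with its scheme and mean b0 image."""

    data: np.ndarray           # (W, H, D, M) float
    scheme: AcquisitionScheme
    mean_b0: np.ndarray        # (W, H, D) float


def default_class_specs() -> list[TissueClassSpec]:
    """Desk-scale tissue inventory.

    Order fixes the geometric role: [white matter, cortical GM, ventricle
    CSF, deep (subcortical) GM, cerebellum].  Diffusivities follow typical
    in-vivo brain values at 3T; S0 gives CSF-bright b0 contrast.
    """
    return [
        TissueClassSpec(1, (1.6e-3, 0.4e-3, 0.4e-3), "tangential", s0_mean=0.72),
        TissueClassSpec(2, (1.0e-3, 0.75e-3, 0.65e-3), "radial", s0_mean=0.85),
        TissueClassSpec(3, (3.0e-3, 3.0e-3, 3.0e-3), "constant", s0_mean=1.6, s0_cv=0.01),
        TissueClassSpec(4, (0.85e-3, 0.7e-3, 0.65e-3), "constant", s0_mean=0.8),
        TissueClassSpec(5, (1.2e-3, 0.6e-3, 0.5e-3), "constant",
                        orientation_vector=(1.0, 0.0, 0.0), s0_mean=0.78),
    ]


def default_scheme(
    n_directions: int = 90,
    n_b0: int = 3,
    bval: float = DEFAULT_BVAL,
    seed: int = 0,
) -> AcquisitionScheme:
    """Single-shell scheme with evenly interleaved b0 images."""
    dirs = generate_directions(n_directions, seed=seed)
    m = n_directions + n_b0
    b0_pos = np.linspace(0, m - 1, n_b0).round().astype(int) if n_b0 else np.array([], int)
    bvecs = np.zeros((m, 3))
    bvals = np.zeros(m)
    dw_pos = np.setdiff1d(np.arange(m), b0_pos)
    bvecs[dw_pos] = dirs
    bvals[dw_pos] = bval
    return AcquisitionScheme(bvecs, bvals)


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _ellipsoid_q(coords, center, radii):
    """Normalized squared radius: q <= 1 inside the ellipsoid."""
    q = np.zeros(coords[0].shape)
    for x, c, r in zip(coords, center, radii):
        q += ((x - c) / r) ** 2
    return q


def build_phantom(
    shape=(64, 64, 64),
    class_specs: list[TissueClassSpec] | None = None,
    seed: int = 0,
    spacing: float = 1.0,
) -> PhantomVolume:
    """Build a seeded anatomical phantom.

    Geometry (ellipsoidal brain, cortical ribbon, ventricles, deep nuclei,
    cerebellar lobule) is jittered per seed so that different seeds yield
    different "participants".  ``class_specs`` maps positionally to the
    roles documented in :func:`default_class_specs`; at least the first
    three (white matter, gray matter, CSF) are required.

    Raises
    ------
    SpecificationError
        If fewer than three classes are supplied, label ids collide, or any
        axis of ``shape`` is below 32.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 32 for s in shape):
        raise SpecificationError(f"shape must be 3D with every axis >= 32, got {shape}")
    specs = list(class_specs) if class_specs is not None else default_class_specs()
    if len(specs) < 3:
        raise SpecificationError("need at least 3 tissue classes (WM, GM, CSF)")
    ids = [s.label_id for s in specs]
    if len(set(ids)) != len(ids) or 0 in ids:
        raise SpecificationError(
            f"overlapping label specification: label ids {ids} must be unique and non-zero"
        )

    rng = np.random.default_rng(seed)
    sh = np.array(shape, dtype=float)
    center = (sh - 1) / 2 + rng.uniform(-1.5, 1.5, size=3)
    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")

    # Brain ellipsoid with a cortical ribbon on its outer rim.
    brain_radii = sh * np.array([0.40, 0.44, 0.38]) * rng.uniform(0.93, 1.05, size=3)
    q_brain = _ellipsoid_q(coords, center, brain_radii)
    ribbon_q = rng.uniform(0.68, 0.74)  # inner boundary of the GM ribbon (in q units)

    labels = np.zeros(shape, dtype=np.int32)
    wm, gm, csf = specs[0], specs[1], specs[2]
    labels[q_brain <= 1.0] = gm.label_id
    labels[q_brain <= ribbon_q] = wm.label_id

    if len(specs) >= 5:  # cerebellar lobule below/behind the main body
        cb = specs[4]
        cb_center = center + sh * np.array([0.0, -0.27, -0.24]) + rng.uniform(-1, 1, 3)
        cb_radii = sh * np.array([0.20, 0.15, 0.12]) * rng.uniform(0.9, 1.1, 3)
        labels[_ellipsoid_q(coords, cb_center, cb_radii) <= 1.0] = cb.label_id

    if len(specs) >= 4:  # paired deep nuclei between ventricles and ribbon
        dgm = specs[3]
        for side in (-1.0, 1.0):
            c = center + sh * np.array([side * 0.17, 0.03, 0.02]) + rng.uniform(-1, 1, 3)
            r = sh * np.array([0.075, 0.10, 0.085]) * rng.uniform(0.9, 1.1, 3)
            labels[_ellipsoid_q(coords, c, r) <= 1.0] = dgm.label_id

    for side in (-1.0, 1.0):  # paired lateral-ventricle cavities (CSF)
        c = center + sh * np.array([side * 0.07, -0.02, 0.05]) + rng.uniform(-0.8, 0.8, 3)
        r = sh * np.array([0.045, 0.16, 0.10]) * rng.uniform(0.9, 1.1, 3)
        labels[_ellipsoid_q(coords, c, r) <= 1.0] = csf.label_id

    # Per-voxel orientation frames and tensors.
    radial = np.stack([x - c for x, c in zip(coords, center)], axis=-1)
    rnorm = np.linalg.norm(radial, axis=-1, keepdims=True)
    radial = np.where(rnorm > 1e-9, radial / np.where(rnorm == 0, 1, rnorm),
                      np.array([1.0, 0.0, 0.0]))

    tensor = np.zeros(shape + (3, 3))
    s0 = np.zeros(shape)
    for spec in specs:
        sel = labels == spec.label_id
        if not np.any(sel):
            continue
        e1 = _principal_direction(spec, radial[sel])
        d = _tensor_from_frame(e1, spec.eigenvalues)
        tensor[sel] = d
        n = int(sel.sum())
        s0[sel] = spec.s0_mean * np.clip(
            1.0 + spec.s0_cv * rng.standard_normal(n), 0.05, None
        )

    mask = ndimage.binary_dilation(labels > 0, iterations=2)
    mask = ndimage.binary_fill_holes(mask)
    # in-mask rim outside tissue: weak CSF-like signal (dura/partial volume)
    rim = mask & (labels == 0)
    if np.any(rim):
        s0[rim] = 0.2 * np.clip(1.0 + 0.05 * rng.standard_normal(int(rim.sum())),
                                0.5, None)
        tensor[rim] = np.eye(3) * 2.0e-3
    return PhantomVolume(labels=labels, tensor_field=tensor, s0=s0, mask=mask,
                         spacing=float(spacing))


def _principal_direction(spec: TissueClassSpec, radial: np.ndarray) -> np.ndarray:
    if spec.orientation == "constant":
        v = np.asarray(spec.orientation_vector, dtype=float)
        v = v / np.linalg.norm(v)
        return np.broadcast_to(v, radial.shape).copy()
    if spec.orientation == "radial":
        return radial
    # tangential: perpendicular to radial, via cross with a fixed axis
    ez = np.array([0.0, 0.0, 1.0])
    ex = np.array([1.0, 0.0, 0.0])
    t = np.cross(radial, ez)
    tn = np.linalg.norm(t, axis=-1, keepdims=True)
    fallback = np.cross(radial, ex)
    t = np.where(tn > 1e-6, t, fallback)
    t /= np.linalg.norm(t, axis=-1, keepdims=True)
    return t


def _tensor_from_frame(e1: np.ndarray, eigenvalues) -> np.ndarray:
    """Tensors with principal eigenvector ``e1`` and the given eigenvalues.

    The secondary axes are completed by Gram-Schmidt against fixed
    reference axes; for lambda2 == lambda3 the choice is immaterial.
    """
    l1, l2, l3 = eigenvalues
    ref = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(e1, np.broadcast_to(ref, e1.shape))
    n2 = np.linalg.norm(e2, axis=-1, keepdims=True)
    alt = np.cross(e1, np.broadcast_to(np.array([1.0, 0.0, 0.0]), e1.shape))
    e2 = np.where(n2 > 1e-6, e2, alt)
    e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(e1, e2)
    return (
        l1 * e1[..., :, None] * e1[..., None, :]
        + l2 * e2[..., :, None] * e2[..., None, :]
        + l3 * e3[..., :, None] * e3[..., None, :]
    )


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA from tensor eigenvalues (last axis of length 3)."""
    ev = np.asarray(eigenvalues, dtype=float)
    mean = ev.mean(axis=-1, keepdims=True)
    num = ((ev - mean) ** 2).sum(axis=-1)
    den = (ev**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


# ---------------------------------------------------------------------------
# Signal simulation
# ---------------------------------------------------------------------------

def tensor_signal(d: np.ndarray, b: float, g: np.ndarray, s0: float) -> float:
    """Single-tensor diffusion signal S = S0 * exp(-b * g^T D g).

    ``d`` must be symmetric positive semi-definite (mm^2/s); ``g`` must be a
    unit vector whenever ``b > 0``.
    """
    if b < 0:
        raise InvalidArgumentError(f"b-value must be non-negative, got {b}")
    d = np.asarray(d, dtype=float)
    g = np.asarray(g, dtype=float)
    if d.shape != (3, 3):
        raise InvalidArgumentError(f"tensor must be 3x3, got {d.shape}")
    if not np.allclose(d, d.T, atol=1e-12):
        raise InvalidArgumentError("tensor must be symmetric")
    if b > 0 and abs(np.linalg.norm(g) - 1.0) > 1e-6:
        raise InvalidArgumentError("gradient direction must be unit norm for b > 0")
    return float(s0 * np.exp(-b * (g @ d @ g)))


def _noiseless_signals(phantom: PhantomVolume, scheme: AcquisitionScheme) -> np.ndarray:
    """Noise-free signal array (W, H, D, M); zero outside the mask."""
    g = scheme.bvecs  # (M, 3)
    quad = np.einsum("...ij,mi,mj->...m", phantom.tensor_field, g, g, optimize=True)
    signals = phantom.s0[..., None] * np.exp(-scheme.bvals * quad)
    return np.where(phantom.mask[..., None], signals, 0.0).astype(np.float64)


def simulate_acquisition(
    phantom: PhantomVolume,
    scheme: AcquisitionScheme,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DWIVolume:
    """Simulate a 4D acquisition of the phantom under the given scheme.

    Each measurement is the closed-form tensor signal corrupted by Rician
    noise of scale ``noise_sigma`` (magnitude of two independent Gaussian
    channels).  Out-of-mask voxels receive pure noise.  The mean b0 image is
    the voxel-wise mean over the scheme's b0 entries of the (noisy) data.
    ``noise_sigma = 0`` reproduces the closed form exactly.  Deterministic
    given ``seed``.
    """
    if noise_sigma < 0:
        raise InvalidArgumentError("noise_sigma must be >= 0")
    if not np.any(scheme.b0_mask):
        raise SpecificationError(
            "scheme contains no b0 entry; a mean b0 image is required downstream"
        )
    signals = _noiseless_signals(phantom, scheme)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, noise_sigma, size=signals.shape)
        n2 = rng.normal(0.0, noise_sigma, size=signals.shape)
        data = np.hypot(signals + n1, n2)
    else:
        data = signals
    mean_b0 = data[..., scheme.b0_mask].mean(axis=-1)
    return DWIVolume(data=data, scheme=scheme, mean_b0=mean_b0)


def noise_sigma_for_snr(phantom: PhantomVolume, snr: float = DEFAULT_SNR) -> float:
    """Noise scale sigma = mean in-mask S0 / SNR."""
    if snr <= 0:
        raise InvalidArgumentError("SNR must be positive")
    return float(phantom.s0[phantom.mask].mean() / snr)
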