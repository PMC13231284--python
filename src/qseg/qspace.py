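"""Gradient tables: generation, sub-sampling, rotation, and FSL-dialect I/O.

An acquisition scheme is the q-space sampling identity of a dataset: ``M``
unit b-vectors with b-values (s/mm^2).  Entries with ``bval == 0`` are b0
measurements and are excluded from all direction-coverage computations.

Direction sets are scored by an antipodally symmetric electrostatic
repulsion energy,

    E = sum_{i<j} 1/||g_i - g_j|| + 1/||g_i + g_j||,

which treats a vector and its antipode as the same measurement direction.
Both the de-novo generator and the maximum-coverage sub-sampler minimize
this energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GradientTableError, InvalidArgumentError

__all__ = [
    "AcquisitionScheme",
    "Rotation",
    "generate_directions",
    "repulsion_energy",
    "subsample_max_coverage",
    "sample_rotation",
    "read_gradient_table",
    "write_gradient_table",
]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class AcquisitionScheme:
    """A gradient table of ``M`` measurements.

    Parameters
    ----------
    bvecs : (M, 3) float array
        Diffusion-encoding directions.  Unit norm is required wherever the
        matching b-value is positive; b0 rows may be zero vectors.
    bvals : (M,) float array
        Diffusion weightings in s/mm^2.
    """

    bvecs: np.ndarray
    bvals: np.ndarray

    def __post_init__(self):
        bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=float))
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise InvalidArgumentError(f"bvecs must be (M, 3), got {bvecs.shape}")
        if bvals.ndim != 1 or len(bvals) != len(bvecs):
            raise InvalidArgumentError(
                f"bvals length {len(bvals)} does not match bvecs length {len(bvecs)}"
            )
        if len(bvals) < 1:
            raise InvalidArgumentError("scheme must contain at least one measurement")
        if np.any(bvals < 0):
            raise InvalidArgumentError("b-values must be non-negative")
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise InvalidArgumentError(
                "b-vectors with bval > 0 must have unit norm within "
                f"{_UNIT_TOL}; worst deviation {np.abs(norms - 1.0).max():.3g}"
            )
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "bvals", bvals)

    @property
    def M(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean mask flagging b0 (``bval == 0``) entries."""
        return self.bvals == 0

    @property
    def dw_indices(self) -> np.ndarray:
        """Original indices of diffusion-weighted (``bval > 0``) entries."""
        return np.flatnonzero(~self.b0_mask)

    def subset(self, indices) -> "AcquisitionScheme":
        idx = np.asarray(indices, dtype=int)
        return AcquisitionScheme(self.bvecs[idx], self.bvals[idx])

    def rotated(self, rotation: "Rotation") -> "AcquisitionScheme":
        return AcquisitionScheme(self.bvecs @ rotation.matrix.T, self.bvals)


@dataclass(frozen=True)
class Rotation:
    """A proper rotation of 3-space (orthonormal matrix, det +1)."""

    matrix: np.ndarray

    _ORTHO_TOL = 1e-10

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InvalidArgumentError(f"rotation matrix must be 3x3, got {m.shape}")
        if not np.allclose(m @ m.T, np.eye(3), atol=self._ORTHO_TOL):
            raise InvalidArgumentError("matrix is not orthonormal within 1e-10")
        if abs(np.linalg.det(m) - 1.0) > self._ORTHO_TOL:
            raise InvalidArgumentError("matrix determinant is not +1 within 1e-10")
        object.__setattr__(self, "matrix", m)

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate an array of 3-vectors stored in the last axis."""
        return np.asarray(vectors) @ self.matrix.T

    def compose(self, other: "Rotation") -> "Rotation":
        return Rotation(self.matrix @ other.matrix)


# ---------------------------------------------------------------------------
# Repulsion energy and direction generation
# ---------------------------------------------------------------------------

def _pair_energy_matrix(vecs: np.ndarray) -> np.ndarray:
    """Symmetric matrix A[i, j] = 1/||gi-gj|| + 1/||gi+gj|| with zero diagonal."""
    diff = vecs[:, None, :] - vecs[None, :, :]
    summ = vecs[:, None, :] + vecs[None, :, :]
    dn = np.linalg.norm(diff, axis=-1)
    sn = np.linalg.norm(summ, axis=-1)
    n = len(vecs)
    eye = np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        a = np.where(eye, 0.0, 1.0 / np.where(eye, 1.0, dn))
        a = a + np.where(eye, 0.0, 1.0 / np.where(sn == 0, np.inf, sn))
    return a


def repulsion_energy(vecs: np.ndarray) -> float:
    """Antipodal electrostatic energy of a set of unit vectors.

    Invariant under sign flips of any subset of the vectors.
    """
    vecs = np.atleast_2d(np.asarray(vecs, dtype=float))
    if len(vecs) < 2:
        return 0.0
    a = _pair_energy_matrix(vecs)
    iu = np.triu_indices(len(vecs), k=1)
    return float(a[iu].sum())


def _energy_gradient(vecs: np.ndarray) -> np.ndarray:
    n = len(vecs)
    diff = vecs[:, None, :] - vecs[None, :, :]
    summ = vecs[:, None, :] + vecs[None, :, :]
    dn = np.linalg.norm(diff, axis=-1)
    sn = np.linalg.norm(summ, axis=-1)
    eye = np.eye(n, dtype=bool)
    dn = np.where(eye, np.inf, dn)
    sn = np.where(sn == 0, np.inf, sn)
    grad = -(diff / dn[..., None] ** 3).sum(axis=1)
    grad += -(summ / sn[..., None] ** 3).sum(axis=1)
    return grad


def generate_directions(n: int, seed: int = 0, max_iter: int = 2000) -> np.ndarray:
    """Generate ``n`` unit vectors minimizing the antipodal repulsion energy.

    Projected gradient descent with backtracking line search from a seeded
    random start; deterministic given ``seed``.

    Returns
    -------
    (n, 3) float array of unit vectors.
    """
    if n < 1:
        raise InvalidArgumentError(f"need n >= 1 directions, got {n}")
    rng = np.random.default_rng(seed)
    vecs = rng.standard_normal((n, 3))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    if n == 1:
        return vecs
    energy = repulsion_energy(vecs)
    step = 0.1
    for _ in range(max_iter):
        grad = _energy_gradient(vecs)
        # project to the tangent space of the sphere
        grad -= (grad * vecs).sum(axis=1, keepdims=True) * vecs
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-12:
            break
        improved = False
        for _ in range(40):
            cand = vecs - step * grad
            cand /= np.linalg.norm(cand, axis=1, keepdims=True)
            cand_energy = repulsion_energy(cand)
            if cand_energy < energy:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        converged = energy - cand_energy < 1e-13 * max(1.0, abs(energy))
        vecs, energy = cand, cand_energy
        step = min(step * 1.5, 0.5)
        if converged:
            break
    return vecs


# ---------------------------------------------------------------------------
# Maximum-coverage sub-sampling
# ---------------------------------------------------------------------------

def subsample_max_coverage(
    scheme: AcquisitionScheme, k: int, max_sweeps: int = 200
) -> np.ndarray:
    """Select ``k`` diffusion-weighted measurements with maximum angular coverage.

    Greedy construction followed by best-improvement pairwise exchange of the
    antipodal repulsion energy over size-``k`` subsets.  Deterministic: ties
    are broken by the lowest original index.  Each applied exchange strictly
    decreases the energy, so coverage is monotonically non-increasing in the
    allotted ``max_sweeps``.

    Returns
    -------
    Sorted original scheme indices of the selected measurements.
    """
    dw = scheme.dw_indices
    if not 1 <= k <= len(dw):
        raise InvalidArgumentError(
            f"k must be in [1, {len(dw)}] (available directions), got {k}"
        )
    if k == len(dw):
        return dw.copy()
    vecs = scheme.bvecs[dw]
    a = _pair_energy_matrix(vecs)
    m = len(dw)

    selected = [0]  # all singletons have zero energy; lowest index wins
    in_set = np.zeros(m, dtype=bool)
    in_set[0] = True
    while len(selected) < k:
        cost = a[selected].sum(axis=0)
        cost[in_set] = np.inf
        j = int(np.argmin(cost))
        selected.append(j)
        in_set[j] = True

    sel = np.array(sorted(selected))
    for _ in range(max_sweeps):
        in_cost = a[np.ix_(sel, sel)].sum(axis=1)  # energy carried by each member
        out = np.flatnonzero(~in_set)
        # delta[i, j] = energy change when replacing sel[i] with out[j]
        col = a[np.ix_(sel, out)]
        delta = col.sum(axis=0)[None, :] - col - in_cost[:, None]
        i, j = np.unravel_index(int(np.argmin(delta)), delta.shape)
        if delta[i, j] >= -1e-12:
            break
        in_set[sel[i]] = False
        in_set[out[j]] = True
        sel = np.flatnonzero(in_set)
    return dw[np.flatnonzero(in_set)]


# ---------------------------------------------------------------------------
# Uniform rotations
# ---------------------------------------------------------------------------

def sample_rotation(seed: int) -> Rotation:
    """Draw a rotation uniformly (Haar measure) over SO(3), via a uniform
    unit quaternion."""
    rng = np.random.default_rng(seed)
    return Rotation(_quaternions_to_matrices(rng.standard_normal((1, 4)))[0])


def _quaternions_to_matrices(q: np.ndarray) -> np.ndarray:
    """Convert (B, 4) quaternions (not necessarily normalized) to (B, 3, 3)
    rotation matrices.  Normalizing iid Gaussian quaternions yields Haar-
    uniform rotations."""
    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    return np.stack(
        [
            np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x**2 + z**2), 2 * (y * z - w * x)], axis=-1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x**2 + y**2)], axis=-1),
        ],
        axis=1,
    )


def sample_rotation_batch(rng: np.random.Generator, count: int) -> np.ndarray:
    """Batch of Haar-uniform rotation matrices, shape (count, 3, 3)."""
    return _quaternions_to_matrices(rng.standard_normal((count, 4)))


# ---------------------------------------------------------------------------
# FSL-dialect gradient-table files
# ---------------------------------------------------------------------------
# bvec: 3 whitespace-separated rows of M columns; bval: 1 row of M columns.

def _parse_rows(path, expected_rows: int, label: str) -> np.ndarray:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) != expected_rows:
        raise GradientTableError(
            f"{label} file {path}: expected {expected_rows} non-empty row(s), "
            f"found {len(lines)}"
        )
    rows = []
    for r, line in enumerate(lines):
        vals = []
        for c, tok in enumerate(line.split()):
            try:
                vals.append(float(tok))
            except ValueError:
                raise GradientTableError(
                    f"{label} file {path}: non-numeric token {tok!r} at "
                    f"row {r + 1}, column {c + 1}"
                ) from None
        rows.append(vals)
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise GradientTableError(
            f"{label} file {path}: rows have inconsistent column counts {sorted(ncols)}"
        )
    return np.array(rows, dtype=float)


def read_gradient_table(bvec_path, bval_path) -> AcquisitionScheme:
    """Read an FSL-dialect bvec/bval pair.

    b-vectors with positive b-value are renormalized to unit norm; zero
    vectors paired with ``bval == 0`` are accepted as b0 entries.
    """
    bvecs = _parse_rows(bvec_path, 3, "bvec").T  # (M, 3)
    bvals = _parse_rows(bval_path, 1, "bval")[0]
    if len(bvals) != len(bvecs):
        raise GradientTableError(
            f"bval file {bval_path} has {len(bvals)} entries but bvec file "
            f"{bvec_path} has {len(bvecs)} columns"
        )
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(norms == 0):
        bad = np.flatnonzero(dw)[norms == 0]
        raise GradientTableError(
            f"bvec file {bvec_path}: zero-norm b-vector with bval > 0 at "
            f"column(s) {bad.tolist()}"
        )
    bvecs[dw] /= norms[:, None]
    return AcquisitionScheme(bvecs, bvals)


def write_gradient_table(scheme: AcquisitionScheme, bvec_path, bval_path) -> None:
    """Write a scheme in the FSL dialect; round-trips within 1e-6."""
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.10g")
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.10g")
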