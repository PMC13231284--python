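"""NIfTI-1 volume I/O with integrity checks.

Coordinate convention: 0-based voxel indices, axis order (W, H, D),
RAS-oriented grids with a diagonal affine built from the voxel spacing.
Paired volumes must share shape and affine.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .errors import AlignmentError, FormatError

__all__ = ["read_volume", "write_volume", "read_label_volume", "check_aligned"]


def write_volume(data: np.ndarray, path, spacing=1.0) -> None:
    """Write a volume with an RAS diagonal affine from ``spacing`` (mm)."""
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    affine = np.diag([*spacing, 1.0])
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.bool_):
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume(path):
    """Read a NIfTI volume.  Returns (data, spacing, affine)."""
    try:
        img = nib.load(str(path), mmap=False)  # no mmap: callers may overwrite
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, img.affine


def read_label_volume(path):
    """Read an integer label volume; non-integer values are a format error."""
    data, spacing, affine = read_volume(path)
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"label volume {path} contains non-integer values")
    return data.astype(np.int32), spacing, affine


def check_aligned(shape_a, affine_a, shape_b, affine_b, what="volumes") -> None:
    """Paired volumes must share grid shape and affine within 1e-4."""
    if tuple(shape_a[:3]) != tuple(shape_b[:3]):
        raise AlignmentError(f"{what} have different shapes: {shape_a} vs {shape_b}")
    if not np.allclose(affine_a, affine_b, atol=1e-4):
        raise AlignmentError(f"{what} have different orientations/affines")
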