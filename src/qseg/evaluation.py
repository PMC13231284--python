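"""Segmentation evaluation: label merging, DSC, HD99, grouping, and paired
one-sided signed-rank testing.

Conventions pinned here (and verified against brute-force oracles in the
test suite):

* HD99 pools the two directed boundary-distance multisets (surfaces are
  face-connectivity boundary voxel centers, distances in mm) and returns
  the 99th percentile with the linear-interpolation convention.
* Dice of two empty masks is defined as 1.0 (perfect agreement on
  absence); if exactly one side is empty, Dice is 0 and HD99 is undefined.
* The exact signed-rank null (used for n <= 25 nonzero differences) drops
  zero differences, assigns midranks to ties, and enumerates all sign
  assignments; above that, a normal approximation with continuity and tie
  correction is used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    MappingError,
    ShapeError,
    UndefinedMetricError,
    UndefinedTestError,
)

__all__ = [
    "merge_labels",
    "dice",
    "hd99",
    "group_metrics",
    "wilcoxon_one_sided",
    "significance_marker",
    "compute_metric_records",
]


def merge_labels(labels: np.ndarray, merge_map: dict) -> np.ndarray:
    """Voxel-wise relabeling; the map must cover every label present.

    Idempotent after one application provided the map's target ids map to
    themselves (checked).
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    missing = [int(v) for v in present if int(v) not in merge_map]
    if missing:
        raise MappingError(f"labels not covered by the merge map: {missing}")
    for src, dst in merge_map.items():
        if dst in merge_map and merge_map[dst] != dst:
            raise MappingError(
                f"merge map is not idempotent: {src} -> {dst} -> {merge_map[dst]}"
            )
    lut_size = int(present.max()) + 1 if present.size else 1
    lut = np.arange(lut_size)
    for src, dst in merge_map.items():
        if src < lut_size:
            lut[src] = dst
    return lut[labels]


def dice(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|); two empty masks -> 1.0."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(ref_mask, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates of face-connectivity boundary voxels (eroded complement)."""
    struct = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return np.argwhere(mask & ~interior)


def hd99(pred_mask: np.ndarray, ref_mask: np.ndarray, spacing_mm=1.0) -> float:
    """99th percentile of the pooled symmetric boundary-distance multiset (mm).

    Raises :class:`UndefinedMetricError` if either mask is empty.
    """
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(ref_mask, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise UndefinedMetricError("HD99 is undefined for an empty mask")
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (a.ndim,))
    pa = _boundary_points(a) * spacing
    pb = _boundary_points(b) * spacing
    d_ab = cKDTree(pb).query(pa, workers=1)[0]
    d_ba = cKDTree(pa).query(pb, workers=1)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 99))


def compute_metric_records(
    pred_labels: np.ndarray,
    ref_labels: np.ndarray,
    region_ids,
    participant,
    spacing_mm=1.0,
) -> pd.DataFrame:
    """Tidy (participant, region, metric, value, undefined) rows.

    Dice of a region empty on exactly one side is 0; HD99 of a region empty
    on either side is recorded as NaN with ``undefined=True`` so that group
    averaging can exclude it (with an exclusion count).
    """
    rows = []
    for region in region_ids:
        p = pred_labels == region
        r = ref_labels == region
        both_empty = not p.any() and not r.any()
        rows.append({
            "participant": participant, "region": int(region), "metric": "DSC",
            "value": dice(p, r), "undefined": bool(both_empty),
        })
        try:
            value, undef = hd99(p, r, spacing_mm), False
        except UndefinedMetricError:
            value, undef = np.nan, True
        rows.append({
            "participant": participant, "region": int(region), "metric": "HD99",
            "value": value, "undefined": undef,
        })
    return pd.DataFrame(rows)


def group_metrics(records: pd.DataFrame, group_map: dict) -> pd.DataFrame:
    """Average metrics over each group's regions, per participant.

    Undefined entries (NaN values) are excluded from their group mean and
    counted in ``n_excluded``.  Every region must belong to exactly one
    group; a group without any records raises.
    """
    df = records.copy()
    missing = sorted(set(df["region"]) - set(group_map))
    if missing:
        raise MappingError(f"regions not covered by the group map: {missing}")
    df["group"] = df["region"].map(group_map)
    empty = sorted(set(group_map.values()) - set(df["group"]))
    if empty:
        raise ConfigurationError(f"group(s) with no evaluated regions: {empty}")
    out = (
        df.groupby(["participant", "group", "metric"], sort=True)
        .agg(value=("value", "mean"), n_regions=("value", "size"),
             n_excluded=("value", lambda v: int(v.isna().sum())))
        .reset_index()
    )
    return out


def wilcoxon_one_sided(paired_diffs, alternative: str = "greater") -> float:
    """One-sided Wilcoxon signed-rank p-value for paired differences.

    ``alternative='greater'`` tests whether the differences are positive
    (method A exceeds B, the DSC convention); ``'less'`` the opposite (the
    HD99 convention).  Zero differences are dropped; ties get midranks.
    Exact enumeration of the null for n <= 25 nonzero differences, normal
    approximation with continuity and tie correction above.
    """
    if alternative not in ("greater", "less"):
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    d = np.asarray(paired_diffs, dtype=float).reshape(-1)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # exact null: convolution over doubled (integer) midranks
        r2 = np.round(2 * ranks).astype(int)
        counts = np.zeros(r2.sum() + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            nxt = counts.copy()
            nxt[r:] += counts[:len(counts) - r]
            counts = nxt
        total = 2.0**n
        w2 = int(round(2 * w_plus))
        if alternative == "greater":
            return float(counts[w2:].sum() / total)
        return float(counts[:w2 + 1].sum() / total)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    sd = np.sqrt(var)
    if alternative == "greater":
        return float(stats.norm.sf((w_plus - mean - 0.5) / sd))
    return float(stats.norm.cdf((w_plus - mean + 0.5) / sd))


def significance_marker(p: float) -> str:
    """Render a p-value: *** p<0.001, ** p<0.01, * p<0.05, else 'n.s.'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."
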