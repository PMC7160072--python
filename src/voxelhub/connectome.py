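"""Per-subject functional-connectome statistics.

Two voxel-wise measures are computed inside a gray-matter mask:

* **Weighted degree centrality.**  For voxel i with Pearson correlations
  r_ij to every other in-mask voxel j,

      DC(i) = sum_j r_ij * [r_ij > r0]          (weighted)
      DC(i) = sum_j       [r_ij > r0]           (binarized)

  with a strict inequality, self-correlation excluded, and only positive
  correlations eligible (r0 >= 0).  The DC map is z-scored within the
  mask before group statistics.  The correlation matrix is never
  materialized: rows are processed in blocks of standardized series, so
  memory stays O(block x N) while remaining numerically equivalent to the
  full N x N matrix.

* **Seed-based functional connectivity.**  The Pearson correlation map
  between a seed ROI's mean time series and every in-mask voxel, Fisher
  z-transformed (atanh) for group-level testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import BoldImage, MaskImage, world_to_voxel

__all__ = [
    "DcMap",
    "FcMap",
    "RoiSpec",
    "compute_dc",
    "dc_multi_threshold",
    "zscore_map",
    "extract_roi_timeseries",
    "compute_fc",
    "fisher_z",
    "DEFAULT_THRESHOLDS",
    "PRIMARY_THRESHOLD",
]

log = logging.getLogger(__name__)

#: the five correlation thresholds analysed for stability
DEFAULT_THRESHOLDS = (0.15, 0.20, 0.25, 0.30, 0.35)
#: primary reporting threshold (weighted graph of positive correlations)
PRIMARY_THRESHOLD = 0.25

_FISHER_CLIP = 1.0 - 1e-7


@dataclass
class DcMap:
    """Per-subject degree-centrality result at one threshold."""

    dc: np.ndarray            # raw DC, 0 outside mask
    z: np.ndarray             # z-scored within mask
    r0: float
    weighted: bool
    mask: MaskImage           # analysis mask actually used (zero-variance voxels dropped)


@dataclass
class FcMap:
    """Per-subject seed-FC result: Pearson r and Fisher z maps."""

    r: np.ndarray
    z: np.ndarray
    seed_label: str


@dataclass
class RoiSpec:
    """A seed region: an explicit cluster mask or a sphere in world mm."""

    kind: str                               # "cluster_mask" | "sphere"
    label: str = "roi"
    mask: MaskImage | None = None
    center_mm: tuple[float, float, float] | None = None
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.kind not in ("cluster_mask", "sphere"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "cluster_mask" and self.mask is None:
            raise ValueError("cluster_mask ROI needs a mask")
        if self.kind == "sphere" and self.center_mm is None:
            raise ValueError("sphere ROI needs a center")

    def to_mask(self, like: MaskImage) -> np.ndarray:
        """Boolean voxel selection on the grid of ``like``."""
        if self.kind == "cluster_mask":
            self.mask.assert_same_grid(like)
            return self.mask.data.copy()
        shape = like.data.shape
        affine = like.affine
        # world coordinates of all voxels; keep those within radius of center
        idx = np.indices(shape).reshape(3, -1)
        world = affine[:3, :3] @ idx + affine[:3, 3:4]
        d2 = ((world - np.asarray(self.center_mm).reshape(3, 1)) ** 2).sum(axis=0)
        return (d2 <= self.radius_mm**2).reshape(shape)


def _standardize(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows -> zero mean, unit L2 norm; returns (standardized, sd)."""
    ts = ts - ts.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(ts, axis=1)
    good = norm > 0
    out = np.zeros_like(ts)
    out[good] = ts[good] / norm[good, None]
    return out, norm


def _drop_zero_variance(b: BoldImage, mask: MaskImage) -> tuple[np.ndarray, MaskImage]:
    """In-mask series with zero-variance voxels removed (logged)."""
    mask.assert_same_grid(b)
    ts = b.data[mask.data]
    sd = ts.std(axis=1)
    if (sd == 0).any():
        n_bad = int((sd == 0).sum())
        log.warning("dropping %d zero-variance voxels from the mask", n_bad)
        new = np.zeros_like(mask.data)
        new[mask.data] = sd > 0
        mask = MaskImage(new, mask.affine)
        ts = ts[sd > 0]
    return ts, mask


def compute_dc(
    b: BoldImage,
    mask: MaskImage,
    r0: float,
    weighted: bool = True,
    block_size: int = 1024,
) -> DcMap:
    """Voxel-wise degree centrality at a single correlation threshold.

    Parameters
    ----------
    b : BoldImage
        Preprocessed BOLD series (>= 3 frames).
    mask : MaskImage
        Analysis (gray-matter) mask; zero-variance voxels are dropped
        with a warning.
    r0 : float
        Correlation threshold in [0, 1); only r_ij strictly above r0
        contribute (weak and negative correlations are eliminated).
    weighted : bool
        Sum surviving correlations (True) or count them (False).
    block_size : int
        Number of voxel rows correlated against all others per block.
    """
    return dc_multi_threshold(b, mask, [r0], weighted, block_size)[0]


def dc_multi_threshold(
    b: BoldImage,
    mask: MaskImage,
    thresholds=DEFAULT_THRESHOLDS,
    weighted: bool = True,
    block_size: int = 1024,
) -> list[DcMap]:
    """Degree centrality at several thresholds from one correlation pass.

    Thresholds must be strictly increasing, each in [0, 1).  All maps are
    accumulated while each correlation block is in memory, so the cost of
    five thresholds is one threshold plus five cheap reductions.
    """
    thresholds = [float(r) for r in thresholds]
    if not thresholds:
        raise ValueError("empty threshold list")
    if any(t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if any(not (0.0 <= r < 1.0) for r in thresholds):
        raise ValueError("each threshold must lie in [0, 1)")
    if b.n_frames < 3:
        raise ValueError("need at least 3 frames for voxel-wise correlation")

    ts, mask = _drop_zero_variance(b, mask)
    X, _ = _standardize(ts)          # N x t, rows unit norm -> R = X X^T
    n = X.shape[0]
    acc = np.zeros((len(thresholds), n))
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        R = X[start:stop] @ X.T                      # block x N of Pearson r
        rows = np.arange(start, stop)
        R[rows - start, rows] = -np.inf              # exclude self-correlation
        for k, r0 in enumerate(thresholds):
            above = R > r0
            if weighted:
                acc[k, start:stop] = np.where(above, R, 0.0).sum(axis=1)
            else:
                acc[k, start:stop] = above.sum(axis=1)

    out = []
    for k, r0 in enumerate(thresholds):
        dc = np.zeros(mask.data.shape)
        dc[mask.data] = acc[k]
        if np.ptp(acc[k]) == 0:
            # constant DC (e.g. identical series everywhere): z undefined
            log.warning("DC map constant at r0=%.2f; z set to 0", r0)
            z = np.zeros_like(dc)
        else:
            z = zscore_map(dc, mask)
        out.append(DcMap(dc=dc, z=z, r0=r0, weighted=weighted, mask=mask))
    return out


def zscore_map(m: np.ndarray, mask: MaskImage) -> np.ndarray:
    """Z-score a 3-D map within the mask (sample SD, ddof=1); 0 outside."""
    m = np.asarray(m, dtype=np.float64)
    vals = m[mask.data]
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    if sd == 0:
        raise ValueError("zero in-mask standard deviation; cannot z-score")
    out = np.zeros_like(m)
    out[mask.data] = (vals - vals.mean()) / sd
    return out


def extract_roi_timeseries(b: BoldImage, roi: RoiSpec, mask: MaskImage) -> np.ndarray:
    """Mean time series over ROI ∩ analysis mask."""
    mask.assert_same_grid(b)
    sel = roi.to_mask(mask) & mask.data
    if not sel.any():
        raise ValueError(f"ROI {roi.label!r} does not intersect the analysis mask")
    return b.data[sel].mean(axis=0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing Fisher transform atanh(r), clipped to stay finite."""
    return np.arctanh(np.clip(r, -_FISHER_CLIP, _FISHER_CLIP))


def compute_fc(
    b: BoldImage,
    seed_ts: np.ndarray,
    mask: MaskImage,
    seed_label: str = "seed",
) -> FcMap:
    """Seed-to-voxel Pearson correlation map with Fisher z transform.

    Zero-variance voxels get r = 0 (logged); |r| is clipped just inside
    1 before atanh so z stays finite for voxels identical to the seed.
    """
    mask.assert_same_grid(b)
    seed_ts = np.asarray(seed_ts, dtype=np.float64)
    if seed_ts.shape != (b.n_frames,):
        raise ValueError("seed series length must equal the number of frames")
    s = seed_ts - seed_ts.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ValueError("constant seed series")
    ts = b.data[mask.data]
    X, norms = _standardize(ts)
    if (norms == 0).any():
        log.warning("%d zero-variance voxels set to r=0", int((norms == 0).sum()))
    r_vals = X @ (s / s_norm)
    r = np.zeros(mask.data.shape)
    r[mask.data] = r_vals
    z = np.zeros_like(r)
    z[mask.data] = fisher_z(r_vals)
    return FcMap(r=r, z=z, seed_label=seed_label)
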