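"""Shuffle-calibrated clustering of dendritic ROIs into dendrite units.

Segmented dendritic ROIs frequently sample the same dendrite, so their
calcium traces are near-duplicates.  The pipeline groups them: traces
are sparsified (frames below mean + 3 SD zeroed), pairwise Pearson
correlations computed and double-thresholded (> 0.7 absolute, or > 2.5
SD above either ROI's mean coefficient), cosine similarity taken
between rows of the thresholded matrix, and the ROIs agglomerated by
WPGMA on 1 - cosine similarity.  The distance cutoff is calibrated per
dataset: each ROI trace is circularly rotated by an independent random
offset (destroying all true coupling), the pipeline re-run, and the
largest cutoff accepted for which fewer than 5% of shuffles produce any
multi-ROI cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ROITraces",
    "ClusterAssignment",
    "sparsify_activity",
    "thresholded_similarity",
    "cluster_rois",
    "select_cutoff",
    "cluster_pipeline",
]

DEFAULT_GRID = np.round(np.arange(0.01, 0.51, 0.01), 2)


@dataclass
class ROITraces:
    traces: np.ndarray          # (frames, rois), raw fluorescence
    frame_rate: float = 15.5
    roi_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be frames x ROIs")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")
        if self.roi_ids is None:
            self.roi_ids = np.arange(self.traces.shape[1])

    @property
    def n_rois(self) -> int:
        return self.traces.shape[1]


@dataclass
class ClusterAssignment:
    labels: np.ndarray          # roi -> cluster id (1-based, contiguous)
    cutoff_used: float
    n_shuffles: int = 0

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    @property
    def mean_cluster_size(self) -> float:
        return self.labels.size / self.n_clusters


def sparsify_activity(t: ROITraces, k: float = 3.0) -> np.ndarray:
    """Zero every frame below mean + k*SD of its ROI's trace."""
    x = t.traces
    mu, sd = x.mean(axis=0), x.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("constant trace(s): sparsified to all-zero")
    out = np.where(x > mu + k * sd, x, 0.0)
    return out


def thresholded_similarity(sparse: np.ndarray) -> np.ndarray:
    """Cosine similarity between rows of the double-thresholded
    correlation matrix.

    A correlation entry survives if it exceeds 0.7, or 2.5 SD above the
    mean of *either* ROI's off-diagonal coefficients (the per-ROI
    criterion is symmetrized by OR); all other entries are zeroed.
    All-zero ROIs have similarity 0 to everything.
    """
    sparse = np.asarray(sparse, float)
    n = sparse.shape[1]
    if n < 2:
        raise ValueError("need at least 2 ROIs")
    sd = sparse.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sparse.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    off = corr.copy()
    np.fill_diagonal(off, np.nan)
    row_mu = np.nanmean(off, axis=1)
    row_sd = np.nanstd(off, axis=1)
    crit = row_mu + 2.5 * row_sd
    keep = (corr > 0.7) | (corr > crit[:, None]) | (corr > crit[None, :])
    np.fill_diagonal(keep, True)
    thr = np.where(keep, corr, 0.0)
    thr[sd == 0, :] = 0.0
    thr[:, sd == 0] = 0.0
    norms = np.linalg.norm(thr, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (thr @ thr.T) / np.outer(norms, norms)
    cos = np.nan_to_num(cos, nan=0.0)
    cos = np.clip((cos + cos.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cos, 1.0)
    return cos


def _wpgma_linkage(similarity: np.ndarray) -> np.ndarray:
    dist = 1.0 - np.asarray(similarity, float)
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return linkage(squareform(dist, checks=False), method="weighted")


def cluster_rois(similarity: np.ndarray, cutoff: float) -> ClusterAssignment:
    """Cut the WPGMA dendrogram of 1 - similarity at ``cutoff``."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must be in [0, 1]")
    Z = _wpgma_linkage(similarity)
    labels = fcluster(Z, t=cutoff, criterion="distance")
    return ClusterAssignment(labels=labels, cutoff_used=float(cutoff))


def _min_merge_distance(t_sparse: np.ndarray) -> float:
    """Smallest dendrogram merge height for one (shuffled) dataset; any
    cutoff at or above it yields at least one multi-ROI cluster."""
    sim = thresholded_similarity(t_sparse)
    Z = _wpgma_linkage(sim)
    return float(Z[0, 2])


def select_cutoff(
    t: ROITraces,
    n_shuffles: int = 500,
    alpha: float = 0.05,
    grid: np.ndarray = DEFAULT_GRID,
    rng: np.random.Generator | None = None,
) -> float:
    """Circular-shuffle calibration of the clustering cutoff.

    For each shuffle every ROI trace is rotated by an independent random
    offset and the full pipeline re-run; the largest grid cutoff at
    which fewer than ``alpha`` of shuffles produce any multi-ROI
    ("inaccurate") cluster is returned.  Falls back to the grid minimum
    with a warning if no cutoff qualifies.
    """
    rng = rng or np.random.default_rng()
    x = t.traces
    n_frames, n_rois = x.shape
    if n_rois < 2 or n_frames < 10:
        raise ValueError("need >= 2 ROIs and a non-trivial trace length")
    d_min = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shifts = rng.integers(0, n_frames, n_rois)
        rolled = np.empty_like(x)
        for j in range(n_rois):
            rolled[:, j] = np.roll(x[:, j], int(shifts[j]))
        sp = sparsify_activity(ROITraces(rolled, t.frame_rate))
        d_min[s] = _min_merge_distance(sp)
    grid = np.asarray(grid, float)
    frac_bad = np.array([(d_min <= c).mean() for c in grid])
    ok = grid[frac_bad < alpha]
    if ok.size == 0:
        warnings.warn("no cutoff qualified; returning grid minimum")
        return float(grid.min())
    return float(ok.max())


def cluster_pipeline(
    t: ROITraces,
    cutoff: float | str = "auto",
    n_shuffles: int = 500,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterAssignment:
    """Sparsify, threshold, and cluster; ``cutoff='auto'`` calibrates it
    by circular shuffling."""
    used_shuffles = 0
    if cutoff == "auto":
        cutoff = select_cutoff(t, n_shuffles=n_shuffles, alpha=alpha, rng=rng)
        used_shuffles = n_shuffles
    sim = thresholded_similarity(sparsify_activity(t))
    out = cluster_rois(sim, float(cutoff))
    out.n_shuffles = used_shuffles
    return out
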