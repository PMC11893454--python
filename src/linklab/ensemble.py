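"""Cross-session statistics for binarized calcium-imaging ensembles.

A session is a frames x cells binary event matrix with its frame rate,
cell centroids and a footprint-overlap adjacency.  The statistics here
quantify how a population representation carries over between two
context exposures: the fraction of ROIs active in both sessions,
correlation of per-cell firing-rate vectors, a naive-Bayes context
decoder scored by the rank-statistic AUC, the stability of pairwise
coactivity (PWC) maps with nearby-pair exclusion and cell subsampling,
the Euclidean distance between coactivity maps with optional exclusion
of the most active cells, and the reactivation probability of the most
active decile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB

__all__ = [
    "SessionEvents",
    "MatchedSessions",
    "session_overlap",
    "firing_rates",
    "population_vector_correlation",
    "nb_classifier_auc",
    "pwc_map",
    "pwc_stability",
    "connectivity_distance",
    "top_decile_reactivation",
    "reactivated_rate_correlation",
]


@dataclass
class SessionEvents:
    """Binarized per-frame activity for one imaging session."""

    events: np.ndarray                 # (frames, cells) uint8/bool in {0,1}
    frame_rate: float                  # Hz
    cell_ids: np.ndarray | None = None
    centroids: np.ndarray | None = None          # (cells, 2) pixels
    footprint_overlap: np.ndarray | None = None  # (cells, cells) bool
    context_label: str = ""
    session_time: float = 0.0

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events)
        if self.events.ndim != 2:
            raise ValueError("events must be a frames x cells matrix")
        vals = np.unique(self.events)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("events must be binarized to {0, 1}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.events.shape[1])
        if self.footprint_overlap is not None:
            fo = np.asarray(self.footprint_overlap, bool)
            if not np.array_equal(fo, fo.T) or fo.diagonal().any():
                raise ValueError("footprint adjacency must be symmetric, irreflexive")
            self.footprint_overlap = fo

    @property
    def n_cells(self) -> int:
        return self.events.shape[1]

    @property
    def n_frames(self) -> int:
        return self.events.shape[0]

    def active_cells(self) -> np.ndarray:
        return np.flatnonzero(self.events.any(axis=0))


@dataclass
class MatchedSessions:
    """Two sessions plus a partial injection between their cell indices.

    ``id_map`` is an (n, 2) integer array of (index in s1, index in s2)
    pairs; both columns must be duplicate-free.
    """

    s1: SessionEvents
    s2: SessionEvents
    id_map: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.id_map)
        if m.size == 0:
            m = m.reshape(0, 2)
        if m.ndim != 2 or m.shape[1] != 2:
            raise ValueError("id_map must be (n, 2)")
        for col in (0, 1):
            if len(np.unique(m[:, col])) != len(m):
                raise ValueError("id_map must be injective in both directions")
        self.id_map = m.astype(int)


def session_overlap(m: MatchedSessions) -> float:
    """Percentage of ROIs active in both sessions, normalized by the
    average number of active ROIs per session."""
    a1, a2 = m.s1.active_cells(), m.s2.active_cells()
    if a1.size == 0 or a2.size == 0:
        raise ValueError("cannot compute overlap with an empty session")
    in1 = np.isin(m.id_map[:, 0], a1)
    in2 = np.isin(m.id_map[:, 1], a2)
    both = int(np.sum(in1 & in2))
    return 100.0 * both / ((a1.size + a2.size) / 2.0)


def firing_rates(s: SessionEvents) -> np.ndarray:
    """Per-cell event rate in Hz (active frames per second)."""
    return s.events.sum(axis=0) * s.frame_rate / s.n_frames


def population_vector_correlation(
    rates_1: np.ndarray,
    rates_2: np.ndarray,
    id_map: np.ndarray | None = None,
    normalize_to: np.ndarray | None = None,
) -> float:
    """Pearson correlation between matched per-cell rate vectors.

    ``normalize_to`` optionally divides both vectors cell-wise by a
    reference session's rates (cells with zero reference rate are
    dropped).  Returns nan if either vector has zero variance.
    """
    r1 = np.asarray(rates_1, float)
    r2 = np.asarray(rates_2, float)
    if id_map is not None:
        m = np.asarray(id_map, int)
        r1, r2 = r1[m[:, 0]], r2[m[:, 1]]
        if normalize_to is not None:
            normalize_to = np.asarray(normalize_to, float)[m[:, 0]]
    if normalize_to is not None:
        keep = normalize_to > 0
        r1, r2 = r1[keep] / normalize_to[keep], r2[keep] / normalize_to[keep]
    if r1.size < 3:
        raise ValueError("need at least 3 matched cells")
    if np.std(r1) == 0 or np.std(r2) == 0:
        warnings.warn("zero-variance rate vector; correlation undefined")
        return float("nan")
    return float(np.corrcoef(r1, r2)[0, 1])


def _bin_events(events: np.ndarray, frames_per_bin: int, binarize: bool) -> np.ndarray:
    n = (events.shape[0] // frames_per_bin) * frames_per_bin
    if n == 0:
        raise ValueError("session shorter than one bin")
    binned = events[:n].reshape(-1, frames_per_bin, events.shape[1]).sum(axis=1)
    return (binned > 0).astype(float) if binarize else binned.astype(float)


def rank_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUC from the Wilcoxon-Mann-Whitney rank statistic: U / (n1 * n2)."""
    u = stats.mannwhitneyu(scores_pos, scores_neg, alternative="two-sided").statistic
    return float(u / (len(scores_pos) * len(scores_neg)))


def nb_classifier_auc(
    s1: SessionEvents,
    s2: SessionEvents,
    bin_sizes_s: np.ndarray | None = None,
    folds: int = 10,
    rng: np.random.Generator | None = None,
) -> dict:
    """Context decoding with a Bernoulli naive-Bayes classifier.

    Each session is resampled into time bins (the labeled "trials");
    per trial the feature vector is each cell's binary activity in the
    bin.  A Bernoulli naive Bayes (Laplace alpha = 1) is cross-validated
    with stratified ``folds``; held-out log-posterior scores for the
    *first* session's class are pooled and the AUC computed from the
    rank statistic.  Orientation is kept raw (no max(AUC, 1-AUC)).

    Returns ``{"bin_sizes": array, "auc": array, "mean_auc": float}``.
    """
    rng = rng or np.random.default_rng()
    if bin_sizes_s is None:
        bin_sizes_s = np.arange(0.5, 60.5, 0.5)
    if s1.n_cells != s2.n_cells:
        raise ValueError("sessions must share a matched cell set")
    aucs = []
    for b in np.atleast_1d(bin_sizes_s):
        f1 = max(1, int(round(b * s1.frame_rate)))
        f2 = max(1, int(round(b * s2.frame_rate)))
        X1 = _bin_events(s1.events, f1, binarize=True)
        X2 = _bin_events(s2.events, f2, binarize=True)
        if len(X1) < 2 or len(X2) < 2:
            aucs.append(np.nan)
            continue
        X = np.vstack([X1, X2])
        y = np.r_[np.ones(len(X1), int), np.zeros(len(X2), int)]
        n_min = min(len(X1), len(X2))
        k = min(folds, n_min)
        if k < folds:
            warnings.warn(f"bin {b}s: only {n_min} trials per class; folds={k}")
        if k < 2:
            aucs.append(np.nan)
            continue
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(rng.integers(2**31))
        )
        scores = np.empty(len(y))
        for train, test in skf.split(X, y):
            clf = BernoulliNB(alpha=1.0)
            clf.fit(X[train], y[train])
            pos = list(clf.classes_).index(1)
            scores[test] = clf.predict_log_proba(X[test])[:, pos]
        aucs.append(rank_auc(scores[y == 1], scores[y == 0]))
    aucs = np.asarray(aucs, float)
    return {
        "bin_sizes": np.atleast_1d(bin_sizes_s),
        "auc": aucs,
        "mean_auc": float(np.nanmean(aucs)),
    }


def pwc_map(s: SessionEvents, bin_ms: float = 100.0, binarize: bool = False) -> np.ndarray:
    """Pairwise-coactivity map: Pearson correlation of binned counts.

    Cells with zero variance get nan rows/columns (excluded downstream).
    """
    frames_per_bin = max(1, int(round(bin_ms / 1000.0 * s.frame_rate)))
    binned = _bin_events(s.events, frames_per_bin, binarize=binarize)
    if binned.shape[0] < 2:
        raise ValueError("too few bins for a coactivity map")
    with np.errstate(invalid="ignore", divide="ignore"):
        cmat = np.corrcoef(binned.T)
    sd = binned.std(axis=0)
    cmat[sd == 0, :] = np.nan
    cmat[:, sd == 0] = np.nan
    return cmat


def _nearby_pair_mask(
    n: int,
    centroids: np.ndarray | None,
    footprint_overlap: np.ndarray | None,
    max_dist_px: float,
) -> np.ndarray:
    """Boolean (n, n) matrix of pairs to exclude as spatially confounded."""
    mask = np.zeros((n, n), bool)
    if footprint_overlap is not None:
        mask |= np.asarray(footprint_overlap, bool)
    if centroids is not None:
        c = np.asarray(centroids, float)
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        near = d <= max_dist_px
        np.fill_diagonal(near, False)
        mask |= near
    return mask


def _upper(mat: np.ndarray, keep: np.ndarray | None = None) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    vals = mat[iu]
    if keep is not None:
        vals = vals[keep[iu]]
    return vals


def pwc_stability(
    map_1: np.ndarray,
    map_2: np.ndarray,
    centroids: np.ndarray | None = None,
    footprint_overlap: np.ndarray | None = None,
    max_dist_px: float = 20.0,
    subsample_n: int = 10,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean correlation of subsampled coactivity maps across sessions.

    Nearby cell pairs (any footprint overlap, or centroid distance
    <= ``max_dist_px``) are excluded; per repetition ``subsample_n``
    cells are drawn, both maps restricted, and the upper-triangle
    vectors correlated; the average over ``reps`` repetitions is
    returned.
    """
    rng = rng or np.random.default_rng()
    m1, m2 = np.asarray(map_1, float), np.asarray(map_2, float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise ValueError("maps must be square and matched")
    n = m1.shape[0]
    excl = _nearby_pair_mask(n, centroids, footprint_overlap, max_dist_px)
    usable = np.flatnonzero(
        ~np.all(np.isnan(m1) | np.eye(n, dtype=bool), axis=0)
    )
    if usable.size < subsample_n:
        raise ValueError(
            f"only {usable.size} usable cells for subsample of {subsample_n}"
        )
    out = np.empty(reps)
    for r in range(reps):
        sel = rng.choice(usable, size=subsample_n, replace=False)
        sub1, sub2 = m1[np.ix_(sel, sel)], m2[np.ix_(sel, sel)]
        keep = ~excl[np.ix_(sel, sel)]
        v1, v2 = _upper(sub1, keep), _upper(sub2, keep)
        good = np.isfinite(v1) & np.isfinite(v2)
        v1, v2 = v1[good], v2[good]
        if v1.size < 2 or np.std(v1) == 0 or np.std(v2) == 0:
            out[r] = np.nan
            continue
        out[r] = np.corrcoef(v1, v2)[0, 1]
    return float(np.nanmean(out))


def connectivity_distance(
    map_1: np.ndarray,
    map_2: np.ndarray,
    rates: np.ndarray | None = None,
    exclude_top_frac: float = 0.10,
) -> float:
    """Euclidean distance between upper-triangle coactivity vectors,
    optionally after dropping the most active fraction of cells."""
    if not (0.0 <= exclude_top_frac < 1.0):
        raise ValueError("exclude_top_frac must be in [0, 1)")
    m1, m2 = np.asarray(map_1, float), np.asarray(map_2, float)
    if m1.shape != m2.shape:
        raise ValueError("maps must be matched")
    keep_idx = np.arange(m1.shape[0])
    if exclude_top_frac > 0:
        if rates is None:
            raise ValueError("rates required to exclude most active cells")
        n_drop = int(np.floor(exclude_top_frac * len(keep_idx)))
        if n_drop > 0:
            drop = np.argsort(np.asarray(rates))[::-1][:n_drop]
            keep_idx = np.setdiff1d(keep_idx, drop)
    m1, m2 = m1[np.ix_(keep_idx, keep_idx)], m2[np.ix_(keep_idx, keep_idx)]
    v1, v2 = _upper(m1), _upper(m2)
    good = np.isfinite(v1) & np.isfinite(v2)
    return float(np.linalg.norm(v1[good] - v2[good]))


def top_decile_reactivation(m: MatchedSessions, decile: float = 0.10) -> float:
    """Fraction of session-1 top-decile (by rate) cells that are matched
    and active in session 2."""
    if m.s1.n_cells < 10:
        raise ValueError("need at least 10 cells")
    rates = firing_rates(m.s1)
    n_top = max(1, int(round(decile * m.s1.n_cells)))
    top = np.argsort(rates)[::-1][:n_top]
    lut = dict(zip(m.id_map[:, 0].tolist(), m.id_map[:, 1].tolist()))
    active2 = set(m.s2.active_cells().tolist())
    hits = sum(1 for c in top if lut.get(int(c)) in active2)
    return hits / n_top


def reactivated_rate_correlation(
    rates_pairs: np.ndarray,
    subsample: int = 30,
    reps: int = 500,
    rng: np.random.Generator | None = None,
) -> dict:
    """Distribution of rate correlations over subsampled reactivated pairs.

    ``rates_pairs`` is (n, 2): reference and comparison session rates of
    matched reactivated ROIs.  Per repetition ``subsample`` pairs are
    drawn and their Pearson correlation computed; also returns the
    least-squares slope/intercept on the full set.
    """
    rng = rng or np.random.default_rng()
    pairs = np.asarray(rates_pairs, float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("rates_pairs must be (n, 2)")
    n = len(pairs)
    k = subsample
    if n < subsample:
        warnings.warn(f"only {n} pairs; subsampling disabled")
        k = n
    rs = np.empty(reps)
    for r in range(reps):
        sel = rng.choice(n, size=k, replace=False)
        x, y = pairs[sel, 0], pairs[sel, 1]
        if np.std(x) == 0 or np.std(y) == 0:
            rs[r] = np.nan
        else:
            rs[r] = np.corrcoef(x, y)[0, 1]
    slope, intercept = np.polyfit(pairs[:, 0], pairs[:, 1], 1)
    return {
        "correlations": rs,
        "slope": float(slope),
        "intercept": float(intercept),
    }
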