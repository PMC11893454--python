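"""Longitudinal dendritic-spine statistics with permutation nulls.

A :class:`SpineMap` records dendritic segments (length in µm, optional
animal id) and spines (arc-length position, per-session presence).  The
statistics quantify clustered spine addition (a new spine within 5 µm
of another new spine on the same segment), its chance level under
random placement, cross-session dependence of per-segment addition
counts (Spearman rank correlation and mutual information with
permutation nulls), co-allocation of clustered additions to the same
segments across context exposures, nearest-neighbor co-clustering of
new spines, dendrite-subsampled comparisons between conditions, and the
volume-overlap enrichment arithmetic used for transcript colocalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SpineMap",
    "NewSpineSet",
    "extract_dynamics",
    "clustered_flags",
    "clustering_ratio",
    "chance_clustering_resample",
    "addition_spearman",
    "addition_mutual_information",
    "fisher_compare",
    "cross_session_coallocation",
    "nn_coclustering",
    "subsample_statistic",
    "colocalization_enrichment",
]

CLUSTER_UM = 5.0


@dataclass
class SpineMap:
    """Dendritic segments and their spines across imaging sessions."""

    lengths: np.ndarray                # (n_dendrites,) µm
    spine_dendrite: np.ndarray         # (n_spines,) dendrite index
    positions: np.ndarray              # (n_spines,) µm along the dendrite
    presence: np.ndarray               # (n_spines, n_sessions) bool
    sessions: list[str]
    animals: np.ndarray | None = None  # (n_dendrites,) animal index

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, float)
        self.spine_dendrite = np.asarray(self.spine_dendrite, int)
        self.positions = np.asarray(self.positions, float)
        self.presence = np.asarray(self.presence, bool)
        if self.animals is None:
            self.animals = np.zeros(len(self.lengths), int)
        self.animals = np.asarray(self.animals, int)
        if self.presence.shape != (len(self.positions), len(self.sessions)):
            raise ValueError("presence must be (n_spines, n_sessions)")
        if np.any(self.positions < 0) or np.any(
            self.positions > self.lengths[self.spine_dendrite]
        ):
            raise ValueError("spine positions must lie within dendrite length")
        if self.presence.size and not self.presence.any(axis=1).all():
            raise ValueError("every spine must be present in >= 1 session")

    @property
    def n_dendrites(self) -> int:
        return len(self.lengths)

    def session_index(self, s: str) -> int:
        try:
            return self.sessions.index(s)
        except ValueError:
            raise KeyError(f"unknown session {s!r}") from None


@dataclass
class NewSpineSet:
    """Spines newly present in one session transition, grouped by dendrite."""

    dendrite: np.ndarray       # (n_new,) dendrite index
    positions: np.ndarray      # (n_new,) µm
    spine_index: np.ndarray    # (n_new,) row into the parent SpineMap
    n_dendrites: int
    clustered: np.ndarray = field(default=None)  # filled in __post_init__

    def __post_init__(self) -> None:
        if self.clustered is None:
            self.clustered = clustered_flags(
                self.dendrite, self.positions, CLUSTER_UM
            )

    def counts(self) -> np.ndarray:
        return np.bincount(self.dendrite, minlength=self.n_dendrites)

    def clustered_counts(self) -> np.ndarray:
        return np.bincount(
            self.dendrite[self.clustered], minlength=self.n_dendrites
        )


def clustered_flags(
    dendrite: np.ndarray, positions: np.ndarray, threshold: float = CLUSTER_UM
) -> np.ndarray:
    """A spine is clustered iff another spine of the same set lies
    strictly within ``threshold`` µm on the same dendrite."""
    dendrite = np.asarray(dendrite, int)
    positions = np.asarray(positions, float)
    out = np.zeros(len(positions), bool)
    for d in np.unique(dendrite):
        idx = np.flatnonzero(dendrite == d)
        if idx.size < 2:
            continue
        pos = positions[idx]
        dist = np.abs(pos[:, None] - pos[None, :])
        np.fill_diagonal(dist, np.inf)
        out[idx] = (dist < threshold).any(axis=1)
    return out


def extract_dynamics(m: SpineMap, s_prev: str, s_next: str) -> dict:
    """Spine gains/losses/turnover between two sessions.

    Returns a dict with the :class:`NewSpineSet` of gained spines plus
    per-dendrite gained / lost / total counts and the turnover ratio
    (gained + lost) / total-in-prev.
    """
    i, j = m.session_index(s_prev), m.session_index(s_next)
    gained_rows = np.flatnonzero(~m.presence[:, i] & m.presence[:, j])
    lost_rows = np.flatnonzero(m.presence[:, i] & ~m.presence[:, j])
    new = NewSpineSet(
        dendrite=m.spine_dendrite[gained_rows],
        positions=m.positions[gained_rows],
        spine_index=gained_rows,
        n_dendrites=m.n_dendrites,
    )
    gained = new.counts()
    lost = np.bincount(m.spine_dendrite[lost_rows], minlength=m.n_dendrites)
    total_prev = np.bincount(
        m.spine_dendrite[m.presence[:, i]], minlength=m.n_dendrites
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        turnover = np.where(total_prev > 0, (gained + lost) / total_prev, np.nan)
    return {
        "new": new,
        "gained": gained,
        "lost": lost,
        "total_prev": total_prev,
        "turnover": turnover,
    }


def clustering_ratio(n: NewSpineSet) -> float:
    """Clustered new spines / total new spines."""
    total = len(n.positions)
    if total == 0:
        raise ValueError("clustering ratio undefined with zero new spines")
    return float(n.clustered.sum()) / total


def chance_clustering_resample(
    m: SpineMap,
    n: NewSpineSet,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Null distribution of the clustered-spine percentage under uniform
    placement.

    Per repetition, each dendrite's observed new-spine count is placed
    uniformly at random along that dendrite, the per-animal clustered
    percentage computed, and animals averaged.  Returns the null
    distribution, the observed per-animal-averaged percentage and its
    percentile within the null.
    """
    rng = rng or np.random.default_rng()
    counts = n.counts()
    if counts.sum() == 0:
        raise ValueError("no new spines to resample")
    animals = m.animals

    def pct_by_animal(dend, clustered):
        vals = []
        for a in np.unique(animals):
            sel = np.isin(dend, np.flatnonzero(animals == a))
            if sel.sum() == 0:
                continue
            vals.append(100.0 * clustered[sel].mean())
        return float(np.mean(vals))

    observed = pct_by_animal(n.dendrite, n.clustered)
    dend_rep = np.repeat(np.arange(m.n_dendrites), counts)
    null = np.empty(reps)
    for r in range(reps):
        pos = rng.uniform(0.0, m.lengths[dend_rep])
        cl = clustered_flags(dend_rep, pos)
        null[r] = pct_by_animal(dend_rep, cl)
    percentile = 100.0 * np.mean(null < observed)
    return {"observed": observed, "null": null, "percentile": percentile}


def _perm_pvalue(n_ge: int, n_perm: int) -> float:
    # add-one correction keeps permutation p-values strictly positive
    return (n_ge + 1) / (n_perm + 1)


def addition_spearman(
    counts_A: np.ndarray,
    counts_B: np.ndarray,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Spearman rank correlation of per-dendrite addition counts with a
    one-sided permutation p (shuffling the second session's counts)."""
    rng = rng or np.random.default_rng()
    a = np.asarray(counts_A, float)
    b = np.asarray(counts_B, float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need matched counts over >= 5 dendrites")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant counts: rho undefined")
        return {"rho": float("nan"), "p": float("nan"), "null": None}
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    rho = float(np.corrcoef(ra, rb)[0, 1])
    # vectorized permutation: correlation of standardized ranks
    za = (ra - ra.mean()) / ra.std()
    zb = (rb - rb.mean()) / rb.std()
    perm_idx = np.argsort(rng.random((n_perm, a.size)), axis=1)
    null = (zb[perm_idx] @ za) / a.size
    p = _perm_pvalue(int((null >= rho).sum()), n_perm)
    return {"rho": rho, "p": p, "null": null}


def _mi_bins(x: np.ndarray, cap: int = 4) -> np.ndarray:
    return np.minimum(np.asarray(x, int), cap)


def mutual_information(x: np.ndarray, y: np.ndarray, cap: int = 4) -> float:
    """Plug-in MI (nats) of integer counts capped at ``cap``."""
    xb, yb = _mi_bins(x, cap), _mi_bins(y, cap)
    joint = np.zeros((cap + 1, cap + 1))
    np.add.at(joint, (xb, yb), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


def addition_mutual_information(
    counts_A: np.ndarray,
    counts_B: np.ndarray,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
    cap: int = 4,
) -> dict:
    """Mutual information of per-dendrite addition counts with a z-score
    against the permutation null (significant iff z > 2)."""
    rng = rng or np.random.default_rng()
    a = np.asarray(counts_A, int)
    b = np.asarray(counts_B, int)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need matched counts over >= 5 dendrites")
    xb, yb = _mi_bins(a, cap), _mi_bins(b, cap)
    if len(np.unique(xb)) < 2 or len(np.unique(yb)) < 2:
        warnings.warn("degenerate count histogram: MI z-score unreliable")
    mi = mutual_information(a, b, cap)
    n = a.size
    k = cap + 1
    # vectorized null: joint histograms of all permutations at once via
    # bincount over flattened (perm, x, y) codes
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    codes = xb[None, :] * k + yb[perm_idx]
    flat = (np.arange(n_perm)[:, None] * (k * k) + codes).ravel()
    joint = np.bincount(flat, minlength=n_perm * k * k).reshape(n_perm, k, k) / n
    px = np.bincount(xb, minlength=k) / n
    py = joint.sum(axis=1)                      # (n_perm, k)
    denom = px[None, :, None] * py[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = joint * np.log(joint / denom)
    null = np.nansum(terms, axis=(1, 2))
    sd = null.std()
    z = (mi - null.mean()) / sd if sd > 0 else float("nan")
    return {"mi": mi, "z": float(z), "null": null, "significant": bool(z > 2)}


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> dict:
    """Compare two correlations via the Fisher z-transformation.

    Returns the Z statistic and a one-tailed p in the direction of the
    observed sign (p = 0.5 when r1 == r2).
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise ValueError("correlations must satisfy |r| < 1")
        if n <= 3:
            raise ValueError("need n > 3 per group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = stats.norm.sf(z) if z >= 0 else stats.norm.cdf(z)
    return {"Z": float(z), "p": float(p)}


def cross_session_coallocation(
    new_1: NewSpineSet,
    new_2: NewSpineSet,
    animals: np.ndarray | None = None,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Do segments gaining clustered spines in the second transition
    coincide with those that gained clustered spines in the first?

    Observed: percentage of transition-1 clustered spines that sit on a
    segment which also gained clustered spines in transition 2.  Null:
    those spines are redistributed uniformly over the same animal's
    segments ``n_perm`` times and the percentage recomputed.
    """
    rng = rng or np.random.default_rng()
    n_dend = new_1.n_dendrites
    if animals is None:
        animals = np.zeros(n_dend, int)
    cl1 = new_1.dendrite[new_1.clustered]
    seg2 = np.flatnonzero(new_2.clustered_counts() > 0)
    if cl1.size == 0 or seg2.size == 0:
        raise ValueError("no clustered spines in one of the transitions")
    in_seg2 = np.zeros(n_dend, bool)
    in_seg2[seg2] = True
    observed = 100.0 * in_seg2[cl1].mean()
    # null: redistribute each segment's clustered-spine group as a unit to
    # a uniformly random segment of the same animal — clustered spines are
    # co-located by definition, so moving them independently would
    # understate the null variance
    groups, group_counts = np.unique(cl1, return_counts=True)
    anim_of_group = animals[groups]
    pools = {a: np.flatnonzero(animals == a) for a in np.unique(anim_of_group)}
    total = group_counts.sum()
    null = np.empty(n_perm)
    for r in range(n_perm):
        newseg = np.empty(groups.size, int)
        for a, pool in pools.items():
            sel = anim_of_group == a
            newseg[sel] = rng.choice(pool, size=int(sel.sum()), replace=True)
        null[r] = 100.0 * (group_counts @ in_seg2[newseg]) / total
    percentile = 100.0 * np.mean(null < observed)
    return {"observed": observed, "null": null, "percentile": percentile}


def nn_coclustering(
    new_s1: NewSpineSet,
    new_s2: NewSpineSet,
    lengths: np.ndarray | None = None,
    threshold: float = CLUSTER_UM,
    fallback: bool = False,
) -> dict:
    """Nearest-neighbor distances from each later new spine to the
    earlier transition's new spines on the same dendrite.

    Co-clustered = distance strictly below ``threshold``.  Dendrites
    where the later transition gained spines but the earlier one has no
    eligible spine are excluded by default; with ``fallback=True`` the
    dendrite's full length is recorded as the distance instead.
    """
    dists = []
    for d in np.unique(new_s2.dendrite):
        pos2 = new_s2.positions[new_s2.dendrite == d]
        pos1 = new_s1.positions[new_s1.dendrite == d]
        if pos1.size == 0:
            if fallback:
                if lengths is None:
                    raise ValueError("fallback requires dendrite lengths")
                dists.extend([float(lengths[d])] * pos2.size)
            continue
        for x in pos2:
            dists.append(float(np.min(np.abs(pos1 - x))))
    if not dists:
        raise ValueError("no eligible spine pairs")
    dists = np.asarray(dists)
    return {
        "distances": dists,
        "co_clustered_pct": 100.0 * float((dists < threshold).mean()),
        "mean_distance": float(dists.mean()),
    }


def subsample_statistic(
    data_exp: tuple[np.ndarray, ...],
    data_ctrl: tuple[np.ndarray, ...],
    statistic,
    n_dendrites: int = 40,
    reps: int = 10000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Dendrite-subsampled comparison of a statistic between conditions.

    ``data_*`` are tuples of equal-length per-dendrite arrays; per
    repetition ``n_dendrites`` rows are drawn without replacement from
    each condition and ``statistic(*subarrays)`` recomputed.  The
    comparison p-value is the fraction of repetitions in which
    experimental minus control is negative.
    """
    rng = rng or np.random.default_rng()
    n_e = len(data_exp[0])
    n_c = len(data_ctrl[0])
    if n_e < n_dendrites or n_c < n_dendrites:
        raise ValueError("not enough dendrites to subsample")
    dist_e = np.empty(reps)
    dist_c = np.empty(reps)
    for r in range(reps):
        ie = rng.choice(n_e, size=n_dendrites, replace=False)
        ic = rng.choice(n_c, size=n_dendrites, replace=False)
        dist_e[r] = statistic(*(a[ie] for a in data_exp))
        dist_c[r] = statistic(*(a[ic] for a in data_ctrl))
    p = float(np.mean(dist_e - dist_c < 0))
    return {"exp": dist_e, "ctrl": dist_c, "p": p}


def colocalization_enrichment(
    gfp_vol: float, arc_vol: float, overlap_vol: float, roi_vol: float
) -> dict:
    """Volume-overlap enrichment of two signals within an ROI.

    chance = (gfp/roi) * (arc/roi); enrichment = (overlap/roi) / chance.
    """
    vols = (gfp_vol, arc_vol, overlap_vol, roi_vol)
    if any(v < 0 for v in vols):
        raise ValueError("volumes must be >= 0")
    if overlap_vol > min(gfp_vol, arc_vol) or max(gfp_vol, arc_vol) > roi_vol:
        raise ValueError("require overlap <= min(gfp, arc) <= roi")
    if roi_vol == 0:
        raise ValueError("roi volume must be > 0")
    chance = (gfp_vol / roi_vol) * (arc_vol / roi_vol)
    if chance == 0:
        warnings.warn("zero chance level; enrichment undefined")
        return {"chance": 0.0, "enrichment": float("nan")}
    return {"chance": chance, "enrichment": (overlap_vol / roi_vol) / chance}
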