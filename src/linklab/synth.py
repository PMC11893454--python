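"""Seeded generators for sessions, ROI traces and spine maps.

These produce data with the statistical structure the analyses assume,
plus the ground truth needed to score every downstream estimator:

* :func:`gen_sessions` — binarized calcium event matrices for repeated
  context exposures, with log-normal firing rates, condition-dependent
  ensemble reactivation (boosted for the most active decile), rate
  persistence, and latent coactivity modules.
* :func:`gen_roi_traces` — fluorescence traces with planted ROI
  clusters sharing a transient train at a configured correlation.
* :func:`gen_spine_maps` — longitudinal spine maps with tunable
  clustered-addition bias, cross-session count correlation (Gaussian
  copula over Poisson marginals) and co-allocation bias.

Defaults emulate the recorded data's scale: ~130 cells per 10-min
session at 15.5 Hz, and 45 dendritic segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ensemble import MatchedSessions, SessionEvents
from .roicluster import ROITraces
from .spines import SpineMap

__all__ = [
    "CalciumSimConfig",
    "ROISimConfig",
    "SpineSimConfig",
    "gen_sessions",
    "gen_exchangeable_pair",
    "gen_roi_traces",
    "gen_spine_maps",
]


# --------------------------------------------------------------------------
# calcium sessions
# --------------------------------------------------------------------------

@dataclass
class CalciumSimConfig:
    n_cells: int = 130
    duration_s: float = 600.0
    frame_rate: float = 15.5
    rate_mean_hz: float = 0.15          # log-normal event-rate distribution
    rate_sigma: float = 0.8
    ensemble_fraction: float = 0.7      # cells active in a given session
    reactivation_linked: float = 0.85   # P(active again | linked condition)
    reactivation_independent: float = 0.60
    top_decile_boost: float = 0.12      # extra reactivation for top-rate cells
    rate_persistence: float = 0.8       # log-rate correlation across sessions
    n_modules: int = 5                  # latent coactivity modules
    module_rate_hz: float = 0.1
    module_coupling: float = 0.5        # P(member adopts a module event)
    module_size: int = 8
    field_px: float = 300.0
    min_rate_hz: float = 0.0            # rate of cells outside the ensemble

    def __post_init__(self) -> None:
        for name in ("ensemble_fraction", "reactivation_linked",
                     "reactivation_independent", "top_decile_boost",
                     "module_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.duration_s <= 0 or self.frame_rate <= 0 or self.rate_mean_hz <= 0:
            raise ValueError("durations and rates must be > 0")
        if not -1.0 <= self.rate_persistence <= 1.0:
            raise ValueError("rate_persistence must be in [-1, 1]")


def _lognormal_rates(c: CalciumSimConfig, rng: np.random.Generator) -> np.ndarray:
    mu = np.log(c.rate_mean_hz) - c.rate_sigma**2 / 2.0
    return rng.lognormal(mu, c.rate_sigma, c.n_cells)


def _events_from_rates(
    rates: np.ndarray, n_frames: int, frame_rate: float,
    rng: np.random.Generator,
    module_members: list[np.ndarray] | None = None,
    module_rate: float = 0.0,
    coupling: float = 0.0,
) -> np.ndarray:
    p = np.clip(rates / frame_rate, 0.0, 1.0)
    ev = rng.random((n_frames, len(rates))) < p[None, :]
    if module_members:
        for members in module_members:
            members = members[rates[members] > 0]   # silent cells stay silent
            if members.size == 0:
                continue
            train = rng.random(n_frames) < module_rate / frame_rate
            adopt = rng.random((n_frames, len(members))) < coupling
            ev[:, members] |= train[:, None] & adopt
    return ev.astype(np.uint8)


def gen_sessions(
    c: CalciumSimConfig,
    n_sessions: int = 2,
    condition: str = "linked",
    rng: np.random.Generator | None = None,
) -> dict:
    """Generate matched sessions for one animal under a condition.

    ``condition`` is ``"linked"`` (high reactivation, persistent rates,
    top-decile boost) or ``"independent"``.  Returns the sessions, the
    full identity ``id_map`` (cells are tracked by construction), and
    ground truth (per-session active sets, base rates).
    """
    if condition not in ("linked", "independent"):
        raise ValueError("condition must be 'linked' or 'independent'")
    rng = rng or np.random.default_rng()
    n_frames = int(round(c.duration_s * c.frame_rate))
    base_log = np.log(_lognormal_rates(c, rng))
    react = (
        c.reactivation_linked if condition == "linked"
        else c.reactivation_independent
    )
    persistence = c.rate_persistence if condition == "linked" else 0.0
    centroids = rng.uniform(0, c.field_px, (c.n_cells, 2))
    d = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
    overlap = d < 6.0
    np.fill_diagonal(overlap, False)
    modules = [
        rng.choice(c.n_cells, size=min(c.module_size, c.n_cells), replace=False)
        for _ in range(c.n_modules)
    ]

    sessions, active_sets, rate_truth = [], [], []
    prev_active = None
    top = np.argsort(base_log)[::-1][: max(1, c.n_cells // 10)]
    for s in range(n_sessions):
        if prev_active is None:
            active = rng.random(c.n_cells) < c.ensemble_fraction
        else:
            p_re = np.full(c.n_cells, react)
            p_re[top] = np.clip(p_re[top] + c.top_decile_boost, 0, 1)
            # non-members enter so the expected ensemble size is stationary
            p_in = c.ensemble_fraction * (1 - react) / max(1e-12, 1 - c.ensemble_fraction * react)
            p = np.where(prev_active, p_re, min(1.0, p_in))
            active = rng.random(c.n_cells) < p
        noise = rng.normal(0, c.rate_sigma * np.sqrt(1 - persistence**2), c.n_cells)
        log_rates = persistence * (base_log - np.mean(base_log)) + np.mean(base_log) + noise
        rates = np.where(active, np.exp(log_rates), c.min_rate_hz)
        ev = _events_from_rates(
            rates, n_frames, c.frame_rate, rng,
            module_members=modules, module_rate=c.module_rate_hz,
            coupling=c.module_coupling,
        )
        sessions.append(
            SessionEvents(
                events=ev,
                frame_rate=c.frame_rate,
                centroids=centroids,
                footprint_overlap=overlap,
                context_label=chr(ord("A") + s),
            )
        )
        active_sets.append(np.flatnonzero(active))
        rate_truth.append(rates)
        prev_active = active
    id_map = np.column_stack([np.arange(c.n_cells)] * 2)
    return {
        "sessions": sessions,
        "id_map": id_map,
        "active_sets": active_sets,
        "rates": rate_truth,
        "top_decile": top,
        "condition": condition,
    }


def gen_exchangeable_pair(
    c: CalciumSimConfig, rng: np.random.Generator | None = None
) -> MatchedSessions:
    """Two sessions from one identical per-cell Bernoulli model.

    Rates are shared exactly and events drawn independently, so the two
    sessions are exchangeable and any context decoder is at chance.
    """
    rng = rng or np.random.default_rng()
    n_frames = int(round(c.duration_s * c.frame_rate))
    rates = _lognormal_rates(c, rng)
    s = [
        SessionEvents(
            events=_events_from_rates(rates, n_frames, c.frame_rate, rng),
            frame_rate=c.frame_rate,
            context_label=lbl,
        )
        for lbl in ("A", "B")
    ]
    id_map = np.column_stack([np.arange(c.n_cells)] * 2)
    return MatchedSessions(s[0], s[1], id_map)


# --------------------------------------------------------------------------
# ROI traces
# --------------------------------------------------------------------------

@dataclass
class ROISimConfig:
    n_rois: int = 30
    cluster_sizes: tuple[int, ...] = (3, 3, 2)   # remaining ROIs are singletons
    within_correlation: float = 0.9
    duration_s: float = 600.0
    frame_rate: float = 15.5
    transient_rate_hz: float = 0.08
    transient_amplitude: float = 5.0
    decay_s: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.within_correlation <= 1.0:
            raise ValueError("within_correlation must be in (0, 1]")
        if sum(self.cluster_sizes) > self.n_rois:
            raise ValueError("cluster sizes exceed n_rois")


def _transient_trace(
    n_frames: int, c: ROISimConfig, rng: np.random.Generator
) -> np.ndarray:
    spikes = rng.random(n_frames) < c.transient_rate_hz / c.frame_rate
    kernel_len = int(5 * c.decay_s * c.frame_rate)
    kernel = c.transient_amplitude * np.exp(
        -np.arange(kernel_len) / (c.decay_s * c.frame_rate)
    )
    return np.convolve(spikes.astype(float), kernel)[:n_frames]


def gen_roi_traces(
    c: ROISimConfig, rng: np.random.Generator | None = None
) -> tuple[ROITraces, np.ndarray]:
    """Traces with planted clusters; returns (traces, true labels).

    Members of a cluster share a latent transient train; independent
    Gaussian noise is scaled so the expected pairwise correlation
    within a cluster equals ``within_correlation``.  Singletons get
    independent trains.  True labels: cluster index, singletons get
    unique labels.
    """
    rng = rng or np.random.default_rng()
    n_frames = int(round(c.duration_s * c.frame_rate))
    traces = np.empty((n_frames, c.n_rois))
    labels = np.empty(c.n_rois, int)
    rho = c.within_correlation
    idx = 0
    lab = 0
    for size in c.cluster_sizes:
        shared = _transient_trace(n_frames, c, rng)
        sig_var = shared.var()
        noise_sd = np.sqrt(sig_var * (1 - rho) / rho) if rho < 1 else 0.0
        for _ in range(size):
            traces[:, idx] = shared + rng.normal(0, noise_sd, n_frames)
            labels[idx] = lab
            idx += 1
        lab += 1
    while idx < c.n_rois:
        traces[:, idx] = _transient_trace(n_frames, c, rng) + rng.normal(
            0, c.noise_sd, n_frames
        )
        labels[idx] = lab
        idx += 1
        lab += 1
    return ROITraces(traces, c.frame_rate), labels


# --------------------------------------------------------------------------
# spine maps
# --------------------------------------------------------------------------

@dataclass
class SpineSimConfig:
    n_dendrites: int = 45
    n_animals: int = 6
    length_mean_um: float = 40.0
    length_sigma: float = 0.3
    init_density_per_um: float = 0.4
    addition_rate_per_um: float = 0.06   # mean new spines per µm per transition
    elimination_rate: float = 0.08       # per-spine loss per transition
    pi_clust: float = 0.0                # P(new spine placed near another new one)
    rho_co: float = 0.0                  # Spearman corr of addition counts
    coalloc_bias: float = 0.0            # clustered additions target prior segments
    n_sessions: int = 3
    corr_transitions: tuple[int, int] = (0, 1)
    # additions scale with segment length by default; homogeneous rates
    # remove the shared length effect (used when calibrating nulls that
    # redistribute spines uniformly per segment)
    length_dependent_addition: bool = True

    def __post_init__(self) -> None:
        for name in ("pi_clust", "coalloc_bias", "elimination_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not -1.0 <= self.rho_co <= 1.0:
            raise ValueError("|rho_co| must be <= 1")
        if self.n_sessions < 2:
            raise ValueError("need >= 2 sessions")


_COPULA_CACHE: dict[tuple, float] = {}


def _calibrate_copula_r(lams: np.ndarray, rho_target: float) -> float:
    """Gaussian-copula correlation giving the target Spearman correlation
    for Poisson counts with rates ``lams`` (numeric bisection, cached)."""
    if rho_target == 0.0:
        return 0.0
    key = (round(float(np.mean(lams)), 3), round(float(np.std(lams)), 3),
           round(rho_target, 3))
    if key in _COPULA_CACHE:
        return _COPULA_CACHE[key]
    rng = np.random.default_rng(123456)
    reps = max(2, 30_000 // len(lams))
    lam = np.tile(lams, reps)

    def spearman_at(r: float) -> float:
        z1 = rng.standard_normal(lam.size)
        z2 = r * z1 + np.sqrt(1 - r**2) * rng.standard_normal(lam.size)
        x = stats.poisson.ppf(stats.norm.cdf(z1), lam)
        y = stats.poisson.ppf(stats.norm.cdf(z2), lam)
        return stats.spearmanr(x, y).statistic

    lo, hi = 0.0, 0.999
    sign = np.sign(rho_target)
    target = abs(rho_target)
    for _ in range(18):
        mid = (lo + hi) / 2
        if spearman_at(mid) < target:
            lo = mid
        else:
            hi = mid
    r = sign * (lo + hi) / 2
    _COPULA_CACHE[key] = r
    return r


def gen_spine_maps(
    c: SpineSimConfig, rng: np.random.Generator | None = None
) -> tuple[SpineMap, dict]:
    """Longitudinal spine map plus ground truth.

    Per transition, per-dendrite addition counts are Poisson with rate
    proportional to length; across the two ``corr_transitions`` the
    counts follow a Gaussian copula calibrated so their Spearman
    correlation is ``rho_co``.  Each new spine is placed uniformly, or
    with probability ``pi_clust`` within 5 µm of a previously placed
    new spine of the same transition (dendrites shorter than 5 µm are
    resampled to uniform placement).  With probability ``coalloc_bias``
    a clustered addition is routed to a segment that gained clustered
    spines in the previous transition.  Existing spines are thinned by
    ``elimination_rate``.
    """
    rng = rng or np.random.default_rng()
    n_d = c.n_dendrites
    lengths = np.exp(rng.normal(np.log(c.length_mean_um), c.length_sigma, n_d))
    lengths = np.maximum(lengths, 12.0)
    animals = rng.integers(0, c.n_animals, n_d)
    n_trans = c.n_sessions - 1

    # per-transition addition counts, with the designated pair correlated
    if c.length_dependent_addition:
        lam = c.addition_rate_per_um * lengths
    else:
        lam = np.full(n_d, c.addition_rate_per_um * c.length_mean_um)
    counts = np.empty((n_trans, n_d), int)
    t1, t2 = c.corr_transitions
    r = _calibrate_copula_r(lam, c.rho_co)
    z1 = rng.standard_normal(n_d)
    z2 = r * z1 + np.sqrt(max(0.0, 1 - r**2)) * rng.standard_normal(n_d)
    for t in range(n_trans):
        if t == t1 and t2 < n_trans:
            counts[t] = stats.poisson.ppf(stats.norm.cdf(z1), lam).astype(int)
        elif t == t2:
            counts[t] = stats.poisson.ppf(stats.norm.cdf(z2), lam).astype(int)
        else:
            counts[t] = rng.poisson(lam)

    sp_dend: list[int] = []
    sp_pos: list[float] = []
    sp_present: list[list[bool]] = []

    def add_spine(d: int, pos: float, born: int) -> None:
        sp_dend.append(d)
        sp_pos.append(float(np.clip(pos, 0.0, lengths[d])))
        sp_present.append([False] * born + [True] * (c.n_sessions - born))

    # initial population, present from session 0
    for d in range(n_d):
        for _ in range(rng.poisson(c.init_density_per_um * lengths[d])):
            add_spine(d, rng.uniform(0, lengths[d]), 0)

    prev_clustered_segments: np.ndarray = np.array([], int)
    for t in range(n_trans):
        # eliminations: thin spines alive at session t
        for i, pres in enumerate(sp_present):
            if pres[t] and rng.random() < c.elimination_rate:
                for s in range(t + 1, c.n_sessions):
                    pres[s] = False
        new_dend: list[int] = []
        new_pos: list[float] = []
        for d in range(n_d):
            for _ in range(counts[t, d]):
                target = d
                clustered_attempt = rng.random() < c.pi_clust
                if (
                    clustered_attempt
                    and c.coalloc_bias > 0
                    and prev_clustered_segments.size
                    and rng.random() < c.coalloc_bias
                ):
                    pool = prev_clustered_segments[
                        animals[prev_clustered_segments] == animals[d]
                    ]
                    if pool.size:
                        target = int(rng.choice(pool))
                anchors = [p for dd, p in zip(new_dend, new_pos) if dd == target]
                if clustered_attempt and anchors and lengths[target] > 5.0:
                    anchor = anchors[int(rng.integers(len(anchors)))]
                    pos = anchor + rng.uniform(-5.0, 5.0)
                else:
                    pos = rng.uniform(0, lengths[target])
                new_dend.append(target)
                new_pos.append(float(np.clip(pos, 0.0, lengths[target])))
        for d, pos in zip(new_dend, new_pos):
            add_spine(d, pos, t + 1)
        from .spines import clustered_flags

        nd = np.asarray(new_dend, int)
        npos = np.asarray(new_pos, float)
        cl = clustered_flags(nd, npos)
        prev_clustered_segments = np.unique(nd[cl])

    sessions = [f"s{t}" for t in range(c.n_sessions)]
    m = SpineMap(
        lengths=lengths,
        spine_dendrite=np.asarray(sp_dend, int),
        positions=np.asarray(sp_pos, float),
        presence=np.asarray(sp_present, bool),
        sessions=sessions,
        animals=animals,
    )
    truth = {
        "counts": counts,
        "lengths": lengths,
        "animals": animals,
        "rho_co": c.rho_co,
        "copula_r": r,
        "corr_transitions": c.corr_transitions,
    }
    return m, truth
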