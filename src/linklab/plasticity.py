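"""Synaptic tagging, PRP transients, weight commits and homeostatic scaling.

Plasticity follows a synaptic tagging-and-capture scheme: during a
stimulus, synapses that received calcium become candidates; candidates
on neurons firing above ``ff_threshold`` are tagged for potentiation
with probability ``min(1, p_ltp_base + X_dend * N_s / 2)`` (N_s counts
preexisting potentiated synapses on the same dendrite), otherwise for
depression.  If the neuron's calcium crossed ``Theta_PRP``, a
plasticity-related-protein transient ``PRP(T) = ((T-20)/30) e^{-(T+10)/30}``
(T in minutes, zero for T <= 20) gates weight commits
``dw = lr * PRP * tag`` applied when |tag| > tag_gate and PRP > prp_gate.
Memories consolidate independently — there is no competition for PRPs.
Between stimuli, weights relax by homeostatic synaptic scaling
``dw_j/dt = (1/tau_H)(1 - sum_j w_j / (w_init * N_syn))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NeuronState, SynapseState, _x_or_zero
from .params import ModelParams

__all__ = [
    "PlasticityEvent",
    "p_ltp_probability",
    "tag_synapses",
    "prp_transient",
    "commit_weight_updates",
    "homeostatic_step",
    "homeostatic_relax",
]


@dataclass
class PlasticityEvent:
    synapse: SynapseState
    tag_set: int                 # -1 or +1
    p_ltp_used: float
    committed_dw: float = 0.0
    commit_time: float | None = None   # minutes since stimulus onset


def p_ltp_probability(x_dend, n_s, p: ModelParams, variant: str = "full"):
    """Potentiation-tag probability, clipped to [0, 1].

    Under the ``no_dendritic`` variant the probability is the flat
    ``p_ltp_nodend`` (0.32) regardless of dendritic excitability or
    preexisting clustering.
    """
    if variant == "no_dendritic":
        return np.clip(
            np.full_like(np.asarray(x_dend, dtype=float), p.p_ltp_nodend), 0.0, 1.0
        ) if np.ndim(x_dend) else min(1.0, p.p_ltp_nodend)
    raw = np.asarray(x_dend, dtype=float) * np.asarray(n_s, dtype=float) * p.p_ltp_slope
    out = np.clip(p.p_ltp_base + raw, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def tag_synapses(
    neuron: NeuronState,
    rate_hz: float,
    now_hours: float,
    p: ModelParams,
    variant: str = "full",
    rng: np.random.Generator | None = None,
) -> list[PlasticityEvent]:
    """Tag this neuron's stimulus-active synapses for potentiation/depression.

    ``rate_hz`` is the neuron's firing rate over the stimulus window;
    a missing rate is rejected because the potentiation gate cannot be
    evaluated without it.  N_s is evaluated from the ``potentiated``
    flags as they stand (i.e. before this memory's commits).
    """
    if rate_hz is None or not np.isfinite(rate_hz):
        raise ValueError("stimulus firing rate is required for tagging")
    rng = rng or np.random.default_rng()
    events: list[PlasticityEvent] = []
    for d in neuron.dendrites:
        n_s = sum(s.potentiated for s in d.synapses)
        x = 0.0 if variant == "no_dendritic" else _x_or_zero(d.t_exc_dend, now_hours)
        prob = p_ltp_probability(x, n_s, p, variant)
        for s in d.synapses:
            if s.ca_in <= 0:
                continue
            if rate_hz > p.ff_threshold:
                tag = 1 if rng.random() < prob else -1
            else:
                tag = -1
            s.tag = tag
            events.append(PlasticityEvent(s, tag, prob))
    return events


def prp_transient(T_minutes, ca_soma: float, p: ModelParams):
    """PRP availability T minutes after a stimulus whose calcium crossed
    ``Theta_PRP``; zero otherwise and for T <= 20 min (peak at T = 50)."""
    T = np.asarray(T_minutes, dtype=float)
    if np.any(T < 0):
        raise ValueError("elapsed time must be >= 0")
    if ca_soma <= p.Theta_PRP:
        out = np.zeros_like(T)
    else:
        out = np.where(T > 20.0, (T - 20.0) / 30.0 * np.exp(-(T + 10.0) / 30.0), 0.0)
    return float(out) if out.ndim == 0 else out


def prp_exposure(p: ModelParams) -> float:
    """Integrated PRP drive over the consolidation window, in seconds.

    The weight update ``dw = lr * PRP(t) * tag`` is specified per second
    while the tag and PRP gates hold, so the total commit is
    ``lr * tag * integral_{PRP>prp_gate} PRP(T) dT`` with the transient
    evaluated in minutes and the integral converted to seconds.  The
    result is large enough that tagged weights saturate at their bounds,
    which is what makes the potentiated/depressed trace durable.
    """
    T = np.arange(20.0, 400.0, 0.05)
    prp = (T - 20.0) / 30.0 * np.exp(-(T + 10.0) / 30.0)
    keep = prp > p.prp_gate
    return float(np.trapezoid(prp[keep], T[keep]) * 60.0)


def commit_weight_updates(
    events: list[PlasticityEvent], prp_level: float, p: ModelParams,
    commit_time: float | None = None,
) -> list[PlasticityEvent]:
    """Apply ``dw = lr * PRP * tag`` to tagged synapses, clip to bounds.

    Commits require |tag| > tag_gate and PRP > prp_gate; a positive
    commit marks the synapse ``potentiated``.  Tags are consumed.
    """
    for ev in events:
        s = ev.synapse
        if abs(s.tag) > p.tag_gate and prp_level > p.prp_gate:
            dw = p.lr * prp_level * s.tag
            new_w = float(np.clip(s.w + dw, p.w_min, p.w_max))
            ev.committed_dw = new_w - s.w
            ev.commit_time = commit_time
            s.w = new_w
            if ev.committed_dw > 0:
                s.potentiated = True
        s.tag = 0
    return events


def homeostatic_relax(
    w: np.ndarray,
    neuron_idx: np.ndarray,
    n_neurons: int,
    elapsed_hours: float,
    p: ModelParams,
) -> np.ndarray:
    """Closed-form homeostatic scaling for a flat synapse array.

    Every synapse of a neuron receives the same additive drift, so the
    per-neuron total relaxes exponentially toward ``w_init * N_syn``.
    Weights are pinned at [w_min, w_max]: when a weight reaches a bound
    it stops drifting and the remaining weights continue (the drift sign
    is constant along the relaxation, so pinned weights never rejoin).
    The piecewise-exponential solution is computed exactly.
    """
    if elapsed_hours < 0:
        raise ValueError("elapsed time must be >= 0")
    if elapsed_hours == 0 or w.size == 0:
        return w
    w = np.asarray(w, float).copy()
    for nrn in range(n_neurons):
        sel = np.flatnonzero(neuron_idx == nrn)
        if sel.size == 0:
            continue
        wn = w[sel]
        n_tot = sel.size
        s0 = p.w_init * n_tot
        remaining = float(elapsed_hours)
        for _ in range(n_tot + 1):
            total = wn.sum()
            gap = s0 - total
            if abs(gap) < 1e-15 or remaining <= 0:
                break
            up = gap > 0
            active = wn < p.w_max if up else wn > p.w_min
            n_a = int(active.sum())
            if n_a == 0:
                break
            tau_eff = p.tau_H * s0 / n_a
            shift_full = gap * (1.0 - np.exp(-remaining / tau_eff)) / n_a
            headroom = (
                (p.w_max - wn[active]).min() if up else (wn[active] - p.w_min).min()
            )
            if abs(shift_full) <= headroom:
                wn[active] += shift_full
                break
            shift_hit = headroom if up else -headroom
            frac = shift_hit * n_a / gap          # in (0, 1)
            t_hit = -tau_eff * np.log(1.0 - frac)
            wn[active] += shift_hit
            remaining -= t_hit
        w[sel] = np.clip(wn, p.w_min, p.w_max)
    return w


def homeostatic_step(
    neuron: NeuronState, elapsed_hours: float, p: ModelParams
) -> NeuronState:
    """Homeostatic scaling over ``elapsed_hours`` for one neuron's synapses."""
    syns = [s for d in neuron.dendrites for s in d.synapses]
    if not syns:
        return neuron
    w = np.array([s.w for s in syns])
    new_w = homeostatic_relax(
        w, np.zeros(len(syns), dtype=int), 1, elapsed_hours, p
    )
    for s, v in zip(syns, new_w):
        s.w = float(v)
    return neuron
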