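"""Build networks, encode/recall memories, and run linking experiments.

The experiment mirrors the behavioral design: memory A is encoded (its
input pool fires at 35 Hz for 4 s), the network idles for 5 h, 2 d or
7 d (excitability transients decay, homeostatic scaling relaxes
weights), memory B is encoded, and after a further 2 d both memories
are recalled with plasticity frozen.  Overlap metrics above chance are
computed for neuronal ensembles, for branches carrying potentiated
synapse clusters, and for branches gaining newly potentiated clusters.

Variants
--------
``full``
    somatic and dendritic allocation mechanisms active.
``no_dendritic``
    dendritic excitability is clamped to zero and the potentiation
    probability is the flat 0.32; somatic mechanisms remain.
``dendritic_separation``
    the two memories' inputs are confined to disjoint halves of the
    dendrite pool, eliminating dendritic overlap by construction.

The engine is a flat-array (structure-of-arrays) implementation of the
per-unit dynamics in :mod:`linklab.network`; states advance
synchronously at ``dt`` with delta-conductance synapses and a one-step
spike delay on recurrent (interneuron and feedforward) pathways.
Inter-stimulus gaps are event-driven: nothing spikes, so excitability
and homeostatic scaling are evaluated in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allocation import (
    OverlapSummary,
    branch_cluster_overlap,
    ensemble_overlap_above_chance,
    new_clustered_synapse_overlap,
)
from .params import ModelParams
from .plasticity import (
    homeostatic_relax,
    p_ltp_probability,
    prp_exposure,
    prp_transient,
)
from .network import excitability_level

__all__ = [
    "ExperimentConfig",
    "TrialResult",
    "LinkingNetwork",
    "build_network",
    "assign_memory_inputs",
    "encode_memory",
    "advance_time",
    "recall_memory",
    "run_trial",
    "run_linking_experiment",
    "INTERVALS_H",
]

INTERVALS_H = {"5h": 5.0, "2d": 48.0, "7d": 168.0}
VARIANTS = ("full", "no_dendritic", "dendritic_separation")


def _fixed_indegree(
    rng: np.random.Generator, n_rows: int, n_cols: int, k: int
) -> np.ndarray:
    """0/1 matrix with exactly k ones per row (random partners)."""
    W = np.zeros((n_rows, n_cols))
    for i in range(n_rows):
        W[i, rng.choice(n_cols, size=min(k, n_cols), replace=False)] = 1.0
    return W


@dataclass
class ExperimentConfig:
    interval: str = "5h"                  # {"5h", "2d", "7d"}
    variant: str = "full"
    n_trials: int = 10
    seed: int = 0
    recall_delay_h: float = 48.0
    ensemble_rate_threshold: float | None = None   # defaults to ff_threshold

    def __post_init__(self) -> None:
        if self.interval not in INTERVALS_H:
            raise ValueError(f"interval must be one of {sorted(INTERVALS_H)}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def interval_hours(self) -> float:
        return INTERVALS_H[self.interval]


@dataclass
class TrialResult:
    """Ensembles and potentiation bookkeeping for one simulated trial."""

    ensembles: dict[str, frozenset]
    pot_synapses: dict[str, np.ndarray]        # per memory: synapse indices
    newpot_synapses: dict[str, np.ndarray]
    branch_pot_counts: dict[str, np.ndarray]   # per memory: counts per branch
    branch_newpot_counts: dict[str, np.ndarray]
    n_exc: int
    seed: int
    params: ModelParams


class LinkingNetwork:
    """Flat-array state of the two-layer network plus interneurons."""

    def __init__(self, p: ModelParams, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self.now_hours = 0.0
        n_exc = p.n_exc_l1 + p.n_exc_l2
        self.n_exc = n_exc
        self.layer = np.r_[np.ones(p.n_exc_l1, int), np.full(p.n_exc_l2, 2)]
        self.n_dend = n_exc * p.n_branches
        self.dend_owner = np.repeat(np.arange(n_exc), p.n_branches)

        # somatic / dendritic dynamic state
        self.V = np.full(n_exc, p.E_L)
        self.I_adapt = np.zeros(n_exc)
        self.I_inh = np.zeros(n_exc)
        self.refrac = np.zeros(n_exc, int)
        self.beta_adapt = np.full(n_exc, p.beta_adapt_base)
        self.V_d = np.full(self.n_dend, p.E_L)
        self.a_exc = np.full(self.n_dend, p.a_exc_base)

        # per-stimulus accumulators
        self.ca_soma = np.zeros(n_exc)
        self.ca_branch = np.zeros(self.n_dend)

        # excitability transient triggers (hours; nan = never triggered)
        self.t_exc_soma = np.full(n_exc, np.nan)
        self.t_exc_dend = np.full(self.n_dend, np.nan)

        # source table: [0, n_bg) background, [n_bg, n_bg + n_l1) feedforward
        self.n_bg_sources = p.n_bg_sources
        self.n_sources = p.n_bg_sources + p.n_exc_l1
        self.memory_sources: dict[str, tuple[int, int]] = {}
        self.encoded: set[str] = set()

        # synapses: background on every dendrite, feedforward onto layer 2
        dend_bg = np.repeat(np.arange(self.n_dend), p.n_bg_syn_per_branch)
        src_bg = rng.integers(0, p.n_bg_sources, dend_bg.size)
        l2_dend = np.flatnonzero(self.dend_owner >= p.n_exc_l1)
        dend_ff = np.repeat(l2_dend, p.n_ff_syn_per_branch)
        # per layer-2 neuron, feedforward partners are sampled without
        # replacement so multiplicity variance cannot couple the drives the
        # two memories deliver through shared layer-1 hubs
        k_ff = p.n_ff_syn_per_branch * p.n_branches
        src_ff = np.concatenate(
            [
                rng.choice(p.n_exc_l1, size=min(k_ff, p.n_exc_l1), replace=False)
                if k_ff <= p.n_exc_l1
                else rng.integers(0, p.n_exc_l1, k_ff)
                for _ in range(p.n_exc_l2)
            ]
        )
        src_ff = p.n_bg_sources + src_ff
        self.syn_dend = np.r_[dend_bg, dend_ff].astype(np.int64)
        self.syn_src = np.r_[src_bg, src_ff].astype(np.int64)
        self.syn_w = np.full(self.syn_dend.size, p.w_init)
        self.syn_label = np.full(self.syn_dend.size, -1, np.int8)  # -1 = background
        # kind: 0 background, 1 feedforward, 2 memory input
        self.syn_kind = np.r_[
            np.zeros(dend_bg.size, np.int8), np.ones(dend_ff.size, np.int8)
        ]
        self.labels: list[str] = []
        self.syn_ca = np.zeros(self.syn_dend.size)
        self.syn_tag = np.zeros(self.syn_dend.size, np.int8)
        self.syn_pot = np.zeros(self.syn_dend.size, bool)
        self.pot_by: dict[str, np.ndarray] = {}
        self.newpot_by: dict[str, np.ndarray] = {}

        # interneurons: two classes, random partners but fixed in-degrees so
        # quenched wiring does not bias which neurons win the competition
        self.n_inter = p.n_soma_inter + p.n_dend_inter
        self.inter_V = np.zeros(self.n_inter)
        self.inter_refrac = np.zeros(self.n_inter, int)
        self.W_ie = _fixed_indegree(
            rng, self.n_inter, n_exc, max(1, int(round(p.p_exc_to_inter * n_exc)))
        )
        # inhibitory output is a uniform pool: every excitatory unit sees the
        # same effective inhibitory weight, so rate differences among
        # interneurons cannot bias which excitatory neurons win
        self.W_si = np.full((n_exc, p.n_soma_inter), p.p_inter_to_exc)
        self.W_di = np.full((self.n_dend, p.n_dend_inter), p.p_inter_to_dend)
        self.inter_C = 100.0
        self.exc_spiked = np.zeros(n_exc, bool)

    # -- bookkeeping ---------------------------------------------------
    @property
    def syn_neuron(self) -> np.ndarray:
        return self.dend_owner[self.syn_dend]

    def _label_index(self, label: str) -> int:
        if label not in self.labels:
            raise KeyError(f"unknown memory label {label!r}")
        return self.labels.index(label)

    def x_dend(self) -> np.ndarray:
        """Current dendritic excitability levels (0 where never triggered)."""
        x = np.zeros(self.n_dend)
        mask = ~np.isnan(self.t_exc_dend)
        if mask.any():
            x[mask] = excitability_level(self.now_hours - self.t_exc_dend[mask])
        return x

    def x_soma(self) -> np.ndarray:
        x = np.zeros(self.n_exc)
        mask = ~np.isnan(self.t_exc_soma)
        if mask.any():
            x[mask] = excitability_level(self.now_hours - self.t_exc_soma[mask])
        return x

    def refresh_modulation(self, variant: str = "full") -> None:
        p = self.p
        if variant == "no_dendritic":
            self.a_exc[:] = p.a_exc_base
        else:
            self.a_exc[:] = np.where(
                self.x_dend() > p.x_dend_gate,
                p.a_exc_base * (1 + p.a_exc_boost),
                p.a_exc_base,
            )
        factor = (
            1 - p.beta_adapt_boost
            if p.soma_excitability_lowers_adaptation
            else 1 + p.beta_adapt_boost
        )
        self.beta_adapt[:] = np.where(
            self.x_soma() > p.x_soma_gate,
            p.beta_adapt_base * factor,
            p.beta_adapt_base,
        )


def build_network(
    cfg: ExperimentConfig, p: ModelParams, rng: np.random.Generator
) -> LinkingNetwork:
    """Construct the wired network (no memory inputs assigned yet)."""
    return LinkingNetwork(p, rng)


def assign_memory_inputs(
    net: LinkingNetwork,
    memory_label: str,
    cfg: ExperimentConfig,
    rng: np.random.Generator,
) -> LinkingNetwork:
    """Place a memory's input synapses on random excitatory dendrites.

    Weights are uniform on [mem_w_low, mem_w_high].  Under the
    ``dendritic_separation`` variant the two memories are confined to
    disjoint random halves of the dendrite pool, so no dendrite can
    host synapses of both.
    """
    p = net.p
    if memory_label in net.memory_sources:
        raise ValueError(f"memory {memory_label!r} already assigned")
    l1_dend = np.arange(net.n_dend)
    if cfg.variant == "dendritic_separation":
        # memories are confined to disjoint halves of the dendrite pool so
        # no dendrite can host synapses of both memories at any density
        if not hasattr(net, "_sep_perm"):
            net._sep_perm = rng.permutation(net.n_dend)
        half = net.n_dend // 2
        if half < 1:
            raise ValueError("dendritic separation infeasible: <2 dendrites")
        k = len(net.labels)
        if k > 1:
            raise ValueError(
                "dendritic separation supports two memories; "
                f"cannot place memory {memory_label!r}"
            )
        l1_dend = net._sep_perm[:half] if k == 0 else net._sep_perm[half:]
    n_syn_new = p.n_mem_sources * p.n_mem_contacts
    src0 = net.n_sources
    net.memory_sources[memory_label] = (src0, p.n_mem_sources)
    net.n_sources += p.n_mem_sources
    code = len(net.labels)
    net.labels.append(memory_label)
    new_dend = rng.choice(l1_dend, size=n_syn_new, replace=True)
    new_src = src0 + np.repeat(np.arange(p.n_mem_sources), p.n_mem_contacts)
    new_w = rng.uniform(p.mem_w_low, p.mem_w_high, n_syn_new)
    net.syn_dend = np.r_[net.syn_dend, new_dend]
    net.syn_src = np.r_[net.syn_src, new_src]
    net.syn_w = np.r_[net.syn_w, new_w]
    net.syn_label = np.r_[net.syn_label, np.full(n_syn_new, code, np.int8)]
    net.syn_kind = np.r_[net.syn_kind, np.full(n_syn_new, 2, np.int8)]
    net.syn_ca = np.r_[net.syn_ca, np.zeros(n_syn_new)]
    net.syn_tag = np.r_[net.syn_tag, np.zeros(n_syn_new, np.int8)]
    net.syn_pot = np.r_[net.syn_pot, np.zeros(n_syn_new, bool)]
    for k in net.pot_by:
        net.pot_by[k] = np.r_[net.pot_by[k], np.zeros(n_syn_new, bool)]
        net.newpot_by[k] = np.r_[net.newpot_by[k], np.zeros(n_syn_new, bool)]
    return net


def _simulate_stimulus(
    net: LinkingNetwork,
    memory_label: str | None,
    dur_s: float,
    rng: np.random.Generator,
    accumulate_calcium: bool,
    noise: bool = True,
) -> np.ndarray:
    """Integrate the network for one stimulus window; returns exc rates (Hz)."""
    p = net.p
    dt = p.dt
    n_steps = int(round(dur_s * 1000.0 / dt))
    ref_steps = max(1, int(round(p.refractory / dt)))
    p_bg = p.bg_rate * dt / 1000.0
    p_mem = p.stim_rate * dt / 1000.0
    mem_slice = None
    if memory_label is not None:
        s0, cnt = net.memory_sources[memory_label]
        mem_slice = slice(s0, s0 + cnt)
    S = np.zeros(net.n_sources, bool)
    ff_lo, ff_hi = net.n_bg_sources, net.n_bg_sources + p.n_exc_l1
    spike_count = np.zeros(net.n_exc)
    inter_g_L = net.inter_C / p.inter_tau_m
    inter_spiked = np.zeros(net.n_inter, bool)
    sign_inh = -1.0 if p.eq1_literal_sign else 1.0

    syn_dend, syn_src, dend_owner = net.syn_dend, net.syn_src, net.dend_owner
    a_exc_g = None  # refreshed each step from dendrite a_exc (constant in window)
    ca_args = (p.ca_slope, p.ca_mid, p.ca_div)

    if p.regular_input_trains:
        period_bg = max(1, int(round(1000.0 / (p.bg_rate * dt))))
        period_mem = max(1, int(round(1000.0 / (p.stim_rate * dt))))

    for step in range(n_steps):
        # --- presynaptic source spikes this step
        if p.regular_input_trains:
            S[: net.n_bg_sources] = step % period_bg == 0
            if mem_slice is not None:
                S[mem_slice] = step % period_mem == 0
        else:
            S[: net.n_bg_sources] = rng.random(net.n_bg_sources) < p_bg
            if mem_slice is not None:
                S[mem_slice] = rng.random(mem_slice.stop - mem_slice.start) < p_mem
        S[ff_lo:ff_hi] = net.exc_spiked[: p.n_exc_l1]

        # --- interneurons (driven by last step's excitatory spikes)
        drive = net.W_ie @ net.exc_spiked
        free_i = net.inter_refrac == 0
        net.inter_V += dt * (-inter_g_L * (net.inter_V - p.E_L)) / net.inter_C
        net.inter_V = p.E_E + (net.inter_V - p.E_E) * np.exp(
            -p.g_exc_to_inter * drive / net.inter_C
        )
        inter_spiked = free_i & (net.inter_V >= p.inter_V_th)
        net.inter_V[inter_spiked] = p.E_L
        net.inter_V[~free_i] = p.E_L
        net.inter_refrac[inter_spiked] = ref_steps
        net.inter_refrac[~free_i] -= 1

        # --- dendrites
        active = S[syn_src]
        sE = np.bincount(
            syn_dend[active], weights=net.syn_w[active], minlength=net.n_dend
        )
        net.V_d += dt * (-p.g_L_d * (net.V_d - p.E_L)) / p.C_d
        net.V_d = p.E_E + (net.V_d - p.E_E) * np.exp(
            -net.a_exc * p.g_E * sE / p.C_d
        )
        dend_inter = inter_spiked[p.n_soma_inter:]
        if dend_inter.any():
            sI = net.W_di @ dend_inter
            if sign_inh > 0:
                net.V_d = p.E_I + (net.V_d - p.E_I) * np.exp(-p.g_I * sI / p.C_d)
            else:
                net.V_d -= (p.g_I * sI / p.C_d) * (p.E_I - net.V_d)
        if accumulate_calcium and active.any():
            arg = np.clip(-ca_args[0] * (net.V_d - ca_args[1]), -60.0, 60.0)
            dca = 1.0 / (1.0 + np.exp(arg) / ca_args[2])
            wca = net.syn_w[active] * dca[syn_dend[active]]
            net.syn_ca[active] += wca
            net.ca_branch += np.bincount(
                syn_dend[active], weights=wca, minlength=net.n_dend
            )

        # --- soma
        I_ax = np.bincount(
            dend_owner,
            weights=p.g_ax * np.maximum(net.V_d - net.V[dend_owner], 0.0),
            minlength=net.n_exc,
        )
        net.I_inh += dt * (-net.I_inh) / p.tau_inh
        soma_inter = inter_spiked[: p.n_soma_inter]
        if soma_inter.any():
            net.I_inh += p.g_inh * (net.W_si @ soma_inter)
        I_noise = rng.uniform(0.0, p.noise_max, net.n_exc) if noise else 0.0
        free = net.refrac == 0
        dV = dt * (
            -p.g_L * (net.V - p.E_L) + I_noise + I_ax - net.I_inh - net.I_adapt
        ) / p.C
        net.V = np.where(free, net.V + dV, p.V_reset)
        net.I_adapt += dt * (p.alpha_adapt * (net.V - p.E_L) - net.I_adapt) / p.tau_adapt
        spiked = free & (net.V >= p.V_th)
        net.V[spiked] = p.V_reset
        net.refrac[spiked] = ref_steps
        net.refrac[~free] -= 1
        net.I_adapt[spiked] += net.beta_adapt[spiked]
        if accumulate_calcium:
            net.ca_soma[spiked] += 1.0
        spike_count += spiked
        net.exc_spiked = spiked
        # backpropagating spike depolarizes the spiking neuron's dendrites,
        # making NMDA calcium selective for co-active branch and soma
        if p.g_bap > 0 and spiked.any():
            bap = spiked[dend_owner]
            net.V_d[bap] = p.E_E + (net.V_d[bap] - p.E_E) * np.exp(
                -p.g_bap / p.C_d
            )

    if not np.all(np.isfinite(net.V)) or not np.all(np.isfinite(net.V_d)):
        raise FloatingPointError("network state diverged during stimulus")
    return spike_count / dur_s


def _reset_stimulus_accumulators(net: LinkingNetwork) -> None:
    net.ca_soma[:] = 0.0
    net.ca_branch[:] = 0.0
    net.syn_ca[:] = 0.0
    net.V[:] = net.p.E_L
    net.V_d[:] = net.p.E_L
    net.I_adapt[:] = 0.0
    net.I_inh[:] = 0.0
    net.refrac[:] = 0
    net.inter_V[:] = net.p.E_L
    net.inter_refrac[:] = 0
    net.exc_spiked[:] = False


def encode_memory(
    net: LinkingNetwork,
    memory_label: str,
    cfg: ExperimentConfig,
    rng: np.random.Generator,
) -> frozenset:
    """Present a memory's inputs for ``stim_dur`` seconds and consolidate.

    Returns the encoding ensemble (excitatory neurons with stimulus
    firing rate above the ensemble threshold).  Consolidation tags
    stimulus-active synapses, starts excitability transients where
    branch/somatic calcium crossed threshold, and commits weight
    changes at the PRP peak (``commit_time_min``), recording which
    synapses each memory potentiated.
    """
    p = net.p
    if memory_label not in net.memory_sources:
        raise KeyError(f"memory {memory_label!r} has no assigned inputs")
    variant = cfg.variant
    net.refresh_modulation(variant)
    _reset_stimulus_accumulators(net)
    rates = _simulate_stimulus(net, memory_label, p.stim_dur, rng, True)
    thr = (cfg.ensemble_rate_threshold
           if cfg.ensemble_rate_threshold is not None else p.ff_threshold)
    ensemble = frozenset(np.flatnonzero(rates > thr).tolist())
    if not ensemble:
        warnings.warn(f"empty ensemble while encoding {memory_label!r}")
    net.encoded.add(memory_label)
    if not p.plasticity_enabled:
        return ensemble

    # ---- synaptic tagging (N_s evaluated before this memory's commits)
    cand = net.syn_ca > 0
    if not p.ff_plastic:
        cand &= net.syn_kind != 1
    n_s_branch = np.bincount(
        net.syn_dend[net.syn_pot], minlength=net.n_dend
    ).astype(float)
    if variant == "no_dendritic":
        prob = np.full(net.n_dend, p.p_ltp_nodend)
    else:
        prob = p_ltp_probability(net.x_dend(), n_s_branch, p)
    neuron_of_syn = net.syn_neuron
    hi_rate = rates[neuron_of_syn] > p.ff_threshold
    draw = rng.random(net.syn_w.size)
    net.syn_tag[:] = 0
    pot_tag = cand & hi_rate & (draw < prob[net.syn_dend])
    dep_tag = cand & ~(hi_rate & (draw < prob[net.syn_dend]))
    net.syn_tag[pot_tag] = 1
    net.syn_tag[dep_tag] = -1

    # ---- excitability transients: a dendritic transient requires both the
    # branch calcium and the owner's somatic calcium to cross threshold
    if variant != "no_dendritic":
        crossed_d = (net.ca_branch > p.Theta_dend) & (
            net.ca_soma[net.dend_owner] > p.Theta_soma
        )
        net.t_exc_dend[crossed_d] = net.now_hours
    crossed_s = net.ca_soma > p.Theta_soma
    net.t_exc_soma[crossed_s] = net.now_hours

    # ---- weight commits over the PRP transient (asymmetric by default:
    # potentiation integrates the transient, depression is bounded)
    prp_peak = prp_transient(p.commit_time_min, p.Theta_PRP + 1.0, p)
    prp_pot = prp_exposure(p) if p.commit_mode == "exposure" else prp_peak
    prp_dep = prp_exposure(p) if p.depression_mode == "exposure" else prp_peak
    has_prp = net.ca_soma > p.Theta_PRP
    gate = (
        (np.abs(net.syn_tag) > p.tag_gate)
        & has_prp[neuron_of_syn]
        & (min(prp_pot, prp_dep) > p.prp_gate)
    )
    prp_of = np.where(net.syn_tag > 0, prp_pot, prp_dep)
    dw = np.where(gate, p.lr * prp_of * net.syn_tag, 0.0)
    new_w = np.clip(net.syn_w + dw, p.w_min, p.w_max)
    committed = new_w - net.syn_w
    pos = committed > 0
    was_pot = net.syn_pot.copy()
    net.syn_w = new_w
    net.syn_pot |= pos
    net.pot_by[memory_label] = pos
    net.newpot_by[memory_label] = pos & ~was_pot
    net.syn_tag[:] = 0
    return ensemble


def advance_time(net: LinkingNetwork, delta_hours: float) -> LinkingNetwork:
    """Advance the clock; relax weights homeostatically; refresh modulation."""
    if delta_hours < 0:
        raise ValueError("delta must be >= 0")
    if delta_hours == 0:
        return net
    plastic = (
        slice(None) if net.p.ff_plastic else np.flatnonzero(net.syn_kind != 1)
    )
    net.syn_w[plastic] = homeostatic_relax(
        net.syn_w[plastic],
        net.syn_neuron[plastic],
        net.n_exc,
        delta_hours,
        net.p,
    )
    net.now_hours += delta_hours
    net.refresh_modulation()
    return net


def recall_memory(
    net: LinkingNetwork,
    memory_label: str,
    cfg: ExperimentConfig,
    rng: np.random.Generator,
) -> frozenset:
    """Re-present a memory's input pattern with plasticity frozen.

    Returns the recall ensemble under the same rate threshold as
    encoding.  Weights, tags and excitability triggers are untouched.
    """
    if memory_label not in net.encoded:
        raise KeyError(f"memory {memory_label!r} was never encoded")
    p = net.p
    net.refresh_modulation(cfg.variant)
    _reset_stimulus_accumulators(net)
    rates = _simulate_stimulus(
        net, memory_label, p.recall_dur, rng, accumulate_calcium=False
    )
    thr = (cfg.ensemble_rate_threshold
           if cfg.ensemble_rate_threshold is not None else p.ff_threshold)
    return frozenset(np.flatnonzero(rates > thr).tolist())


def run_trial(
    cfg: ExperimentConfig, p: ModelParams, seed: int
) -> TrialResult:
    """One full linking trial: encode A, delay, encode B, delay, recall both."""
    rng = np.random.default_rng(seed)
    net = build_network(cfg, p, rng)
    assign_memory_inputs(net, "A", cfg, rng)
    assign_memory_inputs(net, "B", cfg, rng)
    enc_A = encode_memory(net, "A", cfg, rng)
    advance_time(net, cfg.interval_hours)
    enc_B = encode_memory(net, "B", cfg, rng)
    advance_time(net, cfg.recall_delay_h)
    rec_A = recall_memory(net, "A", cfg, rng)
    rec_B = recall_memory(net, "B", cfg, rng)
    for m in net.labels:
        net.pot_by.setdefault(m, np.zeros(net.syn_w.size, bool))
        net.newpot_by.setdefault(m, np.zeros(net.syn_w.size, bool))
    branch_pot = {
        m: np.bincount(net.syn_dend[net.pot_by[m]], minlength=net.n_dend)
        for m in net.labels
    }
    branch_newpot = {
        m: np.bincount(net.syn_dend[net.newpot_by[m]], minlength=net.n_dend)
        for m in net.labels
    }
    return TrialResult(
        ensembles={
            "encode_A": enc_A,
            "encode_B": enc_B,
            "recall_A": rec_A,
            "recall_B": rec_B,
        },
        pot_synapses={m: np.flatnonzero(net.pot_by[m]) for m in net.labels},
        newpot_synapses={m: np.flatnonzero(net.newpot_by[m]) for m in net.labels},
        branch_pot_counts=branch_pot,
        branch_newpot_counts=branch_newpot,
        n_exc=net.n_exc,
        seed=seed,
        params=p,
    )


def _trial_measures(trial: TrialResult) -> dict[str, OverlapSummary]:
    out = {
        "neuronal_encoding": ensemble_overlap_above_chance(
            trial.ensembles["encode_A"], trial.ensembles["encode_B"], trial.n_exc
        ),
        "neuronal_recall": ensemble_overlap_above_chance(
            trial.ensembles["recall_A"], trial.ensembles["recall_B"], trial.n_exc
        ),
        "branch_clusters": branch_cluster_overlap(trial),
        "new_clusters": new_clustered_synapse_overlap(trial),
    }
    return out


def run_linking_experiment(
    cfg: ExperimentConfig, p: ModelParams | None = None
) -> tuple[pd.DataFrame, list[TrialResult]]:
    """Run ``cfg.n_trials`` independent trials and tabulate overlap metrics.

    Returns a tidy DataFrame with one row per (trial, measure) and the
    raw per-trial results.  Trials use independent seeds derived from
    ``cfg.seed``.
    """
    p = p or ModelParams()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_trials)
    rows, trials = [], []
    for t, s in enumerate(seeds):
        trial = run_trial(cfg, p, int(s) % (2**31))
        trials.append(trial)
        for measure, summ in _trial_measures(trial).items():
            rows.append(
                {
                    "trial": t,
                    "interval": cfg.interval,
                    "variant": cfg.variant,
                    "measure": measure,
                    "observed_pct": summ.observed_pct,
                    "chance_pct": summ.chance_pct,
                    "above_chance": summ.above_chance,
                }
            )
    return pd.DataFrame(rows), trials
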