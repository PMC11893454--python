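"""State containers and single-step dynamics of the memory-allocation network.

The model neuron is a leaky integrate-and-fire soma with spike-rate
adaptation, coupled to independent dendritic subunits by a rectified
axial current.  Dendrites integrate conductance-based excitatory and
inhibitory impulses; every excitatory spike also deposits calcium scaled
by a voltage-dependent NMDA unblock sigmoid.  Strong stimulus-driven
calcium starts hours-long excitability transients (a double sigmoid in
elapsed time) that transiently raise dendritic gain and, at the soma,
modulate the adaptation increment.

Synaptic impulses are delta conductances, integrated exactly: an
excitatory spike of weight ``w`` maps the dendritic voltage to
``E_E + (V_d - E_E) * exp(-a_exc * g_E * w / C_d)`` (inhibition
analogously toward ``E_I``), which is the closed-form solution of the
conductance equation across the impulse and is stable for any total
conductance.  The same
convention is used by the vectorized engine in :mod:`linklab.protocol`;
the scalar operations here are the reference semantics and the unit the
fine-step ODE oracles check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "SynapseState",
    "DendriteState",
    "NeuronState",
    "calcium_increment",
    "excitability_level",
    "apply_excitability_modulation",
    "dendritic_voltage_step",
    "somatic_voltage_step",
]

BACKGROUND = "background"


@dataclass
class SynapseState:
    """One synapse: weight, tag, per-stimulus calcium and provenance."""

    w: float
    source: int = -1
    memory_label: str = BACKGROUND
    tag: int = 0                 # -1 depression, 0 none, +1 potentiation
    ca_in: float = 0.0           # calcium accumulated this stimulus
    potentiated: bool = False    # set on first positive weight commit


@dataclass
class DendriteState:
    """Dendritic subunit: voltage, branch calcium, gain and its transient."""

    V_d: float = 0.0
    ca_branch: float = 0.0
    a_exc: float = 1.0
    t_exc_dend: float | None = None   # trigger time of the X transient (hours)
    synapses: list[SynapseState] = field(default_factory=list)


@dataclass
class NeuronState:
    V: float = 0.0
    I_adapt: float = 0.0
    I_inh: float = 0.0
    ca_soma: float = 0.0
    t_exc_soma: float | None = None
    beta_adapt: float = 0.0
    refrac_left: float = 0.0
    spikes: list[float] = field(default_factory=list)
    dendrites: list[DendriteState] = field(default_factory=list)
    layer: int = 1
    cls: str = "excitatory"


def calcium_increment(V_d, p: ModelParams | None = None):
    """Voltage-dependent calcium influx per presynaptic spike.

    A logistic function of dendritic voltage modeling magnesium unblock
    of NMDA receptors: ``1 / (1 + exp(-s (V_d - m)) / d)`` with the
    published constants s=0.07, m=70 mV, d=9.  Monotone increasing,
    bounded in (0, 1).
    """
    p = p or _DEFAULTS
    V_d = np.asarray(V_d, dtype=float)
    if not np.all(np.isfinite(V_d)):
        raise ValueError("non-finite dendritic voltage in calcium_increment")
    out = 1.0 / (1.0 + np.exp(-p.ca_slope * (V_d - p.ca_mid)) / p.ca_div)
    return float(out) if out.ndim == 0 else out


def excitability_level(T_hours, p: ModelParams | None = None):
    """Excitability transient X(T): rises after ~1 h, decays by ~26 h.

    ``X(T) = 1/(1+e^{-3(T-1)}) - 1/(1+e^{-(T-26)})`` with T in hours
    since the calcium trigger.  Callers with no trigger should use
    X = 0 rather than calling this.
    """
    T = np.asarray(T_hours, dtype=float)
    if np.any(T < 0):
        raise ValueError("elapsed time must be >= 0")
    out = 1.0 / (1.0 + np.exp(-3.0 * (T - 1.0))) - 1.0 / (1.0 + np.exp(-(T - 26.0)))
    return float(out) if out.ndim == 0 else out


def _x_or_zero(trigger_time: float | None, now_hours: float) -> float:
    if trigger_time is None or now_hours < trigger_time:
        return 0.0
    return excitability_level(now_hours - trigger_time)


def apply_excitability_modulation(
    n: NeuronState, p: ModelParams, now_hours: float
) -> NeuronState:
    """Refresh a_exc and beta_adapt from the current excitability levels.

    Dendritic gain rises by ``a_exc_boost`` (10%) whenever X_dend > 0;
    the adaptation increment changes by ``beta_adapt_boost`` (28%)
    whenever X_soma exceeds ``x_soma_gate``.  The adaptation change is
    an increase by default (the printed direction); the
    ``soma_excitability_lowers_adaptation`` switch gives the opposite
    interpretation.
    """
    for d in n.dendrites:
        x = _x_or_zero(d.t_exc_dend, now_hours)
        d.a_exc = (
            p.a_exc_base * (1.0 + p.a_exc_boost)
            if x > p.x_dend_gate
            else p.a_exc_base
        )
    x_soma = _x_or_zero(n.t_exc_soma, now_hours)
    if x_soma > p.x_soma_gate:
        factor = (
            1.0 - p.beta_adapt_boost
            if p.soma_excitability_lowers_adaptation
            else 1.0 + p.beta_adapt_boost
        )
        n.beta_adapt = p.beta_adapt_base * factor
    else:
        n.beta_adapt = p.beta_adapt_base
    return n


def dendritic_voltage_step(
    d: DendriteState,
    exc_spikes: list[int],
    inh_weight: float,
    p: ModelParams,
    dt: float,
) -> DendriteState:
    """Advance one dendrite by dt given this step's presynaptic events.

    ``exc_spikes`` lists indices into ``d.synapses`` whose source fired
    this step; ``inh_weight`` is the summed weight of dendrite-targeting
    inhibitory spikes.  Leak relaxes V_d toward E_L; each excitatory
    impulse moves V_d toward E_E scaled by a_exc and the synaptic
    weight; inhibition pulls toward E_I (the ``eq1_literal_sign`` switch
    restores the printed, depolarizing sign).  Every excitatory spike
    deposits ``w * dCa(V_d)`` into the synapse and the branch calcium.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not math.isfinite(d.V_d):
        raise FloatingPointError(f"non-finite dendritic voltage {d.V_d}")
    d.V_d += dt * (-p.g_L_d * (d.V_d - p.E_L)) / p.C_d
    if exc_spikes:
        s_exc = sum(d.synapses[j].w for j in exc_spikes)
        # exact map for a delta conductance: exponential approach to E_E
        d.V_d = p.E_E + (d.V_d - p.E_E) * math.exp(
            -d.a_exc * p.g_E * s_exc / p.C_d
        )
    if inh_weight:
        if p.eq1_literal_sign:
            d.V_d -= (p.g_I * inh_weight / p.C_d) * (p.E_I - d.V_d)
        else:
            d.V_d = p.E_I + (d.V_d - p.E_I) * math.exp(-p.g_I * inh_weight / p.C_d)
    if exc_spikes:
        dca = calcium_increment(d.V_d, p)
        for j in exc_spikes:
            syn = d.synapses[j]
            syn.ca_in += syn.w * dca
            d.ca_branch += syn.w * dca
    if not math.isfinite(d.V_d):
        raise FloatingPointError("dendritic voltage diverged")
    return d


def somatic_voltage_step(
    n: NeuronState,
    inh_spike_count: float,
    p: ModelParams,
    dt: float,
    rng: np.random.Generator | None,
    t_ms: float = 0.0,
) -> NeuronState:
    """Advance the soma by dt (dendrites must already be updated).

    The axial current sums rectified dendro-somatic voltage gradients;
    the inhibitory current low-pass filters soma-targeting interneuron
    spikes; the noise current is uniform on [0, noise_max] (pass
    ``rng=None`` to disable).  Threshold crossing records a spike,
    increments the adaptation current by beta_adapt, deposits one unit
    of somatic calcium and holds the voltage refractory.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not math.isfinite(n.V):
        raise FloatingPointError(f"non-finite somatic voltage {n.V}")
    I_ax = sum(p.g_ax * max(d.V_d - n.V, 0.0) for d in n.dendrites)
    n.I_inh += dt * (-n.I_inh) / p.tau_inh
    if inh_spike_count:
        n.I_inh += p.g_inh * inh_spike_count
    I_noise = float(rng.uniform(0.0, p.noise_max)) if rng is not None else 0.0
    if n.refrac_left > 0:
        n.refrac_left = max(0.0, n.refrac_left - dt)
        n.V = p.V_reset
    else:
        n.V += dt * (
            -p.g_L * (n.V - p.E_L) + I_noise + I_ax - n.I_inh - n.I_adapt
        ) / p.C
    n.I_adapt += dt * (p.alpha_adapt * (n.V - p.E_L) - n.I_adapt) / p.tau_adapt
    if n.refrac_left == 0 and n.V >= p.V_th:
        n.spikes.append(t_ms)
        n.V = p.V_reset
        n.refrac_left = p.refractory
        beta = n.beta_adapt if n.beta_adapt else p.beta_adapt_base
        n.I_adapt += beta
        n.ca_soma += 1.0
    if not math.isfinite(n.V):
        raise FloatingPointError("somatic voltage diverged")
    return n


_DEFAULTS = ModelParams()
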