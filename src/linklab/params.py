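"""Model parameters and configuration for the memory-linking network.

All biophysical constants of the two-layer spiking network live in
:class:`ModelParams`.  Constants printed in the model description (the
NMDA calcium sigmoid, the tagging probabilities, the PRP transient, the
excitability double sigmoid, the stimulation protocol) are fixed here at
their published values; membrane constants, thresholds and network sizes
that the description defers to a supplementary table are free defaults,
chosen so the network operates with sparse stimulus-recruited ensembles,
and every one of them can be overridden from a YAML/JSON config.

Units: voltages mV, conductances nS, capacitances pF, currents pA,
times ms unless a field name says otherwise (hours, minutes, seconds).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ModelParams", "load_params"]


@dataclass
class ModelParams:
    # --- membrane / synapse biophysics (free defaults, config-exposed) ---
    C: float = 200.0            # somatic capacitance (pF)
    g_L: float = 25.0           # somatic leak conductance (nS)
    C_d: float = 50.0           # dendritic capacitance (pF)
    g_L_d: float = 5.0          # dendritic leak conductance (nS)
    E_L: float = 0.0            # resting potential (mV); 0 mV convention
    E_E: float = 70.0           # excitatory reversal (mV)
    E_I: float = -10.0          # inhibitory reversal (mV)
    g_E: float = 30.0          # maximal excitatory synaptic conductance (nS)
    g_I: float = 30.0           # maximal inhibitory synaptic conductance (nS)
    a_exc_base: float = 1.0     # dendritic excitability multiplier
    g_ax: float = 60.0          # axial conductance dendrite->soma (nS)
    g_bap: float = 150.0         # backpropagating-spike conductance into dendrites (nS)
    tau_adapt: float = 100.0    # adaptation time constant (ms)
    alpha_adapt: float = 2.0    # adaptation voltage coupling (nS)
    beta_adapt_base: float = 40.0   # adaptation increment per spike (pA)
    tau_inh: float = 10.0       # somatic inhibition filter constant (ms)
    g_inh: float = 60.0         # somatic inhibition jump per spike (pA)
    noise_max: float = 500.0    # uniform noise current maximum (pA)
    V_th: float = 15.0          # spike threshold (mV)
    V_reset: float = 0.0        # reset potential (mV)
    refractory: float = 2.0     # absolute refractory period (ms)
    dt: float = 0.5             # integration step (ms)

    # --- NMDA calcium sigmoid (published constants) ---
    ca_slope: float = 0.07
    ca_mid: float = 70.0
    ca_div: float = 9.0

    # --- calcium thresholds for excitability / PRP (free defaults) ---
    Theta_PRP: float = 40.0     # somatic spikes per stimulus (10 Hz x 4 s)
    Theta_dend: float = 10.0    # accumulated branch calcium (a.u.)
    Theta_soma: float = 40.0    # somatic spikes per stimulus

    # --- plasticity (published constants) ---
    p_ltp_base: float = 0.29
    p_ltp_slope: float = 0.5    # X_dend * N_s / 2
    p_ltp_nodend: float = 0.32
    ff_threshold: float = 10.0  # Hz; potentiation gate and ensemble criterion
    tag_gate: float = 0.1
    prp_gate: float = 0.1
    lr: float = 0.15            # weight update gain (dw = lr * PRP * tag)
    w_min: float = 0.0
    w_max: float = 1.0
    w_init: float = 0.3
    commit_time_min: float = 50.0   # consolidation commit time (minutes)
    # "exposure": integrate the per-second update over the whole PRP
    # transient (tagged weights saturate); "peak": single commit at the
    # transient's maximum (dw = +/- lr * e^-2).  Depression defaults to
    # the bounded peak commit: a saturating LTD would erase the whole
    # background/feedforward weight matrix at every stimulus.
    commit_mode: str = "exposure"
    depression_mode: str = "peak"
    # homeostatic scaling is slow relative to the one-week protocol; the
    # effective relaxation time of the per-neuron total is tau_H * w_init
    tau_H: float = 20000.0      # homeostatic scaling time constant (hours)
    mem_w_low: float = 0.16
    mem_w_high: float = 0.36

    # --- stimulation protocol (published) ---
    stim_dur: float = 4.0       # s
    stim_rate: float = 35.0     # Hz
    recall_dur: float = 2.0     # s (recall cue; procedure unspecified)

    # --- excitability modulation (published) ---
    a_exc_boost: float = 0.10   # a_exc +10% when X_dend > 0
    beta_adapt_boost: float = 0.28  # beta_adapt +28% when X_soma > 0.1
    x_soma_gate: float = 0.1
    # numerical gate for "X_dend > 0": the double sigmoid stays strictly
    # positive for all T > ~1 h, so a literal zero test would never end the
    # transient; 1e-3 closes the window by ~33 h (X(48 h) ~ 3e-10)
    x_dend_gate: float = 1e-3

    branch_cluster_k: int = 3   # >= 3 potentiated synapses per memory

    # --- sizes and wiring (free defaults, config-exposed) ---
    n_exc_l1: int = 60
    n_exc_l2: int = 60
    n_branches: int = 8
    n_bg_syn_per_branch: int = 5
    n_bg_sources: int = 60
    bg_rate: float = 0.0        # Hz, background input during any stimulus
    n_mem_sources: int = 20     # input units per memory
    n_mem_contacts: int = 210    # synapses per input unit
    n_ff_syn_per_branch: int = 2    # layer-1 -> layer-2 contacts per branch
    n_soma_inter: int = 10
    n_dend_inter: int = 10
    p_exc_to_inter: float = 0.5
    g_exc_to_inter: float = 60.0    # conductance per exc spike onto interneuron (nS)
    p_inter_to_exc: float = 0.5     # soma-targeting innervation probability
    p_inter_to_dend: float = 0.2    # dendrite-targeting innervation probability
    inter_V_th: float = 15.0
    inter_tau_m: float = 8.0        # ms

    # --- interpretation switches (see docs/methods.md) ---
    ff_plastic: bool = False    # feedforward layer-1->2 synapses frozen
    eq1_literal_sign: bool = False
    soma_excitability_lowers_adaptation: bool = True
    regular_input_trains: bool = False
    plasticity_enabled: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "C", "g_L", "C_d", "g_L_d", "tau_adapt", "tau_inh", "dt",
            "tau_H", "stim_dur", "stim_rate", "inter_tau_m",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (self.w_min <= 0 or self.w_min < self.w_init):
            raise ValueError("require w_min < w_init")
        if not (self.w_min < self.w_init < self.w_max):
            raise ValueError("require w_min < w_init < w_max")
        if not (self.mem_w_low < self.mem_w_high):
            raise ValueError("require mem_w_low < mem_w_high")
        if not (self.E_I <= self.E_L <= self.E_E):
            raise ValueError("require E_I <= E_L <= E_E")
        if self.refractory < 0 or self.noise_max < 0:
            raise ValueError("refractory and noise_max must be >= 0")
        sizes = [
            "n_exc_l1", "n_exc_l2", "n_branches", "n_bg_syn_per_branch",
            "n_bg_sources", "n_mem_sources", "n_mem_contacts",
            "n_soma_inter", "n_dend_inter",
        ]
        for name in sizes:
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def load_params(path: str | Path) -> ModelParams:
    """Load a ``model:`` section from a YAML or JSON config file.

    Unknown keys are rejected so typos cannot silently fall back to
    defaults.
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if doc is None:
        return ModelParams()
    section = doc.get("model", doc) if isinstance(doc, dict) else doc
    if not isinstance(section, dict):
        raise ValueError(f"config {path} does not contain a mapping")
    unknown = set(section) - _FIELDS
    if unknown:
        raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
    return ModelParams(**section)
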