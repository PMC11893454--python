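# Methods

`linklab` has two halves: a spiking network model of how two contextual
memories encoded close in time come to share neurons and dendritic
branches, and the statistics used to quantify such sharing in calcium
imaging and longitudinal spine-imaging data.  This note documents the
model, the interpretation decisions that were genuinely open, the
statistical estimators, what the synthetic-data generators do and do
not emulate, and the numerical choices.

## The linking network

### Architecture

Two layers of excitatory neurons (default 60 + 60), each a leaky
integrate-and-fire soma with spike-rate adaptation coupled to
independent dendritic subunits (default 8 per neuron) through a
rectified axial current `I_ax = Σ_i g_ax (V_d,i − V)+`.  Inhibition
comes from two interneuron classes: soma-targeting cells feed a
low-pass-filtered hyperpolarizing current `I_inh` (time constant
`tau_inh`), dendrite-targeting cells deliver conductance impulses that
pull dendritic voltage toward `E_I`.  A uniform noise current on
[0, 500] pA, redrawn each step, depolarizes all somata.

Each memory is a pool of input units (default 20) firing independent
Poisson trains at 35 Hz for 4 s during encoding; each unit contacts
random dendrites (default 210 contacts) with weights drawn uniformly
from [0.16, 0.36].  Background synapses exist on every branch at the
homeostatic reference weight and layer 1 additionally drives layer 2
through a fixed feedforward map.

Wiring defaults are deliberately homogeneous: inhibitory output is a
uniform pool per class, excitatory-to-interneuron wiring has fixed
in-degree, and feedforward partners are sampled without replacement per
layer-2 neuron.  This is a design choice, not an accident: quenched
wiring heterogeneity makes the same intrinsically favored neurons win
the competition for *every* memory, producing interval-independent
ensemble overlap that masks the excitability-driven linking the model
is about.  Overlap structure should come from where the memory inputs
land and from the activity-dependent mechanisms, so the quenched
variance is placed there.

### Dendritic nonlinearity and calcium

Synaptic impulses are delta conductances integrated exactly: a spike of
weight `w` maps `V_d ← E_E + (V_d − E_E) exp(−a_exc g_E w / C_d)`,
which is the closed-form solution across the impulse and is stable for
any conductance.  Every excitatory spike deposits calcium
`w · ΔCa(V_d)` into its synapse and branch, with the NMDA
magnesium-unblock sigmoid `ΔCa(V) = 1 / (1 + e^{−0.07 (V − 70)} / 9)`.

A somatic spike also depolarizes the spiking neuron's own dendrites
through a backpropagation conductance `g_bap`.  Without this
soma-to-dendrite coupling the printed equations leave branch calcium
independent of whether the neuron was recruited, and no mechanism can
make dendritic excitability or tagging selective for branches of
recruited neurons; with it, the calcium sigmoid reads out the
coincidence of presynaptic input and postsynaptic firing.

Somatic calcium is not given an explicit equation in the model
description; it is modeled as one unit per somatic spike, so the
thresholds `Theta_soma` and `Theta_PRP` (default 40 over a 4-s
stimulus) are spike-count equivalents of the 10 Hz criterion used
everywhere else.

### Excitability transients

When a stimulus ends, branches whose accumulated calcium crossed
`Theta_dend` *and* whose neuron's somatic calcium crossed `Theta_soma`
start an excitability transient; somatic crossing alone starts the
somatic transient.  The conjunctive branch gate is an interpretation
decision (the description couples the two thresholds in a single
sentence); the disjunctive reading triggers branches regardless of
recruitment, which again prevents any neuronal co-allocation.

The transient is the double sigmoid
`X(T) = 1/(1+e^{−3(T−1)}) − 1/(1+e^{−(T−26)})` in hours: ~0.5 at 1 h,
~1 between ~2 and ~24 h, ~0.5 at 26 h, and ~0 by 48 h.  Because the
expression stays *strictly* positive for every T beyond ~1 h
(asymptotically `e^{−(T−26)}`), a literal `X > 0` gate would never end
the dendritic boost; the implementation uses `X > 1e-3`, which closes
the window at ~33 h, consistent with treating X(48 h) as zero at that
tolerance.

While a dendritic transient is positive, that branch's gain rises by
10% (`a_exc`).  While the somatic transient exceeds 0.1, the neuron's
adaptation increment changes by 28%.  The printed direction is an
*increase* of `beta_adapt`, but increased adaptation suppresses exactly
the previously recruited neurons and inverts the phenomenon; the same
source describes memory formation as *increasing* somatic excitability.
The default is therefore a 28% *decrease*
(`soma_excitability_lowers_adaptation = True`), with the literal
reading available as a switch.

### Tagging and capture

After a stimulus, every synapse that received calcium is a plasticity
candidate.  On neurons that fired above 10 Hz, candidates are tagged
for potentiation with probability `min(1, 0.29 + X_dend · N_s / 2)`,
where `N_s` counts already-potentiated synapses on the same branch
(evaluated before this memory's commits); other candidates are tagged
for depression.  The `no_dendritic` ablation clamps `X_dend = 0` and
uses a flat probability 0.32.

If somatic calcium crossed `Theta_PRP`, a protein transient
`PRP(T) = ((T−20)/30) e^{−(T+10)/30}` (T in minutes, zero for T ≤ 20,
peak e⁻² at T = 50) gates weight commits `dw = 0.15 · PRP · tag` when
|tag| > 0.1 and PRP > 0.1.  Two readings of the commit are implemented:

* **exposure** (default for potentiation): the per-second update is
  integrated over the whole window in which PRP exceeds its gate.  The
  integral is large (~48 in weight units), so tagged weights saturate
  at their bounds — this is what makes "potentiated" a durable trace,
  engages the documented clipping to [0, 1], and supports co-recall.
* **peak**: a single commit of ±0.15·e⁻² ≈ ±0.02 at the transient's
  maximum.  Under this reading recall fidelity collapses to ~50–65%
  (a ±8% perturbation of a 0.26 weight cannot fix ensemble
  membership), which is why it is not the default.

Depression uses the bounded peak magnitude by default
(`depression_mode = "peak"`).  A saturating symmetric depression zeroes
~70% of all stimulus-active background/feedforward weights per memory,
silencing non-ensemble neurons for hours and producing a spurious,
excitability-independent 5-hour "linking" through the surviving
feedforward matrix (verified by running with all modulation disabled).
Weak depression alongside strong, protein-synthesis-gated potentiation
is also the standard reading of tagging-and-capture asymmetry.

Memories consolidate independently; there is no competition for
proteins.

### Homeostatic scaling and event-driven gaps

Between stimuli nothing spikes; excitability is evaluated in closed
form and weights follow
`dw_j/dt = (1/tau_H)(1 − Σ_j w_j / (w_init N_syn))` — an additive
drift, identical for every synapse of a neuron, relaxing the per-neuron
total toward `w_init · N_syn` with effective time constant
`tau_H · w_init`.  The solution is computed exactly, piecewise between
bound-pinning events.  The default `tau_H` (20 000 h) makes scaling
negligible within the one-week protocol: because the additive drift
redistributes any potentiation excess onto a neuron's *other* synapses,
a fast `tau_H` systematically weakens the second memory's inputs on
first-memory neurons and manufactures anti-linking at long intervals.

### Protocol, measures and ablations

A trial encodes memory A, idles 5 h / 2 d / 7 d, encodes memory B,
idles 2 d, then recalls both cues for 2 s each with plasticity frozen.
Ensembles are neurons above 10 Hz during the stimulus.  Reported
measures (all as (observed − chance)/chance with chance =
pct_A · pct_B / 100):

* neuronal overlap at encoding and at recall;
* overlap of branches holding ≥ 3 potentiated synapses per memory;
* overlap of branches gaining ≥ 3 *newly* potentiated synapses per
  memory.

`dendritic_separation` confines the two memories to disjoint halves of
the dendrite pool.  With default parameters and 10 matched trials the
model shows 5 h ≫ 2 d ≈ 7 d on all measures, loss of the recall
advantage without dendritic mechanisms, and loss of both encoding and
recall overlap under separation.  Because trials share derived seeds
across conditions, directional comparisons use paired Wilcoxon
signed-rank tests; the 2 d ≈ 7 d equivalences use unpaired two-sided
Mann-Whitney tests.

### Free parameters

The published description fixes the plasticity constants (0.29, 0.32,
0.15, the PRP and excitability transients, the calcium sigmoid, 10%
and 28% modulations, 0.16–0.36 input weights, w_init = 0.3, 35 Hz / 4 s
stimulation, the ≥ 3-synapse cluster criterion) but defers membrane
constants, thresholds, wiring and sizes to a supplementary table that
is not part of the available text.  Those are free parameters of this
implementation, chosen once so that stimuli recruit ~20% ensembles
above 10 Hz and the published modulation sizes act near the recruitment
threshold; all of them can be overridden from the YAML config (`model:`
section, unknown keys rejected).  Defaults are in
`linklab.params.ModelParams`.

## Imaging statistics

* **Session overlap** divides matched both-active ROIs by the *average*
  per-session active count, as is done for recorded ROIs.  The model
  metrics above divide by the population size instead, matching the
  chance formula's percentage algebra; the two conventions are kept
  deliberately distinct.
* **Context decoder**: sessions are resampled into time bins; the
  per-bin, per-cell feature is binary activity; a Bernoulli naive Bayes
  with Laplace smoothing (α = 1) is stratified-10-fold cross-validated
  and the pooled held-out scores for the first session's class give the
  AUC via the Wilcoxon–Mann–Whitney statistic.  Orientation is kept raw
  (no max(AUC, 1−AUC)).
* **Coactivity (PWC)**: Pearson correlations of 100-ms binned counts
  (counts, not re-binarized; a switch re-binarizes).  Stability removes
  pairs with footprint overlap or centroid distance ≤ 20 px, then
  averages the correlation of upper-triangle vectors over 1000 random
  10-cell subsamples.  Zero-variance cells propagate as NaN and are
  dropped pairwise, never imputed.
* **Connectivity distance**: Euclidean norm of the difference of
  upper-triangle vectors, optionally after dropping the top decile of
  cells by rate from both maps.
* **ROI clustering**: traces sparsified at mean + 3 SD; pairwise
  Pearson correlations double-thresholded (> 0.7, or > 2.5 SD above the
  mean of *either* ROI's coefficients — the per-ROI criterion is
  symmetrized by OR because cosine/WPGMA require symmetry); cosine
  similarity between rows of the thresholded matrix; WPGMA
  agglomeration (scipy `linkage(method="weighted")`) on 1 − cosine.
  The cutoff grid is 0.01–0.50.  Calibration circularly rotates every
  trace by an independent offset, re-runs the full pipeline (thresholds
  recomputed per shuffle), and takes the largest cutoff at which fewer
  than 5% of shuffles yield any multi-ROI cluster; on shuffled data any
  ≥ 2-ROI cluster counts as inaccurate, since rotation destroys all
  true coupling.
* **Spine statistics**: clustering uses strict < 5 µm along-dendrite
  distance on the same segment.  The chance-clustering null redraws
  each dendrite's new-spine count at uniform positions, averages the
  clustered percentage per animal, 1000×.  Cross-session dependence of
  per-segment addition counts uses Spearman's rho (average ranks for
  ties) and plug-in mutual information on integer counts capped at 4+
  (per-segment additions are small integers), each against 10 000
  permutations of the second session's counts; permutation p-values use
  the add-one rule (b+1)/(n+1); MI significance is z > 2 against the
  permutation null.  Correlation pairs are compared by Fisher
  z-transformation with a one-tailed p in the direction of the observed
  sign.  Co-allocation measures the percentage of first-transition
  clustered spines sitting on segments that also gained clustered
  spines in the next transition; the null redistributes each segment's
  clustered-spine *group* as a unit over the same animal's segments
  (clustered spines are co-located by definition, so independent
  redistribution understates the null variance).  Nearest-neighbor
  co-clustering excludes segments without eligible earlier spines by
  default, or substitutes the segment length for the distance in
  fallback mode.  Condition comparisons subsample 40 dendrites per
  condition 10 000× with p = fraction of repetitions where
  experimental − control < 0.  The colocalization module implements
  only the enrichment arithmetic
  (chance = (gfp/roi)(arc/roi); enrichment = (overlap/roi)/chance).

## Synthetic data

The generators provide the statistical structure the estimators assume
plus the ground truth to score them, at the recorded data's scale
(~130 cells per 10-min session at 15.5 Hz; 45 dendritic segments).

* **Sessions**: log-normal event rates; per-session ensembles with
  condition-dependent reactivation (defaults 0.85 linked / 0.60
  independent, +0.12 for the most active decile); log-rate persistence
  0.8 in the linked condition; latent coactivity modules whose members
  adopt a shared event train; Bernoulli events per frame.  Events are
  not spike-shaped calcium — everything downstream of deconvolution is
  out of scope, so binarized events are the generator's native
  currency.  An exchangeable-pair generator shares rates exactly
  between two sessions for decoder chance-level checks.
* **ROI traces**: cluster members share a latent transient train
  (Poisson events, exponential decay) plus independent Gaussian noise
  scaled so the expected within-cluster correlation equals the
  configured value.
* **Spine maps**: per-transition addition counts are Poisson with rate
  proportional to segment length (a homogeneous-rate switch exists
  because the shared length effect is itself a real cross-transition
  dependence, which must be absent when calibrating nulls); the
  designated transition pair follows a Gaussian copula whose
  correlation is calibrated numerically so the *counts'* Spearman
  correlation equals `rho_co`; clustered placement with probability
  `pi_clust`; optional co-allocation bias toward previously gaining
  segments; Bernoulli eliminations.

What passing tests on these generators show is that the estimators
recover planted structure and hold their nominal error rates under the
generators' assumptions (independent noise, stationary rates, exact
cell/segment identity across sessions).  They do not certify behavior
under real-data pathologies: registration errors, demixing cross-talk
beyond the modeled nearby-pair exclusion, non-stationary behavior
within a session, or spine-scoring ambiguity.

## Numerical choices and problem sizes

Integration uses dt = 0.5 ms with synchronous updates and a one-step
delay on recurrent pathways; impulse conductances use the exact
exponential map; the state is validated finite after every stimulus.
Inter-stimulus gaps are event-driven (closed-form excitability and
homeostatic evaluation; nothing spikes in the gap).  The test suite
runs the full linking battery at the default 120-neuron network with
10 trials per condition, decoder checks on 10-minute 100-cell sessions
over 20 seeds, null calibrations at 1000 permutations over 200 count
datasets and 40 resampling datasets at 300 repetitions, and recovery
checks over 50 (counts) and 20 (ROI) seeds — sizes chosen to keep the
whole suite in the tens of minutes while leaving every comparison
well-powered.

## Known limitations

* The model is a minimal two-layer caricature: no conductance-based
  interneuron diversity, no structural spine turnover (new synapses are
  modeled as newly *potentiated* background/memory synapses), no
  within-branch spatial resolution, and branch-level (not spine-level)
  cluster counting.
* Several interpretation switches change quantitative behavior
  (`commit_mode`, `depression_mode`, `eq1_literal_sign`,
  `soma_excitability_lowers_adaptation`); the defaults are the readings
  under which the model functions, and each switch preserves the
  literal alternative.
* The shuffle-calibrated ROI cutoff depends on the dataset's size and
  correlation structure; on small synthetic datasets the calibrated
  cutoff often sits at the top of the grid because shuffled data are
  almost never mergeable below it.
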