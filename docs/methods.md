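# Methods

## Network model

The simulated circuit is a feed-forward projection from 100 CA3/2 sources to
100 CA1 targets. CA3/2 neurons are not integrated; they are independent
homogeneous Poisson processes at r = 10 Hz. Connectivity is bouton-centric:
each source neuron owns 12 boutons, 5 assigned to stratum oriens (SO) and 7
to stratum radiatum (SR). A bouton carries α active zones, α ∈ {1..5}; every
active zone synapses onto one CA1 neuron, drawn uniformly and — a modelling
choice, since MSB contacts are observed on different cells — without
replacement within a bouton. There are no inhibitory neurons and no
recurrence.

Active-zone counts are sampled per stratum. The empirical per-α proportions
are only available graphically, so the defaults are fixed to satisfy the
published aggregate constraints: SO uses P(1..5) = (0.55, 0.18, 0.12, 0.10,
0.05), giving P(α≥2) = 0.45 (the MSB fraction in SO) and P(α≥4) = 0.15; SR
keeps the SO multi-AZ shape rescaled by 5/9, giving P(α≥2) = 0.25. Both are
overridable in configuration.

Each bouton draws one release probability p from Gamma(shape 2, scale 0.15),
clipped (not resampled) at 1; expected value ≈ 0.3. All active zones of a
bouton share p, but each transmits an *independent* Bernoulli thinning of the
source train — identical reliability, different realisations. Each bouton is
facilitating or depressing; all its active zones inherit that identity, while
the dynamic STP state evolves per active zone, driven by that zone's own
transmitted train (the shared-bouton statement is read as shared identity and
parameters, not a shared trajectory). The default assignment is an
independent fair coin per bouton (the published proportion is not stated);
the `matched` scheme instead pairs high p with depression and low p with
facilitation, split at the median of the sampled p values.

Experiment-grid conditions: the four full-model wiring conditions (SSB
everywhere; MSBs in SO only; in SR only; everywhere); three single-mechanism
controls in which each source contributes either 5 single-AZ boutons (SSB
scenario) or 1 five-AZ bouton (MSB scenario) — *multiplicative only* (full
stratified wiring, p = 1, no STP), *release only* (Gamma p, no STP), *STP
only* (p = 1, STP on); and the matched-p/STP variant of the full model.

## Neuron and synapse dynamics

CA1 neurons are current-based leaky integrate-and-fire units: τ_m = 60 ms,
R = 1 GΩ, threshold 20 mV, reset 10 mV, absolute refractory period 2 ms.
Background input is Gaussian, mean 12 pA, SD 20 pA; the discretisation is not
prescribed by the model statement, so a fresh value is drawn and held for
each 1 ms update interval (configurable; results are mildly sensitive to this
interval since it sets the effective noise bandwidth). Without STP a
transmitted spike injects an exponential postsynaptic current of amplitude
A = 200 pA and decay τ_syn = 1.5 ms.

Plastic synapses follow the Tsodyks–Markram three-state resource model:
fractions x (recovered), y (active), z (inactive) with x + y + z = 1, and
utilisation u. Between spikes, y decays with τ_syn, z recovers to x with
τ_rec and u decays with τ_fac; at a spike u is updated first,
u ← u + U(1 − u), then the release u·x moves from x to y (the canonical
update order; the delta-function notation is ambiguous). τ_fac = 0 is
treated as instantaneous decay, i.e. u = U at every spike. Presets:
facilitating A = 1540 pA, U = 0.03, τ_rec = 130 ms, τ_fac = 530 ms;
depressing A = 250 pA, U = 0.5, τ_rec = 800 ms, τ_fac = 0 ms. The
postsynaptic current is A·y, so each transmitted spike contributes a PSC of
amplitude A·u·x with decay τ_syn.

### Integration

All inter-event dynamics here are linear, so no ODE solver is used:

* Per active zone, STP releases are computed event-by-event with the exact
  closed-form solution of the (x, y, z, u) system between transmitted spikes.
* The membrane and the summed synaptic current are advanced on a fixed
  dt = 0.1 ms grid with exact exponential propagators (the standard treatment
  for LIF neurons with exponential currents); transmitted spikes arrive as
  amplitude increments on the grid after a uniform 1 ms synaptic delay
  (delay unstated in the model; configurable). A single PSC therefore matches
  A·exp(−t/τ_syn) at step boundaries to machine precision, and the only
  discretisation error is locating threshold crossings on the grid (the test
  suite checks the constant-current firing period against the closed form
  T = t_ref + τ_m ln((RI − V_reset)/(RI − V_th)) to within one step).
* Initial conditions: V(0) = 0, STP state (x, y, z, u) = (1, 0, 0, 0). The
  analysis window drops the first second of every run, absorbing the
  transient.

The membrane loop is compiled with numba; a full 51 s, 100-neuron run
integrates in well under a second.

### Synchrony readout

Spike trains from the analysis window (the last 50 s of a 51 s run at full
scale) are binned into half-open 20 ms bins; μ_cc is the mean Pearson
correlation over all n(n−1)/2 distinct pairs. Pairs in which either train
has zero variance are undefined; they are excluded from the mean and counted
(an all-excluded run reports μ_cc as missing, not 0). Each run of a
condition redraws connectivity, source trains and noise from a child seed of
the condition's master seed — runs are fully independent realisations (a
`fixed_graph` flag reuses one graph for sensitivity analysis). Seeds derive
from `numpy.random.SeedSequence`, so any master seed reproduces every run
bit-for-bit.

### Scales used by the test suite

Full published scale is 100 runs of 51 s per condition. The test suite
exercises the complete grid at reduced scale — 20 runs of 11 s with a 10 s
analysis window for the MSB-vs-SSB ordering checks, and 2 runs of 2 s for
enumeration/determinism checks — chosen so the whole suite runs in about a
minute while the orderings remain far outside run-to-run noise. The
`msb suite` command runs the full scale.

## Morphometrics

**Variance comparison.** For a chosen measure (spine volume, PSD area, AZ
area), one unbiased (n−1 denominator; the denominator is a package choice)
sample variance is computed per MSB with 2–5 contacts. The comparison group
chops the SSB contacts of each dendrite, ordered by position, into
consecutive non-overlapping runs whose lengths are drawn from the empirical
MSB contact-count histogram, so group sizes match the MSBs; leftover contacts
are unused, and a fixed-size grouping is available as an option. Data from
all animals/tables are pooled. The two variance populations are contrasted
with:

* **Cliff's delta**, computed exactly over all pairs (a rank-based path is
  used above 4×10⁶ pairs);
* a **two-sided permutation test** on the mean difference (a pooled t
  statistic is available), 5000 reshuffles, add-one correction
  p = (1 + #extreme)/(n_perm + 1);
* a **BCa bootstrap CI** for the difference (median or mean), 5000 resamples
  drawn independently per group, bias correction from the bootstrap CDF at
  the observed statistic and acceleration from delete-one jackknife skewness;
  degenerate bootstrap or jackknife distributions fall back to the percentile
  interval with a warning;
* **Ryan–Holm step-down levels** for families of comparisons: rank-k of m
  gets confidence level 1 − α/(m − k + 1), with the dual Holm p-value
  adjustment.

**Dendrite self-proximity.** A traced arbor (SWC) is decomposed into maximal
unbranched segments and resampled at constant 0.5 μm arc-length spacing. For
each node, the analysis counts distinct *other* segments having at least one
node within 5 μm Euclidean distance — but ignores nodes closer than 5 μm
*along the tree*, so the smooth continuation of a path across a branch point
does not count as a separate nearby branch (both radii configurable; the
path-exclusion radius defaults to the Euclidean threshold). Nodes are sorted
by path distance to the soma and split into 10 equal-count bins; the per-bin
mean count is reported.

## Synthetic generators

**Synapse tables.** Bouton i draws α_i from the configured active-zone-count
distribution and a bouton-level log-factor shared by its contacts; contact j
adds an independent residual of log-SD σ_w. σ_b parameterises the *total*
log-SD of a measure across the population, so the shared factor carries
variance σ_b² − σ_w² (σ_w ≤ σ_b required) and the within-bouton intraclass
correlation is 1 − σ_w²/σ_b². This parameterisation makes σ_w = σ_b the
exact null of the variance comparison — the bouton factor vanishes and
within-MSB groups are statistically identical to across-bouton groups —
which is what the calibration tests assert. The three measures are
equicorrelated (default ρ = 0.6) at both levels via a shared latent.
Defaults: 200 boutons, σ_w = 0.35, σ_b = 0.80, log-means set to plausible
values (median spine volume 0.04 μm³, PSD 0.05 μm², AZ 0.06 μm²); lognormal
marginals because synaptic size distributions are right-skewed. Bouton
volume is 0.1·α^γ μm³ (γ = 1) times lognormal noise, so volume grows with
contact count. Contacts are placed uniformly on 20 dendrites. The generator
emulates the *relational* structure only — shared bouton factors, size
scaling, stratified α — not absolute empirical distributions; passing tests
demonstrate the pipeline recovers planted structure, not that real tissue
has it.

**Neurite trees.** Five primary branches leave a soma at the origin with
directions drawn uniformly inside a 40° half-angle cone around a common
axis, wander with small angular noise clamped to the cone, and split with
probability 0.008 per μm grown (daughters diverge); growth stops at 120 μm
of path length. Nodes are laid down every 0.5 μm, so emitted trees are
already at constant spacing. The construction makes branches spread apart
with distance, so self-proximity counts decrease from proximal to distal
bins — the qualitative shape the analysis is designed to quantify. Real
arbors differ in many ways the generator does not attempt (taper, tortuosity,
tropism, realistic branch-order statistics).

## Known limitations

* The per-α probabilities of the default distributions reproduce the printed
  aggregate fractions, not the (graphical-only) empirical histogram.
* Noise discretisation, synaptic delay and integration step are package
  choices (1 ms, 1 ms, 0.1 ms) — the reference values are not stated; all
  three are configurable.
* μ_cc magnitudes depend on these choices and on run length; the package's
  claims about MSB wiring are the *orderings* between conditions, which are
  robust across the scales tested.
* The permutation test assumes exchangeability under the null; variance
  groups sharing a dendrite are treated as independent observations, as in
  the original analysis design.
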