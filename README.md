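# msbnet

Multi-synaptic boutons (MSBs) are single presynaptic terminals in the
hippocampus that form active zones onto dendritic spines of *several
different* CA1 pyramidal neurons, rather than the canonical one-bouton /
one-spine arrangement (SSBs). In the stratum oriens nearly half of all
boutons are MSBs. `msbnet` asks, in simulation, what this wiring motif does
to the CA1 population, and provides the estimation statistics used to compare
synaptic morphology within and across boutons.

The package has three parts:

1. **Network model and simulation** — a CA3/2 → CA1 feed-forward spiking
   network. CA3/2 sources are independent 10 Hz Poisson trains; each source
   owns 12 boutons (5 to stratum oriens, 7 to stratum radiatum), each bouton
   carries α ∈ {1..5} active zones targeting distinct CA1 neurons, a release
   probability p ~ Gamma(k=2, θ=0.15) clipped at 1 shared by its active
   zones, and a facilitating or depressing short-term-plasticity (STP)
   identity. CA1 neurons are leaky integrate-and-fire units,

       τ_m dV/dt = −V + R (I_b + I_syn),      I_syn(i) = Σ_j A y_ij(t),

   with exponential postsynaptic currents and Tsodyks–Markram three-state
   STP (recovered x, active y, inactive z, utilisation u). Synchrony is
   summarised by μ_cc, the mean Pearson correlation over all distinct pairs
   of CA1 spike trains binned at 20 ms over the analysis window. The
   experiment grid contrasts SSB-only wiring against MSB wiring, overall and
   for each mechanism in isolation (multiplicative connectivity, shared
   release probability, shared STP identity, and STP matched to p).

2. **Morphometrics** — given a per-contact synapse table (spine volume, PSD
   area, active-zone area), compares the variance of measures *within* each
   MSB against size-matched groups of neighboring SSBs on a dendrite, using
   Cliff's delta, a two-sided label-permutation test (5000 reshuffles), a
   bias-corrected and accelerated (BCa) bootstrap CI (5000 samples), and
   Ryan–Holm step-down adjustment across comparisons. A companion analysis
   resamples traced dendritic arbors (SWC) at 0.5 μm and counts, per node,
   the separate branches within 5 μm — how often an arbor comes close to
   itself, binned by distance to the soma.

3. **Synthetic data** — generators for synapse tables (bouton-shared
   lognormal factors with known within/between log-SDs) and fanned dendritic
   trees, so every analysis is testable against ground truth without any
   imaging data.

## Worked example: does MSB wiring synchronise CA1?

```python
import numpy as np
from msbnet import network as net, correlation as corr

spec = net.NetworkSpec(sim_duration=11.0, analysis_window=10.0)
conds = {c.name: c for c in corr.EXPERIMENT_CONDITIONS}
for name in ("full_ssb_all", "full_msb_all"):
    res = corr.run_condition(spec, conds[name], n_runs=10, master_seed=1)
    print(f"{name}: mean mu_cc = {res.mean():.4f} (sd {res.mu_cc.std(ddof=1):.4f})")
```

prints

```
full_ssb_all: mean mu_cc = 0.0048 (sd 0.0015)
full_msb_all: mean mu_cc = 0.0141 (sd 0.0021)
```

i.e. with every stratum wired through MSBs the mean pairwise correlation of
CA1 spike trains roughly triples relative to the SSB-only network — boutons
that contact several CA1 neurons inject shared, identically-filtered input
into all of them.

## Worked example: are contacts of one MSB more alike?

```python
import numpy as np
from msbnet.synthetic import SynapseGenParams, generate_synapse_table
from msbnet.morphometrics import compare_msb_ssb_variances

table = generate_synapse_table(SynapseGenParams(n_boutons=200, seed=3))
res = compare_msb_ssb_variances(table, "spine_volume_um3",
                                np.random.default_rng(3))
print(f"Cliff's delta = {res.cliffs_delta:.3f}")
print(f"permutation p = {res.permutation_p:.4f}")
print(f"95% BCa CI: [{res.bootstrap.low:.4f}, {res.bootstrap.high:.4f}]")
```

prints

```
Cliff's delta = -0.431
permutation p = 0.0012
95% BCa CI: [-0.0019, -0.0004]
```

The generator plants a shared bouton-level factor (within-bouton log-SD 0.35
vs 0.80 across boutons); the pipeline recovers it: within-MSB spine-volume
variances are stochastically smaller than the variances of size-matched
neighboring-SSB groups (negative delta, CI separated from zero).

## Command line

```sh
msb build --condition msb_all --seed 7 -o graph.tsv
msb simulate --graph graph.tsv --duration 51 --seed 3 -o spikes.h5
msb suite --runs 100 --seed 11 -o results.tsv
msb synth table --n-boutons 500 --seed 1 -o synapses.tsv
msb synth tree --seed 2 -o cell.swc
msb morph variance --table synapses.tsv --measure psd_area_um2 -o result.json
msb morph proximity --swc cell.swc -o bins.tsv
```

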