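"""Spike-train synchrony analysis and the simulation experiment grid.

The synchrony readout is mu_cc: CA1 spike trains from the analysis window are
binned at 20 ms, Pearson's correlation coefficient is computed for every
distinct pair of neurons, and mu_cc is the mean over all defined pairs.  One
simulation run yields one mu_cc; an experimental condition is characterised by
the distribution of mu_cc over independent runs.

Conditions cover the full model (all four SSB/MSB stratum combinations), the
three single-mechanism controls (multiplicative connectivity, shared release
probability, shared STP identity) and the variant in which STP identity is
matched to release probability (high p -> depressing, low p -> facilitating).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as net
from .dynamics import (NeuronParams, NoiseParams, SpikeTrains,
                       generate_poisson_trains, simulate_ca1)

__all__ = [
    "BinnedTrains",
    "CorrelationResult",
    "Condition",
    "ExperimentResult",
    "bin_spike_trains",
    "mean_pairwise_correlation",
    "build_graph_for_condition",
    "run_condition",
    "run_experiment_suite",
    "EXPERIMENT_CONDITIONS",
]

DEFAULT_BIN_MS = 20.0
DEFAULT_RATE_HZ = 10.0


@dataclass
class BinnedTrains:
    counts: np.ndarray       # (n_neurons, n_bins) spike counts
    bin_ms: float
    window: tuple            # (start_s, end_s)


@dataclass
class CorrelationResult:
    matrix: np.ndarray       # pairwise Pearson r, NaN where undefined
    mu_cc: float             # mean over defined distinct pairs (NaN if none)
    n_pairs: int             # number of pairs entering mu_cc
    excluded_pairs: int      # pairs undefined because a train had zero variance

    @property
    def degenerate(self) -> bool:
        return self.n_pairs == 0


def bin_spike_trains(trains: SpikeTrains, bin_ms: float = DEFAULT_BIN_MS,
                     window: tuple | None = None) -> BinnedTrains:
    """Bin each train into half-open bins [t, t + bin) inside ``window``.

    Spikes at exactly the window start fall in the first bin; spikes at or
    beyond ``start + n_bins * bin`` are dropped.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    t0, t1 = (0.0, trains.duration) if window is None else window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    bin_s = bin_ms / 1000.0
    n_bins = int(np.floor((t1 - t0) / bin_s + 1e-9))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    counts = np.zeros((trains.n, n_bins), dtype=np.int64)
    for i, t in enumerate(trains.trains):
        idx = np.floor((np.asarray(t) - t0) / bin_s).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts[i] = np.bincount(idx, minlength=n_bins)
    return BinnedTrains(counts, bin_ms, (t0, t1))


def mean_pairwise_correlation(binned: BinnedTrains) -> CorrelationResult:
    """Pearson r for every distinct pair of binned trains and their mean.

    Pairs in which either train has zero variance (silent or constant) have an
    undefined correlation; they are excluded from mu_cc and counted.
    """
    x = binned.counts
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two neurons")
    var = x.var(axis=1)
    valid = var > 0
    matrix = np.full((n, n), np.nan)
    np.fill_diagonal(matrix, 1.0)
    nv = int(valid.sum())
    if nv >= 2:
        sub = np.corrcoef(x[valid].astype(float))
        ii = np.where(valid)[0]
        matrix[np.ix_(ii, ii)] = sub
        np.fill_diagonal(matrix, 1.0)
        vals = sub[np.triu_indices(nv, k=1)]
        mu = float(np.mean(vals))
        n_pairs = len(vals)
    else:
        mu = float("nan")
        n_pairs = 0
    total_pairs = n * (n - 1) // 2
    return CorrelationResult(matrix, mu, n_pairs, total_pairs - n_pairs)


@dataclass(frozen=True)
class Condition:
    """One experiment-grid cell: mechanism, wiring and STP scheme."""

    name: str
    mechanism: str = "full"            # full | multiplicative_only | release_only | stp_only
    connectivity: str = net.SSB_ALL    # full/multiplicative: ssb_all..msb_all
    msb: bool = False                  # release/stp variants: 1x5 AZ vs 5x1
    stp_scheme: str = net.INDEPENDENT  # independent | matched | none

    @property
    def stp_on(self) -> bool:
        return self.mechanism in ("full", "stp_only")


EXPERIMENT_CONDITIONS = (
    # full model, four wiring conditions
    Condition("full_ssb_all", "full", net.SSB_ALL),
    Condition("full_msb_so", "full", net.MSB_SO),
    Condition("full_msb_sr", "full", net.MSB_SR),
    Condition("full_msb_all", "full", net.MSB_ALL),
    # single-mechanism controls, SSB vs MSB each
    Condition("multiplicative_only_ssb", net.MULTIPLICATIVE_ONLY, net.SSB_ALL),
    Condition("multiplicative_only_msb", net.MULTIPLICATIVE_ONLY, net.MSB_ALL, msb=True),
    Condition("release_only_ssb", net.RELEASE_ONLY),
    Condition("release_only_msb", net.RELEASE_ONLY, msb=True),
    Condition("stp_only_ssb", net.STP_ONLY),
    Condition("stp_only_msb", net.STP_ONLY, msb=True),
    # full model with STP identity matched to release probability
    Condition("matched_ssb_all", "full", net.SSB_ALL, stp_scheme=net.MATCHED),
    Condition("matched_msb_all", "full", net.MSB_ALL, stp_scheme=net.MATCHED),
)


def build_graph_for_condition(
    spec: net.NetworkSpec,
    cond: Condition,
    rng: np.random.Generator,
    so_dist: net.AZCountDistribution | None = None,
    sr_dist: net.AZCountDistribution | None = None,
) -> net.ConnectivityGraph:
    if cond.mechanism == "full":
        graph = net.build_connectivity(spec, cond.connectivity, so_dist, sr_dist, rng)
        net.sample_release_probabilities(graph, rng=rng)
        net.assign_stp_types(graph, cond.stp_scheme, rng=rng)
        graph.condition = cond.name
        return graph
    if cond.mechanism == net.MULTIPLICATIVE_ONLY:
        graph = net.build_mechanism_variant(spec, net.MULTIPLICATIVE_ONLY, cond.msb,
                                            so_dist, sr_dist, rng)
    elif cond.mechanism in (net.RELEASE_ONLY, net.STP_ONLY):
        graph = net.build_mechanism_variant(spec, cond.mechanism, cond.msb,
                                            so_dist, sr_dist, rng,
                                            stp_scheme=cond.stp_scheme
                                            if cond.mechanism == net.STP_ONLY
                                            else net.NONE)
    else:
        raise net.ConfigurationError(f"unknown mechanism {cond.mechanism!r}")
    graph.condition = cond.name
    return graph


@dataclass
class ExperimentResult:
    condition: str
    mu_cc: np.ndarray        # one value per run (NaN where degenerate)
    excluded_pairs: np.ndarray
    seeds: list

    @property
    def n_runs(self) -> int:
        return len(self.mu_cc)

    def mean(self) -> float:
        return float(np.nanmean(self.mu_cc))


def run_condition(
    spec: net.NetworkSpec,
    cond: Condition,
    n_runs: int,
    master_seed,
    rate_hz: float = DEFAULT_RATE_HZ,
    bin_ms: float = DEFAULT_BIN_MS,
    neuron: NeuronParams | None = None,
    noise: NoiseParams | None = None,
    fixed_graph: bool = False,
    so_dist: net.AZCountDistribution | None = None,
    sr_dist: net.AZCountDistribution | None = None,
) -> ExperimentResult:
    """Run ``n_runs`` independent end-to-end simulations of one condition.

    Each run draws a fresh connectivity graph (unless ``fixed_graph``), fresh
    CA3/2 Poisson trains and fresh noise from a child seed derived
    deterministically from ``master_seed``, then reports the run's mu_cc over
    the analysis window (the last ``spec.analysis_window`` seconds).
    """
    ss = (master_seed if isinstance(master_seed, np.random.SeedSequence)
          else np.random.SeedSequence(master_seed))
    children = ss.spawn(n_runs)
    window = (spec.sim_duration - spec.analysis_window, spec.sim_duration)
    mus = np.empty(n_runs)
    excl = np.empty(n_runs, dtype=int)
    graph = None
    for r in range(n_runs):
        rng = np.random.default_rng(children[r])
        if graph is None or not fixed_graph:
            graph = build_graph_for_condition(spec, cond, rng, so_dist, sr_dist)
        ca3 = generate_poisson_trains(spec.n_ca3, rate_hz, spec.sim_duration, rng)
        ca1 = simulate_ca1(graph, ca3, neuron=neuron, noise=noise,
                           stp_on=cond.stp_on, dt=spec.dt, rng=rng)
        res = mean_pairwise_correlation(bin_spike_trains(ca1, bin_ms, window))
        mus[r] = res.mu_cc
        excl[r] = res.excluded_pairs
    return ExperimentResult(cond.name, mus, excl, [c.entropy for c in children])


def run_experiment_suite(
    spec: net.NetworkSpec,
    n_runs: int = 100,
    master_seed: int = 0,
    conditions: tuple = EXPERIMENT_CONDITIONS,
    **kwargs,
) -> pd.DataFrame:
    """Run the whole experiment grid; returns a tidy per-run results table.

    Columns: condition, run, mu_cc, excluded_pairs.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(conditions))
    frames = []
    for cond, child in zip(conditions, children):
        res = run_condition(spec, cond, n_runs, child, **kwargs)
        frames.append(pd.DataFrame({
            "condition": cond.name,
            "run": np.arange(n_runs),
            "mu_cc": res.mu_cc,
            "excluded_pairs": res.excluded_pairs,
        }))
    return pd.concat(frames, ignore_index=True)


def summarize_suite(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition summary (mean, SD, quantiles) of mu_cc."""
    g = table.groupby("condition", sort=False)["mu_cc"]
    out = g.agg(mean="mean", sd="std",
                q025=lambda s: s.quantile(0.025),
                median="median",
                q975=lambda s: s.quantile(0.975))
    return out.reset_index()
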