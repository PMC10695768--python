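"""CA3/2 -> CA1 connectivity construction.

The hippocampal stratum oriens contains a large fraction of multi-synaptic
boutons (MSBs): single presynaptic boutons whose several active zones contact
spines of *different* CA1 pyramidal neurons.  This module builds the
bouton-centric wiring used by the network simulation: each CA3/2 source neuron
owns a fixed number of boutons split between stratum oriens (SO) and stratum
radiatum (SR); each bouton carries 1-5 active zones, a release probability and
a short-term-plasticity identity shared by all of its active zones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "NetworkSpec",
    "AZCountDistribution",
    "Bouton",
    "ActiveZone",
    "ConnectivityGraph",
    "sample_az_counts",
    "build_connectivity",
    "sample_release_probabilities",
    "assign_stp_types",
    "build_mechanism_variant",
    "write_graph",
    "read_graph",
    "load_network_spec",
]

# connectivity conditions (Fig-4-style experiment labels)
SSB_ALL = "ssb_all"
MSB_SO = "msb_so"
MSB_SR = "msb_sr"
MSB_ALL = "msb_all"
CONDITIONS = (SSB_ALL, MSB_SO, MSB_SR, MSB_ALL)

# mechanism-only variants
MULTIPLICATIVE_ONLY = "multiplicative_only"
RELEASE_ONLY = "release_only"
STP_ONLY = "stp_only"
VARIANTS = (MULTIPLICATIVE_ONLY, RELEASE_ONLY, STP_ONLY)

# STP identity of a bouton
FACILITATING = "facilitating"
DEPRESSING = "depressing"
STATIC = "static"

# STP assignment schemes
INDEPENDENT = "independent"
MATCHED = "matched"
NONE = "none"


class ConfigurationError(ValueError):
    """Raised for invalid network specifications or distributions."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and timing parameters of one simulated network.

    Defaults are the published full-simulation setup: 100 CA3/2 Poisson
    sources and 100 CA1 neurons, 12 boutons per source neuron split 5 to SO
    and 7 to SR, 51 s of simulation analysed over the last 50 s.
    """

    n_ca1: int = 100
    n_ca3: int = 100
    boutons_per_neuron: int = 12
    boutons_so: int = 5
    boutons_sr: int = 7
    sim_duration: float = 51.0      # s
    analysis_window: float = 50.0   # s
    dt: float = 0.1                 # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boutons_so + self.boutons_sr != self.boutons_per_neuron:
            raise ConfigurationError(
                f"boutons_so + boutons_sr = {self.boutons_so + self.boutons_sr} "
                f"!= boutons_per_neuron = {self.boutons_per_neuron}"
            )
        if min(self.n_ca1, self.n_ca3, self.boutons_per_neuron) < 1:
            raise ConfigurationError("counts must be positive")
        if self.dt <= 0 or self.sim_duration <= 0:
            raise ConfigurationError("dt and sim_duration must be positive")
        if not 0 < self.analysis_window <= self.sim_duration:
            raise ConfigurationError("analysis_window must lie within sim_duration")


# default per-alpha probabilities for alpha = 1..5.  The SO values satisfy the
# two published constraints P(alpha>=2) = 0.45 and P(alpha>=4) = 0.15; the SR
# tail keeps the SO shape rescaled so that P(alpha>=2) = 0.25.
_SO_PROBS = (0.55, 0.18, 0.12, 0.10, 0.05)
_SR_PROBS = (0.75,) + tuple(p * (0.25 / 0.45) for p in _SO_PROBS[1:])

MAX_AZ = 5


@dataclass(frozen=True)
class AZCountDistribution:
    """Probability distribution over active-zone counts alpha in {1..5}."""

    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or len(p) != MAX_AZ:
            raise ConfigurationError(f"need {MAX_AZ} probabilities, got {len(p)}")
        if (p < 0).any():
            raise ConfigurationError("negative probability")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ConfigurationError(f"probabilities sum to {p.sum()!r}, not 1")

    @classmethod
    def default_so(cls) -> "AZCountDistribution":
        return cls(_SO_PROBS)

    @classmethod
    def default_sr(cls) -> "AZCountDistribution":
        return cls(_SR_PROBS)

    @classmethod
    def ssb(cls) -> "AZCountDistribution":
        """Degenerate distribution: every bouton has a single active zone."""
        return cls((1.0, 0.0, 0.0, 0.0, 0.0))

    def p_at_least(self, alpha: int) -> float:
        return float(np.sum(self.probs[alpha - 1:]))

    @property
    def msb_fraction(self) -> float:
        return self.p_at_least(2)


@dataclass
class Bouton:
    id: int
    source_neuron: int
    stratum: str            # "SO", "SR" or "NONE"
    az_count: int
    release_prob: float = float("nan")
    stp_type: str = STATIC

    def __post_init__(self) -> None:
        if self.az_count < 1:
            raise ConfigurationError("az_count must be >= 1")


@dataclass(frozen=True)
class ActiveZone:
    bouton_id: int
    target_neuron: int


@dataclass
class ConnectivityGraph:
    """Bouton-centric wiring of one CA3/2 -> CA1 network realisation."""

    spec: NetworkSpec
    boutons: list[Bouton]
    active_zones: list[ActiveZone]
    condition: str = ""

    def validate(self) -> None:
        per_bouton: dict[int, int] = {b.id: 0 for b in self.boutons}
        for az in self.active_zones:
            if az.bouton_id not in per_bouton:
                raise ConfigurationError(f"active zone references unknown bouton {az.bouton_id}")
            if not 0 <= az.target_neuron < self.spec.n_ca1:
                raise ConfigurationError(f"invalid CA1 target {az.target_neuron}")
            per_bouton[az.bouton_id] += 1
        for b in self.boutons:
            if per_bouton[b.id] != b.az_count:
                raise ConfigurationError(
                    f"bouton {b.id}: {per_bouton[b.id]} active zones, az_count={b.az_count}"
                )

    def as_arrays(self):
        """Per-active-zone flat arrays (source, target, p, stp code, bouton id).

        STP codes: 0 static, 1 facilitating, 2 depressing.
        """
        code = {STATIC: 0, FACILITATING: 1, DEPRESSING: 2}
        by_id = {b.id: b for b in self.boutons}
        n = len(self.active_zones)
        src = np.empty(n, dtype=np.int64)
        tgt = np.empty(n, dtype=np.int64)
        p = np.empty(n, dtype=np.float64)
        stp = np.empty(n, dtype=np.int64)
        bid = np.empty(n, dtype=np.int64)
        for i, az in enumerate(self.active_zones):
            b = by_id[az.bouton_id]
            src[i] = b.source_neuron
            tgt[i] = az.target_neuron
            p[i] = b.release_prob
            stp[i] = code[b.stp_type]
            bid[i] = b.id
        return src, tgt, p, stp, bid

    def to_frame(self) -> pd.DataFrame:
        by_id = {b.id: b for b in self.boutons}
        az_index: dict[int, int] = {}
        rows = []
        for az in self.active_zones:
            b = by_id[az.bouton_id]
            k = az_index.get(b.id, 0)
            az_index[b.id] = k + 1
            rows.append((b.id, b.source_neuron, b.stratum, k, az.target_neuron,
                         b.release_prob, b.stp_type))
        return pd.DataFrame(
            rows,
            columns=["bouton_id", "source_neuron", "stratum", "az_index",
                     "target_neuron", "p", "stp_type"],
        )


def sample_az_counts(n: int, dist: AZCountDistribution,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. active-zone counts alpha in {1..5} from ``dist``."""
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    return rng.choice(np.arange(1, MAX_AZ + 1), size=n, p=np.asarray(dist.probs))


def _draw_targets(az_count: int, n_ca1: int, rng: np.random.Generator) -> np.ndarray:
    # within-bouton targets are distinct CA1 neurons
    if az_count > n_ca1:
        raise ConfigurationError(
            f"bouton with {az_count} active zones cannot pick distinct targets "
            f"among {n_ca1} CA1 neurons"
        )
    if az_count == 1:
        return rng.integers(0, n_ca1, size=1)
    return rng.choice(n_ca1, size=az_count, replace=False)


def build_connectivity(
    spec: NetworkSpec,
    condition: str,
    so_dist: AZCountDistribution | None = None,
    sr_dist: AZCountDistribution | None = None,
    rng: np.random.Generator | None = None,
) -> ConnectivityGraph:
    """Build the stratified wiring for one of the four full-model conditions.

    ``condition`` selects which strata carry MSBs: ``ssb_all`` (every bouton a
    single active zone), ``msb_so``, ``msb_sr`` or ``msb_all``.  Strata
    flagged MSB sample alpha from the stratum's distribution; strata flagged
    SSB force alpha = 1.  Each active zone targets a uniformly random CA1
    neuron, distinct within a bouton.
    """
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    so_dist = AZCountDistribution.default_so() if so_dist is None else so_dist
    sr_dist = AZCountDistribution.default_sr() if sr_dist is None else sr_dist
    so_msb = condition in (MSB_SO, MSB_ALL)
    sr_msb = condition in (MSB_SR, MSB_ALL)

    boutons: list[Bouton] = []
    zones: list[ActiveZone] = []
    bid = 0
    for neuron in range(spec.n_ca3):
        for stratum, count, msb, dist in (
            ("SO", spec.boutons_so, so_msb, so_dist),
            ("SR", spec.boutons_sr, sr_msb, sr_dist),
        ):
            alphas = (sample_az_counts(count, dist, rng) if msb
                      else np.ones(count, dtype=int))
            for a in alphas:
                boutons.append(Bouton(bid, neuron, stratum, int(a)))
                for t in _draw_targets(int(a), spec.n_ca1, rng):
                    zones.append(ActiveZone(bid, int(t)))
                bid += 1
    return ConnectivityGraph(spec, boutons, zones, condition=condition)


def sample_release_probabilities(
    graph: ConnectivityGraph,
    shape: float = 2.0,
    scale: float = 0.15,
    rng: np.random.Generator | None = None,
) -> ConnectivityGraph:
    """Assign per-bouton release probabilities p ~ Gamma(k, theta) clipped at 1.

    One draw per bouton; every active zone of a bouton inherits the bouton's
    value (transmission at different active zones is then an independent
    Bernoulli realisation with this shared p).
    """
    if shape <= 0 or scale <= 0:
        raise ConfigurationError("Gamma shape and scale must be positive")
    rng = np.random.default_rng() if rng is None else rng
    draws = np.minimum(rng.gamma(shape, scale, size=len(graph.boutons)), 1.0)
    for b, p in zip(graph.boutons, draws):
        b.release_prob = float(p)
    return graph


def assign_stp_types(
    graph: ConnectivityGraph,
    scheme: str = INDEPENDENT,
    facil_fraction: float = 0.5,
    threshold: float | None = None,
    rng: np.random.Generator | None = None,
) -> ConnectivityGraph:
    """Label each bouton facilitating, depressing or static.

    ``independent``: facilitating with probability ``facil_fraction``,
    independently of p.  ``matched``: boutons with p above ``threshold``
    (default: the median of the sampled p values) are depressing, the rest
    facilitating — high release probability paired with depression, low with
    facilitation.  ``none``: all static.
    """
    if scheme == NONE:
        for b in graph.boutons:
            b.stp_type = STATIC
        return graph
    if scheme == INDEPENDENT:
        rng = np.random.default_rng() if rng is None else rng
        coins = rng.random(len(graph.boutons)) < facil_fraction
        for b, facil in zip(graph.boutons, coins):
            b.stp_type = FACILITATING if facil else DEPRESSING
        return graph
    if scheme == MATCHED:
        ps = np.array([b.release_prob for b in graph.boutons])
        if np.isnan(ps).any():
            raise ConfigurationError(
                "matched STP assignment requires release probabilities to be set first"
            )
        thr = float(np.median(ps)) if threshold is None else threshold
        for b in graph.boutons:
            b.stp_type = DEPRESSING if b.release_prob > thr else FACILITATING
        return graph
    raise ConfigurationError(f"unknown STP scheme {scheme!r}")


def build_mechanism_variant(
    spec: NetworkSpec,
    variant: str,
    msb: bool,
    so_dist: AZCountDistribution | None = None,
    sr_dist: AZCountDistribution | None = None,
    rng: np.random.Generator | None = None,
    stp_scheme: str = INDEPENDENT,
    facil_fraction: float = 0.5,
) -> ConnectivityGraph:
    """Build connectivity for one single-mechanism control simulation.

    ``multiplicative_only`` keeps the stratified SSB/MSB wiring but sets p = 1
    everywhere and disables STP, isolating the purely multiplicative effect of
    extra active zones.  ``release_only`` and ``stp_only`` compare 5 single-AZ
    boutons (SSB scenario) against 1 five-AZ bouton (MSB scenario) per source
    neuron, isolating shared release probability and shared STP identity.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if variant == MULTIPLICATIVE_ONLY:
        graph = build_connectivity(spec, MSB_ALL if msb else SSB_ALL,
                                   so_dist, sr_dist, rng)
        for b in graph.boutons:
            b.release_prob = 1.0
            b.stp_type = STATIC
        graph.condition = f"{variant}_{'msb' if msb else 'ssb'}"
        return graph
    if variant not in (RELEASE_ONLY, STP_ONLY):
        raise ConfigurationError(f"unknown variant {variant!r}")

    boutons: list[Bouton] = []
    zones: list[ActiveZone] = []
    bid = 0
    for neuron in range(spec.n_ca3):
        layout = [MAX_AZ] if msb else [1] * MAX_AZ
        for a in layout:
            boutons.append(Bouton(bid, neuron, "NONE", a))
            for t in _draw_targets(a, spec.n_ca1, rng):
                zones.append(ActiveZone(bid, int(t)))
            bid += 1
    graph = ConnectivityGraph(spec, boutons, zones,
                              condition=f"{variant}_{'msb' if msb else 'ssb'}")
    if variant == RELEASE_ONLY:
        sample_release_probabilities(graph, rng=rng)
        for b in graph.boutons:
            b.stp_type = STATIC
    else:  # STP_ONLY
        for b in graph.boutons:
            b.release_prob = 1.0
        assign_stp_types(graph, stp_scheme, facil_fraction=facil_fraction, rng=rng)
    return graph


# ---------------------------------------------------------------------------
# serialization

def write_graph(graph: ConnectivityGraph, path: str | Path) -> None:
    """Write one active zone per TSV row plus a JSON sidecar with the spec."""
    path = Path(path)
    df = graph.to_frame()
    # str() of a Python float is the shortest round-tripping representation
    df["p"] = [str(v) for v in df["p"]]
    df.to_csv(path, sep="\t", index=False)
    sidecar = {"condition": graph.condition, "spec": vars(graph.spec).copy()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_graph(path: str | Path) -> ConnectivityGraph:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec = NetworkSpec(**meta["spec"])
    df = pd.read_csv(path, sep="\t", dtype={"p": float},
                     float_precision="round_trip")
    counts = df.groupby("bouton_id", sort=False).size()
    boutons: dict[int, Bouton] = {}
    zones: list[ActiveZone] = []
    for row in df.itertuples(index=False):
        if row.bouton_id not in boutons:
            boutons[row.bouton_id] = Bouton(
                int(row.bouton_id), int(row.source_neuron), str(row.stratum),
                az_count=int(counts[row.bouton_id]), release_prob=float(row.p),
                stp_type=str(row.stp_type))
        zones.append(ActiveZone(int(row.bouton_id), int(row.target_neuron)))
    graph = ConnectivityGraph(spec, list(boutons.values()), zones,
                              condition=meta["condition"])
    graph.validate()
    return graph


def load_network_spec(path: str | Path) -> NetworkSpec:
    """Read a NetworkSpec from a TOML, YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".toml":
        import tomllib
        data = tomllib.loads(text)
    elif path.suffix in (".yml", ".yaml"):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return NetworkSpec(**data)
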