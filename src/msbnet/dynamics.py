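"""CA1 population dynamics.

CA1 neurons are current-based leaky integrate-and-fire units with exponential
postsynaptic currents,

    tau_m dV/dt = -V + R (I_b + I_syn),

driven by a Gaussian background current I_b and by spikes transmitted at the
active zones of CA3/2 boutons.  CA3/2 sources are independent 10 Hz Poisson
trains; transmission at each active zone is a Bernoulli thinning of the source
train with the bouton's release probability.  Plastic boutons filter the
transmitted train through the Tsodyks-Markram three-state resource model
(recovered x, active y, inactive z; utilisation u), so each transmitted spike
injects a postsynaptic current of amplitude A*u*x instead of the fixed static
amplitude.

All linear state (membrane, PSC, STP resources) is advanced with exact
exponential propagators; releases are computed event-by-event in closed form,
so the integration error is limited to locating threshold crossings on the
dt grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numba as nb
import numpy as np

from .network import ConnectivityGraph

__all__ = [
    "NeuronParams",
    "NoiseParams",
    "STPParams",
    "STPState",
    "STPTrace",
    "SpikeTrains",
    "FACILITATING_PARAMS",
    "DEPRESSING_PARAMS",
    "generate_poisson_trains",
    "thin_train",
    "stp_event_trace",
    "simulate_ca1",
    "write_spike_trains_tsv",
    "read_spike_trains_tsv",
    "write_spike_trains_h5",
    "read_spike_trains_h5",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF membrane and static-synapse parameters (mV, ms, pA, GOhm)."""

    tau_m: float = 60.0     # membrane time constant, ms
    R: float = 1.0          # input resistance, GOhm
    V_th: float = 20.0      # spike threshold, mV
    V_reset: float = 10.0   # post-spike reset, mV
    t_ref: float = 2.0      # absolute refractory period, ms
    A_static: float = 200.0  # static PSC amplitude, pA
    tau_syn: float = 1.5    # PSC decay time constant, ms

    def __post_init__(self) -> None:
        if min(self.tau_m, self.tau_syn) <= 0 or self.t_ref < 0:
            raise ValueError("time constants must be positive")
        if self.V_reset >= self.V_th:
            raise ValueError("V_reset must be below V_th")


@dataclass(frozen=True)
class NoiseParams:
    """Background current: N(mu_b, sigma_b) redrawn every update_interval."""

    mu_b: float = 12.0           # pA
    sigma_b: float = 20.0        # pA
    update_interval: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.update_interval <= 0:
            raise ValueError("sigma_b >= 0 and update_interval > 0 required")


@dataclass(frozen=True)
class STPParams:
    """Tsodyks-Markram synapse parameters.

    A is the absolute synaptic weight (pA): a transmitted spike injects a PSC
    of amplitude A*u*x.  U is the baseline utilisation, tau_rec the recovery
    time constant of depressed resources, tau_fac the facilitation time
    constant (0 means u decays instantaneously, i.e. u = U at every spike),
    and tau_syn the decay of the active state y.
    """

    A: float
    U: float
    tau_rec: float
    tau_fac: float
    tau_syn: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.U <= 1:
            raise ValueError("U must be in (0, 1]")
        if self.tau_rec <= 0 or self.tau_syn <= 0 or self.tau_fac < 0:
            raise ValueError("invalid STP time constants")


FACILITATING_PARAMS = STPParams(A=1540.0, U=0.03, tau_rec=130.0, tau_fac=530.0)
DEPRESSING_PARAMS = STPParams(A=250.0, U=0.5, tau_rec=800.0, tau_fac=0.0)


@dataclass
class STPState:
    """Instantaneous (x, y, z, u) of one active zone; x + y + z = 1."""

    x: float = 1.0
    y: float = 0.0
    z: float = 0.0
    u: float = 0.0


@dataclass
class STPTrace:
    """Per-spike record of an STP synapse driven by a spike train.

    ``releases[i] = u*x`` is the fraction of resources released by spike i
    (the PSC amplitude is ``params.A * releases[i]``); the state arrays hold
    the post-release values at each spike time.
    """

    times: np.ndarray
    releases: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    u: np.ndarray


@dataclass
class SpikeTrains:
    """Per-neuron ordered spike-time arrays (seconds) over [0, duration]."""

    trains: list
    duration: float
    label: str = ""

    @property
    def n(self) -> int:
        return len(self.trains)

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.trains])

    def mean_rate(self) -> float:
        if self.duration == 0:
            return 0.0
        return float(self.counts().sum() / (self.n * self.duration))


def generate_poisson_trains(n: int, rate: float, duration: float,
                            rng: np.random.Generator) -> SpikeTrains:
    """n independent homogeneous Poisson spike trains of the given rate (Hz)."""
    if rate < 0 or duration < 0 or n < 0:
        raise ValueError("n, rate and duration must be non-negative")
    trains = []
    counts = rng.poisson(rate * duration, size=n)
    for c in counts:
        trains.append(np.sort(rng.random(c)) * duration)
    return SpikeTrains(trains, duration, label="poisson")


def thin_train(train: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Keep each spike independently with probability p (Bernoulli thinning)."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    train = np.asarray(train, dtype=float)
    if p == 1.0:
        return train.copy()
    return train[rng.random(len(train)) < p]


def _decay_coeffs(dt: float, tau_rec: float, tau_syn: float):
    """Closed-form inter-spike propagation coefficients for (x, y, z)."""
    er = math.exp(-dt / tau_rec)
    es = math.exp(-dt / tau_syn)
    if abs(tau_rec - tau_syn) > 1e-12:
        w = (er - es) / (tau_rec - tau_syn)
    else:  # confluent limit
        w = dt * er / (tau_rec * tau_rec)
    return er, es, w


def stp_event_trace(train: np.ndarray, params: STPParams) -> STPTrace:
    """Drive one Tsodyks-Markram synapse with a sorted spike train.

    Between spikes the state follows the exact solution of the linear system
    (y decays with tau_syn, resources drain from z back to x with tau_rec, u
    decays with tau_fac); at each spike u is updated first, u <- u + U(1-u),
    then the release u*x moves from the recovered to the active pool.
    """
    train = np.asarray(train, dtype=float)
    if len(train) > 1 and (np.diff(train) < 0).any():
        raise ValueError("spike train must be sorted")
    n = len(train)
    rel = np.empty(n)
    xs = np.empty(n)
    ys = np.empty(n)
    zs = np.empty(n)
    us = np.empty(n)
    x, y, z, u = 1.0, 0.0, 0.0, 0.0
    t_prev = 0.0
    for i in range(n):
        dt = (train[i] - t_prev) * 1000.0  # s -> ms
        er, es, w = _decay_coeffs(dt, params.tau_rec, params.tau_syn)
        x = 1.0 + (x - 1.0) * er - y * params.tau_syn * w
        z = z * er + y * params.tau_rec * w
        y = y * es
        u = u * math.exp(-dt / params.tau_fac) if params.tau_fac > 0 else 0.0
        u = u + params.U * (1.0 - u)
        r = u * x
        x -= r
        y += r
        rel[i] = r
        xs[i], ys[i], zs[i], us[i] = x, y, z, u
        t_prev = train[i]
    return STPTrace(train, rel, xs, ys, zs, us)


@nb.njit(cache=False)
def _tm_release_amplitudes(times_ms, U, tau_rec, tau_fac, tau_syn):  # pragma: no cover
    """Release fraction u*x at each spike (times in ms); numba fast path."""
    n = len(times_ms)
    rel = np.empty(n)
    x, y, u = 1.0, 0.0, 0.0
    t_prev = 0.0
    for i in range(n):
        dt = times_ms[i] - t_prev
        er = math.exp(-dt / tau_rec)
        es = math.exp(-dt / tau_syn)
        if abs(tau_rec - tau_syn) > 1e-12:
            w = (er - es) / (tau_rec - tau_syn)
        else:
            w = dt * er / (tau_rec * tau_rec)
        x = 1.0 + (x - 1.0) * er - y * tau_syn * w
        y = y * es
        if tau_fac > 0:
            u = u * math.exp(-dt / tau_fac)
        else:
            u = 0.0
        u = u + U * (1.0 - u)
        r = u * x
        x -= r
        y += r
        rel[i] = r
        t_prev = times_ms[i]
    return rel


@nb.njit(cache=False)
def _lif_loop(n_steps, n, ev_step, ev_target, ev_amp, noise, spi,
              pm, ps, p21, r_in, v_th, v_reset, ref_steps):  # pragma: no cover
    """Clock-driven LIF integration with exact exponential propagators.

    State is sampled at step boundaries t_k = k*dt; synaptic events arriving
    in (t_{k-1}, t_k] are added to I_syn at t_k.  Spikes are detected at step
    boundaries; the membrane is clamped at V_reset for ref_steps afterwards.
    """
    V = np.zeros(n)
    I = np.zeros(n)
    ref = np.zeros(n, dtype=np.int64)
    cap = n * (n_steps // max(ref_steps, 1) + 2)
    sp_step = np.empty(cap, dtype=np.int64)
    sp_neuron = np.empty(cap, dtype=np.int64)
    m = 0
    ei = 0
    n_ev = len(ev_step)
    one_minus_pm = 1.0 - pm
    for k in range(1, n_steps + 1):
        row = (k - 1) // spi
        for i in range(n):
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = v_reset
            else:
                V[i] = V[i] * pm + r_in * noise[row, i] * one_minus_pm + p21 * I[i]
        for i in range(n):
            I[i] *= ps
        while ei < n_ev and ev_step[ei] == k:
            I[ev_target[ei]] += ev_amp[ei]
            ei += 1
        for i in range(n):
            if ref[i] == 0 and V[i] >= v_th:
                sp_step[m] = k
                sp_neuron[m] = i
                m += 1
                V[i] = v_reset
                ref[i] = ref_steps
    return sp_step[:m], sp_neuron[:m]


def _lif_propagators(neuron: NeuronParams, dt: float):
    pm = math.exp(-dt / neuron.tau_m)
    ps = math.exp(-dt / neuron.tau_syn)
    if abs(neuron.tau_m - neuron.tau_syn) > 1e-12:
        p21 = neuron.R * neuron.tau_syn / (neuron.tau_m - neuron.tau_syn) * (pm - ps)
    else:
        p21 = neuron.R * dt / neuron.tau_m * pm
    return pm, ps, p21


def simulate_ca1(
    graph: ConnectivityGraph,
    ca3_trains: SpikeTrains,
    neuron: NeuronParams | None = None,
    noise: NoiseParams | None = None,
    stp_on: bool = True,
    dt: float | None = None,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
    delay_ms: float = 1.0,
    facil_params: STPParams = FACILITATING_PARAMS,
    depr_params: STPParams = DEPRESSING_PARAMS,
) -> SpikeTrains:
    """Simulate the CA1 population driven by CA3/2 trains through ``graph``.

    Each active zone independently thins its bouton's source train with the
    bouton's release probability, applies the bouton's STP filter (when
    ``stp_on`` and the bouton is plastic) and delivers delayed PSC events to
    its CA1 target.  Returns the CA1 spike trains in seconds.
    """
    neuron = NeuronParams() if neuron is None else neuron
    noise = NoiseParams() if noise is None else noise
    dt = graph.spec.dt if dt is None else dt
    duration = ca3_trains.duration if duration is None else duration
    rng = np.random.default_rng() if rng is None else rng
    if ca3_trains.n != graph.spec.n_ca3:
        raise ValueError(
            f"graph expects {graph.spec.n_ca3} source trains, got {ca3_trains.n}"
        )
    for p in (facil_params, depr_params):
        if abs(p.tau_syn - neuron.tau_syn) > 1e-12:
            raise ValueError("STP tau_syn must match the neuron PSC tau_syn")

    n_ca1 = graph.spec.n_ca1
    n_steps = int(round(duration * 1000.0 / dt))
    spi = max(1, int(round(noise.update_interval / dt)))
    n_intervals = (n_steps + spi - 1) // spi + 1

    src, tgt, p_rel, stp_code, _ = graph.as_arrays()
    steps_list = []
    tgt_list = []
    amp_list = []
    for i in range(len(src)):
        train = ca3_trains.trains[src[i]]
        transmitted = thin_train(train, float(p_rel[i]), rng)
        if len(transmitted) == 0:
            continue
        if stp_on and stp_code[i] == 1:
            amps = facil_params.A * _tm_release_amplitudes(
                transmitted * 1000.0, facil_params.U, facil_params.tau_rec,
                facil_params.tau_fac, facil_params.tau_syn)
        elif stp_on and stp_code[i] == 2:
            amps = depr_params.A * _tm_release_amplitudes(
                transmitted * 1000.0, depr_params.U, depr_params.tau_rec,
                depr_params.tau_fac, depr_params.tau_syn)
        else:
            amps = np.full(len(transmitted), neuron.A_static)
        t_ms = transmitted * 1000.0 + delay_ms
        steps = np.ceil(t_ms / dt - 1e-9).astype(np.int64)
        keep = steps <= n_steps
        steps_list.append(steps[keep])
        tgt_list.append(np.full(keep.sum(), tgt[i], dtype=np.int64))
        amp_list.append(np.asarray(amps)[keep])

    if steps_list:
        ev_step = np.concatenate(steps_list)
        ev_target = np.concatenate(tgt_list)
        ev_amp = np.concatenate(amp_list)
        order = np.argsort(ev_step, kind="stable")
        ev_step, ev_target, ev_amp = ev_step[order], ev_target[order], ev_amp[order]
    else:
        ev_step = np.empty(0, dtype=np.int64)
        ev_target = np.empty(0, dtype=np.int64)
        ev_amp = np.empty(0, dtype=np.float64)

    noise_mat = noise.mu_b + noise.sigma_b * rng.standard_normal((n_intervals, n_ca1))
    pm, ps, p21 = _lif_propagators(neuron, dt)
    ref_steps = max(1, int(round(neuron.t_ref / dt)))
    sp_step, sp_neuron = _lif_loop(
        n_steps, n_ca1, ev_step, ev_target, ev_amp, noise_mat, spi,
        pm, ps, p21, neuron.R, neuron.V_th, neuron.V_reset, ref_steps)

    times = sp_step.astype(float) * dt / 1000.0
    trains = [times[sp_neuron == i] for i in range(n_ca1)]
    return SpikeTrains(trains, duration, label="ca1")


def psc_trace(event_times_s, amps, tau_syn: float, dt: float,
              duration_s: float) -> np.ndarray:
    """Postsynaptic current sampled at step boundaries t_k = k*dt.

    Uses the same exact exponential propagator and event convention as the
    network integrator (events in (t_{k-1}, t_k] are added at t_k), so a
    single event of amplitude A at t = 0 yields exactly A*exp(-t_k/tau_syn).
    """
    n_steps = int(round(duration_s * 1000.0 / dt))
    ps = math.exp(-dt / tau_syn)
    steps = np.ceil(np.asarray(event_times_s) * 1000.0 / dt - 1e-9).astype(np.int64)
    inc = np.zeros(n_steps + 1)
    for s, a in zip(steps, np.broadcast_to(amps, steps.shape)):
        if 0 <= s <= n_steps:
            inc[s] += a
    out = np.empty(n_steps + 1)
    out[0] = inc[0]
    for k in range(1, n_steps + 1):
        out[k] = out[k - 1] * ps + inc[k]
    return out


# ---------------------------------------------------------------------------
# spike-train I/O

def write_spike_trains_tsv(trains: SpikeTrains, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# duration_s={trains.duration!r}\tlabel={trains.label}\n")
        fh.write("neuron_id\ttime_s\n")
        for i, t in enumerate(trains.trains):
            for v in t:
                fh.write(f"{i}\t{float(v)!r}\n")


def read_spike_trains_tsv(path: str | Path) -> SpikeTrains:
    path = Path(path)
    lines = path.read_text().splitlines()
    header = lines[0].lstrip("# ").split("\t")
    duration = float(header[0].split("=")[1])
    label = header[1].split("=")[1]
    ids, times = [], []
    for line in lines[2:]:
        if not line:
            continue
        i, t = line.split("\t")
        ids.append(int(i))
        times.append(float(t))
    n = max(ids) + 1 if ids else 0
    ids_a = np.array(ids, dtype=int)
    times_a = np.array(times)
    trains = [times_a[ids_a == i] for i in range(n)]
    return SpikeTrains(trains, duration, label=label)


def write_spike_trains_h5(trains: SpikeTrains, path: str | Path,
                          group: str = "spikes") -> None:
    """Ragged HDF5 layout: one dataset per neuron under ``group``."""
    import h5py

    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.attrs["duration_s"] = trains.duration
        g.attrs["label"] = trains.label
        g.attrs["n"] = trains.n
        for i, t in enumerate(trains.trains):
            g.create_dataset(str(i), data=np.asarray(t, dtype=float))


def read_spike_trains_h5(path: str | Path, group: str = "spikes") -> SpikeTrains:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh[group]
        n = int(g.attrs["n"])
        trains = [g[str(i)][...] for i in range(n)]
        return SpikeTrains(trains, float(g.attrs["duration_s"]),
                           label=str(g.attrs["label"]))
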