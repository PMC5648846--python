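"""Simplified spiking layer: from connectome to swimming activity.

Maps an anatomical connectome onto a network of single-compartment
Hodgkin-Huxley-style neurons and simulates touch-evoked activity.  This
layer is deliberately an approximation: channel kinetics are a standard HH
parameterization (with a slow NMDA-like conductance on dINs that supports
pacemaker firing), not a fit to tadpole electrophysiology, and it is used
for qualitative network behaviour only.

Synaptic strength between a connected pair is the unitary conductance times
the number of anatomical contacts.  Events are delivered with a
distance-dependent axonal delay (contact arc length / conduction speed) plus
a fixed synaptic delay.  dINs on the same side are electrically coupled
(gap junctions) when their somata are close.

Detectors operate on spike rasters alone: ``detect_swimming`` looks for
sustained strict left/right alternation of motoneuron population bursts in
the 10-25 Hz band, and ``midcycle_dIN_count`` counts dINs spiking in the
middle of their own side's cycle, i.e. during contralateral activity — a
marker of degraded rhythm quality.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .population import TYPE_ORDER
from .synaptogenesis import Connectome


class SimConfigError(ValueError):
    pass


class DetectorUsageError(RuntimeError):
    pass


#: presynaptic sign convention: cIN and aIN are inhibitory, the rest excite
INHIBITORY_TYPES = frozenset({"cIN", "aIN"})


@dataclass(frozen=True)
class CellModelParams:
    """Single-compartment membrane parameters (µF/cm², mS/cm², mV)."""

    c_m: float = 1.0
    g_na: float = 120.0
    g_k: float = 36.0
    g_leak: float = 0.3
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.4
    spike_threshold: float = 0.0     # upward crossing defines a spike
    # dIN extra: NMDA-like slow conductance enabling post-spike pacemaker
    # firing; zero for other types
    g_nmda_unit: float = 0.0         # conductance added per dIN->dIN contact event
    nmda_tau: float = 80.0           # ms
    nmda_tonic: float = 0.0          # standing NMDA conductance (mS/cm²)


DEFAULT_CELL_PARAMS: dict[str, CellModelParams] = {
    **{t: CellModelParams() for t in TYPE_ORDER},
    "dIN": CellModelParams(g_nmda_unit=0.02, nmda_tau=80.0),
}


@dataclass(frozen=True)
class SynapseParams:
    """Per-presynaptic-type synaptic kinetics and delays."""

    unitary_g: float = 0.12          # mS/cm² per anatomical contact
    tau_rise: float = 0.5            # ms
    tau_decay: float = 3.0           # ms
    syn_delay: float = 1.0           # fixed synaptic delay, ms
    conduction_speed: float = 500.0  # µm/ms (0.5 m/s)
    e_exc: float = 0.0               # mV
    e_inh: float = -80.0             # mV
    gap_g: float = 0.1               # dIN-dIN electrical coupling, mS/cm²
    gap_range: float = 150.0         # µm, max soma RC distance for coupling

    def __post_init__(self) -> None:
        if self.syn_delay <= 0 or self.conduction_speed <= 0:
            raise SimConfigError("delays must be positive")


@dataclass(frozen=True)
class Stimulus:
    """Brief current injection into a set of neurons (skin touch to RBs)."""

    neuron_ids: tuple[int, ...]
    t_start: float = 10.0            # ms
    duration: float = 5.0            # ms
    amplitude: float = 20.0          # µA/cm²


def touch_stimulus(connectome: Connectome, side: int = 1,
                   n_rb: int = 4, **kw) -> Stimulus:
    """Stimulate the n most rostral RB neurons on one side."""
    rbs = sorted(
        (n for n in connectome.population if n.cell_type == "RB" and n.side == side),
        key=lambda n: n.soma[0],
    )
    return Stimulus(neuron_ids=tuple(n.id for n in rbs[:n_rb]), **kw)


@dataclass
class SpikeRaster:
    """Per-neuron ordered spike times (ms) plus neuron metadata."""

    spikes: dict[int, np.ndarray]
    neuron_types: dict[int, str]
    neuron_sides: dict[int, int]
    dt: float = 0.0
    duration: float = 0.0
    stimulus: dict = field(default_factory=dict)

    def of_type(self, cell_type: str, side: int | None = None) -> dict[int, np.ndarray]:
        return {
            nid: ts
            for nid, ts in self.spikes.items()
            if self.neuron_types[nid] == cell_type
            and (side is None or self.neuron_sides[nid] == side)
        }

    def total_spikes(self) -> int:
        return sum(len(v) for v in self.spikes.values())


# ---------------------------------------------------------------------------
# integration

def _hh_rates(v: np.ndarray):
    """Classic HH rate functions (ms^-1), singularities removed."""
    vm = v + 40.0
    a_m = np.where(np.abs(vm) < 1e-7, 1.0, 0.1 * vm / (1.0 - np.exp(-vm / 10.0)))
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    vn = v + 55.0
    a_n = np.where(np.abs(vn) < 1e-7, 0.1, 0.01 * vn / (1.0 - np.exp(-vn / 10.0)))
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def _mg_block(v: np.ndarray) -> np.ndarray:
    """Voltage-dependent magnesium block of the NMDA conductance."""
    return 1.0 / (1.0 + 0.28 * np.exp(-0.062 * v))


def simulate(
    connectome: Connectome,
    cell_params: dict[str, CellModelParams] | None = None,
    syn_params: SynapseParams | None = None,
    stimulus: Stimulus | None = None,
    dt: float = 0.02,
    duration: float = 400.0,
    seed: int = 0,
) -> SpikeRaster:
    """Fixed-step network integration; deterministic given its inputs.

    Gating variables advance by exponential Euler, the membrane potential by
    forward Euler; synaptic conductances are difference-of-exponentials
    driven by an event queue of delayed deliveries.
    """
    if dt > 0.05:
        raise SimConfigError("dt must be <= 0.05 ms")
    cell_params = cell_params or DEFAULT_CELL_PARAMS
    sp = syn_params or SynapseParams()

    neurons = sorted(connectome.population, key=lambda n: n.id)
    idx = {n.id: i for i, n in enumerate(neurons)}
    n_cells = len(neurons)
    types = [n.cell_type for n in neurons]
    for t in set(types):
        if t not in cell_params:
            raise SimConfigError(f"no cell model parameters for type {t}")

    def arr(attr):
        return np.array([getattr(cell_params[t], attr) for t in types])

    c_m, g_na, g_k, g_leak = arr("c_m"), arr("g_na"), arr("g_k"), arr("g_leak")
    e_na, e_k, e_leak = arr("e_na"), arr("e_k"), arr("e_leak")
    thresh = arr("spike_threshold")
    g_nmda_unit, nmda_tau, nmda_tonic = (
        arr("g_nmda_unit"), arr("nmda_tau"), arr("nmda_tonic"),
    )

    # outgoing synapses grouped by presynaptic neuron
    out: dict[int, list[tuple[int, float, bool, float]]] = {i: [] for i in range(n_cells)}
    for s in connectome.synapses:
        pre_i, post_i = idx[s.pre_id], idx[s.post_id]
        delay = sp.syn_delay + (s.step * 1.0) / sp.conduction_speed
        inhib = s.pre_type in INHIBITORY_TYPES
        nmda_w = g_nmda_unit[post_i] if (s.pre_type == "dIN" and types[post_i] == "dIN") else 0.0
        out[pre_i].append((post_i, sp.unitary_g, inhib, nmda_w, delay))

    # dIN gap junction pairs (same side, nearby somata)
    dins = [i for i, t in enumerate(types) if t == "dIN"]
    gap_pairs = []
    for a in range(len(dins)):
        for b in range(a + 1, len(dins)):
            na, nb = neurons[dins[a]], neurons[dins[b]]
            if na.side == nb.side and abs(na.soma[0] - nb.soma[0]) <= sp.gap_range:
                gap_pairs.append((dins[a], dins[b]))
    gap_i = np.array([p[0] for p in gap_pairs], dtype=int)
    gap_j = np.array([p[1] for p in gap_pairs], dtype=int)

    # state
    v = e_leak.copy()
    a_m, b_m, a_h, b_h, a_n, b_n = _hh_rates(v)
    m = a_m / (a_m + b_m)
    h = a_h / (a_h + b_h)
    ngate = a_n / (a_n + b_n)
    s_rise_e = np.zeros(n_cells)
    s_decay_e = np.zeros(n_cells)
    s_rise_i = np.zeros(n_cells)
    s_decay_i = np.zeros(n_cells)
    s_nmda = np.zeros(n_cells)

    dec_r = math.exp(-dt / sp.tau_rise)
    dec_d = math.exp(-dt / sp.tau_decay)
    dec_nmda = np.exp(-dt / nmda_tau)
    # normalize the dual-exponential peak to 1 per unit weight
    tp = (sp.tau_rise * sp.tau_decay / (sp.tau_decay - sp.tau_rise)) * math.log(
        sp.tau_decay / sp.tau_rise
    )
    peak = math.exp(-tp / sp.tau_decay) - math.exp(-tp / sp.tau_rise)

    events: list[tuple[float, int, int, float, bool, float]] = []  # (t, seq, post, w, inhib, nmda_w)
    seq = 0

    stim_ids = np.zeros(n_cells, dtype=bool)
    stim = stimulus
    if stim is not None:
        for nid in stim.neuron_ids:
            if nid in idx:
                stim_ids[idx[nid]] = True

    n_steps = int(round(duration / dt))
    spikes: dict[int, list[float]] = {n.id: [] for n in neurons}
    last_spike = np.full(n_cells, -1e9)
    refractory = 2.0  # ms, for spike *detection* only

    prev_above = v >= thresh
    for step_i in range(n_steps):
        t = step_i * dt
        # deliver due events
        while events and events[0][0] <= t:
            _, _, post, w, inhib, nmda_w = heapq.heappop(events)
            if inhib:
                s_rise_i[post] += w
                s_decay_i[post] += w
            else:
                s_rise_e[post] += w
                s_decay_e[post] += w
                if nmda_w:
                    s_nmda[post] += nmda_w

        g_e = (s_decay_e - s_rise_e) / peak
        g_i = (s_decay_i - s_rise_i) / peak
        g_nmda = (s_nmda + nmda_tonic) * _mg_block(v)

        i_ion = (
            g_na * m ** 3 * h * (e_na - v)
            + g_k * ngate ** 4 * (e_k - v)
            + g_leak * (e_leak - v)
            + g_e * (sp.e_exc - v)
            + g_i * (sp.e_inh - v)
            + g_nmda * (sp.e_exc - v)
        )
        if len(gap_i):
            dv_gap = np.zeros(n_cells)
            diff = v[gap_j] - v[gap_i]
            np.add.at(dv_gap, gap_i, sp.gap_g * diff)
            np.add.at(dv_gap, gap_j, -sp.gap_g * diff)
            i_ion = i_ion + dv_gap
        if stim is not None and stim.t_start <= t < stim.t_start + stim.duration:
            i_ion = i_ion + np.where(stim_ids, stim.amplitude, 0.0)

        v = v + dt * i_ion / c_m

        a_m, b_m, a_h, b_h, a_n, b_n = _hh_rates(v)
        for gate, a, b in ((0, a_m, b_m), (1, a_h, b_h), (2, a_n, b_n)):
            tau = 1.0 / (a + b)
            inf = a * tau
            f = np.exp(-dt / tau)
            if gate == 0:
                m = inf + (m - inf) * f
            elif gate == 1:
                h = inf + (h - inf) * f
            else:
                ngate = inf + (ngate - inf) * f

        s_rise_e *= dec_r
        s_decay_e *= dec_d
        s_rise_i *= dec_r
        s_decay_i *= dec_d
        s_nmda *= dec_nmda

        above = v >= thresh
        fired = above & ~prev_above & (t - last_spike > refractory)
        prev_above = above
        if fired.any():
            t_spike = t + dt
            for i in np.nonzero(fired)[0]:
                last_spike[i] = t_spike
                spikes[neurons[i].id].append(t_spike)
                for (post, w, inhib, nmda_w, delay) in out[i]:
                    heapq.heappush(
                        events, (t_spike + delay, seq, post, w, inhib, nmda_w)
                    )
                    seq += 1

    return SpikeRaster(
        spikes={nid: np.asarray(ts) for nid, ts in spikes.items()},
        neuron_types={n.id: n.cell_type for n in neurons},
        neuron_sides={n.id: n.side for n in neurons},
        dt=dt,
        duration=duration,
        stimulus={} if stim is None else {
            "neuron_ids": list(stim.neuron_ids), "t_start": stim.t_start,
            "duration": stim.duration, "amplitude": stim.amplitude,
        },
    )


# ---------------------------------------------------------------------------
# detectors

def _population_bursts(times: np.ndarray, gap_ms: float) -> list[float]:
    """Burst midpoints of a pooled spike train, split at gaps > gap_ms."""
    if len(times) == 0:
        return []
    times = np.sort(times)
    split = np.nonzero(np.diff(times) > gap_ms)[0] + 1
    return [float(0.5 * (grp[0] + grp[-1])) for grp in np.split(times, split)]


def detect_swimming(
    raster: SpikeRaster,
    window: tuple[float, float] | None = None,
    gap_ms: float = 15.0,
    n_cyc: int = 5,
    band_hz: tuple[float, float] = (10.0, 25.0),
) -> dict:
    """Is the raster swimming?  {"swims": bool, "frequency": Hz}.

    Motoneuron spikes per side are pooled into population bursts (inter-spike
    gap threshold ``gap_ms``); swimming requires at least ``n_cyc``
    consecutive cycles of strict left/right burst alternation with the cycle
    frequency inside ``band_hz``.  Frequency is the reciprocal of the median
    same-side burst interval.
    """
    def side_spikes(side):
        sp = raster.of_type("mn", side)
        return np.concatenate(list(sp.values())) if sp else np.array([])

    t_lo, t_hi = window if window else (0.0, math.inf)
    left = _population_bursts(
        side_spikes(1)[(side_spikes(1) >= t_lo) & (side_spikes(1) <= t_hi)], gap_ms
    )
    right = _population_bursts(
        side_spikes(-1)[(side_spikes(-1) >= t_lo) & (side_spikes(-1) <= t_hi)], gap_ms
    )
    intervals = np.diff(left) if len(left) >= len(right) else np.diff(right)
    freq = float(1000.0 / np.median(intervals)) if len(intervals) else float("nan")

    merged = sorted([(t, 1) for t in left] + [(t, -1) for t in right])
    best_run = run = 1 if merged else 0
    for k in range(1, len(merged)):
        if merged[k][1] != merged[k - 1][1]:
            run += 1
        else:
            run = 1
        best_run = max(best_run, run)
    swims = (
        best_run >= 2 * n_cyc
        and len(intervals) > 0
        and band_hz[0] <= freq <= band_hz[1]
    )
    return {"swims": bool(swims), "frequency": freq,
            "n_left_bursts": len(left), "n_right_bursts": len(right)}


def midcycle_dIN_count(
    raster: SpikeRaster,
    swim_result: dict,
    k_spikes: int = 3,
    mid_fraction: float = 0.5,
    gap_ms: float = 15.0,
) -> int:
    """Number of dINs firing mid-cycle, i.e. during contralateral activity.

    A dIN counts as mid-cycle if at least ``k_spikes`` of its spikes fall
    within the middle ``mid_fraction`` of the interval between consecutive
    bursts of its own side's motoneuron population.
    """
    if not swim_result.get("swims", False):
        raise DetectorUsageError("midcycle_dIN_count requires a swimming raster")
    bursts = {}
    for side in (1, -1):
        sp = raster.of_type("mn", side)
        pooled = np.concatenate(list(sp.values())) if sp else np.array([])
        bursts[side] = _population_bursts(pooled, gap_ms)

    count = 0
    for nid, times in raster.of_type("dIN").items():
        side = raster.neuron_sides[nid]
        own = bursts[side]
        if len(own) < 2 or len(times) == 0:
            continue
        hits = 0
        for t0, t1 in zip(own[:-1], own[1:]):
            period = t1 - t0
            lo = t0 + (1.0 - mid_fraction) / 2.0 * period
            hi = t1 - (1.0 - mid_fraction) / 2.0 * period
            hits += int(np.sum((times >= lo) & (times <= hi)))
        if hits >= k_spikes:
            count += 1
    return count
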