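"""Synthetic data generators for testing and self-contained runs.

The anatomical measurement tables consumed by the population module come
from microscopy of real neurons; this package ships no measured data.
``make_measurement_tables`` generates synthetic stand-ins — Gaussian-mixture
samples whose locations mimic the qualitative anatomy (RB somata and axons
in the dorsal tract, motoneurons ventral, commissural initial angles aimed
at the floor plate) — which are documented constants, never presented as
measurements.  ``make_toy_scenario`` builds minimal growth set-ups with
analytically known outcomes, and ``make_synthetic_raster`` constructs spike
rasters whose detector ground truth is known by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .environment import Arena, Environment, build_standard_environment, apply_gaps
from .gradient_fields import GradientField, NoiseSpec, null_field
from .growth_engine import InteractionParams
from .population import (
    CELL_TYPES, MeasurementTable, Neuron, PopulationConfig, TYPE_ORDER,
    build_population, _wrap,
)
from .functional_sim import SpikeRaster


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    parameters: dict
    seed: int


# soma DV level, initial-angle mean, axon length scale per type; left-side
# convention (y > 0, ascending = theta near +/-pi).  Chosen for qualitative
# resemblance to the anatomy: dorsal sensory types, ventral motor types.
_TYPE_ANATOMY = {
    #        y_mu, y_sd, th_mu,  th_sd, Lp,   Ls,   dend, branch
    "RB":  (132.0, 1.0, math.pi, 0.10, 450.0, 250.0, 4.0, 180.0),
    "dla": (124.0, 2.0, -2.75,   0.20, 450.0, 250.0, 25.0, 180.0),
    "dlc": (122.0, 2.0, -1.60,   0.20, 500.0, 250.0, 25.0, 200.0),
    "aIN": (65.0, 8.0, -2.85,    0.20, 450.0, 250.0, 15.0, 180.0),
    "cIN": (60.0, 8.0, -1.60,    0.20, 500.0, 260.0, 15.0, 200.0),
    "dIN": (50.0, 8.0, -0.30,    0.20, 500.0, 260.0, 15.0, 200.0),
    "mn":  (35.0, 4.0, -0.25,    0.20, 400.0, 200.0, 10.0, 160.0),
}


def make_measurement_tables(
    seed: int = 0, n_samples: int = 120
) -> dict[str, MeasurementTable]:
    """Synthetic per-type measurement tables (>= 100 samples each)."""
    tables = {}
    for k, name in enumerate(TYPE_ORDER):
        rng = np.random.default_rng([seed, 100 + k])
        y_mu, y_sd, th_mu, th_sd, lp, ls, dend, br = _TYPE_ANATOMY[name]
        if name == "RB":
            # RB somata and axons live strictly inside the dorsal tract
            y = np.clip(rng.normal(y_mu, y_sd, n_samples), 130.0, 134.0)
        else:
            y = np.clip(rng.normal(y_mu, y_sd, n_samples), 2.0, 143.0)
        theta = np.array([_wrap(t) for t in rng.normal(th_mu, th_sd, n_samples)])
        # log-normal lengths: sigma 0.25 about the type's scale
        plen = lp * rng.lognormal(0.0, 0.25, n_samples)
        slen = ls * rng.lognormal(0.0, 0.25, n_samples)
        half = np.abs(rng.normal(dend, 0.3 * dend, n_samples))
        branch = np.abs(rng.normal(br, 0.3 * br, n_samples))
        tables[name] = MeasurementTable(
            cell_type=name, soma_theta=np.column_stack([y, theta]),
            primary_length=plen, secondary_length=slen,
            dendrite_half_extent=half, branch_offset=branch,
        )
    return tables


# ---------------------------------------------------------------------------
# toy growth scenarios

@dataclass
class ToyScenario:
    name: str
    population: list[Neuron]
    environment: Environment
    fields: GradientField
    noise: NoiseSpec
    interaction: InteractionParams
    wave_spacing: float = 200.0


def _quiet_noise() -> NoiseSpec:
    return NoiseSpec(alpha={t: 0.0 for t in CELL_TYPES}, pre_crossing_alpha=0.0)


def _neuron(nid, cell_type, side, soma, theta0, length, *, pioneer=False,
            secondary=None, branch=None, dendrite_half=5.0) -> Neuron:
    y = soma[1]
    y_lo, y_hi = y - dendrite_half, y + dendrite_half
    if side > 0:
        y_lo = max(0.0, y_lo)
    else:
        y_hi = min(0.0, y_hi)
    return Neuron(
        id=nid, cell_type=cell_type, side=side, soma=soma,
        dendrite=(y_lo, y_hi),
        primary_length=length, secondary_length=secondary,
        branch_arc_length=branch, theta0=theta0,
        theta0_secondary=_wrap(math.pi - theta0) if secondary else None,
        pioneer_primary=pioneer, pioneer_secondary=pioneer and secondary is not None,
    )


def make_toy_scenario(name: str) -> ToyScenario:
    """Minimal growth set-ups with analytically known behaviour."""
    arena = Arena()
    env = build_standard_environment(arena)
    if name == "straight_pioneer_follower":
        # one zero-noise pioneer growing straight ascending along y = 50,
        # one follower starting 0.5 µm below; with s = 1, r = 1 the follower
        # angle locks to the pioneer angle exactly
        fields = null_field(arena)
        pioneer = _neuron(0, "dla", 1, (1900.0, 50.0), math.pi, 200.0, pioneer=True)
        follower = _neuron(1, "dla", 1, (1900.0, 49.5), math.pi, 150.0)
        return ToyScenario(
            name, [pioneer, follower], env, fields, _quiet_noise(),
            InteractionParams(s_pr=1.0, s_se=1.0, r=1.0),
        )
    if name == "two_parallel_pioneers":
        fields = null_field(arena)
        p1 = _neuron(0, "aIN", 1, (1800.0, 60.0), math.pi, 300.0, pioneer=True)
        p2 = _neuron(1, "aIN", 1, (1800.0, 70.0), math.pi, 300.0, pioneer=True)
        return ToyScenario(
            name, [p1, p2], env, fields, _quiet_noise(),
            InteractionParams(s_pr=0.5, s_se=0.5, r=1.0),
        )
    if name == "commissural_single":
        fields = GradientField(arena=arena)
        cin = _neuron(0, "cIN", 1, (1200.0, 55.0), -1.6, 400.0, pioneer=True)
        return ToyScenario(
            name, [cin], env, fields, _quiet_noise(),
            InteractionParams(s_pr=0.0, s_se=0.0, r=1.0),
        )
    if name == "gapped_tract_minimal":
        fields = GradientField(arena=arena)
        genv = apply_gaps(env, 25.0, 25.0)
        neurons = []
        for i in range(6):
            neurons.append(
                _neuron(i, "RB", 1, (1900.0 - 30.0 * i, 132.0), math.pi, 400.0,
                        pioneer=(i % 3 == 0))
            )
        return ToyScenario(
            name, neurons, genv, fields, NoiseSpec(), InteractionParams(0.2, 0.2, 1.0),
        )
    raise ValueError(f"unknown toy scenario {name!r}")


def make_type_population(
    cell_type: str,
    n_per_side: int = 30,
    n_pioneers: int = 4,
    seed: int = 0,
    one_side: bool = True,
    primary_only: bool = True,
    length: float | None = None,
    x_range: tuple[float, float] = (1000.0, 2000.0),
) -> list[Neuron]:
    """A single-type population for bundling/escape/repulsion experiments.

    Neurons of one type spread along one side (or both) with equally spaced
    pioneers; ``primary_only`` strips secondary axons for faster single-wave
    experiments.  Somata default to the caudal half so that ascending axons
    fit inside the modelled region instead of piling up against the rostral
    edge.
    """
    tables = make_measurement_tables(seed)
    # build both sides then optionally keep the left, preserving structure
    counts = {cell_type: n_per_side * 2}
    cfg = PopulationConfig(counts=counts, pioneers={cell_type: n_pioneers},
                           x_min=x_range[0], x_max=x_range[1])
    pop = build_population(cfg, tables, seed)
    if one_side:
        pop = [n for n in pop if n.side > 0]
    if primary_only:
        for n in pop:
            n.secondary_length = None
            n.branch_arc_length = None
            n.theta0_secondary = None
            n.pioneer_secondary = False
    if length is not None:
        for n in pop:
            n.primary_length = length
            if n.secondary_length is not None:
                n.secondary_length = length / 2.0
                n.branch_arc_length = min(n.branch_arc_length or length / 3.0,
                                          0.9 * length)
    return pop


def make_rb_population(*args, **kw) -> list[Neuron]:
    """RB-specific shorthand for :func:`make_type_population`."""
    return make_type_population("RB", *args, **kw)


# ---------------------------------------------------------------------------
# synthetic spike rasters

def make_synthetic_raster(
    freq_hz: float,
    n_cycles: int = 20,
    midcycle_dINs: int = 0,
    jitter_ms: float = 0.0,
    seed: int = 0,
    n_mn_per_side: int = 5,
    n_dIN_per_side: int = 10,
    one_sided: bool = False,
) -> SpikeRaster:
    """Alternating left/right motoneuron bursts with known detector truth.

    Left mn bursts sit at t = k*T (T = 1000/freq_hz), right bursts offset by
    half a cycle.  dINs spike inside their own side's bursts; the first
    ``midcycle_dINs`` left-side dINs additionally spike at their own side's
    mid-cycle in every cycle (ground truth for the mid-cycle counter).
    """
    if not 1.0 <= freq_hz <= 50.0:
        raise ValueError("freq_hz must be in [1, 50]")
    rng = np.random.default_rng([seed, 42])
    period = 1000.0 / freq_hz
    t0 = 20.0
    spikes: dict[int, np.ndarray] = {}
    types: dict[int, str] = {}
    sides: dict[int, int] = {}
    nid = 0

    burst_times = {1: [t0 + k * period for k in range(n_cycles)]}
    burst_times[-1] = [] if one_sided else [
        t0 + (k + 0.5) * period for k in range(n_cycles)
    ]

    for side in (1, -1):
        for j in range(n_mn_per_side):
            ts = []
            for bt in burst_times[side]:
                ts.append(bt + (rng.uniform(-jitter_ms, jitter_ms) if jitter_ms else 0.0)
                          + 0.2 * j)
            spikes[nid] = np.sort(np.asarray(ts))
            types[nid] = "mn"
            sides[nid] = side
            nid += 1

    for side in (1, -1):
        for j in range(n_dIN_per_side):
            ts = []
            for bt in burst_times[side]:
                ts.append(bt + 0.5 + 0.1 * j)
            is_mid = side == 1 and j < midcycle_dINs
            if is_mid:
                for bt in burst_times[side][:-1]:
                    ts.append(bt + 0.5 * period)  # during contralateral activity
            spikes[nid] = np.sort(np.asarray(ts))
            types[nid] = "dIN"
            sides[nid] = side
            nid += 1

    duration = t0 + (n_cycles + 1) * period
    return SpikeRaster(
        spikes=spikes, neuron_types=types, neuron_sides=sides,
        dt=0.0, duration=duration,
        stimulus={"synthetic": True, "freq_hz": freq_hz,
                  "midcycle_dINs": midcycle_dINs},
    )
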