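"""Packaged in-silico experiments comparing growth with and without
axon-axon interaction.

Each driver runs matched simulations (identical populations and RNG streams,
differing only in the sensitivity s) and returns per-seed summary metrics:

- ``bundling_experiment``: DV dispersion and bundle count of a dorsolateral
  sensory population across increasing fasciculation.
- ``repulsion_experiment``: mean tortuosity with weak repulsion vs none.
- ``gapped_barrier_experiment``: fraction of sensory axon points escaping
  the dorsal tract when its barriers are perforated, with and without
  fasciculation.  Primary axons only, so the outcome does not depend on the
  antiparallel-encounter convention.
- ``synapse_reduction_experiment``: total synapse counts of full
  connectomes, fasciculated vs not.
- ``recovery_problem``: a self-consistency calibration problem whose true
  parameters are known.
"""

from __future__ import annotations

import math

import numpy as np

from .environment import apply_gaps, build_standard_environment
from .gradient_fields import DEFAULT_TYPE_PARAMS, GradientField, NoiseSpec
from .growth_engine import InteractionParams, grow_all
from .metrics import bundle_stats, dv_dispersion, escape_fraction, mean_tortuosity
from .optimization import CostSpec, normalized_hist
from .population import PopulationConfig, build_population
from . import fixtures


def bundling_experiment(
    seeds, s_values=(0.0, 0.1, 0.5), n_axons: int = 20, n_pioneers: int = 4,
    length: float = 400.0, cell_type: str = "dla",
) -> dict[float, dict[str, list[float]]]:
    """DV dispersion and bundle count of a sensory population vs s."""
    env = build_standard_environment()
    f = GradientField()
    out = {s: {"dispersion": [], "bundle_count": []} for s in s_values}
    for seed in seeds:
        pop = fixtures.make_type_population(
            cell_type, n_axons, n_pioneers, seed=seed, length=length
        )
        for s in s_values:
            trajs = grow_all(pop, env, f, InteractionParams(s, s, 1.0), seed)
            out[s]["dispersion"].append(dv_dispersion(trajs))
            out[s]["bundle_count"].append(bundle_stats(trajs).mean_bundle_count)
    return out


def repulsion_experiment(
    seeds, s_repulse: float = -0.05, n_axons: int = 30, n_pioneers: int = 6,
    length: float = 400.0, cell_type: str = "RB",
) -> dict[float, list[float]]:
    """Mean tortuosity without interaction vs with weak repulsion."""
    env = build_standard_environment(dl_barrier_x_start=500.0)
    f = GradientField()
    out = {0.0: [], s_repulse: []}
    for seed in seeds:
        pop = fixtures.make_type_population(
            cell_type, n_axons, n_pioneers, seed=seed, length=length
        )
        for s in (0.0, s_repulse):
            trajs = grow_all(pop, env, f, InteractionParams(s, s, 1.0), seed)
            out[s].append(mean_tortuosity(trajs))
    return out


def gapped_barrier_experiment(
    seeds, s_fasc: float = 0.2, n_rb_per_side: int = 63, n_pioneers: int = 9,
    gap_length: float = 25.0, gap_interval: float = 25.0,
) -> dict[float, list[float]]:
    """Dorsal-tract escape (% of RB axon points) with perforated barriers.

    Both tract barriers carry 25 µm gaps at 25 µm intervals and span the
    whole arena; nine equally spaced pioneers per run, primary axons only.
    """
    env = build_standard_environment(dl_barrier_x_start=500.0)
    genv = apply_gaps(env, gap_length, gap_interval)
    f = GradientField()
    out = {0.0: [], s_fasc: []}
    for seed in seeds:
        pop = fixtures.make_rb_population(
            n_rb_per_side, n_pioneers, seed=seed, primary_only=True
        )
        for s in (0.0, s_fasc):
            trajs = grow_all(pop, genv, f, InteractionParams(s, s, 1.0), seed)
            out[s].append(escape_fraction(trajs, env.tract))
    return out


def synapse_reduction_experiment(seeds, s_fasc: float = 0.2):
    """Total synapses of matched full connectomes, s = 0 vs fasciculated."""
    from .io_cli import RunConfig, run_connectome

    out = {0.0: [], s_fasc: []}
    connectomes = {0.0: [], s_fasc: []}
    for seed in seeds:
        for s in (0.0, s_fasc):
            conn = run_connectome(RunConfig(seed=seed, s_pr=s, s_se=s))
            out[s].append(conn.count())
            connectomes[s].append(conn)
    return out, connectomes


def recovery_problem(
    cell_type: str = "aIN", seed: int = 1, replicates: int = 3,
    n_per_side: int = 10, length: float = 300.0,
):
    """Self-consistency calibration: recover known (k_dv, alpha).

    Target statistics are generated by the engine itself at the packaged
    default parameters; the cost evaluates candidates with common random
    numbers, so the truth has near-zero cost.
    """
    from .optimization import cost as cost_op

    tables = fixtures.make_measurement_tables(seed)
    cfg = PopulationConfig(counts={cell_type: n_per_side * 2},
                           pioneers={cell_type: 0})
    pop = [n for n in build_population(cfg, tables, seed) if n.side > 0]
    for n in pop:
        n.primary_length = length
        n.secondary_length = None
        n.branch_arc_length = None
        n.theta0_secondary = None
    env = build_standard_environment()
    base_field = GradientField()

    def run(params, run_seed):
        f = base_field.with_type_params(cell_type, k_dv=params["k_dv"])
        noise = NoiseSpec(alpha={**NoiseSpec().alpha, cell_type: params["alpha"]})
        return grow_all(pop, env, f, InteractionParams(0.0, 0.0, 1.0),
                        run_seed, noise)

    truth = {"k_dv": DEFAULT_TYPE_PARAMS[cell_type].k_dv,
             "alpha": NoiseSpec().alpha[cell_type]}
    bounds = {"k_dv": (0.0, 0.3), "alpha": (0.0, 0.5)}
    bin_edges = np.linspace(0.0, 145.0, 30)
    base_seed = 40_000 + seed
    target_trajs = [run(truth, base_seed + i) for i in range(replicates)]
    target_hist = np.mean(
        [normalized_hist(t, bin_edges) for t in target_trajs], axis=0
    )
    target_tort = float(np.mean([mean_tortuosity(t) for t in target_trajs]))
    spec = CostSpec(
        target_hist=target_hist, bin_edges=bin_edges,
        target_tortuosity=target_tort, replicates=replicates,
        base_seed=base_seed, bounds=bounds,
    )

    def cost_fn(params):
        return cost_op(params, spec, run)

    initial = {"k_dv": truth["k_dv"] * 0.4, "alpha": truth["alpha"] * 2.2}
    return {"cost_fn": cost_fn, "initial": initial, "bounds": bounds,
            "truth": truth, "spec": spec, "run": run}
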