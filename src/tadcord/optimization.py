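"""Pattern-search calibration of growth parameters.

Per-type growth parameters (gradient sensitivities and the noise half-width
alpha) are fitted so that generated axons statistically match target axons
in two respects: the dorso-ventral distribution of trajectory points and the
mean tortuosity.  The cost is

    cost = w_dv * L1(normalized DV histograms)
         + w_tort * |mean_tortuosity - target| / target

averaged over a fixed set of simulation replicates (common random numbers,
so the cost is a deterministic function of the parameters).  Minimization
uses compass pattern search: poll +/- step along each coordinate, accept the
first strict improvement, halve the step when a full poll fails, stop when
the step falls below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import dv_distribution, mean_tortuosity


class OptimizationDomainError(ValueError):
    pass


@dataclass
class CostSpec:
    """Targets, weights and evaluation policy for the calibration cost."""

    target_hist: np.ndarray          # normalized DV histogram (sums to 1)
    bin_edges: np.ndarray
    target_tortuosity: float
    w_dv: float = 1.0
    w_tort: float = 1.0
    replicates: int = 4
    base_seed: int = 1000            # replicate i uses seed base_seed + i
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.w_dv < 0 or self.w_tort < 0 or (self.w_dv == 0 and self.w_tort == 0):
            raise ValueError("weights must be >= 0 and not both zero")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        self.target_hist = np.asarray(self.target_hist, float)
        total = self.target_hist.sum()
        if total > 0:
            self.target_hist = self.target_hist / total


def normalized_hist(trajectories, bin_edges: np.ndarray) -> np.ndarray:
    h = dv_distribution(trajectories, bins=np.asarray(bin_edges))
    total = h.counts.sum()
    return h.counts / total if total else h.counts.astype(float)


def hist_l1(p: np.ndarray, q: np.ndarray) -> float:
    """L1 distance between two normalized histograms (in [0, 2])."""
    return float(np.abs(np.asarray(p, float) - np.asarray(q, float)).sum())


def cost(params: dict[str, float], cost_spec: CostSpec, engine_context) -> float:
    """Nonnegative calibration cost of a parameter set.

    ``engine_context`` is a callable (params, seed) -> trajectories; it runs
    the growth engine for one replicate.  Replicates use the fixed seeds
    base_seed..base_seed+replicates-1 (common random numbers).
    """
    for name, (lo, hi) in cost_spec.bounds.items():
        if name in params and not (lo <= params[name] <= hi):
            raise OptimizationDomainError(
                f"parameter {name}={params[name]} outside [{lo}, {hi}]"
            )
    hists = []
    torts = []
    for i in range(cost_spec.replicates):
        trajs = engine_context(params, cost_spec.base_seed + i)
        if cost_spec.w_dv:
            hists.append(normalized_hist(trajs, cost_spec.bin_edges))
        if cost_spec.w_tort:
            torts.append(mean_tortuosity(trajs))
    # replicate statistics are pooled before comparison, so evaluating the
    # very parameters that generated the targets (same seeds) costs zero
    c = 0.0
    if cost_spec.w_dv:
        c += cost_spec.w_dv * hist_l1(np.mean(hists, axis=0), cost_spec.target_hist)
    if cost_spec.w_tort:
        c += cost_spec.w_tort * abs(
            float(np.mean(torts)) - cost_spec.target_tortuosity
        ) / cost_spec.target_tortuosity
    return float(c)


@dataclass
class PatternSearchResult:
    best_params: dict[str, float]
    best_cost: float
    trace: list[dict]            # iteration, params, cost, step size
    n_evaluations: int
    converged: bool


def pattern_search(
    cost_fn,
    initial_params: dict[str, float],
    bounds: dict[str, tuple[float, float]],
    initial_step: float | dict[str, float] = 0.1,
    shrink: float = 0.5,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> PatternSearchResult:
    """Compass search with step halving; cost trace is non-increasing.

    Polls +step then -step along each coordinate in turn, accepting the
    first strict improvement; when a full poll round fails the step is
    multiplied by ``shrink``.  Polls falling outside ``bounds`` are clipped
    to the boundary.  Stops when every coordinate step is below ``tol`` or
    after ``max_iter`` iterations.
    """
    names = list(initial_params)
    x = dict(initial_params)
    for name in names:
        lo, hi = bounds[name]
        if not lo <= x[name] <= hi:
            raise OptimizationDomainError(f"initial {name}={x[name]} outside bounds")
    if isinstance(initial_step, dict):
        step = dict(initial_step)
    else:
        step = {n: float(initial_step) for n in names}

    best = cost_fn(x)
    n_eval = 1
    trace = [{"iteration": 0, "params": dict(x), "cost": best,
              "step": max(step.values())}]
    converged = False
    for it in range(1, max_iter + 1):
        if max(step.values()) < tol:
            converged = True
            break
        improved = False
        for name in names:
            for direction in (+1.0, -1.0):
                lo, hi = bounds[name]
                cand = dict(x)
                cand[name] = min(hi, max(lo, x[name] + direction * step[name]))
                if cand[name] == x[name]:
                    continue
                c = cost_fn(cand)
                n_eval += 1
                if c < best:
                    x, best = cand, c
                    improved = True
                    break
            if improved:
                break
        if not improved:
            step = {n: s * shrink for n, s in step.items()}
        trace.append({"iteration": it, "params": dict(x), "cost": best,
                      "step": max(step.values())})
    return PatternSearchResult(
        best_params=x, best_cost=best, trace=trace,
        n_evaluations=n_eval, converged=converged,
    )
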