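"""Axon-dendrite crossing detection and probabilistic synapse formation.

Each neuron's dendritic field is a single vertical (dorso-ventral) line
segment at its soma's RC position.  Whenever a grown axon's elongation step
crosses a dendrite, a synapse forms with a probability specific to the
(presynaptic type, postsynaptic type) pair; every crossing is an independent
Bernoulli trial, so an axon repeatedly crossing the same dendrite can make
multiple contacts.  Segments laid by commissural axons before they crossed
the ventral midline are ineligible, which (together with the floor-plate
barrier) restricts commissural output to the contralateral side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth_engine import Trajectory
from .population import CELL_TYPES, Neuron, TYPE_ORDER


class MatrixError(KeyError):
    """A connection probability is missing for an occurring type pair."""


@dataclass(frozen=True)
class Dendrite:
    """Vertical dendritic segment at the soma's RC position, one body side."""

    neuron_id: int
    cell_type: str
    side: int
    x: float
    y_lo: float
    y_hi: float

    def __post_init__(self) -> None:
        if self.y_lo > self.y_hi:
            raise ValueError("dendrite requires y_lo <= y_hi")


def dendrites_from_population(population: list[Neuron]) -> list[Dendrite]:
    return [
        Dendrite(n.id, n.cell_type, n.side, n.soma[0], n.dendrite[0], n.dendrite[1])
        for n in population
    ]


@dataclass(frozen=True)
class ProbabilityMatrix:
    """P[pre_type][post_type] of synapse formation at a crossing.

    The packaged default is a uniform placeholder (0.5 for every ordered
    pair); the real pairwise probabilities come from paired recordings and
    are supplied through the run configuration.
    """

    table: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for pre, row in self.table.items():
            for post, p in row.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"P[{pre}][{post}]={p} outside [0, 1]")

    def get(self, pre: str, post: str) -> float:
        try:
            return self.table[pre][post]
        except KeyError:
            raise MatrixError(f"no connection probability for {pre} -> {post}")

    @classmethod
    def uniform(cls, p: float = 0.5) -> "ProbabilityMatrix":
        return cls({a: {b: p for b in TYPE_ORDER} for a in TYPE_ORDER})

    def scaled(self, factor: float) -> "ProbabilityMatrix":
        return ProbabilityMatrix(
            {a: {b: min(1.0, p * factor) for b, p in row.items()}
             for a, row in self.table.items()}
        )


@dataclass(frozen=True)
class Synapse:
    pre_id: int
    post_id: int
    pre_type: str
    post_type: str
    axon_class: str
    x: float
    y: float
    step: int  # index of the presynaptic segment (arc position / delta)


@dataclass
class Connectome:
    population: list[Neuron]
    synapses: list[Synapse]
    provenance: dict = field(default_factory=dict)

    def by_id(self) -> dict[int, Neuron]:
        return {n.id: n for n in self.population}

    def count(self) -> int:
        return len(self.synapses)


def _segment_dendrite_crossing(
    x0: float, y0: float, x1: float, y1: float, d: Dendrite
):
    """Intersection point of a step segment with a vertical dendrite, or None.

    Endpoint touching counts as a crossing.  A degenerate segment lying on
    the dendrite's x counts if the y intervals overlap.
    """
    if x0 == x1:
        if x0 != d.x:
            return None
        lo, hi = min(y0, y1), max(y0, y1)
        if hi < d.y_lo or lo > d.y_hi:
            return None
        y_c = min(max(y0, d.y_lo), d.y_hi)
        return (d.x, y_c)
    if (x0 - d.x) * (x1 - d.x) > 0:
        return None
    t = (d.x - x0) / (x1 - x0)
    y_c = y0 + t * (y1 - y0)
    if d.y_lo <= y_c <= d.y_hi:
        return (d.x, y_c)
    return None


class DendriteIndex:
    """Dendrites sorted by RC position for fast per-segment queries."""

    def __init__(self, dendrites: list[Dendrite]):
        self.dendrites = sorted(dendrites, key=lambda d: (d.x, d.neuron_id))
        self.xs = np.array([d.x for d in self.dendrites])

    def candidates(self, x_lo: float, x_hi: float) -> list[Dendrite]:
        i = int(np.searchsorted(self.xs, x_lo, side="left"))
        j = int(np.searchsorted(self.xs, x_hi, side="right"))
        return self.dendrites[i:j]


def detect_crossings(
    segment: tuple[tuple[float, float], tuple[float, float]],
    dendrites: "DendriteIndex | list[Dendrite]",
) -> list[tuple[Dendrite, tuple[float, float]]]:
    """All dendrites crossed by one elongation segment, with crossing points."""
    (x0, y0), (x1, y1) = segment
    if isinstance(dendrites, DendriteIndex):
        cands = dendrites.candidates(min(x0, x1), max(x0, x1))
    else:
        cands = dendrites
    out = []
    for d in cands:
        pt = _segment_dendrite_crossing(x0, y0, x1, y1, d)
        if pt is not None:
            out.append((d, pt))
    return out


def _all_crossings(
    trajectories: dict[tuple[int, str], Trajectory],
    dendrites: list[Dendrite],
    population: list[Neuron],
) -> list[tuple[int, str, int, int, float, float]]:
    """(pre_id, axon_class, step, post_id, x, y) for every eligible crossing.

    Vectorized over segments per (trajectory, dendrite) pair.  Excludes
    pre-crossing-phase segments, self-crossings, and (belt and braces, the
    geometry already forbids it) commissural-presynaptic contacts onto
    neurons ipsilateral to the presynaptic soma.
    """
    by_id = {n.id: n for n in population}
    crossings = []
    for (nid, klass) in sorted(trajectories):
        traj = trajectories[(nid, klass)]
        pts = traj.points
        if len(pts) < 2:
            continue
        x0s, y0s = pts[:-1, 0], pts[:-1, 1]
        x1s, y1s = pts[1:, 0], pts[1:, 1]
        # a segment is eligible if the point it lays down is not pre-crossing
        eligible = traj.point_phases[1:] != "pre_crossing"
        pre = by_id[nid]
        for d in dendrites:
            if d.neuron_id == nid:
                continue
            if pre.is_commissural and d.side == pre.side:
                continue
            lo = np.minimum(x0s, x1s)
            hi = np.maximum(x0s, x1s)
            hit = (lo <= d.x) & (d.x <= hi) & eligible
            if not hit.any():
                continue
            idx = np.nonzero(hit)[0]
            dx = x1s[idx] - x0s[idx]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(dx != 0.0, (d.x - x0s[idx]) / dx, 0.0)
            y_c = y0s[idx] + t * (y1s[idx] - y0s[idx])
            ok = (d.y_lo <= y_c) & (y_c <= d.y_hi)
            # degenerate vertical segments exactly on the dendrite line
            vert = dx == 0.0
            if vert.any():
                s_lo = np.minimum(y0s[idx], y1s[idx])
                s_hi = np.maximum(y0s[idx], y1s[idx])
                overlap = (s_hi >= d.y_lo) & (s_lo <= d.y_hi)
                ok = np.where(vert, overlap, ok)
                y_c = np.where(vert, np.clip(y0s[idx], d.y_lo, d.y_hi), y_c)
            for k, j in enumerate(idx):
                if ok[k]:
                    crossings.append(
                        (nid, klass, int(j), d.neuron_id, float(d.x), float(y_c[k]))
                    )
    return crossings


def form_synapses(
    trajectories: dict[tuple[int, str], Trajectory],
    dendrites: list[Dendrite],
    matrix: ProbabilityMatrix,
    seed: int,
    population: list[Neuron],
    provenance: dict | None = None,
) -> Connectome:
    """Bernoulli synapse formation at every eligible crossing.

    Deterministic given seed: crossings are enumerated in a canonical order
    (pre id, axon class, step, post id) and each draws once from a single
    stream.
    """
    by_id = {n.id: n for n in population}
    crossings = _all_crossings(trajectories, dendrites, population)
    crossings.sort()
    rng = np.random.default_rng([seed, 7])
    draws = rng.random(len(crossings))
    synapses = []
    for (c, u) in zip(crossings, draws):
        pre_id, klass, step, post_id, x, y = c
        pre_t = by_id[pre_id].cell_type
        post_t = by_id[post_id].cell_type
        if u < matrix.get(pre_t, post_t):
            synapses.append(
                Synapse(pre_id, post_id, pre_t, post_t, klass, x, y, step)
            )
    prov = {"seed": seed, "n_crossings": len(crossings)}
    prov.update(provenance or {})
    return Connectome(population=population, synapses=synapses, provenance=prov)


def prune_synapses(connectome: Connectome, keep_prob: float, seed: int) -> Connectome:
    """Retain each synapse independently with probability keep_prob."""
    if not 0.0 <= keep_prob <= 1.0:
        raise ValueError("keep_prob must be in [0, 1]")
    rng = np.random.default_rng([seed, 11])
    keep = rng.random(len(connectome.synapses)) < keep_prob
    kept = [s for s, k in zip(connectome.synapses, keep) if k]
    prov = dict(connectome.provenance)
    prov["pruned_keep_prob"] = keep_prob
    return Connectome(connectome.population, kept, prov)


def synapse_count_matrix(
    connectome: Connectome,
    reference: Connectome | None = None,
    negligible_threshold: int = 50,
) -> dict:
    """Type x type synapse counts (both sides pooled), optional % change.

    Returns {"counts": DataFrame, and with a reference connectome also
    "reference_counts", "percent_change", "negligible" (pairs below the
    threshold in both connectomes)}.
    """
    def counts_of(c: Connectome) -> pd.DataFrame:
        m = pd.DataFrame(0, index=list(TYPE_ORDER), columns=list(TYPE_ORDER))
        for s in c.synapses:
            m.loc[s.pre_type, s.post_type] += 1
        return m

    counts = counts_of(connectome)
    out = {"counts": counts}
    if reference is not None:
        ref = counts_of(reference)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = (counts - ref) / ref.replace(0, np.nan) * 100.0
        out["reference_counts"] = ref
        out["percent_change"] = pct
        out["negligible"] = (counts < negligible_threshold) & (
            ref < negligible_threshold
        )
    return out
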