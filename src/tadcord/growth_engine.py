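"""Lock-step parallel axon growth with fasciculation/repulsion.

All axons grow simultaneously in discrete time, one elongation of Delta
(default 1 µm) per time unit.  Each step updates the tip angle from three
influences: the gradient cues, uniform angular noise, and — new relative to
sequential growth models — the nearest point of another axon of the same
type within range r.  The interaction blends the gradient-and-noise
candidate angle theta_A with an interaction angle theta_B:

    theta_A   = theta_n - g_rc*sin(theta_n) + g_dv*cos(theta_n) + xi_n
    theta_B   = theta_p          (s > 0, fasciculation: copy the neighbour)
              = theta_p_perp     (s < 0, repulsion: grow away, perpendicular)
    theta_n+1 = theta_A + |s| * wrap(theta_B - theta_A)

where theta_p is the growth angle recorded when the neighbouring axon laid
down its nearest point.  The blend is circular-aware: it equals the plain
linear combination (1-|s|)*theta_A + |s|*theta_B whenever the two angles are
less than pi apart, but is chart-independent.  s = 0 disables interaction
entirely; |s| = 1 slaves the growing tip to the neighbour.

Axons interact only with axons of the *same* cell type (primary or
secondary), never with their own neuron's axons, and commissural axons
neither exert nor feel interaction before they have crossed the ventral
midline.  Nearest-point queries are served from a uniform spatial hash with
cell size max(r, Delta); a brute-force scan defines correctness.

Each axon consumes an independent RNG stream keyed by (master seed, neuron
id, axon class), which makes trajectories at s = 0 bit-identical to growing
the same axon alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import environment as env_mod
from .environment import Environment
from .gradient_fields import GradientField, NoiseSpec, evaluate, sample_noise
from .population import CELL_TYPES, Neuron, _wrap

TWO_PI = 2.0 * math.pi
HALF_PI = 0.5 * math.pi


class UsageError(RuntimeError):
    pass


class NonTerminationError(RuntimeError):
    pass


@dataclass(frozen=True)
class StepParams:
    """Elongation per step, µm.  One time unit = time to elongate delta."""

    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass(frozen=True)
class InteractionParams:
    """Axon-axon sensitivity s (per axon class) and range r, µm.

    s > 0: fasciculation (attraction); s < 0: repulsion; s = 0: none.
    """

    s_pr: float = 0.0
    s_se: float = 0.0
    r: float = 1.0
    #: attraction onto an antiparallel neighbour (relative angle > pi/2):
    #: "copy" takes the neighbour's growth angle literally (the follower
    #: turns around — the default, matching the angle-copy update rule),
    #: "align" follows the neighbour's axis in the axon's own direction of
    #: travel, "ignore" disables the interaction for that step
    antiparallel: str = "copy"

    def __post_init__(self) -> None:
        if not (abs(self.s_pr) <= 1 and abs(self.s_se) <= 1):
            raise ValueError("|s| must be <= 1")
        if self.r <= 0:
            raise ValueError("interaction range r must be positive")
        if self.antiparallel not in ("align", "copy", "ignore"):
            raise ValueError(f"unknown antiparallel mode {self.antiparallel!r}")


@dataclass
class GrowthState:
    """A growing axon: polyline, angle history and phase."""

    neuron: Neuron
    axon_class: str               # "primary" | "secondary"
    xs: list[float]
    ys: list[float]
    thetas: list[float]           # thetas[k] = angle of segment k->k+1; the
                                  # stored angle *at* point k (theta_p) is
                                  # thetas[k-1], and theta0 at point 0
    point_phases: list[str]
    clipped: list[bool]
    theta0: float
    phase: str                    # "normal" | "pre_crossing" | "crossed"
    remaining: int                # steps left to grow
    active: bool
    start_time: float
    crossed_midline: bool = False
    stuck_count: int = 0
    rng: np.random.Generator | None = None

    @property
    def tip(self) -> tuple[float, float]:
        return (self.xs[-1], self.ys[-1])

    @property
    def tip_angle(self) -> float:
        return self.thetas[-1] if self.thetas else self.theta0

    def angle_at(self, k: int) -> float:
        """Growth angle recorded at point k (initial angle at the root)."""
        return self.theta0 if k == 0 else self.thetas[k - 1]


@dataclass
class Trajectory:
    """Finished axon path (immutable result of grow_all)."""

    neuron_id: int
    cell_type: str
    side: int
    axon_class: str
    points: np.ndarray          # (n, 2)
    angles: np.ndarray          # (n-1,) segment angles
    point_phases: np.ndarray    # (n,) phase labels per point
    clipped: np.ndarray         # (n-1,) whether the segment was barrier-clipped
    start_time: float
    stuck: bool = False

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# nearest-neighbour machinery

def nearest_axon_point(
    tip: tuple[float, float],
    candidates,
    r: float,
    exclude_neuron: int | None = None,
):
    """Globally closest same-type axon point within Euclidean distance r.

    ``candidates`` is an iterable of (x, y, theta, neuron_id, step_index).
    Returns ((x, y), theta_p) or None.  Ties are broken by (lower neuron id,
    lower step index).  This is the reference (brute-force) implementation;
    the engine uses a spatial hash that must agree with it.
    """
    tx, ty = tip
    r2 = r * r
    best = None
    for (x, y, theta, nid, step) in candidates:
        if nid == exclude_neuron:
            continue
        d2 = (x - tx) ** 2 + (y - ty) ** 2
        if d2 > r2:
            continue
        key = (d2, nid, step)
        if best is None or key < best[0]:
            best = (key, (x, y), theta)
    if best is None:
        return None
    return (best[1], best[2])


class SpatialHash:
    """Uniform grid over axon points; 3x3 neighbourhood covers radius <= cell."""

    __slots__ = ("cell", "inv_cell", "cells")

    def __init__(self, cell_size: float):
        self.cell = cell_size
        self.inv_cell = 1.0 / cell_size
        self.cells: dict[tuple[int, int], list] = {}

    def insert(self, x: float, y: float, theta: float, nid: int, step: int) -> None:
        key = (int(math.floor(x * self.inv_cell)), int(math.floor(y * self.inv_cell)))
        bucket = self.cells.get(key)
        if bucket is None:
            self.cells[key] = [(x, y, theta, nid, step)]
        else:
            bucket.append((x, y, theta, nid, step))

    def query_nearest(self, tx: float, ty: float, r: float, exclude_nid: int):
        """Same contract and tie-breaking as nearest_axon_point."""
        r2 = r * r
        ix = int(math.floor(tx * self.inv_cell))
        iy = int(math.floor(ty * self.inv_cell))
        cells = self.cells
        best_key = None
        best_pt = None
        best_theta = 0.0
        for cx in (ix - 1, ix, ix + 1):
            for cy in (iy - 1, iy, iy + 1):
                bucket = cells.get((cx, cy))
                if not bucket:
                    continue
                for (x, y, theta, nid, step) in bucket:
                    if nid == exclude_nid:
                        continue
                    dx = x - tx
                    dy = y - ty
                    d2 = dx * dx + dy * dy
                    if d2 > r2:
                        continue
                    key = (d2, nid, step)
                    if best_key is None or key < best_key:
                        best_key = key
                        best_pt = (x, y)
                        best_theta = theta
        if best_key is None:
            return None
        return (best_pt, best_theta)


# ---------------------------------------------------------------------------
# single-step update

def growth_step(
    state: GrowthState,
    fields: GradientField,
    noise: NoiseSpec,
    interaction: InteractionParams,
    neighbor,
    environment: Environment,
    delta: float = 1.0,
) -> GrowthState:
    """Advance one elongation step.  ``neighbor`` is ((x, y), theta_p) or None."""
    if not state.active:
        raise UsageError("growth_step on an inactive axon")
    ct = state.neuron.cell_type
    x_n, y_n = state.tip
    theta_n = state.tip_angle
    phase = state.phase

    direction = CELL_TYPES[ct].primary_direction
    if state.axon_class == "secondary":
        direction = "descending" if direction == "ascending" else "ascending"
    g_rc, g_dv = evaluate(fields, x_n, y_n, ct, phase, direction)
    xi = sample_noise(noise.for_type(ct, phase), state.rng)
    theta_a = theta_n - g_rc * math.sin(theta_n) + g_dv * math.cos(theta_n) + xi

    s = interaction.s_pr if state.axon_class == "primary" else interaction.s_se
    if neighbor is not None and s != 0.0 and phase != "pre_crossing":
        (px, py), theta_p = neighbor
        if s > 0.0:
            # adhesion copies the neighbour's growth angle (theta_B =
            # theta_p).  For an antiparallel neighbour (relative angle >
            # pi/2, e.g. a descending secondary meeting the ascending
            # primary scaffold) the configured mode applies: literal copy
            # (U-turn), alignment with the track's axis, or no interaction
            theta_b = theta_p
            if abs(_wrap(theta_p - theta_a)) > HALF_PI:
                mode = interaction.antiparallel
                if mode == "align":
                    theta_b = theta_p + math.pi
                elif mode == "ignore":
                    theta_b = None
        else:
            # perpendicular pointing away from the neighbour point; an exact
            # tie resolves toward theta_p + pi/2
            cand = theta_p + HALF_PI
            if math.cos(cand) * (x_n - px) + math.sin(cand) * (y_n - py) >= 0.0:
                theta_b = cand
            else:
                theta_b = theta_p - HALF_PI
        if theta_b is None:
            theta_new = _wrap(theta_a)
        else:
            theta_new = _wrap(theta_a + abs(s) * _wrap(theta_b - theta_a))
    else:
        theta_new = _wrap(theta_a)

    x_p = x_n + delta * math.cos(theta_new)
    y_p = y_n + delta * math.sin(theta_new)
    x_f, y_f, theta_f, was_clipped = env_mod.resolve_step(
        environment, (x_n, y_n), (x_p, y_p), theta_new, ct, phase
    )

    if was_clipped and (x_f - x_n) ** 2 + (y_f - y_n) ** 2 < 1e-18:
        state.stuck_count += 1
    else:
        state.stuck_count = 0

    state.xs.append(x_f)
    state.ys.append(y_f)
    state.thetas.append(theta_f)
    state.clipped.append(was_clipped)
    state.remaining -= 1

    if state.neuron.is_commissural and state.phase == "pre_crossing":
        commissural_update(state, environment)
    state.point_phases.append(state.phase)

    if state.remaining <= 0 or state.stuck_count >= 2:
        state.active = False
    return state


def commissural_update(state: GrowthState, environment: Environment) -> GrowthState:
    """Advance the crossing state machine of a commissural axon.

    The axon stays pre_crossing while on its soma side or inside the floor
    plate; once its trajectory has crossed y = 0 and the tip exits the floor
    plate (|y| >= floor level) on the contralateral side, it becomes crossed
    and switches to the regular parameter set, fasciculation and synapse
    eligibility.
    """
    if not state.neuron.is_commissural:
        raise UsageError(f"commissural_update on type {state.neuron.cell_type}")
    if state.phase != "pre_crossing":
        return state
    y_prev = state.ys[-2] if len(state.ys) > 1 else state.ys[-1]
    y_new = state.ys[-1]
    if y_prev == 0.0 or y_new == 0.0 or (y_prev > 0) != (y_new > 0):
        state.crossed_midline = True
    floor = _floor_level(environment)
    if (
        state.crossed_midline
        and abs(y_new) >= floor
        and (y_new > 0) != (state.neuron.side > 0)
    ):
        state.phase = "crossed"
    return state


def _floor_level(environment: Environment) -> float:
    levels = [abs(b.y_level) for b in environment.barriers if b.exempt_types]
    return min(levels) if levels else 25.0


# ---------------------------------------------------------------------------
# scheduling

def build_schedule(
    population: list[Neuron], wave_spacing: float = 200.0, delta: float = 1.0
) -> dict[tuple[int, str], float]:
    """Start times for every axon; writes them back onto the neurons.

    Primary wave: pioneers of each (type, side) group start at t = 0; the
    group's followers start sequentially, most rostral (lowest soma x) first,
    ``wave_spacing`` time units apart, beginning when the group's last
    pioneer finishes.  The secondary wave begins only after every primary
    axon has reached full length, with the same pioneer/follower structure
    (secondary pioneers are the pioneer neurons that have secondary axons).
    """
    start: dict[tuple[int, str], float] = {}
    groups: dict[tuple[str, int], list[Neuron]] = {}
    for n in population:
        groups.setdefault((n.cell_type, n.side), []).append(n)

    primary_finish = 0.0
    for members in groups.values():
        pioneers = [n for n in members if n.pioneer_primary]
        followers = sorted(
            (n for n in members if not n.pioneer_primary),
            key=lambda n: (n.soma[0], n.id),
        )
        pio_steps = max((math.ceil(n.primary_length / delta) for n in pioneers), default=0)
        for n in pioneers:
            start[(n.id, "primary")] = 0.0
            n.start_primary = 0.0
        for k, n in enumerate(followers):
            t = pio_steps + k * wave_spacing
            start[(n.id, "primary")] = t
            n.start_primary = t
        finish = max(
            (start[(n.id, "primary")] + math.ceil(n.primary_length / delta) for n in members),
            default=0.0,
        )
        primary_finish = max(primary_finish, finish)

    for members in groups.values():
        withsec = [n for n in members if n.secondary_length is not None]
        if not withsec:
            continue
        pioneers = [n for n in withsec if n.pioneer_secondary]
        followers = sorted(
            (n for n in withsec if not n.pioneer_secondary),
            key=lambda n: (n.soma[0], n.id),
        )
        pio_steps = max(
            (math.ceil(n.secondary_length / delta) for n in pioneers), default=0
        )
        for n in pioneers:
            start[(n.id, "secondary")] = primary_finish
            n.start_secondary = primary_finish
        for k, n in enumerate(followers):
            t = primary_finish + pio_steps + k * wave_spacing
            start[(n.id, "secondary")] = t
            n.start_secondary = t
    return start


# ---------------------------------------------------------------------------
# the lock-step loop

_CLASS_CODE = {"primary": 1, "secondary": 2}


def _axon_rng(seed: int, neuron_id: int, axon_class: str) -> np.random.Generator:
    return np.random.default_rng([seed, neuron_id, _CLASS_CODE[axon_class]])


def _make_state(neuron: Neuron, axon_class: str, start_time: float,
                delta: float, seed: int) -> GrowthState:
    if axon_class == "primary":
        x0, y0 = neuron.soma
        theta0 = neuron.theta0
        length = neuron.primary_length
        phase = "pre_crossing" if neuron.is_commissural else "normal"
    else:
        # the sprout point on the primary is filled in when the wave starts
        x0, y0 = neuron.soma
        theta0 = neuron.theta0_secondary
        length = neuron.secondary_length
        # secondary commissural axons arise on the contralateral side, after
        # crossing, so they grow in the regular (crossed) regime
        phase = "crossed" if neuron.is_commissural else "normal"
    return GrowthState(
        neuron=neuron, axon_class=axon_class,
        xs=[x0], ys=[y0], thetas=[], point_phases=[phase], clipped=[],
        theta0=theta0, phase=phase,
        remaining=max(1, math.ceil(length / delta)),
        active=True, start_time=start_time,
        rng=_axon_rng(seed, neuron.id, axon_class),
    )


def grow_all(
    population: list[Neuron],
    environment: Environment,
    fields: GradientField,
    interaction: InteractionParams,
    seed: int,
    noise: NoiseSpec | None = None,
    step_params: StepParams | None = None,
    wave_spacing: float = 200.0,
    max_extra_steps: int = 10_000,
) -> dict[tuple[int, str], Trajectory]:
    """Grow every axon of the population; fully deterministic given seed.

    Returns {(neuron_id, axon_class): Trajectory}.  Secondary axons sprout at
    the stored branch point of the finished primary, aimed in the opposite
    RC direction.  Interaction candidates are all same-type points already
    laid down by other neurons (pioneers and concurrent followers alike),
    except points laid during a commissural pre-crossing phase.
    """
    noise = noise or NoiseSpec()
    sp = step_params or StepParams()
    delta = sp.delta
    schedule = build_schedule(population, wave_spacing, delta)

    hashes: dict[str, SpatialHash] = {
        t: SpatialHash(max(interaction.r, delta)) for t in CELL_TYPES
    }
    interacting = (interaction.s_pr != 0.0) or (interaction.s_se != 0.0)

    primary_states = {
        n.id: _make_state(n, "primary", schedule[(n.id, "primary")], delta, seed)
        for n in population
    }
    secondary_start = {
        n.id: schedule[(n.id, "secondary")]
        for n in population
        if (n.id, "secondary") in schedule
    }

    # event lists sorted by start time, processed lock-step
    pending: list[tuple[float, int, str]] = sorted(
        [(st.start_time, nid, "primary") for nid, st in primary_states.items()]
        + [(t, nid, "secondary") for nid, t in secondary_start.items()]
    )
    live: list[GrowthState] = []
    states: dict[tuple[int, str], GrowthState] = {}
    done: dict[tuple[int, str], Trajectory] = {}

    t = 0.0
    horizon = (max(s for s, _, _ in pending) if pending else 0.0) + max_extra_steps + sum(
        math.ceil(n.primary_length / delta)
        + math.ceil((n.secondary_length or 0.0) / delta)
        for n in population
    )
    p_idx = 0
    while p_idx < len(pending) or live:
        if t > horizon:
            raise NonTerminationError(
                f"growth loop exceeded {horizon} time units; "
                f"{len(live)} axons still active"
            )
        # activate axons whose start time has passed
        while p_idx < len(pending) and pending[p_idx][0] <= t:
            _, nid, klass = pending[p_idx]
            p_idx += 1
            if klass == "primary":
                st = primary_states[nid]
            else:
                st = _sprout_secondary(
                    primary_states[nid], delta, seed, secondary_start[nid]
                )
                if st is None:
                    continue
            states[(nid, klass)] = st
            live.append(st)
            _insert_point(hashes, st, 0)

        # one growth step per live axon, in (neuron id, class) order
        live.sort(key=lambda s: (s.neuron.id, s.axon_class))
        still = []
        for st in live:
            r = interaction.r
            s_here = interaction.s_pr if st.axon_class == "primary" else interaction.s_se
            neighbor = None
            if interacting and s_here != 0.0 and st.phase != "pre_crossing":
                tx, ty = st.tip
                neighbor = hashes[st.neuron.cell_type].query_nearest(
                    tx, ty, r, st.neuron.id
                )
            growth_step(st, fields, noise, interaction, neighbor,
                        environment, delta)
            if st.phase != "pre_crossing":
                _insert_point(hashes, st, len(st.xs) - 1)
            if st.active:
                still.append(st)
            else:
                done_key = (st.neuron.id, st.axon_class)
                done[done_key] = _finish(st)
        live = still
        t += 1.0

    # axons that never started (e.g. zero-length) — should not happen, but
    # keep the contract total
    for key, st in states.items():
        if key not in done:
            done[key] = _finish(st)
    return done


def _insert_point(hashes, st: GrowthState, k: int) -> None:
    if st.point_phases[k] == "pre_crossing":
        return
    hashes[st.neuron.cell_type].insert(
        st.xs[k], st.ys[k], st.angle_at(k), st.neuron.id, k
    )


def _sprout_secondary(
    primary: GrowthState, delta: float, seed: int, start_time: float
) -> GrowthState | None:
    n = primary.neuron
    if n.secondary_length is None:
        return None
    k = min(int(round((n.branch_arc_length or 0.0) / delta)), len(primary.xs) - 1)
    if n.is_commissural:
        # commissural branch points lie beyond the floor-plate crossing, so
        # the secondary arises on the contralateral side; a primary that
        # never crossed (stuck) yields no secondary
        crossed_idx = next(
            (i for i, p in enumerate(primary.point_phases) if p == "crossed"), None
        )
        if crossed_idx is None:
            return None
        k = max(k, crossed_idx)
    st = _make_state(n, "secondary", start_time, delta, seed)
    st.xs = [primary.xs[k]]
    st.ys = [primary.ys[k]]
    st.point_phases = [st.phase]
    return st


def _finish(st: GrowthState) -> Trajectory:
    return Trajectory(
        neuron_id=st.neuron.id,
        cell_type=st.neuron.cell_type,
        side=st.neuron.side,
        axon_class=st.axon_class,
        points=np.column_stack([st.xs, st.ys]),
        angles=np.asarray(st.thetas),
        point_phases=np.asarray(st.point_phases, dtype=object),
        clipped=np.asarray(st.clipped, dtype=bool),
        start_time=st.start_time,
        stuck=st.stuck_count >= 2,
    )
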