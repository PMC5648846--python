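"""2D growth arena of the hatchling tadpole spinal cord.

The spinal cord is modelled as a flat rectangle, the result of opening the
neural tube like a book along the dorsal midline.  The x axis runs
rostro-caudally (distance from the midbrain, µm); the y axis runs
dorso-ventrally with y > 0 on the left side of the body, y < 0 on the right,
and y = 0 at the ventral midline.  Somata of particular cell types form hard
longitudinal barriers to axon growth: Rohon-Beard (RB) somata at |y| = 137,
dorsolateral interneuron somata at |y| = 127 (together these bound the dorsal
tract that confines RB axons), and the floor plate boundary at |y| = 25 which
only commissural axons may cross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


class ConfigurationError(ValueError):
    """Raised for inconsistent arena/barrier configuration."""


@dataclass(frozen=True)
class Arena:
    """Rectangular modelling area, µm.  y > 0 is the left side of the body."""

    x_min: float = 500.0
    x_max: float = 2000.0
    y_abs_max: float = 145.0

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ConfigurationError(
                f"arena requires x_min < x_max, got [{self.x_min}, {self.x_max}]"
            )
        if not self.y_abs_max > 0:
            raise ConfigurationError("arena requires y_abs_max > 0")

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and abs(y) <= self.y_abs_max


@dataclass(frozen=True)
class Barrier:
    """A longitudinal hard barrier at a fixed DV level.

    ``gaps`` are open intervals of x inside [x_start, x_end] where the barrier
    is absent (e.g. spaces between the somata that form it).  ``exempt_types``
    are cell types allowed through (commissural types at the floor plate);
    exemption applies only while an axon is in its pre-crossing phase, so a
    commissural axon that has crossed cannot return.
    """

    y_level: float
    x_start: float
    x_end: float
    gaps: tuple[tuple[float, float], ...] = ()
    exempt_types: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.x_start < self.x_end:
            raise ConfigurationError(
                f"barrier requires x_start < x_end, got [{self.x_start}, {self.x_end}]"
            )
        prev_hi = None
        for lo, hi in sorted(self.gaps):
            if not (self.x_start <= lo < hi <= self.x_end):
                raise ConfigurationError(f"gap ({lo}, {hi}) outside barrier span")
            if prev_hi is not None and lo < prev_hi:
                raise ConfigurationError("barrier gaps must be pairwise disjoint")
            prev_hi = hi

    def is_open_at(self, x: float) -> bool:
        """True if x falls inside a gap (the barrier does not block there)."""
        for lo, hi in self.gaps:
            if lo < x < hi:
                return True
        return False


@dataclass(frozen=True)
class DorsalTract:
    """Dorsal corridor containing RB axons: y_inner <= |y| <= y_outer."""

    y_inner: float = 127.0
    y_outer: float = 137.0

    def __post_init__(self) -> None:
        if not self.y_inner < self.y_outer:
            raise ConfigurationError("dorsal tract requires y_inner < y_outer")

    def contains(self, y: float) -> bool:
        return self.y_inner <= abs(y) <= self.y_outer


@dataclass(frozen=True)
class Environment:
    arena: Arena
    barriers: tuple[Barrier, ...]
    tract: DorsalTract


#: cell types allowed through the floor-plate barrier while pre-crossing
COMMISSURAL_TYPES = frozenset({"dlc", "cIN"})

#: how far inside the obstruction line a blocked growth cone is replaced, µm
_SLIDE_OFFSET = 1e-6


def build_standard_environment(
    arena: Arena | None = None,
    *,
    rb_barrier_y: float = 137.0,
    dl_barrier_y: float = 127.0,
    dl_barrier_x_start: float = 700.0,
    floor_plate_y: float = 25.0,
    commissural_types: frozenset[str] = COMMISSURAL_TYPES,
) -> Environment:
    """Standard intact environment: six barriers (three per side).

    Per side: the RB-soma barrier at |y| = 137 spanning the whole arena, the
    dla/dlc-soma barrier at |y| = 127 for x > 700, and the floor-plate
    boundary at |y| = 25 spanning the whole arena with commissural types
    exempt (while pre-crossing).
    """
    arena = arena or Arena()
    barriers = []
    for side in (1.0, -1.0):
        barriers.append(
            Barrier(side * rb_barrier_y, arena.x_min, arena.x_max)
        )
        barriers.append(
            Barrier(side * dl_barrier_y, dl_barrier_x_start, arena.x_max)
        )
        barriers.append(
            Barrier(
                side * floor_plate_y,
                arena.x_min,
                arena.x_max,
                exempt_types=frozenset(commissural_types),
            )
        )
    tract = DorsalTract(dl_barrier_y, rb_barrier_y)
    return Environment(arena=arena, barriers=tuple(barriers), tract=tract)


def _alternating_gaps(
    x_start: float, x_end: float, gap_length: float, interval: float
) -> tuple[tuple[float, float], ...]:
    """Blocked interval / gap alternation starting blocked at x_start."""
    gaps = []
    x = x_start + interval
    while x < x_end:
        hi = min(x + gap_length, x_end)
        if hi > x:
            gaps.append((x, hi))
        x = hi + interval
    return tuple(gaps)


def apply_gaps(
    environment: Environment, gap_length: float, interval: float
) -> Environment:
    """Perforate the two dorsal-tract barrier levels with periodic gaps.

    Starting with a blocked block of length ``interval`` at each barrier's
    x_start, blocked intervals alternate with open gaps of length
    ``gap_length`` until the barrier end (the final gap is truncated there).
    Only the barriers bounding the dorsal tract (|y| at the tract's inner and
    outer levels) are modified; the floor plate stays intact.
    """
    if gap_length <= 0 or interval <= 0:
        raise ConfigurationError("gap_length and interval must be positive")
    tract = environment.tract
    dorsal_levels = {tract.y_inner, tract.y_outer}
    new_barriers = []
    for b in environment.barriers:
        if abs(b.y_level) in dorsal_levels:
            new_barriers.append(
                replace(b, gaps=_alternating_gaps(b.x_start, b.x_end, gap_length, interval))
            )
        else:
            new_barriers.append(b)
    return replace(environment, barriers=tuple(new_barriers))


def _barrier_crossing(
    b: Barrier, p0: tuple[float, float], p1: tuple[float, float]
) -> tuple[float, float, float] | None:
    """(t, x, y) of the first crossing of barrier b by segment p0->p1, or None."""
    y0, y1 = p0[1], p1[1]
    d0, d1 = y0 - b.y_level, y1 - b.y_level
    if d0 == d1:  # parallel to the barrier (includes lying on it)
        return None
    if d0 * d1 > 0:
        return None
    t = d0 / (d0 - d1)
    x_c = p0[0] + t * (p1[0] - p0[0])
    if not (b.x_start <= x_c <= b.x_end):
        return None
    if b.is_open_at(x_c):
        return None
    return (t, x_c, b.y_level)


def blocks(
    environment: Environment,
    segment: tuple[tuple[float, float], tuple[float, float]],
    cell_type: str,
    phase: str = "normal",
) -> tuple[bool, tuple[float, float] | None]:
    """Does this elongation step hit a barrier?  Returns (blocked, point).

    Exempt cell types pass through their exempting barriers only while in the
    ``pre_crossing`` phase; once crossed they are contained like everyone
    else.  When several barriers are hit, the crossing nearest the segment
    origin is reported.
    """
    p0, p1 = segment
    best = None
    for b in environment.barriers:
        if cell_type in b.exempt_types and phase == "pre_crossing":
            continue
        hit = _barrier_crossing(b, p0, p1)
        if hit is not None and (best is None or hit[0] < best[0]):
            best = hit
    if best is None:
        return (False, None)
    return (True, (best[1], best[2]))


def resolve_step(
    environment: Environment,
    p0: tuple[float, float],
    p1: tuple[float, float],
    theta: float,
    cell_type: str,
    phase: str = "normal",
) -> tuple[float, float, float, bool]:
    """Apply barrier and arena-bound sliding to a proposed step.

    Returns (x, y, theta, clipped).  A blocked step places the growth cone at
    the intersection point offset a hair onto the origin side, and replaces
    the step angle with the direction along the obstruction that preserves
    the sign of the step's component parallel to it (sliding, not
    reflection).  Arena x-bounds and |y| = y_abs_max are treated the same
    way, sliding along the boundary.
    """
    arena = environment.arena
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0

    # candidate obstructions: (t, x_c, y_c, kind) with kind 'h' (horizontal
    # line: barriers and y bounds) or 'v' (vertical: arena x bounds)
    best = None
    for b in environment.barriers:
        if cell_type in b.exempt_types and phase == "pre_crossing":
            continue
        hit = _barrier_crossing(b, p0, p1)
        if hit is not None and (best is None or hit[0] < best[0]):
            best = (hit[0], hit[1], hit[2], "h")
    for y_bound in (arena.y_abs_max, -arena.y_abs_max):
        d0, d1 = y0 - y_bound, y1 - y_bound
        if d0 != d1 and d0 * d1 <= 0:
            t = d0 / (d0 - d1)
            x_c = x0 + t * dx
            if best is None or t < best[0]:
                best = (t, x_c, y_bound, "h")
    for x_bound in (arena.x_min, arena.x_max):
        d0, d1 = x0 - x_bound, x1 - x_bound
        if d0 != d1 and d0 * d1 <= 0:
            t = d0 / (d0 - d1)
            y_c = y0 + t * dy
            if best is None or t < best[0]:
                best = (t, x_bound, y_c, "v")

    if best is None:
        return (x1, y1, theta, False)

    _, x_c, y_c, kind = best
    if kind == "h":
        # slide longitudinally, preserving the x direction of travel
        new_theta = 0.0 if dx >= 0 else math.pi
        side = 1.0 if y0 >= y_c else -1.0
        return (x_c, y_c + side * _SLIDE_OFFSET, new_theta, True)
    # vertical obstruction: slide dorso-ventrally, preserving y direction
    new_theta = math.pi / 2 if dy >= 0 else -math.pi / 2
    side = 1.0 if x0 >= x_c else -1.0
    return (x_c + side * _SLIDE_OFFSET, y_c, new_theta, True)
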