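"""Chemotactic guidance fields G_RC(x, y) and G_DV(x, y).

Axon growth is steered by two gradient systems: a rostro-caudal cue that
biases growth toward the type's preferred longitudinal direction, and a
dorso-ventral cue modelling a diffusible attractant emitted at the floor
plate, strongest near the ventral midline and decaying dorsally.  The engine
only requires that both cues are pure functions of position; the default
family here is

    g_rc(x, y) = ±k_rc                 (sign from the axon's RC direction)
    g_dv(x, y) = sgn(y) * (k_dv * exp(-|y| / lambda) + k_off)

so the DV term is antisymmetric across the midline (left/right mirror
symmetry).  k_dv < 0 pulls axons ventrally (toward y = 0 on either side),
k_dv > 0 pushes them dorsally; k_off adds a distance-independent DV bias.
Commissural axons (dlc, cIN) use an override coefficient set with a strong
ventral pull while navigating to the floor plate (pre-crossing phase) and
revert to the regular set after crossing.

The exact parameter values are calibration targets, fitted per type against
axon statistics (see the optimization module), not ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .environment import Arena
from .population import CELL_TYPES


class DomainError(ValueError):
    """Raised when a field is evaluated outside the arena."""


@dataclass(frozen=True)
class TypeFieldParams:
    """Per-type gradient sensitivities.

    k_rc: magnitude of the RC cue (the sign is derived from the growth
          direction: ascending axons are pulled toward theta = pi,
          descending toward theta = 0).
    k_dv: DV sensitivity; negative pulls ventrally.
    k_off: DV offset, a position-independent bias (ventral when negative).
    """

    k_rc: float = 0.1
    k_dv: float = 0.0
    k_off: float = 0.0


@dataclass(frozen=True)
class NoiseSpec:
    """Per-type half-width alpha of the uniform angular noise, radians."""

    alpha: dict[str, float] = field(
        default_factory=lambda: {
            **{t: 0.15 for t in CELL_TYPES}, "RB": 0.05, "dla": 0.25,
        }
    )
    pre_crossing_alpha: float = 0.1

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.alpha.values()) or self.pre_crossing_alpha < 0:
            raise ValueError("noise half-width alpha must be >= 0")

    def for_type(self, cell_type: str, phase: str = "normal") -> float:
        if phase == "pre_crossing":
            return self.pre_crossing_alpha
        return self.alpha[cell_type]


#: default per-type sensitivities.  The DV couple combines a floor-plate
#: repellent (k_dv > 0, decaying with |y|) with a constant ventral bias
#: (k_off < 0), giving each marginal-zone type a stable preferred DV level
#: y* = lambda * ln(-k_dv / k_off) around which its axons run
#: longitudinally.  RB axons carry no DV couple: the dorsal tract barriers
#: confine them.
DEFAULT_TYPE_PARAMS: dict[str, TypeFieldParams] = {
    "RB": TypeFieldParams(k_rc=0.15, k_dv=0.0, k_off=0.0),
    "dla": TypeFieldParams(k_rc=0.10, k_dv=0.02, k_off=-0.00145),   # y* ~ 105
    "dlc": TypeFieldParams(k_rc=0.10, k_dv=0.06, k_off=-0.00384),   # y* ~ 110
    "aIN": TypeFieldParams(k_rc=0.10, k_dv=0.06, k_off=-0.01948),   # y* ~ 45
    "cIN": TypeFieldParams(k_rc=0.10, k_dv=0.06, k_off=-0.02207),   # y* ~ 40
    "dIN": TypeFieldParams(k_rc=0.10, k_dv=0.06, k_off=-0.02501),   # y* ~ 35
    "mn": TypeFieldParams(k_rc=0.10, k_dv=0.06, k_off=-0.02834),    # y* ~ 30
}

#: pre-crossing override for commissural types: strong ventral pull, no RC
#: bias, so axons dive to the floor plate and cross.
DEFAULT_PRE_CROSSING_PARAMS: dict[str, TypeFieldParams] = {
    "dlc": TypeFieldParams(k_rc=0.0, k_dv=-0.25, k_off=-0.1),
    "cIN": TypeFieldParams(k_rc=0.0, k_dv=-0.25, k_off=-0.1),
}


@dataclass(frozen=True)
class GradientField:
    """Exponential floor-plate DV field plus constant RC bias, per type."""

    arena: Arena = field(default_factory=Arena)
    lam: float = 40.0  # DV decay length of the floor-plate cue, µm
    floor_level: float = 25.0  # |y| of the floor-plate boundary, µm
    per_type: dict[str, TypeFieldParams] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PARAMS)
    )
    pre_crossing: dict[str, TypeFieldParams] = field(
        default_factory=lambda: dict(DEFAULT_PRE_CROSSING_PARAMS)
    )

    def with_type_params(self, cell_type: str, **kw) -> "GradientField":
        per_type = dict(self.per_type)
        per_type[cell_type] = replace(per_type[cell_type], **kw)
        return replace(self, per_type=per_type)


def null_field(arena: Arena | None = None) -> GradientField:
    """A field with all coefficients zero (axons grow straight + noise)."""
    zero = {t: TypeFieldParams(0.0, 0.0, 0.0) for t in CELL_TYPES}
    return GradientField(
        arena=arena or Arena(), per_type=dict(zero),
        pre_crossing={t: TypeFieldParams(0.0, 0.0, 0.0) for t in ("dlc", "cIN")},
    )


def evaluate(
    field: GradientField,
    x: float,
    y: float,
    cell_type: str,
    phase: str = "normal",
    direction: str | None = None,
) -> tuple[float, float]:
    """Angular-influence couple (g_rc, g_dv) at a point, radians-scale.

    ``direction`` is the axon's RC growth direction ("ascending" or
    "descending"); it defaults to the type's primary direction and is flipped
    by the engine for secondary axons.  Commissural axons in the
    pre-crossing phase use the override coefficient set.
    """
    if not field.arena.contains(x, y):
        raise DomainError(f"point ({x}, {y}) outside arena")
    pre = phase == "pre_crossing" and cell_type in field.pre_crossing
    p = field.pre_crossing[cell_type] if pre else field.per_type[cell_type]
    direction = direction or CELL_TYPES[cell_type].primary_direction
    # theta' = theta - g_rc*sin(theta): g_rc > 0 makes theta = 0 attracting
    # (descending growth), g_rc < 0 makes theta = pi attracting (ascending).
    g_rc = p.k_rc if direction == "descending" else -p.k_rc
    sgn = 0.0 if y == 0 else math.copysign(1.0, y)
    if pre:
        # the floor plate is the source of the commissural attractant: the
        # cue is flat inside the plate, so a crossing axon traverses it
        # ballistically instead of being pulled back to the midline
        depth = abs(y) - field.floor_level
        if depth <= 0:
            g_dv = 0.0
        else:
            g_dv = sgn * (p.k_dv * math.exp(-depth / field.lam) + p.k_off)
    else:
        g_dv = sgn * (p.k_dv * math.exp(-abs(y) / field.lam) + p.k_off)
    return (g_rc, g_dv)


def sample_noise(alpha: float, rng) -> float:
    """One uniform draw on [-alpha, alpha]; exactly 0 when alpha is 0."""
    if alpha == 0:
        # still consume a draw so RNG streams are alignment-independent of alpha
        rng.uniform(-1.0, 1.0)
        return 0.0
    return float(rng.uniform(-alpha, alpha))
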