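"""Neuron populations of the tadpole spinal cord model.

Seven cell types are modelled: sensory Rohon-Beard neurons (RB), dorsolateral
ascending and commissural sensory interneurons (dla, dlc), ascending,
commissural and descending interneurons (aIN, cIN, dIN) and motoneurons (mn).
Anatomical attributes — soma DV position and initial growth angle, axon
lengths, dendritic extents, branch-point positions — are drawn from
"measurement tables" via a smoothed bootstrap: pick a measured row uniformly
at random and add independent zero-mean Gaussian jitter per dimension.  This
generalizes a finite set of measurements into a continuous sampling
distribution without assuming a parametric form.

Tables are stored in left-side convention (y > 0); right-side neurons mirror
y -> -y and theta -> -theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Raised for unusable measurement tables."""


class PopulationConfigError(ValueError):
    """Raised for inconsistent population configuration."""


@dataclass(frozen=True)
class CellType:
    name: str
    is_commissural: bool
    has_secondary: bool
    primary_direction: str  # "ascending" (toward the head, -x) or "descending"

    def __post_init__(self) -> None:
        if self.primary_direction not in ("ascending", "descending"):
            raise PopulationConfigError(
                f"unknown primary_direction {self.primary_direction!r}"
            )


#: the seven modelled types.  Primary axons ascend except dIN and mn; dla and
#: mn have no secondary axon; for dIN a secondary is optional (per-neuron).
CELL_TYPES: dict[str, CellType] = {
    "RB": CellType("RB", False, True, "ascending"),
    "dla": CellType("dla", False, False, "ascending"),
    "dlc": CellType("dlc", True, True, "ascending"),
    "aIN": CellType("aIN", False, True, "ascending"),
    "cIN": CellType("cIN", True, True, "ascending"),
    "dIN": CellType("dIN", False, True, "descending"),
    "mn": CellType("mn", False, False, "descending"),
}

TYPE_ORDER = tuple(CELL_TYPES)


@dataclass
class MeasurementTable:
    """Anatomical samples for one cell type (left-side convention).

    ``soma_theta`` holds measured (y_soma, theta_init) pairs, sampled jointly
    to preserve their correlation.  All lengths in µm, angles in radians.
    """

    cell_type: str
    soma_theta: np.ndarray          # (n, 2): y_soma, theta_init
    primary_length: np.ndarray      # (n,)
    secondary_length: np.ndarray    # (n,) — ignored for types without secondaries
    dendrite_half_extent: np.ndarray  # (n,)
    branch_offset: np.ndarray       # (n,) arc length of branch point on primary

    def __post_init__(self) -> None:
        self.soma_theta = np.atleast_2d(np.asarray(self.soma_theta, float))
        for name in ("primary_length", "secondary_length",
                     "dendrite_half_extent", "branch_offset"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if self.soma_theta.size == 0 or self.primary_length.size == 0:
            raise DataError(f"empty measurement table for {self.cell_type}")
        if np.any(self.primary_length <= 0) or np.any(self.secondary_length <= 0):
            raise DataError("axon lengths must be positive")
        if np.any(self.dendrite_half_extent < 0):
            raise DataError("dendritic extents must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        n = len(self.primary_length)
        return pd.DataFrame(
            {
                "y_soma": self.soma_theta[:, 0],
                "theta_init": self.soma_theta[:, 1],
                "primary_length": self.primary_length,
                "secondary_length": self.secondary_length,
                "dendrite_half_extent": self.dendrite_half_extent,
                "branch_offset": self.branch_offset,
            },
            index=range(n),
        )

    @classmethod
    def from_frame(cls, cell_type: str, frame: pd.DataFrame) -> "MeasurementTable":
        return cls(
            cell_type=cell_type,
            soma_theta=frame[["y_soma", "theta_init"]].to_numpy(),
            primary_length=frame["primary_length"].to_numpy(),
            secondary_length=frame["secondary_length"].to_numpy(),
            dendrite_half_extent=frame["dendrite_half_extent"].to_numpy(),
            branch_offset=frame["branch_offset"].to_numpy(),
        )


@dataclass
class Neuron:
    id: int
    cell_type: str
    side: int                      # +1 left, -1 right
    soma: tuple[float, float]
    dendrite: tuple[float, float]  # (y_lo, y_hi), same side as the soma
    primary_length: float
    secondary_length: float | None
    branch_arc_length: float | None
    theta0: float
    theta0_secondary: float | None
    pioneer_primary: bool = False
    pioneer_secondary: bool = False
    start_primary: float = 0.0
    start_secondary: float = 0.0

    @property
    def is_commissural(self) -> bool:
        return CELL_TYPES[self.cell_type].is_commissural


def sample_generalized(
    samples: np.ndarray,
    n: int,
    bandwidth: float | np.ndarray,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Smoothed bootstrap: uniform row choice + Gaussian jitter per dimension.

    ``samples`` is (m,) or (m, d); returns (n,) or (n, d) to match.
    ``bandwidth`` is the jitter standard deviation (scalar or per-dimension).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    arr = np.asarray(samples, float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr.T).T if squeeze else arr
    if arr.size == 0:
        raise DataError("cannot sample from an empty table")
    bw = np.broadcast_to(np.asarray(bandwidth, float), (arr.shape[1],))
    if np.any(bw < 0):
        raise DataError("bandwidth must be non-negative")
    idx = rng.integers(0, arr.shape[0], size=n)
    out = arr[idx] + rng.standard_normal((n, arr.shape[1])) * bw
    return out[:, 0] if squeeze else out


@dataclass(frozen=True)
class PopulationConfig:
    """Counts and placement policy for population generation.

    ``counts`` are totals per type (split evenly across sides).
    ``pioneers`` are per-type, per-side pioneer counts.
    """

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    pioneers: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PIONEERS))
    bandwidth: float = 2.0           # smoothed-bootstrap jitter, µm / radians-scale
    theta_bandwidth: float = 0.05    # jitter on initial angles, radians
    rc_jitter: float = 0.3           # soma RC jitter as a fraction of grid pitch
    din_secondary_fraction: float = 0.5
    x_min: float = 500.0
    x_max: float = 2000.0
    y_abs_max: float = 145.0


#: desk-scale default totals per type (left + right).  The real animal has
#: more neurons; these defaults keep runs small while preserving the relative
#: prevalence of the types.
DEFAULT_COUNTS: dict[str, int] = {
    "RB": 30, "dla": 20, "dlc": 20, "aIN": 40, "cIN": 50, "dIN": 50, "mn": 40,
}

#: default pioneer axons per type per side
DEFAULT_PIONEERS: dict[str, int] = {
    "RB": 4, "dla": 3, "dlc": 3, "aIN": 4, "cIN": 5, "dIN": 5, "mn": 4,
}


def assign_pioneers(
    neurons: list[Neuron], n_pioneers: int, policy: str = "equally_spaced"
) -> list[Neuron]:
    """Flag ``n_pioneers`` of the given neurons as pioneers (in place).

    With policy "equally_spaced" the pioneers are the neurons nearest to n
    equally spaced RC positions across the group's soma extent; each target
    position claims the nearest still-unflagged neuron, ties broken by lower
    id.  Returns the flagged neurons.
    """
    if policy != "equally_spaced":
        raise PopulationConfigError(f"unknown pioneer policy {policy!r}")
    if not 0 <= n_pioneers <= len(neurons):
        raise PopulationConfigError(
            f"n_pioneers={n_pioneers} out of range for {len(neurons)} neurons"
        )
    if n_pioneers == 0:
        return []
    xs = [nrn.soma[0] for nrn in neurons]
    lo, hi = min(xs), max(xs)
    targets = [lo + (j + 0.5) * (hi - lo) / n_pioneers for j in range(n_pioneers)]
    flagged: list[Neuron] = []
    taken: set[int] = set()
    for tx in targets:
        best = min(
            (nrn for nrn in neurons if nrn.id not in taken),
            key=lambda nrn: (abs(nrn.soma[0] - tx), nrn.id),
        )
        taken.add(best.id)
        best.pioneer_primary = True
        best.pioneer_secondary = best.secondary_length is not None
        flagged.append(best)
    return flagged


def build_population(
    config: PopulationConfig,
    tables: dict[str, MeasurementTable],
    seed: int,
) -> list[Neuron]:
    """Create all neurons with sampled attributes; deterministic under seed.

    Somata are placed on a jittered RC grid per (type, side); DV positions
    and initial angles are drawn jointly from the type's measurement table,
    mirrored for the right side.  Left/right counts are equal.
    """
    neurons: list[Neuron] = []
    nid = 0
    for type_name in TYPE_ORDER:
        total = config.counts.get(type_name, 0)
        if total == 0:
            continue
        if total % 2:
            raise PopulationConfigError(
                f"count for {type_name} must be even across sides, got {total}"
            )
        n_side = total // 2
        n_pio = config.pioneers.get(type_name, 0)
        if n_pio > n_side:
            raise PopulationConfigError(
                f"{type_name}: {n_pio} pioneers requested but only {n_side} per side"
            )
        table = tables.get(type_name)
        if table is None:
            raise DataError(f"no measurement table for type {type_name}")
        ct = CELL_TYPES[type_name]
        for side in (1, -1):
            # independent, stable stream per (seed, type, side)
            rng = np.random.default_rng(
                [seed, TYPE_ORDER.index(type_name), 1 if side > 0 else 2]
            )
            pitch = (config.x_max - config.x_min) / n_side
            grid = config.x_min + (np.arange(n_side) + 0.5) * pitch
            x_soma = grid + rng.uniform(-config.rc_jitter, config.rc_jitter, n_side) * pitch
            x_soma = np.clip(x_soma, config.x_min, config.x_max)
            yt = sample_generalized(
                table.soma_theta, n_side,
                np.array([config.bandwidth, config.theta_bandwidth]), rng,
            )
            # the generalization never extrapolates soma DV levels beyond the
            # measured range (keeps e.g. RB somata inside the dorsal tract)
            y_obs = np.abs(table.soma_theta[:, 0])
            yt[:, 0] = np.clip(np.abs(yt[:, 0]), y_obs.min(), y_obs.max())
            prim_len = np.abs(
                sample_generalized(table.primary_length, n_side, config.bandwidth, rng)
            ) + 1.0
            sec_len = np.abs(
                sample_generalized(table.secondary_length, n_side, config.bandwidth, rng)
            ) + 1.0
            half_ext = np.abs(
                sample_generalized(table.dendrite_half_extent, n_side, config.bandwidth, rng)
            )
            branch = np.abs(
                sample_generalized(table.branch_offset, n_side, config.bandwidth, rng)
            )
            has_secondary = np.full(n_side, ct.has_secondary)
            if type_name == "dIN":
                has_secondary &= rng.random(n_side) < config.din_secondary_fraction
            side_neurons = []
            for i in range(n_side):
                y = float(np.clip(abs(yt[i, 0]), 1.0, config.y_abs_max - 1.0)) * side
                theta = float(yt[i, 1]) * side  # mirror for the right side
                # mirror about the DV axis: the secondary runs in the
                # opposite RC direction to the primary
                theta_sec = _wrap(math.pi - theta)
                y_lo = max(0.0, abs(y) - half_ext[i]) * side
                y_hi = min(config.y_abs_max, abs(y) + half_ext[i]) * side
                dendrite = (min(y_lo, y_hi), max(y_lo, y_hi))
                sec = float(sec_len[i]) if has_secondary[i] else None
                br = min(float(branch[i]), 0.9 * float(prim_len[i])) if sec else None
                side_neurons.append(
                    Neuron(
                        id=nid,
                        cell_type=type_name,
                        side=side,
                        soma=(float(x_soma[i]), y),
                        dendrite=dendrite,
                        primary_length=float(prim_len[i]),
                        secondary_length=sec,
                        branch_arc_length=br,
                        theta0=_wrap(theta),
                        theta0_secondary=theta_sec if sec else None,
                    )
                )
                nid += 1
            assign_pioneers(side_neurons, n_pio)
            neurons.extend(side_neurons)
    return neurons


def population_to_frame(neurons: list[Neuron]) -> pd.DataFrame:
    rows = []
    for n in neurons:
        rows.append(
            {
                "id": n.id, "cell_type": n.cell_type, "side": n.side,
                "x_soma": n.soma[0], "y_soma": n.soma[1],
                "dendrite_y_lo": n.dendrite[0], "dendrite_y_hi": n.dendrite[1],
                "primary_length": n.primary_length,
                "secondary_length": n.secondary_length if n.secondary_length else np.nan,
                "branch_arc_length": n.branch_arc_length if n.branch_arc_length else np.nan,
                "theta0": n.theta0,
                "theta0_secondary": n.theta0_secondary if n.theta0_secondary is not None else np.nan,
                "pioneer_primary": n.pioneer_primary,
                "pioneer_secondary": n.pioneer_secondary,
                "start_primary": n.start_primary,
                "start_secondary": n.start_secondary,
            }
        )
    return pd.DataFrame(rows)


def population_from_frame(frame: pd.DataFrame) -> list[Neuron]:
    neurons = []
    for _, r in frame.iterrows():
        sec = None if pd.isna(r["secondary_length"]) else float(r["secondary_length"])
        neurons.append(
            Neuron(
                id=int(r["id"]), cell_type=str(r["cell_type"]), side=int(r["side"]),
                soma=(float(r["x_soma"]), float(r["y_soma"])),
                dendrite=(float(r["dendrite_y_lo"]), float(r["dendrite_y_hi"])),
                primary_length=float(r["primary_length"]),
                secondary_length=sec,
                branch_arc_length=None if pd.isna(r["branch_arc_length"]) else float(r["branch_arc_length"]),
                theta0=float(r["theta0"]),
                theta0_secondary=None if pd.isna(r["theta0_secondary"]) else float(r["theta0_secondary"]),
                pioneer_primary=bool(r["pioneer_primary"]),
                pioneer_secondary=bool(r["pioneer_secondary"]),
                start_primary=float(r["start_primary"]),
                start_secondary=float(r["start_secondary"]),
            )
        )
    return neurons


def _wrap(theta: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    w = math.fmod(theta + math.pi, 2.0 * math.pi)
    if w <= 0.0:
        w += 2.0 * math.pi
    return w - math.pi
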