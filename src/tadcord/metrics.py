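"""Quantitative descriptors of axonal patterns and connectomes.

Covers the dorso-ventral distribution of axon points, trajectory tortuosity
("wiggliness"), bundle structure at RC slices, the fraction of sensory axon
points escaping the dorsal tract, and dIN neurons isolated from recurrent
dIN excitation.  All metrics are pure functions of their inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .environment import DorsalTract
from .growth_engine import Trajectory
from .synaptogenesis import Connectome


class DataError(ValueError):
    pass


@dataclass
class DVHistogram:
    """Histogram of trajectory-point DV positions.

    Bins are left-closed, right-open; the final bin is closed.  ``density``
    integrates to 1; ``counts`` sum to the number of points.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    normalized: bool

    @property
    def values(self) -> np.ndarray:
        return self.counts

    def interquartile_range(self) -> float:
        """IQR of the underlying point distribution, from bin midpoints."""
        mids = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        total = self.counts.sum()
        cum = np.cumsum(self.counts) / total
        q1 = float(np.interp(0.25, cum, mids))
        q3 = float(np.interp(0.75, cum, mids))
        return q3 - q1


@dataclass
class BundleReport:
    """Per-RC-slice clusters of axon crossings and summary statistics."""

    slice_x: np.ndarray
    clusters: list[list[np.ndarray]]  # per slice: list of y-arrays
    mean_bundle_count: float
    mean_bundle_size: float


def _all_points(trajectories) -> np.ndarray:
    if isinstance(trajectories, dict):
        trajs = list(trajectories.values())
    else:
        trajs = list(trajectories)
    pts = [t.points for t in trajs if len(t.points)]
    if not pts:
        raise DataError("no trajectory points")
    return np.vstack(pts)


def dv_distribution(
    trajectories, bins: int | np.ndarray = 29, normalized: bool = False,
    y_range: tuple[float, float] | None = None,
) -> DVHistogram:
    """Histogram of all trajectory-point y values."""
    if isinstance(bins, int) and bins < 2:
        raise DataError("need at least 2 bins")
    pts = _all_points(trajectories)
    counts, edges = np.histogram(
        pts[:, 1], bins=bins, range=y_range, density=normalized
    )
    return DVHistogram(edges, counts, normalized)


def tortuosity(trajectory: Trajectory | np.ndarray) -> float:
    """Arc length over end-to-end distance; 1 for a straight path.

    A closed path (zero end-to-end distance) reports infinity.
    """
    pts = trajectory.points if isinstance(trajectory, Trajectory) else np.asarray(trajectory)
    if len(pts) < 2:
        raise DataError("tortuosity needs at least 2 points")
    seg = np.diff(pts, axis=0)
    arc = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    chord = float(math.hypot(*(pts[-1] - pts[0])))
    if chord == 0.0:
        return math.inf
    return arc / chord


def mean_tortuosity(trajectories) -> float:
    trajs = trajectories.values() if isinstance(trajectories, dict) else trajectories
    vals = [tortuosity(t) for t in trajs if len(t.points) >= 2]
    finite = [v for v in vals if math.isfinite(v)]
    if not finite:
        raise DataError("no finite tortuosity values")
    return float(np.mean(finite))


def escape_fraction(trajectories, tract: DorsalTract) -> float:
    """Percentage of axon points lying outside the dorsal tract.

    Primary and secondary points are pooled, each elongation-step point
    weighted equally.
    """
    pts = _all_points(trajectories)
    ay = np.abs(pts[:, 1])
    outside = (ay < tract.y_inner) | (ay > tract.y_outer)
    return 100.0 * float(outside.mean())


def dv_dispersion(trajectories, slice_spacing: float = 50.0) -> float:
    """Mean over RC slices of the std of axon crossing y-values.

    A summary of how spread out trajectories are dorso-ventrally; bundling
    reduces it.
    """
    xs, ys_per_slice = _slice_crossings(trajectories, slice_spacing)
    stds = [float(np.std(ys)) for ys in ys_per_slice if len(ys) >= 2]
    if not stds:
        raise DataError("no slice with >= 2 crossings")
    return float(np.mean(stds))


def _slice_crossings(trajectories, slice_spacing: float):
    trajs = list(trajectories.values()) if isinstance(trajectories, dict) else list(trajectories)
    if not trajs:
        raise DataError("no trajectories")
    pts = _all_points(trajs)
    x_lo, x_hi = pts[:, 0].min(), pts[:, 0].max()
    slices = np.arange(x_lo + slice_spacing, x_hi, slice_spacing)
    ys_per_slice = [[] for _ in slices]
    for t in trajs:
        p = t.points
        if len(p) < 2:
            continue
        x0, y0 = p[:-1, 0], p[:-1, 1]
        x1, y1 = p[1:, 0], p[1:, 1]
        for i, sx in enumerate(slices):
            lo = np.minimum(x0, x1)
            hi = np.maximum(x0, x1)
            hit = (lo <= sx) & (sx < hi)
            if not hit.any():
                continue
            dx = x1[hit] - x0[hit]
            tpar = (sx - x0[hit]) / dx
            ys_per_slice[i].extend(y0[hit] + tpar * (y1[hit] - y0[hit]))
    return slices, [np.asarray(v) for v in ys_per_slice]


def bundle_stats(
    trajectories, slice_spacing: float = 50.0, gap_threshold: float = 5.0
) -> BundleReport:
    """1D gap-based clustering of axon crossings at regular RC slices.

    At each slice the crossing y-values are sorted and split into clusters
    wherever the gap between neighbours exceeds ``gap_threshold``.
    """
    if slice_spacing <= 0 or gap_threshold <= 0:
        raise DataError("slice_spacing and gap_threshold must be positive")
    slices, ys_per_slice = _slice_crossings(trajectories, slice_spacing)
    clusters: list[list[np.ndarray]] = []
    counts, sizes = [], []
    for ys in ys_per_slice:
        if len(ys) == 0:
            clusters.append([])
            continue
        ys = np.sort(ys)
        split = np.nonzero(np.diff(ys) > gap_threshold)[0] + 1
        cl = np.split(ys, split)
        clusters.append(cl)
        counts.append(len(cl))
        sizes.extend(len(c) for c in cl)
    if not counts:
        raise DataError("no slice crossings")
    return BundleReport(
        slice_x=slices,
        clusters=clusters,
        mean_bundle_count=float(np.mean(counts)),
        mean_bundle_size=float(np.mean(sizes)),
    )


def isolated_dIN_count(connectome: Connectome) -> int:
    """dIN neurons receiving no synapse whose presynaptic neuron is a dIN."""
    din_ids = {n.id for n in connectome.population if n.cell_type == "dIN"}
    receiving = {
        s.post_id
        for s in connectome.synapses
        if s.pre_type == "dIN" and s.post_id in din_ids
    }
    return len(din_ids - receiving)
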