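"""Shared builders for hand-constructed trajectories in tests."""

import numpy as np

from tadcord.growth_engine import Trajectory


def make_traj(nid, pts, cell_type="dIN", side=1, phases=None, klass="primary"):
    pts = np.asarray(pts, float)
    n = len(pts)
    return Trajectory(
        neuron_id=nid, cell_type=cell_type, side=side, axon_class=klass,
        points=pts, angles=np.zeros(n - 1),
        point_phases=np.asarray(phases or ["normal"] * n, dtype=object),
        clipped=np.zeros(n - 1, bool), start_time=0.0,
    )
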