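import numpy as np
import pytest

from tadcord import (
    CellModelParams, Connectome, Stimulus, Synapse, detect_swimming,
    make_synthetic_raster, midcycle_dIN_count, simulate,
)
from tadcord.fixtures import _neuron
from tadcord.functional_sim import (
    DEFAULT_CELL_PARAMS, DetectorUsageError, SimConfigError, SynapseParams,
)


def _single_din():
    n = _neuron(0, "dIN", 1, (1000.0, 50.0), 0.0, 100.0)
    return Connectome([n], [])


class TestSimulate:
    def test_quiescent_without_stimulus(self):
        raster = simulate(_single_din(), duration=100.0)
        assert raster.total_spikes() == 0

    def test_nmda_enables_repetitive_firing(self):
        """With the slow NMDA conductance a modest depolarization drives
        sustained firing; without it the same current gives a single spike."""
        stim = Stimulus((0,), 10.0, 300.0, 4.0)
        cp = dict(DEFAULT_CELL_PARAMS)
        cp["dIN"] = CellModelParams(g_nmda_unit=0.02, nmda_tonic=0.4)
        with_nmda = simulate(_single_din(), cell_params=cp, stimulus=stim,
                             duration=350.0)
        without = simulate(_single_din(), stimulus=stim, duration=350.0)
        assert len(with_nmda.spikes[0]) >= 10
        assert len(without.spikes[0]) <= 2

    def test_dt_convergence(self):
        """Halving dt moves spike times by well under 0.5 ms."""
        stim = Stimulus((0,), 10.0, 150.0, 8.0)
        a = simulate(_single_din(), stimulus=stim, duration=200.0, dt=0.01)
        b = simulate(_single_din(), stimulus=stim, duration=200.0, dt=0.005)
        k = min(len(a.spikes[0]), len(b.spikes[0]))
        assert k > 3
        assert np.max(np.abs(a.spikes[0][:k] - b.spikes[0][:k])) < 0.5

    def test_large_dt_rejected(self):
        with pytest.raises(SimConfigError):
            simulate(_single_din(), dt=0.1, duration=10.0)

    def test_deterministic(self):
        stim = Stimulus((0,), 10.0, 100.0, 8.0)
        a = simulate(_single_din(), stimulus=stim, duration=150.0)
        b = simulate(_single_din(), stimulus=stim, duration=150.0)
        assert np.array_equal(a.spikes[0], b.spikes[0])

    def _two_sided_net(self):
        """RB -> mn on each side plus a cross-side cIN inhibiting mn."""
        pop = [
            _neuron(0, "RB", 1, (800.0, 132.0), 0.0, 10.0),
            _neuron(1, "mn", 1, (900.0, 40.0), 0.0, 10.0),
            _neuron(2, "RB", -1, (800.0, -132.0), 0.0, 10.0),
            _neuron(3, "mn", -1, (900.0, -40.0), 0.0, 10.0),
        ]
        syn = [
            Synapse(0, 1, "RB", "mn", "primary", 850.0, 40.0, 50),
            Synapse(2, 3, "RB", "mn", "primary", 850.0, -40.0, 50),
        ]
        return Connectome(pop, syn)

    def test_mirror_symmetry(self):
        """Swapping sides of connectome and stimulus mirrors the raster."""
        conn = self._two_sided_net()
        left = simulate(conn, stimulus=Stimulus((0,), 10.0, 5.0, 25.0),
                        duration=80.0)
        right = simulate(conn, stimulus=Stimulus((2,), 10.0, 5.0, 25.0),
                         duration=80.0)
        assert np.array_equal(left.spikes[1], right.spikes[3])
        assert np.array_equal(left.spikes[0], right.spikes[2])

    def test_synapse_multiplicity_strengthens_connection(self):
        conn1 = self._two_sided_net()
        weak = SynapseParams(unitary_g=0.04)
        r1 = simulate(conn1, syn_params=weak,
                      stimulus=Stimulus((0,), 10.0, 5.0, 25.0), duration=60.0)
        conn5 = self._two_sided_net()
        conn5.synapses += [
            Synapse(0, 1, "RB", "mn", "primary", 850.0, 40.0, 50 + k)
            for k in range(6)
        ]
        r5 = simulate(conn5, syn_params=weak,
                      stimulus=Stimulus((0,), 10.0, 5.0, 25.0), duration=60.0)
        assert len(r5.spikes[1]) >= len(r1.spikes[1])
        assert len(r5.spikes[1]) > 0


class TestDetectSwimming:
    def test_constructed_18hz_detected(self):
        r = make_synthetic_raster(18.0, n_cycles=20, seed=1)
        out = detect_swimming(r)
        assert out["swims"] and out["frequency"] == pytest.approx(18.0, abs=0.1)

    def test_jittered_18hz_still_detected(self):
        r = make_synthetic_raster(18.0, n_cycles=20, jitter_ms=1.0, seed=5)
        out = detect_swimming(r)
        assert out["swims"] and out["frequency"] == pytest.approx(18.0, abs=0.5)

    def test_30hz_outside_band_rejected(self):
        r = make_synthetic_raster(30.0, n_cycles=20, seed=2)
        assert not detect_swimming(r)["swims"]

    def test_one_sided_rejected(self):
        r = make_synthetic_raster(18.0, n_cycles=20, one_sided=True, seed=3)
        assert not detect_swimming(r)["swims"]

    def test_empty_raster_rejected(self):
        from tadcord.functional_sim import SpikeRaster
        r = SpikeRaster(spikes={}, neuron_types={}, neuron_sides={})
        assert not detect_swimming(r)["swims"]


class TestMidcycleCount:
    def test_no_midcycle_spikes_counts_zero(self):
        r = make_synthetic_raster(18.0, n_cycles=20, midcycle_dINs=0, seed=4)
        assert midcycle_dIN_count(r, detect_swimming(r)) == 0

    def test_constructed_count_recovered(self):
        r = make_synthetic_raster(18.0, n_cycles=20, midcycle_dINs=5, seed=4)
        assert midcycle_dIN_count(r, detect_swimming(r)) == 5

    def test_requires_swimming(self):
        r = make_synthetic_raster(18.0, n_cycles=20, one_sided=True, seed=4)
        with pytest.raises(DetectorUsageError):
            midcycle_dIN_count(r, detect_swimming(r))
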