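import numpy as np
import pytest

from tadcord import (
    Connectome, Dendrite, DendriteIndex, ProbabilityMatrix, Synapse,
    dendrites_from_population, detect_crossings, form_synapses,
    prune_synapses, synapse_count_matrix,
)
from tadcord.synaptogenesis import MatrixError, _all_crossings
from tadcord.fixtures import _neuron
from _helpers import make_traj as _traj





class TestDetectCrossings:
    def test_orthogonal_intersection(self):
        d = Dendrite(1, "mn", 1, 100.0, 0.0, 20.0)
        hits = detect_crossings(((99.5, 10.0), (100.5, 10.0)), [d])
        assert len(hits) == 1 and hits[0][1] == (100.0, 10.0)

    def test_miss_outside_dendrite_span(self):
        d = Dendrite(1, "mn", 1, 100.0, 11.0, 20.0)
        assert detect_crossings(((99.5, 10.0), (100.5, 10.0)), [d]) == []

    def test_endpoint_touch_counts(self):
        d = Dendrite(1, "mn", 1, 100.0, 0.0, 20.0)
        assert detect_crossings(((100.0, 5.0), (100.9, 5.2)), [d])

    def test_random_segments_match_brute_force(self):
        """1000 random segments: indexed query equals all-pairs check."""
        rng = np.random.default_rng(8)
        dendrites = [
            Dendrite(i, "mn", 1, float(x), float(lo), float(lo + ext))
            for i, (x, lo, ext) in enumerate(
                zip(rng.uniform(0, 100, 60), rng.uniform(0, 50, 60),
                    rng.uniform(1, 30, 60))
            )
        ]
        index = DendriteIndex(dendrites)
        for _ in range(1000):
            p0 = (float(rng.uniform(0, 100)), float(rng.uniform(0, 80)))
            ang = float(rng.uniform(-np.pi, np.pi))
            p1 = (p0[0] + np.cos(ang), p0[1] + np.sin(ang))
            via_index = {d.neuron_id for d, _ in detect_crossings((p0, p1), index)}
            brute = {d.neuron_id for d, _ in detect_crossings((p0, p1), dendrites)}
            assert via_index == brute


class TestFormSynapses:
    def _setup(self):
        pre = _neuron(0, "dIN", 1, (1000.0, 50.0), 0.0, 30.0)
        post = _neuron(1, "mn", 1, (1010.0, 45.0), 0.0, 30.0, dendrite_half=10.0)
        traj = _traj(0, [(1000.3 + k, 50.0) for k in range(31)])
        dend = dendrites_from_population([pre, post])
        return [pre, post], {(0, "primary"): traj}, dend

    def test_probability_one_equals_crossing_count(self):
        pop, trajs, dend = self._setup()
        conn = form_synapses(trajs, dend, ProbabilityMatrix.uniform(1.0), 1, pop)
        assert conn.count() == len(_all_crossings(trajs, dend, pop)) == 1

    def test_probability_zero_empty(self):
        pop, trajs, dend = self._setup()
        conn = form_synapses(trajs, dend, ProbabilityMatrix.uniform(0.0), 1, pop)
        assert conn.count() == 0

    def test_binomial_rate_at_half(self):
        """~1000 crossings at P=0.5: count within 4-sigma binomial band."""
        pop = [_neuron(0, "dIN", 1, (1000.0, 50.0), 0.0, 30.0)]
        dendrites = [
            Dendrite(100 + i, "mn", 1, 1000.5, 40.0, 60.0) for i in range(1000)
        ]
        trajs = {(0, "primary"): _traj(0, [(1000.0, 50.0), (1001.0, 50.0)])}
        pop += [
            _neuron(100 + i, "mn", 1, (1000.5, 50.0), 0.0, 10.0)
            for i in range(1000)
        ]
        conn = form_synapses(trajs, dendrites, ProbabilityMatrix.uniform(0.5), 3, pop)
        assert abs(conn.count() - 500) < 4 * np.sqrt(1000 * 0.25)

    def test_pre_crossing_segments_excluded(self):
        pre = _neuron(0, "cIN", 1, (1000.0, 50.0), 0.0, 5.0)
        post = _neuron(1, "mn", -1, (1002.0, -45.0), 0.0, 5.0, dendrite_half=40.0)
        phases = ["pre_crossing"] * 6
        trajs = {(0, "primary"): _traj(
            0, [(1000.0 + k, -50.0) for k in range(6)], "cIN", 1, phases)}
        dend = dendrites_from_population([pre, post])
        conn = form_synapses(trajs, dend, ProbabilityMatrix.uniform(1.0), 1, [pre, post])
        assert conn.count() == 0

    def test_commissural_never_ipsilateral(self):
        pre = _neuron(0, "cIN", 1, (1000.0, 50.0), 0.0, 5.0)
        ipsi = _neuron(1, "mn", 1, (1002.0, 45.0), 0.0, 5.0, dendrite_half=40.0)
        trajs = {(0, "primary"): _traj(
            0, [(1000.0 + k, 50.0) for k in range(6)], "cIN", 1)}
        dend = dendrites_from_population([pre, ipsi])
        conn = form_synapses(trajs, dend, ProbabilityMatrix.uniform(1.0), 1, [pre, ipsi])
        assert conn.count() == 0

    def test_no_autapses(self):
        n = _neuron(0, "dIN", 1, (1000.0, 50.0), 0.0, 5.0, dendrite_half=20.0)
        trajs = {(0, "primary"): _traj(0, [(998.0 + k, 50.0) for k in range(6)])}
        conn = form_synapses(trajs, dendrites_from_population([n]),
                             ProbabilityMatrix.uniform(1.0), 1, [n])
        assert conn.count() == 0

    def test_missing_matrix_entry_raises(self):
        pop, trajs, dend = self._setup()
        bad = ProbabilityMatrix({"dIN": {"dIN": 0.5}})
        with pytest.raises(MatrixError):
            form_synapses(trajs, dend, bad, 1, pop)

    def test_deterministic_under_seed(self):
        pop, trajs, dend = self._setup()
        m = ProbabilityMatrix.uniform(0.5)
        c1 = form_synapses(trajs, dend, m, 9, pop)
        c2 = form_synapses(trajs, dend, m, 9, pop)
        assert [s.__dict__ for s in c1.synapses] == [s.__dict__ for s in c2.synapses]


class TestPruneSynapses:
    def _connectome(self, n):
        pop = [_neuron(0, "dIN", 1, (1000.0, 50.0), 0.0, 5.0),
               _neuron(1, "mn", 1, (1001.0, 45.0), 0.0, 5.0)]
        syn = [Synapse(0, 1, "dIN", "mn", "primary", 1000.0, 45.0, k)
               for k in range(n)]
        return Connectome(pop, syn)

    def test_keep_all_and_none(self):
        c = self._connectome(50)
        assert prune_synapses(c, 1.0, 1).count() == 50
        assert prune_synapses(c, 0.0, 1).count() == 0

    def test_binomial_keep_rate(self):
        c = self._connectome(80_000)
        kept = prune_synapses(c, 0.55, 2).count()
        assert abs(kept - 44_000) < 4 * np.sqrt(80_000 * 0.55 * 0.45)

    def test_invalid_prob_rejected(self):
        with pytest.raises(ValueError):
            prune_synapses(self._connectome(5), 1.5, 1)


class TestCountMatrix:
    def test_empty_connectome_all_zero(self):
        c = Connectome([], [])
        m = synapse_count_matrix(c)["counts"]
        assert (m.to_numpy() == 0).all()

    def test_hand_built_counts(self):
        pop = [_neuron(0, "dIN", 1, (1000, 50), 0, 5),
               _neuron(1, "mn", 1, (1001, 45), 0, 5),
               _neuron(2, "cIN", -1, (1002, -45), 0, 5)]
        syn = [
            Synapse(0, 1, "dIN", "mn", "primary", 0, 0, 0),
            Synapse(0, 1, "dIN", "mn", "primary", 0, 0, 1),
            Synapse(2, 1, "cIN", "mn", "primary", 0, 0, 0),
        ]
        m = synapse_count_matrix(Connectome(pop, syn))["counts"]
        assert m.loc["dIN", "mn"] == 2 and m.loc["cIN", "mn"] == 1
        assert m.to_numpy().sum() == 3

    def test_identical_connectomes_zero_percent_change(self):
        pop = [_neuron(0, "dIN", 1, (1000, 50), 0, 5),
               _neuron(1, "mn", 1, (1001, 45), 0, 5)]
        syn = [Synapse(0, 1, "dIN", "mn", "primary", 0, 0, 0)]
        c = Connectome(pop, syn)
        out = synapse_count_matrix(c, reference=c)
        pct = out["percent_change"]
        filled = pct.to_numpy()[np.isfinite(pct.to_numpy())]
        assert np.allclose(filled, 0.0)
        assert out["negligible"].loc["RB", "RB"]
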