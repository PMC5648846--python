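# tadcord

A developmental connectome simulator for the hatchling *Xenopus* tadpole
spinal cord, centred on one question: what does axon–axon interaction —
fasciculation (adhesion into bundles) or mutual repulsion — do to the wiring
and function of a developing motor circuit?

The spinal cord is modelled as a 2D rectangle (the neural tube opened like a
book along the dorsal midline): x is the rostro-caudal distance from the
midbrain (500–2000 µm), y the dorso-ventral distance from the ventral
midline (|y| ≤ 145 µm, y > 0 = left side). Seven neuron types grow axons
simultaneously in discrete time (Δ = 1 µm per time unit). Each growth cone
updates its angle from chemotactic gradient cues, uniform angular noise, and
the nearest point of a same-type axon within range *r*:

    x_{n+1}  = x_n + Δ cos θ_n
    y_{n+1}  = y_n + Δ sin θ_n
    θ_A      = θ_n − G_RC(x_n, y_n) sin θ_n + G_DV(x_n, y_n) cos θ_n + ξ_n,   ξ_n ~ U[−α, α]
    θ_B      = θ_p   (s > 0, fasciculation: copy the nearest axon's angle)
             = θ̄_p   (s < 0, repulsion: perpendicular pointing away)
    θ_{n+1}  = (1 − |s|) θ_A + |s| θ_B        (circular-aware blend)

Hard barriers formed by cell somata bound a dorsal tract (127 ≤ |y| ≤ 137)
that confines sensory Rohon–Beard (RB) axons, and a floor-plate boundary at
|y| = 25 that only commissural axons (dlc, cIN) may cross — once. Axons that
cross dendrites (vertical segments centred on somata) form synapses with
per-type-pair probabilities, yielding a connectome; a simplified
single-compartment spiking layer with delayed synapses, dIN gap junctions
and an NMDA-like slow conductance turns the connectome into touch-evoked
activity, scored by swim and mid-cycle-spike detectors.

## Worked example

```python
import tadcord as tc

# matched pair of connectomes: no interaction vs fasciculation s = 0.2, r = 1
plain = tc.run_connectome(tc.RunConfig(seed=1))
fasc  = tc.run_connectome(tc.RunConfig(seed=1, s_pr=0.2, s_se=0.2))
print(plain.count(), fasc.count())
m = tc.synapse_count_matrix(fasc, reference=plain)
print(m["counts"].loc["dIN", ["cIN", "dIN", "mn"]].to_dict())
```

prints

```
1728 1641
{'cIN': 87, 'dIN': 125, 'mn': 118}
```

— the fasciculated connectome has ~5 % fewer synapses than its matched
control (1641 vs 1728), a reduction that holds for every matched seed pair,
and the 7×7 count matrix breaks the change down by presynaptic and
postsynaptic type. The same `RunConfig` drives the CLI:

```bash
tadcord grow --seed 1 --s-pr 0.2 --s-se 0.2 --out trajs.csv --swc-dir swc/
tadcord synapses --seed 1 --out connectome.csv --graphml connectome.graphml
tadcord metrics --seed 1 --out report.json
```

Every artifact carries the configuration hash and seed; identical
invocations are byte-identical.

## What the model reproduces

With attraction even as weak as s = 0.1, axons group into visible bundles:
the dorso-ventral dispersion of trajectories and the number of distinct
bundles both fall monotonically as s rises. Weak repulsion (s = −0.05) makes
trajectories more tortuous, spreading them over the available space. When
the dorsal-tract barriers are perforated (25 µm gaps at 25 µm intervals),
fasciculation onto the pioneer scaffold roughly halves the fraction of
sensory axon points that escape the tract. And fasciculated connectomes
form consistently fewer synapses than matched controls, because descending
secondary axons are deflected by the ascending primary scaffold they adhere
to. The spiking layer's detectors recognise left/right-alternating
motoneuron bursts in the 10–25 Hz swimming band and count dINs that fire
mid-cycle — the signature of degraded rhythm quality when synapse counts are
artificially lowered.

## Layout

| module | role |
| --- | --- |
| `environment` | arena, soma barriers (intact or gapped), dorsal tract, sliding collision rule |
| `population` | cell types, smoothed-bootstrap attribute sampling, soma placement, pioneers |
| `gradient_fields` | G_RC / G_DV evaluators with per-type sensitivities and the commissural pre-crossing override |
| `growth_engine` | lock-step growth loop, fasciculation/repulsion, scheduling, branching, midline crossing |
| `synaptogenesis` | axon–dendrite crossing detection, Bernoulli synapse formation, pruning, count matrices |
| `metrics` | DV distributions, tortuosity, bundle statistics, tract-escape fraction, isolated dINs |
| `optimization` | calibration cost (DV histogram + tortuosity) and compass pattern search |
| `functional_sim` | spiking network, swim detector, mid-cycle dIN counter |
| `fixtures` | synthetic measurement tables, toy scenarios, synthetic rasters |
| `experiments` | packaged matched-seed comparisons used by the tests and the acceptance script |
| `io_cli` | run configs, CSV/SWC/GraphML/JSON readers and writers, `tadcord` CLI |

See `docs/methods.md` for the model's assumptions, parameter choices and
known limitations.
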