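# Methods

## Model overview

The package simulates the development of spinal-cord wiring in the
hatchling *Xenopus* tadpole as three coupled stages: (1) simultaneous,
gradient-guided axon growth with axon–axon attraction or repulsion; (2)
probabilistic synaptogenesis where grown axons cross static dendrites; (3)
a simplified spiking network driven by the resulting connectome. Stages are
strictly feed-forward: activity never feeds back into growth.

### Coordinates and arena

The cord is a 2D rectangle, the neural tube opened like a book along the
dorsal midline: x ∈ [500, 2000] µm is rostro-caudal distance from the
midbrain, y ∈ [−145, 145] µm is dorso-ventral distance from the ventral
midline with y > 0 the left side. Angles are measured counter-clockwise
from +x; "ascending" (toward the head) means growth in −x. The thin third
dimension of the real tube is disregarded.

### Growth rule

Axons elongate Δ = 1 µm per discrete time unit. The tip angle update
combines stiffness (the tendency to keep the previous angle), two gradient
cues projected perpendicular to the current heading, uniform noise
ξ ~ U[−α, α], and — when another axon of the same type has a laid-down
point within range r — an interaction term:

    θ_A     = θ_n − G_RC sin θ_n + G_DV cos θ_n + ξ_n
    θ_B     = θ_p  (s > 0)   or   θ̄_p (s < 0, perpendicular pointing away)
    θ_{n+1} = θ_A + |s| · wrap(θ_B − θ_A)

where θ_p is the growth angle recorded when the neighbouring axon laid its
nearest point, and wrap maps to (−π, π]. The circular-aware blend equals
the plain convex combination (1−|s|)θ_A + |s|θ_B whenever the two angles
are less than π apart, and avoids wrap-around artifacts otherwise. s = 0
reduces exactly to non-interacting growth; |s| = 1 slaves the tip to the
neighbour. Primary and secondary axons carry separate sensitivities
(s_pr, s_se); r defaults to 1 µm.

Design choices the update rule leaves open, and how they were fixed:

- **Repulsion perpendicular.** Of θ_p ± π/2, the one whose unit vector has
  non-negative dot product with (tip − neighbour point); an exact tie
  resolves to θ_p + π/2.
- **Antiparallel attraction.** When the neighbour's recorded angle differs
  from the candidate heading by more than π/2 (e.g. a descending secondary
  axon meeting the ascending primary scaffold), the default is to copy
  θ_p literally, which turns the follower around. This is what the plain
  angle-copy rule prescribes, and it is the mechanism behind the
  fasciculation-induced synapse reduction (below). Two alternatives are
  available on `InteractionParams.antiparallel`: `"align"` (follow the
  neighbour's axis in the axon's own direction of travel) and `"ignore"`
  (no interaction for that step). The choice matters only where axons of
  one type run in both directions through the same space.
- **Neighbour choice.** The single globally closest same-type point within
  r (primary or secondary, pioneer or concurrently growing follower),
  re-selected independently every step; ties break on (lower neuron id,
  lower step index); a neuron's own points are excluded. Queries are served
  by a uniform spatial hash with cell size max(r, Δ), verified against a
  brute-force scan.
- **Commissural axons** (dlc, cIN) neither exert nor feel interaction and
  form no synapses before crossing; their pre-crossing points are also
  withheld from the neighbour index, since interaction and synaptogenesis
  are defined contralaterally only.

### Gradient fields

The cue functions are pluggable; the packaged default family is

    g_rc = ±k_rc                                (sign from RC direction)
    g_dv = sgn(y) · (k_dv · exp(−|y|/λ) + k_off),     λ = 40 µm

The DV couple combines a floor-plate-centred exponential with a constant
bias and is antisymmetric across the midline, so left and right develop as
mirror images. With k_dv > 0 (a floor-plate repellent) and k_off < 0 (a
ventral drift) each type acquires a stable preferred depth
y\* = λ ln(−k_dv/k_off) around which its axons run longitudinally. Defaults
place interneuron and motoneuron axons ventrally (y\* ≈ 28–45 µm),
dorsolateral sensory axons at y\* ≈ 105–110 µm, and give RB axons no DV
couple at all (the dorsal tract barriers confine them). Commissural axons
use an override set while pre-crossing: strong ventral attraction toward
the floor plate, with the cue flat inside the plate (|y| < 25 µm) so that a
crossing axon traverses it ballistically instead of being pulled back to
the midline. These coefficients are calibration targets, not ground truth;
the optimization module exists to fit them to axon statistics.

### Barriers and collision handling

Hard barriers: RB somata at |y| = 137 (full length), dla/dlc somata at
|y| = 127 (x > 700 in the standard environment), and the floor-plate
boundary at |y| = 25 (full length, passable only by pre-crossing
commissural axons — so a crossed axon cannot return). A blocked step places
the cone at the intersection offset 10⁻⁶ µm on the origin side and replaces
the angle with the longitudinal direction that preserves the sign of the
step's x-component (sliding, not reflection); arena edges use the same rule
along their own axis. An axon making no progress on two consecutive clipped
steps (a corner) terminates. Clipped steps are flagged in the output; all
unclipped steps are exactly Δ long.

For the dorsal-tract experiments (escape fraction, gapped barriers) both
tract barriers are run full length, because with the 127-µm barrier absent
rostrally of x = 700 the tract is open there and "zero escape with intact
barriers" cannot hold. `build_standard_environment(dl_barrier_x_start=...)`
exposes the choice; the default keeps the 700 µm start.

Gapped barriers alternate a blocked block (length = `interval`) with an
open gap (length = `gap_length`) starting blocked at the barrier's rostral
end, truncated at the caudal end — 25 µm gaps at 25 µm intervals leave half
the barrier open.

### Scheduling

Per (type, side) group: pioneer primaries (equally spaced along the RC
axis) start at t = 0; followers start most-rostral-first at 200-time-unit
spacing once the group's pioneers have finished. All secondary axons wait
until every primary axon in the simulation has reached full length, then
repeat the pioneer/follower structure (the secondary pioneers are the
pioneer neurons that have secondary axons). Secondaries sprout at the
stored branch point of the finished primary, aimed in the opposite RC
direction (initial angle mirrored about the DV axis); a commissural
secondary sprouts on the contralateral part of its primary, or not at all
if the primary never crossed.

Every axon draws from an independent RNG stream keyed by (master seed,
neuron id, axon class). This makes the s = 0 case bit-identical to growing
each axon alone and makes runs reproducible under scheduling changes.

### Populations and the generalization procedure

Anatomical attributes are drawn from per-type measurement tables by a
smoothed bootstrap: a uniformly chosen row plus independent zero-mean
Gaussian jitter per dimension (bandwidth 2 µm for lengths/positions, 0.05
rad for angles). Soma DV positions are additionally clipped to the table's
observed range, so the generalization interpolates but never extrapolates —
this keeps RB somata strictly inside the dorsal tract. Somata are placed on
a jittered RC grid per (type, side); left/right counts are equal, and
right-side neurons mirror (y, θ) → (−y, −θ).

The packaged tables are synthetic Gaussian-mixture stand-ins generated by
the fixtures module (≥ 100 rows per type), chosen for qualitative
resemblance to the anatomy — RB somata at |y| ≈ 132, dorsolateral
interneurons at ≈ 122–124, ventral motoneurons, commissural initial angles
aimed at the floor plate, log-normal axon lengths of 400–500 µm. They stand
in for microscopy measurements that are not shipped with the package and
are never presented as data. Default counts (30 RB, 20 dla, 20 dlc, 40
aIN, 50 cIN, 50 dIN, 40 mn across both sides) are desk-scale: large enough
for axons to interact at r = 1 µm, small enough that a full growth run
takes ~2 s. The real animal has roughly an order of magnitude more
neurons, so absolute synapse counts here are not comparable to in-vivo
estimates; matched-pair comparisons are.

### Synaptogenesis

Dendrites are single DV-oriented segments centred on the soma, clipped to
the soma's body side. Every elongation segment is intersected exactly
against the dendrite set (endpoint touching counts); each crossing draws an
independent Bernoulli with probability P[pre type][post type], so repeated
crossings of one pair can make multiple contacts. Excluded: self-contacts
(no autapses), pre-crossing commissural segments, and commissural contacts
ipsilateral to the presynaptic soma (the floor-plate barrier already makes
these geometrically impossible; the filter is belt-and-braces). The default
matrix is a uniform 0.5 placeholder — the real pairwise probabilities come
from paired recordings and enter through the run configuration; all
packaged tests are independent of the specific values.

### Metrics

Escape fraction pools primary and secondary Δ-step points with equal
weight. DV dispersion is the mean over 50-µm RC slices of the standard
deviation of axon crossing heights. Bundle statistics sort the crossing
heights at each slice and split clusters at gaps > 5 µm (1D, deterministic;
the bundling experiment uses a sparse open-zone population where this
resolution is meaningful — inside the 10-µm dorsal tract, gap-based counts
are pinned near 1 regardless of bundling). Tortuosity is arc length over
end-to-end distance, ∞ for closed paths. Histogram bins are left-closed,
right-open, final bin closed.

### Calibration

The cost compares candidate-generated axons to target statistics:
w_dv · L1(normalized DV histograms) + w_tort · |mean tortuosity −
target|/target. Replicates use fixed seeds (common random numbers) and are
pooled before comparison, so evaluating the parameters that generated the
targets with the same seeds costs exactly zero, and the cost is a
deterministic function of the parameters. Minimization is compass pattern
search: poll ±step per coordinate, accept the first strict improvement,
halve the step on a full poll failure, stop below tolerance — the trace is
non-increasing by construction. The packaged self-consistency problem
recovers (k_dv, α) for one type to within a few percent from a 2.5×/2.2×
perturbed start.

### Functional layer

Each neuron is a single compartment with classic Hodgkin–Huxley Na/K/leak
kinetics (rest ≈ −65 mV); this is deliberately a generic parameterization
used for qualitative network behaviour, not a fit to tadpole
electrophysiology. dINs additionally carry an NMDA-like conductance with a
sigmoidal magnesium block and slow (80 ms) decay, incremented by dIN→dIN
contacts; with this conductance active, a modest sustained depolarization
drives repetitive (pacemaker-like) firing that the same current cannot
sustain without it. Synapses are difference-of-exponentials conductances
(rise 0.5 ms, decay 3 ms), excitatory at 0 mV except cIN and aIN
(inhibitory, −80 mV); strength = unitary conductance × number of anatomical
contacts; delay = contact arc length / 0.5 m s⁻¹ + 1 ms. Same-side dINs
within 150 µm RC are electrically coupled. Integration: exponential Euler
for gates, forward Euler for voltage, dt ≤ 0.05 ms (default 0.02; halving
dt moves spike times by ≪ 0.5 ms). The dynamics contain no noise, so
mirrored inputs produce exactly mirrored rasters.

Detectors operate on rasters alone. Swimming: motoneuron spikes pooled per
side, split into bursts at inter-spike gaps > 15 ms; swimming requires ≥ 5
consecutive cycles of strict left/right alternation with the reciprocal
median same-side burst interval inside 10–25 Hz. Mid-cycle dINs: a dIN
counts if ≥ 3 of its spikes fall inside the middle 50 % of its own side's
inter-burst intervals (i.e. during contralateral activity). The window rule
is a documented operational definition; detector correctness is established
on constructed rasters with known ground truth, independent of the neuron
model.

## What the packaged experiments show — and do not show

All comparisons are matched-seed (identical populations and RNG streams,
only s differs), 12 seeds, on synthetic anatomy:

- **Bundling**: DV dispersion and bundle count of a dorsolateral sensory
  population decrease monotonically across s ∈ {0, 0.1, 0.5}.
- **Repulsion**: s = −0.05 raises mean tortuosity (p < 10⁻⁸). The increase
  is small in absolute terms because the baseline axons are nearly
  straight.
- **Gapped-barrier rescue**: with both tract barriers half-open, s = 0.2
  drops the escape fraction of 63 RB primary axons per side from ~10–13 %
  to ~7–9 % (paired p ≈ 0.002). Pioneers rarely escape; followers adhering
  to their scaffold are steered past the gaps.
- **Synapse reduction**: fasciculated full connectomes (s = 0.2, r = 1)
  carry ~5–6 % fewer synapses than matched controls, in every seed pair.
  In this implementation the reduction is driven by antiparallel
  deflection of secondary axons by the primary scaffold; marginal
  sharpening of the DV distribution contributes little at these densities.
- **Not reproduced**: the count of dINs isolated from recurrent dIN
  excitation shows no reliable increase under fasciculation at this scale
  (it changes by well under one standard deviation); the published effect
  appears to require the much larger populations and the original gradient
  parameterization. The isolated-dIN counter itself is exact and tested on
  hand-built connectomes. Similarly, absolute swim frequency and the
  synapse-count threshold for swimming depend on cellular parameters this
  package intentionally approximates, and are out of scope.

Because the anatomy is synthetic, passing tests demonstrate properties of
the growth *mechanism* — limits, invariants, and directions of change under
interaction — not agreement with measured tadpole axons.

## Numerical choices and degenerate inputs

Angles are wrapped to (−π, π] everywhere. α = 0 yields exactly zero noise
(a draw is still consumed so streams stay aligned). Zero-length dendrites
are points and can still be touched. A zero end-to-end trajectory reports
infinite tortuosity and is excluded from means. Degenerate vertical
step-segments lying exactly on a dendrite's RC position count as one
crossing. The growth loop is guarded by a step cap and raises with
diagnostics rather than hanging. All randomness flows from explicit seeds;
no global RNG state is used anywhere.
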