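# Methods

`fastmapnet` simulates grounded word learning in a brain-constrained spiking
network of twelve cortical areas and analyses how quickly auditory word forms
become linked to object/action referents under two-stage (fast-mapping) versus
one-stage learning.  This note records the model, its assumptions, the
parameters that matter, the design choices made where the published model
family leaves the design open, and what the synthetic experiments do and do
not establish.

## Model

### Areas and connectivity

Twelve areas represent the perisylvian language cortex (auditory A1, AB, PB;
articulatory M1_i, PM_i, PF_i) and extrasylvian referent systems (visual V1,
TO, AT; hand-motor M1_L, PM_L, PF_L).  Each area holds a 25x25 grid of
excitatory spiking cells and a matching grid of graded inhibitory cells.  The
22 reciprocal between-area links comprise next-neighbor, second-next-neighbor
("jumping") and long-distance connections; the four connector hubs (PB, PF_i,
AT, PF_L) have the highest graph degree, and no two primary areas are linked
directly.

Synapses exist only between excitatory cells and are created once, randomly
and topographically: the probability of a link between cells at Euclidean grid
distance d is `p0 * exp(-d^2 / 2 sigma^2)`, clipped to zero outside a 19x19
neighborhood window (both within and between areas; between-area grids are
taken in register).  Learning changes weights, never topology.  Inhibitory
cells pool the spikes of the 5x5 excitatory neighborhood and feed back
subtractively onto the in-register excitatory cell.

### Cell dynamics

All integrators use the explicit-Euler form `x(t+1) = x(t) + (-x(t) +
drive)/tau` with a step of one simulation tick.  Excitatory membranes
integrate `k1 * (V_in + k2 * eta)` with tau = 2.5 steps, where `V_in` sums
synaptic input, external stimulus drive, local inhibition (weighted by a
strength factor) and the area's global inhibition, and `eta` is per-cell
uniform white noise (excitatory cells only, on during all learning phases,
off during read-out probes).  A cell spikes when `V - alpha * omega_A >=
thresh`; the adaptation variable `omega_A` and the rate estimate `omega_E`
relax toward the spike train with time constants 10 and 30 steps.  Inhibitory
cells are graded: a rectified leaky integrator (tau = 5) of the pooled local
spike count.  Each area's global inhibition integrates its total excitatory
output scaled by `kG` (tau = 12); lowering `kG` from 0.70 to 0.50 models
heightened attention.

### Plasticity

Every excitatory-excitatory synapse updates each step by the discretized
Hebbian rule with LTP, homosynaptic LTD and heterosynaptic LTD (cases selected
by presynaptic `omega_E` against theta_pre = 0.15 and postsynaptic `V` against
theta_plus = 0.15 / theta_minus = 0.14; increment Delta = 0.0012, clamped to
[0, w_max]).  Plasticity is on during stimulation and the inter-trial
relaxation period, and off during all read-out probes.

## Learning protocols

A trial presents its patterns (22 cells each, ~3.5% of an area) to the
relevant primary areas for 16 steps, then relaxes input-free until global
inhibition in the six gate areas (V1, M1_L, A1, M1_i, PF_L, PB) drops below
0.75.  Variable uncorrelated inputs (fresh random 22-cell patterns per trial)
go to the non-relevant primary areas as specified per regime; they are the
force that depresses spurious cross-pattern associations.

* Phase 1: the six referents (V1 or M1_L) and six word forms (A1 + M1_i
  simultaneously) are trained separately, in random interleaved order.
* Phase 2 (fast-mapping): auditory word form + referent co-presented; variable
  noise only to the irrelevant referent primary; nothing to M1_i.
* One-stage: word form (A1 + M1_i) + referent co-presented to a naive sibling
  network with bit-identical initial weights and patterns.
* High attention: fast-mapping with kG = 0.50 for the first three learning
  steps.

After each learning step (one presentation of every word) an A1-only probe
reactivates each word's circuit with noise and learning off, from a rest
state; cell assemblies (CAs) are the cells whose 16-step mean firing reaches
gamma = 0.5 of their area's maximum.  A word is *linked* when the probe
reactivates at least 10% (inclusive) of its referent representation's cells
pooled over the associated areas (V1/TO/AT for object words, M1_L/PM_L/PF_L
for action words); reactivation of every non-paired referent is recorded the
same way.  Referent representations are frozen at the end of phase 1 for
two-stage runs and re-extracted per probe step for one-stage runs (which have
no phase-1 reference).  A network is excluded as "merged" when any single-word
probe reactivates >= 10% of more than one referent representation.

## Calibration choices

The published constants (Table-2-style values: time constants, k1, k2, kG,
thresh, alpha, theta thresholds, Delta) are used verbatim.  The quantities the
model family leaves to its appendix — stimulus amplitudes, noise amplitude,
the weight scale, connection-kernel densities, inhibition feedback strengths —
were calibrated once, against the qualitative behavior the model must show
(stable sparse activity, cross-area assembly growth, no runaway), and then
frozen:

* **Stimulus drive 1500** (input units; membrane asymptote k1*1500 = 15):
  pattern cells fire on essentially every stimulation step despite
  adaptation, which makes the stimulated pattern the dominant presynaptic
  source of learning.  Static jitter is +/-10% multiplicative.
* **Variable-noise amplitude 200** (~13% of the stimulus drive): noise-pattern
  cells still fire (rate ~0.2-0.4), preserving their role of depressing
  spurious cross-pattern associations, but their downstream depolarization no
  longer erodes every forming assembly.  At equal amplitudes each fresh noise
  pattern drives its own tail of downstream cells over θ_+, and the 9-of-12
  noise-exposed trials per sweep then depress more weight than an item's own
  trials can add — measured directly, this freezes assembly growth entirely.
* **White-noise bound 0.25 at k2 = 2*sqrt(24/0.5)**, giving a stationary
  membrane s.d. of ~0.01: sharp enough that θ_+ crossings are essentially
  deterministic in the drive (cells above the LTP threshold gain on nearly
  every stimulation step, cells below it almost never cross), which keeps the
  LTP/LTD event ledger from self-cancelling across the narrow
  [θ_-, θ_+) band.
* **Weight ceiling w_max = 10, initial weights U[0, 3]**: a 22-cell pattern
  through the between-area kernel converges ~7 synapses onto a typical
  downstream cell, so the ceiling must allow tens of co-active afferents to
  depolarize a cell past threshold; a ceiling an order of magnitude smaller
  leaves downstream membranes numerically unreachable from any pattern.
* **Local inhibition strength 3000, global-inhibition input scale 12**
  (subtractive, as is the package's design choice for the unpublished
  inhibition form): strong enough that the double-stimulation (word-form) and
  triple-stimulation (one-stage) trials cannot ignite network-wide bursts,
  which otherwise sweep all areas over θ_+ for a few steps per trial and
  heterosynaptically erase cross-area learning; the relaxation gate then
  clears in a few tens of steps per trial.

## What the synthetic world does and does not establish

The generator emulates exactly the stated experimental structure: per
network, 6 word forms (paired A1+M1_i patterns) and 3+3 object/action
referents, all 22-of-625 uniform random patterns, plus fresh per-trial noise
patterns.  It does not emulate structured (correlated, hierarchical) sensory
input, phoneme sequence structure, or any cross-network pattern sharing — a
green test therefore speaks to the learning dynamics of arbitrary pattern
associations, not to realistic stimulus statistics.

Desk-scale runs (reduced networks/presentations, documented in the README)
replicate directions and zero-error properties, not the published magnitudes;
full-scale runs (3000-presentation phase 1, 20 networks) are hours of CPU per
network and are driven through the same code paths by configuration only.

## Numerical notes

* Explicit Euler with leak factor (1 - 1/tau); all state in float64.
* The engine's update order is: synaptic propagation from the previous step's
  spikes (inhibition lagged one step), excitatory update + spikes, inhibitory
  pool of the new spikes, global inhibition of the new spikes, plasticity.
  A per-cell scalar reference implementation reproduces the engine bit-for-bit
  on micro-networks (tested).
* Ties: the gamma CA threshold and the 10% linking criterion are inclusive
  (>=); the plasticity thresholds follow the rule's printed inequalities
  (theta_pre and theta_plus inclusive, theta_minus inclusive from below).
* Degenerate inputs: an area with zero maximal probe firing yields an empty
  CA; an empty referent representation makes the linking fraction undefined
  and raises.
* Relaxation is capped at 500 steps; exceeding the cap raises a stability
  error (runaway activity), which at full scale is how unanalyzable "merged"
  subjects announce themselves during one-stage learning.
* RNG discipline: master seed -> per-network seed -> independent streams for
  connectivity (one per area pair), patterns, and trial noise; every output
  embeds the config hash and seed.

## Known limitations

* Conductance-based dynamics, axonal delays, spike-timing windows and
  inhibitory plasticity are out of scope.
* The desk-scale runs use far fewer phase-1 presentations than the published
  3000; assembly maturity is correspondingly reduced.  Two quantitative walls
  follow from the published constants themselves and bound what reduced runs
  can show.  First, a synapse changes by at most 16Δ ≈ 0.02 per
  co-presentation, while reigniting a referent cell in a noise-free probe
  needs a summed bridge weight of order 20 input units across the few
  synapses arriving from a small word assembly — hundreds of co-presentations,
  not tens.  Second, presynaptic eligibility (ω_E ≥ θ_pre = 0.15 under
  adaptation strength α = 7) requires a sustained membrane potential of
  ~1.2, reachable only inside large mature assemblies.  Desk runs therefore
  replicate the zero-error specificity properties and the category-specific
  topography of the grounded referent representations, but word-referent
  linking itself stays at zero within 50 desk-scale fast-mapping steps, in
  both the two-stage and one-stage regimes; the published linking-speed
  contrast is out of desk-scale reach (and, in this reimplementation, may
  additionally depend on unpublished appendix-level equation details).
* The exclusion criterion for merged networks is an operationalization (>=10%
  reactivation of more than one referent by a single probe); the published
  analysis states the phenomenon but not its quantitative rule.
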