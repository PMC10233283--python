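# fastmapnet

A brain-constrained spiking neural network for simulating **fast-mapping**:
the rapid linking of a newly heard word form to its object or action referent.
The package is aimed at computational neuroscientists who want to study how
Hebbian cell-assembly dynamics in a cortically structured network support
rapid associative word learning, and how prior phonological/conceptual
knowledge (two-stage learning) compares with direct word-meaning association
(one-stage learning).

## The model

Twelve cortical areas — auditory (A1, AB, PB), articulatory (M1_i, PM_i,
PF_i), visual (V1, TO, AT) and hand-motor (M1_L, PM_L, PF_L), with connector
hubs PB, PF_i, AT, PF_L — each hold a 25x25 grid of excitatory
integrate-and-fire cells plus graded local inhibition and an area-specific
global inhibition level. The 22 reciprocal between-area connections follow
the neuroanatomical next-neighbor / jumping / long-distance scheme. All
excitatory synapses obey the discretized Hebbian rule

```
            +Δ   if ω_E(i,t) ≥ θ_pre and V(j,t) ≥ θ_+          (LTP)
Δw(i,j) =   -Δ   if ω_E(i,t) ≥ θ_pre and θ_- ≤ V(j,t) < θ_+    (homosynaptic LTD)
            -Δ   if ω_E(i,t) < θ_pre and V(j,t) ≥ θ_+          (heterosynaptic LTD)
             0   otherwise
```

with θ_pre = θ_+ = 0.15, θ_- = 0.14, Δ = 0.0012, and weights clamped to
[0, w_max]. Stimuli are random 22-cell binary patterns in primary areas; per
network there are 6 word forms (paired A1 + M1_i patterns) and 3 object + 3
action referents (V1 / M1_L patterns). Learning trials present patterns for
16 steps and relax until the gate areas' global inhibition falls below 0.75.
Word comprehension is probed by A1-only stimulation with noise and learning
off; cell assemblies are the cells whose mean probe firing reaches γ = 0.5 of
their area's maximum, and a word counts as *linked* when ≥ 10% of its
referent representation reactivates in the associated extrasylvian areas.

See `docs/methods.md` for assumptions, calibration choices and limitations.

## Worked example

```python
from fastmapnet import ExperimentConfig
from fastmapnet.protocols import run_two_stage
from fastmapnet.analysis import linking_rate

cfg = ExperimentConfig.desk(master_seed=1)   # 2 networks, 300 phase-1 presentations
res = run_two_stage(cfg, network_id=0)       # phase 1 + 50 fast-mapping steps
for word, rep in res.referent_reps.items():
    print(word, {a: c for a, c in rep.counts().items() if c})
print("incorrect-referent max:", res.curves_fastmap["frac_incorrect_max"].max())
```

prints (seed 1, network 0; phase 1 takes a couple of minutes):

```
w0 {'V1': 22, 'TO': 7, 'AT': 7}
w1 {'V1': 22, 'TO': 10, 'AT': 7}
w2 {'V1': 22, 'TO': 7, 'AT': 6}
w3 {'PF_L': 9, 'PM_L': 9, 'M1_L': 22}
w4 {'PF_L': 6, 'PM_L': 6, 'M1_L': 22}
w5 {'PF_L': 6, 'PM_L': 5, 'M1_L': 22}
incorrect-referent max: 0.0
```

Each referent representation contains its 22 stimulated primary-area cells
plus the cells recruited downstream during grounding — object circuits extend
into the visual stream (TO, AT), action circuits into the hand-motor stream
(PM_L, PF_L), and no word probe ever reactivates a non-paired referent. At
this reduced desk scale the downstream assemblies stay small (a handful of
cells per area, versus tens at the published 3000-presentation scale), which
is why desk runs replicate directions and zero-error properties rather than
published linking-speed magnitudes (see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```
fastmapnet reproduce --scale desk --seed 1 --out results/
fastmapnet run --regime fastmap --network 0 --out results/
```

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the reduced two-stage experiment from scratch (networks built,
grounded, fast-mapped and probed at every learning step; merged networks
excluded) and reports the maximum proportion of any non-paired referent
representation reactivated by an auditory word probe, over all words, steps
and networks. Runtime is a few minutes on one CPU.
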