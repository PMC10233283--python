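"""Trial structure and the learning regimes.

A learning trial presents its input patterns to the primary areas for 16
steps (white noise and plasticity on throughout), then lets the network relax
input-free until the global inhibition of the gate areas (V1, M1_L, A1, M1_i,
PF_L, PB) falls below 0.75, which marks readiness for the next trial.

Regimes:

* phase 1 — referents (V1 objects / M1_L actions) and word forms (A1 + M1_i
  simultaneously) trained separately, 3000 presentations each at full scale,
  with variable uncorrelated inputs to the non-relevant primary areas;
* phase 2 (fast-mapping) — auditory word form + referent co-presented on top
  of the phase-1 network; variable noise only to the irrelevant referent
  primary area, none to M1_i;
* one-stage — word form (A1 + M1_i) + referent co-presented to a naive
  sibling network (same seed, identical initial weights and patterns);
* high attention — fast-mapping with kG lowered to 0.50 for the first three
  learning steps.

After every learning step (one presentation of each word) an auditory-only
comprehension probe is run per word and scored against the frozen referent
representations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .analysis import (
    ACTION_AREAS,
    OBJECT_AREAS,
    CellAssembly,
    curve_row,
    is_linked,
    probe_word_comprehension,
    reactivated_fraction,
    referent_representation,
)
from .network import NetworkState, build_network
from .params import ExperimentConfig
from .stimuli import (
    SemanticPatternSet,
    StimulusPattern,
    generate_network_patterns,
    pattern_rng,
    stimulus_drive,
    variable_noise_input,
)

__all__ = [
    "TrialSpec",
    "StabilityError",
    "run_trial",
    "run_phase1",
    "run_phase2_fastmap",
    "run_one_stage",
    "attention_schedule_high",
    "attention_schedule_baseline",
    "network_seed_for",
    "prepare_network",
    "TwoStageResult",
    "run_two_stage",
    "is_merged",
]

logger = logging.getLogger("fastmapnet")

PRIMARIES = ("A1", "M1_i", "V1", "M1_L")


class StabilityError(RuntimeError):
    """Relaxation did not reach the readiness gate: runaway activity."""


@dataclass(frozen=True)
class TrialSpec:
    """One learning trial: which patterns go where, and at which attention."""

    stimuli: dict[str, StimulusPattern]
    noise_areas: tuple[str, ...] = ()
    stimulus_steps: int = 16
    attention_kG: float | None = None  # None = the configured baseline

    def __post_init__(self) -> None:
        overlap = set(self.stimuli) & set(self.noise_areas)
        if overlap:
            raise ValueError(f"noise areas overlap stimulus areas: {sorted(overlap)}")
        if self.stimulus_steps < 1:
            raise ValueError("stimulus_steps must be >= 1")


def run_trial(net: NetworkState, trial: TrialSpec) -> int:
    """Run one learning trial in place; returns the relaxation duration."""
    arch, cfg = net.arch, net.config
    ext = np.zeros((arch.n_areas, arch.n_cells))
    for area, pat in trial.stimuli.items():
        ext[arch.index(area)] = stimulus_drive(
            pat, cfg.stimulus, rng=net.rng_trial, n_cells=arch.n_cells
        )
    if trial.noise_areas:
        for area, drive in variable_noise_input(
            trial.noise_areas, cfg.stimulus, net.rng_trial, arch.n_cells
        ).items():
            ext[arch.index(area)] = drive
    for _ in range(trial.stimulus_steps):
        net.step(external=ext, noise_on=True, learning=True, kG=trial.attention_kG)
    relax = 0
    cap = cfg.protocol.relaxation_cap
    while not net.gate_satisfied():
        if relax >= cap:
            raise StabilityError(
                f"relaxation exceeded {cap} steps (glob_inhib="
                f"{np.round(net.glob_inhib, 3).tolist()})"
            )
        net.step(external=None, noise_on=True, learning=True, kG=trial.attention_kG)
        relax += 1
    return relax


# ---------------------------------------------------------------------------
# phase 1: grounding of referents and word forms, trained separately
# ---------------------------------------------------------------------------

def phase1_trials(sets: Sequence[SemanticPatternSet]) -> list[TrialSpec]:
    """The 12 phase-1 items (6 referents + 6 word forms) as trial specs."""
    trials = []
    for s in sets:
        noise = tuple(a for a in PRIMARIES if a != s.referent.area)
        trials.append(TrialSpec(stimuli={s.referent.area: s.referent}, noise_areas=noise))
        trials.append(
            TrialSpec(
                stimuli={"A1": s.auditory, "M1_i": s.articulatory},
                noise_areas=("V1", "M1_L"),
            )
        )
    return trials


def run_phase1(
    net: NetworkState,
    sets: Sequence[SemanticPatternSet],
    presentations: int | None = None,
    progress: Callable[[int], None] | None = None,
) -> NetworkState:
    """Train referent and word-form representations separately.

    Each of the 12 items is presented ``presentations`` times; presentation
    order is a fresh uniformly random permutation of the item list per sweep.
    """
    presentations = presentations or net.config.protocol.phase1_presentations
    items = phase1_trials(sets)
    for sweep in range(presentations):
        for i in net.rng_trial.permutation(len(items)):
            run_trial(net, items[i])
        if progress is not None:
            progress(sweep + 1)
    return net


# ---------------------------------------------------------------------------
# attention schedules
# ---------------------------------------------------------------------------

def attention_schedule_baseline(kG: float = 0.70) -> Callable[[int], float]:
    """Constant baseline global inhibition."""
    return lambda step: kG


def attention_schedule_high(
    kG_high: float = 0.50, kG_base: float = 0.70, high_steps: int = 3
) -> Callable[[int], float]:
    """High attention (lowered kG) for the first ``high_steps`` learning steps."""

    def schedule(step: int) -> float:
        return kG_high if 1 <= step <= high_steps else kG_base

    return schedule


# ---------------------------------------------------------------------------
# phase 2 (fast-mapping) and one-stage learning
# ---------------------------------------------------------------------------

def _word_trial(s: SemanticPatternSet, one_stage: bool, kG: float | None) -> TrialSpec:
    irrelevant = "M1_L" if s.word_type == "object" else "V1"
    stimuli = {"A1": s.auditory, s.referent.area: s.referent}
    if one_stage:
        # naive networks also get the articulatory half of the word form
        stimuli["M1_i"] = s.articulatory
    return TrialSpec(stimuli=stimuli, noise_areas=(irrelevant,), attention_kG=kG)


def _probe_all(
    net: NetworkState,
    sets: Sequence[SemanticPatternSet],
    referent_reps: dict[str, CellAssembly],
    step: int,
    rows: list[dict],
) -> None:
    """Auditory comprehension probe for every word; appends curve rows."""
    params = net.config.ca_extraction
    for s in sets:
        ca = probe_word_comprehension(
            net, s, params, provenance=(net.network_seed, s.word, step)
        )
        link = is_linked(ca, referent_reps[s.word], s.word_type, params)
        frac_inc = 0.0
        for other in sets:
            if other.word == s.word:
                continue
            areas = OBJECT_AREAS if other.word_type == "object" else ACTION_AREAS
            frac_inc = max(
                frac_inc, reactivated_fraction(ca, referent_reps[other.word], areas)
            )
        rows.append(
            curve_row(
                net.network_seed, s.word, s.word_type, step,
                link, frac_inc, ca, net.arch.names,
            )
        )


def run_phase2_fastmap(
    net: NetworkState,
    sets: Sequence[SemanticPatternSet],
    referent_reps: dict[str, CellAssembly],
    n_steps: int | None = None,
    attention_schedule: Callable[[int], float] | None = None,
    progress: Callable[[int], None] | None = None,
) -> pd.DataFrame:
    """Fast-mapping on a phase-1-trained network.

    One learning step = one presentation of every word (random order); a
    comprehension probe for every word follows each step.  ``referent_reps``
    are the frozen end-of-phase-1 referent representations the linking
    criterion is scored against.  Returns the tidy learning-curve table
    (including a step-0 probe before any pairing).
    """
    n_steps = n_steps or net.config.protocol.phase2_presentations
    schedule = attention_schedule or attention_schedule_baseline(
        net.config.global_inhibition.kG
    )
    rows: list[dict] = []
    _probe_all(net, sets, referent_reps, 0, rows)
    for step in range(1, n_steps + 1):
        kG = schedule(step)
        for i in net.rng_trial.permutation(len(sets)):
            run_trial(net, _word_trial(sets[i], one_stage=False, kG=kG))
        _probe_all(net, sets, referent_reps, step, rows)
        if progress is not None:
            progress(step)
    return pd.DataFrame(rows)


def run_one_stage(
    net: NetworkState,
    sets: Sequence[SemanticPatternSet],
    n_steps: int | None = None,
    progress: Callable[[int], None] | None = None,
) -> pd.DataFrame:
    """Direct word-meaning learning on a naive network.

    The word form (A1 + M1_i) and the referent are co-presented from the very
    first trial.  The referent representations used by the linking criterion
    are re-extracted at every probe step from the same network (no phase-1
    reference exists).  The first ``one_stage_burn_in`` learning steps are
    flagged (``analyzed == False``) and excluded from linking comparisons.
    """
    n_steps = n_steps or net.config.protocol.phase2_presentations
    burn_in = net.config.protocol.one_stage_burn_in
    params = net.config.ca_extraction
    rows: list[dict] = []

    def reps_now() -> dict[str, CellAssembly]:
        return {s.word: referent_representation(net, s, params) for s in sets}

    _probe_all(net, sets, reps_now(), 0, rows)
    for step in range(1, n_steps + 1):
        for i in net.rng_trial.permutation(len(sets)):
            run_trial(net, _word_trial(sets[i], one_stage=True, kG=None))
        _probe_all(net, sets, reps_now(), step, rows)
        if progress is not None:
            progress(step)
    df = pd.DataFrame(rows)
    df["analyzed"] = df["step"] > burn_in
    return df


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

def network_seed_for(master_seed: int, network_id: int) -> int:
    """Derived per-network seed (stable, < 2**31)."""
    ss = np.random.SeedSequence([master_seed, network_id])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def prepare_network(
    config: ExperimentConfig, network_id: int
) -> tuple[NetworkState, list[SemanticPatternSet]]:
    """Build one naive network and its fixed pattern inventory."""
    seed = network_seed_for(config.master_seed, network_id)
    net = build_network(config, seed)
    sets = generate_network_patterns(
        pattern_rng(seed), config.stimulus, net.arch.n_cells
    )
    return net, sets


def is_merged(curves: pd.DataFrame, linking_fraction: float = 0.10) -> bool:
    """A network is flagged as merged when any single-word probe reactivates
    at least the linking fraction of more than one referent representation."""
    both = (curves["frac_correct"] >= linking_fraction) & (
        curves["frac_incorrect_max"] >= linking_fraction
    )
    return bool(both.any())


@dataclass
class TwoStageResult:
    """Everything one network contributes to the two-stage experiment."""

    network_id: int
    network_seed: int
    curves_fastmap: pd.DataFrame
    curves_attention: pd.DataFrame | None = None
    curves_one_stage: pd.DataFrame | None = None
    merged: bool = False
    referent_reps: dict[str, CellAssembly] = field(default_factory=dict)


def run_two_stage(
    config: ExperimentConfig,
    network_id: int,
    with_attention: bool = False,
    with_one_stage: bool = False,
    attention_steps: int | None = None,
    progress: Callable[[str, int], None] | None = None,
) -> TwoStageResult:
    """Phase 1 + fast-mapping for one subject, with optional siblings.

    The high-attention sibling restarts fast-mapping from the same end-of-
    phase-1 state; the one-stage sibling is a naive rebuild with identical
    initial weights and patterns (same network seed).
    """
    net, sets = prepare_network(config, network_id)
    cb = (lambda tag: (lambda k: progress(tag, k))) if progress else (lambda tag: None)
    run_phase1(net, sets, progress=cb("phase1"))
    reps = {s.word: referent_representation(net, s, config.ca_extraction) for s in sets}
    snap = net.snapshot_transient()
    weights0 = net.pack.data.copy()
    rng_state = net.rng_trial.bit_generator.state

    curves = run_phase2_fastmap(net, sets, reps, progress=cb("fastmap"))
    result = TwoStageResult(
        network_id=network_id,
        network_seed=net.network_seed,
        curves_fastmap=curves,
        merged=is_merged(curves, config.ca_extraction.linking_fraction),
        referent_reps=reps,
    )
    if with_attention:
        net.restore_transient(snap)
        np.copyto(net.pack.data, weights0)
        net.rng_trial.bit_generator.state = rng_state
        proto = config.protocol
        result.curves_attention = run_phase2_fastmap(
            net, sets, reps,
            n_steps=attention_steps,
            attention_schedule=attention_schedule_high(
                proto.attention_high_kG,
                config.global_inhibition.kG,
                proto.attention_high_steps,
            ),
            progress=cb("attention"),
        )
    if with_one_stage:
        naive, sets2 = prepare_network(config, network_id)
        result.curves_one_stage = run_one_stage(naive, sets2, progress=cb("one_stage"))
    return result
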