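"""Synthetic stimulus generation.

Every input the experiments use is synthetic: binary activation patterns of 22
cells (of 625) in a primary area.  A network's inventory is 18 patterns — 6
auditory (A1), 6 articulatory (M1_i), 3 visual-object (V1) and 3 hand-motor
action (M1_L) — paired into 6 semantic pattern sets (3 object words, 3 action
words).  The inventory is a pure function of the network's pattern seed.

Stimulus drive is a constant supra-threshold input to the pattern cells for
the duration of a trial, with a multiplicative static jitter fixed within the
trial.  Variable "uncorrelated" noise inputs are fresh random 22-cell patterns
redrawn every trial, driven at a weaker amplitude than real stimuli (strong
enough that the noise cells fire and depress spurious associations, weak
enough that their downstream depolarization does not erode forming
assemblies; see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .architecture import PRIMARY_AREAS
from .params import StimulusParams

__all__ = [
    "StimulusPattern",
    "SemanticPatternSet",
    "generate_pattern",
    "generate_network_patterns",
    "pattern_rng",
    "stimulus_drive",
    "variable_noise_input",
    "export_patterns",
    "import_patterns",
]

_PATTERN_STREAM = 7919


@dataclass(frozen=True)
class StimulusPattern:
    """A binary activation pattern in one primary area."""

    area: str
    cells: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("pattern cells must be distinct")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class SemanticPatternSet:
    """One word: paired auditory + articulatory form patterns and a referent."""

    word: str
    word_type: str  # "object" | "action"
    auditory: StimulusPattern      # A1
    articulatory: StimulusPattern  # M1_i
    referent: StimulusPattern      # V1 (object) or M1_L (action)

    def __post_init__(self) -> None:
        if self.word_type not in ("object", "action"):
            raise ValueError(f"bad word_type {self.word_type!r}")
        expected = "V1" if self.word_type == "object" else "M1_L"
        if self.referent.area != expected:
            raise ValueError(
                f"{self.word_type} word requires a {expected} referent, "
                f"got {self.referent.area}"
            )


def pattern_rng(network_seed: int) -> np.random.Generator:
    """The dedicated pattern stream of a network (independent of trial noise)."""
    return np.random.default_rng(np.random.SeedSequence([network_seed, _PATTERN_STREAM]))


def generate_pattern(
    area: str,
    rng: np.random.Generator,
    n_pattern_cells: int = 22,
    n_cells: int = 625,
) -> StimulusPattern:
    """Sample one pattern: cells drawn uniformly without replacement."""
    if area not in PRIMARY_AREAS:
        raise ValueError(f"patterns are presented to primary areas only, got {area!r}")
    cells = rng.choice(n_cells, size=n_pattern_cells, replace=False)
    return StimulusPattern(area=area, cells=tuple(int(c) for c in np.sort(cells)))


def generate_network_patterns(
    rng: np.random.Generator,
    params: StimulusParams | None = None,
    n_cells: int = 625,
) -> list[SemanticPatternSet]:
    """A network's full inventory: 6 word forms paired with 3+3 referents.

    All 18 patterns are mutually distinct within the network; the pairing is
    fixed for the network's lifetime.
    """
    params = params or StimulusParams()
    k = params.pattern_cells

    def draw(area: str, seen: set) -> StimulusPattern:
        while True:
            p = generate_pattern(area, rng, k, n_cells)
            if (p.area, p.cells) not in seen:
                seen.add((p.area, p.cells))
                return p

    seen: set = set()
    sets: list[SemanticPatternSet] = []
    for i in range(6):
        word_type = "object" if i < 3 else "action"
        ref_area = "V1" if word_type == "object" else "M1_L"
        sets.append(
            SemanticPatternSet(
                word=f"w{i}",
                word_type=word_type,
                auditory=draw("A1", seen),
                articulatory=draw("M1_i", seen),
                referent=draw(ref_area, seen),
            )
        )
    return sets


def stimulus_drive(
    pattern: StimulusPattern,
    params: StimulusParams,
    rng: np.random.Generator | None = None,
    n_cells: int = 625,
) -> np.ndarray:
    """Per-cell external input for one trial (one area).

    Pattern cells receive the base amplitude perturbed by a static
    (fixed-within-trial) multiplicative jitter drawn from ``rng``; all other
    cells receive 0.
    """
    drive = np.zeros(n_cells)
    cells = np.asarray(pattern.cells, dtype=int)
    if params.static_noise_frac > 0.0 and rng is not None:
        jitter = rng.uniform(-params.static_noise_frac, params.static_noise_frac, cells.size)
    else:
        jitter = np.zeros(cells.size)
    drive[cells] = params.amplitude * (1.0 + jitter)
    return drive


def variable_noise_input(
    target_areas: list[str] | tuple[str, ...],
    params: StimulusParams,
    rng: np.random.Generator,
    n_cells: int = 625,
) -> dict[str, np.ndarray]:
    """Fresh uncorrelated pattern-like input per trial to each listed area."""
    out: dict[str, np.ndarray] = {}
    for area in target_areas:
        p = generate_pattern(area, rng, params.pattern_cells, n_cells)
        field = np.zeros(n_cells)
        field[list(p.cells)] = params.noise_amplitude
        out[area] = field
    return out


# ---------------------------------------------------------------------------
# JSON round-trip of a pattern inventory
# ---------------------------------------------------------------------------

def export_patterns(sets: list[SemanticPatternSet], path: str | Path, seed: int | None = None) -> None:
    doc = {
        "seed": seed,
        "sets": [
            {
                "word": s.word,
                "word_type": s.word_type,
                "auditory": list(s.auditory.cells),
                "articulatory": list(s.articulatory.cells),
                "referent_area": s.referent.area,
                "referent": list(s.referent.cells),
            }
            for s in sets
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def import_patterns(path: str | Path) -> list[SemanticPatternSet]:
    doc = json.loads(Path(path).read_text())
    out = []
    for s in doc["sets"]:
        out.append(
            SemanticPatternSet(
                word=s["word"],
                word_type=s["word_type"],
                auditory=StimulusPattern("A1", tuple(s["auditory"])),
                articulatory=StimulusPattern("M1_i", tuple(s["articulatory"])),
                referent=StimulusPattern(s["referent_area"], tuple(s["referent"])),
            )
        )
    return out
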