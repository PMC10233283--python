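"""Cell-assembly extraction, word-comprehension probing and linking analysis.

A cell assembly (CA) is read out by presenting a probe stimulus for 16 steps
with white noise and learning switched off, time-averaging each excitatory
cell's firing and keeping, per area, the cells whose average reaches gamma
(default 0.5) of the area's maximum.  A word counts as *linked* to its
referent when an A1-only auditory probe reactivates at least 10% of the
referent representation's cells in the associated extrasylvian areas (V1/TO/AT
for object words, M1_L/PM_L/PF_L for action words).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import CAExtractionParams
from .stimuli import SemanticPatternSet, StimulusPattern, stimulus_drive

__all__ = [
    "CellAssembly",
    "LinkResult",
    "extract_ca",
    "probe_word_comprehension",
    "referent_representation",
    "word_form_representation",
    "reactivated_fraction",
    "is_linked",
    "linking_rate",
    "category_specificity",
    "export_tidy_results",
    "OBJECT_AREAS",
    "ACTION_AREAS",
    "RANKED_AREAS",
]

OBJECT_AREAS: tuple[str, ...] = ("V1", "TO", "AT")
ACTION_AREAS: tuple[str, ...] = ("M1_L", "PM_L", "PF_L")
#: associated referent area per (word_type, rank)
RANKED_AREAS = {
    ("object", "primary"): "V1",
    ("object", "secondary"): "TO",
    ("object", "hub"): "AT",
    ("action", "primary"): "M1_L",
    ("action", "secondary"): "PM_L",
    ("action", "hub"): "PF_L",
}


@dataclass(frozen=True)
class CellAssembly:
    """Per-area sets of excitatory cells exceeding the gamma threshold."""

    cells: dict[str, frozenset[int]]
    provenance: tuple = ()

    def count(self, area: str) -> int:
        return len(self.cells.get(area, frozenset()))

    def counts(self) -> dict[str, int]:
        return {a: len(c) for a, c in self.cells.items()}

    def total(self, areas) -> int:
        return sum(self.count(a) for a in areas)


@dataclass(frozen=True)
class LinkResult:
    linked: bool
    fraction: float                       # pooled over the associated areas
    fraction_by_rank: dict[str, float]    # primary/secondary/hub of that system


def threshold_rates(rates: np.ndarray, gamma: float) -> list[np.ndarray]:
    """Per-area gamma-relative thresholding of a (n_areas, n_cells) rate field.

    An area with zero maximum yields an empty selection.
    """
    out = []
    for a in range(rates.shape[0]):
        m = rates[a].max()
        if m <= 0.0:
            out.append(np.empty(0, dtype=int))
        else:
            out.append(np.flatnonzero(rates[a] >= gamma * m))
    return out


def _probe_rates(net, stimuli: dict[str, np.ndarray], params: CAExtractionParams) -> np.ndarray:
    """Run a noise-free, learning-free probe from rest; return mean firing."""
    arch = net.arch
    ext = np.zeros((arch.n_areas, arch.n_cells))
    for area, drive in stimuli.items():
        ext[arch.index(area)] = drive
    snap = net.snapshot_transient()
    net.reset_transient()
    acc = np.zeros((arch.n_areas, arch.n_cells))
    for _ in range(params.probe_steps):
        net.step(external=ext, noise_on=not params.noise_off, learning=False)
        acc += net.O_e
    net.restore_transient(snap)
    net.step_count -= params.probe_steps
    return acc / params.probe_steps


def extract_ca(
    net,
    probe_stimuli: dict[str, StimulusPattern],
    params: CAExtractionParams | None = None,
    provenance: tuple = (),
) -> CellAssembly:
    """Extract the CA reactivated by a probe stimulus.

    ``probe_stimuli`` maps primary-area names to the binary patterns driven
    during the probe (full amplitude, no static jitter, no white noise, no
    learning; the network's ongoing state is left untouched).
    """
    params = params or CAExtractionParams()
    drives = {
        area: stimulus_drive(pat, net.config.stimulus, rng=None, n_cells=net.arch.n_cells)
        for area, pat in probe_stimuli.items()
    }
    rates = _probe_rates(net, drives, params)
    picked = threshold_rates(rates, params.gamma)
    cells = {
        net.arch.names[a]: frozenset(int(i) for i in picked[a])
        for a in range(net.arch.n_areas)
    }
    return CellAssembly(cells=cells, provenance=provenance)


def probe_word_comprehension(
    net, word: SemanticPatternSet, params: CAExtractionParams | None = None,
    provenance: tuple = (),
) -> CellAssembly:
    """Simulated auditory word recognition: the A1 pattern alone is presented."""
    return extract_ca(net, {"A1": word.auditory}, params, provenance)


def referent_representation(
    net, word: SemanticPatternSet, params: CAExtractionParams | None = None,
) -> CellAssembly:
    """Reactivate the referent circuit (V1 input for objects, M1_L for actions)."""
    return extract_ca(
        net, {word.referent.area: word.referent}, params,
        provenance=(net.network_seed, f"referent:{word.word}"),
    )


def word_form_representation(
    net, word: SemanticPatternSet, params: CAExtractionParams | None = None,
) -> CellAssembly:
    """Reactivate the phonological circuit (simultaneous A1 + M1_i input)."""
    return extract_ca(
        net, {"A1": word.auditory, "M1_i": word.articulatory}, params,
        provenance=(net.network_seed, f"wordform:{word.word}"),
    )


def reactivated_fraction(
    probe_ca: CellAssembly, referent_ca: CellAssembly, areas
) -> float:
    """Fraction of the referent representation's cells (pooled over ``areas``)
    that the probe CA reactivates."""
    ref_total = referent_ca.total(areas)
    if ref_total == 0:
        raise ValueError("empty referent representation in the associated areas")
    hit = 0
    for a in areas:
        hit += len(probe_ca.cells.get(a, frozenset()) & referent_ca.cells.get(a, frozenset()))
    return hit / ref_total


def is_linked(
    word_ca: CellAssembly,
    referent_ca: CellAssembly,
    word_type: str,
    params: CAExtractionParams | None = None,
) -> LinkResult:
    """Apply the (inclusive) 10% linking criterion, pooled over the associated
    referent areas, and report per-rank reactivation fractions."""
    params = params or CAExtractionParams()
    areas = OBJECT_AREAS if word_type == "object" else ACTION_AREAS
    frac = reactivated_fraction(word_ca, referent_ca, areas)
    by_rank = {}
    for rank in ("primary", "secondary", "hub"):
        area = RANKED_AREAS[(word_type, rank)]
        n_ref = referent_ca.count(area)
        if n_ref == 0:
            by_rank[rank] = float("nan")
        else:
            hit = len(word_ca.cells.get(area, frozenset()) & referent_ca.cells[area])
            by_rank[rank] = hit / n_ref
    return LinkResult(
        linked=frac >= params.linking_fraction, fraction=frac, fraction_by_rank=by_rank
    )


# ---------------------------------------------------------------------------
# learning-curve summaries
# ---------------------------------------------------------------------------

CURVE_SCHEMA_VERSION = 1


def curve_row(
    network: int, word: str, word_type: str, step: int,
    link: LinkResult, frac_incorrect_max: float, ca: CellAssembly, area_names,
) -> dict:
    row = {
        "network": network,
        "word": word,
        "word_type": word_type,
        "step": step,
        "linked": bool(link.linked),
        "frac_correct": link.fraction,
        "frac_correct_primary": link.fraction_by_rank["primary"],
        "frac_correct_secondary": link.fraction_by_rank["secondary"],
        "frac_correct_hub": link.fraction_by_rank["hub"],
        "frac_incorrect_max": frac_incorrect_max,
    }
    for a in area_names:
        row[f"cells_{a}"] = ca.count(a)
    return row


def linking_rate(curves: pd.DataFrame, step: int) -> tuple[float, float]:
    """Mean percentage of linked words per network at ``step``, and its SE."""
    sub = curves[curves["step"] == step]
    if sub.empty:
        raise ValueError(f"no rows at step {step}")
    per_net = sub.groupby("network")["linked"].mean() * 100.0
    mean = float(per_net.mean())
    se = float(per_net.std(ddof=1) / np.sqrt(len(per_net))) if len(per_net) > 1 else 0.0
    return mean, se


def category_specificity(curves: pd.DataFrame, area: str, step: int | None = None) -> float:
    """Mean cell-count difference between the area's preferred and non-preferred
    word type (positive = the category-preferred word type dominates).

    Visual areas (V1/TO/AT): object minus action counts; motor areas
    (M1_L/PM_L/PF_L): action minus object counts.  Averaged over networks
    (and over steps when ``step`` is None).
    """
    if area in OBJECT_AREAS:
        preferred = "object"
    elif area in ACTION_AREAS:
        preferred = "action"
    else:
        raise ValueError(f"{area!r} is not an extrasylvian area")
    sub = curves if step is None else curves[curves["step"] == step]
    col = f"cells_{area}"
    per_net = sub.groupby(["network", "word_type"])[col].mean().unstack("word_type")
    other = "action" if preferred == "object" else "object"
    return float((per_net[preferred] - per_net[other]).mean())


def export_tidy_results(
    curves: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> Path:
    """Write the tidy per-probe table to CSV (with a small JSON sidecar)."""
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curves.to_csv(path, index=False)
    meta = {"schema_version": CURVE_SCHEMA_VERSION, "n_rows": int(len(curves))}
    meta.update(metadata or {})
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return path
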