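"""Chemical-defense scoring and grouping of species.

Antifeedant and toxicity assays yield, per extract, an unpalatability
index (1 - normalized ED50, the dose eliciting 50% feeding rejection)
and a toxicity index (1 - normalized LD50, the dose killing 50% of
assay organisms), both on [0, 1] with 1 = most defended. Species-level
indices average over whole-body extracts only; body-part extracts are
not comparable across species and are dropped.

Classification cut-offs: 0 -> palatable; up to 0.25 -> weakly
unpalatable; between 0.25 and 0.74 -> medium; 0.74 and higher -> highly
unpalatable (0.74 being the median unpalatability among defended
species in the motivating dataset). The three analysis groups combine
unpalatability class with presence of toxicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DefenseRecord",
    "score_species",
    "classify",
    "assign_group",
    "score_assay_table",
    "DEFENSE_CLASSES",
    "ANALYSIS_GROUPS",
]

DEFENSE_CLASSES = (
    "palatable",
    "weakly_unpalatable",
    "medium_unpalatable",
    "highly_unpalatable",
)
ANALYSIS_GROUPS = ("undefended", "toxic_moderate", "toxic_high")


@dataclass
class DefenseRecord:
    """Per-species defense summary used by the group models."""

    species: str
    unpalatability_index: float
    toxicity_index: float
    n_extracts: int
    defense_class: str | None = None
    analysis_group: str | None = None

    @property
    def missing(self) -> bool:
        return self.n_extracts == 0


def classify(
    index: float, weak_cutoff: float = 0.25, high_cutoff: float = 0.74
) -> str:
    """Map an unpalatability index to its defense class.

    0 -> palatable; (0, weak_cutoff] -> weakly unpalatable (boundary
    inclusive-low); (weak_cutoff, high_cutoff) -> medium; >= high_cutoff
    -> highly unpalatable. Cut-offs are configurable.
    """
    if not 0.0 <= index <= 1.0 or not np.isfinite(index):
        raise ValueError(f"index must lie in [0, 1], got {index}")
    if index == 0:
        return "palatable"
    if index <= weak_cutoff:
        return "weakly_unpalatable"
    if index < high_cutoff:
        return "medium_unpalatable"
    return "highly_unpalatable"


def score_species(assays: pd.DataFrame, species: str | None = None) -> DefenseRecord:
    """Average whole-body extract indices into one record per species.

    ``assays`` needs columns species, extract_id, extract_type,
    unpalatability_index, toxicity_index. Multiple whole-body extracts
    are averaged; other extract types are dropped. A species with no
    usable rows is returned as a missing record (indices NaN), never as
    zero — absence of assay data is not evidence of palatability.
    """
    df = assays
    if species is not None:
        df = df[df["species"] == species]
    elif df["species"].nunique() > 1:
        raise ValueError("assay table holds several species; pass `species`")
    name = species if species is not None else str(df["species"].iloc[0])
    usable = df[df["extract_type"] == "whole_body"]
    if usable.empty:
        return DefenseRecord(name, np.nan, np.nan, 0)
    rec = DefenseRecord(
        species=name,
        unpalatability_index=float(usable["unpalatability_index"].mean()),
        toxicity_index=float(usable["toxicity_index"].mean()),
        n_extracts=len(usable),
    )
    rec.defense_class = classify(rec.unpalatability_index)
    rec.analysis_group = assign_group(rec)
    return rec


def assign_group(record: DefenseRecord) -> str:
    """Combine unpalatability class and toxicity into an analysis group.

    undefended: palatable and no toxicity; toxic_moderate: some
    toxicity with weak/medium unpalatability; toxic_high: some toxicity
    with high unpalatability. Other combinations (e.g. unpalatable but
    non-toxic) have no defined group and raise for manual assignment.
    """
    if record.defense_class is None:
        record.defense_class = classify(record.unpalatability_index)
    cls, tox = record.defense_class, record.toxicity_index
    if cls == "palatable" and tox == 0:
        return "undefended"
    if tox > 0 and cls in ("weakly_unpalatable", "medium_unpalatable"):
        return "toxic_moderate"
    if tox > 0 and cls == "highly_unpalatable":
        return "toxic_high"
    raise ValueError(
        f"{record.species}: class {cls!r} with toxicity {tox} has no "
        "defined analysis group; assign manually"
    )


def score_assay_table(assays: pd.DataFrame) -> pd.DataFrame:
    """Score every species in an assay table.

    Returns one row per species with indices, defense_class and
    analysis_group; species without usable extracts appear with NaN
    indices and empty class/group.
    """
    rows = []
    for sp in assays["species"].unique():
        rec = score_species(assays, sp)
        rows.append(
            {
                "species": rec.species,
                "unpalatability_index": rec.unpalatability_index,
                "toxicity_index": rec.toxicity_index,
                "n_extracts": rec.n_extracts,
                "defense_class": rec.defense_class or "",
                "analysis_group": rec.analysis_group or "",
            }
        )
    return pd.DataFrame(rows)
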