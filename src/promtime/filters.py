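"""Confidence-tiered selection of activity records.

Two record tiers are supported.  The high-confidence tier keeps direct
interactions (assay relationship type ``"D"``) with human single-protein
targets at assay confidence score 9, measured as an exact (relation ``"="``)
Ki or IC50 value, with no inactivity flag in the activity comment.  The
low-confidence tier keeps every record against a human single-protein
target regardless of confidence score, measurement type, relation or
comment.  The high rules strictly strengthen the low rules, so the high
output is always a record subset of the low output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from promtime.records import Dataset

#: Comment phrases that flag a record as an inactivity report (matched
#: case-insensitively as containment in the trimmed comment).
INACTIVITY_PHRASES = ("inactive", "inconclusive", "not active")

HIGH_TIER_PREDICATES = (
    "relationship_type_D",
    "confidence_score_9",
    "single_protein_target",
    "human_organism",
    "ki_or_ic50",
    "exact_relation",
    "value_present",
    "comment_clean",
)

LOW_TIER_PREDICATES = ("single_protein_target", "human_organism")


@dataclass(frozen=True)
class FilterReport:
    """Entity tallies over a filtered record set (the audit-table shape)."""

    label: str
    n_compounds: int
    n_targets: int
    n_assays: int
    n_activities: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [self.label],
                "n_compounds": [self.n_compounds],
                "n_targets": [self.n_targets],
                "n_assays": [self.n_assays],
                "n_activities": [self.n_activities],
            }
        )


def _predicate_masks(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    comment = frame["activity_comment"].str.strip().str.lower()
    flagged = np.zeros(len(frame), dtype=bool)
    for phrase in INACTIVITY_PHRASES:
        flagged |= comment.str.contains(phrase, regex=False).to_numpy()
    return {
        "relationship_type_D": (frame["relationship_type"] == "D").to_numpy(),
        "confidence_score_9": frame["confidence_score"].eq(9).fillna(False).to_numpy(dtype=bool),
        "single_protein_target": (frame["target_type"] == "SINGLE PROTEIN").to_numpy(),
        "human_organism": (frame["organism"] == "Homo sapiens").to_numpy(),
        "ki_or_ic50": frame["measurement_type"].isin(["Ki", "IC50"]).to_numpy(),
        "exact_relation": (frame["measurement_relation"] == "=").to_numpy(),
        "value_present": frame["measurement_value"].notna().to_numpy(),
        "comment_clean": ~flagged,
    }


def _apply(dataset: Dataset, predicates: tuple[str, ...], label: str) -> Dataset:
    masks = _predicate_masks(dataset.frame)
    keep = np.ones(len(dataset.frame), dtype=bool)
    for name in predicates:
        keep &= masks[name]
    return dataset.subset(keep, provenance=f"{dataset.provenance}|{label}")


def apply_high_confidence(dataset: Dataset) -> Dataset:
    """Records passing all high-confidence predicates.

    A record is kept iff it is a direct (type "D") assay at confidence
    score 9 against a human single-protein target, with an exactly defined
    (relation "=", value present) Ki or IC50 measurement and no inactivity
    phrase in its comment.  Filtering is per record: a compound enters the
    high-confidence set through its conforming records even if other records
    of the same compound are dropped.
    """
    return _apply(dataset, HIGH_TIER_PREDICATES, "high")


def apply_low_confidence(dataset: Dataset) -> Dataset:
    """Records against human single-protein targets, with no further predicate."""
    return _apply(dataset, LOW_TIER_PREDICATES, "low")


def apply_tier(dataset: Dataset, tier: str) -> Dataset:
    """Dispatch on tier name: ``"high"`` or ``"low"``."""
    if tier == "high":
        return apply_high_confidence(dataset)
    if tier == "low":
        return apply_low_confidence(dataset)
    raise ValueError(f"unknown tier {tier!r}; expected 'high' or 'low'")


def explain_exclusions(dataset: Dataset, tier: str = "high") -> pd.DataFrame:
    """Per excluded record, the named predicates it failed.

    Returns a frame with one row per excluded record: compound_id,
    target_id, assay_id and a comma-joined ``failed_predicates`` column.
    Every excluded record fails at least one named predicate.
    """
    predicates = HIGH_TIER_PREDICATES if tier == "high" else LOW_TIER_PREDICATES
    masks = _predicate_masks(dataset.frame)
    failed = pd.DataFrame({name: ~masks[name] for name in predicates})
    excluded = failed.any(axis=1)
    joined = failed.loc[excluded].apply(
        lambda row: ",".join(name for name in predicates if row[name]), axis=1
    )
    out = dataset.frame.loc[excluded, ["compound_id", "target_id", "assay_id"]].copy()
    out["failed_predicates"] = joined
    return out.reset_index(drop=True)


def filter_report(dataset: Dataset, label: str) -> FilterReport:
    """Distinct-entity tallies over a (typically filtered) record set."""
    f = dataset.frame
    return FilterReport(
        label=label,
        n_compounds=int(f["compound_id"].nunique()),
        n_targets=int(f["target_id"].nunique()),
        n_assays=int(f["assay_id"].nunique()),
        n_activities=len(f),
    )
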