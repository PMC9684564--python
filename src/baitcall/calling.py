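"""Candidate-interactor calling for bait pulldowns with isotype controls.

The classification is a presence/absence rule set applied per condition
(cell line):

1. keep protein groups with q-value strictly below ``q_max`` (default 0.01);
2. drop decoy (reverse) hits and common contaminants;
3. binarize detection: a group is present in a sample iff its intensity is
   strictly positive;
4. a group is a candidate interactor of the bait in a condition iff it is
   present in every bait replicate of that condition (or at least
   ``min_bait_replicates`` of them) and not detected in the condition's
   isotype-control samples under the configured control rule.

Control subtraction is per-condition, never pooled.  The default control
rule discards a group detected in *any* control replicate; the stricter
"all control replicates" variant is selectable.  The bait itself is subject
to the same rules, with no special-casing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Literal, Union

import pandas as pd

from .io import ProteinGroupTable, Pulldown, SampleDesign

__all__ = [
    "ControlRule",
    "PresenceRule",
    "CallingParams",
    "DetectionMatrix",
    "CandidateSets",
    "filter_quality",
    "strip_decoys_contaminants",
    "presence_matrix",
    "control_detected",
    "replicate_consistent",
    "call_candidates",
]

MinReps = Union[Literal["all"], int]


class ControlRule(enum.Enum):
    """Scope of isotype-control subtraction."""

    ANY_CONTROL_REPLICATE = "any"
    ALL_CONTROL_REPLICATES = "all"


class PresenceRule(enum.Enum):
    """How a detection event is defined from the quantitative columns."""

    INTENSITY_POSITIVE = "intensity_positive"


@dataclass(frozen=True)
class CallingParams:
    q_max: float = 0.01
    min_bait_replicates: MinReps = "all"
    control_rule: ControlRule = ControlRule.ANY_CONTROL_REPLICATE
    presence_rule: PresenceRule = PresenceRule.INTENSITY_POSITIVE

    def __post_init__(self) -> None:
        if not 0.0 < self.q_max <= 1.0:
            raise ValueError(f"q_max {self.q_max!r} outside (0, 1]")
        if self.min_bait_replicates != "all" and (
            not isinstance(self.min_bait_replicates, int)
            or self.min_bait_replicates < 1
        ):
            raise ValueError("min_bait_replicates must be 'all' or a positive integer")


@dataclass
class DetectionMatrix:
    """Boolean (protein group x sample) detection matrix."""

    frame: pd.DataFrame  # index: group ids, columns: design sample ids, dtype bool

    def present(self, group_id: str, sample_id: str) -> bool:
        return bool(self.frame.at[group_id, sample_id])

    @property
    def group_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class CandidateSets:
    """Per-condition candidate-interactor sets plus the parameters used."""

    sets: dict[str, frozenset[str]]
    provenance: CallingParams = field(default_factory=CallingParams)

    def __getitem__(self, condition: str) -> frozenset[str]:
        return self.sets[condition]

    @property
    def conditions(self) -> list[str]:
        return list(self.sets)


def filter_quality(table: ProteinGroupTable, q_max: float = 0.01) -> ProteinGroupTable:
    """Retain records with q-value strictly below ``q_max``; order preserved.

    The comparison is strict, so a record sitting exactly on the threshold is
    excluded.
    """
    if not 0.0 < q_max <= 1.0:
        raise ValueError(f"q_max {q_max!r} outside (0, 1]")
    return ProteinGroupTable(
        records=[r for r in table.records if r.q_value < q_max],
        sample_ids=list(table.sample_ids),
    )


def strip_decoys_contaminants(table: ProteinGroupTable) -> ProteinGroupTable:
    """Drop decoy (reverse) hits and flagged contaminants; order preserved."""
    return ProteinGroupTable(
        records=[
            r for r in table.records if not r.is_reverse and not r.is_contaminant
        ],
        sample_ids=list(table.sample_ids),
    )


def presence_matrix(
    table: ProteinGroupTable,
    design: SampleDesign,
    rule: PresenceRule = PresenceRule.INTENSITY_POSITIVE,
) -> DetectionMatrix:
    """Binarize the table over the design's samples: present iff intensity > 0."""
    if rule is not PresenceRule.INTENSITY_POSITIVE:  # pragma: no cover - single rule
        raise ValueError(f"unknown presence rule {rule!r}")
    missing = [s for s in design.sample_ids if s not in table.sample_ids]
    if missing:
        raise KeyError(f"design samples missing from table: {missing}")
    intensities = table.intensity_frame()
    return DetectionMatrix(frame=intensities[design.sample_ids] > 0)


def control_detected(
    matrix: DetectionMatrix,
    design: SampleDesign,
    condition: str,
    rule: ControlRule = ControlRule.ANY_CONTROL_REPLICATE,
) -> frozenset[str]:
    """Identifiers detected in the condition's isotype-control samples.

    Under ``ANY_CONTROL_REPLICATE`` a single detection in any control sample
    is enough; under ``ALL_CONTROL_REPLICATES`` the group must be detected in
    every control sample of the condition.
    """
    controls = design.samples(condition, Pulldown.CONTROL)
    if not controls:
        raise ValueError(f"condition {condition!r} has no control samples")
    sub = matrix.frame[controls]
    hits = sub.any(axis=1) if rule is ControlRule.ANY_CONTROL_REPLICATE else sub.all(axis=1)
    return frozenset(hits.index[hits])


def replicate_consistent(
    matrix: DetectionMatrix,
    design: SampleDesign,
    condition: str,
    min_reps: MinReps = "all",
) -> frozenset[str]:
    """Identifiers detected in enough bait replicates of the condition.

    ``min_reps="all"`` demands detection in every bait sample; an integer k
    demands detection in at least k of them.
    """
    baits = design.samples(condition, Pulldown.BAIT)
    if not baits:
        raise ValueError(f"condition {condition!r} has no bait samples")
    k = len(baits) if min_reps == "all" else int(min_reps)
    if k > len(baits):
        raise ValueError(
            f"min_reps={k} exceeds the {len(baits)} bait samples of {condition!r}"
        )
    counts = matrix.frame[baits].sum(axis=1)
    return frozenset(counts.index[counts >= k])


def call_candidates(
    table: ProteinGroupTable,
    design: SampleDesign,
    params: CallingParams | None = None,
) -> CandidateSets:
    """Run the full classification and return per-condition candidate sets.

    Quality and decoy/contaminant filters are applied *before* binarization,
    so a decoy detected in a control cannot mask a genuine protein.
    """
    params = params or CallingParams()
    filtered = strip_decoys_contaminants(filter_quality(table, params.q_max))
    matrix = presence_matrix(filtered, design, params.presence_rule)
    sets: dict[str, frozenset[str]] = {}
    for condition in design.conditions:
        consistent = replicate_consistent(
            matrix, design, condition, params.min_bait_replicates
        )
        in_controls = control_detected(matrix, design, condition, params.control_rule)
        sets[condition] = consistent - in_controls
    return CandidateSets(sets=sets, provenance=params)
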