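"""Synthetic AP-MS experiments with planted ground truth.

The generator emulates the study design the pipeline targets: several
conditions (cell lines), each with a bait IP and an IgG isotype control in
triplicate.  Planted protein classes:

* one bait, detected in every bait sample and never in controls;
* common true interactors, planted in the bait samples of every condition;
* group-specific true interactors (e.g. "cancer lines only"), planted in
  the bait samples of the group's conditions;
* nonspecific background ("sticky") binders, detected in bait and control
  samples alike, condition-agnostically;
* contaminants and decoys, carrying the corresponding flags and high
  q-values so the quality filters remove them.

Detection events are independent Bernoulli draws per sample, which makes
the all-of-n replicate rule's recall exactly ``p_det_true ** n`` -- the
closed form in :func:`expected_recall`.  Detected log2 intensities follow
mu + protein effect + sample effect + noise; protein effects are shared
across samples, so replicate correlations are high when sigma_protein
dominates sigma_noise (r ~= sigma_p^2 / (sigma_p^2 + sigma_noise^2)).
Undetected cells are written as intensity 0, matching the parser's
semantics, and every generated table round-trips through the reader with
zero row errors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np

from .calling import CandidateSets
from .compare import ComparisonResult, unique_to
from .io import (
    DesignEntry,
    ProteinGroupRecord,
    ProteinGroupTable,
    Pulldown,
    SampleDesign,
)

__all__ = [
    "SimParams",
    "TruthLabel",
    "SyntheticTruth",
    "RecoveryMetrics",
    "study_like_params",
    "noiseless_params",
    "generate_truth",
    "simulate_protein_groups",
    "simulate_experiment",
    "evaluate_recovery",
    "expected_recall",
]

#: condition groups of the default four-cell-line layout
_DEFAULT_CONDITIONS = ("hTERT-RPE1", "HeLa", "WHCO5", "KYSE30")
_DEFAULT_GROUPS = {"cancer": ("HeLa", "WHCO5", "KYSE30")}


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults mirror the four-cell-line triplicate design."""

    conditions: tuple[str, ...] = _DEFAULT_CONDITIONS
    n_replicates: int = 3
    n_common_interactors: int = 38
    n_unique_interactors: Mapping[str, int] = field(
        default_factory=lambda: {"cancer": 18}
    )
    condition_groups: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS)
    )
    n_background: int = 60
    n_contaminants: int = 5
    n_decoys: int = 5
    p_det_true: float = 0.9
    p_det_bg_bait: float = 0.6
    p_det_bg_ctrl: float = 0.9
    mu_log2: float = 25.0
    sigma_protein: float = 3.0
    sigma_sample: float = 0.25
    sigma_noise: float = 0.4
    sigma_noise_control: float = 1.2
    q_true_max: float = 0.005
    q_junk_min: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_det_true", "p_det_bg_bait", "p_det_bg_ctrl"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p!r} outside [0, 1]")
        for name in (
            "n_replicates",
            "n_common_interactors",
            "n_background",
            "n_contaminants",
            "n_decoys",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("sigma_protein", "sigma_sample", "sigma_noise", "sigma_noise_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.q_true_max <= 1.0 or not 0.0 <= self.q_junk_min <= 1.0:
            raise ValueError("q ranges must lie in (0, 1]")
        if len(self.conditions) < 1:
            raise ValueError("need at least one condition")
        for group, members in self.condition_groups.items():
            unknown = set(members) - set(self.conditions)
            if unknown:
                raise ValueError(f"group {group!r} names unknown conditions {unknown}")
        for group in self.n_unique_interactors:
            if group not in self.condition_groups:
                raise ValueError(f"n_unique_interactors names undefined group {group!r}")


def study_like_params(seed: int = 0, **overrides) -> SimParams:
    """The default preset: 1 normal + 3 cancer lines, triplicates, a planted
    common core of 38 and a cancer-unique set of 18."""
    return replace(SimParams(seed=seed), **overrides)


def noiseless_params(seed: int = 0, **overrides) -> SimParams:
    """Deterministic-detection preset: every planted interactor is seen in
    every bait replicate and every background binder in every sample, so the
    caller must recover the planted classes exactly."""
    base = SimParams(
        seed=seed,
        p_det_true=1.0,
        p_det_bg_bait=1.0,
        p_det_bg_ctrl=1.0,
    )
    return replace(base, **overrides)


class TruthLabel(enum.Enum):
    BAIT = "bait"
    TRUE_COMMON = "true_common"
    TRUE_GROUP = "true_group"
    BACKGROUND = "background"
    CONTAMINANT = "contaminant"
    DECOY = "decoy"


@dataclass
class SyntheticTruth:
    """Planted class labels; ``group_of`` maps group-specific interactors to
    their group and ``group_membership`` maps groups to condition tuples."""

    label: dict[str, TruthLabel]
    group_of: dict[str, str]
    group_membership: dict[str, tuple[str, ...]]
    bait_id: str

    def ids_with(self, label: TruthLabel) -> frozenset[str]:
        return frozenset(i for i, l in self.label.items() if l is label)

    def true_interactors(self, condition: str) -> frozenset[str]:
        """Planted positives for one condition: bait, common, and the
        group-specific interactors of every group containing the condition."""
        out = {self.bait_id} | set(self.ids_with(TruthLabel.TRUE_COMMON))
        for identifier, group in self.group_of.items():
            if condition in self.group_membership[group]:
                out.add(identifier)
        return frozenset(out)


def generate_truth(params: SimParams) -> SyntheticTruth:
    """Assign planted labels; deterministic for fixed params (no RNG needed)."""
    label: dict[str, TruthLabel] = {}
    group_of: dict[str, str] = {}
    bait_id = "BAIT00001"
    label[bait_id] = TruthLabel.BAIT
    for i in range(params.n_common_interactors):
        label[f"COM{i + 1:05d}"] = TruthLabel.TRUE_COMMON
    for group in sorted(params.n_unique_interactors):
        for i in range(params.n_unique_interactors[group]):
            identifier = f"GRP{group.upper()}{i + 1:05d}"
            label[identifier] = TruthLabel.TRUE_GROUP
            group_of[identifier] = group
    for i in range(params.n_background):
        label[f"BKG{i + 1:05d}"] = TruthLabel.BACKGROUND
    for i in range(params.n_contaminants):
        label[f"CON{i + 1:05d}"] = TruthLabel.CONTAMINANT
    for i in range(params.n_decoys):
        label[f"REV{i + 1:05d}"] = TruthLabel.DECOY
    return SyntheticTruth(
        label=label,
        group_of=group_of,
        group_membership={
            g: tuple(members) for g, members in params.condition_groups.items()
        },
        bait_id=bait_id,
    )


def _make_design(params: SimParams) -> SampleDesign:
    entries: dict[str, DesignEntry] = {}
    for condition in params.conditions:
        for r in range(1, params.n_replicates + 1):
            entries[f"{condition}_bait_{r}"] = DesignEntry(condition, Pulldown.BAIT, r)
        for r in range(1, params.n_replicates + 1):
            entries[f"{condition}_ctrl_{r}"] = DesignEntry(
                condition, Pulldown.CONTROL, r
            )
    return SampleDesign(entries=entries)


def _detection_probs(
    truth: SyntheticTruth, identifier: str, entry: DesignEntry, params: SimParams
) -> float:
    """Per-sample detection probability of one protein."""
    label = truth.label[identifier]
    bait_sample = entry.pulldown is Pulldown.BAIT
    if label is TruthLabel.BAIT:
        return 1.0 if bait_sample else 0.0
    if label is TruthLabel.TRUE_COMMON:
        return params.p_det_true if bait_sample else 0.0
    if label is TruthLabel.TRUE_GROUP:
        group = truth.group_of[identifier]
        in_group = entry.condition in truth.group_membership[group]
        return params.p_det_true if (bait_sample and in_group) else 0.0
    # background binders, contaminants and decoys are condition-agnostic
    return params.p_det_bg_bait if bait_sample else params.p_det_bg_ctrl


def simulate_protein_groups(
    truth: SyntheticTruth, params: SimParams
) -> tuple[ProteinGroupTable, SampleDesign]:
    """Draw one experiment: detection events, intensities, q-values, flags."""
    rng = np.random.default_rng(params.seed)
    design = _make_design(params)
    samples = design.sample_ids
    sample_effect = {s: rng.normal(0.0, params.sigma_sample) for s in samples}

    records: list[ProteinGroupRecord] = []
    for identifier in truth.label:  # insertion order: stable across runs
        label = truth.label[identifier]
        protein_effect = rng.normal(0.0, params.sigma_protein)
        intensities: dict[str, float] = {}
        for sample in samples:
            entry = design.entries[sample]
            p = _detection_probs(truth, identifier, entry, params)
            detected = p > 0 and rng.random() < p
            if detected:
                # nonspecific carryover in the control IP is poorly
                # reproducible, hence the larger residual there
                noise_sd = (
                    params.sigma_noise
                    if entry.pulldown is Pulldown.BAIT
                    else params.sigma_noise_control
                )
                log2_val = (
                    params.mu_log2
                    + protein_effect
                    + sample_effect[sample]
                    + rng.normal(0.0, noise_sd)
                )
                intensities[sample] = float(2.0 ** log2_val)
            else:
                intensities[sample] = 0.0
        junk = label in (TruthLabel.CONTAMINANT, TruthLabel.DECOY)
        if junk:
            q = float(rng.uniform(params.q_junk_min, 1.0))
        else:
            q = float(rng.uniform(0.0, params.q_true_max))
        records.append(
            ProteinGroupRecord(
                group_id=identifier,
                accessions=(identifier,),
                gene_name=f"G{identifier}",
                q_value=q,
                is_reverse=label is TruthLabel.DECOY,
                is_contaminant=label is TruthLabel.CONTAMINANT,
                intensities=intensities,
                molecular_weight_kda=float(rng.uniform(10.0, 300.0)),
            )
        )
    return ProteinGroupTable(records=records, sample_ids=list(samples)), design


def simulate_experiment(
    params: SimParams,
) -> tuple[ProteinGroupTable, SampleDesign, SyntheticTruth]:
    """Convenience wrapper: truth + one simulated experiment."""
    truth = generate_truth(params)
    table, design = simulate_protein_groups(truth, params)
    return table, design, truth


@dataclass
class RecoveryMetrics:
    """How well the calling pipeline recovered the planted truth."""

    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    common_core_recovery: float  # fraction of planted common interactors in common_all
    unique_set_recovery: dict[str, float]  # per group
    false_positives: dict[str, frozenset[str]]


def _safe_div(num: float, den: float, empty: float = 1.0) -> float:
    return num / den if den else empty


def evaluate_recovery(
    candidates: CandidateSets,
    comparison: Optional[ComparisonResult],
    truth: SyntheticTruth,
) -> RecoveryMetrics:
    """Precision/recall/F1 per condition plus core/unique-set recovery.

    ``comparison`` may be None when only per-condition metrics are wanted.
    An empty candidate set has precision 1 by convention (no false calls).
    Raises if a candidate identifier is outside the truth namespace.
    """
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    f1: dict[str, float] = {}
    false_positives: dict[str, frozenset[str]] = {}
    for condition, called in candidates.sets.items():
        unknown = called - set(truth.label)
        if unknown:
            raise ValueError(
                f"candidates outside the truth namespace in {condition!r}: "
                f"{sorted(unknown)[:5]}"
            )
        positives = truth.true_interactors(condition)
        tp = len(called & positives)
        precision[condition] = _safe_div(tp, len(called), empty=1.0)
        recall[condition] = _safe_div(tp, len(positives), empty=1.0)
        denom = precision[condition] + recall[condition]
        f1[condition] = _safe_div(
            2 * precision[condition] * recall[condition], denom, empty=0.0
        )
        false_positives[condition] = frozenset(called - positives)

    common = truth.ids_with(TruthLabel.TRUE_COMMON)
    common_recovery = 1.0
    unique_recovery: dict[str, float] = {}
    if comparison is not None:
        common_recovery = _safe_div(
            len(common & comparison.common_all), len(common), empty=1.0
        )
        for group, members in truth.group_membership.items():
            planted = frozenset(
                i for i, g in truth.group_of.items() if g == group
            )
            present_members = [m for m in members if m in comparison.sets]
            if planted and len(present_members) == len(members):
                recovered = unique_to(comparison.sets, list(members))
                unique_recovery[group] = len(planted & recovered) / len(planted)
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        common_core_recovery=common_recovery,
        unique_set_recovery=unique_recovery,
        false_positives=false_positives,
    )


def expected_recall(p_det: float, n_reps: int) -> float:
    """Closed-form recall of the all-replicates rule under independent
    per-replicate detection: ``p_det ** n_reps``."""
    if not 0.0 <= p_det <= 1.0:
        raise ValueError("p_det must be in [0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return float(p_det) ** int(n_reps)
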