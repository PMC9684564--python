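"""Replicate-concordance QC: log2 intensities and pairwise Pearson matrices.

Raw MS intensities are log2-transformed; zero intensities (not detected)
become missing values rather than receiving a pseudocount, and correlations
are computed over pairwise-complete observations.  Bait-IP replicates of
the same condition are expected to correlate highly (the study design this
emulates used r > 0.93 as its concordance narrative), while isotype-control
replicates -- dominated by sporadic nonspecific binders -- correlate less.
A pair sharing fewer than 3 proteins has no meaningful correlation and is
reported as undefined together with its count, never silently dropped.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import ProteinGroupTable, Pulldown, SampleDesign

__all__ = [
    "CorrelationMatrix",
    "PairFlag",
    "QCReport",
    "log2_intensity",
    "pearson_matrix",
    "qc_report",
]

MIN_SHARED = 3  # pairs sharing fewer proteins are undefined


def log2_intensity(table: ProteinGroupTable) -> pd.DataFrame:
    """log2 of strictly positive intensities; zeros become NaN (missing)."""
    frame = table.intensity_frame()
    return np.log2(frame.where(frame > 0))


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson matrix with per-pair observation counts.

    ``r`` is symmetric with unit diagonal where at least 2 observations
    exist; undefined cells (fewer than 3 shared proteins, or zero variance)
    are NaN and ``n_pairs`` still reports the shared-protein count.
    """

    sample_ids: list[str]
    r: pd.DataFrame
    n_pairs: pd.DataFrame
    policy: str = "pairwise_complete"

    def get(self, a: str, b: str) -> float:
        return float(self.r.at[a, b])

    def undefined_pairs(self) -> list[tuple[str, str, int]]:
        out = []
        for a, b in itertools.combinations(self.sample_ids, 2):
            if math.isnan(self.r.at[a, b]):
                out.append((a, b, int(self.n_pairs.at[a, b])))
        return out


def pearson_matrix(
    values: pd.DataFrame,
    design: Optional[SampleDesign] = None,
    policy: str = "pairwise_complete",
) -> CorrelationMatrix:
    """Pearson correlations between sample columns over shared proteins.

    ``values`` is a (protein x sample) frame with NaN for missing, as
    produced by :func:`log2_intensity`.  When a design is given, columns are
    restricted to its samples (in design order).
    """
    if policy != "pairwise_complete":
        raise ValueError(f"unknown missing-data policy {policy!r}")
    if design is not None:
        values = values[design.sample_ids]
    samples = list(values.columns)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    notna = values.notna()
    n_pairs = notna.T.astype(int).dot(notna.astype(int))
    r = values.corr(method="pearson", min_periods=MIN_SHARED)
    # unit diagonal only where a sample has >= 2 observations
    for s in samples:
        r.at[s, s] = 1.0 if int(n_pairs.at[s, s]) >= 2 else np.nan
    return CorrelationMatrix(sample_ids=samples, r=r, n_pairs=n_pairs, policy=policy)


@dataclass(frozen=True)
class PairFlag:
    condition: str
    sample_a: str
    sample_b: str
    r: float


@dataclass
class QCReport:
    """Replicate-concordance summary against a correlation threshold."""

    threshold: float
    min_bait_r: dict[str, float]  # per condition; NaN when undefined
    min_control_r: dict[str, float]
    flagged_bait_pairs: list[PairFlag]
    undefined_pairs: list[tuple[str, str, int]]
    policy: str
    passed: bool

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "policy": self.policy,
            "passed": self.passed,
            "min_bait_replicate_r": self.min_bait_r,
            "min_control_replicate_r": self.min_control_r,
            "flagged_bait_pairs": [
                {"condition": f.condition, "samples": [f.sample_a, f.sample_b], "r": f.r}
                for f in self.flagged_bait_pairs
            ],
            "undefined_pairs": [
                {"samples": [a, b], "n_shared": n} for a, b, n in self.undefined_pairs
            ],
        }


def _within_pairs(design: SampleDesign, condition: str, pulldown: Pulldown):
    return itertools.combinations(design.samples(condition, pulldown), 2)


def qc_report(
    matrix: CorrelationMatrix,
    design: SampleDesign,
    threshold: float = 0.93,
) -> QCReport:
    """Summarize within-condition replicate correlations.

    Reports, per condition, the minimum bait-replicate and control-replicate
    pairwise r, and flags every bait pair at or below ``threshold``
    (undefined pairs are listed separately, not flagged).
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [-1, 1]")
    min_bait: dict[str, float] = {}
    min_control: dict[str, float] = {}
    flagged: list[PairFlag] = []
    for condition in design.conditions:
        bait_rs = [
            matrix.get(a, b) for a, b in _within_pairs(design, condition, Pulldown.BAIT)
        ]
        ctrl_rs = [
            matrix.get(a, b)
            for a, b in _within_pairs(design, condition, Pulldown.CONTROL)
        ]
        defined_bait = [r for r in bait_rs if not math.isnan(r)]
        defined_ctrl = [r for r in ctrl_rs if not math.isnan(r)]
        min_bait[condition] = min(defined_bait) if defined_bait else float("nan")
        min_control[condition] = min(defined_ctrl) if defined_ctrl else float("nan")
        for a, b in _within_pairs(design, condition, Pulldown.BAIT):
            r = matrix.get(a, b)
            if not math.isnan(r) and r < threshold:
                flagged.append(PairFlag(condition=condition, sample_a=a, sample_b=b, r=r))
    return QCReport(
        threshold=threshold,
        min_bait_r=min_bait,
        min_control_r=min_control,
        flagged_bait_pairs=flagged,
        undefined_pairs=matrix.undefined_pairs(),
        policy=matrix.policy,
        passed=not flagged,
    )
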