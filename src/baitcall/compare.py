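"""Set algebra across conditions: Venn regions, common cores, unique sets.

Given per-condition candidate sets, each identifier is assigned its exact
membership signature (the subset of conditions that called it), which
partitions the union into 2**n - 1 Venn regions.  The common core is the
region covering every condition; a group-unique set (e.g. "called in all
cancer lines but no normal line") is the intersection of a group of
conditions minus the union of the rest.  Reference-interactome comparisons
are plain overlap statistics on identifier sets.

Bait handling: by default the bait identifier is a member like any other
and is included in every count; use ``drop_bait`` to remove it everywhere.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .calling import CandidateSets

__all__ = [
    "ComparisonResult",
    "OverlapStats",
    "ConsistencyReport",
    "compare_conditions",
    "unique_to",
    "consistency_check",
    "overlap_stats",
    "venn_export",
    "drop_bait",
]

SetsLike = Union[CandidateSets, Mapping[str, Iterable[str]]]


def _as_mapping(sets: SetsLike) -> dict[str, frozenset[str]]:
    mapping = sets.sets if isinstance(sets, CandidateSets) else sets
    return {label: frozenset(members) for label, members in mapping.items()}


@dataclass
class ComparisonResult:
    """Exact-membership partition of the union of condition sets.

    ``region_counts`` has one entry per non-empty condition subset (all
    2**n - 1 of them, zero counts included, for a deterministic output
    shape); ``common_all`` is the full-signature region; ``unique_by_group``
    holds each single condition's exclusive region.
    """

    labels: tuple[str, ...]
    sets: dict[str, frozenset[str]]
    membership: dict[str, frozenset[str]]
    region_counts: dict[frozenset[str], int]
    common_all: frozenset[str]
    unique_by_group: dict[str, frozenset[str]]

    def region_members(self, signature: Iterable[str]) -> frozenset[str]:
        sig = frozenset(signature)
        return frozenset(
            i for i, member_of in self.membership.items() if member_of == sig
        )


def compare_conditions(sets: SetsLike) -> ComparisonResult:
    """Partition the union of >=2 condition sets by membership signature."""
    mapping = _as_mapping(sets)
    if len(mapping) < 2:
        raise ValueError("need at least 2 condition sets to compare")
    labels = tuple(mapping)
    union = frozenset().union(*mapping.values())
    membership = {
        identifier: frozenset(l for l in labels if identifier in mapping[l])
        for identifier in union
    }
    region_counts: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            region_counts[frozenset(combo)] = 0
    for signature in membership.values():
        region_counts[signature] += 1
    common_all = frozenset(
        i for i, signature in membership.items() if len(signature) == len(labels)
    )
    unique_by_group = {
        label: frozenset(
            i for i, signature in membership.items() if signature == frozenset({label})
        )
        for label in labels
    }
    return ComparisonResult(
        labels=labels,
        sets=mapping,
        membership=membership,
        region_counts=region_counts,
        common_all=common_all,
        unique_by_group=unique_by_group,
    )


def unique_to(sets: SetsLike, group: Sequence[str]) -> frozenset[str]:
    """Identifiers in every set of ``group`` and in no set outside it.

    With ``group`` equal to all conditions this degenerates to the common
    core (the complement union is empty).
    """
    mapping = _as_mapping(sets)
    if not group:
        raise ValueError("group must be non-empty")
    unknown = [label for label in group if label not in mapping]
    if unknown:
        raise KeyError(f"unknown condition labels: {unknown}")
    core = frozenset.intersection(*(mapping[label] for label in group))
    rest = [mapping[label] for label in mapping if label not in set(group)]
    if rest:
        core -= frozenset().union(*rest)
    return core


@dataclass
class ConsistencyReport:
    """Outcome of the group-core = common-all + group-unique identity check."""

    passed: bool
    group: tuple[str, ...]
    n_group_core: int
    n_common_all: int
    n_unique: int
    discrepancies: frozenset[str]


def consistency_check(result: ComparisonResult, group: Sequence[str]) -> ConsistencyReport:
    """Verify intersection(group) = common_all | unique_to(group), disjointly.

    The identity is exact when the complement of ``group`` is a single
    condition (every member of the group core is then either in all
    conditions or in none outside the group); the check reports the
    discrepancy set otherwise.
    """
    core = frozenset.intersection(*(result.sets[label] for label in group))
    unique = unique_to(result.sets, group)
    expected = result.common_all | unique
    disjoint = not (result.common_all & unique) or set(group) == set(result.labels)
    return ConsistencyReport(
        passed=(core == expected) and disjoint,
        group=tuple(group),
        n_group_core=len(core),
        n_common_all=len(result.common_all),
        n_unique=len(unique),
        discrepancies=core ^ expected,
    )


@dataclass
class OverlapStats:
    """Overlap of a query set against a reference list.

    Percentages are on the 0-100 scale; ``degenerate`` flags an empty side
    (percentages and Jaccard then report 0 rather than raising).
    """

    count: int
    pct_of_query: float
    pct_of_reference: float
    jaccard: float
    n_query: int
    n_reference: int
    degenerate: bool = False


def overlap_stats(query: Iterable[str], reference: Iterable[str]) -> OverlapStats:
    q, r = frozenset(query), frozenset(reference)
    inter = q & r
    union = q | r
    degenerate = not q or not r
    return OverlapStats(
        count=len(inter),
        pct_of_query=100.0 * len(inter) / len(q) if q else 0.0,
        pct_of_reference=100.0 * len(inter) / len(r) if r else 0.0,
        jaccard=len(inter) / len(union) if union else 0.0,
        n_query=len(q),
        n_reference=len(r),
        degenerate=degenerate,
    )


def drop_bait(sets: SetsLike, bait_id: str) -> dict[str, frozenset[str]]:
    """Remove the bait identifier from every condition set."""
    return {
        label: members - {bait_id} for label, members in _as_mapping(sets).items()
    }


def _region_rows(result: ComparisonResult) -> pd.DataFrame:
    rows = []
    for r in range(1, len(result.labels) + 1):
        for combo in itertools.combinations(result.labels, r):
            signature = frozenset(combo)
            rows.append(
                {
                    "conditions": "&".join(combo),
                    "n_conditions": r,
                    "count": result.region_counts[signature],
                }
            )
    return pd.DataFrame(rows, columns=["conditions", "n_conditions", "count"])


def venn_export(
    result: ComparisonResult,
    path: str | Path,
    figure_path: str | Path | None = None,
) -> None:
    """Write the region counts as TSV and optionally a Venn figure.

    The TSV always contains all 2**n - 1 regions, zero counts included.
    A figure is drawn for 2 or 3 condition sets; beyond that only the
    counts table is written and a warning is emitted.
    """
    _region_rows(result).to_csv(path, sep="\t", index=False)
    if figure_path is None:
        return
    if len(result.labels) > 3:
        warnings.warn(
            f"Venn figure supports 2-3 sets, got {len(result.labels)}; "
            "wrote region counts only",
            stacklevel=2,
        )
        return
    _draw_venn(result, figure_path)


def _draw_venn(result: ComparisonResult, figure_path: str | Path) -> None:
    # Counts-annotated circle diagram for 2 or 3 sets; positions are the
    # classic symmetric layout.
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    labels = result.labels
    if len(labels) == 2:
        centers = {labels[0]: (-0.5, 0.0), labels[1]: (0.5, 0.0)}
    else:
        centers = {
            labels[0]: (-0.5, -0.29),
            labels[1]: (0.5, -0.29),
            labels[2]: (0.0, 0.58),
        }
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, (x, y) in centers.items():
        ax.add_patch(Circle((x, y), 1.0, fill=False, lw=1.5))
        ax.annotate(label, (x, y + 1.08), ha="center", fontsize=10)
    for signature, count in result.region_counts.items():
        inside = [centers[l] for l in signature]
        outside = [centers[l] for l in labels if l not in signature]
        x = sum(p[0] for p in inside) / len(inside)
        y = sum(p[1] for p in inside) / len(inside)
        # nudge exclusive regions away from the shared middle
        if outside:
            ox = sum(p[0] for p in outside) / len(outside)
            oy = sum(p[1] for p in outside) / len(outside)
            x += 0.55 * (x - ox)
            y += 0.55 * (y - oy)
        ax.annotate(str(count), (x, y), ha="center", va="center", fontsize=11)
    ax.set_xlim(-2.4, 2.4)
    ax.set_ylim(-2.4, 2.4)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(figure_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
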