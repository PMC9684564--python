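"""Shared fixtures: tiny hand-built tables and designs."""

from __future__ import annotations

import pytest

from baitcall.io import (
    DesignEntry,
    ProteinGroupRecord,
    ProteinGroupTable,
    Pulldown,
    SampleDesign,
)


def make_record(
    gid: str,
    intensities: dict[str, float],
    q: float = 0.001,
    reverse: bool = False,
    contaminant: bool = False,
    gene: str | None = None,
    mw: float | None = None,
    accessions: tuple[str, ...] | None = None,
) -> ProteinGroupRecord:
    return ProteinGroupRecord(
        group_id=gid,
        accessions=accessions or (gid,),
        gene_name=gene or f"G{gid}",
        q_value=q,
        is_reverse=reverse,
        is_contaminant=contaminant,
        intensities=intensities,
        molecular_weight_kda=mw,
    )


def make_design(conditions: list[str], n_bait: int = 3, n_ctrl: int = 3) -> SampleDesign:
    entries: dict[str, DesignEntry] = {}
    for c in conditions:
        for r in range(1, n_bait + 1):
            entries[f"{c}_bait_{r}"] = DesignEntry(c, Pulldown.BAIT, r)
        for r in range(1, n_ctrl + 1):
            entries[f"{c}_ctrl_{r}"] = DesignEntry(c, Pulldown.CONTROL, r)
    return SampleDesign(entries=entries)


@pytest.fixture
def one_condition_design() -> SampleDesign:
    return make_design(["A"])


@pytest.fixture
def two_condition_design() -> SampleDesign:
    return make_design(["A", "B"])


def table_from_presence(
    presence: dict[str, dict[str, bool]],
    design: SampleDesign,
    intensity: float = 1e7,
    **record_kwargs,
) -> ProteinGroupTable:
    """Build a table whose detections follow the given truth map."""
    records = []
    for gid, row in presence.items():
        intensities = {
            s: (intensity if row.get(s, False) else 0.0) for s in design.sample_ids
        }
        records.append(make_record(gid, intensities, **record_kwargs))
    return ProteinGroupTable(records=records, sample_ids=design.sample_ids)
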