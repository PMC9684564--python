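"""Readers and writers for the tabular formats an AP-MS analysis touches.

The central input is a MaxQuant-style ``proteinGroups`` table: one row per
protein group (a set of accessions indistinguishable by the identified
peptides) with a q-value, decoy/contaminant flags and one raw-intensity
column per sample.  An intensity of 0 means the group was not detected in
that sample.  Alongside it the pipeline consumes a small experimental-design
table (sample -> condition / pulldown type / replicate), GMT annotation
files for enrichment, and plain one-identifier-per-line reference lists.

Cross-table protein identity is the *leading* accession of the group; the
gene name is carried as a reported attribute and falls back to the leading
accession when the cell is empty.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "RowError",
    "Pulldown",
    "GoCategory",
    "MaxQuantDialect",
    "ProteinGroupRecord",
    "ProteinGroupTable",
    "DesignEntry",
    "SampleDesign",
    "AnnotationTerm",
    "AnnotationMap",
    "read_protein_groups",
    "write_protein_groups",
    "read_design",
    "write_design",
    "read_gmt",
    "read_id_list",
    "write_id_list",
    "read_alias_map",
    "write_candidate_table",
    "read_candidate_table",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class RowError(FormatError):
    """A single row could not be parsed; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class Pulldown(enum.Enum):
    """Type of a pulldown sample: the bait IP or the isotype (IgG) control."""

    BAIT = "bait"
    CONTROL = "control"


class GoCategory(enum.Enum):
    BIOLOGICAL_PROCESS = "biological_process"
    CELLULAR_COMPONENT = "cellular_component"
    MOLECULAR_FUNCTION = "molecular_function"
    OTHER = "other"


@dataclass(frozen=True)
class MaxQuantDialect:
    """Column naming of the protein-group table.

    Defaults match MaxQuant 1.5.x output; every name is overridable so the
    reader stays search-engine agnostic.  Flag cells equal to ``+`` are true,
    empty cells false.  Intensity columns are discovered by prefix; the text
    after the prefix is the sample identifier.
    """

    accession_col: str = "Majority protein IDs"
    gene_col: str = "Gene names"
    qvalue_col: str = "Q-value"
    reverse_col: str = "Reverse"
    contaminant_col: str = "Potential contaminant"
    intensity_prefix: str = "Intensity "
    mw_col: str = "Mol. weight [kDa]"  # optional; parsed when present


DEFAULT_DIALECT = MaxQuantDialect()


@dataclass(frozen=True)
class ProteinGroupRecord:
    """One identified protein group.

    ``group_id`` is the leading (majority) accession and is the identifier
    used for all cross-table matching.  ``intensities`` maps sample id to a
    non-negative raw intensity; 0 means not detected in that sample.
    """

    group_id: str
    accessions: tuple[str, ...]
    gene_name: str
    q_value: float
    is_reverse: bool
    is_contaminant: bool
    intensities: Mapping[str, float]
    molecular_weight_kda: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("accessions must be non-empty")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value {self.q_value!r} outside [0, 1]")
        for sample, value in self.intensities.items():
            if value < 0:
                raise ValueError(f"negative intensity {value!r} in sample {sample!r}")
        if self.molecular_weight_kda is not None and self.molecular_weight_kda <= 0:
            raise ValueError("molecular_weight_kda must be > 0")

    def intensity(self, sample_id: str) -> float:
        return float(self.intensities.get(sample_id, 0.0))


@dataclass
class ProteinGroupTable:
    """An ordered collection of protein-group records plus the sample roster.

    ``sample_ids`` preserves the column order of the source file; every
    intensity key of every record must appear in it and group ids are unique.
    """

    records: list[ProteinGroupRecord]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        known = set(self.sample_ids)
        seen: set[str] = set()
        for rec in self.records:
            if rec.group_id in seen:
                raise ValueError(f"duplicate group_id {rec.group_id!r}")
            seen.add(rec.group_id)
            extra = set(rec.intensities) - known
            if extra:
                raise ValueError(
                    f"record {rec.group_id!r} has intensities for unknown samples {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinGroupRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [rec.group_id for rec in self.records]

    def get(self, group_id: str) -> ProteinGroupRecord:
        for rec in self.records:
            if rec.group_id == group_id:
                return rec
        raise KeyError(group_id)

    def intensity_frame(self) -> pd.DataFrame:
        """Raw intensities as a (group x sample) DataFrame, zeros for absences."""
        data = {
            rec.group_id: [rec.intensity(s) for s in self.sample_ids]
            for rec in self.records
        }
        return pd.DataFrame(data, index=list(self.sample_ids)).T


@dataclass(frozen=True)
class DesignEntry:
    condition: str
    pulldown: Pulldown
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be a positive integer")


@dataclass
class SampleDesign:
    """Maps sample identifiers to (condition, pulldown type, replicate).

    Replicate indices must be distinct within a (condition, pulldown) pair
    and every condition needs at least one bait sample.
    """

    entries: dict[str, DesignEntry]

    def __post_init__(self) -> None:
        seen: set[tuple[str, Pulldown, int]] = set()
        for sample, entry in self.entries.items():
            key = (entry.condition, entry.pulldown, entry.replicate)
            if key in seen:
                raise ValueError(
                    f"duplicate replicate index {entry.replicate} for "
                    f"({entry.condition!r}, {entry.pulldown.value}) at sample {sample!r}"
                )
            seen.add(key)
        for condition in self.conditions:
            if not self.samples(condition, Pulldown.BAIT):
                raise ValueError(f"condition {condition!r} has no bait sample")

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        out: list[str] = []
        for entry in self.entries.values():
            if entry.condition not in out:
                out.append(entry.condition)
        return out

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries)

    def samples(
        self,
        condition: Optional[str] = None,
        pulldown: Optional[Pulldown] = None,
    ) -> list[str]:
        return [
            s
            for s, e in self.entries.items()
            if (condition is None or e.condition == condition)
            and (pulldown is None or e.pulldown == pulldown)
        ]


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    name: str
    category: GoCategory
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")


@dataclass
class AnnotationMap:
    """term_id -> (name, ontology category, member gene set)."""

    terms: dict[str, AnnotationTerm]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[AnnotationTerm]:
        return iter(self.terms.values())

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for term in self.terms.values():
            out |= term.members
        return frozenset(out)


# ---------------------------------------------------------------------------
# protein-group table


def _parse_flag(cell: str, column: str, row: int) -> bool:
    cell = cell.strip()
    if cell == "+":
        return True
    if cell == "":
        return False
    raise RowError(row, f"unexpected value {cell!r} in flag column {column!r}")


def read_protein_groups(
    path: str | Path,
    dialect: MaxQuantDialect = DEFAULT_DIALECT,
) -> ProteinGroupTable:
    """Parse a tab-delimited protein-group table.

    Semicolon-delimited accession cells are split in order; blank intensity
    cells map to 0; sample identifiers are the intensity column suffixes, in
    file column order.  Raises :class:`FormatError` for a missing mandatory
    column or empty file and :class:`RowError` (with the 0-based data-row
    index) for unparseable cells.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    for col in (
        dialect.accession_col,
        dialect.gene_col,
        dialect.qvalue_col,
        dialect.reverse_col,
        dialect.contaminant_col,
    ):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    intensity_cols = [
        c for c in df.columns if c.startswith(dialect.intensity_prefix)
    ]
    if not intensity_cols:
        raise FormatError(
            f"{path}: no intensity columns with prefix {dialect.intensity_prefix!r}"
        )
    sample_ids = [c[len(dialect.intensity_prefix):] for c in intensity_cols]
    has_mw = dialect.mw_col in df.columns

    records: list[ProteinGroupRecord] = []
    seen_ids: set[str] = set()
    for row_idx, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        accessions = tuple(
            a.strip() for a in row[dialect.accession_col].split(";") if a.strip()
        )
        if not accessions:
            raise RowError(row_idx, "empty accession cell")
        group_id = accessions[0]
        if group_id in seen_ids:
            raise FormatError(
                f"{path}: duplicate leading accession {group_id!r} (row {row_idx})"
            )
        seen_ids.add(group_id)
        try:
            q_value = float(row[dialect.qvalue_col])
        except ValueError:
            raise RowError(
                row_idx, f"non-numeric q-value {row[dialect.qvalue_col]!r}"
            ) from None
        if not 0.0 <= q_value <= 1.0:
            raise RowError(row_idx, f"q-value {q_value} outside [0, 1]")
        intensities: dict[str, float] = {}
        for col, sample in zip(intensity_cols, sample_ids):
            cell = row[col].strip()
            if cell == "":
                intensities[sample] = 0.0
                continue
            try:
                value = float(cell)
            except ValueError:
                raise RowError(
                    row_idx, f"non-numeric intensity {cell!r} in column {col!r}"
                ) from None
            if value < 0:
                raise RowError(row_idx, f"negative intensity in column {col!r}")
            intensities[sample] = value
        mw: Optional[float] = None
        if has_mw and row[dialect.mw_col].strip():
            try:
                mw = float(row[dialect.mw_col])
            except ValueError:
                raise RowError(
                    row_idx, f"non-numeric molecular weight {row[dialect.mw_col]!r}"
                ) from None
        gene = row[dialect.gene_col].strip() or group_id
        records.append(
            ProteinGroupRecord(
                group_id=group_id,
                accessions=accessions,
                gene_name=gene,
                q_value=q_value,
                is_reverse=_parse_flag(row[dialect.reverse_col], dialect.reverse_col, row_idx),
                is_contaminant=_parse_flag(
                    row[dialect.contaminant_col], dialect.contaminant_col, row_idx
                ),
                intensities=intensities,
                molecular_weight_kda=mw,
            )
        )
    return ProteinGroupTable(records=records, sample_ids=sample_ids)


def write_protein_groups(
    table: ProteinGroupTable,
    path: str | Path,
    dialect: MaxQuantDialect = DEFAULT_DIALECT,
) -> None:
    """Write a table in the same dialect :func:`read_protein_groups` parses."""
    columns: dict[str, list[str]] = {
        dialect.accession_col: [";".join(r.accessions) for r in table.records],
        dialect.gene_col: [r.gene_name for r in table.records],
        dialect.qvalue_col: [repr(r.q_value) for r in table.records],
        dialect.reverse_col: ["+" if r.is_reverse else "" for r in table.records],
        dialect.contaminant_col: [
            "+" if r.is_contaminant else "" for r in table.records
        ],
        dialect.mw_col: [
            "" if r.molecular_weight_kda is None else repr(r.molecular_weight_kda)
            for r in table.records
        ],
    }
    for sample in table.sample_ids:
        columns[dialect.intensity_prefix + sample] = [
            repr(r.intensity(sample)) if r.intensity(sample) else "0"
            for r in table.records
        ]
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# experimental design


_DEFAULT_PULLDOWN_ALIASES = {"bait": Pulldown.BAIT, "control": Pulldown.CONTROL}


def read_design(
    path: str | Path,
    pulldown_aliases: Optional[Mapping[str, Pulldown | str]] = None,
) -> SampleDesign:
    """Read a sample_id / condition / pulldown / replicate design table.

    ``pulldown_aliases`` extends the case-insensitive mapping of pulldown
    labels, e.g. ``{"igg": Pulldown.CONTROL}`` for designs written with the
    control antibody's name.
    """
    path = Path(path)
    aliases: dict[str, Pulldown] = dict(_DEFAULT_PULLDOWN_ALIASES)
    for key, value in (pulldown_aliases or {}).items():
        aliases[key.lower()] = Pulldown(value) if isinstance(value, str) else value
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    for col in ("sample_id", "condition", "pulldown", "replicate"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    entries: dict[str, DesignEntry] = {}
    for row_idx, row in df.iterrows():
        sample = row["sample_id"].strip()
        if sample in entries:
            raise FormatError(f"{path}: duplicate sample_id {sample!r}")
        label = row["pulldown"].strip().lower()
        if label not in aliases:
            raise FormatError(
                f"{path}: unknown pulldown value {row['pulldown']!r} "
                f"(known: {sorted(aliases)})"
            )
        try:
            replicate = int(row["replicate"])
        except ValueError:
            raise RowError(
                int(row_idx), f"non-integer replicate {row['replicate']!r}"
            ) from None
        entries[sample] = DesignEntry(
            condition=row["condition"].strip(),
            pulldown=aliases[label],
            replicate=replicate,
        )
    return SampleDesign(entries=entries)


def write_design(design: SampleDesign, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": list(design.entries),
            "condition": [e.condition for e in design.entries.values()],
            "pulldown": [e.pulldown.value for e in design.entries.values()],
            "replicate": [e.replicate for e in design.entries.values()],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation sets and identifier lists


_CATEGORY_HINTS = {
    "biological_process": GoCategory.BIOLOGICAL_PROCESS,
    "cellular_component": GoCategory.CELLULAR_COMPONENT,
    "molecular_function": GoCategory.MOLECULAR_FUNCTION,
}


def _infer_category(description: str) -> GoCategory:
    lowered = description.lower()
    for hint, category in _CATEGORY_HINTS.items():
        if hint in lowered:
            return category
    return GoCategory.OTHER


def read_gmt(
    path: str | Path,
    categories: Optional[Mapping[str, GoCategory]] = None,
) -> AnnotationMap:
    """Read a GMT file: ``term<TAB>description<TAB>gene...`` per line.

    The ontology category is taken from ``categories`` when supplied,
    otherwise inferred from a ``biological_process`` / ``cellular_component``
    / ``molecular_function`` token in the description (``OTHER`` if none).
    Duplicate member genes within a line are deduplicated.
    """
    path = Path(path)
    terms: dict[str, AnnotationTerm] = {}
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {line_no}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            term_id, description = fields[0].strip(), fields[1].strip()
            if term_id in terms:
                raise FormatError(f"{path}: line {line_no}: duplicate term {term_id!r}")
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not members:
                raise FormatError(
                    f"{path}: line {line_no}: term {term_id!r} has no members"
                )
            category = (
                categories[term_id]
                if categories and term_id in categories
                else _infer_category(description)
            )
            terms[term_id] = AnnotationTerm(
                term_id=term_id, name=description, category=category, members=members
            )
    return AnnotationMap(terms=terms)


def read_id_list(path: str | Path) -> set[str]:
    """Read a one-identifier-per-line list.

    Blank lines and ``#`` comments are ignored, surrounding whitespace is
    stripped and the result deduplicated.  An empty result emits a warning
    rather than an error.
    """
    path = Path(path)
    out: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.add(line)
    if not out:
        warnings.warn(f"{path}: identifier list is empty", stacklevel=2)
    return out


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for identifier in sorted(ids):
            handle.write(identifier + "\n")


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping identifiers to their aliases.

    Blank lines and ``#`` comments are ignored; duplicate left-hand
    identifiers with conflicting targets raise a format error.
    """
    path = Path(path)
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2 or not all(fields):
                raise FormatError(
                    f"{path}: line {line_no}: expected exactly 2 non-empty "
                    "tab-separated fields"
                )
            src, dst = fields
            if src in out and out[src] != dst:
                raise FormatError(
                    f"{path}: line {line_no}: conflicting aliases for {src!r}"
                )
            out[src] = dst
    return out


# ---------------------------------------------------------------------------
# candidate tables


_CANDIDATE_COLUMNS = ("accession", "gene_name", "molecular_weight_kda")


def write_candidate_table(
    candidates: Iterable[str],
    table: ProteinGroupTable,
    path: str | Path,
) -> None:
    """Write the per-condition candidate list as a TSV.

    One row per candidate (sorted by accession for deterministic output) with
    accession, gene name and molecular weight looked up from ``table``.
    A candidate absent from the table raises ``KeyError`` naming it.
    """
    by_id = {rec.group_id: rec for rec in table.records}
    rows = []
    for candidate in sorted(set(candidates)):
        if candidate not in by_id:
            raise KeyError(f"candidate {candidate!r} not present in table")
        rec = by_id[candidate]
        rows.append(
            {
                "accession": rec.group_id,
                "gene_name": rec.gene_name,
                "molecular_weight_kda": (
                    "" if rec.molecular_weight_kda is None else rec.molecular_weight_kda
                ),
            }
        )
    pd.DataFrame(rows, columns=list(_CANDIDATE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_candidate_table(path: str | Path) -> set[str]:
    """Read back the accession set written by :func:`write_candidate_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "accession" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column 'accession'")
    return set(df["accession"])
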