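"""Packaged reference tables for the Kpnβ1 (importin-β1) interactome study
this pipeline models.

Two small tables ship with the package, transcribed from the printed
results of the underlying four-cell-line IP-MS experiment (hTERT-RPE1
normal retinal epithelium; HeLa cervical cancer; WHCO5 and KYSE30
oesophageal cancer):

* ``common core`` -- Kpnβ1 binding partners called in all four cell lines,
  the bait included.  Note: the study's narrative reports this set as 38
  proteins including the bait, but its printed table lists 39 distinct
  accessions; the transcription here preserves the printed table
  verbatim, so :func:`common_core_ids` has 39 members.
* ``cancer unique`` -- the 18 partners called in all three cancer lines
  and not in the normal line.

The two sets are disjoint by construction (common implies present in the
normal line).  Identifiers are leading Uniprot accessions, the namespace
the rest of the pipeline matches on.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_common_core",
    "load_cancer_unique",
    "common_core_ids",
    "cancer_unique_ids",
    "BAIT_ACCESSION",
]

#: leading accession of the bait, importin subunit beta-1 (KPNB1)
BAIT_ACCESSION = "Q14974"


def _load(name: str) -> pd.DataFrame:
    with resources.files("baitcall.data").joinpath(name).open("rb") as handle:
        return pd.read_csv(handle, sep="\t", dtype={"accession": str})


def load_common_core() -> pd.DataFrame:
    """The printed common-core table: accession, protein/gene name, MW, group."""
    return _load("kpnb1_common_core.tsv")


def load_cancer_unique() -> pd.DataFrame:
    """The printed cancer-unique table (18 rows)."""
    return _load("kpnb1_cancer_unique.tsv")


def common_core_ids() -> frozenset[str]:
    return frozenset(load_common_core()["accession"])


def cancer_unique_ids() -> frozenset[str]:
    return frozenset(load_cancer_unique()["accession"])
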