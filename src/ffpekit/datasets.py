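"""Packaged per-library metadata tables.

Small TSV fixtures with the published per-library accounting of the FFPE
melanoma/carcinoma study this package models: ddPCR molecule yields for
three library preparations (Table-1 style), sequencing characteristics of
genomic single-/double-strand libraries (Table-2 style) and of single-strand
exome libraries (Table-3 style), plus the list of called coding missense
SNVs (Table-4 style).  These are inputs — the derived columns
(``mappable_bp_printed``, ``coverage_printed``) are retained only so tests
can compare recomputation against them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("ffpekit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_yield_table() -> pd.DataFrame:
    """ddPCR molecule yields per sample and library preparation method.

    Columns: sample, cancer, storage_years, molecules_dsNEB, molecules_dsMPI,
    molecules_ss, library_id, is_ntc.  21 paired melanoma samples, 12
    ss-only carcinoma samples and 4 no-template controls.
    """
    return _load("table1_yield.tsv")


def load_genomic_metrics_table() -> pd.DataFrame:
    """Shotgun-sequencing accounting of 9 ss + 10 ds genomic libraries."""
    return _load("table2_genomic.tsv")


def load_exome_metrics_table() -> pd.DataFrame:
    """Exome-capture accounting of 15 ss exome libraries (+2 NTCs)."""
    return _load("table3_exome.tsv")


def load_called_variants_table() -> pd.DataFrame:
    """Coding missense SNVs called from the exome libraries (1-based pos)."""
    return _load("table4_variants.tsv")
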