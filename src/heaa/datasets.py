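"""Packaged dataset: the published Hachijojima humpback DNAm table.

The study's entire deliverable dataset is a 25-sample table of per-gene
DNAm frequencies (%) and coverages, with duplicate-biopsy assignments
and genetically determined sex.  It ships with the package so the age
estimation and cohort analysis stages can be run and checked without
any sequencing input.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_hachijojima", "frequency_records", "sheet_from_table"]

GENE_COLUMNS = {
    "GRIA2": ("gria2_freq", "gria2_cov"),
    "CDKN2A": ("cdkn2a_freq", "cdkn2a_cov"),
    "TET2": ("tet2_freq", "tet2_cov"),
}


def load_hachijojima() -> pd.DataFrame:
    """The 25-sample biopsy table, one row per sample (wide format).

    Columns: sample_id, individual_id, sex, per-gene DNAm frequency (%)
    and coverage, and a free-text annotation (mother-calf sightings).
    """
    src = resources.files("heaa").joinpath("data/hachijojima_dnam.tsv")
    with resources.as_file(src) as path:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str})
    df["annotation"] = df["annotation"].fillna("")
    return df


def frequency_records(table: pd.DataFrame) -> pd.DataFrame:
    """Wide table -> long (sample_id, gene, frequency, coverage) records."""
    rows = []
    for _, r in table.iterrows():
        for gene, (fc, cc) in GENE_COLUMNS.items():
            rows.append(
                {
                    "sample_id": r["sample_id"],
                    "gene": gene,
                    "frequency": float(r[fc]),
                    "coverage": int(r[cc]),
                }
            )
    return pd.DataFrame(rows)


def sheet_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Sample sheet (sample_id, individual_id, sex, annotation) view."""
    cols = ["sample_id", "individual_id", "sex"]
    if "annotation" in table.columns:
        cols.append("annotation")
    return table[cols].copy()
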