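"""File I/O: FASTQ/FASTA via Biopython, sample sheets and tables via pandas."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicons import AmpliconReference
from .reads import ReadRecord
from .simulate import SampleTruth

__all__ = [
    "write_fastq",
    "read_fastq",
    "write_reference_fasta",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_truth_table",
    "read_truth_table",
]


def _to_seqrecord(read: ReadRecord) -> SeqRecord:
    rec = SeqRecord(Seq(read.bases), id=read.read_id, description="")
    rec.letter_annotations["phred_quality"] = list(read.quals)
    return rec


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write 4-line Sanger FASTQ (gzipped iff the path ends in .gz)."""
    path = Path(path)
    records = (_to_seqrecord(r) for r in reads)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            return SeqIO.write(records, fh, "fastq")
    return SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            records = list(SeqIO.parse(fh, "fastq"))
    else:
        records = list(SeqIO.parse(str(path), "fastq"))
    return [
        ReadRecord(
            rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"])
        )
        for rec in records
    ]


def write_reference_fasta(refs: Iterable[AmpliconReference], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.gene_name,
            description=f"target_cpg={r.target_site} label={r.site_label}",
        )
        for r in refs
    ]
    SeqIO.write(records, str(path), "fasta")


def write_sample_sheet(
    truths: Iterable[SampleTruth],
    fastq_paths: dict[str, tuple[str, str]],
    path: str | Path,
) -> None:
    """CSV sample sheet: sample_id,individual_id,sex,fastq_r1,fastq_r2."""
    rows = [
        {
            "sample_id": t.sample_id,
            "individual_id": t.individual_id,
            "sex": t.sex,
            "fastq_r1": fastq_paths[t.sample_id][0],
            "fastq_r2": fastq_paths[t.sample_id][1],
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "individual_id": str})
    required = {"sample_id", "individual_id", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"malformed sample sheet {path}: needs columns {sorted(required)}"
        )
    if df["sample_id"].duplicated().any():
        raise ValueError(f"malformed sample sheet {path}: duplicate sample_id")
    return df


def write_truth_table(truths: Iterable[SampleTruth], path: str | Path) -> None:
    """TSV of per-sample, per-gene simulation ground truth."""
    rows = []
    for t in truths:
        for gene, frac in t.meth_fraction.items():
            rows.append(
                {
                    "sample_id": t.sample_id,
                    "individual_id": t.individual_id,
                    "sex": t.sex,
                    "true_age": t.true_age,
                    "gene": gene,
                    "true_fraction": frac,
                    "emitted_reads": t.emitted_reads.get(gene, 0),
                    "methylated_molecules": t.methylated_molecules.get(gene, 0),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str})
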