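"""Stage orchestration: simulate -> process -> call -> age -> summarize.

Each ``run_*`` stage reads its inputs from and writes its outputs to the
configured output directory, so stages can be re-run independently; the
in-memory cores (:func:`process_sample`, :func:`call_sample`) are what
the tests drive directly.  Every stage logs one structured line of
read-loss accounting, and the per-sample counts are also written to
disk, so no read disappears without a recorded reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .amplicons import AmpliconReference, default_references, reverse_complement
from .calling import CpGCall, align_reads, call_cpg
from .clock import AgeEstimate, estimate_age
from .cohort import cohort_summary, merge_duplicates, replicate_concordance
from .config import PipelineConfig
from .reads import MergedRead, ReadRecord, merge_pair, quality_filter, trim_adapter
from .simulate import QualityProfile, generate_cohort, simulate_reads

logger = logging.getLogger("heaa")

__all__ = [
    "StageCounts",
    "process_sample",
    "call_sample",
    "run_simulate",
    "run_process",
    "run_call",
    "run_age",
    "run_summarize",
    "run_all",
]


@dataclass
class StageCounts:
    """Per-sample read-loss accounting through the processing stages."""

    input_pairs: int = 0
    quality_discarded_pairs: int = 0
    unmerged_pairs: int = 0
    merged_pairs: int = 0

    def check_conservation(self) -> None:
        lost = self.quality_discarded_pairs + self.unmerged_pairs
        if self.merged_pairs + lost != self.input_pairs:
            raise AssertionError("read accounting does not balance")


def process_sample(
    r1_reads: list[ReadRecord],
    r2_reads: list[ReadRecord],
    adapter_r1: str,
    adapter_r2: str,
    min_q: int = 20,
    min_len: int = 40,
    min_overlap: int = 10,
    merge_max_mismatch_frac: float = 0.25,
) -> tuple[list[MergedRead], StageCounts]:
    """Adapter-trim, quality-filter and merge one sample's read pairs.

    ``adapter_r1``/``adapter_r2`` are the 3' read-through adapters (the
    reverse complements of the reverse/forward universal primer tails
    respectively).  Pairs are dropped whole if either mate fails the
    quality filter; unmergeable pairs are counted and dropped.
    """
    counts = StageCounts(input_pairs=len(r1_reads))
    merged: list[MergedRead] = []
    for r1, r2 in zip(r1_reads, r2_reads):
        t1 = trim_adapter(r1, adapter_r1)
        t2 = trim_adapter(r2, adapter_r2)
        f1 = quality_filter(t1, min_q=min_q, min_len=min_len)
        f2 = quality_filter(t2, min_q=min_q, min_len=min_len)
        if f1 is None or f2 is None:
            counts.quality_discarded_pairs += 1
            continue
        m = merge_pair(
            f1, f2, min_overlap=min_overlap, max_mismatch_frac=merge_max_mismatch_frac
        )
        if m is None:
            counts.unmerged_pairs += 1
            continue
        merged.append(m)
    counts.merged_pairs = len(merged)
    counts.check_conservation()
    return merged, counts


def call_sample(
    merged: list[MergedRead],
    refs: list[AmpliconReference],
    sample_id: str,
    align_max_mismatch_frac: float = 0.1,
    coverage_floor: int = 1000,
) -> tuple[list[CpGCall], int]:
    """Align one sample's merged reads and call every target CpG.

    Returns the per-gene calls plus the number of unaligned reads.
    """
    alignments = align_reads(merged, refs, align_max_mismatch_frac)
    unaligned = sum(1 for a in alignments if not a.aligned)
    calls = [
        call_cpg(
            alignments,
            merged,
            ref,
            ref.target_site,
            sample_id=sample_id,
            coverage_floor=coverage_floor,
        )
        for ref in refs
    ]
    return calls, unaligned


# ---------------------------------------------------------------------------
# file-level stages


def _out(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(
    config: PipelineConfig, quality: QualityProfile = QualityProfile()
) -> Path:
    """Generate references, cohort truth, and per-sample paired FASTQ."""
    out = _out(config)
    rng = np.random.default_rng(config.seed)
    refs = default_references(seed=int(rng.integers(2**31)))
    io.write_reference_fasta(refs, out / "references.fasta")
    cohort = generate_cohort(
        n_individuals=config.n_individuals,
        duplicate_pairs=config.duplicate_pairs,
        sex_ratio=config.sex_ratio,
        age_range=(config.age_min, config.age_max),
        seed=int(rng.integers(2**31)),
        conversion_efficiency=config.conversion_efficiency,
    )
    fastq_paths: dict[str, tuple[str, str]] = {}
    updated = []
    for truth in cohort:
        r1, r2, truth = simulate_reads(
            truth,
            refs,
            reads_per_gene=config.reads_per_gene,
            error_rate=config.error_rate,
            seed=int(rng.integers(2**31)),
            quality=quality,
        )
        p1 = out / f"{truth.sample_id}_R1.fastq"
        p2 = out / f"{truth.sample_id}_R2.fastq"
        io.write_fastq(r1, p1)
        io.write_fastq(r2, p2)
        fastq_paths[truth.sample_id] = (p1.name, p2.name)
        updated.append(truth)
    io.write_sample_sheet(updated, fastq_paths, out / "sample_sheet.csv")
    io.write_truth_table(updated, out / "truth.tsv")
    logger.info(
        "simulate: samples=%d reads_per_gene=%d error_rate=%g",
        len(updated), config.reads_per_gene, config.error_rate,
    )
    return out


def run_process(config: PipelineConfig) -> Path:
    """Trim, filter and merge every sample listed in the sample sheet."""
    out = _out(config)
    sheet = io.read_sample_sheet(out / "sample_sheet.csv")
    refs = _load_refs(out)
    adapter_r1 = reverse_complement(refs[0].adapter_rev)
    adapter_r2 = reverse_complement(refs[0].adapter_fwd)
    stats_rows = []
    for _, row in sheet.iterrows():
        r1 = io.read_fastq(out / row["fastq_r1"])
        r2 = io.read_fastq(out / row["fastq_r2"])
        merged, counts = process_sample(
            r1, r2, adapter_r1, adapter_r2,
            min_q=config.min_q,
            min_len=config.min_len,
            min_overlap=config.min_overlap,
            merge_max_mismatch_frac=config.merge_max_mismatch_frac,
        )
        io.write_fastq(
            (ReadRecord(m.read_id, m.bases, m.quals) for m in merged),
            out / f"{row['sample_id']}_merged.fastq",
        )
        stats_rows.append({"sample_id": row["sample_id"], **counts.__dict__})
        logger.info(
            "process: sample=%s pairs=%d discarded=%d unmerged=%d merged=%d",
            row["sample_id"], counts.input_pairs, counts.quality_discarded_pairs,
            counts.unmerged_pairs, counts.merged_pairs,
        )
    pd.DataFrame(stats_rows).to_csv(out / "process_stats.tsv", sep="\t", index=False)
    return out


def run_call(config: PipelineConfig) -> Path:
    """Align merged reads and write the per-sample frequency table."""
    out = _out(config)
    sheet = io.read_sample_sheet(out / "sample_sheet.csv")
    refs = _load_refs(out)
    rows = []
    for sid in sheet["sample_id"]:
        merged = io.read_fastq(out / f"{sid}_merged.fastq")
        mreads = [MergedRead(r.read_id, r.bases, r.quals, 0, 0) for r in merged]
        calls, unaligned = call_sample(
            mreads, refs, sid,
            align_max_mismatch_frac=config.align_max_mismatch_frac,
            coverage_floor=config.coverage_floor,
        )
        logger.info("call: sample=%s reads=%d unaligned=%d", sid, len(mreads), unaligned)
        for c in calls:
            rows.append(
                {
                    "sample_id": sid,
                    "gene": c.gene_name,
                    "site_label": c.site_label,
                    "methylated": c.methylated,
                    "unmethylated": c.unmethylated,
                    "coverage": c.coverage,
                    "frequency": c.frequency,
                    "low_coverage": c.low_coverage,
                    "unaligned_reads": unaligned,
                }
            )
    pd.DataFrame(rows).to_csv(out / "frequencies.tsv", sep="\t", index=False)
    return out


def estimates_from_records(
    records: pd.DataFrame, ci_half_width: float
) -> list[AgeEstimate]:
    """Clock estimates from long (sample_id, gene, frequency) records."""
    estimates = []
    for sid, grp in records.groupby("sample_id", sort=False):
        calls = dict(zip(grp["gene"], grp["frequency"]))
        missing = [g for g in ("GRIA2", "CDKN2A", "TET2") if g not in calls]
        if missing:
            raise ValueError(f"sample {sid!r}: missing gene(s) {missing}")
        estimates.append(
            estimate_age(
                str(sid), calls["GRIA2"], calls["CDKN2A"], calls["TET2"],
                half_width=ci_half_width,
            )
        )
    return estimates


def run_age(config: PipelineConfig, frequencies: str | Path | None = None) -> Path:
    """Apply the clock to a frequency table and write the estimates TSV.

    ``frequencies`` defaults to the table produced by :func:`run_call`;
    any long-format TSV with sample_id/gene/frequency columns works, so
    published tables can be fed straight in.
    """
    out = _out(config)
    src = Path(frequencies) if frequencies else out / "frequencies.tsv"
    records = pd.read_csv(src, sep="\t", dtype={"sample_id": str})
    estimates = estimates_from_records(records, config.ci_half_width)
    rows = [
        {
            "sample_id": e.sample_id,
            "gria2_freq": e.x,
            "cdkn2a_freq": e.y,
            "tet2_freq": e.z,
            "age": f"{e.age:.2f}",
            "ci_low": f"{e.ci_low:.2f}",
            "ci_high": f"{e.ci_high:.2f}",
            "negative_flag": e.negative,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(out / "estimates.tsv", sep="\t", index=False)
    logger.info("age: samples=%d", len(rows))
    return out


def run_summarize(config: PipelineConfig, make_plot: bool = True) -> Path:
    """Merge duplicates and write cohort summary, histogram, individuals."""
    out = _out(config)
    est_df = pd.read_csv(out / "estimates.tsv", sep="\t", dtype={"sample_id": str})
    estimates = [
        AgeEstimate(
            sample_id=r["sample_id"],
            x=r["gria2_freq"], y=r["cdkn2a_freq"], z=r["tet2_freq"],
            age=float(r["age"]), ci_low=float(r["ci_low"]),
            ci_high=float(r["ci_high"]), age_raw=float(r["age"]),
        )
        for _, r in est_df.iterrows()
    ]
    sheet = io.read_sample_sheet(out / "sample_sheet.csv")
    individuals = merge_duplicates(estimates, sheet)
    summary = cohort_summary(individuals, bin_width=config.bin_width)
    dmin, dmax, diffs = replicate_concordance(individuals)

    pd.DataFrame(
        [
            {
                "individual_id": i.individual_id,
                "sex": i.sex,
                "sample_ids": ",".join(i.sample_ids),
                "sample_ages": ",".join(f"{a:.2f}" for a in i.sample_ages),
                "consensus_age": f"{i.consensus_age:.2f}",
                "annotation": i.annotation,
            }
            for i in individuals
        ]
    ).to_csv(out / "individuals.tsv", sep="\t", index=False)

    pd.DataFrame(
        {"bin": summary.bin_labels, "count": summary.bin_counts}
    ).to_csv(out / "age_structure.tsv", sep="\t", index=False)

    payload = {
        "n_individuals": summary.n_individuals,
        "age_min": summary.age_min,
        "age_max": summary.age_max,
        "age_mean": summary.age_mean,
        "by_sex": summary.by_sex,
        "peak_bin": summary.peak_bin_label,
        "duplicate_diff_min": dmin,
        "duplicate_diff_max": dmax,
        "duplicate_diffs": diffs,
    }
    (out / "cohort_summary.json").write_text(json.dumps(payload, indent=2))
    logger.info(
        "summarize: individuals=%d mean=%.2f peak=%s",
        summary.n_individuals, summary.age_mean, summary.peak_bin_label,
    )
    if make_plot:
        _plot_histogram(summary, out / "age_structure.png")
    return out


def _plot_histogram(summary, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(summary.bin_counts)), summary.bin_counts, color="#4878a8")
    ax.set_xticks(range(len(summary.bin_labels)))
    ax.set_xticklabels(summary.bin_labels, rotation=45, ha="right")
    ax.set_xlabel("Estimated age class (years)")
    ax.set_ylabel("Number of individuals")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_all(config: PipelineConfig, make_plot: bool = True) -> Path:
    run_simulate(config)
    run_process(config)
    run_call(config)
    run_age(config)
    return run_summarize(config, make_plot=make_plot)


def _load_refs(out: Path) -> list[AmpliconReference]:
    """Rebuild reference objects from the stage-one FASTA."""
    from Bio import SeqIO

    refs = []
    for rec in SeqIO.parse(str(out / "references.fasta"), "fasta"):
        seq = str(rec.seq)
        target = None
        for tok in rec.description.split():
            if tok.startswith("target_cpg="):
                target = int(tok.split("=", 1)[1])
        cpgs = tuple(i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
        from .amplicons import GENE_PRIMERS

        fwd, rev = GENE_PRIMERS[rec.id]
        refs.append(
            AmpliconReference(
                gene_name=rec.id,
                sequence=seq,
                cpg_positions=cpgs,
                target_site=target,
                fwd_primer=fwd,
                rev_primer=rev,
            )
        )
    return refs
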