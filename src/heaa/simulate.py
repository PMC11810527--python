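"""Synthetic cohorts and bisulfite paired-end reads with known truth.

No raw sequencing data are published for the assay this package
implements, so every downstream stage is validated against simulation.
The simulator emulates the study design end to end:

* a cohort shaped like the real one — 21 individuals, 4 of them biopsied
  twice (25 samples), 15 males / 6 females, ages spanning roughly 2–31
  years;
* per-sample true methylation fractions constructed by *inverting* the
  HEAA clock: CDKN2A and TET2 frequencies are drawn within the
  empirically observed assay ranges and the GRIA2 frequency is solved
  so the clock returns the sample's true age exactly;
* 250 bp x 2 paired reads of bisulfite-converted amplicon molecules,
  with 3' adapter read-through, substitution sequencing error, and
  configurable (in)complete conversion.

Conversion model per molecule: the target CpG cytosine stays 'C' with
probability ``meth_fraction``; an unmethylated cytosine (target,
background CpG, or any non-CpG C) converts C->T with probability
``conversion_efficiency``.  Only the original top strand is simulated —
the assay is primer-defined, so the bottom strand never enters a
library.  The exact number of molecules presenting 'C' at each target
CpG is recorded per gene, giving downstream tests an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .amplicons import AmpliconReference, reverse_complement
from .clock import COEF_CDKN2A, COEF_GRIA2, COEF_TET2, INTERCEPT, heaa_age
from .reads import ReadRecord

__all__ = [
    "SampleTruth",
    "QualityProfile",
    "generate_cohort",
    "simulate_reads",
    "DEFAULT_COHORT",
]

#: Cohort shape of the Hachijojima biopsy series: 21 whales, 4 duplicate
#: pairs (25 samples), 15 males of 21, ages ~2-31 years.
DEFAULT_COHORT = dict(
    n_individuals=21, duplicate_pairs=4, sex_ratio=15 / 21, age_range=(2.0, 31.0)
)

#: Empirical per-gene DNAm frequency ranges (%) seen in the assay; the
#: cohort generator draws CDKN2A/TET2 inside these and solves GRIA2.
ASSAY_RANGES = {"GRIA2": (0.66, 2.66), "CDKN2A": (1.34, 4.64), "TET2": (5.59, 19.19)}

GENES = ("GRIA2", "CDKN2A", "TET2")


@dataclass
class SampleTruth:
    """Ground truth for one simulated biopsy sample.

    ``meth_fraction`` maps gene -> true methylation fraction in [0, 1]
    at the target CpG; ``background_meth`` likewise for non-target CpGs.
    ``emitted_reads`` / ``methylated_molecules`` are filled in by
    :func:`simulate_reads` and record, per gene, how many molecules were
    emitted and how many actually present 'C' at the target site — the
    exact quantity the pipeline should recover.
    """

    sample_id: str
    individual_id: str
    sex: str
    true_age: float
    meth_fraction: dict[str, float]
    background_meth: dict[str, float] = field(default_factory=dict)
    conversion_efficiency: float = 1.0
    emitted_reads: dict[str, int] = field(default_factory=dict)
    methylated_molecules: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class QualityProfile:
    """Per-base Phred quality model: flat base quality, optional 3' ramp.

    With ``ramp_len > 0`` the final ``ramp_len`` bases decay linearly
    from ``base_q`` to ``ramp_end_q``, which exercises the Q20
    end-trimmer downstream.  The default is flat Q35.
    """

    base_q: int = 35
    ramp_len: int = 0
    ramp_end_q: int = 15

    def quals(self, length: int) -> tuple[int, ...]:
        q = [self.base_q] * length
        n = min(self.ramp_len, length)
        for i in range(n):
            frac = (i + 1) / n
            q[length - n + i] = round(
                self.base_q + frac * (self.ramp_end_q - self.base_q)
            )
        return tuple(q)


def _solve_x(age: float, y: float, z: float) -> float:
    """GRIA2 frequency (%) that makes the clock return `age` given y, z."""
    return (age - INTERCEPT - COEF_CDKN2A * y - COEF_TET2 * z) / COEF_GRIA2


def generate_cohort(
    n_individuals: int = DEFAULT_COHORT["n_individuals"],
    duplicate_pairs: int = DEFAULT_COHORT["duplicate_pairs"],
    sex_ratio: float = DEFAULT_COHORT["sex_ratio"],
    age_range: tuple[float, float] = DEFAULT_COHORT["age_range"],
    seed: int = 0,
    background_meth: float = 0.02,
    conversion_efficiency: float = 1.0,
    max_retries: int = 100,
) -> list[SampleTruth]:
    """Generate ground-truth samples for a synthetic biopsy cohort.

    Returns ``n_individuals + duplicate_pairs`` samples; the first
    ``duplicate_pairs`` individuals are each sampled twice (ids like
    "2a"/"2b"), sharing sex and true age.  ``sex_ratio`` is the male
    fraction, realised deterministically as ``round(ratio * n)`` males.

    For each individual a true age is drawn uniformly in ``age_range``;
    CDKN2A and TET2 frequencies are drawn uniformly inside the assay's
    empirical ranges and the GRIA2 frequency is solved from the clock.
    Draws that would need a GRIA2 frequency outside [0, 100] % are
    redrawn (up to ``max_retries``, then an error — only reachable for
    age ranges outside what the clock can express).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if not 0 <= duplicate_pairs <= n_individuals:
        raise ValueError("duplicate_pairs must be in [0, n_individuals]")
    if not 0.0 <= sex_ratio <= 1.0:
        raise ValueError("sex_ratio must be in [0, 1]")
    lo, hi = age_range
    if not 0 <= lo <= hi:
        raise ValueError("age_range must satisfy 0 <= lo <= hi")

    rng = np.random.default_rng(seed)
    n_male = int(round(sex_ratio * n_individuals))
    sexes = np.array(["male"] * n_male + ["female"] * (n_individuals - n_male))
    rng.shuffle(sexes)
    dup_ids = set(rng.choice(n_individuals, size=duplicate_pairs, replace=False))

    samples: list[SampleTruth] = []
    for i in range(n_individuals):
        ind = str(i + 1)
        age = float(rng.uniform(lo, hi))
        for attempt in range(max_retries):
            y = float(rng.uniform(*ASSAY_RANGES["CDKN2A"]))
            z = float(rng.uniform(*ASSAY_RANGES["TET2"]))
            x = _solve_x(age, y, z)
            if 0.0 <= x <= 100.0:
                break
        else:
            raise ValueError(
                f"no admissible methylation profile for age {age:.2f}; "
                "age_range is outside what the clock can express"
            )
        fractions = {"GRIA2": x / 100, "CDKN2A": y / 100, "TET2": z / 100}
        n_copies = 2 if i in dup_ids else 1
        for k in range(n_copies):
            sid = ind if n_copies == 1 else ind + "ab"[k]
            samples.append(
                SampleTruth(
                    sample_id=sid,
                    individual_id=ind,
                    sex=str(sexes[i]),
                    true_age=age,
                    meth_fraction=dict(fractions),
                    background_meth={g: background_meth for g in GENES},
                    conversion_efficiency=conversion_efficiency,
                )
            )
    # Sanity: the inverse construction must be clock-consistent.
    for s in samples:
        back = heaa_age(*(100 * s.meth_fraction[g] for g in GENES))
        assert abs(back - s.true_age) < 0.005
    return samples


def simulate_reads(
    truth: SampleTruth,
    refs: list[AmpliconReference],
    reads_per_gene: int = 2000,
    error_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 250,
    quality: QualityProfile = QualityProfile(),
) -> tuple[list[ReadRecord], list[ReadRecord], SampleTruth]:
    """Simulate paired 250 bp reads for one sample across all amplicons.

    Each molecule is a bisulfite-converted copy of the top strand of one
    amplicon.  Read 1 covers the molecule from its 5' end and runs into
    the reverse adapter (reverse complement of the reverse universal
    tail); read 2 is the reverse complement running into the forward
    adapter; templates shorter than ``read_length`` are padded with 'A'
    downstream of the adapter.  Substitution errors are applied
    independently per read at ``error_rate``; qualities come from
    ``quality`` and do not reflect the planted errors.

    Returns (R1 records, R2 records, updated truth) where the truth
    carries exact per-gene emitted-read and methylated-molecule counts.
    """
    if reads_per_gene < 1:
        raise ValueError("reads_per_gene must be >= 1")
    if not 0.0 <= error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    for ref in refs:
        if 2 * read_length < len(ref) + 10:
            raise ValueError(
                f"{ref.gene_name}: {read_length} bp x 2 cannot span a "
                f"{len(ref)} bp amplicon with overlap for merging"
            )
    rng = np.random.default_rng(seed)
    r1_out: list[ReadRecord] = []
    r2_out: list[ReadRecord] = []
    emitted: dict[str, int] = {}
    methylated: dict[str, int] = {}

    for ref in refs:
        gene = ref.gene_name
        n = reads_per_gene
        seq = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
        mol = np.tile(seq, (n, 1))
        conv = truth.conversion_efficiency
        t_code, c_code = ord("T"), ord("C")

        # Target CpG: methylated stays C; unmethylated converts w.p. conv.
        f = truth.meth_fraction[gene]
        is_meth = rng.random(n) < f
        converts = (~is_meth) & (rng.random(n) < conv)
        mol[converts, ref.target_site] = t_code
        methylated[gene] = int(n - converts.sum())
        emitted[gene] = n

        # Background CpGs.
        bg = truth.background_meth.get(gene, 0.0)
        for p in ref.cpg_positions:
            if p == ref.target_site:
                continue
            bm = rng.random(n) < bg
            bc = (~bm) & (rng.random(n) < conv)
            mol[bc, p] = t_code
        # Every non-CpG cytosine converts w.p. conv.
        cpos = np.array(ref.non_cpg_c_positions, dtype=int)
        if cpos.size:
            cmask = rng.random((n, cpos.size)) < conv
            for j, p in enumerate(cpos):
                mol[cmask[:, j], p] = t_code

        ad1 = np.frombuffer(
            reverse_complement(ref.adapter_rev).encode(), dtype=np.uint8
        )
        ad2 = np.frombuffer(
            reverse_complement(ref.adapter_fwd).encode(), dtype=np.uint8
        )
        mol_rc = _COMP_TABLE[mol][:, ::-1]
        t1 = np.concatenate([mol, np.tile(ad1, (n, 1))], axis=1)
        t2 = np.concatenate([mol_rc, np.tile(ad2, (n, 1))], axis=1)
        r1 = _fit_reads(t1, read_length)
        r2 = _fit_reads(t2, read_length)
        if error_rate > 0:
            _apply_errors(r1, error_rate, rng)
            _apply_errors(r2, error_rate, rng)
        quals = quality.quals(read_length)
        for i in range(n):
            rid = f"{truth.sample_id}:{gene}:{i}"
            r1_out.append(ReadRecord(rid, r1[i].tobytes().decode(), quals))
            r2_out.append(ReadRecord(rid, r2[i].tobytes().decode(), quals))

    updated = replace(
        truth,
        emitted_reads={**truth.emitted_reads, **emitted},
        methylated_molecules={**truth.methylated_molecules, **methylated},
    )
    return r1_out, r2_out, updated


_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_a] = _b

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_IDX = np.zeros(256, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _BASE_IDX[_a] = _i


def _fit_reads(templates: np.ndarray, read_length: int) -> np.ndarray:
    """Cut templates to the read length, padding short ones with 'A'."""
    n, width = templates.shape
    if width >= read_length:
        return np.ascontiguousarray(templates[:, :read_length])
    out = np.full((n, read_length), ord("A"), dtype=np.uint8)
    out[:, :width] = templates
    return out


def _apply_errors(reads: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Plant uniform substitution errors in place (never to the same base)."""
    mask = rng.random(reads.shape) < rate
    idx = _BASE_IDX[reads[mask]]
    shift = rng.integers(1, 4, size=idx.size)
    reads[mask] = _BASE_CODES[(idx + shift) % 4]
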