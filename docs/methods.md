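# Methods

## The age model

The Humpback Epigenetic Age Assay (HEAA) is a linear clock over DNA
methylation frequencies (in percent) at one CpG site in each of three
age-associated promoter fragments:

    age = 5.4717·x + 3.9705·y − 0.6793·z + 1.4695

with x = GRIA2+202, y = CDKN2A+297, z = TET2+31. The coefficients were
calibrated on skin samples of whales of known age and are constants in
this package; recalibration and cross-validation are out of scope. GRIA2
and CDKN2A methylation increase with age, TET2 methylation decreases.

Every point estimate carries a fixed-half-width 95 % confidence
interval. The half-width is **4.47 years**: the published interval
*width* is quoted as 8.95, but every tabulated interval in the source
data is exactly (reported age ± 4.47), so the tabulated arithmetic is
taken as authoritative (`CI_HALF_WIDTH` is a named, configurable
constant). Only the lower bound is clamped at zero. Point estimates can
be negative for extreme TET2 frequencies; they are reported as computed
and flagged, never clamped — clamping is a property of the interval, not
the estimate.

### Reporting arithmetic

All internal arithmetic is double precision; rounding to two decimals
happens once, at the reporting boundary, half-away-from-zero. Summary
statistics (consensus ages of duplicate pairs, cohort means) are
computed *from the 2-decimal reported values* in exact decimal
arithmetic. This matters: mean(15.53, 14.02) = 14.775 must report as
14.78, which binary floating point narrowly misses (14.7749…). Using
reported-value decimal arithmetic makes every summary number equal to
what a reader recomputes by hand from a published table.

## Pipeline stages

**Adapter trimming.** Reads run through their insert into the universal
first-PCR primer tail of the opposite end. A full internal adapter
occurrence truncates the read at its start; otherwise the longest read
suffix exactly matching an adapter prefix (≥ 3 bases) is removed.
Exact matching is deliberate: amplicon inserts are fixed-length, so
partial-overlap heuristics with mismatch tolerance buy nothing and cost
reproducibility. The consequence — a sequencing error inside the
adapter tail leaves it untrimmed and the pair is later dropped as
unmergeable — is an unbiased loss, since adapter errors are independent
of methylation state.

**Quality filtering.** End-trimming at Phred ≤ 20 (3′ end first, then
5′), then a length floor: survivors of ≤ 40 bases are discarded, with
the boundary inclusive (a 40-base read is dropped, 41 kept). A
sliding-window trimmer was considered and rejected: pairs fully span
the amplicon, so end-trimming is sufficient and exactly reproducible.

**Pair merging.** Read 2 is reverse-complemented and overlap lengths
are scanned from the longest geometrically possible down to 10; the
first (longest) overlap with mismatch fraction ≤ 0.25 is accepted. At
disagreeing positions the higher-quality base wins; quality ties go to
read 1, so the merge is a pure function of input order. Consensus
quality is the max of the two at agreements and the winner's at
disagreements.

**Bisulfite-tolerant alignment.** Ungapped (the simulator plants only
substitutions, and amplicon data has no structural variation), top
strand only (the assay is primer-defined, so no bottom-strand library
molecules exist). Match rule: read base = reference base is a match;
read T over reference C is a bisulfite match; everything else is a hard
mismatch — the rule is asymmetric, read C over reference T is an error.
All offsets at which the read fits inside a reference are scored (a
sliding-window matrix per reference, cached per read length; identical
read sequences are scored once and fanned out — amplicon redundancy
makes this a large saving). Fewest hard mismatches wins, ties broken by
reference order then smallest offset; reads whose best placement
exceeds a 10 % hard-mismatch fraction are counted as unaligned and
dropped, never raised.

**Methylation calling.** Per aligned read covering the target CpG:
C votes methylated, T unmethylated, any other base is excluded from
coverage entirely (a sequencing error carries no conversion-state
information; the source protocol does not state this rule, so it is an
explicit design choice here). Frequency = 100·methylated/coverage.
Zero usable coverage raises a distinct no-call error — it is never
conflated with a frequency of 0 %. Calls below the coverage QC floor
(default 1,000× for synthetic runs; the real assay clears 10,000×) are
flagged, never silently dropped.

**Cohort analysis.** Duplicate biopsies (individual assignment is an
input; genotyping is upstream of this package) are merged by the mean
of reported ages. Replicate concordance is the absolute difference of
the two reported ages per duplicated individual. Age structure uses
half-open 5-year bins [0,5), [5,10), … labelled "0.00–4.99",
"5.00–9.99", …; the peak is the argmax with ties to the youngest bin.
Five years approximates the age at sexual maturity in this species,
making the first bin a sexually-immature class. Mother–calf sighting
annotations are echoed through to reports; no kinship inference is
performed.

## The simulator

The simulator exists because no raw reads are public for this assay;
it generates the study conditions so the read stages are testable
against exact ground truth.

**References.** The gene-specific primer sequences and universal tails
are the real assay primers; amplicon interiors are synthetic random
sequence (no amplicon sequences or genomic coordinates are published),
with CpG dinucleotides only where planted and never inside a
primer-binding region. Site names "+202/+297/+31" are display labels
bound to reference offsets. Defaults: GRIA2 230 bp (5 CpGs), CDKN2A
260 bp (4), TET2 210 bp (3) — long enough that a 250 bp × 2 pair spans
each with a wide overlap, short enough that reads run through into the
3′ adapter and exercise the trimmer. The primers' top-strand
projections contain no cytosine (they are bisulfite-PCR primers), so
conversion never perturbs the primer-matching ends.

**Cohort.** Default shape mirrors the real biopsy series: 21
individuals, 4 duplicated (25 samples), 15 males/6 females, ages
uniform in [2, 31] years. Per-sample methylation is constructed by
*inverting the clock*: y and z are drawn uniformly inside the assay's
empirically observed ranges (CDKN2A 1.34–4.64 %, TET2 5.59–19.19 %) and
x is solved so the clock returns the true age exactly; draws requiring
x outside [0, 100] % are redrawn (bounded retries). Every generated
sample therefore satisfies clock(100·fractions) = true age to < 0.005
years, an invariant the suite asserts. Background (non-target) CpGs
default to 2 % methylation.

**Reads.** Per molecule: the target-CpG cytosine stays C with
probability equal to the methylation fraction, otherwise converts C→T
with the conversion efficiency (default 1.0; lowering it models
incomplete conversion, which inflates apparent methylation — restriction
fragmentation before treatment is not simulated since its only effect
is through this parameter). Every other unmethylated cytosine converts
likewise. R1 = molecule + reverse-complemented reverse tail, R2 =
reverse complement + forward tail, both cut to 250 bp (padded with A
beyond the adapter). Substitution errors are planted uniformly at the
configured rate, independently per mate; qualities follow a flat-Q35
profile with an optional linear 3′ decay ramp (used in tests to
exercise the Q20 trimmer — planted errors deliberately do *not* lower
quality, so the quality string carries no information about them). No
indels, no index hopping, no chimeras. The exact count of molecules
presenting C at each target CpG is recorded per gene: with zero error
and full conversion the pipeline must recover
methylated_molecules/emitted_reads *exactly*, and does.

**What passing simulation tests does not show.** The simulator draws
reads i.i.d. from a single molecule population; real libraries have PCR
duplicates and amplification bias, strand-specific error profiles,
quality-correlated errors, and context-dependent conversion failure.
Exactness on simulation validates the bookkeeping and the counting
logic, not robustness to those artefacts. With sequencing error ε > 0,
the called frequency estimates f + (ε/3)(1 − 2f) rather than f (C↔T
error flips), a +0.15 percentage-point shift at ε = 0.005 for small f —
negligible against binomial noise at the coverages used here, and the
stochastic tests budget 3 binomial standard deviations accordingly.

## Problem sizes and seeds

End-to-end checks run the default 25-sample cohort at 2,000 reads per
gene and amplicon (150,000 pairs per condition, error-free and
ε = 0.005), chosen to keep binomial noise well inside the assertion
envelopes while the whole suite stays interactive on one core. All
randomness flows through explicit integer seeds (one per operation;
pipeline stages derive per-sample seeds from the master seed), and
FASTQ output is byte-identical under a fixed seed.

## Known limitations

- The clock is applied, not validated: no known-age individuals exist
  in this package's scope, so accuracy claims inherit entirely from the
  original calibration.
- Ungapped alignment cannot place reads with indels; real MiSeq indel
  rates are low but nonzero.
- The quality model is synthetic; the Q20 filter is exercised by a
  configurable ramp, not by realistic error-quality correlation.
- Summary statistics operate on reported (2-decimal) values by design;
  downstream users wanting full-precision propagation should work from
  `AgeEstimate.age_raw`.
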