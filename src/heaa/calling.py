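"""Bisulfite-aware alignment and per-CpG methylation calling.

Bisulfite treatment converts unmethylated cytosine to uracil (read as
T); methylated cytosine stays C.  Alignment of a converted read against
the untreated reference therefore uses an asymmetric match rule:

* read base == reference base        -> match
* read 'T' against reference 'C'     -> bisulfite match (converted)
* anything else                      -> hard mismatch

Only the original top strand is assayed (primer-defined amplicons), and
alignment is ungapped: candidate placements are every offset at which
the read fits fully inside a reference.  The placement with the fewest
hard mismatches wins, ties broken by reference order then smallest
offset.

Methylation at a CpG is then a per-read vote: 'C' at the site counts as
methylated, 'T' as unmethylated, and any other base (sequencing error)
is excluded from coverage entirely.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .amplicons import AmpliconReference
from .reads import MergedRead

__all__ = [
    "BisulfiteAlignment",
    "CpGCall",
    "NoCallError",
    "bisulfite_align",
    "align_reads",
    "call_cpg",
    "sample_frequencies",
    "DEFAULT_COVERAGE_FLOOR",
]

#: QC floor for coverage in synthetic runs; real assay data clears
#: 10,000x easily, synthetic cohorts are run far shallower.
DEFAULT_COVERAGE_FLOOR = 1000

_C = ord("C")
_T = ord("T")


@dataclass(frozen=True)
class BisulfiteAlignment:
    """Placement of one read on one amplicon under the C->T-tolerant rule."""

    read_id: str
    gene_name: str
    offset: int
    n_bs_matches: int
    n_hard_mismatches: int
    aligned: bool


class NoCallError(ValueError):
    """Raised when a CpG has zero usable coverage (distinct from 0 %)."""


@dataclass(frozen=True)
class CpGCall:
    """Methylation call at one CpG of one sample."""

    sample_id: str
    gene_name: str
    site_label: str
    methylated: int
    unmethylated: int
    low_coverage: bool = False

    @property
    def coverage(self) -> int:
        return self.methylated + self.unmethylated

    @property
    def frequency(self) -> float:
        """DNAm frequency in percent."""
        if self.coverage == 0:
            raise NoCallError(f"no coverage at {self.site_label}")
        return 100.0 * self.methylated / self.coverage


class _RefIndex:
    """Per-reference sliding windows, cached by read length."""

    def __init__(self, ref: AmpliconReference):
        self.ref = ref
        self.arr = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
        self._windows: dict[int, np.ndarray] = {}

    def windows(self, read_len: int) -> np.ndarray | None:
        if read_len > len(self.arr):
            return None
        w = self._windows.get(read_len)
        if w is None:
            w = np.lib.stride_tricks.sliding_window_view(self.arr, read_len)
            self._windows[read_len] = w
        return w


def _score(read_arr: np.ndarray, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard mismatches and bisulfite matches per candidate offset."""
    bs = (windows == _C) & (read_arr == _T)
    hard = (windows != read_arr) & ~bs
    return hard.sum(axis=1), bs.sum(axis=1)


def bisulfite_align(
    read: MergedRead,
    refs: list[AmpliconReference],
    max_mismatch_frac: float = 0.1,
    _indexes: list[_RefIndex] | None = None,
) -> BisulfiteAlignment:
    """Place a merged read on the best-matching amplicon reference.

    All offsets at which the read fits fully inside a reference are
    scored; the fewest-hard-mismatch placement wins, ties broken by
    reference order then smallest offset.  A best placement whose hard
    mismatch fraction exceeds ``max_mismatch_frac`` is reported with
    ``aligned=False`` (never raised: unalignable reads are counted and
    dropped by the pipeline).
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    indexes = _indexes or [_RefIndex(r) for r in refs]
    read_arr = np.frombuffer(read.bases.encode(), dtype=np.uint8)
    best: tuple[int, int, int, int] | None = None  # (hard, ref_idx, offset, bs)
    for ri, idx in enumerate(indexes):
        w = idx.windows(len(read_arr))
        if w is None:
            continue
        hard, bs = _score(read_arr, w)
        off = int(hard.argmin())
        cand = (int(hard[off]), ri, off, int(bs[off]))
        if best is None or cand[:3] < best[:3]:
            best = cand
        if best[0] == 0:
            break
    if best is None:
        return BisulfiteAlignment(read.read_id, "", 0, 0, 0, aligned=False)
    n_hard, ri, off, n_bs = best
    ok = n_hard / len(read_arr) <= max_mismatch_frac
    return BisulfiteAlignment(
        read_id=read.read_id,
        gene_name=refs[ri].gene_name,
        offset=off,
        n_bs_matches=n_bs,
        n_hard_mismatches=n_hard,
        aligned=ok,
    )


def align_reads(
    reads: list[MergedRead],
    refs: list[AmpliconReference],
    max_mismatch_frac: float = 0.1,
) -> list[BisulfiteAlignment]:
    """Align a batch of merged reads; identical sequences are scored once.

    Amplicon data is massively redundant (a handful of methylation
    patterns per gene), so alignments are computed per distinct base
    string and fanned back out.
    """
    indexes = [_RefIndex(r) for r in refs]
    cache: dict[str, BisulfiteAlignment] = {}
    out: list[BisulfiteAlignment] = []
    for read in reads:
        hit = cache.get(read.bases)
        if hit is None:
            hit = bisulfite_align(read, refs, max_mismatch_frac, _indexes=indexes)
            cache[read.bases] = hit
        out.append(
            BisulfiteAlignment(
                read.read_id,
                hit.gene_name,
                hit.offset,
                hit.n_bs_matches,
                hit.n_hard_mismatches,
                hit.aligned,
            )
        )
    return out


def call_cpg(
    alignments: list[BisulfiteAlignment],
    reads: list[MergedRead],
    ref: AmpliconReference,
    site: int,
    sample_id: str = "",
    coverage_floor: int = DEFAULT_COVERAGE_FLOOR,
) -> CpGCall:
    """Count methylated/unmethylated molecules at one CpG site.

    For every aligned read covering ``site``: 'C' votes methylated, 'T'
    votes unmethylated, any other base is excluded from coverage (a
    sequencing error cannot be interpreted as a conversion state).
    Calls below ``coverage_floor`` are flagged, never dropped.

    Raises
    ------
    NoCallError
        If no read yields a usable base at the site; distinct from a
        well-covered site with frequency 0.
    """
    if site not in ref.cpg_positions:
        raise ValueError(f"site {site} is not an annotated CpG of {ref.gene_name}")
    by_id = {}
    for read in reads:
        by_id[read.read_id] = read
    meth = unmeth = 0
    for aln in alignments:
        if not aln.aligned or aln.gene_name != ref.gene_name:
            continue
        read = by_id[aln.read_id]
        pos = site - aln.offset
        if not 0 <= pos < len(read.bases):
            continue
        b = read.bases[pos]
        if b == "C":
            meth += 1
        elif b == "T":
            unmeth += 1
        # other bases: sequencing error, excluded from coverage
    if meth + unmeth == 0:
        raise NoCallError(
            f"zero usable coverage at {ref.site_label} for sample {sample_id!r}"
        )
    return CpGCall(
        sample_id=sample_id,
        gene_name=ref.gene_name,
        site_label=ref.site_label,
        methylated=meth,
        unmethylated=unmeth,
        low_coverage=(meth + unmeth) < coverage_floor,
    )


def sample_frequencies(
    calls: list[CpGCall],
    genes: tuple[str, str, str] = ("GRIA2", "CDKN2A", "TET2"),
) -> tuple[tuple[float, float, float], dict[str, int]]:
    """Clock inputs (x, y, z) for one sample from its per-gene calls.

    Returns the target-site DNAm frequencies (%) ordered as the clock
    expects — (GRIA2, CDKN2A, TET2) — plus per-gene coverage for QC.
    Input order is irrelevant; a missing or duplicated gene is an error.
    """
    counts = Counter(c.gene_name for c in calls)
    missing = [g for g in genes if counts[g] == 0]
    if missing:
        raise ValueError(f"missing call(s) for gene(s): {', '.join(missing)}")
    dupes = [g for g in genes if counts[g] > 1]
    if dupes:
        raise ValueError(f"multiple calls for gene(s): {', '.join(dupes)}")
    by_gene = {c.gene_name: c for c in calls}
    freqs = tuple(by_gene[g].frequency for g in genes)
    coverage = {g: by_gene[g].coverage for g in genes}
    return freqs, coverage
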