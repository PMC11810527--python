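"""Read-level processing: adapter trimming, quality filtering, pair merging.

Native, deterministic analogues of the three pre-alignment stages of a
paired-end amplicon workflow:

1. :func:`trim_adapter` — exact-match removal of 3' read-through adapter
   (full internal occurrences and partial suffix overlaps).
2. :func:`quality_filter` — end-trimming at a Phred threshold with a
   minimum surviving length; reads of length <= ``min_len`` are
   discarded (a 40 bp read is dropped at the default threshold; 41 bp
   is kept).
3. :func:`merge_pair` — quality-aware overlap merging of a read pair
   into one fragment, taking the longest admissible overlap.

These are intentionally simple and fully reproducible: amplicon pairs
span the whole insert, so sliding-window trimming and probabilistic
overlap scoring buy nothing here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .amplicons import reverse_complement

__all__ = ["ReadRecord", "MergedRead", "trim_adapter", "quality_filter", "merge_pair"]

DISCARD = None  #: sentinel meaning the read failed the length filter
UNMERGED = None  #: sentinel meaning no admissible overlap was found


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: bases over {A,C,G,T,N} and per-base Phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, stop: int) -> "ReadRecord":
        return ReadRecord(self.read_id, self.bases[start:stop], self.quals[start:stop])


@dataclass(frozen=True)
class MergedRead:
    """A merged pair: consensus bases/quals plus overlap diagnostics."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    overlap_len: int
    mismatches_in_overlap: int

    def __len__(self) -> int:
        return len(self.bases)


def trim_adapter(read: ReadRecord, adapter: str, min_match: int = 3) -> ReadRecord:
    """Remove 3' adapter sequence from a read.

    If the full adapter occurs anywhere in the read, the read is
    truncated at the occurrence's start (read-through into adapter and
    beyond).  Otherwise the longest read suffix that exactly matches a
    prefix of the adapter, of length >= ``min_match``, is removed.
    Qualities are trimmed in lockstep.  Reads without adapter signal are
    returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_match < 3:
        raise ValueError("min_match must be >= 3")
    hit = read.bases.find(adapter)
    if hit >= 0:
        return read.slice(0, hit)
    longest = min(len(read), len(adapter) - 1)
    for k in range(longest, min_match - 1, -1):
        if read.bases.endswith(adapter[:k]):
            return read.slice(0, len(read) - k)
    return read


def quality_filter(
    read: ReadRecord, min_q: int = 20, min_len: int = 40
) -> ReadRecord | None:
    """End-trim low-quality bases; drop short survivors.

    Bases are trimmed from the 3' end, then the 5' end, while the
    terminal base quality is <= ``min_q``.  If the surviving read length
    is <= ``min_len`` the read is discarded (``None``); note the
    boundary is inclusive: a read of exactly ``min_len`` bases is
    dropped.
    """
    end = len(read)
    while end > 0 and read.quals[end - 1] <= min_q:
        end -= 1
    start = 0
    while start < end and read.quals[start] <= min_q:
        start += 1
    if end - start <= min_len:
        return DISCARD
    return read.slice(start, end)


def _count_mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance with early exit once `limit` is exceeded."""
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def merge_pair(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> MergedRead | None:
    """Merge a read pair via its 3' overlap; ``None`` if none admissible.

    ``r2`` is the raw second read and is reverse-complemented here.
    Overlap lengths are scanned from the longest possible down to
    ``min_overlap``; the first (longest) overlap whose mismatch fraction
    is <= ``max_mismatch_frac`` is accepted.  Within the overlap the
    higher-quality base wins disagreements (ties go to read 1, making
    the output a pure function of input order); consensus quality is the
    maximum of the two at agreements and the winner's at disagreements.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    b2 = reverse_complement(r2.bases)
    q2 = r2.quals[::-1]
    n1, n2 = len(r1), len(r2)
    for ov in range(min(n1, n2), min_overlap - 1, -1):
        limit = int(max_mismatch_frac * ov)
        tail1 = r1.bases[n1 - ov :]
        head2 = b2[:ov]
        mm = _count_mismatches(tail1, head2, limit)
        if mm > limit:
            continue
        cons: list[str] = []
        consq: list[int] = []
        for i in range(ov):
            a, b = tail1[i], head2[i]
            qa, qb = r1.quals[n1 - ov + i], q2[i]
            if a == b:
                cons.append(a)
                consq.append(max(qa, qb))
            elif qb > qa:
                cons.append(b)
                consq.append(qb)
            else:
                cons.append(a)
                consq.append(qa)
        bases = r1.bases[: n1 - ov] + "".join(cons) + b2[ov:]
        quals = r1.quals[: n1 - ov] + tuple(consq) + q2[ov:]
        return MergedRead(
            read_id=r1.read_id,
            bases=bases,
            quals=quals,
            overlap_len=ov,
            mismatches_in_overlap=mm,
        )
    return UNMERGED
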