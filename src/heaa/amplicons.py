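"""Synthetic amplicon references for the three-gene methylation assay.

The assay targets single CpG sites in promoter fragments of *GRIA2*,
*CDKN2A* and *TET2*, amplified by a two-round PCR whose first-round
primers carry universal tails (the sequencing adapters).  The primer
sequences are real assay primers; the amplicon interiors are synthetic,
since no genomic coordinates or amplicon sequences are published.  The
conventional site names ("+202", "+297", "+31") are display labels bound
to a reference offset, not genomic coordinates.

References are constructed so that

* the forward primer is a prefix of the top strand and the reverse
  complement of the reverse primer is its suffix,
* CpG dinucleotides occur only where planted, never inside a
  primer-binding region, and
* a 250 bp x 2 paired read fully spans the amplicon.

The gene-specific primers are bisulfite-PCR primers: their top-strand
projections contain no cytosine, so conversion chemistry cannot alter
the primer-matching ends of a molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ADAPTER_FWD",
    "ADAPTER_REV",
    "GENE_PRIMERS",
    "TARGET_SITE_LABELS",
    "AmpliconReference",
    "build_reference",
    "default_references",
    "reverse_complement",
]

#: Universal first-PCR primer tails (Illumina-style adapters); shared by
#: all three genes.  These are what adapter trimming removes.
ADAPTER_FWD = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"
ADAPTER_REV = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"

#: Gene-specific first-PCR primer portions (5'->3', excluding the tails).
GENE_PRIMERS: dict[str, tuple[str, str]] = {
    "GRIA2": ("GTGTGTGAGTGTATGGG", "CCCTATTTCCCAAATCCTAC"),
    "CDKN2A": ("AATGATTTTTGGTAAAGGGGAGAT", "CCCCATATACTTTTCAATCCTCC"),
    "TET2": ("GTGGTTAAAGTAAATAGAAGGT", "CAAAAACACTCCCCAATTTC"),
}

#: Conventional display labels of the assayed CpG per gene.
TARGET_SITE_LABELS: dict[str, str] = {
    "GRIA2": "+202",
    "CDKN2A": "+297",
    "TET2": "+31",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconReference:
    """One amplicon's top-strand reference and CpG annotation.

    ``cpg_positions`` are 0-based offsets of the 'C' of each CpG;
    ``target_site`` is the single assayed CpG among them.
    ``site_label`` is the display name, e.g. ``"GRIA2+202"``.
    """

    gene_name: str
    sequence: str
    cpg_positions: tuple[int, ...]
    target_site: int
    fwd_primer: str
    rev_primer: str
    adapter_fwd: str = ADAPTER_FWD
    adapter_rev: str = ADAPTER_REV
    site_label: str = field(default="")

    def __post_init__(self) -> None:
        if not 120 <= len(self.sequence) <= 500:
            raise ValueError("amplicon length must be in [120, 500]")
        for p in self.cpg_positions:
            if self.sequence[p : p + 2] != "CG":
                raise ValueError(f"position {p} is not a CpG 'C'")
        if self.target_site not in self.cpg_positions:
            raise ValueError("target_site must be one of cpg_positions")
        if not self.sequence.startswith(self.fwd_primer):
            raise ValueError("forward primer must be a prefix of the reference")
        if not self.sequence.endswith(reverse_complement(self.rev_primer)):
            raise ValueError(
                "reverse complement of reverse primer must be a suffix"
            )
        if not self.site_label:
            object.__setattr__(
                self,
                "site_label",
                f"{self.gene_name}{TARGET_SITE_LABELS.get(self.gene_name, '')}"
                or self.gene_name,
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def non_cpg_c_positions(self) -> tuple[int, ...]:
        """Offsets of cytosines outside annotated CpGs (conversion-prone)."""
        return tuple(
            i
            for i, b in enumerate(self.sequence)
            if b == "C" and i not in self.cpg_positions
        )


def build_reference(
    gene_name: str,
    length: int = 220,
    n_cpgs: int = 4,
    target_index: int = 1,
    seed: int = 0,
) -> AmpliconReference:
    """Construct a synthetic amplicon reference for one gene.

    The interior between the primer-binding ends is random sequence with
    exactly ``n_cpgs`` planted CpG dinucleotides (no accidental CpGs),
    the ``target_index``-th of which is designated as the assayed site.
    Deterministic for a given ``seed``.

    Raises
    ------
    ValueError
        If the geometry is impossible (length out of [120, 500], too
        many CpGs, primers longer than the requested amplicon).
    """
    if not 120 <= length <= 500:
        raise ValueError("length must be in [120, 500]")
    if not 1 <= n_cpgs <= length // 10:
        raise ValueError("n_cpgs must be in [1, length/10]")
    if not 0 <= target_index < n_cpgs:
        raise ValueError("target_index must be in [0, n_cpgs)")
    if gene_name in GENE_PRIMERS:
        fwd, rev = GENE_PRIMERS[gene_name]
    else:  # non-default gene: borrow the GRIA2 primer pair
        fwd, rev = GENE_PRIMERS["GRIA2"]
    suffix = reverse_complement(rev)
    interior_len = length - len(fwd) - len(suffix)
    # Each CpG needs 2 bases plus a spacer so plantings cannot collide.
    if interior_len < 3 * n_cpgs + 2:
        raise ValueError(
            f"cannot place {n_cpgs} CpGs in a {interior_len} bp interior"
        )

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    interior = list(rng.choice(bases, size=interior_len))
    # Remove accidental CpGs so the annotation is exhaustive.
    for i in range(interior_len - 1):
        if interior[i] == "C" and interior[i + 1] == "G":
            interior[i + 1] = "A"
    # Junctions with the primer ends could also form CpGs.
    if fwd.endswith("C") and interior[0] == "G":
        interior[0] = "A"
    if interior[-1] == "C" and suffix.startswith("G"):
        interior[-1] = "A"

    # Plant CpGs evenly across the interior, >=1 base apart.
    slots = np.linspace(1, interior_len - 3, num=n_cpgs)
    cpg_local = [int(round(s)) for s in slots]
    for k in range(1, len(cpg_local)):  # enforce spacing on tiny interiors
        cpg_local[k] = max(cpg_local[k], cpg_local[k - 1] + 3)
    if cpg_local[-1] > interior_len - 3:
        raise ValueError("CpG placement exceeded interior")
    for p in cpg_local:
        interior[p] = "C"
        interior[p + 1] = "G"
        if interior[p - 1] == "C":  # avoid creating an unannotated CpG
            interior[p - 1] = "A"
        if p + 2 < interior_len and interior[p + 2] == "G":
            pass  # GG after the planted CpG is harmless

    sequence = fwd + "".join(interior) + suffix
    cpg_positions = tuple(len(fwd) + p for p in cpg_local)
    return AmpliconReference(
        gene_name=gene_name,
        sequence=sequence,
        cpg_positions=cpg_positions,
        target_site=cpg_positions[target_index],
        fwd_primer=fwd,
        rev_primer=rev,
    )


def default_references(seed: int = 20180103) -> list[AmpliconReference]:
    """The three default assay amplicons (GRIA2, CDKN2A, TET2).

    Lengths are chosen so a 250 bp x 2 pair spans each amplicon with a
    long overlap and reads run through into the 3' adapter, exercising
    adapter trimming.
    """
    rng = np.random.default_rng(seed)
    specs = [("GRIA2", 230, 5, 2), ("CDKN2A", 260, 4, 1), ("TET2", 210, 3, 0)]
    return [
        build_reference(g, length, n, t, seed=int(rng.integers(2**31)))
        for g, length, n, t in specs
    ]
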