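"""Individual-level cohort analysis and age-structure construction.

Duplicate biopsies of the same whale (matched by genotype upstream; the
pipeline receives the individual assignment in the sample sheet) are
merged by averaging their reported ages.  The cohort is then summarised
overall and per sex, and binned into 5-year age classes — the increment
conventionally used to split humpback whales at the approximate age of
sexual maturity (~5 years).

All statistics are computed from the 2-decimal *reported* ages, in exact
decimal arithmetic, so the numbers printed here match what a reader
recomputes from a published table by hand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .clock import AgeEstimate, mean_reported, round_half_up

__all__ = [
    "Individual",
    "CohortSummary",
    "merge_duplicates",
    "replicate_concordance",
    "cohort_summary",
    "bin_ages",
    "frequency_table_summary",
]


@dataclass(frozen=True)
class Individual:
    """One whale: its biopsy samples and consensus (mean) reported age."""

    individual_id: str
    sex: str
    sample_ids: tuple[str, ...]
    sample_ages: tuple[float, ...]
    consensus_age: float
    annotation: str = ""


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level age statistics and the 5-year age structure."""

    n_individuals: int
    age_min: float
    age_max: float
    age_mean: float
    by_sex: dict[str, dict[str, float]]
    bin_labels: tuple[str, ...]
    bin_counts: tuple[int, ...]
    peak_bin_label: str


def merge_duplicates(
    estimates: Sequence[AgeEstimate],
    sample_sheet: pd.DataFrame,
) -> list[Individual]:
    """Collapse per-sample age estimates to per-individual consensus ages.

    ``sample_sheet`` must map every estimate's ``sample_id`` to an
    ``individual_id`` and ``sex`` (an ``annotation`` column, if present,
    is echoed through).  The consensus age is the mean of the rounded
    per-sample ages, re-rounded to 2 decimals.  Conflicting sex entries
    within one individual are a data-integrity error.
    """
    sheet = sample_sheet.set_index("sample_id")
    groups: dict[str, list[AgeEstimate]] = {}
    order: list[str] = []
    for est in estimates:
        if est.sample_id not in sheet.index:
            raise KeyError(f"sample {est.sample_id!r} missing from sample sheet")
        ind = str(sheet.loc[est.sample_id, "individual_id"])
        if ind not in groups:
            groups[ind] = []
            order.append(ind)
        groups[ind].append(est)

    individuals = []
    for ind in order:
        ests = groups[ind]
        sexes = {str(sheet.loc[e.sample_id, "sex"]) for e in ests}
        if len(sexes) != 1:
            raise ValueError(
                f"individual {ind!r} has conflicting sex entries: {sorted(sexes)}"
            )
        ages = tuple(e.age for e in ests)
        notes = ""
        if "annotation" in sheet.columns:
            vals = {
                str(sheet.loc[e.sample_id, "annotation"])
                for e in ests
                if str(sheet.loc[e.sample_id, "annotation"]) not in ("", "nan")
            }
            notes = "; ".join(sorted(vals))
        individuals.append(
            Individual(
                individual_id=ind,
                sex=sexes.pop(),
                sample_ids=tuple(e.sample_id for e in ests),
                sample_ages=ages,
                consensus_age=mean_reported(ages),
                annotation=notes,
            )
        )
    return individuals


def replicate_concordance(
    individuals: Iterable[Individual],
) -> tuple[float | None, float | None, dict[str, float]]:
    """Absolute age differences between duplicate biopsies per individual.

    Returns ``(min, max, per-individual diffs)`` over individuals with
    exactly two samples; all three are empty/None when the cohort has no
    duplicates.
    """
    diffs: dict[str, float] = {}
    for ind in individuals:
        if len(ind.sample_ages) == 2:
            a, b = ind.sample_ages
            diffs[ind.individual_id] = round_half_up(abs(a - b))
    if not diffs:
        return None, None, {}
    return min(diffs.values()), max(diffs.values()), diffs


def cohort_summary(
    individuals: Sequence[Individual],
    bin_width: float = 5.0,
) -> CohortSummary:
    """Overall and per-sex age statistics plus the binned age structure."""
    if not individuals:
        raise ValueError("cohort is empty")
    ages = [ind.consensus_age for ind in individuals]
    by_sex: dict[str, dict[str, float]] = {}
    for sex in dict.fromkeys(ind.sex for ind in individuals):
        sub = [i.consensus_age for i in individuals if i.sex == sex]
        by_sex[sex] = {
            "n": len(sub),
            "age_min": min(sub),
            "age_max": max(sub),
            "age_mean": mean_reported(sub),
        }
    labels, counts, peak = bin_ages(individuals, width=bin_width)
    return CohortSummary(
        n_individuals=len(individuals),
        age_min=min(ages),
        age_max=max(ages),
        age_mean=mean_reported(ages),
        by_sex=by_sex,
        bin_labels=labels,
        bin_counts=counts,
        peak_bin_label=peak,
    )


def bin_ages(
    individuals: Sequence[Individual],
    width: float = 5.0,
) -> tuple[tuple[str, ...], tuple[int, ...], str]:
    """Histogram of consensus ages over half-open ``[k·w, (k+1)·w)`` bins.

    Labels follow the display convention "a.00–b.99" (so the bin
    [10, 15) reads "10.00–14.99").  The peak is the argmax count, ties
    going to the youngest bin.  Negative consensus ages (possible for
    extreme TET2 frequencies) land in the lowest bin.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    if not individuals:
        raise ValueError("cohort is empty")
    ages = [ind.consensus_age for ind in individuals]
    n_bins = max(int(math.floor(max(ages) / width)) + 1, 1)
    counts = [0] * n_bins
    for a in ages:
        counts[max(0, int(math.floor(a / width)))] += 1
    labels = tuple(
        f"{k * width:.2f}–{(k + 1) * width - 0.01:.2f}" for k in range(n_bins)
    )
    peak = labels[max(range(n_bins), key=lambda k: (counts[k], -k))]
    return labels, tuple(counts), peak


def frequency_table_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene min/max/mean of DNAm frequency and coverage across samples.

    ``records`` is long-format with columns ``sample_id``, ``gene``,
    ``frequency`` (%), ``coverage``.  Summaries are per biopsy sample —
    duplicates are deliberately not merged.  Frequency statistics are
    reported to 2 decimals, coverage to the nearest integer.
    """
    required = {"gene", "frequency", "coverage"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    rows = []
    for gene, grp in records.groupby("gene", sort=False):
        rows.append(
            {
                "gene": gene,
                "n": len(grp),
                "freq_min": round_half_up(grp["frequency"].min()),
                "freq_max": round_half_up(grp["frequency"].max()),
                "freq_mean": mean_reported(grp["frequency"]),
                "coverage_min": int(grp["coverage"].min()),
                "coverage_max": int(grp["coverage"].max()),
                "coverage_mean": int(round_half_up(grp["coverage"].mean(), 0)),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
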