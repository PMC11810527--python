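"""Humpback Epigenetic Age Assay (HEAA).

The HEAA is a three-site linear epigenetic clock for humpback whales
(*Megaptera novaeangliae*).  It maps DNA-methylation frequencies (in
percent) at single CpG sites in the promoters of three age-associated
genes to chronological age in years:

    age = 5.4717 x + 3.9705 y - 0.6793 z + 1.4695

where ``x``, ``y`` and ``z`` are the DNAm frequencies (%) at
GRIA2+202, CDKN2A+297 and TET2+31 respectively.  The coefficients were
calibrated elsewhere on whales of known age and are treated as fixed
constants here; this module does no refitting.

A fixed-half-width 95 % confidence interval is attached to every point
estimate.  The half-width is 4.47 years; only the lower bound is clamped
at zero (point estimates below the half-width are reported as computed).

Reported values are rounded half-away-from-zero to two decimals at the
reporting boundary only; all internal arithmetic is double precision.
Rounding and the mean of already-reported values are carried out in
exact decimal arithmetic, because e.g. mean(15.53, 14.02) = 14.775 must
report as 14.78, which float64 arithmetic misses by one ulp.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

__all__ = [
    "COEF_GRIA2",
    "COEF_CDKN2A",
    "COEF_TET2",
    "INTERCEPT",
    "CI_HALF_WIDTH",
    "AgeEstimate",
    "heaa_age",
    "attach_ci",
    "estimate_age",
    "round_half_up",
    "mean_reported",
]

#: Clock coefficients (years per percentage point of DNAm frequency).
COEF_GRIA2 = 5.4717
COEF_CDKN2A = 3.9705
COEF_TET2 = -0.6793
#: Clock intercept (years).
INTERCEPT = 1.4695

#: Half-width of the 95 % confidence interval attached to every point
#: estimate (years).  The published interval width is 8.94 years.
CI_HALF_WIDTH = 4.47


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half-away-from-zero to `ndigits` decimals, exactly.

    Operates on the shortest decimal representation of ``value`` so that
    quantities that are exact in decimal (e.g. 14.775) round the way a
    human reading the printed number would round them.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def mean_reported(values: Iterable[float], ndigits: int = 2) -> float:
    """Mean of already-rounded (reported) values, re-rounded to `ndigits`.

    The mean is taken in exact decimal arithmetic over the reported
    2-decimal values, matching how summary statistics are quoted.
    """
    decs = [Decimal(repr(float(v))) for v in values]
    if not decs:
        raise ValueError("mean of empty sequence")
    q = Decimal(1).scaleb(-ndigits)
    return float((sum(decs) / len(decs)).quantize(q, rounding=ROUND_HALF_UP))


def heaa_age(x: float, y: float, z: float) -> float:
    """Point age (years) from DNAm frequencies in percent.

    Parameters are the DNAm frequencies (%) at GRIA2+202 (`x`),
    CDKN2A+297 (`y`) and TET2+31 (`z`).  Returns the full-precision
    linear-model output; round with :func:`round_half_up` for reporting.
    High ``z`` can drive the estimate negative — negative values are
    returned as computed, never clamped.
    """
    for name, v in (("x", x), ("y", y), ("z", z)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(
                f"{name}={v!r}: DNAm frequencies are percentages in [0, 100]"
            )
    return COEF_GRIA2 * x + COEF_CDKN2A * y + COEF_TET2 * z + INTERCEPT


def attach_ci(age: float, half_width: float = CI_HALF_WIDTH) -> tuple[float, float]:
    """95 % confidence interval (lower clamped at 0) around a point age.

    Only the lower bound is clamped; the point estimate itself is not.
    """
    lo = max(0.0, age - half_width)
    hi = age + half_width
    return round_half_up(lo), round_half_up(hi)


@dataclass(frozen=True)
class AgeEstimate:
    """One biopsy sample's clock inputs and age estimate.

    ``age`` is the reported (2-decimal) point estimate; ``age_raw`` the
    full-precision model output.  ``ci_low``/``ci_high`` are the fixed
    half-width interval around the reported age.
    """

    sample_id: str
    x: float
    y: float
    z: float
    age: float
    ci_low: float
    ci_high: float
    age_raw: float

    @property
    def negative(self) -> bool:
        """True when the raw model output is below zero (flagged, kept)."""
        return self.age_raw < 0.0


def estimate_age(
    sample_id: str,
    x: float,
    y: float,
    z: float,
    half_width: float = CI_HALF_WIDTH,
) -> AgeEstimate:
    """Apply the clock to one sample and attach the confidence interval.

    The interval is centred on the reported (rounded) age so that
    reported age and bounds are mutually consistent on the page.
    """
    raw = heaa_age(x, y, z)
    age = round_half_up(raw)
    lo, hi = attach_ci(age, half_width)
    return AgeEstimate(
        sample_id=sample_id, x=x, y=y, z=z,
        age=age, ci_low=lo, ci_high=hi, age_raw=raw,
    )
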