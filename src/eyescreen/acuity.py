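"""Distance visual acuity: Snellen notation, logMAR conversion, thresholds.

Snellen acuity ``m/d`` means the subject resolves at ``m`` metres what a
standard eye resolves at ``d`` metres.  The canonical internal scale is
logMAR, ``log10(d/m)``: 6/6 is 0.0, 6/60 is 1.0, and *larger logMAR is
worse vision*.  Ordering and thresholding are always done on logMAR, so
"6/12", "5/10" and "3/6" are one and the same acuity.

All acuities here are presenting (unaided, as-measured) values; the
distinction between presenting and best-corrected acuity is outside this
module's scope.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from functools import total_ordering

__all__ = [
    "VisualAcuity",
    "AcuityBand",
    "AcuityParseError",
    "parse_snellen",
    "worse_than",
    "acuity_band",
    "SNELLEN_LINES",
]

_SNELLEN_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*/\s*(\d+(?:\.\d+)?)\s*$")

#: Discrete Snellen chart lines used for sampling and display, best to worst.
SNELLEN_LINES: tuple[str, ...] = (
    "6/6", "6/9", "6/12", "6/18", "6/24", "6/36", "6/60", "3/60", "2/60", "1/60",
)


class AcuityParseError(ValueError):
    """Raised when a Snellen string cannot be parsed into an acuity."""


@total_ordering
@dataclass(frozen=True)
class VisualAcuity:
    """A distance visual acuity measurement.

    Parameters
    ----------
    numerator : float
        Test distance in metres (conventionally 6). Must be positive.
    denominator : float
        Snellen denominator in metres. Must be positive.

    Attributes
    ----------
    logmar : float
        ``log10(denominator / numerator)``; dimensionless, higher is worse.

    Ordering compares logMAR, so ``a < b`` means *a is better vision than b*.
    """

    numerator: float
    denominator: float
    logmar: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (self.numerator > 0 and self.denominator > 0):
            raise AcuityParseError(
                f"Snellen fraction parts must be positive, got "
                f"{self.numerator}/{self.denominator}"
            )
        object.__setattr__(self, "logmar", math.log10(self.denominator / self.numerator))

    def __str__(self) -> str:
        def fmt(x: float) -> str:
            return str(int(x)) if float(x).is_integer() else str(x)

        return f"{fmt(self.numerator)}/{fmt(self.denominator)}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VisualAcuity):
            return NotImplemented
        return math.isclose(self.logmar, other.logmar, abs_tol=1e-12)

    def __lt__(self, other: "VisualAcuity") -> bool:
        return self.logmar < other.logmar and self != other

    def __hash__(self) -> int:
        return hash(round(self.logmar, 12))


class AcuityBand(str, enum.Enum):
    """Reporting bands for better-eye presenting acuity."""

    NORMAL_6_6_TO_6_12 = "normal_6_6_to_6_12"
    IMPAIRED_6_18_TO_6_60 = "impaired_6_18_to_6_60"
    SEVERE_BELOW_6_60 = "severe_below_6_60"
    NOT_ASSESSED = "not_assessed"


def parse_snellen(text: str) -> VisualAcuity:
    """Parse a Snellen string like ``"6/12"`` into a :class:`VisualAcuity`.

    Raises :class:`AcuityParseError` on malformed input or non-positive parts,
    naming the offending token.
    """
    if not isinstance(text, str):
        raise AcuityParseError(f"expected a Snellen string, got {text!r}")
    m = _SNELLEN_RE.match(text)
    if m is None:
        raise AcuityParseError(f"malformed Snellen acuity {text!r}")
    num, den = float(m.group(1)), float(m.group(2))
    if num <= 0:
        raise AcuityParseError(f"non-positive test distance {m.group(1)!r} in {text!r}")
    if den <= 0:
        raise AcuityParseError(f"non-positive denominator {m.group(2)!r} in {text!r}")
    return VisualAcuity(num, den)


def worse_than(va: VisualAcuity, threshold: VisualAcuity) -> bool:
    """True iff ``va`` is *strictly* worse (higher logMAR) than ``threshold``.

    The referral rule is "less than 6/12": acuity exactly at the threshold
    does not trigger, so ``worse_than(6/12, 6/12)`` is False.
    """
    return va.logmar > threshold.logmar and va != threshold

# Band edges are the printed ones: 6/12 closes the normal band, 6/18 and
# 6/60 both belong to the impaired band.
_BAND_NORMAL_MAX = parse_snellen("6/12")
_BAND_IMPAIRED_MAX = parse_snellen("6/60")


def acuity_band(better_eye: VisualAcuity | None) -> AcuityBand:
    """Classify a better-eye acuity into a reporting band.

    ``None`` (vision not assessed, i.e. children under 6) maps to
    :attr:`AcuityBand.NOT_ASSESSED`.  Bands partition the acuity line:
    6/6-6/12, 6/18-6/60, worse than 6/60.
    """
    if better_eye is None:
        return AcuityBand.NOT_ASSESSED
    if not worse_than(better_eye, _BAND_NORMAL_MAX):
        return AcuityBand.NORMAL_6_6_TO_6_12
    if not worse_than(better_eye, _BAND_IMPAIRED_MAX):
        return AcuityBand.IMPAIRED_6_18_TO_6_60
    return AcuityBand.SEVERE_BELOW_6_60
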