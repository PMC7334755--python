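"""Diagnostic-accuracy statistics for index-vs-reference referral decisions.

Covers the 2x2 machinery of a screening validation: confusion tables,
sensitivity/specificity/PPV/NPV with exact (Clopper-Pearson) binomial
confidence intervals, percent agreement and Cohen's kappa, reconstruction of
a 2x2 table from published marginals, precision-driven sample size
(Buderer's method), odds ratios, and logistic regression.

Conventions: the *reference* standard defines the rows (tp+fn = reference
positives), the *index* test the columns.  Percentages are displayed at one
decimal place, kappa and odds ratios at two, rounding half up.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "ConfusionTable",
    "ProportionEstimate",
    "AgreementResult",
    "AgreementBand",
    "AccuracySummary",
    "LogisticFit",
    "OddsRatioResult",
    "UndefinedMetricError",
    "ReconstructionError",
    "build_confusion",
    "accuracy_summary",
    "exact_binomial_ci",
    "cohen_kappa",
    "percent_agreement",
    "reconstruct_2x2",
    "sample_size_sensitivity",
    "achieved_half_width",
    "fit_logistic",
    "odds_ratio_2x2",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, matching clinical-report display."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; the value is undefined, not fabricated."""


class ReconstructionError(ValueError):
    """Printed marginals and agreement are mutually inconsistent."""


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-classification of reference vs index referral decisions.

    ``tp``: reference refer & index refer; ``fn``: reference refer & index
    not; ``fp``: reference not & index refer; ``tn``: neither refers.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def reference_positives(self) -> int:
        return self.tp + self.fn

    @property
    def reference_negatives(self) -> int:
        return self.fp + self.tn

    @property
    def index_positives(self) -> int:
        return self.tp + self.fp

    @property
    def index_negatives(self) -> int:
        return self.fn + self.tn

    def transpose(self) -> "ConfusionTable":
        """Swap the roles of index and reference (fn <-> fp)."""
        return ConfusionTable(self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with an exact confidence interval."""

    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    @property
    def percent(self) -> float:
        """Point estimate as a percentage at the 1 d.p. display precision."""
        return round_half_up(100.0 * self.point, 1)

    def __str__(self) -> str:
        return (f"{self.percent:.1f}% "
                f"({round_half_up(100 * self.ci_low, 1):.1f}-"
                f"{round_half_up(100 * self.ci_high, 1):.1f})")


class AgreementBand(str, enum.Enum):
    """Verbal bands for kappa used in the study's reporting scheme."""

    POOR = "poor"            # < 0.41
    MODERATE = "moderate"    # 0.41-0.60
    FAIR = "fair"            # 0.61-0.80 (sic: the scheme ranks fair above moderate)
    GOOD = "good"            # >= 0.81


@dataclass(frozen=True)
class AgreementResult:
    observed_agreement: float
    expected_agreement: float
    kappa: float
    band: AgreementBand


@dataclass(frozen=True)
class AccuracySummary:
    """Sensitivity, specificity and predictive values of one 2x2 table.

    A metric whose denominator is zero is ``None`` (undefined), never a
    fabricated number.
    """

    sensitivity: ProportionEstimate | None
    specificity: ProportionEstimate | None
    ppv: ProportionEstimate | None
    npv: ProportionEstimate | None

    def as_dict(self) -> dict[str, ProportionEstimate | None]:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "ppv": self.ppv, "npv": self.npv}


def build_confusion(index_decisions: Sequence[bool],
                    reference_decisions: Sequence[bool]) -> ConfusionTable:
    """Cross-tabulate paired index and reference referral decisions."""
    if len(index_decisions) != len(reference_decisions):
        raise ValueError(
            f"length mismatch: {len(index_decisions)} index vs "
            f"{len(reference_decisions)} reference decisions"
        )
    tp = fn = fp = tn = 0
    for pos, (idx, ref) in enumerate(zip(index_decisions, reference_decisions)):
        if idx is None or ref is None:
            raise ValueError(f"missing decision at record position {pos}")
        if ref:
            tp, fn = (tp + 1, fn) if idx else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if idx else (fp, tn + 1)
    return ConfusionTable(tp, fn, fp, tn)


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for a binomial proportion.

    Obtained by inverting the binomial tail probabilities, i.e. beta
    quantiles: low = Beta(alpha/2; k, n-k+1), high = Beta(1-alpha/2; k+1, n-k),
    with the degenerate endpoints 0 at k=0 and 1 at k=n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def _proportion(k: int, n: int, level: float) -> ProportionEstimate:
    low, high = exact_binomial_ci(k, n, level)
    return ProportionEstimate(k, n, k / n, low, high, level)


def accuracy_summary(t: ConfusionTable, level: float = 0.95) -> AccuracySummary:
    """Sensitivity, specificity, PPV and NPV with Clopper-Pearson intervals.

    sensitivity = tp/(tp+fn), specificity = tn/(fp+tn), ppv = tp/(tp+fp),
    npv = tn/(fn+tn); any metric with a zero denominator is returned as None.
    """
    def safe(k: int, n: int) -> ProportionEstimate | None:
        return _proportion(k, n, level) if n > 0 else None

    return AccuracySummary(
        sensitivity=safe(t.tp, t.reference_positives),
        specificity=safe(t.tn, t.reference_negatives),
        ppv=safe(t.tp, t.index_positives),
        npv=safe(t.tn, t.index_negatives),
    )


def percent_agreement(t: ConfusionTable) -> float:
    """Raw observed agreement (tp+tn)/N between the two raters."""
    if t.total == 0:
        raise UndefinedMetricError("agreement undefined for an empty table")
    return (t.tp + t.tn) / t.total


def _kappa_band(kappa: float) -> AgreementBand:
    # Band on the displayed (2 d.p.) value, matching how the scheme is quoted.
    k = round_half_up(kappa, 2)
    if k >= 0.81:
        return AgreementBand.GOOD
    if k >= 0.61:
        return AgreementBand.FAIR
    if k >= 0.41:
        return AgreementBand.MODERATE
    return AgreementBand.POOR


def cohen_kappa(t: ConfusionTable) -> AgreementResult:
    """Cohen's chance-corrected agreement for a 2x2 decision table.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and p_e
    the marginal-product chance agreement.  Degenerate marginals with
    p_e = 1 leave kappa undefined.
    """
    n = t.total
    if n == 0:
        raise UndefinedMetricError("kappa undefined for an empty table")
    po = percent_agreement(t)
    pe = (t.reference_positives * t.index_positives
          + t.reference_negatives * t.index_negatives) / (n * n)
    if pe >= 1.0:
        raise UndefinedMetricError(
            "kappa undefined: chance agreement is 1 (degenerate marginals)"
        )
    kappa = (po - pe) / (1.0 - pe)
    return AgreementResult(po, pe, kappa, _kappa_band(kappa))


def reconstruct_2x2(n: int, rater_a_pos: int, rater_b_pos: int,
                    percent_agreement: float) -> ConfusionTable:
    """Recover the unique 2x2 table from published marginals and agreement.

    With concordant count ``c = round(agreement * n)``, the both-positive
    cell is ``a = (rater_a_pos + rater_b_pos - (n - c)) / 2``; the rest
    follow from the marginals.  Inconsistent inputs (non-integer or negative
    cell) raise :class:`ReconstructionError` naming the violated constraint.
    """
    if n <= 0:
        raise ReconstructionError(f"n must be positive, got {n}")
    if not 0.0 <= percent_agreement <= 1.0:
        raise ReconstructionError(f"agreement must be in [0,1], got {percent_agreement}")
    if not (0 <= rater_a_pos <= n and 0 <= rater_b_pos <= n):
        raise ReconstructionError("rater positive counts must be within [0, n]")
    c = round_half_up(percent_agreement * n)
    if abs(c - percent_agreement * n) > 0.5 + 1e-9:
        raise ReconstructionError("agreement does not correspond to a count")
    c = int(c)
    two_a = rater_a_pos + rater_b_pos - (n - c)
    if two_a % 2 != 0:
        raise ReconstructionError(
            f"parity violation: marginals ({rater_a_pos}, {rater_b_pos}) and "
            f"concordant count {c} do not admit an integer both-positive cell"
        )
    a = two_a // 2
    tp, fn, fp = a, rater_a_pos - a, rater_b_pos - a
    tn = n - tp - fn - fp
    for name, v in (("tp", tp), ("fn", fn), ("fp", fp), ("tn", tn)):
        if v < 0:
            raise ReconstructionError(
                f"cell {name} = {v} < 0: marginals and agreement are inconsistent"
            )
    return ConfusionTable(tp, fn, fp, tn)


def sample_size_sensitivity(target_sens: float, half_width: float,
                            prevalence: float, level: float = 0.95
                            ) -> tuple[int, int]:
    """Required (cases, total n) to estimate sensitivity to a given precision.

    Buderer's method: cases = ceil(z^2 s(1-s) / d^2) reference positives are
    needed for a Wald half-width d around sensitivity s, and the total sample
    is n = ceil(cases / prevalence).
    """
    for name, v in (("target_sens", target_sens), ("half_width", half_width),
                    ("prevalence", prevalence), ("level", level)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {v}")
    z = sps.norm.ppf(1 - (1 - level) / 2)
    cases = math.ceil(z * z * target_sens * (1 - target_sens) / half_width ** 2)
    return cases, math.ceil(cases / prevalence)


def achieved_half_width(target_sens: float, cases: int, level: float = 0.95) -> float:
    """Wald half-width attained with a given number of reference positives."""
    if cases < 1:
        raise ValueError(f"cases must be >= 1, got {cases}")
    z = sps.norm.ppf(1 - (1 - level) / 2)
    return float(z * math.sqrt(target_sens * (1 - target_sens) / cases))


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression summary.

    Arrays are ordered (intercept, covariates...).  ``odds_ratios`` are
    exp(coef); intervals and p-values are Wald-based at the fit's level.
    """

    params: np.ndarray
    std_errors: np.ndarray
    odds_ratios: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    p_values: np.ndarray
    level: float
    n_obs: int


class SeparationError(RuntimeError):
    """The likelihood is unbounded (complete separation) or the fit diverged."""


def fit_logistic(outcomes: Sequence[int] | np.ndarray,
                 covariates: Sequence[Sequence[float]] | np.ndarray,
                 level: float = 0.95) -> LogisticFit:
    """Fit a logistic regression of a binary outcome on covariates.

    An intercept is always prepended.  The maximum-likelihood fit (Newton /
    iteratively reweighted least squares) must converge; separation or
    non-convergence raises :class:`SeparationError` rather than returning a
    silently unstable result.
    """
    y = np.asarray(outcomes, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("outcomes and covariates must have matching length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcomes must be binary (0/1)")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, Xc).fit(disp=0, tol=1e-10, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as e:
        raise SeparationError(str(e)) from e
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge")
    if not np.all(np.isfinite(res.bse)):
        raise SeparationError("infinite standard errors: separation suspected")
    z = sps.norm.ppf(1 - (1 - level) / 2)
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    return LogisticFit(
        params=params,
        std_errors=bse,
        odds_ratios=np.exp(params),
        or_ci_low=np.exp(params - z * bse),
        or_ci_high=np.exp(params + z * bse),
        p_values=np.asarray(res.pvalues),
        level=level,
        n_obs=int(res.nobs),
    )


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    level: float
    continuity_corrected: bool


def odds_ratio_2x2(a: int, b: int, c: int, d: int,
                   level: float = 0.95) -> OddsRatioResult:
    """Odds ratio (a*d)/(b*c) with a log-scale Wald interval.

    When any cell is zero, 0.5 is added to every cell (Haldane-Anscombe
    continuity correction) and the result is flagged as corrected.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"cell {name} must be non-negative, got {v}")
    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = ((x + 0.5) for x in (a, b, c, d)) if corrected else (a, b, c, d)
    or_ = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = sps.norm.ppf(1 - (1 - level) / 2)
    return OddsRatioResult(
        odds_ratio=or_,
        ci_low=math.exp(math.log(or_) - z * se),
        ci_high=math.exp(math.log(or_) + z * se),
        level=level,
        continuity_corrected=corrected,
    )
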