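"""Method-agreement and reliability statistics for repeated index measurements.

Implements the battery used in method-comparison studies of morphometric
indices: intraclass correlation coefficients (ICC) from Shrout–Fleiss ANOVA
mean squares with Landis–Koch verbal interpretation, Bland–Altman limits of
agreement, Pearson correlation, paired mean comparison with a
normality-driven branch, Shapiro–Wilk / Lilliefors normality tests,
pathological/normal × sex proportion tables, and an a-priori sample-size
helper parameterized by the effect size η².
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.power import FTestAnovaPower

from .geometry import IndexMeasurement, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "RatingsTable",
    "ICCResult",
    "BlandAltmanResult",
    "CorrelationResult",
    "PairedComparisonResult",
    "SampleSizeSpec",
    "icc",
    "interpret_agreement",
    "bland_altman",
    "pearson",
    "paired_comparison",
    "normality_test",
    "proportion_table",
    "required_sample_size",
    "round_half_up",
]

ICC_MODELS = ("oneway_random", "twoway_random_absolute", "twoway_mixed_consistency")
ICC_UNITS = ("single", "average")

#: Landis–Koch interpretation buckets, upper edge inclusive.  Estimates below
#: 0.01 (including negative ones) are "poor".
_LANDIS_KOCH = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass(frozen=True)
class RatingsTable:
    """A complete subjects × raters (or subjects × repeats) block of ratings."""

    values: np.ndarray
    modality: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise InputError("ratings must be a 2-D subjects x raters array")
        if arr.shape[0] < 2:
            raise InputError("need at least 2 subjects")
        if arr.shape[1] < 2:
            raise InputError("need at least 2 raters/repeats")
        if not np.all(np.isfinite(arr)):
            raise InputError("ratings table contains missing or non-finite cells")
        object.__setattr__(self, "values", arr)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    model: str
    unit: str
    band: str
    anova_mean_squares: dict
    degenerate: bool = False


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    z: float
    outlier_ids: tuple
    n: int
    diffs: np.ndarray = field(repr=False)
    means: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation; ``r_squared`` is always the square of ``r``."""

    r: float
    p_value: float
    n: int
    r_squared: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_squared", self.r * self.r)


@dataclass(frozen=True)
class PairedComparisonResult:
    p_value: float
    statistic: float
    test: str  # "paired_t" or "wilcoxon"
    normality_p: float
    degenerate: bool = False


@dataclass(frozen=True)
class SampleSizeSpec:
    """A-priori sample-size request: η² effect size, power 1−β and α."""

    eta_squared: float
    power: float = 0.9
    alpha: float = 0.05
    assumed_test: str = "oneway_anova_2groups"

    def __post_init__(self) -> None:
        if not 0 < self.eta_squared < 1:
            raise InputError("eta_squared must be in (0, 1)")
        if not 0 < self.power < 1:
            raise InputError("power must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise InputError("alpha must be in (0, 1)")


def _anova_mean_squares(x: np.ndarray) -> dict:
    """Two-way crossed ANOVA mean squares for an n × k ratings table.

    MSB/MSR: between-subjects (rows); MSC: between-raters (columns);
    MSE: interaction/residual; MSW: within-subjects pooled over raters.
    """
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    ss_within = ss_total - ss_rows
    return {
        "MSR": ss_rows / (n - 1),
        "MSC": ss_cols / (k - 1),
        "MSE": ss_err / ((n - 1) * (k - 1)),
        "MSW": ss_within / (n * (k - 1)),
    }


def icc(
    table: RatingsTable,
    model: str = "twoway_random_absolute",
    unit: str = "single",
) -> ICCResult:
    """Intraclass correlation coefficient from ANOVA mean squares.

    Shrout–Fleiss forms: ``oneway_random`` → ICC(1), ``twoway_random_absolute``
    → ICC(2) (absolute agreement), ``twoway_mixed_consistency`` → ICC(3)
    (consistency); ``unit`` selects single-measure or average-of-k forms.
    A table with zero between-subject variance carries no reliability signal:
    the estimate is returned as 0 with ``degenerate=True`` and a warning.
    """
    if model not in ICC_MODELS:
        raise InputError(f"unknown ICC model {model!r}")
    if unit not in ICC_UNITS:
        raise InputError(f"unknown ICC unit {unit!r}")
    x = table.values
    n, k = x.shape
    ms = _anova_mean_squares(x)
    msr, msc, mse, msw = ms["MSR"], ms["MSC"], ms["MSE"], ms["MSW"]

    if msr <= 1e-300:
        logger.warning("zero between-subject variance: ICC undefined, returning 0")
        return ICCResult(0.0, model, unit, interpret_agreement(0.0), ms, degenerate=True)

    if model == "oneway_random":
        if unit == "single":
            est = (msr - msw) / (msr + (k - 1) * msw)
        else:
            est = (msr - msw) / msr
    elif model == "twoway_random_absolute":
        if unit == "single":
            est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        else:
            est = (msr - mse) / (msr + (msc - mse) / n)
    else:  # twoway_mixed_consistency
        if unit == "single":
            est = (msr - mse) / (msr + (k - 1) * mse)
        else:
            est = (msr - mse) / msr
    est = float(est)
    return ICCResult(est, model, unit, interpret_agreement(est), ms)


def interpret_agreement(estimate: float) -> str:
    """Landis–Koch verbal band for an agreement coefficient.

    Below 0.01 (including negative estimates): "poor"; then slight
    (0.01–0.20), fair (0.21–0.40), moderate (0.41–0.60), substantial
    (0.61–0.80), almost perfect (0.81–1.00); bucket upper edges inclusive.
    """
    if estimate > 1.0:
        raise InputError(f"agreement estimate {estimate} exceeds 1")
    if estimate < 0.01:
        return "poor"
    for upper, label in _LANDIS_KOCH:
        if estimate <= upper:
            return label
    return "almost perfect"  # unreachable; estimate <= 1 guaranteed


def bland_altman(
    a: Sequence[float],
    b: Sequence[float],
    z: float = 1.96,
    ids: Sequence | None = None,
) -> BlandAltmanResult:
    """Bland–Altman agreement of two paired measurement series (diffs a − b).

    Limits of agreement are mean ± z·SD with the sample SD (n−1 denominator);
    outliers are the subjects whose difference falls strictly outside the
    closed interval [loa_low, loa_high].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired series must be 1-D and of equal length")
    if a.size < 2:
        raise InputError("need at least 2 pairs")
    if ids is None:
        ids = np.arange(a.size)
    ids = np.asarray(ids)
    if ids.size != a.size:
        raise InputError("ids length mismatch")
    diffs = a - b
    means = (a + b) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    lo, hi = mean_diff - z * sd_diff, mean_diff + z * sd_diff
    outside = (diffs < lo) | (diffs > hi)
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=lo,
        loa_high=hi,
        z=z,
        outlier_ids=tuple(ids[outside].tolist()),
        n=int(a.size),
        diffs=diffs,
        means=means,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with two-sided p-value (t distribution, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise InputError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=int(x.size))


def paired_comparison(a: Sequence[float], b: Sequence[float]) -> PairedComparisonResult:
    """Test H0: mean(a − b) = 0.

    Uses the paired t-test when the differences pass Shapiro–Wilk normality
    (p > 0.05), otherwise the Wilcoxon signed-rank test; the branch taken is
    reported.  All-zero differences return p = 1 with a degenerate flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired series must be 1-D and of equal length")
    if a.size < 3:
        raise InputError("need at least 3 pairs")
    d = a - b
    if np.allclose(d, 0.0):
        return PairedComparisonResult(1.0, 0.0, "paired_t", 1.0, degenerate=True)
    sw_stat, sw_p = stats.shapiro(d)
    if sw_p > 0.05:
        t, p = stats.ttest_rel(a, b)
        return PairedComparisonResult(float(p), float(t), "paired_t", float(sw_p))
    w, p = stats.wilcoxon(a, b)
    return PairedComparisonResult(float(p), float(w), "wilcoxon", float(sw_p))


def normality_test(
    x: Sequence[float], method: str = "shapiro_wilk"
) -> tuple[float, float]:
    """Normality test: Shapiro–Wilk, or Kolmogorov–Smirnov with the
    Lilliefors correction for estimated mean/SD.  Returns (statistic, p)."""
    x = np.asarray(x, dtype=float)
    if method == "shapiro_wilk":
        if x.size < 3:
            raise InputError("Shapiro-Wilk needs at least 3 observations")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-constant input warnings
            stat, p = stats.shapiro(x)
        return float(stat), float(p)
    if method == "kolmogorov_smirnov":
        if x.size < 5:
            raise InputError("Lilliefors-corrected KS needs at least 5 observations")
        stat, p = lilliefors(x, dist="norm")
        return float(stat), float(p)
    raise InputError(f"unknown normality test {method!r}")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the convention of printed clinical tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def proportion_table(
    measurements: Sequence[IndexMeasurement],
    sex: Mapping[str, str],
) -> dict:
    """Pathological/normal × male/female counts and percentages.

    ``measurements`` holds one consensus measurement per patient (a single
    modality); ``sex`` maps patient_id → "male"/"female".  Percentages use
    round-half-up to one decimal; within-classification sex percentages use
    the subgroup size as denominator, matching clinical table conventions.
    """
    table: dict = {}
    n_total = len(measurements)
    for label in ("pathological", "normal"):
        group = [m for m in measurements if m.classification == label]
        n = len(group)
        by_sex = {"male": 0, "female": 0}
        for m in group:
            s = sex.get(m.patient_id)
            if s not in by_sex:
                raise InputError(f"unknown sex label {s!r} for patient {m.patient_id}")
            by_sex[s] += 1
        table[label] = {
            "n": n,
            "percent": round_half_up(100.0 * n / n_total, 1) if n_total else 0.0,
            "male": {
                "n": by_sex["male"],
                "percent": round_half_up(100.0 * by_sex["male"] / n, 1) if n else 0.0,
            },
            "female": {
                "n": by_sex["female"],
                "percent": round_half_up(100.0 * by_sex["female"] / n, 1) if n else 0.0,
            },
        }
    table["n_total"] = n_total
    return table


def required_sample_size(spec: SampleSizeSpec) -> int:
    """Smallest total n reaching the requested power for the assumed test.

    The effect size is converted via Cohen's f² = η² / (1 − η²); the default
    assumed test is a one-way ANOVA with two groups (the specific test family
    behind a given published a-priori calculation is a configuration choice
    and is recorded on the spec).
    """
    if spec.assumed_test != "oneway_anova_2groups":
        raise InputError(f"unsupported assumed test {spec.assumed_test!r}")
    f = math.sqrt(spec.eta_squared / (1.0 - spec.eta_squared))
    solver = FTestAnovaPower()
    nobs = solver.solve_power(
        effect_size=f, alpha=spec.alpha, power=spec.power, k_groups=2
    )
    if not np.isfinite(nobs) or nobs <= 0:
        raise InputError("requested power unreachable for this effect size")
    n = int(math.ceil(nobs))
    # ceil can overshoot the grid by one; walk down to the true minimum
    while n > 4 and solver.power(effect_size=f, nobs=n - 1, alpha=spec.alpha, k_groups=2) >= spec.power:
        n -= 1
    return n
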