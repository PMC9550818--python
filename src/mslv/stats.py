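"""Cohort-level statistics.

Everything the shoulder-imbalance analysis needs: 2x2 odds ratios with Woolf
(log-normal) confidence intervals, Fisher's exact test, Welch's t-test, the
exact Mann-Whitney U test, Cohen's kappa, and maximum-likelihood logistic
regression (IRLS) with Wald intervals.

Conventions
-----------
The 2x2 table rows are (unmatched, matched) and columns (imbalanced,
balanced), so the odds ratio (a*d)/(b*c) is the odds of shoulder imbalance
in the unmatched group relative to the matched group.  No multiple-testing
adjustment is applied anywhere; p < 0.05 is the significance convention of
the downstream report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.inter_rater import cohens_kappa

from .errors import InsufficientDataError, SeparationError, ZeroCellError

log = logging.getLogger(__name__)

#: Two-sided 95% normal quantile used for Wald-type intervals.
Z_95 = sps.norm.ppf(0.975)  # 1.959964...


# --------------------------------------------------------------------------
# Shoulder imbalance
# --------------------------------------------------------------------------

#: |RSH| threshold (mm) defining shoulder imbalance at follow-up.
IMBALANCE_THRESHOLD_MM = 10.0


def shoulder_imbalance(rsh_2yr: float) -> bool:
    """Shoulder imbalance: absolute radiographic shoulder height >= 10 mm."""
    return bool(abs(rsh_2yr) >= IMBALANCE_THRESHOLD_MM)


# --------------------------------------------------------------------------
# 2x2 tables
# --------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class ContingencyTable2x2:
    """Counts: a = unmatched & imbalanced, b = unmatched & balanced,
    c = matched & imbalanced, d = matched & balanced."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if sum(cells) < 1:
            raise ValueError("table total must be at least 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True, slots=True)
class ORResult:
    """Odds ratio with a Woolf (log-normal) confidence interval."""

    or_point: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    continuity_corrected: bool = False


def odds_ratio_woolf(
    t: ContingencyTable2x2, conf: float = 0.95, continuity: bool = False
) -> ORResult:
    """Cross-product odds ratio with the Woolf CI
    exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).

    Zero cells raise :class:`ZeroCellError` unless ``continuity=True``, in
    which case 0.5 is added to every cell (with a logged warning).
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = False
    if min(a, b, c, d) == 0.0:
        if not continuity:
            raise ZeroCellError(f"zero cell in table ({t.a},{t.b},{t.c},{t.d})")
        log.warning(
            "zero cell in 2x2 table (%d,%d,%d,%d); applying +0.5 continuity correction",
            t.a, t.b, t.c, t.d,
        )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    orp = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = sps.norm.ppf(0.5 + conf / 2.0)
    return ORResult(
        or_point=orp,
        ci_low=math.exp(math.log(orp) - z * se),
        ci_high=math.exp(math.log(orp) + z * se),
        conf_level=conf,
        continuity_corrected=corrected,
    )


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (probability-mass method: the sum of
    hypergeometric probabilities no larger than the observed table's, over
    all tables with the same margins)."""
    return float(sps.fisher_exact(t.as_array(), alternative="two-sided")[1])


# --------------------------------------------------------------------------
# Two-sample tests
# --------------------------------------------------------------------------


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("Welch t-test needs at least 2 observations per group")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if np.mean(x) == np.mean(y):
            # Degenerate but well-defined: identical constant samples.
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise InsufficientDataError("both samples have zero variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True, slots=True)
class MannWhitneyResult:
    u: float
    p: float
    mode: str  # "exact" or "asymptotic"


def mann_whitney(x, y, exact_max_n: int = 12) -> MannWhitneyResult:
    """Mann-Whitney U test.

    Exact p by enumeration of rank assignments when the combined sample size
    is at most *exact_max_n* and there are no ties; otherwise the mid-rank
    statistic with the tie-corrected normal approximation.  The mode used is
    recorded in the result for reproducibility.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("Mann-Whitney needs non-empty samples")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= exact_max_n and not ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MannWhitneyResult(float(res.statistic), float(res.pvalue), "exact")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return MannWhitneyResult(float(res.statistic), min(1.0, float(res.pvalue)), "asymptotic")


# --------------------------------------------------------------------------
# Interobserver agreement
# --------------------------------------------------------------------------


def cohen_kappa(r1, r2) -> float:
    """Unweighted Cohen's kappa between two raters' label sequences.

    Returns NaN (undefined) when chance agreement is 1, i.e. both raters
    assign a single identical label throughout.
    """
    r1, r2 = list(r1), list(r2)
    if len(r1) != len(r2) or len(r1) == 0:
        raise InsufficientDataError("rater sequences must be equal-length and non-empty")
    labels = sorted(set(r1) | set(r2), key=str)
    if len(labels) == 1:
        return float("nan")  # p_e == 1: agreement beyond chance is undefined
    idx = {lab: k for k, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for a, b in zip(r1, r2):
        table[idx[a], idx[b]] += 1
    return float(cohens_kappa(table, return_results=False))


# --------------------------------------------------------------------------
# Logistic regression
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with per-predictor Wald summaries."""

    names: tuple[str, ...]
    coef: tuple[float, ...]  # log-odds scale
    wald_se: tuple[float, ...]
    or_point: tuple[float, ...]
    or_ci_low: tuple[float, ...]
    or_ci_high: tuple[float, ...]
    p_values: tuple[float, ...]
    converged: bool
    n_iter: int

    def by_name(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "coef": self.coef[i],
            "se": self.wald_se[i],
            "or": self.or_point[i],
            "ci": (self.or_ci_low[i], self.or_ci_high[i]),
            "p": self.p_values[i],
        }


#: Coefficient magnitude beyond which we call the fit separated: exp(15) is
#: an odds ratio above 3e6, far outside anything a 2x2-scale dataset supports.
_SEPARATION_COEF = 15.0


def logistic_fit(
    y,
    X,
    names: tuple[str, ...] | None = None,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> LogisticFit:
    """Binary logistic regression by iteratively reweighted least squares.

    *X* must already contain the intercept column.  Separation (diverging
    coefficients) and non-convergence raise :class:`SeparationError` rather
    than returning a silently unreliable fit.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one row per outcome")
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=max_iter, tol=tol, scale=1.0)
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if not res.converged:
        raise SeparationError("IRLS did not converge within the iteration budget")
    if np.any(np.abs(coef) > _SEPARATION_COEF) or np.any(~np.isfinite(se)):
        raise SeparationError("diverging coefficients: (quasi-)complete separation")
    ci = res.conf_int(alpha=0.05)
    ci = np.asarray(ci, dtype=float)
    return LogisticFit(
        names=tuple(names),
        coef=tuple(coef),
        wald_se=tuple(se),
        or_point=tuple(np.exp(coef)),
        or_ci_low=tuple(np.exp(ci[:, 0])),
        or_ci_high=tuple(np.exp(ci[:, 1])),
        p_values=tuple(np.asarray(res.pvalues, dtype=float)),
        converged=bool(res.converged),
        n_iter=int(res.fit_history["iteration"]),
    )


def expand_table(t: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """Expand a 2x2 table into per-subject (y, X) arrays for logistic
    regression: y = imbalanced, x = unmatched indicator (with intercept)."""
    y = np.concatenate(
        [np.ones(t.a), np.zeros(t.b), np.ones(t.c), np.zeros(t.d)]
    )
    x = np.concatenate(
        [np.ones(t.a + t.b), np.zeros(t.c + t.d)]
    )
    X = np.column_stack([np.ones_like(x), x])
    return y, X


# --------------------------------------------------------------------------
# Display rounding (report layer)
# --------------------------------------------------------------------------


def format_ratio(x: float) -> str:
    """Two decimals below 10, three significant figures at or above 10 —
    matching the usual journal display of odds ratios and their bounds."""
    if not math.isfinite(x):
        return "NA"
    if abs(x) < 10.0:
        return f"{x:.2f}"
    return f"{float(f'{x:.3g}'):g}"
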