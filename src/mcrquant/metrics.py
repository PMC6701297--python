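"""Figures of merit, recovery, precision, and method-comparison statistics.

Prediction quality for n samples with known concentrations c_i and
predictions chat_i:

    RMSEP = sqrt( sum (c_i - chat_i)^2 / n )
    bias  = sum (c_i - chat_i) / n
    SEP   = sqrt( sum (c_i - chat_i - bias)^2 / (n - 1) )
    RE%   = 100 * sqrt( sum (c_i - chat_i)^2 / sum c_i^2 )

together with the slope, intercept and r^2 of the least-squares line of
predicted on actual. The same formulas serve the cross-validated variant
(RMSECV) when the predictions come from leave-one-out folds. Note the
algebraic identity RMSEP^2 = bias^2 + SEP^2 * (n-1)/n.

Standard-addition recovery follows recovery% = 100 * (X - Y) / Z with X the
found concentration after spiking, Y before, and Z the spiked amount.

Method comparison against a reference assay uses the paired t-test on
per-replicate differences and the plain variance-ratio F = var_A / var_B in
the tabulation convention of analytical method-comparison tables (the ratio
is *not* reordered larger-over-smaller, so values below 1 occur); both are
judged against two-tailed t and upper-tail F critical values at the given
significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FiguresOfMerit",
    "RecoveryResult",
    "MethodComparison",
    "figures_of_merit",
    "recovery",
    "precision_rsd",
    "compare_methods",
    "f_from_sds",
]


@dataclass(frozen=True)
class FiguresOfMerit:
    rmsep: float
    sep: float
    bias: float
    re_pct: float
    r2: float
    slope: float
    intercept: float
    n: int


@dataclass(frozen=True)
class RecoveryResult:
    """One standard-addition determination at a spiking level (% of test
    concentration)."""

    level_pct: float
    found_after: float  # X, ug/mL
    found_before: float  # Y, ug/mL
    added: float  # Z, ug/mL
    recovery_pct: float


@dataclass(frozen=True)
class MethodComparison:
    t_stat: float
    f_stat: float
    t_crit: float
    f_crit: float
    alpha: float
    n1: int
    n2: int
    t_decision: str  # "difference" | "no-difference"
    f_decision: str


def figures_of_merit(actual, predicted) -> FiguresOfMerit:
    """Prediction figures of merit for one analyte."""
    c = np.asarray(actual, dtype=float)
    chat = np.asarray(predicted, dtype=float)
    if c.shape != chat.shape or c.ndim != 1:
        raise ValueError("actual and predicted must be equal-length vectors")
    n = len(c)
    if n < 2:
        raise ValueError("need at least 2 samples")
    ss_c = np.sum(c**2)
    if ss_c == 0:
        raise ValueError("relative error undefined: actual sum of squares is zero")
    err = c - chat
    rmsep = float(np.sqrt(np.sum(err**2) / n))
    bias = float(np.sum(err) / n)
    sep = float(np.sqrt(np.sum((err - bias) ** 2) / (n - 1)))
    re_pct = float(100.0 * np.sqrt(np.sum(err**2) / ss_c))
    if np.std(c) == 0 or np.std(chat) == 0:
        # degenerate regression (constant axis): define the line directly
        slope, intercept, r2 = 0.0, float(np.mean(chat)), 1.0 if rmsep == 0 else 0.0
    else:
        fit = stats.linregress(c, chat)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return FiguresOfMerit(rmsep, sep, bias, re_pct, r2, slope, intercept, n)


def recovery(found_after: float, found_before: float, added: float) -> float:
    """Standard-addition recovery%, 100 * (X - Y) / Z."""
    if added <= 0:
        raise ValueError("added amount Z must be positive")
    return 100.0 * (found_after - found_before) / added


def precision_rsd(replicate_sets) -> list[float]:
    """Relative standard deviation (%) per replicate group.

    ``replicate_sets`` is an iterable of groups (one per concentration
    level, or per level x day for between-day precision — the grouping is
    the caller's statement of what is being repeated). Sample standard
    deviation (n-1 denominator).
    """
    out = []
    for g, values in enumerate(replicate_sets):
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {g}: need at least 2 replicates")
        m = v.mean()
        if m == 0:
            raise ValueError(f"group {g}: zero mean, RSD undefined")
        out.append(float(100.0 * v.std(ddof=1) / m))
    return out


def f_from_sds(sd1: float, sd2: float) -> float:
    """Variance-ratio F statistic from two standard deviations: (sd1/sd2)^2."""
    if sd2 <= 0:
        raise ValueError("sd2 must be positive")
    return (sd1 / sd2) ** 2


def compare_methods(a, b, alpha: float = 0.05) -> MethodComparison:
    """Paired t and variance-ratio F comparison of two methods' replicates.

    ``a`` and ``b`` are paired replicate determinations (e.g. % recovery of
    the label claim) by the candidate and reference method. The F statistic
    is the plain ratio var(a)/var(b); its critical value is the upper-tail
    F quantile at ``alpha`` with (n1-1, n2-1) degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("replicate vectors must be 1-D")
    n1, n2 = len(a), len(b)
    if n1 != n2 or n1 < 2:
        raise ValueError("paired t-test needs equal-length replicate sets, n >= 2")
    var_b = np.var(b, ddof=1)
    if var_b == 0:
        raise ValueError("zero variance in reference replicates: F undefined")
    t_stat = float(stats.ttest_rel(a, b).statistic)
    f_stat = float(np.var(a, ddof=1) / var_b)
    t_crit = float(stats.t.ppf(1 - alpha / 2, n1 - 1))
    f_crit = float(stats.f.ppf(1 - alpha, n1 - 1, n2 - 1))
    return MethodComparison(
        t_stat=t_stat,
        f_stat=f_stat,
        t_crit=t_crit,
        f_crit=f_crit,
        alpha=alpha,
        n1=n1,
        n2=n2,
        t_decision="no-difference" if abs(t_stat) < t_crit else "difference",
        f_decision="no-difference" if f_stat < f_crit else "difference",
    )
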