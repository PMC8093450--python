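"""Statistical harness: task-accuracy scores, Anderson-Darling normality gate,
Friedman omnibus, Wilcoxon signed-rank, Spearman rank correlation, and
repeated-measures one-way ANOVA with partial eta squared.

The rank-based tests are implemented from their closed-form definitions (they
have exact small-sample oracles and the pipeline depends on their tie
conventions); the test suite cross-checks every one of them against the scipy
and pingouin reference implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from cogload.errors import DegenerateInputError

__all__ = [
    "ConfusionCounts",
    "TestReport",
    "accuracy_nback",
    "accuracy_arithmetic",
    "anderson_darling_normal",
    "friedman",
    "wilcoxon_signed_rank",
    "spearman",
    "rm_anova_oneway",
]


@dataclass
class ConfusionCounts:
    """Psychometric-task outcome tallies.

    correct: responses to targets; wrong: responses to non-targets (false
    alarms / wrong answers); avoid: correctly withheld responses; missed:
    targets without response.
    """

    correct: int
    wrong: int
    avoid: int = 0
    missed: int = 0

    def __post_init__(self) -> None:
        for name in ("correct", "wrong", "avoid", "missed"):
            if getattr(self, name) < 0:
                raise DegenerateInputError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.correct + self.wrong + self.avoid + self.missed


@dataclass
class TestReport:
    """Uniform result record for every statistical test in the harness."""

    test: str
    statistic: float
    df: tuple[float, ...] | float | None
    p_value: float
    effect_size: float | None = None
    n: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def accuracy_nback(c: ConfusionCounts) -> float:
    """N-back accuracy: (correct + avoid) / (correct + wrong + avoid + missed)."""
    if c.total <= 0:
        raise DegenerateInputError("accuracy_nback: zero total count")
    return (c.correct + c.avoid) / c.total


def accuracy_arithmetic(c: ConfusionCounts) -> float:
    """Arithmetic-test accuracy: correct / (correct + wrong)."""
    denom = c.correct + c.wrong
    if denom <= 0:
        raise DegenerateInputError("accuracy_arithmetic: correct + wrong is zero")
    return c.correct / denom


def anderson_darling_normal(x: np.ndarray) -> TestReport:
    """Anderson-Darling test of composite normality (mean and variance estimated).

    Uses the small-sample modification A*^2 = A^2 (1 + 0.75/n + 2.25/n^2) and
    the D'Agostino-Stephens p-value approximation for the estimated-parameters
    case.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 8:
        raise DegenerateInputError("anderson_darling_normal needs n >= 8")
    s = np.std(x, ddof=1)
    if s == 0:
        raise DegenerateInputError("anderson_darling_normal: constant sample")
    z = np.sort((x - x.mean()) / s)
    cdf = sstats.norm.cdf(z)
    eps = np.finfo(float).tiny
    cdf = np.clip(cdf, eps, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log(1 - cdf[::-1])))
    a2_star = a2 * (1 + 0.75 / n + 2.25 / n**2)
    if a2_star >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star > 0.34:
        p = np.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star > 0.2:
        p = 1 - np.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1 - np.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    p = float(np.clip(p, 0.0, 1.0))
    return TestReport(
        test="anderson_darling", statistic=float(a2), df=None, p_value=p, n=n,
        extras={"a2_star": float(a2_star)},
    )


def friedman(table: np.ndarray) -> TestReport:
    """Friedman chi-square test on a participants x conditions table.

    Within-row average ranks; chi^2 = 12/(n k (k+1)) * sum R_j^2 - 3 n (k+1),
    divided by the standard tie-correction factor. Rows containing NaN are
    dropped.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise DegenerateInputError("friedman expects a 2-D table")
    complete = np.isfinite(table).all(axis=1)
    table = table[complete]
    n, k = table.shape
    if k < 2 or n < 2:
        raise DegenerateInputError("friedman needs >=2 conditions and >=2 complete rows")
    ranks = np.apply_along_axis(sstats.rankdata, 1, table)
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:
        # every row fully tied: no rank information, chi2 is exactly 0
        return TestReport(
            test="friedman", statistic=0.0, df=float(k - 1), p_value=1.0,
            effect_size=0.0, n=n, extras={"rank_sums": rj.tolist()},
        )
    chi2 /= c
    df = k - 1
    p = float(sstats.chi2.sf(chi2, df))
    # Kendall's W as effect size
    w = chi2 / (n * (k - 1))
    return TestReport(
        test="friedman", statistic=float(chi2), df=float(df), p_value=p,
        effect_size=float(w), n=n, extras={"rank_sums": rj.tolist()},
    )


def _wilcoxon_exact_sf(n: int, w: float) -> float:
    """P(W+ <= w) under H0 for untied ranks 1..n, by dynamic programming."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: max_sum + 1 - r].copy()
    counts /= 2.0**n
    return float(counts[: int(np.floor(w)) + 1].sum())


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> TestReport:
    """Paired Wilcoxon signed-rank test.

    Zero differences are discarded; |differences| get average ranks. The
    statistic is W = min(W+, W-). For n <= 25 without ties the two-sided p is
    exact (full enumeration of sign assignments); otherwise the normal
    approximation with tie and continuity corrections is used. Both W and the
    normal deviate Z are reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DegenerateInputError("wilcoxon: a and b must be paired (equal length)")
    d = a - b
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateInputError("wilcoxon: all differences are zero")
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    has_ties = len(np.unique(np.abs(d))) < n
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        np.sum(tie_counts**3 - tie_counts)
    ) / 48.0
    sigma = np.sqrt(sigma2) if sigma2 > 0 else np.nan
    z = (abs(w - mu) - 0.5) / sigma if sigma2 > 0 else np.nan
    exact = (n <= 25) and not has_ties
    if exact:
        p = min(1.0, 2.0 * _wilcoxon_exact_sf(n, w))
    else:
        p = float(2.0 * sstats.norm.sf(z))
        p = min(1.0, p)
    return TestReport(
        test="wilcoxon_signed_rank", statistic=w, df=None, p_value=p, n=n,
        extras={
            "w_plus": w_plus,
            "w_minus": w_minus,
            "z": float(z),
            "exact": exact,
        },
    )


def spearman(x: np.ndarray, y: np.ndarray) -> TestReport:
    """Spearman rank correlation, rho = 1 - 6 sum(d_i^2)/(n^3 - n).

    Average ranks for ties; the closed-form rho is used when neither variable
    has ties (it is exact there), and the Pearson correlation of the ranks
    otherwise. Two-sided p by the t approximation with n - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DegenerateInputError("spearman: x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise DegenerateInputError("spearman needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("spearman: constant input, correlation undefined")
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    tied = len(np.unique(x)) < n or len(np.unique(y)) < n
    if not tied:
        d = rx - ry
        rho = 1.0 - 6.0 * float(np.sum(d**2)) / (n**3 - n)
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2.0 * sstats.t.sf(abs(t), n - 2))
    return TestReport(
        test="spearman", statistic=rho, df=float(n - 2), p_value=p,
        effect_size=rho, n=n,
    )


def rm_anova_oneway(table: np.ndarray) -> TestReport:
    """Repeated-measures one-way ANOVA with subject as blocking factor.

    F = MS_condition / MS_error with df (k-1, (k-1)(n-1)); effect size is
    partial eta squared, SS_cond / (SS_cond + SS_error). The table must be
    complete (no NaN); a perfectly additive table (SS_error = 0) is flagged
    degenerate with infinite F and p = 0.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise DegenerateInputError("rm_anova_oneway expects a 2-D table")
    if not np.isfinite(table).all():
        raise DegenerateInputError("rm_anova_oneway: missing cells (no imputation)")
    n, k = table.shape
    if k < 2 or n < 3:
        raise DegenerateInputError("rm_anova_oneway needs >=2 conditions, >=3 subjects")
    gm = table.mean()
    ss_cond = n * float(np.sum((table.mean(axis=0) - gm) ** 2))
    ss_subj = k * float(np.sum((table.mean(axis=1) - gm) ** 2))
    ss_total = float(np.sum((table - gm) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    eta2 = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    if ss_err <= 1e-12 * max(ss_total, 1.0):
        if ss_cond <= 1e-12 * max(ss_total, 1.0):
            # no variation beyond subjects at all
            return TestReport(
                test="rm_anova_oneway", statistic=0.0, df=(df1, df2), p_value=1.0,
                effect_size=0.0, n=n, extras={"degenerate": True},
            )
        return TestReport(
            test="rm_anova_oneway", statistic=float("inf"), df=(df1, df2),
            p_value=0.0, effect_size=1.0, n=n, extras={"degenerate": True},
        )
    f = (ss_cond / df1) / (ss_err / df2)
    p = float(sstats.f.sf(f, df1, df2))
    return TestReport(
        test="rm_anova_oneway", statistic=float(f), df=(float(df1), float(df2)),
        p_value=p, effect_size=float(eta2), n=n,
        extras={"ss_cond": ss_cond, "ss_subj": ss_subj, "ss_err": ss_err},
    )
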