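"""Summary statistics and hypothesis tests of the study design.

The experimental unit is the animal (one slice per animal); groups are
reported as mean +/- SEM with n animals. Single comparisons use paired or
unpaired (pooled-variance Student) t-tests; factorial comparisons (genotype
x treatment) use a between-subjects 2x2 ANOVA with the interaction computed
from the cell-mean contrast

    L = (m11 - m12) - (m21 - m22),    SS_int = L^2 / sum(1/n_ij),
    F = SS_int / MSE,   df = (1, N - 4),

which is the Type-III sum of squares for a 2x2 layout and stays exact under
unbalanced cell sizes. Both the t-test and the ANOVA accept either raw
values or printed summary statistics (mean, SEM, n), so figure-legend
statistics can be recomputed directly from published numbers. All p-values
are two-tailed; degenerate zero-variance inputs are reported as undefined
rather than as infinite statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "sem",
    "paired_t",
    "unpaired_t_raw",
    "unpaired_t_summary",
    "anova2x2",
    "Anova2x2Result",
    "bonferroni_posthoc",
    "correlate",
]


@dataclass
class GroupSummary:
    """Mean +/- SEM summary of one group (n animals)."""

    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sem < 0:
            raise ValueError("SEM must be >= 0")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)

    @classmethod
    def from_values(cls, label: str, values: np.ndarray) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        return cls(label, float(values.mean()), sem(values), len(values))


@dataclass
class TestResult:
    """Outcome of one hypothesis test (two-tailed throughout)."""

    statistic: float
    df: float | tuple[float, float]
    p: float
    comparison: str = ""
    kind: str = "t"
    adjusted_p: float | None = None
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined and not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @classmethod
    def undefined(cls, comparison: str = "", kind: str = "t") -> "TestResult":
        return cls(statistic=float("nan"), df=float("nan"), p=float("nan"),
                   comparison=comparison, kind=kind, defined=False)


def sem(values: np.ndarray) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("SEM needs at least 2 values")
    return float(values.std(ddof=1) / math.sqrt(n))


def paired_t(before: np.ndarray, after: np.ndarray,
             comparison: str = "") -> TestResult:
    """Paired Student's t-test (e.g. post-treatment window vs baseline)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    n = len(before)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = after - before
    sd = d.std(ddof=1)
    if sd == 0:
        return TestResult.undefined(comparison)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult(float(t), n - 1, float(p), comparison)


def unpaired_t_raw(group1: np.ndarray, group2: np.ndarray,
                   welch: bool = False, comparison: str = "") -> TestResult:
    """Unpaired t-test on raw values (pooled Student by default).

    ``welch=True`` switches to the unequal-variance Welch variant.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need n >= 2")
    if welch:
        if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0:
            return TestResult.undefined(comparison)
        t, p = sps.ttest_ind(g1, g2, equal_var=False)
        n1, n2 = len(g1), len(g2)
        v1, v2 = g1.var(ddof=1) / n1, g2.var(ddof=1) / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
        return TestResult(float(t), float(df), float(p), comparison)
    return unpaired_t_summary(
        g1.mean(), sem(g1), len(g1), g2.mean(), sem(g2), len(g2),
        comparison=comparison)


def unpaired_t_summary(m1: float, sem1: float, n1: int,
                       m2: float, sem2: float, n2: int,
                       comparison: str = "") -> TestResult:
    """Pooled-variance Student's t-test from printed mean, SEM and n.

    ``sd_i = sem_i sqrt(n_i)``; pooled variance
    ``sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2)``;
    ``t = (m1-m2) / (sp sqrt(1/n1 + 1/n2))`` with ``df = n1+n2-2``. This is
    the summary-statistics form used to recompute figure-legend p-values
    from published numbers.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sem1 < 0 or sem2 < 0:
        raise ValueError("SEM must be >= 0")
    sd1, sd2 = sem1 * math.sqrt(n1), sem2 * math.sqrt(n2)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if sp2 == 0:
        return TestResult.undefined(comparison)
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), df, float(p), comparison)


# ---------------------------------------------------------------------------
# 2x2 factorial ANOVA
# ---------------------------------------------------------------------------

def _cell_to_summary(cell, label: str) -> GroupSummary:
    if isinstance(cell, GroupSummary):
        return cell
    if isinstance(cell, dict):
        return GroupSummary(label, cell["mean"], cell["sem"], cell["n"])
    return GroupSummary.from_values(label, np.asarray(cell, dtype=float))


@dataclass
class Anova2x2Result:
    """Interaction and main effects of a between-subjects 2x2 ANOVA."""

    interaction: TestResult
    main_a: TestResult
    main_b: TestResult
    mse: float
    df_error: int
    cells: list[GroupSummary]


def anova2x2(cells, factor_names: tuple[str, str] = ("genotype", "treatment"),
             ) -> Anova2x2Result:
    """Between-subjects 2x2 ANOVA from raw values or summaries.

    ``cells`` is a length-4 sequence ordered (a1b1, a1b2, a2b1, a2b2), each
    a ``GroupSummary``, a ``{"mean","sem","n"}`` dict, or an array of raw
    values; raw input is summarized first so both input forms share one
    formula path. Effects are single-df contrasts on the cell means with
    ``SS = L^2 / sum(1/n_ij)`` against the pooled within-cell MSE
    (df = N - 4), i.e. Type-III sums of squares (exact for a 2x2 design,
    balanced or not).
    """
    if len(cells) != 4:
        raise ValueError("anova2x2 needs exactly 4 cells")
    labels = [f"{factor_names[0]}{i}:{factor_names[1]}{j}"
              for i in (1, 2) for j in (1, 2)]
    summ = [_cell_to_summary(c, lab) for c, lab in zip(cells, labels)]
    ns = np.array([s.n for s in summ])
    ms = np.array([s.mean for s in summ])
    sds = np.array([s.sd for s in summ])
    n_total = int(ns.sum())
    df_err = n_total - 4
    if df_err <= 0:
        raise ValueError("not enough observations for a 2x2 ANOVA")
    mse = float(np.sum((ns - 1) * sds ** 2) / df_err)
    inv = float(np.sum(1.0 / ns))

    def contrast(coefs: np.ndarray, name: str) -> TestResult:
        L = float(np.dot(coefs, ms))
        ss = L ** 2 / inv
        if mse == 0:
            return TestResult.undefined(name, kind="F")
        F = ss / mse
        p = float(sps.f.sf(F, 1, df_err))
        return TestResult(float(F), (1, df_err), p, name, kind="F")

    inter = contrast(np.array([1.0, -1.0, -1.0, 1.0]),
                     f"{factor_names[0]} x {factor_names[1]} interaction")
    main_a = contrast(np.array([1.0, 1.0, -1.0, -1.0]),
                      f"{factor_names[0]} main effect")
    main_b = contrast(np.array([1.0, -1.0, 1.0, -1.0]),
                      f"{factor_names[1]} main effect")
    return Anova2x2Result(interaction=inter, main_a=main_a, main_b=main_b,
                          mse=mse, df_error=df_err, cells=summ)


DEFAULT_SIMPLE_EFFECTS = ((0, 1), (2, 3), (0, 2), (1, 3))


def bonferroni_posthoc(
    anova: Anova2x2Result,
    comparisons: tuple[tuple[int, int], ...] = DEFAULT_SIMPLE_EFFECTS,
) -> list[TestResult]:
    """Bonferroni-adjusted pairwise cell contrasts after a 2x2 ANOVA.

    Each comparison (i, j) indexes the ANOVA's cells; the t statistic uses
    the pooled MSE with the error df, and the adjusted p is
    ``min(1, p x m)`` with m the number of comparisons. The default family
    is the 4 simple effects (within each level of either factor).
    """
    if not comparisons:
        raise ValueError("comparison set must be non-empty")
    m = len(comparisons)
    out = []
    for i, j in comparisons:
        a, b = anova.cells[i], anova.cells[j]
        name = f"{a.label} vs {b.label}"
        se = math.sqrt(anova.mse * (1.0 / a.n + 1.0 / b.n))
        if se == 0:
            out.append(TestResult.undefined(name))
            continue
        t = (a.mean - b.mean) / se
        p = 2.0 * sps.t.sf(abs(t), anova.df_error)
        out.append(TestResult(float(t), anova.df_error, float(p), name,
                              adjusted_p=min(1.0, float(p) * m)))
    return out


def correlate(x: np.ndarray, y: np.ndarray,
              comparison: str = "") -> TestResult:
    """Pearson correlation with two-tailed p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        return TestResult.undefined(comparison, kind="r")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r ** 2))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return TestResult(r, n - 2, float(p), comparison, kind="r")
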