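"""Statistics used throughout the pipeline, from explicit formulas.

Pearson product-moment correlation, one-way ANOVA, Tukey–Kramer post hoc
comparisons (studentized-range p-values with the Kramer harmonic-mean
term for unequal group sizes), and Student t tests (pooled-variance
two-sample and one-sample), all two-sided.  Statistic values come from
the textbook formulas written out here; p-values come from the
corresponding scipy reference distributions (t, F, studentized range).

Zero-variance inputs yield NaN statistics (undefined), never a silent 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "TTestResult",
    "pearson_r",
    "one_way_anova",
    "tukey_kramer",
    "t_tests",
]

ALPHA = 0.05  # conventional significance level used for post hoc flags


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: tuple[float, ...]


@dataclass
class PosthocResult:
    """All pairwise Tukey–Kramer comparisons; q is the studentized range."""

    pairwise: list[tuple[int, int, float, float, bool]]
    # (group_a, group_b, q_statistic, p_value, significant at ALPHA)
    alpha: float = ALPHA


@dataclass
class TTestResult:
    t_statistic: float
    df: int
    p_value: float
    kind: str  # "two-sample" or "one-sample"


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; NaN if either variable is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(xc @ yc) / (sx * sy)
    return float(min(1.0, max(-1.0, r)))


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.ndim != 1 or len(g) < 2:
            raise ValueError(f"group {i} needs at least 2 values")
    return gs


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    Degrees of freedom (k − 1, N − k); p from the F distribution.  If
    both between- and within-group variation vanish, F = 0 and p = 1.
    """
    gs = _check_groups(groups)
    k = len(gs)
    n_tot = sum(len(g) for g in gs)
    grand = sum(g.sum() for g in gs) / n_tot
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n_tot - k
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        f = 0.0 if ss_between == 0.0 else float("inf")
    else:
        f = (ss_between / df_b) / ms_w
    p = float(_st.f.sf(f, df_b, df_w)) if math.isfinite(f) else 0.0
    return AnovaResult(f_statistic=float(f), df_between=df_b, df_within=df_w,
                       p_value=p, group_means=tuple(g.mean() for g in gs))


def tukey_kramer(groups, alpha: float = ALPHA) -> PosthocResult:
    """Tukey–Kramer all-pairs comparison after a one-way ANOVA.

    For groups i, j:  q = |m_i − m_j| / sqrt((MSW / 2)(1/n_i + 1/n_j)),
    the Kramer term reducing to the classic Tukey term for equal sizes;
    p from the studentized range distribution with (k, N − k).
    """
    gs = _check_groups(groups)
    k = len(gs)
    n_tot = sum(len(g) for g in gs)
    df_w = n_tot - k
    ms_w = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_w
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(gs[i].mean() - gs[j].mean())
            se = math.sqrt(ms_w / 2.0 * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
            if se == 0.0:
                q = 0.0 if diff == 0.0 else float("inf")
            else:
                q = diff / se
            p = (float(_st.studentized_range.sf(q, k, df_w))
                 if math.isfinite(q) else 0.0)
            pairs.append((i, j, float(q), p, bool(p < alpha)))
    return PosthocResult(pairwise=pairs, alpha=alpha)


def t_tests(a, b=None, mu0: float | None = None) -> TTestResult:
    """Student t test, two-sided.

    Two-sample form (``b`` given): pooled-variance Student t on
    n_a + n_b − 2 df.  One-sample form (``mu0`` given): t of the mean of
    ``a`` against mu0 on n − 1 df.  Zero pooled/sample variance with a
    nonzero mean difference yields NaN (undefined), and t = 0, p = 1 when
    the means agree exactly.
    """
    a = np.asarray(a, dtype=float)
    if (b is None) == (mu0 is None):
        raise ValueError("give exactly one of b (two-sample) or "
                         "mu0 (one-sample)")
    if b is not None:
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each sample needs at least 2 values")
        df = len(a) + len(b) - 2
        sp2 = (((a - a.mean()) ** 2).sum()
               + ((b - b.mean()) ** 2).sum()) / df
        se = math.sqrt(sp2 * (1.0 / len(a) + 1.0 / len(b)))
        diff = a.mean() - b.mean()
        kind = "two-sample"
    else:
        if len(a) < 2:
            raise ValueError("one-sample test needs at least 2 values")
        df = len(a) - 1
        se = a.std(ddof=1) / math.sqrt(len(a))
        diff = a.mean() - mu0
        kind = "one-sample"
    if se == 0.0:
        t = 0.0 if diff == 0.0 else float("nan")
    else:
        t = diff / se
    p = float(2.0 * _st.t.sf(abs(t), df)) if math.isfinite(t) else float("nan")
    if t == 0.0:
        p = 1.0
    return TTestResult(t_statistic=float(t), df=df, p_value=p, kind=kind)
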