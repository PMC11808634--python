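"""Coefficients of variation, small-sample correction, and CV comparison.

The coefficient of variation V = 100 * sd / mean (percent, n-1 sd) is
biased downward in small samples; the standard small-sample correction
multiplies by (1 + 1/(4n)):

    V* = (1 + 1/(4n)) * V

Equality of two coefficients of variation is tested with an asymptotic
t-type statistic on the corrected CVs (as proportions, c = V*/100).  For
normal data the sampling variance of a sample CV c is approximately
c^2 (0.5 + c^2) / (n - 1).  Two variance rules are available:

``pooled`` (default)
    The null hypothesis is equal CVs, so the variance is evaluated at the
    df-weighted pooled CV:  Var = c̄^2 (0.5 + c̄^2) (1/(n_a-1) + 1/(n_b-1)).
    This is the Miller-type equality test and is well calibrated even for
    very unequal sample sizes.
``separate``
    Each sample contributes its own plug-in variance
    c_i^2 (0.5 + c_i^2)/(n_i - 1).  Simpler, but the correlation between
    the numerator and its plug-in variance makes the tails asymmetric
    (conservative in one direction, anticonservative in the other) at
    small n; retained for comparison.

In both cases t is referred to a Student t distribution with
df = n_a + n_b - 2, one-tailed in the caller-specified direction.  The
direction must be stated a priori — downstream batteries fix it from the
hypothesis under test, never from the observed sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError
from .phenodata import GROUPS, MEASUREMENTS

TAILS = ("a_greater", "b_greater")


def cv(values) -> float:
    """Coefficient of variation in percent: 100 * sd(n-1) / mean.

    Requires n >= 2 and a strictly positive mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"cv requires n >= 2, got n={x.size}")
    m = x.mean()
    if m <= 0:
        raise DomainError(f"cv requires a positive mean, got {m}")
    return 100.0 * x.std(ddof=1) / m


def v_star(values) -> float:
    """Small-sample-corrected coefficient of variation (percent).

    V* = (1 + 1/(4n)) * V; the correction factor tends to 1 from above as
    n grows, and V* is the less biased estimator of the population CV at
    small n.
    """
    x = np.asarray(values, dtype=float)
    return (1.0 + 1.0 / (4.0 * x.size)) * cv(x)


@dataclass(frozen=True)
class CVTestResult:
    """One-tailed comparison of two corrected coefficients of variation."""

    group_a: str
    group_b: str
    measurement: str | None
    n_a: int
    n_b: int
    v_star_a: float
    v_star_b: float
    t_statistic: float
    df: int
    p_one_tailed: float
    direction: str


def cv_difference_test(
    sample_a,
    sample_b,
    tail: str = "a_greater",
    variance_rule: str = "pooled",
    group_a: str = "a",
    group_b: str = "b",
    measurement: str | None = None,
) -> CVTestResult:
    """Test whether one sample's corrected CV exceeds the other's.

    ``tail="a_greater"`` tests H1: CV_a > CV_b (upper tail of t);
    ``"b_greater"`` the reverse.  See module docstring for the statistic.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    ca = v_star(a) / 100.0
    cb = v_star(b) / 100.0
    if ca == 0.0 and cb == 0.0:
        raise InsufficientDataError("both samples have zero CV; t undefined")
    na, nb = a.size, b.size
    if variance_rule == "pooled":
        cbar = (ca * (na - 1) + cb * (nb - 1)) / (na + nb - 2)
        var = cbar**2 * (0.5 + cbar**2) * (1.0 / (na - 1) + 1.0 / (nb - 1))
    elif variance_rule == "separate":
        var = ca**2 * (0.5 + ca**2) / (na - 1) + cb**2 * (0.5 + cb**2) / (nb - 1)
    else:
        raise ValueError("variance_rule must be 'pooled' or 'separate'")
    t = (ca - cb) / np.sqrt(var)
    df = na + nb - 2
    p = stats.t.sf(t, df) if tail == "a_greater" else stats.t.cdf(t, df)
    return CVTestResult(
        group_a=group_a, group_b=group_b, measurement=measurement,
        n_a=na, n_b=nb, v_star_a=100 * ca, v_star_b=100 * cb,
        t_statistic=float(t), df=df, p_one_tailed=float(p), direction=tail,
    )


def dispersion_table(
    records: pd.DataFrame,
    measurements: Iterable[str] | None = None,
    groups: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Long-format V and V* per group x measurement.

    Cells with n < 2 or a non-positive mean are omitted with a warning.
    Columns: ``group, measurement, n, V, V_star``.
    """
    if measurements is None:
        measurements = [m for m in MEASUREMENTS if m in records.columns]
    groups = list(GROUPS if groups is None else groups)
    rows = []
    for g in groups:
        sub = records[records["group"] == g]
        for m in measurements:
            vals = sub[m].dropna().to_numpy()
            if vals.size < 2 or vals.mean() <= 0:
                warnings.warn(
                    f"dispersion undefined for group={g!r} measurement={m!r} "
                    f"(n={vals.size}); omitted"
                )
                continue
            v = cv(vals)
            rows.append(
                {"group": g, "measurement": m, "n": vals.size,
                 "V": v, "V_star": (1 + 1 / (4 * vals.size)) * v}
            )
    return pd.DataFrame(rows, columns=["group", "measurement", "n", "V", "V_star"])


def cv_test_table(
    records: pd.DataFrame,
    measurements: Iterable[str] | None = None,
    alpha: float = 0.05,
    m_tests: int | None = None,
    tail: str = "a_greater",
    variance_rule: str = "pooled",
) -> pd.DataFrame:
    """Hybrid-vs-each-full-bred CV comparisons for every measurement.

    The a priori hypothesis is heightened hybrid variability, so sample a
    is always the hybrid group and the default tail is ``a_greater``.
    Bonferroni correction uses ``m_tests`` (default: the number of
    measurements) within each comparison block.  Cells where either group
    has n < 2 are emitted with NaN statistics and a note.
    """
    from .test_battery import bonferroni_alpha  # local to avoid cycle

    if measurements is None:
        measurements = [m for m in MEASUREMENTS if m in records.columns]
    measurements = list(measurements)
    m_tests = len(measurements) if m_tests is None else m_tests
    alpha_adj = bonferroni_alpha(alpha, m_tests)

    rows = []
    hyb = records[records["group"] == "hybrid"]
    for parent in ("indian", "chinese"):
        par = records[records["group"] == parent]
        for m in measurements:
            a = hyb[m].dropna().to_numpy()
            b = par[m].dropna().to_numpy()
            base = {
                "comparison": f"hybrid_vs_{parent}", "measurement": m,
                "n_hybrid": a.size, "n_parent": b.size,
                "alpha_adjusted": alpha_adj, "direction": tail,
            }
            if a.size < 2 or b.size < 2 or a.mean() <= 0 or b.mean() <= 0:
                rows.append({**base, "v_star_hybrid": np.nan, "v_star_parent": np.nan,
                             "t": np.nan, "df": np.nan, "p_one_tailed": np.nan,
                             "significant": False, "note": "insufficient-n"})
                continue
            res = cv_difference_test(
                a, b, tail=tail, variance_rule=variance_rule,
                group_a="hybrid", group_b=parent, measurement=m,
            )
            rows.append({**base, "v_star_hybrid": res.v_star_a,
                         "v_star_parent": res.v_star_b, "t": res.t_statistic,
                         "df": res.df, "p_one_tailed": res.p_one_tailed,
                         "significant": res.p_one_tailed < alpha_adj, "note": ""})
    return pd.DataFrame(rows)
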