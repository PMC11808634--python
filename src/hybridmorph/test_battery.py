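"""One-tailed t-test battery with Bonferroni correction.

The battery asks, for each of the six raw measurements, whether hybrids
are smaller than three parental references:

``vs_smaller_parent_mean``
    hybrid values against the smaller of the two full-bred means;
``vs_larger_parent_mean``
    hybrid values against the larger full-bred mean;
``vs_mid_parental``
    each hybrid's deviation from its own ancestry-weighted additive
    expectation, tested against zero.

Directions are fixed a priori (default: hybrids smaller) rather than read
off the observed signs, to keep the one-tailed p-values honest; an option
runs both tails and doubles the Bonferroni m accordingly.  Within each
block the six measurements are Bonferroni-corrected (alpha/m, m = 6 by
default); composites are excluded because they are linear combinations of
tested traits.

Two comparison modes exist because a hybrid group can be compared either
to a full-bred *mean treated as a constant* (one-sample t, df = n-1) or
to the full-bred *sample* (independent two-sample t, pooled or Welch).
The mid-parental block is always a one-sample test on deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .additive_expectation import expected_value
from .errors import InsufficientDataError
from .phenodata import RAW_MEASUREMENTS, summarize_groups

DIRECTIONS = ("smaller", "larger")
BLOCKS = ("smaller_parent", "larger_parent", "mid_parental")


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m for m planned tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass(frozen=True)
class TTestOutcome:
    """A scalar t test: statistic, degrees of freedom, one-tailed p."""

    t: float
    df: float
    p: float


def one_tailed_t_vs_constant(sample, reference: float, direction: str = "smaller") -> TTestOutcome:
    """One-sample t of a sample mean against a fixed reference value.

    ``direction="smaller"`` tests H1: mean < reference (lower tail);
    ``"larger"`` the upper tail.  df = n - 1.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need n >= 2, got n={x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise InsufficientDataError("zero standard deviation; t undefined")
    t = (x.mean() - reference) / (sd / np.sqrt(x.size))
    df = x.size - 1
    p = stats.t.cdf(t, df) if direction == "smaller" else stats.t.sf(t, df)
    return TTestOutcome(t=float(t), df=df, p=float(p))


def one_tailed_t_two_sample(
    sample_a, sample_b, direction: str = "smaller", variance_rule: str = "pooled"
) -> TTestOutcome:
    """Independent two-sample t, one-tailed on sample a relative to b.

    ``direction="smaller"`` tests H1: mean_a < mean_b.  ``variance_rule``
    selects the pooled-variance statistic (df = n_a + n_b - 2) or Welch's
    statistic with Welch-Satterthwaite df.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("both samples need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise InsufficientDataError("both standard deviations zero; t undefined")
    na, nb = a.size, b.size
    if variance_rule == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    elif variance_rule == "welch":
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    else:
        raise ValueError("variance_rule must be 'pooled' or 'welch'")
    t = (a.mean() - b.mean()) / se
    p = stats.t.cdf(t, df) if direction == "smaller" else stats.t.sf(t, df)
    return TTestOutcome(t=float(t), df=float(df), p=float(p))


def _battery_row(block, mode, m, n, direction, alpha_adj, outcome=None, note=""):
    return {
        "comparison": block, "mode": mode, "measurement": m, "n": n,
        "direction": direction,
        "t": np.nan if outcome is None else outcome.t,
        "df": np.nan if outcome is None else outcome.df,
        "p_one_tailed": np.nan if outcome is None else outcome.p,
        "alpha_adjusted": alpha_adj,
        "significant": False if outcome is None else outcome.p < alpha_adj,
        "note": note,
    }


def run_size_battery(
    records: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "one-sample",
    measurements: Iterable[str] | None = None,
    reference_means: Mapping[str, tuple[float, float]] | None = None,
    expected: pd.DataFrame | None = None,
    direction: str = "smaller",
    both_tails: bool = False,
    blocks: Iterable[str] = BLOCKS,
    variance_rule: str = "pooled",
) -> pd.DataFrame:
    """Run the full hybrid-size battery; returns a long-format DataFrame.

    Parameters
    ----------
    records
        Phenotype frame (conventionally sex-adjusted) with hybrids and,
        unless ``reference_means`` is given, both full-bred groups.
    alpha, both_tails
        Family-wise level; Bonferroni m is the number of measurements per
        block, doubled when both tails are run.
    mode
        ``"one-sample"`` (parental means as constants), ``"two-sample"``
        (parental samples), or ``"both"``.  The mid-parental block is
        one-sample regardless.
    reference_means
        ``{measurement: (indian_mean, chinese_mean)}`` override; defaults
        to means estimated from the full-bred records.
    expected
        Optional per-hybrid expectations for the mid-parental block, long
        format ``id, measurement, expected``; defaults to the additive
        formula applied to ``reference_means``.
    direction
        A priori alternative for every block (ignored if ``both_tails``).
    blocks
        Subset of ``("smaller_parent", "larger_parent", "mid_parental")``.

    Cells that cannot be tested (n < 2, missing reference) are emitted
    with NaN statistics and an explanatory note rather than raising, so a
    partial dataset still yields a complete report skeleton.
    """
    if measurements is None:
        measurements = list(RAW_MEASUREMENTS)
    measurements = [m for m in measurements if m in records.columns]
    blocks = list(blocks)

    m_tests = len(measurements) * (2 if both_tails else 1)
    alpha_adj = bonferroni_alpha(alpha, m_tests)
    tails = list(DIRECTIONS) if both_tails else [direction]

    if reference_means is None:
        summ = summarize_groups(records, measurements=measurements, groups=["indian", "chinese"])
        piv = summ.pivot(index="measurement", columns="group", values="mean")
        reference_means = {
            m: (float(piv.loc[m, "indian"]), float(piv.loc[m, "chinese"]))
            for m in measurements
            if m in piv.index
            and {"indian", "chinese"} <= set(piv.columns)
            and piv.loc[m].notna().all()
        }

    hybrids = records[records["group"] == "hybrid"]
    parents = {
        g: records[records["group"] == g] for g in ("indian", "chinese")
    }
    exp_lut = None
    if expected is not None:
        exp_lut = expected.set_index(["id", "measurement"])["expected"]

    modes = ["one-sample", "two-sample"] if mode == "both" else [mode]
    rows = []
    for m in measurements:
        vals = hybrids[m].dropna()
        ref = reference_means.get(m)
        for tail in tails:
            # parental-mean blocks
            for which in ("smaller_parent", "larger_parent"):
                if which not in blocks:
                    continue
                block = f"vs_{which}"
                for md in modes:
                    if ref is None:
                        rows.append(_battery_row(block, md, m, len(vals), tail, alpha_adj,
                                                 note="no parental reference"))
                        continue
                    pick = int(np.argmin(ref)) if which == "smaller_parent" else int(np.argmax(ref))
                    parent_group = ("indian", "chinese")[pick]
                    try:
                        if md == "one-sample":
                            out = one_tailed_t_vs_constant(vals, ref[pick], direction=tail)
                        else:
                            pvals = parents[parent_group][m].dropna()
                            out = one_tailed_t_two_sample(
                                vals, pvals, direction=tail, variance_rule=variance_rule
                            )
                        rows.append(_battery_row(block, md, m, len(vals), tail, alpha_adj, out))
                    except InsufficientDataError as err:
                        rows.append(_battery_row(block, md, m, len(vals), tail, alpha_adj,
                                                 note=f"insufficient-n ({err})"))
            # mid-parental block (one-sample on deviations)
            if "mid_parental" in blocks:
                if exp_lut is not None:
                    sub = hybrids[["id", m]].dropna(subset=[m])
                    key = pd.MultiIndex.from_arrays([sub["id"], np.repeat(m, len(sub))])
                    e = exp_lut.reindex(key).to_numpy()
                    dev = sub[m].to_numpy() - e
                    dev = dev[~np.isnan(dev)]
                elif ref is not None:
                    sub = hybrids[["ancestry", m]].dropna(subset=[m])
                    dev = sub[m].to_numpy() - expected_value(sub["ancestry"].to_numpy(), *ref)
                else:
                    rows.append(_battery_row("vs_mid_parental", "one-sample", m, len(vals),
                                             tail, alpha_adj, note="no parental reference"))
                    continue
                try:
                    out = one_tailed_t_vs_constant(dev, 0.0, direction=tail)
                    rows.append(_battery_row("vs_mid_parental", "one-sample", m, dev.size,
                                             tail, alpha_adj, out))
                except InsufficientDataError as err:
                    rows.append(_battery_row("vs_mid_parental", "one-sample", m, dev.size,
                                             tail, alpha_adj, note=f"insufficient-n ({err})"))
    return pd.DataFrame(rows)
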