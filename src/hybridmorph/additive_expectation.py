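"""Additive (mid-parent) expectations, parity deviations, transgression.

Under a polygenic model in which a trait is controlled by a very large
number of loci with equal, additive allelic effects (no dominance, no
epistasis), the expected trait value of an admixed individual is the
ancestry-weighted average of the two full-bred means:

    E[y | A] = (1 - A) * mean_indian + A * mean_chinese

where A is the individual's fraction of Chinese ancestry.  Plotting the
actual value against this expectation, the *parity line* (actual =
expected) separates hybrids that exceed their additive expectation
(candidate heterosis) from those that fall short (candidate dysgenesis).

Transgression is classified two ways, which answer different questions:

* versus the two parental *means* — is the individual outside the
  interval spanned by the full-bred averages?
* versus the parental observed *ranges* — is it outside the full range of
  variation seen in either full-bred sample?

Both use closed intervals: a value exactly on a boundary is "between" /
"within".
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .phenodata import MEASUREMENTS, summarize_groups


def expected_value(ancestry, mean_indian, mean_chinese):
    """Ancestry-weighted additive expectation (1-A)*x̄_Ind + A*x̄_Chi.

    ``ancestry`` may be a scalar or array; broadcasting applies.  Raises
    :class:`DomainError` if any ancestry value is outside [0, 1].
    """
    a = np.asarray(ancestry, dtype=float)
    if np.any((a < 0.0) | (a > 1.0)) or np.any(np.isnan(a)):
        raise DomainError("ancestry must lie in [0, 1]")
    out = (1.0 - a) * mean_indian + a * mean_chinese
    return float(out) if out.ndim == 0 else out


def classify_transgression(
    value: float,
    parental_means: tuple[float, float],
    parental_range: tuple[float, float] | None = None,
) -> tuple[str, str | None]:
    """Two independent transgression labels for one value.

    Returns ``(vs_means, vs_range)`` where ``vs_means`` is one of
    ``above_both | between | below_both`` (relative to the two parental
    means) and ``vs_range`` is ``above_parental_max | within |
    below_parental_min`` (relative to the observed parental min/max), or
    None when no range is supplied.  Boundaries classify inward.
    """
    lo_m, hi_m = sorted(parental_means)
    if value > hi_m:
        vs_means = "above_both"
    elif value < lo_m:
        vs_means = "below_both"
    else:
        vs_means = "between"

    vs_range = None
    if parental_range is not None:
        lo_r, hi_r = sorted(parental_range)
        if value > hi_r:
            vs_range = "above_parental_max"
        elif value < lo_r:
            vs_range = "below_parental_min"
        else:
            vs_range = "within"
    return vs_means, vs_range


def _parental_means_from(records: pd.DataFrame, measurements) -> dict[str, tuple[float, float]]:
    summ = summarize_groups(records, measurements=measurements, groups=["indian", "chinese"])
    piv = summ.pivot(index="measurement", columns="group", values="mean")
    out = {}
    for m in measurements:
        if m in piv.index and piv.loc[m].notna().all() and {"indian", "chinese"} <= set(piv.columns):
            out[m] = (float(piv.loc[m, "indian"]), float(piv.loc[m, "chinese"]))
    return out


def _parental_ranges_from(records: pd.DataFrame, measurements) -> dict[str, tuple[float, float]]:
    full = records[records["group"].isin(["indian", "chinese"])]
    out = {}
    for m in measurements:
        vals = full[m].dropna()
        if len(vals):
            out[m] = (float(vals.min()), float(vals.max()))
    return out


def parity_analysis(
    records: pd.DataFrame,
    parental_means: Mapping[str, tuple[float, float]] | None = None,
    parental_ranges: Mapping[str, tuple[float, float]] | None = None,
    measurements: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-hybrid expectations and per-measurement parity summaries.

    Parameters
    ----------
    records
        Phenotype frame containing hybrids and (unless parental references
        are supplied) both full-bred groups.  Conventionally sex-adjusted.
    parental_means, parental_ranges
        Optional overrides ``{measurement: (indian, chinese)}`` /
        ``{measurement: (min, max)}``.  When omitted they are estimated
        from the full-bred records.
    measurements
        Measurements to analyse; defaults to every measurement column
        present.

    Returns
    -------
    expectations : DataFrame
        One row per hybrid x measurement with both values defined:
        ``id, measurement, ancestry, expected, actual, deviation,
        parity_side, transgression_vs_means, transgression_vs_range``.
    parity : DataFrame
        One row per measurement: ``measurement, n_above, n_below, n_on,
        mean_deviation, sign_test_p``.  The sign test is the two-sided
        exact binomial test on above-vs-below counts, ties excluded; it is
        an extension beyond the graphical parity-line comparison.
    """
    if measurements is None:
        measurements = [m for m in MEASUREMENTS if m in records.columns]
    measurements = list(measurements)

    if parental_means is None:
        parental_means = _parental_means_from(records, measurements)
    if parental_ranges is None:
        parental_ranges = _parental_ranges_from(records, measurements)

    hybrids = records[records["group"] == "hybrid"]
    exp_rows, parity_rows = [], []
    for m in measurements:
        if m not in parental_means:
            warnings.warn(f"no parental means for {m!r}; measurement skipped")
            continue
        mi, mc = parental_means[m]
        rng = parental_ranges.get(m)
        sub = hybrids[["id", "ancestry", m]].dropna(subset=[m])
        expected = expected_value(sub["ancestry"].to_numpy(), mi, mc)
        actual = sub[m].to_numpy()
        dev = actual - expected
        side = np.select([dev > 0, dev < 0], ["above", "below"], default="on")
        for rid, a, e, y, d, s in zip(sub["id"], sub["ancestry"], expected, actual, dev, side):
            vs_means, vs_range = classify_transgression(y, (mi, mc), rng)
            exp_rows.append(
                {
                    "id": rid, "measurement": m, "ancestry": a,
                    "expected": e, "actual": y, "deviation": d,
                    "parity_side": s,
                    "transgression_vs_means": vs_means,
                    "transgression_vs_range": vs_range,
                }
            )
        n_above = int((side == "above").sum())
        n_below = int((side == "below").sum())
        n_on = int((side == "on").sum())
        if n_above + n_below > 0:
            p = stats.binomtest(n_above, n_above + n_below, 0.5).pvalue
        else:
            p = 1.0
        parity_rows.append(
            {
                "measurement": m,
                "n_above": n_above, "n_below": n_below, "n_on": n_on,
                "mean_deviation": float(dev.mean()) if len(dev) else np.nan,
                "sign_test_p": float(p),
            }
        )

    expectations = pd.DataFrame(
        exp_rows,
        columns=[
            "id", "measurement", "ancestry", "expected", "actual", "deviation",
            "parity_side", "transgression_vs_means", "transgression_vs_range",
        ],
    )
    parity = pd.DataFrame(
        parity_rows,
        columns=["measurement", "n_above", "n_below", "n_on", "mean_deviation", "sign_test_p"],
    )
    return expectations, parity
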