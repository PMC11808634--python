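"""Sex adjustment by additive male-female offsets.

Lineages can differ in sexual dimorphism, so pooling sexes without
adjustment would confound sex composition with ancestry.  The adjustment
implemented here computes, within each *adjustment group*, the difference
between male and female means for each raw measurement and adds it to
every female value, lifting females to the male level while leaving males
untouched.  After adjustment the female and male means coincide exactly
within every adjustment group.

Two grouping schemes are provided:

``pooled_hybrids`` (default)
    Three adjustment groups: full-bred Indian, full-bred Chinese, and all
    hybrids pooled regardless of ancestry fraction.  This is the only
    feasible scheme when some ancestry bins contain a single sex.
``per_bin``
    One adjustment group per distinct ancestry value.  Errors if any bin
    lacks one sex for a measurement — no silent zero offsets.

Offsets are computed on the raw measurements only; composites must be
re-derived afterwards so that forelimb = humerus + radius stays exact.
:func:`apply_sex_adjustment` does this automatically when composite
columns are present.
"""

from __future__ import annotations

import pandas as pd

from .errors import AdjustmentError
from .phenodata import COMPOSITE_COMPONENTS, RAW_MEASUREMENTS, derive_composites

SCHEMES = ("pooled_hybrids", "per_bin")


def _adjustment_group(df: pd.DataFrame, scheme: str) -> pd.Series:
    if scheme == "pooled_hybrids":
        return df["group"].map(
            {"indian": "indian", "chinese": "chinese", "hybrid": "hybrid_pooled"}
        )
    if scheme == "per_bin":
        return df["ancestry"].map(lambda a: f"A={a:g}")
    raise ValueError(f"unknown adjustment scheme {scheme!r}; choose from {SCHEMES}")


def sex_offsets(
    records: pd.DataFrame, scheme: str = "pooled_hybrids"
) -> pd.DataFrame:
    """Male-minus-female mean offsets per adjustment group and measurement.

    Returns a DataFrame ``adjustment_group, measurement, n_female, n_male,
    offset``.  Raises :class:`AdjustmentError` naming the group and
    measurement if either sex has no non-missing value there.
    """
    grp = _adjustment_group(records, scheme)
    rows = []
    for g in pd.unique(grp):
        sub = records[grp == g]
        for m in RAW_MEASUREMENTS:
            f = sub.loc[sub["sex"] == "F", m].dropna()
            mle = sub.loc[sub["sex"] == "M", m].dropna()
            if len(f) == 0 or len(mle) == 0:
                missing = "males" if len(mle) == 0 else "females"
                raise AdjustmentError(
                    f"adjustment group {g!r} has no {missing} with "
                    f"non-missing {m!r}; cannot compute sex offset"
                )
            rows.append(
                {
                    "adjustment_group": g,
                    "measurement": m,
                    "n_female": len(f),
                    "n_male": len(mle),
                    "offset": mle.mean() - f.mean(),
                }
            )
    return pd.DataFrame(rows)


def apply_sex_adjustment(
    records: pd.DataFrame,
    offsets: pd.DataFrame | None = None,
    scheme: str = "pooled_hybrids",
) -> pd.DataFrame:
    """Add each group's male-female offset to every female value.

    Male values, missingness patterns, and group sizes are unchanged.
    Composite columns, if present, are re-derived from the adjusted
    components.  The returned frame is flagged with
    ``attrs["sex_adjusted"] = True``.

    Raises :class:`AdjustmentError` if a female record has a value for a
    group x measurement without a corresponding offset.
    """
    if offsets is None:
        offsets = sex_offsets(records, scheme=scheme)
    lut = {
        (r.adjustment_group, r.measurement): r.offset
        for r in offsets.itertuples()
    }

    out = records.copy()
    grp = _adjustment_group(out, scheme)
    fem = out["sex"] == "F"
    for g in pd.unique(grp):
        mask = fem & (grp == g)
        if not mask.any():
            continue
        for m in RAW_MEASUREMENTS:
            if (g, m) not in lut:
                if out.loc[mask, m].notna().any():
                    raise AdjustmentError(
                        f"no offset for adjustment group {g!r}, measurement {m!r}"
                    )
                continue
            out.loc[mask, m] = out.loc[mask, m] + lut[(g, m)]

    if any(c in out.columns for c in COMPOSITE_COMPONENTS):
        out = derive_composites(out)
    out.attrs["sex_adjusted"] = True
    return out
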