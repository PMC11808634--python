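"""Phenotype tables: schema, validation, I/O, composites, group summaries.

The in-memory container is a :class:`pandas.DataFrame` with one row per
animal and the following columns:

==============  =======================================================
column          content
==============  =======================================================
``id``          opaque unique identifier (string)
``sex``         ``"F"`` or ``"M"``
``ancestry``    fraction of Chinese ancestry, in [0, 1]
``group``       ``"indian"`` (ancestry 0), ``"chinese"`` (ancestry 1),
                ``"hybrid"`` otherwise — always derived, never read
``weight`` ...  one column per measurement, ``NaN`` = missing
==============  =======================================================

Weight is in kilograms, all length measurements in millimetres.  The
forelimb and hindlimb columns are composites (humerus + radius and
femur + tibia per individual) and are derived by
:func:`derive_composites`, never read from input.

The on-disk dialect is UTF-8 CSV with a header row and columns ``id``,
``sex``, ``chinese_ancestry`` (fraction) *or* ``chinese_ancestry_pct``
(percent, auto-detected by column name), and ``weight_kg``,
``crown_rump_mm``, ``humerus_mm``, ``radius_mm``, ``femur_mm``,
``tibia_mm``.  Empty cells are missing values.
"""

from __future__ import annotations

import warnings
from os import PathLike
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: The six measurements recorded directly on each animal.
RAW_MEASUREMENTS: tuple[str, ...] = (
    "weight", "crown_rump", "humerus", "radius", "femur", "tibia",
)

#: Composite limb lengths and their components.
COMPOSITE_COMPONENTS: dict[str, tuple[str, str]] = {
    "forelimb": ("humerus", "radius"),
    "hindlimb": ("femur", "tibia"),
}

#: All measurements, raw then composite.
MEASUREMENTS: tuple[str, ...] = RAW_MEASUREMENTS + tuple(COMPOSITE_COMPONENTS)

#: Measurement units (weight in kg, everything else in mm).
UNITS: dict[str, str] = {m: ("kg" if m == "weight" else "mm") for m in MEASUREMENTS}

#: CSV column name for each raw measurement (``weight_kg``, ``humerus_mm``...).
COLUMN_FOR: dict[str, str] = {m: f"{m}_{UNITS[m]}" for m in RAW_MEASUREMENTS}

#: Ancestry groups in canonical order.
GROUPS: tuple[str, ...] = ("indian", "chinese", "hybrid")

# Anatomical data dictionary (documentation only; nothing below reads it).
# Limb lengths are maximum lengths measured between bone extremity landmarks;
# crown-rump is a jointed axial length.
MEASUREMENT_DEFINITIONS: dict[str, str] = {
    "weight": "Body weight at scanning (kg).",
    "crown_rump": (
        "Jointed length from the mid-point of the line connecting orbit "
        "mid-points (glabella) to the notch under the spinous process of S3, "
        "traced along the spine."
    ),
    "humerus": "Proximal-most point on the humeral head to the distal-most point on the medial trochlea.",
    "radius": "Proximal-most point on the radial head in line with the styloid process to the distal-most point on the styloid process.",
    "femur": "Proximal-most point on the greater trochanter to the distal-most point on the lateral condyle.",
    "tibia": "Proximal-most point on the medial margin of the proximal condyle to the distal-most point on the medial malleolus.",
    "forelimb": "Humerus plus radius, per individual.",
    "hindlimb": "Femur plus tibia, per individual.",
}


def group_of(ancestry):
    """Ancestry group label(s) for Chinese-ancestry fraction(s).

    0 -> ``indian``, 1 -> ``chinese``, anything strictly between -> ``hybrid``.
    Accepts a scalar or an array-like; returns a scalar string or ndarray.
    """
    a = np.asarray(ancestry, dtype=float)
    out = np.select([a == 0.0, a == 1.0], ["indian", "chinese"], default="hybrid")
    return out.item() if np.isscalar(ancestry) or a.ndim == 0 else out


def _validate_frame(df: pd.DataFrame, strict: bool) -> pd.DataFrame:
    """Row-level domain checks; drops (non-strict) or raises (strict)."""
    bad_reasons: dict[int, str] = {}

    sex_ok = df["sex"].isin(["F", "M"])
    for idx in df.index[~sex_ok]:
        bad_reasons[idx] = f"sex {df.at[idx, 'sex']!r} not in {{F, M}}"

    anc = df["ancestry"]
    anc_ok = anc.notna() & (anc >= 0.0) & (anc <= 1.0)
    for idx in df.index[~anc_ok]:
        bad_reasons.setdefault(idx, f"ancestry {anc[idx]!r} outside [0, 1]")

    for m in RAW_MEASUREMENTS:
        vals = df[m]
        ok = vals.isna() | (vals > 0)
        for idx in df.index[~ok]:
            bad_reasons.setdefault(idx, f"non-positive {m} value {vals[idx]!r}")

    if bad_reasons:
        first = next(iter(bad_reasons))
        msg = f"row id={df.at[first, 'id']!r}: {bad_reasons[first]}"
        if strict:
            raise ValidationError(msg)
        warnings.warn(
            f"skipping {len(bad_reasons)} invalid row(s); first: {msg}",
            stacklevel=3,
        )
        df = df.drop(index=list(bad_reasons))

    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"duplicate id {dup!r}")
    return df


def read_phenotypes(path: str | PathLike, strict: bool = True) -> pd.DataFrame:
    """Read a phenotype CSV into the canonical frame.

    Parameters
    ----------
    path
        CSV file in the dialect described in the module docstring.
    strict
        If True (default), any invalid row raises
        :class:`~hybridmorph.errors.ValidationError` naming the row id;
        otherwise invalid rows are dropped with a warning.

    Returns
    -------
    DataFrame with columns ``id, sex, ancestry, group`` plus the six raw
    measurements (internal names, no unit suffix).  Composites are *not*
    derived here; see :func:`derive_composites`.
    """
    raw = pd.read_csv(path, dtype={"id": str, "sex": str}, float_precision="round_trip")
    cols = set(raw.columns)

    required = ["id", "sex"] + [COLUMN_FOR[m] for m in RAW_MEASUREMENTS]
    missing = [c for c in required if c not in cols]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    if "chinese_ancestry" in cols:
        ancestry = pd.to_numeric(raw["chinese_ancestry"], errors="coerce")
    elif "chinese_ancestry_pct" in cols:
        ancestry = pd.to_numeric(raw["chinese_ancestry_pct"], errors="coerce") / 100.0
    else:
        raise SchemaError(
            "missing required column(s): chinese_ancestry (fraction) "
            "or chinese_ancestry_pct (percent)"
        )

    df = pd.DataFrame({"id": raw["id"], "sex": raw["sex"], "ancestry": ancestry})
    for m in RAW_MEASUREMENTS:
        df[m] = pd.to_numeric(raw[COLUMN_FOR[m]], errors="coerce")

    df = _validate_frame(df, strict=strict)
    df.insert(3, "group", group_of(df["ancestry"].to_numpy()))
    return df.reset_index(drop=True)


def write_phenotypes(df: pd.DataFrame, path: str | PathLike) -> None:
    """Write records back to the input CSV dialect (fraction ancestry)."""
    out = pd.DataFrame({"id": df["id"], "sex": df["sex"], "chinese_ancestry": df["ancestry"]})
    for m in RAW_MEASUREMENTS:
        out[COLUMN_FOR[m]] = df[m]
    out.to_csv(path, index=False)


def derive_composites(df: pd.DataFrame) -> pd.DataFrame:
    """Add forelimb (humerus + radius) and hindlimb (femur + tibia) columns.

    A composite is missing iff any of its components is missing (NaN
    propagation).  Returns a copy; the input is untouched.
    """
    df = df.copy()
    for name, (a, b) in COMPOSITE_COMPONENTS.items():
        df[name] = df[a] + df[b]
    return df


def summarize_groups(
    df: pd.DataFrame,
    measurements: Iterable[str] | None = None,
    groups: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per group x measurement: n, mean, sd over non-missing values.

    Missingness is handled casewise per measurement: each cell uses every
    animal with that measurement present, regardless of other columns.
    The standard deviation uses the n-1 denominator and is NaN for n < 2.
    Empty group x measurement cells are omitted with a warning.

    Returns a long-format DataFrame: ``group, measurement, n, mean, sd``.
    """
    if measurements is None:
        measurements = [m for m in MEASUREMENTS if m in df.columns]
    groups = list(GROUPS if groups is None else groups)

    rows = []
    for g in groups:
        sub = df[df["group"] == g]
        for m in measurements:
            vals = sub[m].dropna()
            if len(vals) == 0:
                warnings.warn(f"no data for group={g!r} measurement={m!r}; summary omitted")
                continue
            rows.append(
                {
                    "group": g,
                    "measurement": m,
                    "n": len(vals),
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if len(vals) >= 2 else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["group", "measurement", "n", "mean", "sd"])


def group_mean_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long summary into a measurement x group table of means."""
    wide = summaries.pivot(index="measurement", columns="group", values="mean")
    order = [m for m in MEASUREMENTS if m in wide.index]
    cols = [g for g in GROUPS if g in wide.columns]
    return wide.loc[order, cols]
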