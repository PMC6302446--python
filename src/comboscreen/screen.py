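"""Combination-screen data model and aggregation.

A screen table holds one row per dosed measurement of a (cell line, drug A,
drug B) tuple.  Single-agent measurements leave the second drug slot empty.
Growth is the relative tumor growth fraction: -1 is total lethality, 0 total
inhibition, 1 unabated growth; raw values slightly above 1 occur and are
capped at 1 before any downstream use.  The modeling target per tuple is the
minimum capped growth over the tuple's dose grid ("MinComboGrowth").
"""

from __future__ import annotations

import io
from typing import Iterable

import numpy as np
import pandas as pd

#: canonical column names of the delimited screen format
SCREEN_COLUMNS = ["CELL", "DRUG_A", "DRUG_B", "DOSE_A", "DOSE_B", "GROWTH", "QC"]

#: canonical column names of the aggregated response format
RESPONSE_COLUMNS = ["CELL", "DRUG_A", "DRUG_B", "MIN_GROWTH"]

TUPLE_KEY = ["CELL", "DRUG_A", "DRUG_B"]


class InvalidMeasurementError(ValueError):
    """Raised for growth fractions below -1 (beyond total lethality)."""


def cap_growth(g):
    """Cap growth fractions at 1.

    Values above 1 ("enhanced growth") are mostly artifacts and are truncated;
    values in [-1, 1] pass through unchanged.  Accepts scalars or arrays.

    Raises
    ------
    InvalidMeasurementError
        If any value is below -1 or non-finite.
    """
    arr = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidMeasurementError("non-finite growth fraction")
    if np.any(arr < -1.0):
        raise InvalidMeasurementError(
            f"growth fraction below -1 (min={arr.min():g})"
        )
    capped = np.minimum(arr, 1.0)
    if np.isscalar(g) or np.ndim(g) == 0:
        return float(capped)
    return capped


def validate_screen(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a screen table: columns, growth range, single-agent slots.

    Single-agent rows must leave DRUG_B and DOSE_B both empty.  Returns the
    frame with identifier whitespace trimmed and QC coerced to boolean.
    """
    missing = [c for c in SCREEN_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"screen table missing columns: {missing}")
    df = records.copy()
    for col in ("CELL", "DRUG_A", "DRUG_B"):
        df[col] = df[col].astype("string").str.strip()
        df.loc[df[col].isin(["", "NA", "nan", "None"]), col] = pd.NA
    if df["CELL"].isna().any() or df["DRUG_A"].isna().any():
        raise ValueError("CELL and DRUG_A identifiers are required on every row")
    growth = df["GROWTH"].astype(float)
    if not np.all(np.isfinite(growth)):
        raise InvalidMeasurementError("non-finite growth fraction in screen table")
    if (growth < -1.0).any():
        raise InvalidMeasurementError("growth fraction below -1 in screen table")
    df["GROWTH"] = growth
    single = df["DRUG_B"].isna()
    bad = single & df["DOSE_B"].notna()
    if bad.any():
        raise ValueError("single-agent rows must leave DOSE_B empty")
    bad = (~single) & df["DOSE_B"].isna()
    if bad.any():
        raise ValueError("pair rows must carry DOSE_B")
    df["QC"] = _coerce_bool(df["QC"])
    return df


def _coerce_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "t": True, "f": False, "yes": True, "no": False,
    }
    out = s.astype("string").str.strip().str.lower().map(mapping)
    if out.isna().any():
        raise ValueError("QC column must be boolean-like (true/false/1/0)")
    return out.astype(bool)


def filter_records(
    records: pd.DataFrame,
    require_qc: bool = False,
    allowed_drugs: Iterable[str] | None = None,
    excluded_cells: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Subset screen rows by QC flag, drug whitelist and cell blacklist.

    The QC rule itself is an input flag on each row (set by the screening
    center), not recomputed here.  For pair rows both drugs must be in the
    allowed set.  An empty result is permitted.
    """
    mask = pd.Series(True, index=records.index)
    if require_qc:
        mask &= records["QC"].astype(bool)
    if allowed_drugs is not None:
        allowed = {str(d).strip() for d in allowed_drugs}
        mask &= records["DRUG_A"].isin(allowed)
        mask &= records["DRUG_B"].isna() | records["DRUG_B"].isin(allowed)
    if excluded_cells is not None:
        excluded = {str(c).strip() for c in excluded_cells}
        mask &= ~records["CELL"].isin(excluded)
    return records.loc[mask].copy()


def aggregate_min_growth(
    records: pd.DataFrame, on_duplicate: str = "min"
) -> pd.DataFrame:
    """Reduce dosed measurements to the per-tuple minimum capped growth.

    Groups rows by (cell, drug A, drug B) and keeps the lowest capped growth
    over the tuple's dose grid — the best inhibition seen at any tested dose
    combination.  Dose indices are consumed only for duplicate detection,
    never as features.

    Parameters
    ----------
    records : validated screen table (see :func:`validate_screen`)
    on_duplicate : {"min", "raise"}
        Behavior when the same (tuple, dose pair) appears more than once with
        conflicting growth.  ``"min"`` (default) keeps the minimum, consistent
        with the min-over-doses target; ``"raise"`` errors.

    Returns
    -------
    DataFrame with columns CELL, DRUG_A, DRUG_B, MIN_GROWTH; one row per
    distinct tuple; DRUG_B is NA for single agents.
    """
    if on_duplicate not in ("min", "raise"):
        raise ValueError("on_duplicate must be 'min' or 'raise'")
    df = records.copy()
    df["GROWTH"] = cap_growth(df["GROWTH"].to_numpy())
    if on_duplicate == "raise":
        dose_key = TUPLE_KEY + ["DOSE_A", "DOSE_B"]
        dup = df.groupby(dose_key, dropna=False)["GROWTH"].nunique()
        if (dup > 1).any():
            bad = dup[dup > 1].index[0]
            raise ValueError(f"conflicting duplicate measurements at {bad}")
    out = (
        df.groupby(TUPLE_KEY, dropna=False, sort=True)["GROWTH"]
        .min()
        .reset_index()
        .rename(columns={"GROWTH": "MIN_GROWTH"})
    )
    return out[RESPONSE_COLUMNS]


def canonical_pair_key(drug_a: str, drug_b) -> tuple:
    """Unordered pair key: sorted (drug_a, drug_b); singles key on (drug_a,)."""
    if drug_b is None or (isinstance(drug_b, float) and np.isnan(drug_b)) or pd.isna(drug_b):
        return (drug_a,)
    return tuple(sorted((str(drug_a), str(drug_b))))


def _detect_sep(path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_screen(path) -> pd.DataFrame:
    """Read a delimited (comma or tab, autodetected) screen table and validate it."""
    df = pd.read_csv(path, sep=_detect_sep(path), dtype={c: str for c in ("CELL", "DRUG_A", "DRUG_B")})
    return validate_screen(df)


def write_screen(records: pd.DataFrame, path, sep: str = ",") -> None:
    records.to_csv(path, sep=sep, index=False)


def read_response(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_detect_sep(path), dtype={c: str for c in ("CELL", "DRUG_A", "DRUG_B")})
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")
    for col in ("CELL", "DRUG_A", "DRUG_B"):
        df[col] = df[col].astype("string").str.strip()
        df.loc[df[col].isin(["", "NA", "nan", "None"]), col] = pd.NA
    return df


def write_response(responses: pd.DataFrame, path, sep: str = ",") -> None:
    responses.to_csv(path, sep=sep, index=False)
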