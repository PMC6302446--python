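"""Modified combination-effect scoring: expected pair growth and BestComboScore.

Let y_a, y_b be the lowest single-agent growth fractions for a cell line and
y_ab the lowest growth over the pair's dose grid.  The modified expected
growth for the combination is

    z = min(y_a, y_b)                      if y_a <= 0 or y_b <= 0
      = min(y_a, 1) * min(y_b, 1)         otherwise

and the BestComboScore, in growth-percentage points, is

    C = (y_ab - z) * 100.

Negative C means the pair inhibited growth beyond the expectation from its
single agents — enhanced (greater-than-additive) activity.  Unlike the
original per-screen ComboScore, which sums over all dose combinations, only
the best-dose responses enter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .screen import RESPONSE_COLUMNS, _detect_sep

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "CELL", "DRUG_A", "DRUG_B", "Y_AB", "Y_A", "Y_B", "Z_AB", "BEST_COMBO_SCORE",
]


def _validate(*arrays):
    for a in arrays:
        if np.any(~np.isfinite(a)) or np.any(a < -1.0):
            raise ValueError("growth fractions must be finite and >= -1")


def expected_growth(y_a, y_b):
    """Modified expected pair growth z from two single-agent growths.

    If either single agent already inhibits growth (<= 0), the expectation is
    the stronger of the two; otherwise it is the product of the growths
    truncated at 1.  Symmetric in its arguments.  Scalar or array inputs.
    """
    a = np.asarray(y_a, dtype=float)
    b = np.asarray(y_b, dtype=float)
    _validate(a, b)
    min_branch = np.minimum(a, b)
    prod_branch = np.minimum(a, 1.0) * np.minimum(b, 1.0)
    z = np.where((a <= 0) | (b <= 0), min_branch, prod_branch)
    if np.ndim(y_a) == 0 and np.ndim(y_b) == 0:
        return float(z)
    return z


def best_combo_score(y_ab, y_a, y_b):
    """BestComboScore C = (y_ab - z) * 100, in growth-percentage points.

    ``y_ab`` is the pair's minimum capped growth.  Negative scores indicate
    better-than-expected inhibition.  Linear in ``y_ab`` with slope 100.
    """
    ab = np.asarray(y_ab, dtype=float)
    _validate(ab)
    c = (ab - expected_growth(y_a, y_b)) * 100.0
    if np.ndim(y_ab) == 0 and np.ndim(y_a) == 0 and np.ndim(y_b) == 0:
        return float(c)
    return c


def score_table(responses: pd.DataFrame, on_missing: str = "skip") -> pd.DataFrame:
    """Score every pair tuple of a response table.

    Joins each (cell, drug A, drug B) pair row with the two single-agent rows
    of the same cell line and computes z and BestComboScore.

    Parameters
    ----------
    responses : DataFrame with columns CELL, DRUG_A, DRUG_B, MIN_GROWTH
        (DRUG_B empty for single-agent rows).
    on_missing : {"skip", "raise"}
        Pairs lacking a single-agent row for either drug are unscorable; by
        default they are skipped with a warning (real screens have gaps).

    Returns
    -------
    DataFrame with columns CELL, DRUG_A, DRUG_B, Y_AB, Y_A, Y_B, Z_AB,
    BEST_COMBO_SCORE, one row per scorable pair tuple, deterministically
    ordered by key.
    """
    if on_missing not in ("skip", "raise"):
        raise ValueError("on_missing must be 'skip' or 'raise'")
    missing_cols = [c for c in RESPONSE_COLUMNS if c not in responses.columns]
    if missing_cols:
        raise ValueError(f"response table missing columns: {missing_cols}")

    singles = responses[responses["DRUG_B"].isna()]
    single_map = singles.set_index(["CELL", "DRUG_A"])["MIN_GROWTH"]
    if single_map.index.has_duplicates:
        raise ValueError("duplicate single-agent rows for the same (cell, drug)")
    pairs = responses[responses["DRUG_B"].notna()].copy()
    if pairs.empty:
        return pd.DataFrame(columns=SCORE_COLUMNS)

    key_a = pd.MultiIndex.from_frame(pairs[["CELL", "DRUG_A"]])
    key_b = pd.MultiIndex.from_frame(
        pairs[["CELL", "DRUG_B"]].rename(columns={"DRUG_B": "DRUG_A"})
    )
    y_a = single_map.reindex(key_a).to_numpy()
    y_b = single_map.reindex(key_b).to_numpy()
    unscorable = np.isnan(y_a) | np.isnan(y_b)
    if unscorable.any():
        n = int(unscorable.sum())
        if on_missing == "raise":
            raise ValueError(f"{n} pair rows lack a single-agent row")
        logger.warning("skipping %d unscorable pair rows (missing single-agent data)", n)
        pairs = pairs.loc[~unscorable]
        y_a, y_b = y_a[~unscorable], y_b[~unscorable]

    out = pairs[["CELL", "DRUG_A", "DRUG_B"]].copy()
    out["Y_AB"] = pairs["MIN_GROWTH"].to_numpy()
    out["Y_A"] = y_a
    out["Y_B"] = y_b
    out["Z_AB"] = expected_growth(y_a, y_b)
    out["BEST_COMBO_SCORE"] = (out["Y_AB"].to_numpy() - out["Z_AB"].to_numpy()) * 100.0
    out = out.sort_values(["CELL", "DRUG_A", "DRUG_B"], kind="mergesort").reset_index(drop=True)
    return out[SCORE_COLUMNS]


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_detect_sep(path), dtype={c: str for c in ("CELL", "DRUG_A", "DRUG_B")})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    return df


def write_scores(scores: pd.DataFrame, path, sep: str = ",") -> None:
    scores.to_csv(path, sep=sep, index=False)
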