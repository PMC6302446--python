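"""Assembly of model design matrices from response tables and feature matrices.

Each response-table row becomes one design row: the cell line's preprocessed
feature blocks side by side, then the descriptor vector of drug A, then the
descriptor vector of drug B.  Single-agent rows replicate the same
descriptor vector into both slots.  The column layout matches what
:class:`~comboscreen.estimator.PairResponseRegressor` expects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PairDataset:
    """A design matrix with its tuple keys and target vector.

    ``keys`` carries CELL, DRUG_A, DRUG_B (DRUG_B NA for single agents) in
    row order of ``X``; ``cell_dims`` records the block layout for the
    estimator.
    """

    X: np.ndarray
    y: np.ndarray
    keys: pd.DataFrame
    cell_dims: dict
    drug_dim: int


def build_dataset(
    responses: pd.DataFrame,
    cell_features: dict[str, pd.DataFrame],
    drug_features: pd.DataFrame,
    drop_unmatched: bool = True,
) -> PairDataset:
    """Join a response table to feature matrices into a design matrix.

    Parameters
    ----------
    responses : DataFrame with CELL, DRUG_A, DRUG_B, MIN_GROWTH
    cell_features : ordered mapping of feature-type name -> cell x feature
        DataFrame (fully preprocessed; no missing values)
    drug_features : drug x descriptor DataFrame (fully preprocessed)
    drop_unmatched : silently drop rows whose cell or drug has no feature row
        (otherwise raise)
    """
    resp = responses.reset_index(drop=True)
    cells_ok = pd.Series(True, index=resp.index)
    for name, mat in cell_features.items():
        if mat.isna().any().any():
            raise ValueError(f"cell feature matrix {name!r} has missing values; preprocess first")
        cells_ok &= resp["CELL"].isin(mat.index)
    if drug_features.isna().any().any():
        raise ValueError("drug feature matrix has missing values; preprocess first")
    drugs_ok = resp["DRUG_A"].isin(drug_features.index)
    drugs_ok &= resp["DRUG_B"].isna() | resp["DRUG_B"].isin(drug_features.index)
    ok = cells_ok & drugs_ok
    if not ok.all():
        if drop_unmatched:
            resp = resp.loc[ok].reset_index(drop=True)
        else:
            raise ValueError(f"{int((~ok).sum())} response rows lack feature data")

    blocks = []
    cell_dims = {}
    for name, mat in cell_features.items():
        arr = mat.reindex(resp["CELL"]).to_numpy(dtype=float)
        blocks.append(arr)
        cell_dims[name] = mat.shape[1]
    drug_a = drug_features.reindex(resp["DRUG_A"]).to_numpy(dtype=float)
    drug_b_ids = resp["DRUG_B"].fillna(resp["DRUG_A"])  # replicate for singles
    drug_b = drug_features.reindex(drug_b_ids).to_numpy(dtype=float)
    X = np.hstack(blocks + [drug_a, drug_b])
    y = resp["MIN_GROWTH"].to_numpy(dtype=float)
    return PairDataset(
        X=X,
        y=y,
        keys=resp[["CELL", "DRUG_A", "DRUG_B"]].copy(),
        cell_dims=cell_dims,
        drug_dim=drug_features.shape[1],
    )
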