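"""Error-aggregation views and virtual-screening rankings.

"Best" pairs are those with the most negative BestComboScore: a combination
growing below the single-agent expectation shows enhanced activity.  Per-cell
top-K lists, true-vs-predicted list differences, pooled frequency rankings
across the cell panel, and drug x drug / per-cell error summaries are the
analysis views over pooled out-of-fold predictions.

All ranking ties break lexicographically on the pair key, so outputs are
deterministic.  For set comparisons the two orderings of a screened pair are
collapsed to one unordered key by default (a flag preserves both orders).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .scoring import score_table


@dataclass
class TopKList:
    """Per-cell ranked list of pair keys, strongest enhancement first."""

    cell_id: str
    pairs: list
    k: int

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pair keys in top-K list")
        if len(self.pairs) > self.k:
            raise ValueError("list longer than K")


def _pair_keys(scores: pd.DataFrame, unordered: bool) -> pd.Series:
    a, b = scores["DRUG_A"].astype(str), scores["DRUG_B"].astype(str)
    if unordered:
        return pd.Series(
            [tuple(sorted(t)) for t in zip(a, b)], index=scores.index
        )
    return pd.Series(list(zip(a, b)), index=scores.index)


def top_k_pairs(
    scores: pd.DataFrame, cell_id: str, k: int = 100, unordered: bool = True
) -> TopKList:
    """The k most enhancing pairs of one cell line by ascending BestComboScore.

    With ``unordered=True`` (default) the two orderings of a pair collapse to
    one key keeping the more negative score.  Exact score ties break
    lexicographically on the pair key.  Fewer than k available pairs yield a
    shorter list; an unknown cell raises.
    """
    sub = scores[scores["CELL"] == cell_id]
    if sub.empty:
        raise KeyError(f"no scored pairs for cell {cell_id!r}")
    df = pd.DataFrame({
        "key": _pair_keys(sub, unordered),
        "score": sub["BEST_COMBO_SCORE"].to_numpy(),
    })
    df = df.groupby("key", as_index=False)["score"].min()
    df = df.sort_values(["score", "key"], kind="mergesort")
    return TopKList(cell_id=cell_id, pairs=list(df["key"].head(k)), k=k)


def top_list_difference(list_true: TopKList, list_pred: TopKList) -> int:
    """Members of the true top list missing from the predicted one (0..K)."""
    if list_true.cell_id != list_pred.cell_id:
        raise ValueError(
            f"cell mismatch: {list_true.cell_id!r} vs {list_pred.cell_id!r}"
        )
    if list_true.k != list_pred.k:
        raise ValueError("top lists use different K")
    return len(set(list_true.pairs) - set(list_pred.pairs))


def pooled_frequency_ranking(top_lists: list[TopKList], n: int = 10) -> list:
    """Pair keys ranked by how many per-cell top lists contain them.

    Invariant to the order of the input lists; count ties break
    lexicographically on the pair key.  Returns the top ``n`` keys.
    """
    if not top_lists:
        raise ValueError("need at least one top list")
    counts = Counter()
    for tl in top_lists:
        counts.update(set(tl.pairs))
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [key for key, _ in ordered[:n]]


def predicted_score_table(oof: pd.DataFrame) -> pd.DataFrame:
    """Recompute BestComboScore from predicted growths.

    Takes a pooled out-of-fold prediction table covering both single-agent
    and pair rows and rebuilds the score table using the predicted growth
    fractions (clipped to the valid [-1, 1] range) in place of the measured
    ones — the virtual-screening view of the model.
    """
    resp = oof[["CELL", "DRUG_A", "DRUG_B"]].copy()
    resp["MIN_GROWTH"] = np.clip(oof["Y_PRED"].to_numpy(dtype=float), -1.0, 1.0)
    return score_table(resp, on_missing="skip")


def per_cell_error_summary(oof: pd.DataFrame, scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell mean prediction error with spread, and mean BestComboScore.

    Error is predicted minus experimental growth.  Returns one row per cell:
    N, MEAN_ERROR, SD_ERROR (NaN below 2 observations), CI95_LO/HI
    (mean +/- 1.96 * standard error), and MEAN_BEST_COMBO_SCORE with its own
    95% CI when a score table is supplied.
    """
    df = oof.copy()
    df["ERROR"] = df["Y_PRED"].astype(float) - df["Y_TRUE"].astype(float)
    g = df.groupby("CELL")["ERROR"]
    out = pd.DataFrame({
        "N": g.size(),
        "MEAN_ERROR": g.mean(),
        "SD_ERROR": g.std(ddof=1),
    })
    se = out["SD_ERROR"] / np.sqrt(out["N"])
    out["CI95_LO"] = out["MEAN_ERROR"] - 1.96 * se
    out["CI95_HI"] = out["MEAN_ERROR"] + 1.96 * se
    if scores is not None:
        gs = scores.groupby("CELL")["BEST_COMBO_SCORE"]
        out["MEAN_BEST_COMBO_SCORE"] = gs.mean()
        se_s = gs.std(ddof=1) / np.sqrt(gs.size())
        out["SCORE_CI95_LO"] = out["MEAN_BEST_COMBO_SCORE"] - 1.96 * se_s
        out["SCORE_CI95_HI"] = out["MEAN_BEST_COMBO_SCORE"] + 1.96 * se_s
    return out.reset_index().sort_values("CELL", kind="mergesort").reset_index(drop=True)


def pair_error_matrix(oof: pd.DataFrame) -> pd.DataFrame:
    """Drug x drug matrix of mean (predicted - experimental) growth.

    Pair observations of both orderings pool into one unordered cell and the
    matrix is mirrored; the diagonal holds single-agent errors.  Cells with
    no observation are NaN.
    """
    df = oof.copy()
    df["ERROR"] = df["Y_PRED"].astype(float) - df["Y_TRUE"].astype(float)
    single = df["DRUG_B"].isna()
    drugs = sorted(set(df["DRUG_A"].astype(str)) | set(df.loc[~single, "DRUG_B"].astype(str)))
    mat = pd.DataFrame(np.nan, index=drugs, columns=drugs)
    if (~single).any():
        pairs = df.loc[~single].copy()
        keys = [tuple(sorted((a, b))) for a, b in zip(pairs["DRUG_A"].astype(str), pairs["DRUG_B"].astype(str))]
        pairs["_key"] = keys
        means = pairs.groupby("_key")["ERROR"].mean()
        for (d1, d2), v in means.items():
            mat.loc[d1, d2] = v
            mat.loc[d2, d1] = v
    if single.any():
        means = df.loc[single].groupby("DRUG_A")["ERROR"].mean()
        for d, v in means.items():
            mat.loc[str(d), str(d)] = v
    return mat


def cluster_order(matrix: pd.DataFrame) -> list:
    """Leaf order of average-linkage hierarchical clustering of drug rows.

    Distance between two drugs is 1 - Pearson correlation of their row
    vectors.  NaN entries are filled with the column mean before computing
    correlations; a constant row has undefined correlation and gets distance
    1 to everything by convention.  Deterministic given the input order.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 drugs to cluster")
    vals = matrix.to_numpy(dtype=float)
    col_means = np.nanmean(np.where(np.isnan(vals), np.nan, vals), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    filled = np.where(np.isnan(vals), col_means[None, :], vals)
    sd = filled.std(axis=1)
    n = len(filled)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    ok = sd > 0
    if ok.sum() >= 2:
        sub = filled[ok]
        corr = np.corrcoef(sub)
        d = 1.0 - corr
        ii = np.where(ok)[0]
        dist[np.ix_(ii, ii)] = np.clip(d, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    order = leaves_list(Z)
    return [matrix.index[i] for i in order]


def plot_pair_error_heatmap(matrix: pd.DataFrame, path, clustered: bool = True):
    """Render the pair-error matrix to an image file (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if clustered and matrix.shape[0] >= 2:
        order = cluster_order(matrix)
        matrix = matrix.loc[order, order]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap="coolwarm")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="mean predicted - experimental growth")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
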