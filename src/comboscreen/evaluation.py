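"""Stratified cross-validation, regression metrics, and the random-pair baseline.

Folds are stratified on binned growth fractions: the targets are binned into
a small number of classes and folds preserve each class's proportion.  Each
pair measurement is treated as an independent data point (no cell-line or
drug blocking by default; blocked splitting on cells or drugs is available
as an option for stricter generalization estimates).

The random-pair baseline predicts every sampled growth fraction with an
independent draw from the same empirical distribution — guessing by random
selection from the real distribution.  Its expected R-squared is -1 for any
distribution (the expected squared error of two independent draws is twice
the variance), which makes it a distribution-free floor for model skill.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .dataset import PairDataset


@dataclass
class MetricReport:
    """Standard regression metrics; r2 may be negative, and r2/correlations
    are NaN when the true targets are constant (undefined)."""

    mse: float
    mae: float
    r2: float
    pearson: float
    spearman: float

    def to_dict(self):
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_metrics(y_true, y_pred) -> MetricReport:
    """MSE, MAE, R^2 = 1 - SS_res/SS_tot, Pearson and Spearman correlations."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, nonempty")
    err = y_pred - y_true
    mse = float(np.mean(err ** 2))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return MetricReport(mse, mae, np.nan, np.nan, np.nan)
    r2 = 1.0 - float(np.sum(err ** 2)) / ss_tot
    if np.std(y_pred) == 0.0:
        pearson = spearman = np.nan
    else:
        pearson = float(stats.pearsonr(y_true, y_pred).statistic)
        spearman = float(stats.spearmanr(y_true, y_pred).statistic)
    return MetricReport(mse, mae, r2, pearson, spearman)


def bin_targets(targets, bins: int = 5, binning: str = "width") -> np.ndarray:
    """Bin real targets into ``bins`` classes for stratification.

    ``binning="width"`` uses equal-width bins over the observed range;
    ``"frequency"`` uses quantile (equal-count) bins.  Constant targets fall
    into a single class.
    """
    t = np.asarray(targets, dtype=float)
    if binning == "width":
        lo, hi = t.min(), t.max()
        if hi == lo:
            return np.zeros(len(t), dtype=int)
        edges = np.linspace(lo, hi, bins + 1)
        return np.clip(np.digitize(t, edges[1:-1]), 0, bins - 1)
    if binning == "frequency":
        edges = np.unique(np.quantile(t, np.linspace(0, 1, bins + 1)[1:-1]))
        return np.digitize(t, edges)
    raise ValueError("binning must be 'width' or 'frequency'")


def stratified_kfold(
    targets, k: int = 5, bins: int = 5, seed=None, binning: str = "width"
) -> tuple[np.ndarray, np.ndarray]:
    """Assign rows to k folds preserving per-bin proportions.

    Returns ``(fold_ids, bin_ids)``.  Per-bin fold counts differ by at most
    one sample; folds partition the rows exactly; reproducible from ``seed``.
    """
    t = np.asarray(targets, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(t) < k:
        raise ValueError(f"need at least k={k} rows, got {len(t)}")
    bin_ids = bin_targets(t, bins=bins, binning=binning)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_ids = np.empty(len(t), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(t)), bin_ids)):
        fold_ids[test_idx] = fold
    return fold_ids, bin_ids


def random_pair_baseline(targets, n_draws: int, seed=None) -> MetricReport:
    """Metrics of predicting growth by random selection from its own distribution.

    Draws ``n_draws`` independent (truth, guess) pairs with replacement from
    the target vector and scores the guesses.  R^2 concentrates near -1 and
    MAE near the mean absolute difference of two independent draws.
    """
    t = np.asarray(targets, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("baseline needs at least two distinct target values")
    rng = np.random.default_rng(seed)
    y_true = rng.choice(t, size=n_draws, replace=True)
    y_pred = rng.choice(t, size=n_draws, replace=True)
    return compute_metrics(y_true, y_pred)


class FoldTrainingError(RuntimeError):
    def __init__(self, fold, cause):
        super().__init__(f"training failed on fold {fold}: {cause}")
        self.fold = fold


def cross_validate(
    dataset: PairDataset,
    estimator,
    k: int = 5,
    bins: int = 5,
    seed=None,
    binning: str = "width",
    group_by: str | None = None,
) -> tuple[list[MetricReport], pd.DataFrame]:
    """Stratified k-fold cross-validation of a pair-response estimator.

    Each row is predicted exactly once by the model of the fold that did not
    train on it.  Returns per-fold metric reports and the pooled out-of-fold
    prediction table (CELL, DRUG_A, DRUG_B, Y_TRUE, Y_PRED, FOLD).

    ``group_by`` in {"cell", "drug"} switches to blocked splitting (all rows
    of a cell line / drug land in the same fold) for stricter generalization
    estimates; stratification on target bins is then approximate.
    """
    X, y = dataset.X, dataset.y
    if group_by is None:
        fold_ids, _ = stratified_kfold(y, k=k, bins=bins, seed=seed, binning=binning)
    else:
        fold_ids = _grouped_folds(dataset.keys, group_by, k, seed)

    reports = []
    oof = np.full(len(y), np.nan)
    for fold in range(k):
        test = fold_ids == fold
        est = clone(estimator)
        if seed is not None and "random_state" in est.get_params():
            est.set_params(random_state=int(seed) + fold)
        try:
            est.fit(X[~test], y[~test])
            pred = est.predict(X[test])
        except Exception as exc:  # noqa: BLE001 - annotate with fold id
            raise FoldTrainingError(fold, exc) from exc
        oof[test] = pred
        reports.append(compute_metrics(y[test], pred))

    table = dataset.keys.copy()
    table["Y_TRUE"] = y
    table["Y_PRED"] = oof
    table["FOLD"] = fold_ids
    return reports, table


def _grouped_folds(keys: pd.DataFrame, group_by: str, k: int, seed) -> np.ndarray:
    if group_by == "cell":
        groups = keys["CELL"]
    elif group_by == "drug":
        groups = keys["DRUG_A"]
    else:
        raise ValueError("group_by must be None, 'cell' or 'drug'")
    uniq = np.array(sorted(groups.unique()))
    if len(uniq) < k:
        raise ValueError(f"need at least k={k} groups for blocked splitting")
    rng = np.random.default_rng(seed)
    assignment = dict(zip(rng.permutation(uniq), np.arange(len(uniq)) % k))
    return groups.map(assignment).to_numpy()


def mean_report(reports: list[MetricReport]) -> MetricReport:
    """Average metrics across folds (NaNs propagate)."""
    return MetricReport(*[
        float(np.mean([getattr(r, f.name) for r in reports]))
        for f in fields(MetricReport)
    ])
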