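"""Preprocessing of omics and drug-descriptor matrices, plus ablation encodings.

Matrices are entity x feature pandas DataFrames with NaN marking missing
cells.  The canonical pipeline for descriptor-style matrices is

    filter sparse columns -> mean impute -> min-max scale to [0, 1]

with statistics fit on a training set and reused on held-out rows.  Omics
matrices that arrive in raw abundance units are log(x+1) transformed first;
matrices that arrive already log-transformed (common for public expression
and microRNA downloads) declare that via their state tags rather than being
sniffed.

Transformers follow scikit-learn conventions (``fit``/``transform``,
fitted attributes with a trailing underscore, clone-able constructors) and
operate on DataFrames, preserving index and columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """An entity x feature matrix with missing-value mask and processing state.

    ``data`` is a DataFrame (index = entity ids, columns = feature names,
    NaN = missing).  ``state`` accumulates tags from
    {"raw", "log_transformed", "imputed", "scaled"}.
    """

    data: pd.DataFrame
    state: set = field(default_factory=lambda: {"raw"})

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValueError("duplicate entity ids in feature matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature names in feature matrix")

    @property
    def row_ids(self):
        return list(self.data.index)

    @property
    def col_ids(self):
        return list(self.data.columns)

    def with_data(self, data: pd.DataFrame, add_state: str | None = None) -> "FeatureMatrix":
        state = set(self.state)
        if add_state:
            state.add(add_state)
        return FeatureMatrix(data, state)


def _as_frame(m) -> pd.DataFrame:
    return m.data if isinstance(m, FeatureMatrix) else m


class Log1pTransformer(TransformerMixin, BaseEstimator):
    """Elementwise log(x+1) on present values; missing cells pass through.

    Raises on negative values, naming the offending row and column: growth in
    abundance units cannot be negative, so a negative cell signals an
    already-transformed or corrupted input.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        fm = X if isinstance(X, FeatureMatrix) else None
        X = _as_frame(X)
        neg = X < 0
        if neg.any().any():
            col = neg.any(axis=0).idxmax()
            row = neg[col].idxmax()
            raise ValueError(f"negative value at row {row!r}, column {col!r}; cannot log(x+1)")
        out = np.log1p(X)
        if fm is not None:
            if "log_transformed" in fm.state:
                raise ValueError("matrix is already log-transformed")
            return fm.with_data(out, "log_transformed")
        return out


class SparseColumnFilter(TransformerMixin, BaseEstimator):
    """Drop columns whose missing fraction is at or above ``missing_frac``.

    The boundary is inclusive: with the default 0.9, a column missing in
    exactly 90% of rows is removed.  Column order is otherwise preserved and
    dropped names are logged.
    """

    def __init__(self, missing_frac: float = 0.9):
        self.missing_frac = missing_frac

    def fit(self, X, y=None):
        X = _as_frame(X)
        if not 0 < self.missing_frac <= 1:
            raise ValueError("missing_frac must be in (0, 1]")
        frac = X.isna().mean(axis=0)
        self.kept_columns_ = list(X.columns[frac.to_numpy() < self.missing_frac])
        self.dropped_columns_ = list(X.columns[frac.to_numpy() >= self.missing_frac])
        if self.dropped_columns_:
            logger.info(
                "dropping %d sparse columns (missing fraction >= %g): %s",
                len(self.dropped_columns_), self.missing_frac, self.dropped_columns_,
            )
        return self

    def transform(self, X):
        fm = X if isinstance(X, FeatureMatrix) else None
        X = _as_frame(X)
        out = X[self.kept_columns_]
        return fm.with_data(out) if fm is not None else out


class ColumnMeanImputer(TransformerMixin, BaseEstimator):
    """Replace missing cells with per-column means fit on the training rows."""

    def fit(self, X, y=None):
        X = _as_frame(X)
        all_missing = X.isna().all(axis=0)
        if all_missing.any():
            bad = list(X.columns[all_missing])
            raise ValueError(f"all-missing columns on fitting set (filter them first): {bad}")
        self.means_ = X.mean(axis=0)
        return self

    def transform(self, X):
        fm = X if isinstance(X, FeatureMatrix) else None
        X = _as_frame(X)
        out = X.fillna(self.means_)
        return fm.with_data(out, "imputed") if fm is not None else out


class ClippedMinMaxScaler(TransformerMixin, BaseEstimator):
    """Min-max scale each column to [0, 1] using training-set bounds.

    Constant columns map to 0.  Transform-only values outside the fitted
    bounds are clipped so the [0, 1] contract holds on held-out rows too.
    Requires a fully imputed matrix.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.isna().any().any():
            raise ValueError("min-max scaling requires no missing values (impute first)")
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        return self

    def transform(self, X):
        fm = X if isinstance(X, FeatureMatrix) else None
        X = _as_frame(X)
        if X.isna().any().any():
            raise ValueError("min-max scaling requires no missing values (impute first)")
        rng = (self.data_max_ - self.data_min_).replace(0.0, 1.0)
        out = ((X - self.data_min_) / rng).clip(0.0, 1.0)
        return fm.with_data(out, "scaled") if fm is not None else out


class MatrixPreprocessor(TransformerMixin, BaseEstimator):
    """Canonical filter -> impute -> scale pipeline for one feature matrix.

    Parameters
    ----------
    log1p : apply log(x+1) before anything else (raw abundance inputs only;
        leave False for descriptor matrices and pre-log-transformed omics).
    missing_frac : sparse-column threshold; None disables the filter.

    After ``transform`` the output has no missing values and every entry in
    [0, 1].  Statistics are fit on the rows passed to ``fit``; passing the
    full matrix reproduces whole-dataset fitting, passing training rows only
    gives leakage-safe fold-wise preprocessing.
    """

    def __init__(self, log1p: bool = False, missing_frac: float | None = 0.9):
        self.log1p = log1p
        self.missing_frac = missing_frac

    def fit(self, X, y=None):
        X = _as_frame(X).copy()
        steps = []
        if self.log1p:
            steps.append(Log1pTransformer())
        if self.missing_frac is not None:
            steps.append(SparseColumnFilter(self.missing_frac))
        steps.append(ColumnMeanImputer())
        steps.append(ClippedMinMaxScaler())
        for step in steps:
            X = step.fit(X).transform(X)
        self.steps_ = steps
        self.columns_ = list(X.columns)
        return self

    def transform(self, X):
        fm = X if isinstance(X, FeatureMatrix) else None
        X = _as_frame(X)
        for step in self.steps_:
            X = step.transform(X)
        return fm.with_data(X) if fm is not None else X


@dataclass
class EncodingSpec:
    """How to represent entities when real assay features are ablated.

    mode "one_hot" gives identifier-only identity vectors; "noise" gives a
    fixed seeded uniform[0,1] vector per entity (same entity, same vector);
    "assay" means real matrices are used and :func:`encode_entities` refuses.
    """

    mode: str = "assay"
    noise_dim: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("assay", "one_hot", "noise"):
            raise ValueError(f"unknown encoding mode {self.mode!r}")
        if self.noise_dim < 1:
            raise ValueError("noise_dim must be positive")


def encode_entities(ids, spec: EncodingSpec) -> pd.DataFrame:
    """Build an ablation feature matrix for a list of entity ids.

    one_hot -> |ids| x |ids| identity pattern; noise -> |ids| x noise_dim
    seeded uniform[0,1], reproducible from spec.seed and the sorted id list.
    """
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate entity ids")
    if spec.mode == "assay":
        raise ValueError("mode 'assay' uses real feature matrices, not encodings")
    if spec.mode == "one_hot":
        return pd.DataFrame(
            np.eye(len(ids)), index=ids, columns=[f"onehot_{i}" for i in ids]
        )
    # noise: one substream per entity so the vector depends only on (seed, id)
    order = sorted(ids)
    rng = np.random.default_rng(spec.seed)
    vecs = {eid: stream.uniform(size=spec.noise_dim)
            for eid, stream in zip(order, rng.spawn(len(order)))}
    mat = np.vstack([vecs[i] for i in ids])
    return pd.DataFrame(mat, index=ids, columns=[f"noise_{j}" for j in range(spec.noise_dim)])


def read_feature_matrix(path, na_values=("", "NA")) -> pd.DataFrame:
    """Read a delimited entity x feature matrix (first column = entity id)."""
    sep = None
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(na_values), keep_default_na=True)
    df.index = df.index.astype(str).str.strip()
    return df


def write_feature_matrix(m, path, sep: str = ",") -> None:
    _as_frame(m).to_csv(path, sep=sep, index=True, na_rep="")
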