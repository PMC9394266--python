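"""Preprocessing pipeline: mean imputation, categorical encoding,
train/test splitting, feature scaling, and Pearson correlation analysis.

All fit/transform pairs are leakage-safe by construction: statistics are
fitted on a caller-chosen row set (normally the training rows) and reused
verbatim on held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import (
    Dataset,
    FeatureSchema,
    KIND_BINARY,
    KIND_CATEGORICAL,
    KIND_CONTINUOUS,
)

MODE_STANDARDIZE = "standardize"
MODE_MINMAX = "minmax"

ENCODE_ONEHOT = "onehot"
ENCODE_INTEGER = "integer"


class DegenerateColumnError(ValueError):
    """A column is constant where variation is required."""


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def correlation_matrix(matrix: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Pearson correlation matrix of the columns of ``matrix``.

    r(x, y) = sum((x_i - x̄)(y_i - ȳ)) / sqrt(sum((x_i - x̄)²) sum((y_i - ȳ)²))

    Requires >= 2 rows, no missing values and non-constant columns (r is
    undefined for a zero-variance column).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("correlation requires fully observed data (impute first)")
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        label = names[bad[0]] if names else f"column {bad[0]}"
        raise DegenerateColumnError(f"constant column {label}: correlation undefined")
    r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_mean(
    data: Dataset, fit_rows: np.ndarray | list[int] | None = None
) -> tuple[Dataset, np.ndarray]:
    """Replace missing cells by per-column means of the non-missing ``fit_rows``.

    Returns the completed dataset (missing mask cleared) and the vector of
    column means used (NaN for columns that had nothing to impute is avoided:
    means are computed for every column so they can complete future data).
    """
    if fit_rows is None:
        fit_rows = np.arange(data.n_rows)
    fit_rows = np.asarray(fit_rows)
    vals = data.values[fit_rows]
    mask = data.missing_mask[fit_rows]
    n_obs = (~mask).sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(
            f"column {data.schema.names[j]!r} has no observed value among fit rows"
        )
    sums = np.where(mask, 0.0, vals).sum(axis=0)
    means = sums / n_obs
    out = data.values.copy()
    out[data.missing_mask] = np.broadcast_to(means, out.shape)[data.missing_mask]
    return (
        Dataset(data.schema, out, np.zeros_like(data.missing_mask), data.target.copy()),
        means,
    )


def apply_imputation(data: Dataset, means: np.ndarray) -> Dataset:
    """Complete ``data`` with previously fitted column means (no refitting)."""
    out = data.values.copy()
    out[data.missing_mask] = np.broadcast_to(means, out.shape)[data.missing_mask]
    return Dataset(data.schema, out, np.zeros_like(data.missing_mask), data.target.copy())


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

@dataclass
class EncodedMatrix:
    """Numeric design matrix with column provenance.

    ``provenance`` maps each expanded column name back to its source feature;
    ``scalable`` flags the columns feature scaling should touch (continuous
    ones; one-hot and binary columns stay as 0/1 by default).
    """

    column_names: list[str]
    values: np.ndarray
    provenance: dict[str, str]
    scalable: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


class Encoder:
    """Deterministic schema-driven encoder.

    one-hot mode: continuous and binary features pass through as single
    columns; each multi-level categorical expands to one 0/1 column per
    admissible level (named ``feature=level``).  integer mode: every feature
    passes through as its numeric code (a 13-column Cleveland design).
    """

    def __init__(self, schema: FeatureSchema, mode: str = ENCODE_ONEHOT):
        if mode not in (ENCODE_ONEHOT, ENCODE_INTEGER):
            raise ValueError(f"unknown encoder mode {mode!r}")
        self.schema = schema
        self.mode = mode
        names: list[str] = []
        provenance: dict[str, str] = {}
        scalable: list[bool] = []
        for f in schema.features:
            if mode == ENCODE_ONEHOT and f.kind == KIND_CATEGORICAL:
                for lv in f.levels:
                    col = f"{f.name}={lv}"
                    names.append(col)
                    provenance[col] = f.name
                    scalable.append(False)
            else:
                names.append(f.name)
                provenance[f.name] = f.name
                scalable.append(f.kind == KIND_CONTINUOUS)
        self.column_names = names
        self.provenance = provenance
        self.scalable = np.asarray(scalable, dtype=bool)

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def encode(self, data: Dataset) -> EncodedMatrix:
        if data.schema.names != self.schema.names:
            raise ValueError("dataset schema does not match encoder schema")
        if data.missing_mask.any():
            raise ValueError("encode requires imputed data (missing values present)")
        cols: list[np.ndarray] = []
        for j, f in enumerate(self.schema.features):
            col = data.values[:, j]
            if self.mode == ENCODE_ONEHOT and f.kind == KIND_CATEGORICAL:
                levels = np.asarray(f.levels)
                is_int = np.round(col) == col
                bad = is_int & ~np.isin(np.round(col), levels)
                if bad.any():
                    raise ValueError(
                        f"feature {f.name!r}: level {int(col[bad][0])} not in schema"
                    )
                if not is_int.all():
                    # mean imputation leaves fractional codes in categorical
                    # slots; snap them to the nearest admissible level
                    snapped = levels[np.abs(col[:, None] - levels[None, :]).argmin(axis=1)]
                    final = np.where(is_int, np.round(col), snapped).astype(int)
                else:
                    final = np.round(col).astype(int)
                for lv in f.levels:
                    cols.append((final == lv).astype(float))
            else:
                if f.kind in (KIND_BINARY, KIND_CATEGORICAL):
                    exactcodes = col[np.round(col) == col].astype(int)
                    bad = ~np.isin(exactcodes, f.levels)
                    if bad.any():
                        raise ValueError(
                            f"feature {f.name!r}: level {exactcodes[bad][0]} not in schema"
                        )
                cols.append(col.astype(float))
        return EncodedMatrix(
            list(self.column_names),
            np.column_stack(cols),
            dict(self.provenance),
            self.scalable.copy(),
        )


def fit_encoder(schema: FeatureSchema, mode: str = ENCODE_ONEHOT) -> Encoder:
    return Encoder(schema, mode)


def encode(encoder: Encoder, data: Dataset) -> EncodedMatrix:
    return encoder.encode(data)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalerParams:
    """Fitted per-column statistics.

    standardize: X' = (X - mu) / sigma with population SD (divide by n).
    minmax:      X' = (X - X_min) / (X_max - X_min), mapping min->0, max->1.
    ``scaled`` marks which columns the transform touches.
    """

    mode: str
    center: np.ndarray  # mu (standardize) or X_min (minmax)
    scale: np.ndarray   # sigma or X_max - X_min
    scaled: np.ndarray  # bool per column

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "scaled": self.scaled.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(
            mode=d["mode"],
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            scaled=np.asarray(d["scaled"], dtype=bool),
        )


def fit_scaler(
    matrix: EncodedMatrix,
    mode: str = MODE_STANDARDIZE,
    ddof: int = 0,
    scale_all: bool = False,
    strict: bool = True,
) -> ScalerParams:
    """Fit scaling statistics on the rows of ``matrix``.

    By default only continuous columns are scaled (``matrix.scalable``);
    ``scale_all`` forces every column in.  A zero-variance (or zero-range)
    column raises :class:`DegenerateColumnError` in strict mode and is
    silently left unscaled otherwise.
    """
    if mode not in (MODE_STANDARDIZE, MODE_MINMAX):
        raise ValueError(f"unknown scaler mode {mode!r}")
    X = matrix.values
    if X.shape[0] < 2:
        raise ValueError("fit requires at least 2 rows")
    scaled = np.ones(X.shape[1], dtype=bool) if scale_all else matrix.scalable.copy()
    if mode == MODE_STANDARDIZE:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=ddof)
    else:
        center = X.min(axis=0)
        scale = X.max(axis=0) - center
    degenerate = scaled & (scale == 0)
    if degenerate.any():
        name = matrix.column_names[int(np.flatnonzero(degenerate)[0])]
        if strict:
            raise DegenerateColumnError(
                f"column {name!r} has zero {'variance' if mode == MODE_STANDARDIZE else 'range'}"
            )
        scaled &= scale != 0
    safe = np.where(scale == 0, 1.0, scale)
    return ScalerParams(mode, center, safe, scaled)


def transform(matrix: EncodedMatrix, params: ScalerParams) -> EncodedMatrix:
    """Apply fitted scaling; unscaled columns pass through unchanged."""
    X = matrix.values.astype(float).copy()
    s = params.scaled
    X[:, s] = (X[:, s] - params.center[s]) / params.scale[s]
    return EncodedMatrix(
        list(matrix.column_names), X, dict(matrix.provenance), matrix.scalable.copy()
    )


def inverse_transform(matrix: EncodedMatrix, params: ScalerParams) -> EncodedMatrix:
    X = matrix.values.astype(float).copy()
    s = params.scaled
    X[:, s] = X[:, s] * params.scale[s] + params.center[s]
    return EncodedMatrix(
        list(matrix.column_names), X, dict(matrix.provenance), matrix.scalable.copy()
    )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def train_test_split(
    data: Dataset,
    train_fraction: float = 0.7,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[Dataset, Dataset]:
    """Disjoint, exhaustive train/test partition, reproducible from the seed.

    Train size is round(n * fraction); stratified mode preserves the class
    proportions within one instance per class.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = data.n_rows
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    if not stratified:
        perm = rng.permutation(n)
        return data.subset(np.sort(perm[:n_train])), data.subset(np.sort(perm[n_train:]))
    classes, counts = np.unique(data.target, return_counts=True)
    if len(classes) < 2:
        raise ValueError("stratified split requires both classes present")
    # proportional per-class allocation, then fix the total to n_train
    alloc = {int(c): int(round(k * train_fraction)) for c, k in zip(classes, counts)}
    diff = n_train - sum(alloc.values())
    order = sorted(alloc, key=lambda c: -alloc[c])
    i = 0
    while diff != 0:
        c = order[i % len(order)]
        nc = int(counts[classes == c][0])
        new = alloc[c] + (1 if diff > 0 else -1)
        if 0 < new < nc:
            alloc[c] = new
            diff += -1 if diff > 0 else 1
        i += 1
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in classes:
        rows = np.flatnonzero(data.target == c)
        perm = rng.permutation(len(rows))
        k = alloc[int(c)]
        train_idx.append(rows[perm[:k]])
        test_idx.append(rows[perm[k:]])
    return (
        data.subset(np.sort(np.concatenate(train_idx))),
        data.subset(np.sort(np.concatenate(test_idx))),
    )
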