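"""Reading and writing clinical tabular data in the UCI Cleveland dialect.

The Cleveland heart-disease table is distributed as a header-less CSV with 14
comma-separated fields per line (13 features + diagnosis) and ``?`` marking a
missing value.  This module defines the feature schema for that dialect, an
in-memory :class:`Dataset` container, and serialization for trained models and
metric reports.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING_TOKEN = "?"

KIND_CONTINUOUS = "continuous"
KIND_BINARY = "binary"
KIND_CATEGORICAL = "categorical"
_KINDS = (KIND_CONTINUOUS, KIND_BINARY, KIND_CATEGORICAL)


class ParseError(ValueError):
    """Malformed input file (wrong field count, non-numeric token, ...)."""


class ValidationError(ValueError):
    """Structurally valid input violating the schema (inadmissible level, ...)."""


class ModelFormatError(ValueError):
    """Malformed or version-mismatched model file."""


@dataclass(frozen=True)
class Feature:
    """One column of the table: a name, a kind, and (for discrete kinds) its
    admissible integer codes."""

    name: str
    kind: str
    levels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == KIND_BINARY and tuple(self.levels) not in ((0, 1), ()):
            raise ValueError(f"binary feature {self.name!r} must have levels (0, 1)")
        if self.kind == KIND_CATEGORICAL and len(self.levels) < 2:
            raise ValueError(f"categorical feature {self.name!r} needs >= 2 levels")
        if self.kind == KIND_BINARY and not self.levels:
            object.__setattr__(self, "levels", (0, 1))


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature definitions plus the target column.

    ``binarize_target`` collapses raw target codes greater than 1 (the UCI file
    grades disease severity 0-4) to the single "presence" label 1.  With the
    flag off, target values above 1 are rejected.
    """

    features: tuple[Feature, ...]
    target_name: str = "target"
    positive_label: int = 1
    binarize_target: bool = True

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if self.target_name in names:
            raise ValueError("target must not be among the features")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_dict(self) -> dict:
        return {
            "features": [
                {"name": f.name, "kind": f.kind, "levels": list(f.levels)}
                for f in self.features
            ],
            "target_name": self.target_name,
            "positive_label": self.positive_label,
            "binarize_target": self.binarize_target,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            features=tuple(
                Feature(f["name"], f["kind"], tuple(f["levels"]))
                for f in d["features"]
            ),
            target_name=d["target_name"],
            positive_label=d["positive_label"],
            binarize_target=d["binarize_target"],
        )


def cleveland_schema(binarize_target: bool = True) -> FeatureSchema:
    """The 13-feature Cleveland heart-disease schema.

    Continuous: age, restbp (resting blood pressure, mmHg), chol (serum
    cholesterol, mg/dL), thalach (max heart rate), oldpeak (exercise-induced
    ST depression).  Binary: sex, fbs (fasting blood sugar > 120 mg/dL),
    exang (exercise-induced angina).  Categorical: cp (chest-pain type 1-4),
    restecg (resting ECG 0-2), slope (peak-exercise ST slope 1-3), ca
    (fluoroscopy-colored major vessels 0-3), thal (thalassemia 3/6/7).
    """
    return FeatureSchema(
        features=(
            Feature("age", KIND_CONTINUOUS),
            Feature("sex", KIND_BINARY),
            Feature("cp", KIND_CATEGORICAL, (1, 2, 3, 4)),
            Feature("restbp", KIND_CONTINUOUS),
            Feature("chol", KIND_CONTINUOUS),
            Feature("fbs", KIND_BINARY),
            Feature("restecg", KIND_CATEGORICAL, (0, 1, 2)),
            Feature("thalach", KIND_CONTINUOUS),
            Feature("exang", KIND_BINARY),
            Feature("oldpeak", KIND_CONTINUOUS),
            Feature("slope", KIND_CATEGORICAL, (1, 2, 3)),
            Feature("ca", KIND_CATEGORICAL, (0, 1, 2, 3)),
            Feature("thal", KIND_CATEGORICAL, (3, 6, 7)),
        ),
        target_name="num",
        positive_label=1,
        binarize_target=binarize_target,
    )


@dataclass
class Dataset:
    """Rows of mixed-type features plus a binary target.

    ``values`` holds numeric codes as floats with NaN in missing slots;
    ``missing_mask`` is True exactly where the source had the missing token.
    """

    schema: FeatureSchema
    values: np.ndarray
    missing_mask: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.target = np.asarray(self.target, dtype=int)
        n, p = self.values.shape
        if p != self.schema.n_features:
            raise ValidationError(
                f"expected {self.schema.n_features} feature columns, got {p}"
            )
        if self.missing_mask.shape != (n, p) or self.target.shape != (n,):
            raise ValidationError("values, missing_mask and target shapes disagree")
        if not np.isin(self.target, (0, 1)).all():
            raise ValidationError("target values must be 0 or 1")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def subset(self, rows: Sequence[int] | np.ndarray) -> "Dataset":
        rows = np.asarray(rows)
        return Dataset(
            self.schema,
            self.values[rows].copy(),
            self.missing_mask[rows].copy(),
            self.target[rows].copy(),
        )

    def copy(self) -> "Dataset":
        return Dataset(
            self.schema,
            self.values.copy(),
            self.missing_mask.copy(),
            self.target.copy(),
        )


def _parse_token(token: str, line_no: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"line {line_no}: non-numeric token {token!r}"
        ) from None


def read_cleveland_csv(
    path: str | Path,
    schema: FeatureSchema | None = None,
    header: bool = False,
) -> Dataset:
    """Parse a UCI-dialect CSV into a :class:`Dataset`.

    Each data line must carry exactly ``n_features + 1`` comma-separated
    fields; ``?`` marks a missing value.  Categorical codes are validated
    against the schema; with ``schema.binarize_target`` raw target codes
    2-4 collapse to 1.

    Parameters
    ----------
    path : file path
    schema : defaults to :func:`cleveland_schema`
    header : skip a leading header line (the canonical file has none)
    """
    if schema is None:
        schema = cleveland_schema()
    n_fields = schema.n_features + 1
    values: list[list[float]] = []
    mask: list[list[bool]] = []
    target: list[int] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for line_no, row in enumerate(reader, start=1):
            if header and line_no == 1:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) != n_fields:
                raise ParseError(
                    f"line {line_no}: expected {n_fields} fields, got {len(row)}"
                )
            row = [tok.strip() for tok in row]
            vrow: list[float] = []
            mrow: list[bool] = []
            for feat, tok in zip(schema.features, row[:-1]):
                if tok == MISSING_TOKEN:
                    vrow.append(math.nan)
                    mrow.append(True)
                    continue
                val = _parse_token(tok, line_no)
                if feat.kind in (KIND_BINARY, KIND_CATEGORICAL):
                    code = int(round(val))
                    if code != val or code not in feat.levels:
                        raise ValidationError(
                            f"line {line_no}: value {tok!r} is not an admissible "
                            f"level of feature {feat.name!r} "
                            f"(levels {list(feat.levels)})"
                        )
                    val = float(code)
                vrow.append(val)
                mrow.append(False)
            tok = row[-1]
            if tok == MISSING_TOKEN:
                raise ParseError(f"line {line_no}: target may not be missing")
            tval = _parse_token(tok, line_no)
            tcode = int(round(tval))
            if tcode != tval or tcode < 0:
                raise ValidationError(
                    f"line {line_no}: target {tok!r} is not a nonnegative integer"
                )
            if tcode > 1:
                if not schema.binarize_target:
                    raise ValidationError(
                        f"line {line_no}: target {tcode} > 1 with binarization off"
                    )
                tcode = 1
            values.append(vrow)
            mask.append(mrow)
            target.append(tcode)
    if not values:
        raise ParseError(f"{path}: no data lines")
    return Dataset(
        schema,
        np.array(values, dtype=float),
        np.array(mask, dtype=bool),
        np.array(target, dtype=int),
    )


def _format_value(feat: Feature, value: float, missing: bool) -> str:
    if missing:
        return MISSING_TOKEN
    if feat.kind in (KIND_BINARY, KIND_CATEGORICAL):
        return str(int(round(value)))
    return repr(float(value))


def write_cleveland_csv(dataset: Dataset, path: str | Path) -> None:
    """Write a :class:`Dataset` back to the UCI dialect (``?`` for missing)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for i in range(dataset.n_rows):
            row = [
                _format_value(f, dataset.values[i, j], dataset.missing_mask[i, j])
                for j, f in enumerate(dataset.schema.features)
            ]
            row.append(str(int(dataset.target[i])))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Model and report serialization
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


def _canonical_json(obj) -> str:
    # sort_keys + fixed separators => byte-stable re-serialization; Python's
    # float repr round-trips the binary value exactly.
    return json.dumps(obj, sort_keys=True, separators=(",", ": "), indent=1)


def save_model(model, path: str | Path) -> None:
    """Serialize a trained model as a self-describing JSON text document.

    Saving, loading and saving again yields a byte-identical file.
    """
    doc = {"format": "mlppso-model", "version": MODEL_FORMAT_VERSION}
    doc.update(model.to_dict())
    Path(path).write_text(_canonical_json(doc) + "\n")


def load_model(path: str | Path):
    """Inverse of :func:`save_model`; raises :class:`ModelFormatError` on a
    malformed or version-mismatched file."""
    from .trainer import TrainedModel  # deferred: trainer imports this module

    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path}: not a valid model file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "mlppso-model":
        raise ModelFormatError(f"{path}: not an mlppso model file")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format version {doc.get('version')!r}"
        )
    try:
        return TrainedModel.from_dict(doc)
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: malformed model document: {exc}") from exc


_METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


def write_metrics_report(report, path: str | Path, format: str = "json") -> None:
    """Write per-fold and mean metrics (plus ROC points) as JSON or TSV."""
    if format == "json":
        Path(path).write_text(_canonical_json(report.to_dict()) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    lines = ["fold\t" + "\t".join(_METRIC_NAMES)]
    for i, fold in enumerate(report.folds, start=1):
        lines.append(
            f"{i}\t" + "\t".join(repr(getattr(fold, m)) for m in _METRIC_NAMES)
        )
    means = report.means()
    lines.append("mean\t" + "\t".join(repr(means[m]) for m in _METRIC_NAMES))
    Path(path).write_text("\n".join(lines) + "\n")


def read_metrics_report(path: str | Path):
    """Read back a JSON metrics report."""
    from .evaluation import MetricsReport  # deferred

    return MetricsReport.from_dict(json.loads(Path(path).read_text()))


def write_roc_points(points: Iterable[tuple[float, float, float]], path: str | Path) -> None:
    """Write ROC sweep points as TSV columns (threshold, FPR, TPR)."""
    lines = ["threshold\tfpr\ttpr"]
    for thr, fpr, tpr in points:
        lines.append(f"{repr(float(thr))}\t{repr(float(fpr))}\t{repr(float(tpr))}")
    Path(path).write_text("\n".join(lines) + "\n")
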