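"""Synthetic Cleveland-schema data with controllable class separation.

The generator draws class-conditional samples that mimic the shape of the
Cleveland heart-disease table: five continuous features with class-shifted
Gaussians, three binary and five multi-level categorical features with
class-tilted level probabilities, a near-balanced binary target, and
missing values injected only into ``ca`` and ``thal`` (where the real
file's nulls live).  A single ``effect_size`` knob controls the separation
of both feature kinds, so the Bayes-optimal accuracy of the generated task
rises smoothly from chance (effect 0) toward 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import (
    Dataset,
    Feature,
    FeatureSchema,
    KIND_BINARY,
    KIND_CONTINUOUS,
    cleveland_schema,
)

# Per-feature base means/SDs loosely scaled to the Cleveland ranges; the
# sign says which direction the diseased class shifts.
_CONTINUOUS_BASE = {
    "age": (54.0, 9.0, +1.0),
    "restbp": (131.0, 17.0, +1.0),
    "chol": (246.0, 52.0, +1.0),
    "thalach": (150.0, 23.0, -1.0),
    "oldpeak": (1.0, 1.1, +1.0),
}

# Base level probabilities; levels are listed in schema order.  Each level
# also carries a centered "risk score" that the class tilt multiplies.
_DISCRETE_BASE = {
    "sex": [0.32, 0.68],
    "cp": [0.08, 0.17, 0.28, 0.47],
    "fbs": [0.85, 0.15],
    "restecg": [0.50, 0.01, 0.49],
    "exang": [0.67, 0.33],
    "slope": [0.46, 0.46, 0.08],
    "ca": [0.59, 0.21, 0.13, 0.07],
    "thal": [0.55, 0.06, 0.39],
}

MISSINGNESS_FEATURES = ("ca", "thal")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    effect_size is the standardized mean shift of each continuous feature
    between classes and, for discrete features, the spread of the log-odds
    tilt applied to level probabilities.  missing_rate applies cellwise
    (MCAR) to ``ca`` and ``thal`` only.
    """

    n_rows: int = 303
    prevalence: float = 0.46
    effect_size: float = 1.0
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2:
            raise ValueError("n_rows must be >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def _level_scores(k: int) -> np.ndarray:
    # centered, unit-spread scores 0..k-1 -> tilt direction per level
    s = np.arange(k, dtype=float)
    s -= s.mean()
    s /= max(s.std(), 1.0)
    return s


def _tilted_probs(base: np.ndarray, shift: float) -> np.ndarray:
    logits = np.log(base) + shift * _level_scores(len(base))
    p = np.exp(logits - logits.max())
    return p / p.sum()


def generate(config: SynthConfig) -> Dataset:
    """Draw a Cleveland-schema dataset from the class-conditional model.

    Labels are Bernoulli(prevalence); continuous features are Gaussian with
    means shifted by ``effect_size`` within-class SDs between classes (split
    symmetrically around the base mean, sign per feature); discrete level
    probabilities are tilted by ``±effect_size/2`` in log-odds along each
    feature's level-risk scores.  Fully reproducible from the seed.
    """
    schema = cleveland_schema()
    rng = np.random.default_rng(config.seed)
    n = config.n_rows
    y = (rng.random(n) < config.prevalence).astype(int)
    values = np.empty((n, schema.n_features), dtype=float)

    for j, feat in enumerate(schema.features):
        if feat.kind == KIND_CONTINUOUS:
            mu, sd, direction = _CONTINUOUS_BASE[feat.name]
            shift = direction * config.effect_size * sd
            means = mu + np.where(y == 1, +0.5, -0.5) * shift
            values[:, j] = rng.normal(means, sd)
            if feat.name == "oldpeak":
                values[:, j] = np.maximum(values[:, j], 0.0)
        else:
            base = np.asarray(_DISCRETE_BASE[feat.name], dtype=float)
            levels = np.asarray(feat.levels, dtype=float)
            p_pos = _tilted_probs(base, +config.effect_size / 2.0)
            p_neg = _tilted_probs(base, -config.effect_size / 2.0)
            u = rng.random(n)
            col = np.empty(n)
            for cls, p in ((1, p_pos), (0, p_neg)):
                idx = y == cls
                col[idx] = levels[np.searchsorted(np.cumsum(p), u[idx], side="right").clip(max=len(levels) - 1)]
            values[:, j] = col

    mask = np.zeros_like(values, dtype=bool)
    if config.missing_rate > 0:
        for name in MISSINGNESS_FEATURES:
            j = schema.index(name)
            hit = rng.random(n) < config.missing_rate
            mask[hit, j] = True
            values[hit, j] = np.nan
    return Dataset(schema, values, mask, y)


def xor_schema() -> FeatureSchema:
    return FeatureSchema(
        features=(Feature("x1", KIND_BINARY), Feature("x2", KIND_BINARY)),
        target_name="xor",
    )


def generate_xor() -> Dataset:
    """The 4-point exclusive-or task: the canonical non-linearly-separable
    fixture for a hidden-layer network."""
    values = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    target = np.array([0, 1, 1, 0], dtype=int)
    return Dataset(xor_schema(), values, np.zeros_like(values, dtype=bool), target)
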