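"""Training the network with the swarm: the mean-squared-error objective
over the (preprocessed) training rows is evaluated at each particle's
decoded parameters, and the final global best becomes the classifier.

MSE = (1/n) * sum_i (y_i - yhat_i)^2 compares the sigmoid output
probabilities (not thresholded labels) against the 0/1 targets, so it is
bounded by [0, 1] and smooth in the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import mlp, preprocess, pso
from .data_io import Dataset, FeatureSchema


def mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared difference between targets and predicted probabilities."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("need at least one instance")
    return float(np.mean((y_true - y_pred) ** 2))


def make_objective(topology: mlp.Topology, X_train: np.ndarray, y_train: np.ndarray):
    """Pure objective over flat parameter vectors: v -> MSE(y, forward(v, X))."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[1] != topology.n_input:
        raise ValueError(
            f"design-matrix width {X_train.shape} does not match n_input {topology.n_input}"
        )
    if y_train.shape != (X_train.shape[0],):
        raise ValueError("target length does not match design-matrix rows")

    def objective(v: np.ndarray) -> float:
        return mse(y_train, mlp.forward(topology, v, X_train))

    return objective


@dataclass(frozen=True)
class PrepConfig:
    """Preprocessing choices carried with the model so prediction on raw
    rows reuses exactly the fitted statistics."""

    encoder_mode: str = preprocess.ENCODE_ONEHOT
    scaler_mode: str = preprocess.MODE_STANDARDIZE
    ddof: int = 0  # population SD by default

    def to_dict(self) -> dict:
        return {
            "encoder_mode": self.encoder_mode,
            "scaler_mode": self.scaler_mode,
            "ddof": self.ddof,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrepConfig":
        return cls(**d)


@dataclass
class TrainedModel:
    """Self-contained classifier: topology + final global-best parameters +
    the fitted preprocessing (imputation means, encoder mode, scaler)."""

    schema: FeatureSchema
    topology: mlp.Topology
    parameters: np.ndarray
    impute_means: np.ndarray
    prep_config: PrepConfig
    scaler_params: preprocess.ScalerParams
    training_history: list[float]
    pso_config: pso.PSOConfig
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "schema": self.schema.to_dict(),
            "topology": self.topology.to_dict(),
            "parameters": np.asarray(self.parameters, dtype=float).tolist(),
            "impute_means": np.asarray(self.impute_means, dtype=float).tolist(),
            "prep_config": self.prep_config.to_dict(),
            "scaler_params": self.scaler_params.to_dict(),
            "training_history": [float(h) for h in self.training_history],
            "pso_config": self.pso_config.to_dict(),
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        return cls(
            schema=FeatureSchema.from_dict(d["schema"]),
            topology=mlp.Topology.from_dict(d["topology"]),
            parameters=np.asarray(d["parameters"], dtype=float),
            impute_means=np.asarray(d["impute_means"], dtype=float),
            prep_config=PrepConfig.from_dict(d["prep_config"]),
            scaler_params=preprocess.ScalerParams.from_dict(d["scaler_params"]),
            training_history=[float(h) for h in d["training_history"]],
            pso_config=pso.PSOConfig.from_dict(d["pso_config"]),
            threshold=float(d["threshold"]),
        )


def _preprocess_fit(data: Dataset, prep: PrepConfig):
    completed, means = preprocess.impute_mean(data)
    encoder = preprocess.Encoder(data.schema, prep.encoder_mode)
    matrix = encoder.encode(completed)
    scaler = preprocess.fit_scaler(
        matrix, mode=prep.scaler_mode, ddof=prep.ddof, strict=False
    )
    return preprocess.transform(matrix, scaler), means, scaler


def _preprocess_apply(data: Dataset, model: "TrainedModel") -> np.ndarray:
    completed = preprocess.apply_imputation(data, model.impute_means)
    encoder = preprocess.Encoder(model.schema, model.prep_config.encoder_mode)
    matrix = encoder.encode(completed)
    return preprocess.transform(matrix, model.scaler_params).values


def train(
    data: Dataset,
    n_hidden: int = 30,
    pso_config: pso.PSOConfig | None = None,
    prep_config: PrepConfig | None = None,
    seed: int | None = None,
    threshold: float = 0.5,
) -> TrainedModel:
    """Fit the classifier on ``data``.

    Pipeline: impute -> encode -> scale (all fitted on these rows only),
    derive the input width from the encoded matrix, build the MSE objective,
    run the swarm, and package the global best with the fitted preprocessing.
    ``seed`` overrides the seed inside ``pso_config``.
    """
    if pso_config is None:
        pso_config = pso.PSOConfig()
    if prep_config is None:
        prep_config = PrepConfig()
    if seed is not None:
        pso_config = replace(pso_config, seed=int(seed))
    if data.n_rows < 2:
        raise ValueError("need at least 2 training rows")
    if len(np.unique(data.target)) < 2:
        raise ValueError("training data must contain both classes")

    matrix, means, scaler = _preprocess_fit(data, prep_config)
    topology = mlp.Topology(n_input=matrix.n_columns, n_hidden=n_hidden)
    objective = make_objective(topology, matrix.values, data.target)
    result = pso.optimize(objective, mlp.param_count(topology), pso_config)
    return TrainedModel(
        schema=data.schema,
        topology=topology,
        parameters=result.position,
        impute_means=means,
        prep_config=prep_config,
        scaler_params=scaler,
        training_history=result.history,
        pso_config=pso_config,
        threshold=threshold,
    )


def predict_model(model: TrainedModel, data: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and thresholded labels for raw rows, using the model's
    fitted preprocessing verbatim (nothing is refitted)."""
    if data.schema.names != model.schema.names:
        raise ValueError("dataset schema does not match the model's schema")
    X = _preprocess_apply(data, model)
    probs = mlp.forward(model.topology, model.parameters, X)
    return probs, mlp.predict(probs, model.threshold)
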