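"""Imputation, encoding, scaling, splitting and correlation — hand-computed
oracles plus leakage-control properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mlppso import preprocess, synthetic
from mlppso.data_io import Dataset, cleveland_schema
from mlppso.preprocess import (
    DegenerateColumnError,
    Encoder,
    correlation_matrix,
    fit_scaler,
    impute_mean,
    inverse_transform,
    train_test_split,
    transform,
)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 4.0, 2.0, 7.0])
        r = correlation_matrix(np.column_stack([x, x * 2 + 1]))
        assert r == pytest.approx(np.ones((2, 2)))

    def test_perfect_negative(self):
        r = correlation_matrix(np.array([[1, -1], [2, -2], [3, -3]], dtype=float))
        assert r[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        # x=(1,2,3,4), y=(2,1,4,3): direct evaluation of the Pearson formula
        # gives cov/ (sd_x sd_y) = 2 / sqrt(5 * 5) ... = 0.6
        r = correlation_matrix(np.array([[1, 2], [2, 1], [3, 4], [4, 3]], dtype=float))
        assert r[0, 1] == pytest.approx(0.6, abs=1e-12)

    def test_constant_column_named(self):
        with pytest.raises(DegenerateColumnError, match="chol"):
            correlation_matrix(
                np.array([[1.0, 5.0], [2.0, 5.0]]), names=["age", "chol"]
            )

    def test_symmetric_psd_on_synthetic(self, small_synth):
        completed, _ = impute_mean(small_synth)
        X = completed.values
        r = correlation_matrix(X)
        assert np.allclose(r, r.T)
        assert np.diag(r) == pytest.approx(np.ones(X.shape[1]))
        assert np.linalg.eigvalsh(r).min() >= -1e-10


def _tiny_dataset(values, mask=None):
    from mlppso.data_io import Feature, FeatureSchema

    schema = FeatureSchema(features=(Feature("x", "continuous"),))
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    if mask is None:
        mask = np.isnan(values)
    return Dataset(schema, values, mask, np.zeros(len(values), dtype=int))


class TestImputeMean:
    def test_mean_of_observed(self):
        data = _tiny_dataset([1.0, np.nan, 3.0])
        out, means = impute_mean(data)
        assert out.values[:, 0].tolist() == [1.0, 2.0, 3.0]
        assert means[0] == 2.0
        assert not out.missing_mask.any()

    def test_no_missing_is_identity(self, small_synth):
        data = small_synth.copy()
        data.missing_mask[:] = False
        data.values[np.isnan(data.values)] = 0.0
        out, _ = impute_mean(data)
        assert np.array_equal(out.values, data.values)

    def test_fit_rows_control_the_statistic(self):
        # train rows mean 2.0, pooled mean would differ -> imputed value
        # must come from the fit rows only
        data = _tiny_dataset([1.0, 3.0, 100.0, np.nan])
        out_train, _ = impute_mean(data, fit_rows=[0, 1])
        out_pooled, _ = impute_mean(data)
        assert out_train.values[3, 0] == 2.0
        assert out_pooled.values[3, 0] != out_train.values[3, 0]

    def test_all_missing_column_errors(self):
        data = _tiny_dataset([np.nan, np.nan])
        with pytest.raises(ValueError, match="x"):
            impute_mean(data)


class TestEncoder:
    def test_onehot_of_cp(self, small_synth):
        completed, _ = impute_mean(small_synth)
        enc = Encoder(small_synth.schema, "onehot")
        matrix = enc.encode(completed)
        j = matrix.column_names.index("cp=3")
        rows = np.flatnonzero(completed.values[:, small_synth.schema.index("cp")] == 3)
        assert (matrix.values[rows, j] == 1).all()
        group = [matrix.column_names.index(f"cp={l}") for l in (1, 2, 3, 4)]
        assert matrix.values[:, group].sum(axis=1) == pytest.approx(np.ones(matrix.values.shape[0]))

    def test_binary_passthrough(self, small_synth):
        completed, _ = impute_mean(small_synth)
        matrix = Encoder(small_synth.schema, "onehot").encode(completed)
        j = matrix.column_names.index("sex")
        assert np.isin(matrix.values[:, j], (0, 1)).all()

    def test_column_counts_by_level_enumeration(self):
        schema = cleveland_schema()
        # 5 continuous + 3 binary + (4 + 3 + 3 + 4 + 3) one-hot = 25
        n_levels = sum(
            len(f.levels) for f in schema.features if f.kind == "categorical"
        )
        assert Encoder(schema, "onehot").n_columns == 8 + n_levels == 25
        assert Encoder(schema, "integer").n_columns == 13

    def test_unknown_level_errors(self):
        schema = cleveland_schema()
        values = np.zeros((1, 13))
        values[0, schema.index("cp")] = 9  # not a cp level
        values[0, schema.index("slope")] = 1
        values[0, schema.index("thal")] = 3
        values[0, schema.index("ca")] = 0
        values[0, schema.index("restecg")] = 0
        data = Dataset(schema, values, np.zeros((1, 13), bool), np.array([0]))
        with pytest.raises(ValueError, match="cp"):
            Encoder(schema, "onehot").encode(data)

    def test_missing_values_rejected(self, small_synth):
        with pytest.raises(ValueError, match="imputed"):
            Encoder(small_synth.schema, "onehot").encode(small_synth)


def _matrix(values, scalable=None):
    values = np.asarray(values, dtype=float)
    p = values.shape[1]
    names = [f"c{j}" for j in range(p)]
    if scalable is None:
        scalable = np.ones(p, dtype=bool)
    return preprocess.EncodedMatrix(names, values, {n: n for n in names}, scalable)


class TestScaler:
    def test_standardize_hand_values(self):
        # (1,2,3) with population SD sqrt(2/3): values -+1.2247..., 0
        params = fit_scaler(_matrix([[1], [2], [3]]), "standardize")
        out = transform(_matrix([[1], [2], [3]]), params)
        expected = np.array([-1, 0, 1]) / np.sqrt(2 / 3)
        assert out.values[:, 0] == pytest.approx(expected, abs=1e-12)
        assert out.values[:, 0].mean() == pytest.approx(0, abs=1e-12)
        assert out.values[:, 0].std() == pytest.approx(1, abs=1e-12)

    def test_minmax_hand_values(self):
        params = fit_scaler(_matrix([[2], [4], [6]]), "minmax")
        out = transform(_matrix([[2], [4], [6]]), params)
        assert out.values[:, 0].tolist() == [0.0, 0.5, 1.0]

    def test_transform_reuses_fitted_stats(self):
        params = fit_scaler(_matrix([[1], [2], [3]]), "standardize")
        out = transform(_matrix([[2]]), params)  # the training mean
        assert out.values[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_onehot_columns_exempt(self):
        matrix = _matrix([[1, 0], [2, 1], [3, 0]], scalable=np.array([True, False]))
        out = transform(matrix, fit_scaler(matrix, "standardize"))
        assert np.isin(out.values[:, 1], (0, 1)).all()

    def test_zero_variance_strict_vs_lenient(self):
        matrix = _matrix([[5], [5]])
        with pytest.raises(DegenerateColumnError, match="c0"):
            fit_scaler(matrix, "standardize", strict=True)
        params = fit_scaler(matrix, "standardize", strict=False)
        assert np.array_equal(transform(matrix, params).values, matrix.values)

    @pytest.mark.parametrize("mode", ["standardize", "minmax"])
    def test_inverse_recovers_input(self, mode, small_synth):
        completed, _ = impute_mean(small_synth)
        matrix = Encoder(small_synth.schema, "onehot").encode(completed)
        params = fit_scaler(matrix, mode)
        back = inverse_transform(transform(matrix, params), params)
        assert np.abs(back.values - matrix.values).max() < 1e-10


class TestTrainTestSplit:
    def test_sizes(self, small_synth):
        train, test = train_test_split(small_synth, 0.7, stratified=False, seed=0)
        assert train.n_rows == 140 and test.n_rows == 60

    def test_disjoint_exhaustive(self, small_synth):
        data = small_synth
        data.values[:, 0] = np.arange(data.n_rows)  # unique row ids in age
        train, test = train_test_split(data, 0.7, stratified=True, seed=1)
        ids = np.concatenate([train.values[:, 0], test.values[:, 0]])
        assert sorted(ids.tolist()) == list(range(data.n_rows))

    def test_stratified_allocation(self):
        rng = np.random.default_rng(0)
        data = synthetic.generate(synthetic.SynthConfig(n_rows=100, seed=9))
        data.target = np.array([1] * 46 + [0] * 54)
        train, _ = train_test_split(data, 0.7, stratified=True, seed=0)
        assert train.n_rows == 70
        assert int(train.target.sum()) in (32, 33)

    def test_seed_determinism(self, small_synth):
        a = train_test_split(small_synth, 0.7, stratified=True, seed=5)
        b = train_test_split(small_synth, 0.7, stratified=True, seed=5)
        assert np.array_equal(a[0].values, b[0].values, equal_nan=True)
        assert np.array_equal(a[1].values, b[1].values, equal_nan=True)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1])
    def test_bad_fraction(self, frac, small_synth):
        with pytest.raises(ValueError):
            train_test_split(small_synth, frac)

    def test_single_class_stratified_errors(self, small_synth):
        data = small_synth.copy()
        data.target[:] = 1
        with pytest.raises(ValueError, match="class"):
            train_test_split(data, 0.7, stratified=True)


class TestLeakageControl:
    def test_heldout_statistics_never_consulted(self):
        """Fitting on train rows then transforming test rows must give the
        same result whatever the test rows contain."""
        from mlppso.data_io import Feature, FeatureSchema

        schema = FeatureSchema(features=(Feature("x", "continuous"),))

        def pipeline(test_value):
            values = np.array([[1.0], [2.0], [3.0], [test_value]])
            data = Dataset(schema, values, np.isnan(values), np.array([0, 1, 0, 1]))
            completed, means = impute_mean(data, fit_rows=[0, 1, 2])
            enc = Encoder(schema, "onehot")
            train_m = enc.encode(completed.subset([0, 1, 2]))
            params = fit_scaler(train_m, "standardize")
            return transform(enc.encode(completed.subset([3])), params).values[0, 0]

        assert pipeline(100.0) != pipeline(2.0)
        # and the transform of the same held-out value is train-determined
        assert pipeline(2.0) == pytest.approx(0.0, abs=1e-12)


@settings(derandomize=True, max_examples=25)
@given(
    rows=st.lists(
        st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=3, max_size=30
    )
)
def test_scaler_roundtrip_property(rows):
    X = np.asarray(rows, dtype=float)
    if (X.std(axis=0) < 1e-9).any():
        return
    matrix = _matrix(X)
    for mode in ("standardize", "minmax"):
        params = fit_scaler(matrix, mode)
        back = inverse_transform(transform(matrix, params), params)
        assert np.abs(back.values - X).max() < 1e-8
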