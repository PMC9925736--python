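"""MLP weight prediction: splits, architecture, training dynamics, metrics."""

import numpy as np
import pandas as pd
import pytest

from porcimetry.errors import InvalidParameterError
from porcimetry.features import clean_records, feature_set
from porcimetry.mlp import (
    EvaluationReport,
    SplitSpec,
    WeightMLPRegressor,
    evaluate,
    split_dataset,
)
from porcimetry.synthetic import generate_herd_records


def toy_table(n=100, seed=0):
    return pd.DataFrame({"x": np.random.default_rng(seed).normal(size=n)})


class TestSplitDataset:
    def test_exact_fraction_sizes(self):
        tr, te, va = split_dataset(toy_table(100))
        assert (len(tr), len(te), len(va)) == (70, 15, 15)

    def test_partition_is_disjoint_and_covers(self):
        table = toy_table(97)
        tr, te, va = split_dataset(table, SplitSpec(seed=3))
        allv = np.concatenate([tr["x"], te["x"], va["x"]])
        assert len(allv) == 97
        np.testing.assert_allclose(np.sort(allv), np.sort(table["x"]))

    def test_deterministic_per_seed(self):
        a = split_dataset(toy_table(50), SplitSpec(seed=11))
        b = split_dataset(toy_table(50), SplitSpec(seed=11))
        for x, y in zip(a, b):
            assert x.equals(y)

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidParameterError):
            split_dataset(pd.DataFrame({"x": []}))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            SplitSpec(train=0.5, test=0.5, validation=0.5)


class TestArchitecture:
    @pytest.mark.parametrize("d, expected", [(10, 104), (5, 79), (4, 74), (2, 64)])
    def test_parameter_count_five_d_plus_54(self, d, expected):
        m = WeightMLPRegressor(epochs=0, random_state=0)
        m.fit(np.zeros((4, d)), np.zeros(4))
        # independent layer-by-layer tally
        sizes = [d, 5, 4, 4, 1]
        tally = sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))
        assert m.n_parameters_ == tally == expected == 5 * d + 54

    def test_same_seed_identical_initialization(self):
        a = WeightMLPRegressor(epochs=0, random_state=42)
        b = WeightMLPRegressor(epochs=0, random_state=42)
        a.fit(np.zeros((4, 3)), np.zeros(4))
        b.fit(np.zeros((4, 3)), np.zeros(4))
        for wa, wb in zip(a.coefs_, b.coefs_):
            np.testing.assert_array_equal(wa, wb)

    def test_zero_epochs_keeps_initial_parameters(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(50, 3)), rng.normal(size=50)
        init = WeightMLPRegressor(epochs=0, random_state=5)
        init.fit(x, y)
        trained = WeightMLPRegressor(epochs=0, random_state=5)
        trained.fit(x, y)
        for wa, wb in zip(init.coefs_, trained.coefs_):
            np.testing.assert_array_equal(wa, wb)


class TestPredict:
    def test_all_zero_parameters_predict_zero(self):
        m = WeightMLPRegressor(epochs=0, random_state=0)
        m.fit(np.zeros((4, 3)), np.zeros(4))
        for w in m.coefs_:
            w[:] = 0.0
        for b in m.intercepts_:
            b[:] = 0.0
        np.testing.assert_array_equal(m.predict(np.random.normal(size=(7, 3))), 0.0)

    def test_matches_hand_rolled_forward_pass(self):
        rng = np.random.default_rng(1)
        m = WeightMLPRegressor(epochs=0, random_state=1)
        x = rng.normal(size=(20, 6))
        m.fit(x, rng.normal(size=20))
        a = x
        for i, (w, b) in enumerate(zip(m.coefs_, m.intercepts_)):
            z = a @ w + b
            a = np.maximum(z, 0) if i < len(m.coefs_) - 1 else z
        np.testing.assert_allclose(m.predict(x), a[:, 0], atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        m = WeightMLPRegressor(epochs=0, random_state=0)
        m.fit(np.zeros((4, 3)), np.zeros(4))
        with pytest.raises(InvalidParameterError):
            m.predict(np.zeros((4, 5)))


class TestTraining:
    def test_converges_on_noiseless_linear_data(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, size=(300, 1))
        y = 3.0 * x[:, 0]
        m = WeightMLPRegressor(epochs=300, random_state=0)
        m.fit(x, y)
        assert m.loss_curve_[-1] < 0.01 * m.loss_curve_[0]

    def test_loss_histories_have_epoch_length(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(60, 2)), rng.normal(size=60)
        m = WeightMLPRegressor(epochs=25, random_state=0)
        m.fit(x, y, validation_data=(x, y))
        assert len(m.loss_curve_) == 25
        assert len(m.validation_curve_) == 25

    def test_end_to_end_reproducibility(self):
        rec = generate_herd_records(300, seed=5)
        table = clean_records(rec)
        cols = feature_set(3)

        def run():
            tr, te, va = split_dataset(table, SplitSpec(seed=5))
            m = WeightMLPRegressor(epochs=30, random_state=5)
            m.fit(tr[cols].to_numpy(), tr["Weight"].to_numpy())
            return evaluate(te["Weight"].to_numpy(), m.predict(te[cols].to_numpy()))

        assert run() == run()

    def test_validation_loss_reduces_and_stabilizes(self):
        """Training and validation losses fall and then plateau: over the
        final 100 epochs the 10-epoch-smoothed validation loss stays inside
        a factor-2 band, far below its early value, with no net increase."""
        rec = generate_herd_records(10_000, seed=0, noise_sd_kg=2.0)
        table = clean_records(rec)
        cols = feature_set(1)
        tr, te, va = split_dataset(table, SplitSpec(seed=0))
        m = WeightMLPRegressor(epochs=300, random_state=0)
        m.fit(
            tr[cols].to_numpy(), tr["Weight"].to_numpy(),
            validation_data=(va[cols].to_numpy(), va["Weight"].to_numpy()),
        )
        v = np.convolve(m.validation_curve_, np.ones(10) / 10, mode="valid")
        tail = v[-100:]
        assert tail.mean() < 0.5 * max(m.validation_curve_)   # losses reduced
        assert tail.max() <= 2 * tail.min()                   # plateau band
        assert tail[-1] <= 1.25 * tail[:10].mean()            # no net increase


class TestNormalizationOrdering:
    def test_reduced_models_match_or_beat_the_full_model_when_normalized(self):
        """On a herd whose weight depends only on abdominal circumference
        and age, the row-normalized reduced models (2, 3, 4) reach a test
        RMSE no worse than the all-feature model 1 — the headline ordering
        of the original protocol, reproduced at its sample size."""
        from porcimetry.features import normalize_rows

        records = generate_herd_records(10_000, seed=0, noise_sd_kg=2.0)
        table = normalize_rows(clean_records(records))
        train, test, _ = split_dataset(table, SplitSpec(seed=0))
        rmse = {}
        for model_id in (1, 2, 3, 4):
            cols = feature_set(model_id)
            m = WeightMLPRegressor(random_state=model_id, n_restarts=0)
            m.fit(train[cols].to_numpy(), train["Weight"].to_numpy())
            rmse[model_id] = evaluate(
                test["Weight"].to_numpy(), m.predict(test[cols].to_numpy())
            ).rmse
        for model_id in (2, 3, 4):
            assert rmse[model_id] <= rmse[1] + 1e-9, rmse


class TestEvaluate:
    def test_perfect_prediction_gives_zeros(self):
        rep = evaluate([100.0, 110.0], [100.0, 110.0])
        assert (rep.mse, rep.rmse, rep.mae, rep.mape) == (0, 0, 0, 0)

    def test_forced_arithmetic_example(self):
        rep = evaluate([100.0], [110.0])
        assert rep.mse == pytest.approx(100.0)
        assert rep.rmse == pytest.approx(10.0)
        assert rep.mae == pytest.approx(10.0)
        assert rep.mape == pytest.approx(0.1)
        assert rep.n == 1

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(50, 150, 1000)
        p = a + rng.normal(0, 5, 1000)
        rep = evaluate(a, p)
        mse = sum((x - y) ** 2 for x, y in zip(a, p)) / 1000
        mae = sum(abs(x - y) for x, y in zip(a, p)) / 1000
        mape = sum(abs((x - y) / x) for x, y in zip(a, p)) / 1000
        assert rep.mse == pytest.approx(mse, abs=1e-12)
        assert rep.rmse == pytest.approx(np.sqrt(mse), abs=1e-12)
        assert rep.mae == pytest.approx(mae, abs=1e-12)
        assert rep.mape == pytest.approx(mape, abs=1e-12)

    def test_metric_identities_and_permutation_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(50, 150, 500)
        p = a + rng.normal(0, 3, 500)
        rep = evaluate(a, p)
        assert rep.rmse**2 == pytest.approx(rep.mse, abs=1e-12)
        assert rep.mae <= rep.rmse + 1e-12
        perm = rng.permutation(500)
        shuffled = evaluate(a[perm], p[perm])
        for attr in ("mse", "rmse", "mae", "mape"):
            assert getattr(shuffled, attr) == pytest.approx(getattr(rep, attr), rel=1e-12)

    def test_zero_actual_rejected(self):
        with pytest.raises(InvalidParameterError):
            evaluate([0.0, 1.0], [1.0, 1.0])

    def test_report_invariants(self):
        rep = EvaluationReport(mse=4.0, rmse=2.0, mae=1.5, mape=0.02, n=10)
        assert rep.to_dict()["rmse"] == 2.0
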