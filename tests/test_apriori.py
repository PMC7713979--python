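"""A-priori prediction: truncation, features, training, validation, intervals."""

import numpy as np
import pandas as pd
import pytest

from seqeffort.apriori import (
    MODEL1_FEATURES,
    build_training_table,
    cross_validate,
    extract_features,
    predict_from_partial,
    predict_with_interval,
    regression_metrics,
    train_predictor,
    truncate_curve,
)
from seqeffort.errors import DataValidationError, ParameterError
from seqeffort.growth_models import eval_weibull2
from seqeffort.matrix_sim import SimulationConfig, simulate_corpus
from seqeffort.rarefaction import build_curve, curve_from_vector, pool_samples


@pytest.fixture(scope="module")
def corpus_table():
    """Small saturated-community corpus with features and full-curve targets."""
    cfg = SimulationConfig(
        k_range=(100, 1000),
        reads_range=(10_000, 80_000),
        alpha_spec=(0.5, 2.0),
        n_matrices=40,
        seed=123,
    )
    table = build_training_table(simulate_corpus(cfg))
    return table.dropna(subset=[*MODEL1_FEATURES, "max_genes"]).reset_index(drop=True)


@pytest.fixture(scope="module")
def hundred_knot_curve():
    x = np.round(np.linspace(1, 500_000, 100)).astype(int)
    return curve_from_vector(x, eval_weibull2(x, 1000.0, 2e-5))


class TestTruncate:
    def test_identity_at_full_fraction(self, hundred_knot_curve):
        t = truncate_curve(hundred_knot_curve, 1.0)
        assert np.array_equal(t.depths, hundred_knot_curve.depths)
        assert t.kinds == hundred_knot_curve.kinds

    def test_first_20_knots(self, hundred_knot_curve):
        t = truncate_curve(hundred_knot_curve, 0.2, mode="by_knots")
        assert t.n_knots == 20
        assert np.array_equal(t.depths, hundred_knot_curve.depths[:20])

    def test_by_depth_filter(self, hundred_knot_curve):
        t = truncate_curve(hundred_knot_curve, 0.2, mode="by_depth")
        assert np.all(t.depths <= 0.2 * hundred_knot_curve.depths.max())

    def test_too_few_survivors(self, hundred_knot_curve):
        with pytest.raises(DataValidationError):
            truncate_curve(hundred_knot_curve, 0.01, mode="by_knots")


class TestExtractFeatures:
    def test_ranges_read_off_knots(self, hundred_knot_curve):
        t = truncate_curve(hundred_knot_curve, 0.2)
        f = extract_features(t)
        assert f.min_reads == t.depths[0]
        assert f.max_reads == t.depths[-1]
        assert f.max_genes == pytest.approx(t.richness[-1])

    def test_asymptote_recovered_from_truncation(self):
        # knots cover well past the half-depth ln(2)/c = 34k reads
        x = np.round(np.linspace(1, 100_000, 40)).astype(int)
        curve = curve_from_vector(x, eval_weibull2(x, 1000.0, 2e-5))
        f = extract_features(curve)
        assert f.weibull_ok
        assert f.asym_weibull4 == pytest.approx(1000.0, rel=0.10)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        assert regression_metrics([1, 2, 3], [1, 2, 3]) == (1.0, 0.0, 0.0)

    def test_worked_arithmetic(self):
        r2, rmse, mae = regression_metrics([1, 4], [1, 2])
        assert mae == pytest.approx(1.0)
        assert rmse == pytest.approx(np.sqrt(2))
        assert r2 == pytest.approx(1 - 4 / 4.5)

    def test_zero_variance_target(self):
        r2, _, _ = regression_metrics([2, 2], [1, 3])
        assert r2 is None

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y, yhat = rng.normal(size=(2, 12))
            _, rmse, mae = regression_metrics(y, yhat)
            assert mae <= rmse + 1e-12


def _linear_frame(n=30, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(1, 100, size=(n, 4)), columns=list(MODEL1_FEATURES)
    )
    y = 3.0 * X["asym_weibull4"] + 0.5 * X["min_reads"] + 7.0
    return X, y


class TestTrainPredictor:
    def test_exact_linear_target_reaches_r2_one(self):
        X, y = _linear_frame()
        model = train_predictor(X, y, "linear", seed=0, bag_size=5)
        r2, _, _ = regression_metrics(y, model.predict(X))
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_reproducible_given_seed(self):
        X, y = _linear_frame()
        m1 = train_predictor(X, y, "boosting", seed=5, bag_size=3)
        m2 = train_predictor(X, y, "boosting", seed=5, bag_size=3)
        assert np.array_equal(m1.predict(X), m2.predict(X))
        p1 = predict_with_interval(m1, X.iloc[[0]])
        p2 = predict_with_interval(m2, X.iloc[[0]])
        assert p1 == p2

    def test_constant_target_rejected(self):
        X, _ = _linear_frame()
        with pytest.raises(DataValidationError):
            train_predictor(X, np.full(len(X), 5.0), "linear")

    def test_kernel_kind_learns_smooth_target(self):
        X, y = _linear_frame(n=60)
        model = train_predictor(X, y, "kernel", seed=0, bag_size=3)
        r2, _, _ = regression_metrics(y, model.predict(X))
        assert r2 > 0.9


class TestPredictWithInterval:
    def test_degenerate_bag_degenerate_interval(self):
        # exactly realizable linear target: zero residuals, zero bag spread
        X, y = _linear_frame()
        model = train_predictor(X, y, "linear", seed=0, bag_size=10)
        res = predict_with_interval(model, X.iloc[[0]])
        lo, hi = res.interval
        assert hi - lo == pytest.approx(0.0, abs=1e-6 * abs(res.point))

    def test_interval_contains_point_and_median(self):
        X, y = _linear_frame()
        y = y + np.random.default_rng(3).normal(0, 5.0, size=len(y))
        model = train_predictor(X, y, "boosting", seed=1, bag_size=20)
        res = predict_with_interval(model, X.iloc[[3]])
        lo, hi = res.interval
        bag_preds = [float(m.predict(X.iloc[[3]].to_numpy(float))[0]) for m in model.bag]
        assert lo <= res.point <= hi
        assert lo <= np.median(bag_preds) <= hi

    def test_levels_nest(self):
        X, y = _linear_frame()
        y = y + np.random.default_rng(3).normal(0, 5.0, size=len(y))
        model = train_predictor(X, y, "linear", seed=1, bag_size=20)
        i95 = predict_with_interval(model, X.iloc[[2]], level=0.95).interval
        i99 = predict_with_interval(model, X.iloc[[2]], level=0.99).interval
        assert i99[0] <= i95[0] and i95[1] <= i99[1]

    def test_missing_features_named(self):
        X, y = _linear_frame()
        model = train_predictor(X, y, "linear", seed=0, bag_size=2)
        bad = X.iloc[[0]].copy()
        bad["asym_weibull4"] = np.nan
        with pytest.raises(DataValidationError, match="asym_weibull4"):
            predict_with_interval(model, bad)


class TestCrossValidate:
    def test_deterministic_target_perfect_scores(self):
        X, y = _linear_frame(n=30)
        rep = cross_validate(X, y, "linear", n_resamples=5, seed=0)
        for r2, rmse, mae in rep.per_resample:
            assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_bands_nest_and_contain_mean(self, corpus_table):
        rep = cross_validate(
            corpus_table, corpus_table["max_genes"], "linear", n_resamples=10, seed=2
        )
        for metric in ("r2", "rmse", "mae"):
            s = rep.summary[metric]
            assert s["band95"][0] <= s["mean"] <= s["band95"][1]
            assert s["band99"][0] <= s["band95"][0]
            assert s["band95"][1] <= s["band99"][1]

    def test_single_resample_summary_equals_entry(self):
        X, y = _linear_frame(n=30)
        y = y + np.random.default_rng(0).normal(0, 1, len(y))
        rep = cross_validate(X, y, "linear", n_resamples=1, seed=0)
        assert rep.summary["rmse"]["mean"] == pytest.approx(rep.per_resample[0][1])
        assert rep.summary["rmse"]["band95"] == rep.summary["rmse"]["band99"]

    def test_too_small_table_rejected(self):
        X, y = _linear_frame(n=10)
        with pytest.raises(ParameterError):
            cross_validate(X, y, "linear")


class TestPredictFromPartial:
    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            predict_from_partial([1, 2, 3], [1.0, 2.0, 3.0], {})

    def test_non_monotone_depth(self):
        with pytest.raises(DataValidationError):
            predict_from_partial([1, 5, 4, 8, 10], [1, 2, 3, 4, 5], {})

    def test_held_out_prediction_tracks_direct_estimate(self, corpus_table):
        # models trained on full-depth features should reproduce the direct
        # Weibull estimate when handed a full-depth vector
        cfg = SimulationConfig(
            k_range=(100, 1000), reads_range=(10_000, 80_000),
            alpha_spec=(0.5, 2.0), n_matrices=1, seed=777,
        )
        mat = simulate_corpus(cfg)[0]
        curve = build_curve(pool_samples(mat))
        full = build_training_table([mat], fraction=1.0)
        # train at fraction=1 so the full vector is in-distribution
        cfg_train = SimulationConfig(
            k_range=(100, 1000), reads_range=(10_000, 80_000),
            alpha_spec=(0.5, 2.0), n_matrices=30, seed=321,
        )
        table = build_training_table(simulate_corpus(cfg_train), fraction=1.0)
        table = table.dropna(subset=[*MODEL1_FEATURES, "max_genes"])
        model = train_predictor(table, table["max_genes"], "linear", seed=0, bag_size=10)
        mask = np.array([k != "extrapolated" for k in curve.kinds])
        report = predict_from_partial(
            curve.depths[mask], curve.richness[mask], {"max_genes": model}
        )
        direct = report["direct_weibull"]["max_genes"]
        pred = report["predictions"]["max_genes"].point
        assert pred == pytest.approx(direct, rel=0.10)
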