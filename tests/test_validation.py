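import math

import numpy as np
import pytest

from miaqsar.qsar_model import fit_pls, predict, select_components
from miaqsar.validation import (
    ChannelStats,
    bootstrap_external,
    build_report,
    calibration_stats,
    ccc,
    loo_q2,
    roy_metrics,
    williams,
    y_randomization,
)


def _linear_data(rng, n=20, p=5, noise=0.2):
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + noise * rng.normal(size=n)
    return X, y


class TestCalibration:
    def test_perfect_fit_gives_unit_r2_zero_rmsec(self, rng):
        X, y = _linear_data(rng, noise=0.0)
        model = fit_pls(X, y, 5)
        r2, rmsec = calibration_stats(model, X, y)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert rmsec == pytest.approx(0.0, abs=1e-8)

    def test_constant_response_is_error(self, rng):
        X, y = _linear_data(rng)
        model = fit_pls(X, y, 2)
        with pytest.raises(ValueError, match="constant"):
            calibration_stats(model, X, np.full_like(y, 3.0))

    def test_matches_direct_formula_oracle(self, rng):
        X, y = _linear_data(rng)
        model = fit_pls(X, y, 3)
        r2, rmsec = calibration_stats(model, X, y)
        resid = y - predict(model, X)
        assert r2 == pytest.approx(1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2), abs=1e-10)
        assert rmsec == pytest.approx(np.sqrt(np.mean(resid**2)), abs=1e-10)


class TestLooQ2:
    def test_noiseless_linear_data_reaches_unit_q2(self, rng):
        X, y = _linear_data(rng, noise=0.0)
        q2, rmsecv = loo_q2(X, y, 5)
        assert q2 == pytest.approx(1.0, abs=1e-10)
        assert rmsecv == pytest.approx(0.0, abs=1e-6)

    def test_matches_explicit_refit_oracle(self, rng):
        X, y = _linear_data(rng, n=8, p=4)
        A = 2
        preds = np.empty(8)
        for i in range(8):
            mask = np.ones(8, dtype=bool)
            mask[i] = False
            preds[i] = predict(fit_pls(X[mask], y[mask], A), X[i : i + 1])[0]
        press = np.sum((y - preds) ** 2)
        q2, rmsecv = loo_q2(X, y, A)
        assert q2 == pytest.approx(1 - press / np.sum((y - y.mean()) ** 2), abs=1e-10)
        assert rmsecv == pytest.approx(np.sqrt(press / 8), abs=1e-10)

    def test_q2_never_exceeds_r2(self, rng):
        for seed in range(5):
            local = np.random.default_rng(seed)
            X, y = _linear_data(local, n=16, p=6, noise=0.4)
            model = fit_pls(X, y, 3)
            r2, _ = calibration_stats(model, X, y)
            q2, _ = loo_q2(X, y, 3)
            assert q2 <= r2 + 1e-10


class TestYRandomization:
    def test_identity_permutation_collapses_penalty(self, rng):
        X, y = _linear_data(rng)
        res = y_randomization(X, y, 2, permutations=[np.arange(len(y))])
        assert res.r2_y_rand == pytest.approx(res.r2, abs=1e-10)
        assert res.c_r2_p == pytest.approx(0.0, abs=1e-6)

    def test_fixed_seed_is_bit_reproducible(self, rng):
        X, y = _linear_data(rng)
        a = y_randomization(X, y, 2, n_perm=10, seed=7)
        b = y_randomization(X, y, 2, n_perm=10, seed=7)
        assert a.c_r2_p == b.c_r2_p
        np.testing.assert_array_equal(a.r2_perm, b.r2_perm)

    def test_informative_model_beats_randomized(self, rng):
        X, y = _linear_data(rng, n=25, noise=0.1)
        res = y_randomization(X, y, 3, n_perm=20, seed=1)
        assert res.r2_y_rand < res.r2 - 0.3
        assert res.c_r2_p > 0.5


class TestRoy:
    def test_perfect_prediction_gives_unit_r2m(self, rng):
        y = rng.normal(size=10)
        r2m, r2m_rev, avg, delta = roy_metrics(y, y)
        assert r2m == pytest.approx(1.0)
        assert avg == pytest.approx(1.0)
        assert delta == pytest.approx(0.0)

    def test_matches_direct_formula_oracle(self, rng):
        obs = rng.normal(size=12)
        pred = obs + 0.3 * rng.normal(size=12)
        r2 = np.corrcoef(obs, pred)[0, 1] ** 2
        k = obs @ pred / (pred @ pred)
        r02 = 1 - np.sum((obs - k * pred) ** 2) / np.sum((obs - obs.mean()) ** 2)
        expected = r2 * (1 - math.sqrt(abs(r2 - r02)))
        r2m, _, _, _ = roy_metrics(obs, pred)
        assert r2m == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_input_is_error(self):
        with pytest.raises(ValueError):
            roy_metrics(np.ones(5), np.arange(5.0))


class TestCcc:
    def test_identical_vectors_give_one(self, rng):
        y = rng.normal(size=15)
        assert ccc(y, y) == pytest.approx(1.0)

    def test_constant_shift_is_penalized_below_pearson(self, rng):
        y = rng.normal(size=15)
        shifted = y + 2.0
        assert ccc(y, shifted) < 1.0
        assert np.corrcoef(y, shifted)[0, 1] == pytest.approx(1.0)

    def test_magnitude_never_exceeds_pearson(self):
        for seed in range(8):
            local = np.random.default_rng(seed)
            a = local.normal(size=20)
            b = 0.5 * a + local.normal(size=20)
            assert abs(ccc(a, b)) <= abs(np.corrcoef(a, b)[0, 1]) + 1e-12

    def test_matches_population_moment_oracle(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        expected = (
            2 * np.mean((a - a.mean()) * (b - b.mean()))
            / (np.var(a) + np.var(b) + (a.mean() - b.mean()) ** 2)
        )
        assert ccc(a, b) == pytest.approx(expected, abs=1e-12)

    def test_double_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            ccc(np.ones(5), np.ones(5))


class TestWilliams:
    def test_leverages_sum_to_components_plus_one(self, rng):
        X, y = _linear_data(rng, n=18, p=7, noise=0.3)
        model = fit_pls(X, y, 4)
        res = williams(model, X, y)
        assert sum(p.leverage for p in res.points) == pytest.approx(5.0, abs=1e-6)
        assert all(0 < p.leverage <= 1 for p in res.points)

    def test_duplicated_samples_share_leverage(self, rng):
        X, y = _linear_data(rng, n=10, p=4, noise=0.3)
        X[1], y[1] = X[0], y[0]
        model = fit_pls(X, y, 2)
        res = williams(model, X, y)
        assert res.points[0].leverage == pytest.approx(res.points[1].leverage, abs=1e-10)

    def test_exact_interpolation_is_degenerate(self, rng):
        X = rng.normal(size=(3, 4))
        y = rng.normal(size=3)
        model = fit_pls(X, y, 2)
        with pytest.raises(ValueError, match="leverage 1"):
            williams(model, X, y)

    def test_planted_five_sigma_outlier_is_the_only_flag(self, props, canvas):
        from miaqsar.imaging import build_descriptor_matrix
        from miaqsar.synthetic_data import GeneratorConfig, generate_dataset

        cfg = GeneratorConfig(
            n_samples=40, noise_sd=0.2, seed=11, outlier_index=7, truncate_noise_sd=2.0
        )
        ds = generate_dataset(cfg)
        y = np.array([a.pki for a in ds.activities])
        dm = build_descriptor_matrix(ds.sketches, "epsilon", canvas, props)
        model = fit_pls(dm.X, y, select_components(dm.X, y, 8))
        res = williams(model, dm.X, y, ids=dm.ids)
        flagged = [p.id for p in res.points if p.residual_outlier]
        assert flagged == [ds.sketches[7].id]


class TestBootstrap:
    def test_quarter_fraction_of_57_holds_out_14(self, rng):
        X, y = _linear_data(rng, n=57, p=8, noise=0.3)
        boot = bootstrap_external(X, y, a_max=3, frac=0.25, n_iter=4, seed=0)
        assert all(it.test_indices.size == 14 for it in boot.iterations)

    def test_noiseless_data_validates_perfectly(self, rng):
        X, y = _linear_data(rng, n=24, p=5, noise=0.0)
        boot = bootstrap_external(X, y, a_max=5, frac=0.25, n_iter=4, seed=3)
        for it in boot.iterations:
            assert it.r2_pred == pytest.approx(1.0, abs=1e-8)
            assert it.ccc == pytest.approx(1.0, abs=1e-8)

    def test_fixed_seed_reproduces_holdout_draws(self, rng):
        X, y = _linear_data(rng, n=30, p=6)
        a = bootstrap_external(X, y, a_max=3, n_iter=5, seed=9)
        b = bootstrap_external(X, y, a_max=3, n_iter=5, seed=9)
        for ia, ib in zip(a.iterations, b.iterations):
            np.testing.assert_array_equal(ia.test_indices, ib.test_indices)

    def test_too_small_holdout_is_error(self, rng):
        X, y = _linear_data(rng, n=10, p=4)
        with pytest.raises(ValueError, match="too small"):
            bootstrap_external(X, y, a_max=2, frac=0.2, n_iter=2, seed=0)

    def test_r2_pred_bounded_above_by_one(self, rng):
        X, y = _linear_data(rng, n=30, p=6, noise=0.5)
        boot = bootstrap_external(X, y, a_max=4, n_iter=6, seed=2)
        assert all(it.r2_pred <= 1.0 for it in boot.iterations)
        assert -1.0 <= boot.stats.ccc <= 1.0


def test_statistics_invariant_to_sample_reordering(rng):
    X, y = _linear_data(rng, n=15, p=5, noise=0.3)
    perm = rng.permutation(15)
    m1 = fit_pls(X, y, 3)
    m2 = fit_pls(X[perm], y[perm], 3)
    assert calibration_stats(m1, X, y) == pytest.approx(
        calibration_stats(m2, X[perm], y[perm]), abs=1e-10
    )
    assert loo_q2(X, y, 3) == pytest.approx(loo_q2(X[perm], y[perm], 3), abs=1e-8)


class TestReport:
    def test_cross_channel_aggregation_and_verdicts(self):
        stats = {
            "r_vdw": ChannelStats(r2=0.90, q2=0.58, r2_pred=0.73, c_r2_p=0.58,
                                  avg_r2_m=0.60, delta_r2_m=0.14, ccc=0.83),
            "epsilon": ChannelStats(r2=0.89, q2=0.59, r2_pred=0.77, c_r2_p=0.59,
                                    avg_r2_m=0.66, delta_r2_m=0.12, ccc=0.86),
            "ratio": ChannelStats(r2=0.91, q2=0.59, r2_pred=0.71, c_r2_p=0.57,
                                  avg_r2_m=0.57, delta_r2_m=0.13, ccc=0.82),
        }
        report = build_report(stats)
        assert report.average.r2 == pytest.approx(0.90, abs=1e-12)
        assert report.all_pass()
        df = report.to_dataframe()
        assert list(df.columns) == ["r_vdw", "epsilon", "ratio", "Average", "Std. Dev.", "Cut-off"]
        assert df.shape[0] == 13

    def test_failing_average_is_reported(self):
        bad = ChannelStats(r2=0.4, q2=0.2, r2_pred=0.3, c_r2_p=0.2,
                           avg_r2_m=0.3, delta_r2_m=0.4, ccc=0.5)
        report = build_report({"epsilon": bad})
        assert not report.all_pass()
        assert not report.verdicts["q2"]
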