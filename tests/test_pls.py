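import numpy as np
import pytest

from nirpls import (
    align,
    default_config,
    evaluate,
    ks_split,
    loo_cv,
    pls_fit,
    pls_predict,
    r_squared,
    rmse,
    simulate_dataset,
)
from nirpls.selection import thin_spectra


class TestPLSFit:
    def test_rank_one_exact_recovery(self):
        rng = np.random.default_rng(30)
        c = rng.uniform(0.5, 2.0, 12)
        p = np.abs(rng.standard_normal(40))
        X = np.outer(c, p)
        model = pls_fit(X, c, 1)
        assert rmse(c, pls_predict(model, X)) < 1e-8

    def test_full_rank_equals_least_squares(self):
        # normal-equations oracle on a 10 x 5 toy matrix
        rng = np.random.default_rng(31)
        X = rng.standard_normal((10, 5))
        c = rng.standard_normal(10)
        Xc = X - X.mean(axis=0)
        yc = c - c.mean()
        b_ls = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        model = pls_fit(X, c, 5)
        np.testing.assert_allclose(model.regression_vector, b_ls, atol=1e-6)
        np.testing.assert_allclose(
            pls_predict(model, X), Xc @ b_ls + c.mean(), atol=1e-6
        )

    def test_variable_permutation_permutes_coefficients(self):
        rng = np.random.default_rng(32)
        X = rng.standard_normal((15, 8))
        c = rng.standard_normal(15)
        perm = rng.permutation(8)
        m1 = pls_fit(X, c, 3)
        m2 = pls_fit(X[:, perm], c, 3)
        np.testing.assert_allclose(
            m2.regression_vector, m1.regression_vector[perm], atol=1e-10
        )

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(33)
        X = rng.standard_normal((20, 50))
        c = rng.standard_normal(20)
        model = pls_fit(X, c, 5)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_adding_factors_never_increases_rmsec(self):
        rng = np.random.default_rng(34)
        X = rng.standard_normal((25, 30))
        c = X[:, :3] @ np.array([1.0, -0.5, 0.3]) + 0.1 * rng.standard_normal(25)
        prev = np.inf
        for a in range(1, 10):
            model = pls_fit(X, c, a)
            err = rmse(c, pls_predict(model, X))
            assert err <= prev + 1e-12
            prev = err

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError):
            pls_fit(np.random.default_rng(0).standard_normal((5, 4)), np.ones(5), 1)


class TestPredict:
    def test_mean_spectrum_predicts_mean_response(self):
        rng = np.random.default_rng(35)
        X = rng.standard_normal((10, 20))
        c = rng.standard_normal(10)
        model = pls_fit(X, c, 3)
        pred = pls_predict(model, X.mean(axis=0)[None, :])
        assert pred[0] == pytest.approx(c.mean(), abs=1e-10)

    def test_prediction_affine_in_input(self):
        rng = np.random.default_rng(36)
        X = rng.standard_normal((10, 20))
        c = rng.standard_normal(10)
        model = pls_fit(X, c, 2)
        x = X[0]
        p0 = pls_predict(model, 0.0 * x[None, :])[0]
        p1 = pls_predict(model, x[None, :])[0]
        p2 = pls_predict(model, 2.0 * x[None, :])[0]
        assert p2 - p1 == pytest.approx(p1 - p0, abs=1e-8)

    def test_matches_score_space_projection(self):
        # independent factor-by-factor oracle on a 5-sample toy set
        rng = np.random.default_rng(37)
        X = rng.standard_normal((5, 7))
        c = rng.standard_normal(5)
        A = 3
        model = pls_fit(X, c, A)
        x_new = rng.standard_normal(7)
        x_res = x_new - model.x_mean
        pred_oracle = model.y_mean
        for a in range(A):
            t = x_res @ model.weights[:, a]
            x_res = x_res - t * model.x_loadings[:, a]
            pred_oracle += t * model.y_loadings[a]
        assert pls_predict(model, x_new[None, :])[0] == pytest.approx(
            pred_oracle, abs=1e-10
        )

    def test_shape_mismatch_rejected(self):
        model = pls_fit(np.random.default_rng(0).standard_normal((6, 5)),
                        np.arange(6.0), 2)
        with pytest.raises(ValueError, match="columns"):
            pls_predict(model, np.zeros((1, 7)))


class TestMetrics:
    def test_rmse_zero_for_perfect(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_rmse_forced_value(self):
        assert rmse([1.0, 2.0], [2.0, 1.0]) == pytest.approx(1.0)

    def test_rmse_matches_brute_force(self):
        rng = np.random.default_rng(38)
        c = rng.standard_normal(20)
        ch = rng.standard_normal(20)
        manual = np.sqrt(sum((a - b) ** 2 for a, b in zip(c, ch)) / 20)
        assert rmse(c, ch) == pytest.approx(manual, abs=1e-14)

    def test_rmse_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])

    def test_r2_perfect_and_mean(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(c, c) == pytest.approx(1.0)
        assert r_squared(c, np.full(4, c.mean())) == pytest.approx(0.0)

    def test_r2_hand_oracle(self):
        c = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ch = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
        sse = np.sum((c - ch) ** 2)
        sst = np.sum((c - 3.0) ** 2)
        assert r_squared(c, ch) == pytest.approx(1 - sse / sst, abs=1e-14)

    def test_r2_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0], [1.0, 2.0])


class TestLooCV:
    def test_matches_explicit_per_fold_oracle(self):
        rng = np.random.default_rng(39)
        X = rng.standard_normal((6, 4))
        c = rng.standard_normal(6)
        A_max = 2
        curve = loo_cv(X, c, A_max)
        press_oracle = np.zeros(A_max)
        for i in range(6):
            keep = [j for j in range(6) if j != i]
            for a in range(1, A_max + 1):
                model = pls_fit(X[keep], c[keep], a)
                press_oracle[a - 1] += (c[i] - pls_predict(model, X[i][None, :])[0]) ** 2
        np.testing.assert_allclose(curve.press, press_oracle, atol=1e-10)
        np.testing.assert_allclose(curve.rmsecv, np.sqrt(press_oracle / 6), atol=1e-10)

    def test_rank_one_chooses_one_factor(self):
        rng = np.random.default_rng(40)
        c = rng.uniform(1, 2, 10)
        X = np.outer(c, np.abs(rng.standard_normal(12)))
        curve = loo_cv(X, c, 3)
        assert curve.chosen == 1
        assert curve.press[0] < 1e-12

    def test_duplicated_rows_match_oracle(self):
        rng = np.random.default_rng(41)
        X = rng.standard_normal((5, 4))
        c = rng.standard_normal(5)
        Xd = np.vstack([X, X])
        cd = np.concatenate([c, c])
        curve = loo_cv(Xd, cd, 2)
        press_oracle = np.zeros(2)
        for i in range(10):
            keep = [j for j in range(10) if j != i]
            for a in (1, 2):
                model = pls_fit(Xd[keep], cd[keep], a)
                press_oracle[a - 1] += (cd[i] - pls_predict(model, Xd[i][None, :])[0]) ** 2
        np.testing.assert_allclose(curve.press, press_oracle, atol=1e-10)

    def test_a_max_bound_enforced(self):
        with pytest.raises(ValueError):
            loo_cv(np.random.default_rng(0).standard_normal((5, 4)),
                   np.arange(5.0), 4)

    def test_chosen_near_true_component_count(self):
        # 4 analytes + water: PRESS minimum expected in [4, 7] across seeds
        from dataclasses import replace

        hits = 0
        for seed in range(20):
            cfg = replace(default_config(seed=seed), n_per_phase=(14, 10, 8))
            dataset, refs = simulate_dataset(cfg)
            X, _ = thin_spectra(dataset.absorbance, dataset.grid, 16)
            c = refs.concentrations("glycyrrhizic_acid").loc[
                dataset.sample_ids
            ].to_numpy()
            curve = loo_cv(X, c, 10)
            if 4 <= curve.chosen <= 7:
                hits += 1
        assert hits >= 16  # allow occasional CV noise


class TestEvaluate:
    def test_validation_equals_calibration(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((12, 10))
        c = rng.standard_normal(12)
        model = pls_fit(X, c, 3)
        met = evaluate(model, X, c, X, c)
        assert met.rmsep == pytest.approx(met.rmsec, abs=1e-14)
        assert met.r2_pred == pytest.approx(met.r2_cal, abs=1e-14)

    def test_noiseless_data_near_zero_errors(self, noiseless93):
        dataset, refs = noiseless93
        X, _ = thin_spectra(dataset.absorbance, dataset.grid, 8)
        c = refs.concentrations("liquiritin").loc[dataset.sample_ids].to_numpy()
        model = pls_fit(X[:60], c[:60], 5)
        met = evaluate(model, X[:60], c[:60], X[60:], c[60:])
        assert met.rmsec < 1e-6 and met.rmsecv < 1e-6 and met.rmsep < 1e-6

    def test_empty_validation_reports_absent(self):
        rng = np.random.default_rng(43)
        X = rng.standard_normal((12, 10))
        c = rng.standard_normal(12)
        met = evaluate(pls_fit(X, c, 2), X, c, None, None)
        assert met.rmsep is None and met.r2_pred is None and met.n_val == 0

    def test_golden_record_seed1_fixture(self, default93):
        # frozen at first verified build: glycyrrhizic acid, 8x-thinned grid,
        # KS 2/3 split, raw spectra, 5 factors
        dataset, refs = default93
        Xf, c, ids, _ = align(dataset, refs, "glycyrrhizic_acid")
        X, _ = thin_spectra(Xf, dataset.grid, 8)
        split = ks_split(X, 2.0 / 3.0, ids)
        cal = [ids.index(s) for s in split.calibration_ids]
        val = [ids.index(s) for s in split.validation_ids]
        model = pls_fit(X[cal], c[cal], 5)
        met = evaluate(model, X[cal], c[cal], X[val], c[val])
        golden = {
            "rmsec": 0.014632966315170437,
            "rmsecv": 0.016664745645366658,
            "rmsep": 0.010291135464582822,
            "r2_cal": 0.9995954398819015,
            "r2_cv": 0.9994752943985804,
            "r2_pred": 0.9997366202755621,
        }
        for key, value in golden.items():
            assert getattr(met, key) == pytest.approx(value, rel=1e-7), key
        assert met.n_cal == 62 and met.n_val == 31

    def test_full_spectrum_quality_ordering(self, default93):
        # the weak analyte calibrates worst; strong analytes exceed 0.98
        dataset, refs = default93
        r2 = {}
        for analyte in refs.analytes:
            Xf, c, ids, _ = align(dataset, refs, analyte)
            X, _ = thin_spectra(Xf, dataset.grid, 8)
            split = ks_split(X, 2.0 / 3.0, ids)
            cal = [ids.index(s) for s in split.calibration_ids]
            val = [ids.index(s) for s in split.validation_ids]
            curve = loo_cv(X[cal], c[cal], 8)
            model = pls_fit(X[cal], c[cal], curve.chosen)
            met = evaluate(model, X[cal], c[cal], X[val], c[val])
            r2[analyte] = met.r2_pred
        weak = r2.pop("isoliquiritin")
        assert all(v > 0.98 for v in r2.values())
        assert weak < min(r2.values())
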