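import numpy as np
import pytest
from sklearn.linear_model import Lasso

from clusso.data_io import DataError, OutcomeVector
from clusso.design import build_design, standardize
from clusso.estimators import (
    FitConfig,
    fit_clusso,
    fit_full_info,
    fit_naive,
    naive_lambda_grid,
    predict_naive,
    predict_with_correspondence,
)
from clusso.simulation import SimulationConfig, generate_dataset
from clusso.structured_lasso import solve_multi_init


@pytest.fixture(scope="module")
def two_cluster_data():
    cfg = SimulationConfig(n=120, q=6, s_beta=0.5, sigma2_R=1.0, seed=31)
    return generate_dataset(cfg)


class TestFitNaive:
    def test_lambda_grid_shape(self, two_cluster_data):
        tubules, outcomes, *_ = two_cluster_data
        archive = fit_naive(tubules, outcomes, FitConfig(seed=1))
        grid = np.asarray(archive.metadata["cv_table"]["lambda"])
        assert grid.size == 100
        assert grid[-1] / grid[0] == pytest.approx(1e-4)
        assert archive.metadata["lambda_max"] == pytest.approx(grid[0])

    def test_all_zero_at_lambda_max(self, two_cluster_data):
        """lambda_max is the smallest lambda with an all-zero lasso solution
        under the (1/n) RSS objective convention."""
        tubules, outcomes, *_ = two_cluster_data
        subjects = tubules.subjects
        Xbar = np.stack(
            [tubules.features[r].mean(axis=0) for r in tubules.subject_row_indices().values()]
        )
        Xs = (Xbar - Xbar.mean(axis=0)) / Xbar.std(axis=0)
        y_c = outcomes.select(subjects) - outcomes.select(subjects).mean()
        grid = naive_lambda_grid(Xs, y_c)
        at_max = Lasso(alpha=grid[0] / 2, fit_intercept=False).fit(Xs, y_c).coef_
        np.testing.assert_allclose(at_max, 0.0, atol=1e-10)
        just_below = Lasso(alpha=grid[0] * 0.98 / 2, fit_intercept=False).fit(Xs, y_c).coef_
        assert np.any(just_below != 0)

    def test_single_feature_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        from clusso.data_io import TubuleTable

        n = 40
        subj = np.repeat([f"S{i:02d}" for i in range(n)], 3)
        feats = rng.normal(5.0, 2.0, size=(3 * n, 1))
        tubules = TubuleTable(subj, np.tile([1, 2, 3], n), feats, ["f0"])
        xbar = np.array([feats[3 * i : 3 * i + 3].mean() for i in range(n)])
        outcomes = OutcomeVector(np.array([f"S{i:02d}" for i in range(n)]), 3.0 * xbar)
        archive = fit_naive(tubules, outcomes, FitConfig(seed=2))
        _, pred = predict_naive(archive, tubules)
        np.testing.assert_allclose(pred, 3.0 * xbar, atol=0.02)

    def test_zero_variance_column_fatal(self):
        from clusso.data_io import TubuleTable

        tubules = TubuleTable(
            np.array(["A", "B", "C"]),
            np.array([1, 1, 1]),
            np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]]),
            ["flat", "ok"],
        )
        outcomes = OutcomeVector(np.array(["A", "B", "C"]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DataError, match="flat"):
            fit_naive(tubules, outcomes, FitConfig(n_folds=3))


class TestFitFullInfo:
    def test_noiseless_support_recovery_and_low_bias(self):
        """On noiseless bilinear data the oracle fit recovers the exact
        support of beta* with small L1-normalized bias."""
        cfg = SimulationConfig(n=500, q=10, s_beta=0.8, sigma2_eps=0.0, seed=77)
        _, outcomes, truth, _ = generate_dataset(cfg)
        archive = fit_full_info(truth, outcomes, FitConfig(seed=5))
        est_support = archive.beta_normalized != 0
        np.testing.assert_array_equal(est_support, truth.beta_star != 0)
        b_hat = np.abs(archive.beta_normalized) / np.abs(archive.beta_normalized).sum()
        b_true = np.abs(truth.beta_star) / np.abs(truth.beta_star).sum()
        assert np.abs(b_hat - b_true).sum() < 0.05

    def test_deterministic_given_seed(self, two_cluster_data):
        _, outcomes, truth, _ = two_cluster_data
        a1 = fit_full_info(truth, outcomes, FitConfig(seed=9))
        a2 = fit_full_info(truth, outcomes, FitConfig(seed=9))
        np.testing.assert_array_equal(a1.beta, a2.beta)
        np.testing.assert_array_equal(a1.alpha, a2.alpha)
        assert a1.lam == a2.lam


class TestFitClusso:
    def test_seeded_support_recovery(self):
        cfg = SimulationConfig(n=500, q=10, s_beta=0.8, sigma2_R=1.0, seed=102)
        tubules, outcomes, truth, _ = generate_dataset(cfg)
        archive = fit_clusso(tubules, outcomes, FitConfig(seed=11))
        np.testing.assert_array_equal(
            archive.beta_normalized != 0, truth.beta_star != 0
        )

    def test_deterministic_given_seed(self, two_cluster_data):
        tubules, outcomes, *_ = two_cluster_data
        a1 = fit_clusso(tubules, outcomes, FitConfig(seed=13))
        a2 = fit_clusso(tubules, outcomes, FitConfig(seed=13))
        np.testing.assert_array_equal(a1.beta, a2.beta)
        np.testing.assert_array_equal(a1.alpha, a2.alpha)
        assert a1.lam == a2.lam
        assert a1.metadata["dropped_subjects"] == a2.metadata["dropped_subjects"]

    def test_single_cluster_config_degenerates_to_plain_lasso(self, two_cluster_data):
        """With G=1 the design collapses to per-subject feature means with
        w=1, and the structured lasso at fixed lambda equals an ordinary
        lasso on the standardized means."""
        tubules, outcomes, *_ = two_cluster_data
        labels = np.ones(tubules.n_objects, dtype=int)
        designs, _ = build_design(tubules, labels, G=1)
        X, y_c, _ = standardize(designs, outcomes)
        lam = 0.5
        sol = solve_multi_init(X, y_c, lam, n_inits=5, seed=3)
        ref = Lasso(alpha=lam / 2, fit_intercept=False, tol=1e-10).fit(X[:, 0, :], y_c).coef_
        np.testing.assert_allclose(
            sol.alpha[0] * sol.beta, ref, atol=1e-5
        )

    def test_in_sample_beats_null_model_on_noiseless_data(self):
        cfg = SimulationConfig(n=150, q=5, s_beta=0.4, sigma2_eps=0.0, sigma2_R=0.5, seed=55)
        tubules, outcomes, truth, _ = generate_dataset(cfg)
        for fitter, data in (
            (fit_clusso, (tubules, outcomes)),
            (fit_naive, (tubules, outcomes)),
            (fit_full_info, (truth, outcomes)),
        ):
            archive = fitter(*data, FitConfig(seed=6))
            if archive.method == "naive":
                ids, pred = predict_naive(archive, tubules)
                y = outcomes.select(ids)
            elif archive.method == "full_info":
                X = (truth.X_dstar - archive.design_mean) / archive.design_scale
                pred = np.einsum("igq,g,q->i", X, archive.alpha, archive.beta) + archive.y_mean
                y = truth.y
            else:
                res = predict_with_correspondence(archive, tubules, outcomes)
                pred = res.predictions[res.chosen]
                y = outcomes.select(res.subject_ids)
            null_mse = np.mean((y - y.mean()) ** 2)
            assert np.mean((y - pred) ** 2) <= null_mse


class TestCorrespondence:
    def test_training_set_identity_permutation_wins(self, two_cluster_data):
        tubules, outcomes, *_ = two_cluster_data
        archive = fit_clusso(tubules, outcomes, FitConfig(seed=21))
        res = predict_with_correspondence(archive, tubules, outcomes)
        assert len(res.permutations) == 2  # G=2 -> two correspondences
        assert res.chosen == (0, 1)

    def test_swapped_rows_mirror_the_mse_multiset(self, two_cluster_data):
        tubules, outcomes, *_ = two_cluster_data
        archive = fit_clusso(tubules, outcomes, FitConfig(seed=21))
        res = predict_with_correspondence(archive, tubules, outcomes)
        mses = sorted(res.mses.values())
        # relabeling the test clusters globally permutes the candidate set
        assert mses[0] <= mses[1]
        assert res.mses[(0, 1)] == min(mses)

    def test_held_out_cohort_prediction(self, two_cluster_data):
        # validation cohort drawn from the same population: shared (alpha*, beta*)
        tubules, outcomes, truth, _ = two_cluster_data
        archive = fit_clusso(tubules, outcomes, FitConfig(seed=21))
        cfg = SimulationConfig(n=80, q=6, s_beta=0.5, sigma2_R=1.0, seed=32)
        test_tub, test_out, *_ = generate_dataset(
            cfg, truth=(truth.alpha_star, truth.beta_star)
        )
        res = predict_with_correspondence(archive, test_tub, test_out)
        assert res.chosen in res.permutations
        y = test_out.select(res.subject_ids)
        null_mse = np.mean((y - y.mean()) ** 2)
        assert res.mses[res.chosen] < null_mse

    def test_without_outcomes_all_permutations_unflagged(self, two_cluster_data):
        tubules, outcomes, *_ = two_cluster_data
        archive = fit_clusso(tubules, outcomes, FitConfig(seed=21))
        res = predict_with_correspondence(archive, tubules)
        assert res.mses is None and res.chosen is None
        assert len(res.predictions) == 2

    def test_feature_mismatch_fatal(self, two_cluster_data):
        tubules, outcomes, *_ = two_cluster_data
        archive = fit_clusso(tubules, outcomes, FitConfig(seed=21))
        cfg = SimulationConfig(n=20, q=4, s_beta=0.5, seed=33)
        test_tub, *_ = generate_dataset(cfg)
        with pytest.raises(DataError, match="mismatch"):
            predict_with_correspondence(archive, test_tub)


def test_clusso_converges_to_full_info_with_many_tubules():
    """With true labels supplied, the cluster-averaged fit approaches the
    oracle fit as the per-subject tubule count grows 40 -> 640."""
    from clusso.design import build_full_info_design

    gaps = {}
    for mu_M in (40, 640):
        diffs = []
        for seed in (201, 202, 203):
            cfg = SimulationConfig(n=200, q=6, s_beta=0.5, sigma2_R=1.0, mu_M=mu_M, seed=seed)
            tubules, outcomes, truth, labels = generate_dataset(cfg)
            designs_c, _ = build_design(tubules, labels, G=2)
            Xc, yc, _ = standardize(designs_c, outcomes)
            Xf, yf, _ = standardize(build_full_info_design(truth), outcomes)
            lam = 1.0
            sol_c = solve_multi_init(Xc, yc, lam, n_inits=3, seed=seed)
            sol_f = solve_multi_init(Xf, yf, lam, n_inits=3, seed=seed)
            diffs.append(np.abs(sol_c.beta - sol_f.beta).sum())
        gaps[mu_M] = np.median(diffs)
    assert gaps[640] < gaps[40]
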