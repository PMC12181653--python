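import numpy as np
import pandas as pd
import pytest

import clpnet as cn
from clpnet.panel_model import (
    PathModelSpec,
    evaluate_fit,
    fit_path_model,
    wald_path_difference,
)

CONSTRUCTS = ("cptsd", "dep", "anx")


def construct_level_scores(forward=0.25, reverse=0.02, n=3000, seed=5, auto=0.3):
    """Continuous construct-level generator: CPTSD -> anxiety = forward,
    anxiety -> CPTSD = reverse; returns the scores frame and the
    standardized true coefficients."""
    B = np.zeros((3, 3))
    idx = {c: i for i, c in enumerate(CONSTRUCTS)}
    B[idx["cptsd"], idx["anx"]] = forward
    B[idx["anx"], idx["cptsd"]] = reverse
    truth = cn.TruthNetwork(CONSTRUCTS, B, np.full(3, auto), 0.5, np.full((2, 3), 0.1))
    cfg = cn.GeneratorConfig(
        n=n, seed=seed, discretize=False, missing_rate=0.0,
        screen_negative_rate=0.0, control_fail_rate=0.0,
    )
    data = cn.simulate_panel(truth, cfg)
    scores = pd.DataFrame(
        {f"{c}_t1": data.wave1[c] for c in CONSTRUCTS}
        | {f"{c}_t2": data.wave2[c] for c in CONSTRUCTS}
    )
    scores["gender"] = data.covariates["gender"]
    scores["age"] = data.covariates["age"]
    # standardized truth: b_std = b * sd(source latent) / sd(target latent)
    M = truth.transition_matrix
    rho = truth.within_wave_corr
    sigma = np.full((3, 3), rho) + (1 - rho) * np.eye(3)
    cg, ca = truth.covariate_effects
    sd2 = np.sqrt(np.einsum("ij,jk,ki->i", M.T, sigma, M) + 0.25 * cg**2 + ca**2 + 1.0)
    b_std = {
        (src, dst): M[idx[src], idx[dst]] / sd2[idx[dst]]
        for src in CONSTRUCTS
        for dst in CONSTRUCTS
    }
    return scores, b_std


class TestFitPathModel:
    def test_saturated_model_identities(self):
        scores, _ = construct_level_scores()
        res = fit_path_model(scores)
        assert res.df == 0
        assert res.chi2 == 0.0
        assert res.cfi == 1.0
        assert res.tli == 1.0
        assert res.rmsea == 0.0
        assert res.srmr <= 1e-8

    def test_recovers_known_construct_paths(self):
        scores, b_std = construct_level_scores(n=3000, seed=5)
        res = fit_path_model(scores)
        for (src, dst), truth_val in b_std.items():
            assert res.path_estimate(src, dst) == pytest.approx(truth_val, abs=0.05)

    def test_wave2_equations_equal_ols_with_identical_regressors(self):
        scores, _ = construct_level_scores(n=800, seed=2)
        res = fit_path_model(scores)
        Z = (scores - scores.mean()) / scores.std(ddof=1)
        X = Z[[f"{c}_t1" for c in CONSTRUCTS] + ["gender", "age"]].to_numpy()
        for c in CONSTRUCTS:
            ols = np.linalg.lstsq(X, Z[f"{c}_t2"].to_numpy(), rcond=None)[0]
            for k, src in enumerate(CONSTRUCTS):
                assert res.path_estimate(src, c) == pytest.approx(ols[k], abs=1e-6)

    def test_standardized_estimates_scale_invariant(self):
        scores, _ = construct_level_scores(n=500, seed=3)
        res = fit_path_model(scores)
        rescaled = scores.copy()
        rescaled["cptsd_t1"] = rescaled["cptsd_t1"] * 7.5
        res2 = fit_path_model(rescaled)
        pd.testing.assert_frame_equal(res.paths, res2.paths, atol=1e-10)

    def test_dropping_null_covariates_barely_moves_paths(self):
        scores, _ = construct_level_scores(n=3000, seed=4)
        # regenerate with zero covariate effects
        B = np.zeros((3, 3))
        B[0, 2] = 0.25
        truth = cn.TruthNetwork(CONSTRUCTS, B, np.full(3, 0.3), 0.5, np.zeros((2, 3)))
        cfg = cn.GeneratorConfig(
            n=3000, seed=4, discretize=False, missing_rate=0.0,
            screen_negative_rate=0.0, control_fail_rate=0.0,
        )
        data = cn.simulate_panel(truth, cfg)
        scores = pd.DataFrame(
            {f"{c}_t1": data.wave1[c] for c in CONSTRUCTS}
            | {f"{c}_t2": data.wave2[c] for c in CONSTRUCTS}
        )
        scores["gender"] = data.covariates["gender"]
        scores["age"] = data.covariates["age"]
        with_cov = fit_path_model(scores)
        spec = PathModelSpec(covariate_paths=())
        without = fit_path_model(scores, spec)
        for src in CONSTRUCTS:
            for dst in CONSTRUCTS:
                assert abs(
                    with_cov.path_estimate(src, dst) - without.path_estimate(src, dst)
                ) < 0.02

    def test_wave1_correlations_reported(self):
        scores, _ = construct_level_scores(n=2000, seed=6)
        res = fit_path_model(scores)
        direct = np.corrcoef(
            scores[[f"{c}_t1" for c in CONSTRUCTS]].to_numpy(), rowvar=False
        )
        assert np.allclose(res.wave1_corr.to_numpy(), direct, atol=1e-12)

    def test_missing_columns_rejected(self):
        with pytest.raises(KeyError, match="missing columns"):
            fit_path_model(pd.DataFrame({"cptsd_t1": [1.0, 2.0]}))


class TestWaldDifference:
    def test_self_comparison_is_null(self):
        scores, _ = construct_level_scores(n=500, seed=7)
        res = fit_path_model(scores)
        d = wald_path_difference(res, "cptsd->anx", "cptsd->anx")
        assert d.difference == 0.0 and d.p == 1.0

    def test_strong_asymmetry_detected(self):
        scores, _ = construct_level_scores(forward=0.3, reverse=0.0, n=3000, seed=9)
        res = fit_path_model(scores)
        d = wald_path_difference(res, ("cptsd", "anx"), ("anx", "cptsd"))
        assert d.p < 0.001
        assert d.difference < 0  # reverse minus forward

    def test_equal_paths_rarely_flagged(self):
        """Null calibration: with truly equal paths (both 0.2), |z| < 1.96
        in >= 90% of 20 seeded replicates."""
        hits = 0
        for s in range(20):
            scores, _ = construct_level_scores(forward=0.2, reverse=0.2, n=3000, seed=400 + s)
            res = fit_path_model(scores)
            d = wald_path_difference(res, ("cptsd", "anx"), ("anx", "cptsd"))
            hits += abs(d.z) < 1.96
        assert hits / 20 >= 0.9

    def test_unknown_path_rejected(self):
        scores, _ = construct_level_scores(n=500, seed=8)
        spec = PathModelSpec(paths=tuple(
            (a, b) for a in CONSTRUCTS for b in CONSTRUCTS if (a, b) != ("dep", "anx")
        ))
        res = fit_path_model(scores, spec)
        with pytest.raises(KeyError):
            wald_path_difference(res, ("dep", "anx"), ("anx", "dep"))


class TestEvaluateFit:
    @pytest.mark.parametrize(
        "indices, expected",
        [
            ({"cfi": 0.96}, {"cfi": "good"}),
            ({"rmsea": 0.08}, {"rmsea": "acceptable"}),
            ({"cfi": 0.875}, {"cfi": "poor"}),
            ({"tli": 0.92, "srmr": 0.1}, {"tli": "acceptable", "srmr": "poor"}),
        ],
    )
    def test_cutoff_labels(self, indices, expected):
        assert evaluate_fit(indices) == expected

    def test_restricted_model_has_positive_df_and_sane_indices(self):
        scores, _ = construct_level_scores(n=2000, seed=10)
        spec = PathModelSpec(
            paths=tuple((c, c) for c in CONSTRUCTS),  # autoregressive only
            covariate_paths=(),
        )
        res = fit_path_model(scores, spec)
        assert res.df > 0
        assert 0 <= res.cfi <= 1 and res.rmsea >= 0 and res.srmr >= 0
        labels = evaluate_fit(res)
        assert set(labels) == {"cfi", "tli", "rmsea", "srmr"}
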