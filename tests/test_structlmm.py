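"""Structured LMM: REML null fit, score test, Bayes factors, verification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gweistools as gt
from gweistools.structlmm import chi2_mixture_sf


def _sim(seed, n=500, k=5, sigma_e=0.0, beta_g=0.1):
    r = np.random.default_rng(seed)
    E = r.standard_normal((n, k))
    X = np.column_stack([np.ones(n), r.standard_normal(n)])
    G = r.binomial(2, 0.3, n).astype(float)
    Es = (E - E.mean(0)) / E.std(0) / np.sqrt(k)
    env = Es @ r.standard_normal(k) * np.sqrt(sigma_e * k) if sigma_e else 0.0
    y = X @ [1.0, 0.2] + beta_g * (G - G.mean()) / G.std() + env + r.standard_normal(n)
    return y, X, G, E


class TestChiSquareMixture:
    def test_single_weight_matches_scaled_chi2(self):
        p, method = chi2_mixture_sf(5.0, np.array([2.0]))
        assert p == pytest.approx(stats.chi2.sf(2.5, 1), rel=1e-10)

    def test_two_equal_weights_match_exponential(self):
        # chi2_1 + chi2_1 = chi2_2, whose survival is exp(-q/2)
        for q in (1.0, 4.0, 10.0):
            p, method = chi2_mixture_sf(q, np.array([1.0, 1.0]))
            assert p == pytest.approx(np.exp(-q / 2), rel=1e-3)
            assert method in ("imhof", "liu")

    def test_matches_monte_carlo(self, rng):
        lam = np.array([3.0, 1.0, 0.5])
        draws = rng.chisquare(1, (200_000, 3)) @ lam
        q = 12.0
        p, _ = chi2_mixture_sf(q, lam)
        assert p == pytest.approx((draws > q).mean(), abs=0.005)


class TestNullLmm:
    def test_single_component_matches_grid_search(self):
        y, X, G, E = _sim(1, n=300, k=1, sigma_e=0.3)
        null = gt.fit_null_lmm(y, X, G, E[:, :1])
        n = len(y)
        E1s = (E[:, :1] - E[:, :1].mean(0)) / E[:, :1].std(0)
        K = E1s @ E1s.T
        Xt = np.column_stack([X, (G - G.mean()) / G.std()])
        p = Xt.shape[1]
        best = -np.inf
        for s_e in np.linspace(0, 1.0, 41):
            for s_n in np.linspace(0.4, 2.0, 41):
                V = s_e * K + s_n * np.eye(n)
                sign, ldV = np.linalg.slogdet(V)
                Vi = np.linalg.inv(V)
                xvx = Xt.T @ Vi @ Xt
                _, ldX = np.linalg.slogdet(xvx)
                b = np.linalg.solve(xvx, Xt.T @ Vi @ y)
                ypy = y @ Vi @ y - (Xt.T @ Vi @ y) @ b
                ll = -0.5 * (ldV + ldX + ypy + (n - p) * np.log(2 * np.pi))
                best = max(best, ll)
        assert null.reml_loglik >= best - 1e-3

    def test_zero_environment_variance_recovered_at_boundary(self):
        ests = []
        for s in range(5):
            y, X, G, E = _sim(10 + s, n=2000, k=5, sigma_e=0.0)
            null = gt.fit_null_lmm(y, X, G, E)
            ests.append(null.sigma2_e)
        assert np.mean(ests) < 0.01

    def test_collapses_to_ols_when_variance_components_zero(self):
        y, X, G, E = _sim(2, n=800, sigma_e=0.0)
        null = gt.fit_null_lmm(y, X, G, E)
        Xt = np.column_stack([X, (G - G.mean()) / G.std()])
        ols = np.linalg.lstsq(Xt, y, rcond=None)[0]
        if null.delta == 0.0:
            assert np.abs(null.beta - ols).max() < 1e-6
        else:  # tiny estimated delta still approximates OLS
            assert np.abs(null.beta - ols).max() < 1e-3

    def test_monomorphic_variant_rejected(self):
        y, X, _, E = _sim(3)
        with pytest.raises(ValueError, match="monomorphic"):
            gt.fit_null_lmm(y, X, np.ones(len(y)), E)


class TestScoreTest:
    def test_invariant_to_exposure_order_and_rotation(self):
        y, X, G, _ = _sim(4, n=400, k=4, sigma_e=0.2)
        r = np.random.default_rng(5)
        n = len(y)
        # exposure columns that stay exactly mean-0, SD-1 under rotation
        raw = r.standard_normal((n, 4))
        raw -= raw.mean(0)
        Eo, _ = np.linalg.qr(raw)
        Eo *= np.sqrt(n)
        base = gt.score_test_gxe(gt.fit_null_lmm(y, X, G, Eo))
        perm = gt.score_test_gxe(gt.fit_null_lmm(y, X, G, Eo[:, [2, 0, 3, 1]]))
        Q, _ = np.linalg.qr(r.standard_normal((4, 4)))
        rot = gt.score_test_gxe(gt.fit_null_lmm(y, X, G, Eo @ Q))
        assert base.p == pytest.approx(perm.p, rel=1e-6)
        assert base.Q == pytest.approx(rot.Q, rel=1e-6)
        assert base.p == pytest.approx(rot.p, rel=1e-4)

    def test_single_exposure_concordant_with_univariate(self):
        """With one exposure the score test ranks variants like the
        univariate interaction t-test."""
        r = np.random.default_rng(6)
        n = 300
        e = r.standard_normal(n)
        y = r.standard_normal(n) + 0.1 * e
        X = np.ones((n, 1))
        p_uni, p_score = [], []
        for _ in range(200):
            G = r.binomial(2, r.uniform(0.1, 0.5), n).astype(float)
            fit = gt.fit_interaction_model(y, G, e)
            null = gt.fit_null_lmm(y, X, G, e[:, None])
            sc = gt.score_test_gxe(null)
            p_uni.append(fit.p_ge)
            p_score.append(sc.p)
        rho = stats.spearmanr(p_uni, p_score).statistic
        assert rho > 0.95

    def test_multivariate_power_exceeds_best_univariate(self):
        """Interaction spread over several exposures: the joint score test
        beats the best single-exposure scan at matched alpha (the method's
        motivating property)."""
        alpha = 0.01
        wins_score, wins_uni = 0, 0
        reps = 60
        for s in range(reps):
            r = np.random.default_rng(1000 + s)
            n, k = 400, 6
            E = r.standard_normal((n, k))
            G = r.binomial(2, 0.3, n).astype(float)
            gs = (G - G.mean()) / G.std()
            # interaction shared across half the exposures
            w = np.zeros(k)
            w[:3] = 1 / np.sqrt(3)
            y = 0.12 * gs * (E @ w) + r.standard_normal(n)
            null = gt.fit_null_lmm(y, np.ones((n, 1)), G, E)
            sc = gt.score_test_gxe(null)
            wins_score += sc.p < alpha
            best_uni = min(
                gt.fit_interaction_model(y, G, E[:, j]).p_ge for j in range(k)
            )
            wins_uni += best_uni < alpha / k  # Bonferroni-matched
        assert wins_score > wins_uni


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = gt.bh_fdr([0.001, 0.01, 0.02, 0.04])
        assert np.allclose(q, [0.004, 0.02, 0.0267, 0.04], atol=1e-4)

    def test_all_equal_p_unchanged(self):
        q = gt.bh_fdr([0.3, 0.3, 0.3])
        assert np.allclose(q, 0.3)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.random(100).clip(1e-6)
        q = gt.bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gt.bh_fdr([])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(50).clip(1e-6)
        q_ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(gt.bh_fdr(p), q_ref)


class TestBayesFactors:
    def test_identical_exposures_tie_and_flag(self):
        r = np.random.default_rng(7)
        n = 400
        e = r.standard_normal(n)
        E = np.column_stack([e, e, r.standard_normal(n)])
        G = r.binomial(2, 0.3, n).astype(float)
        y = r.standard_normal(n)
        null = gt.fit_null_lmm(y, np.ones((n, 1)), G, E)
        bf = gt.exposure_bayes_factors(null, ["a", "b", "c"])
        ra = bf.loc[bf["EXPOSURE"] == "a"].iloc[0]
        rb = bf.loc[bf["EXPOSURE"] == "b"].iloc[0]
        assert ra["LOG_BF"] == rb["LOG_BF"]
        assert ra["BF_RANK"] == rb["BF_RANK"]
        assert ra["TIED"] and rb["TIED"]

    def test_ranks_form_valid_permutation_with_min_ties(self):
        y, X, G, E = _sim(8, n=300, k=6)
        bf = gt.exposure_bayes_factors(gt.fit_null_lmm(y, X, G, E))
        ranks = np.sort(bf["BF_RANK"].to_numpy())
        assert ranks[0] == 1 and ranks.max() <= 6

    def test_planted_driver_attains_rank_one(self):
        hits = 0
        for s in range(10):
            cfg = gt.SimConfig(
                n_participants=2000, n_variants=10, n_exposures=10, n_clusters=2,
                within_cluster_rho=0.0, seed=900 + s,
                planted_effects=[gt.PlantedEffect(5, 3, 1, 0.01)],
            )
            geno, expo, idps, _ = gt.simulate_cohort(cfg)
            null = gt.fit_null_lmm(
                idps.values.iloc[:, 1].to_numpy(), np.ones((2000, 1)),
                geno.column(5), expo.values,
            )
            bf = gt.exposure_bayes_factors(null, expo.exposure_names)
            driver = expo.exposure_names[3]
            hits += int(bf.loc[bf["EXPOSURE"] == driver, "BF_RANK"].iloc[0] == 1)
        assert hits >= 8

    def test_null_ranks_symmetric_across_exposures(self):
        """No driver: the rank of a fixed exposure is uniform across seeds."""
        ranks = []
        for s in range(60):
            r = np.random.default_rng(2000 + s)
            n, k = 250, 5
            E = r.standard_normal((n, k))
            G = r.binomial(2, 0.3, n).astype(float)
            y = r.standard_normal(n)
            null = gt.fit_null_lmm(y, np.ones((n, 1)), G, E)
            bf = gt.exposure_bayes_factors(null)
            ranks.append(int(bf["BF_RANK"].iloc[0]))
        counts = np.bincount(ranks, minlength=6)[1:6]
        chi2 = ((counts - 12.0) ** 2 / 12.0).sum()
        assert stats.chi2.sf(chi2, 4) > 0.01


class TestVerification:
    def _inputs(self):
        univariate = pd.DataFrame(
            {"PAIR": ["p1", "p2", "p2", "p3"],
             "EXPOSURE": ["NL", "e1", "e2", "e9"]}
        )
        scores = pd.DataFrame(
            {"PAIR": ["p1", "p2", "p3"], "SCORE_P": [1e-4, 1e-5, 0.9]}
        )
        bf = {
            "p1": pd.DataFrame({"EXPOSURE": ["NL", "x"], "BF_RANK": [1, 2]}),
            "p2": pd.DataFrame(
                {"EXPOSURE": ["e1", "e2", "x"], "BF_RANK": [1, 3, 2]}
            ),
            "p3": pd.DataFrame({"EXPOSURE": ["e9", "x"], "BF_RANK": [1, 2]}),
        }
        return univariate, scores, bf

    def test_rank_within_n_sig_verifies(self):
        univariate, scores, bf = self._inputs()
        res = gt.verify_interactions(univariate, scores, bf)
        row = res.interactions.set_index(["PAIR", "EXPOSURE"])
        # mirrors the worked single-interaction case: n_sig=1, rank 1, tiny q
        assert row.loc[("p1", "NL"), "VERIFIED"]

    def test_rank_exceeding_n_sig_fails(self):
        univariate, scores, bf = self._inputs()
        res = gt.verify_interactions(univariate, scores, bf)
        row = res.interactions.set_index(["PAIR", "EXPOSURE"])
        assert row.loc[("p2", "e1"), "VERIFIED"]
        assert not row.loc[("p2", "e2"), "VERIFIED"]  # rank 3 > n_sig 2

    def test_pair_failing_fdr_blocks_interactions(self):
        univariate, scores, bf = self._inputs()
        res = gt.verify_interactions(univariate, scores, bf)
        row = res.interactions.set_index(["PAIR", "EXPOSURE"])
        assert not row.loc[("p3", "e9"), "VERIFIED"]  # q >> 0.05

    def test_verified_subset_of_candidates(self):
        univariate, scores, bf = self._inputs()
        res = gt.verify_interactions(univariate, scores, bf)
        assert res.interactions["VERIFIED"].sum() <= len(univariate)

    def test_missing_exposure_rejected(self):
        univariate, scores, bf = self._inputs()
        bf["p1"] = bf["p1"][bf["p1"]["EXPOSURE"] != "NL"]
        with pytest.raises(ValueError, match="absent"):
            gt.verify_interactions(univariate, scores, bf)
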