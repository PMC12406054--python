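"""Group hierarchy tests: PEB fitting, Bayesian Model Reduction (against an
exact linear-Gaussian oracle), the 128-model space, family inference, BMA,
and empirical updates."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from gazedcm.inversion import PosteriorEstimate, PriorSpec
from gazedcm.peb import (FAMILY_NAMES, MODULATORY_ENTRIES,
                         assign_families, automatic_prune, bma_within_family,
                         bmr_reduce, empirical_update_subjects,
                         enumerate_model_space, family_analysis,
                         family_posteriors, fit_peb)


def make_posterior(Ep, var, names=None, prior_var=1.0):
    Ep = np.asarray(Ep, float)
    p = Ep.size
    names = names or tuple(f"B1:p{i}" for i in range(p))
    prior = PriorSpec(np.zeros(p), np.eye(p) * prior_var)
    return PosteriorEstimate(Ep, np.eye(p) * var, 0.0, np.zeros(1), 1, True,
                             tuple(names), prior)


def synthetic_cohort(group_mean, between_sd, within_var, N, seed,
                     prior_var=1.0, return_truth=False):
    """Posteriors as an exact conjugate Gaussian model would produce them:
    theta_s ~ N(mean, sd_b), observed with precision 1/within_var, then
    combined with the N(0, prior_var) prior."""
    rng = np.random.default_rng(seed)
    mean = np.asarray(group_mean, float)
    p = mean.size
    posts, truths = [], []
    post_var = 1.0 / (1.0 / within_var + 1.0 / prior_var)
    for _ in range(N):
        th = mean + between_sd * rng.normal(0, 1, p)
        obs = th + np.sqrt(within_var) * rng.normal(0, 1, p)
        Ep = post_var * obs / within_var
        posts.append(make_posterior(Ep, post_var, prior_var=prior_var))
        truths.append(th)
    if return_truth:
        return posts, np.stack(truths)
    return posts


class TestFitPeb:
    def test_degenerate_cohort_recovers_common_mean(self):
        posts = [make_posterior([0.5, -0.3, 0.1], 1e-8) for _ in range(4)]
        peb = fit_peb(posts, which_params="B")
        assert np.allclose(peb.beta_mean[0], [0.5, -0.3, 0.1], atol=1e-3)

    def test_planted_group_mean_recovery(self):
        # subject posteriors are precise (sd ~ 0.07) so the group mean is
        # recoverable to within sampling error of the N = 36 cohort
        posts = synthetic_cohort([0.3, 0.3, 0.3], between_sd=0.1,
                                 within_var=0.005, N=36, seed=0)
        peb = fit_peb(posts, which_params="B")
        assert np.all(np.abs(peb.beta_mean[0] - 0.3) < 0.05)

    def test_subject_order_exchangeability(self):
        posts = synthetic_cohort([0.4, -0.2], 0.15, 0.05, N=10, seed=1)
        peb1 = fit_peb(posts, which_params="B")
        peb2 = fit_peb(posts[::-1], which_params="B")
        assert np.allclose(peb1.beta_mean, peb2.beta_mean, atol=1e-8)

    def test_rank_deficient_design_errors(self):
        posts = synthetic_cohort([0.3], 0.1, 0.05, N=6, seed=2)
        X = np.ones((6, 2))  # duplicated column
        with pytest.raises(ValueError, match="rank"):
            fit_peb(posts, X=X, which_params="B")

    def test_needs_two_subjects(self):
        posts = synthetic_cohort([0.3], 0.1, 0.05, N=1, seed=3)
        with pytest.raises(ValueError):
            fit_peb(posts, which_params="B")


class TestBayesianModelReduction:
    @staticmethod
    def linear_model(seed=0, n=40, p=3, sigma=0.3, prior_var=1.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, p))
        theta = np.array([0.8, 0.0, -0.4])[:p]
        y = X @ theta + sigma * rng.normal(0, 1, n)
        S0 = np.eye(p) * prior_var
        P = X.T @ X / sigma ** 2 + np.linalg.inv(S0)
        C = np.linalg.inv(P)
        mu = C @ (X.T @ y / sigma ** 2)
        def evidence(S0_):
            return multivariate_normal.logpdf(
                y, np.zeros(n), sigma ** 2 * np.eye(n) + X @ S0_ @ X.T)
        return X, y, sigma, mu, C, S0, evidence

    def test_identity_reduction_is_neutral(self):
        _, _, _, mu, C, S0, _ = self.linear_model()
        (mur, Cr), dF = bmr_reduce((mu, C), (np.zeros(3), S0),
                                   (np.zeros(3), S0))
        assert dF == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(mur, mu) and np.allclose(Cr, C)

    def test_matches_exact_linear_gaussian_evidence(self):
        """On a conjugate linear model, BMR's dF equals the analytic
        evidence difference for any shrunken prior."""
        _, _, _, mu, C, S0, evidence = self.linear_model()
        for pruned in ([1], [2], [1, 2], [0, 1, 2]):
            S0r = S0.copy()
            for j in pruned:
                S0r[j, j] = 1e-8
            (mur, Cr), dF = bmr_reduce((mu, C), (np.zeros(3), S0),
                                       (np.zeros(3), S0r))
            exact = evidence(S0r) - evidence(S0)
            assert dF == pytest.approx(exact, abs=1e-6)
            # posterior matches the exact reduced-prior posterior
            assert abs(mur[pruned[0]]) < 1e-3

    def test_pruning_supported_parameter_loses_evidence(self):
        _, _, _, mu, C, S0, _ = self.linear_model()
        S0r = S0.copy(); S0r[0, 0] = 1e-8  # theta_0 = 0.8 is well supported
        _, dF = bmr_reduce((mu, C), (np.zeros(3), S0), (np.zeros(3), S0r))
        assert dF < -3.0

    def test_enlarged_prior_rejected(self):
        _, _, _, mu, C, S0, _ = self.linear_model()
        with pytest.raises(ValueError, match="larger"):
            bmr_reduce((mu, C), (np.zeros(3), S0), (np.zeros(3), S0 * 2))


class TestAutomaticPrune:
    def test_strong_effects_survive(self):
        posts = synthetic_cohort([0.8, -0.6, 0.7], 0.05, 0.01, N=12, seed=4)
        peb = fit_peb(posts, which_params="B")
        reduced, bma = automatic_prune(peb)
        assert np.all(bma.Pp > 0.95)
        assert np.all(np.abs(np.diag(reduced.prior_cov)) > 1e-6)

    def test_null_effects_pruned(self):
        posts = synthetic_cohort([0.0, 0.0, 0.0], 0.02, 0.01, N=12, seed=5)
        peb = fit_peb(posts, which_params="B")
        reduced, bma = automatic_prune(peb)
        assert np.all(bma.Pp < 0.5)
        assert np.all(np.abs(bma.Ep) < 0.05)

    def test_free_count_monotone(self):
        posts = synthetic_cohort([0.8, 0.0, 0.0], 0.05, 0.01, N=12, seed=6)
        peb = fit_peb(posts, which_params="B")
        reduced, _ = automatic_prune(peb)
        n_free = (np.diag(reduced.prior_cov) > 1e-6).sum()
        assert n_free <= peb.n_params


class TestModelSpace:
    def test_exhaustive_and_distinct(self):
        space = enumerate_model_space()
        assert space.n_models == 128
        assert np.unique(space.masks, axis=0).shape[0] == 128
        assert not space.masks[0].any()       # null model
        assert space.masks[-1].all()          # full model
        assert np.all(space.masks.sum(axis=0) == 64)

    def test_family_sizes(self):
        part = assign_families(enumerate_model_space())
        sizes = part.sizes()
        assert sizes == {"null": 1, "BU": 3, "TD": 3, "BIDIR": 9, "SELF": 7,
                         "BU+SELF": 21, "TD+SELF": 21, "BIDIR+SELF": 63}
        assert sum(sizes.values()) == 128

    def test_model_space_export_table(self):
        from gazedcm.peb import model_space_table
        df = model_space_table()
        assert len(df) == 128
        assert list(df.columns[1:8]) == list(MODULATORY_ENTRIES)
        assert set(df["family"]) == set(FAMILY_NAMES)
        assert df.iloc[0]["family"] == "null"

    def test_full_model_is_bidirectional_self(self):
        space = enumerate_model_space()
        part = assign_families(space)
        assert part.family[-1] == "BIDIR+SELF"
        assert part.family[0] == "null"


class TestFamilyPosteriors:
    def test_flat_evidence_gives_equal_family_mass(self):
        space = enumerate_model_space()
        part = assign_families(space)
        post = family_posteriors(np.zeros(128), part)
        for name in FAMILY_NAMES:
            assert post[name] == pytest.approx(1.0 / 8.0, abs=1e-9)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_boosted_family_dominates(self):
        space = enumerate_model_space()
        part = assign_families(space)
        F = np.zeros(128)
        F[part.members("BIDIR+SELF")] += 20.0
        post = family_posteriors(F, part)
        assert post["BIDIR+SELF"] > 0.999

    def test_shift_invariance(self):
        space = enumerate_model_space()
        part = assign_families(space)
        rng = np.random.default_rng(8)
        F = rng.normal(0, 3, 128)
        p1 = family_posteriors(F, part)
        p2 = family_posteriors(F + 57.0, part)
        for name in p1:
            assert p1[name] == pytest.approx(p2[name], abs=1e-9)

    def test_nonfinite_evidence_errors(self):
        part = assign_families(enumerate_model_space())
        F = np.zeros(128); F[3] = np.nan
        with pytest.raises(ValueError):
            family_posteriors(F, part)


class TestBMA:
    def test_single_member_family(self):
        mu = np.array([0.5, -0.2])
        C = np.eye(2) * 0.01
        bma = bma_within_family([(mu, C)], np.array([0.0]),
                                np.array([[True, True]]),
                                ("a", "b"))
        assert np.allclose(bma.Ep, mu)
        assert np.allclose(bma.Pp, 1.0)

    def test_always_off_parameter(self):
        posts = [(np.array([0.5, 0.0]), np.eye(2) * 0.01),
                 (np.array([0.4, 0.0]), np.eye(2) * 0.01)]
        masks = np.array([[True, False], [True, False]])
        bma = bma_within_family(posts, np.array([0.0, 0.0]), masks,
                                ("a", "b"))
        assert bma.Pp[1] == 0.0
        assert bma.Ep[1] == pytest.approx(0.0)

    def test_mass_weighted_presence(self):
        posts = [(np.array([0.5]), np.eye(1) * 0.01),
                 (np.array([0.0]), np.eye(1) * 0.01)]
        # first model carries e^4.6 ~ 99% of the mass and has the
        # parameter on
        F = np.array([np.log(0.99), np.log(0.01)])
        masks = np.array([[True], [False]])
        bma = bma_within_family(posts, F, masks, ("a",))
        assert bma.Pp[0] == pytest.approx(0.99, abs=1e-6)

    def test_empty_family_errors(self):
        with pytest.raises(ValueError):
            bma_within_family([], np.zeros(0), np.zeros((0, 1), bool), ("a",))


class TestFamilyAnalysisEndToEnd:
    def test_planted_bidir_self_wins(self):
        # group truth with every modulatory entry engaged
        mean = np.array([-0.8, -0.5, -0.6, 0.4, -0.3, 0.3, -1.0])
        posts = synthetic_cohort(mean, 0.1, 0.02, N=14, seed=9)
        posts = [PosteriorEstimate(p.Ep, p.Cp, p.F, p.lam, 1, True,
                                   MODULATORY_ENTRIES, p.prior)
                 for p in posts]
        peb = fit_peb(posts, which_params=list(MODULATORY_ENTRIES))
        bma = family_analysis(peb)
        assert bma.winning_family == "BIDIR+SELF"
        assert bma.family_post["BIDIR+SELF"] > 0.95
        assert np.all(np.sign(bma.Ep) == np.sign(mean))
        assert sum(bma.family_post.values()) == pytest.approx(1.0, abs=1e-9)


class TestEmpiricalUpdate:
    def test_shrinks_toward_group_mean(self):
        posts = synthetic_cohort([0.5, 0.5], 0.1, 0.05, N=10, seed=10)
        peb = fit_peb(posts, which_params="B")
        updated = empirical_update_subjects(peb, posts)
        raw = np.stack([p.Ep for p in posts])
        gm = peb.beta_mean[0]
        # every subject moves toward the group mean, and spread decreases
        assert np.all(np.var(updated, axis=0) <= np.var(raw, axis=0) + 1e-12)
        d_raw = np.abs(raw - gm).sum()
        d_upd = np.abs(updated - gm).sum()
        assert d_upd < d_raw

    def test_subject_at_group_mean_stays(self):
        posts = synthetic_cohort([0.3, -0.3], 0.08, 0.05, N=8, seed=11)
        peb = fit_peb(posts, which_params="B")
        at_mean = make_posterior(peb.beta_mean[0], 1e-10)
        updated = empirical_update_subjects(peb, posts[:-1] + [at_mean])
        assert np.allclose(updated[-1], peb.beta_mean[0], atol=1e-3)
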