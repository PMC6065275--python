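"""HMM core: emission densities, forward/backward, MAP fitting, decoding.

The primary oracle is exhaustive enumeration of the complete-data likelihood
over all 2^T state sequences at small T; one test additionally cross-checks
the forward log-likelihood against hmmlearn's independent implementation.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, normaltest

from fishmove import (
    FitConfig,
    HMMParameters,
    MeanPriors,
    SpeciesSpec,
    TransitionPrior,
    allocate_states,
    emission_logdensity,
    fit_map,
    forward_loglik,
    log_posterior,
    pseudo_residuals,
    smooth_states,
)
from fishmove.hmm import MIGRATING, RESIDENT

from conftest import make_path


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def enum_likelihood_and_marginals(x, p: HMMParameters):
    """Brute-force sum of the complete-data likelihood over all 2^T sequences.

    Returns (loglik, smoothed (T,2)) computed without any recursion.
    """
    T = len(x)
    dens = np.empty((T, 2))
    for j in range(2):
        dens[:, j] = multivariate_normal.pdf(x, p.mu[j], p.covariance(j))
    dens = dens.reshape(T, 2)
    G = p.transition_matrix
    total = 0.0
    marg = np.zeros((T, 2))
    for seq in itertools.product((0, 1), repeat=T):
        w = 0.5 * dens[0, seq[0]]
        for t in range(1, T):
            w *= G[seq[t - 1], seq[t]] * dens[t, seq[t]]
        total += w
        for t, j in enumerate(seq):
            marg[t, j] += w
    return math.log(total), marg / total


def random_instance(rng, T):
    p = HMMParameters(
        rng.uniform(0.1, 0.95),
        rng.uniform(0.1, 0.95),
        rng.uniform(-1, 1, (2, 2)),
        rng.uniform(0.5, 1.5, (2, 2)),
        rng.uniform(-0.8, 0.8, 2),
    )
    x = rng.normal(0, 1.2, (T, 2))
    return x, p


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------


class TestEmission:
    def test_at_mean_identity_covariance(self):
        p = HMMParameters(0.9, 0.9, [[1.0, 2.0], [3.0, 4.0]], [[1.0, 1.0]] * 2, [0.0, 0.0])
        assert emission_logdensity((1.0, 2.0), RESIDENT, p) == pytest.approx(
            -math.log(2 * math.pi), rel=1e-12
        )

    def test_zero_correlation_factorises(self, rng):
        p = HMMParameters(0.9, 0.9, [[1.0, -1.0], [3.0, 4.0]], [[0.7, 1.3], [1, 1]], [0.0, 0.0])
        x = rng.normal(0, 2, 2)
        expect = sum(
            -0.5 * math.log(2 * math.pi) - math.log(s) - 0.5 * ((xi - m) / s) ** 2
            for xi, m, s in zip(x, p.mu[0], p.sigma[0])
        )
        assert emission_logdensity(x, RESIDENT, p) == pytest.approx(expect, rel=1e-12)

    def test_matches_quadratic_form_oracle(self, rng):
        for _ in range(20):
            x, p = random_instance(rng, 1)
            j = int(rng.integers(2))
            # explicit 2x2 inverse and determinant
            S = p.covariance(j)
            det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
            inv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
            d = x[0] - p.mu[j]
            expect = -math.log(2 * math.pi) - 0.5 * math.log(det) - 0.5 * d @ inv @ d
            assert emission_logdensity(x[0], j, p) == pytest.approx(expect, rel=1e-10)

    def test_nonfinite_observation_rejected(self):
        p = HMMParameters(0.9, 0.9, np.zeros((2, 2)), np.ones((2, 2)), np.zeros(2))
        with pytest.raises(ValueError):
            emission_logdensity((np.nan, 0.0), 0, p)


# ---------------------------------------------------------------------------
# Forward likelihood and smoothing vs enumeration
# ---------------------------------------------------------------------------


class TestForwardBackward:
    def test_single_day_marginal(self, rng):
        x, p = random_instance(rng, 1)
        path = make_path(x[:, 0], x[:, 1])
        expect = math.log(
            0.5 * math.exp(emission_logdensity(x[0], 0, p))
            + 0.5 * math.exp(emission_logdensity(x[0], 1, p))
        )
        assert forward_loglik(path, p) == pytest.approx(expect, rel=1e-12)

    def test_identical_states_reduce_to_iid(self, rng):
        mu = np.array([[1.0, 2.0], [1.0, 2.0]])
        sig = np.array([[0.8, 1.1], [0.8, 1.1]])
        x = rng.normal(1, 1, (30, 2))
        path = make_path(x[:, 0], x[:, 1])
        iid = multivariate_normal.logpdf(
            x, mu[0], np.diag(sig[0] ** 2) @ np.eye(2)
        ).sum()
        for g in (0.2, 0.99):
            p = HMMParameters(g, g, mu, sig, [0.0, 0.0])
            assert forward_loglik(path, p) == pytest.approx(iid, rel=1e-10)

    @pytest.mark.parametrize("T", [2, 4, 6, 8])
    def test_loglik_and_smoothing_match_enumeration(self, T, rng):
        for _ in range(10):
            x, p = random_instance(rng, T)
            path = make_path(x[:, 0], x[:, 1])
            ll_enum, marg = enum_likelihood_and_marginals(x, p)
            assert abs(forward_loglik(path, p) - ll_enum) < 1e-8
            np.testing.assert_allclose(smooth_states(path, p), marg, atol=1e-8)

    def test_cross_check_against_hmmlearn(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        x, p = random_instance(rng, 50)
        path = make_path(x[:, 0], x[:, 1])
        m = hmmlearn.GaussianHMM(n_components=2, covariance_type="full", init_params="")
        m.startprob_ = np.array([0.5, 0.5])
        m.transmat_ = p.transition_matrix
        m.means_ = p.mu
        m.covars_ = np.stack([p.covariance(0), p.covariance(1)])
        assert forward_loglik(path, p) == pytest.approx(m.score(x), rel=1e-10)

    def test_smoothed_rows_sum_to_one(self, rng):
        x, p = random_instance(rng, 200)
        sm = smooth_states(make_path(x[:, 0], x[:, 1]), p)
        np.testing.assert_allclose(sm.sum(axis=1), 1.0, atol=1e-10)

    def test_decoding_invariant_to_state_relabeling(self, rng):
        x, p = random_instance(rng, 60)
        path = make_path(x[:, 0], x[:, 1])
        sm = smooth_states(path, p)
        sm_swapped = smooth_states(path, p.swapped())
        np.testing.assert_allclose(sm, sm_swapped[:, ::-1], atol=1e-12)

    def test_symmetric_indistinguishable_states_give_half(self, rng):
        mu = np.array([[0.0, 0.0], [0.0, 0.0]])
        p = HMMParameters(0.7, 0.7, mu, np.ones((2, 2)), [0.0, 0.0])
        x = rng.normal(0, 1, (10, 2))
        sm = smooth_states(make_path(x[:, 0], x[:, 1]), p)
        np.testing.assert_allclose(sm, 0.5, atol=1e-12)


# ---------------------------------------------------------------------------
# Posterior
# ---------------------------------------------------------------------------


class TestLogPosterior:
    def test_flat_prior_equals_loglik(self, rng):
        x, p = random_instance(rng, 40)
        path = make_path(x[:, 0], x[:, 1])
        assert log_posterior(path, p, TransitionPrior(1.0, 1.0)) == pytest.approx(
            forward_loglik(path, p), rel=1e-14
        )

    def test_beta_99_1_penalty_closed_form(self):
        # Beta(99,1) pdf at 0.99 is 99 * 0.99^98
        tp = TransitionPrior(99.0, 1.0)
        assert tp.logpdf(0.99) == pytest.approx(math.log(99) + 98 * math.log(0.99), rel=1e-12)

    def test_mean_prior_terms_added(self, rng):
        x, p = random_instance(rng, 25)
        path = make_path(x[:, 0], x[:, 1])
        tp = TransitionPrior()
        mp = MeanPriors([[0.0, 0.0], [1.0, 1.0]], np.full((2, 2), 0.5))
        expect = log_posterior(path, p, tp) + mp.logpdf(p.mu)
        assert log_posterior(path, p, tp, mp) == pytest.approx(expect, rel=1e-12)

    def test_gamma_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            TransitionPrior().logpdf(1.0)


# ---------------------------------------------------------------------------
# Allocation
# ---------------------------------------------------------------------------


class TestAllocation:
    @pytest.mark.parametrize(
        "p_res,state,unc",
        [(0.9, RESIDENT, False), (0.84, RESIDENT, True), (0.5, RESIDENT, True),
         (0.1, MIGRATING, False), (0.851, RESIDENT, False)],
    )
    def test_threshold_and_tiebreak(self, p_res, state, unc):
        states, uncertain = allocate_states(np.array([[p_res, 1 - p_res]]))
        assert states[0] == state and uncertain[0] == unc


# ---------------------------------------------------------------------------
# MAP fitting
# ---------------------------------------------------------------------------


class TestFitMap:
    def test_recovers_well_separated_parameters(self):
        from fishmove import simulate_individual

        errs, gerrs, accs = [], [], []
        for i in range(3):
            f = simulate_individual(SpeciesSpec.well_separated(), 500, seed=60 + i)
            fit = fit_map(f.path, TransitionPrior(), None, FitConfig(n_restarts=5, seed=i))
            errs.append(np.abs(fit.params.mu - f.params.mu).max())
            gerrs.append(abs(fit.params.gamma_rr - f.params.gamma_rr))
            accs.append((fit.states == f.states).mean())
        assert np.median(errs) < 0.15
        assert np.median(gerrs) < 0.01
        assert np.median(accs) >= 0.95

    def test_data_poor_paths_typically_fail_without_priors(self):
        # T=10 cannot support 12 parameters: degenerate or non-converged fits
        # dominate (an occasional accidental "fit" is expected)
        from fishmove import simulate_individual

        flags = []
        for i in range(6):
            f = simulate_individual(SpeciesSpec.cod(), 10, seed=30 + i)
            fit = fit_map(f.path, TransitionPrior(), None, FitConfig(n_restarts=4, seed=i))
            flags.append(fit.converged)
        assert sum(flags) <= len(flags) // 2

    def test_mean_priors_anchor_data_poor_labels(self):
        from fishmove import simulate_individual

        sp = SpeciesSpec.well_separated()
        mp = MeanPriors(sp.mu_hyper_mean, np.full((2, 2), 0.05))
        hits = []
        for i in range(5):
            f = simulate_individual(sp, 50, seed=80 + i)
            fit = fit_map(f.path, TransitionPrior(), mp, FitConfig(n_restarts=4, seed=i))
            hits.append((fit.states == f.states).mean())
        assert np.median(hits) >= 0.9

    def test_deterministic_given_seed(self, well_sep_fish):
        cfg = FitConfig(n_restarts=3, seed=9)
        a = fit_map(well_sep_fish.path, TransitionPrior(), None, cfg)
        b = fit_map(well_sep_fish.path, TransitionPrior(), None, cfg)
        assert a.log_posterior == b.log_posterior
        assert np.array_equal(a.states, b.states)

    def test_transition_prior_monotonicity(self, well_sep_fish):
        # stronger prior mean self-transition never lowers the fitted gamma
        path = well_sep_fish.path
        prev = -1.0
        fitted = []
        for alpha in (9.0, 49.0, 99.0, 499.0):
            fit = fit_map(path, TransitionPrior(alpha, 1.0), None, FitConfig(n_restarts=3, seed=2))
            g = min(fit.params.gamma_rr, fit.params.gamma_mm)
            fitted.append(g)
            assert g >= prev - 1e-6
            prev = g
        assert fitted[-1] > fitted[0]  # the prior has visible pull


class TestPriorLimits:
    def test_tight_prior_pins_means(self, well_sep_fish):
        m = np.array([[2.1, 1.9], [4.2, 3.9]])
        mp = MeanPriors(m, np.full((2, 2), 1e-10))
        fit = fit_map(well_sep_fish.path, TransitionPrior(), mp, FitConfig(n_restarts=3, seed=1))
        assert np.abs(fit.params.mu - m).max() < 1e-3

    def test_vague_prior_recovers_unprimed_fit(self, well_sep_fish):
        tp = TransitionPrior()
        cfg = FitConfig(n_restarts=4, seed=1)
        un = fit_map(well_sep_fish.path, tp, None, cfg)
        mp = MeanPriors(np.array([[2.0, 2.0], [4.0, 4.0]]), np.full((2, 2), 1e8))
        cfg2 = FitConfig(n_restarts=4, seed=1, extra_initials=[un.params])
        ad = fit_map(well_sep_fish.path, tp, mp, cfg2)
        # compare posteriors with the constant prior terms removed
        lp_un = log_posterior(well_sep_fish.path, un.params, tp)
        lp_ad = log_posterior(well_sep_fish.path, ad.params, tp)
        assert abs(lp_un - lp_ad) < 1e-4


# ---------------------------------------------------------------------------
# Pseudo-residuals
# ---------------------------------------------------------------------------


class TestPseudoResiduals:
    def test_standard_normal_under_correct_model(self):
        from fishmove import simulate_individual

        f = simulate_individual(SpeciesSpec.well_separated(), 500, seed=17)
        r = pseudo_residuals(f.path, f.params)
        for d in range(2):
            assert normaltest(r[:, d]).pvalue > 0.01

    def test_detects_location_shift(self):
        from fishmove import simulate_individual

        f = simulate_individual(SpeciesSpec.well_separated(), 500, seed=18)
        shifted = make_path(f.path.h + 1.5, f.path.v)
        r = pseudo_residuals(shifted, f.params)
        assert r[:, 0].mean() > 0.5  # clearly displaced from 0

    def test_single_day_defined_from_mixture(self):
        p = HMMParameters(0.9, 0.9, [[0.0, 0.0], [1.0, 1.0]], np.ones((2, 2)), [0.0, 0.0])
        r = pseudo_residuals(make_path([0.5], [0.5]), p)
        assert r.shape == (1, 2) and np.all(np.isfinite(r))
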