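"""Monte-Carlo first-passage likelihoods and their analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from metabound import (
    ModelVariant,
    SyntheticObserver,
    Type1Params,
    Type2Params,
    choice_prob_analytic,
    convolve_nondecision,
    nll_replay,
    nll_stopping,
    response_pmf_mc,
    simulate_type1_trial,
)
from metabound.likelihood import replay_joint_pmf
from metabound.model_core import bound_value, compute_evidence


class TestResponsePMF:
    @given(st.floats(0.1, 2.0), st.floats(0.7, 1.3), st.floats(0.05, 0.5),
           st.floats(0.0, 2.0), st.floats(0.5, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_mass_conservation(self, sigma, alpha, a, b, lam):
        p = Type1Params(sigma=sigma, alpha=alpha, a=a, b=b, lam=lam)
        ors = np.linspace(-0.7, 0.7, 40)
        pmf = response_pmf_mc(p, ors, n_mc=400, seed=3)
        assert pmf.total_mass() == pytest.approx(1.0, abs=1e-9)
        assert np.all(pmf.f >= 0)
        forced = pmf.forced()
        assert forced.total_mass() == pytest.approx(1.0, abs=1e-9)
        assert forced.censor_mass == 0.0

    def test_noiseless_pmf_is_degenerate_at_simulator_outcome(self, bank):
        p = Type1Params(sigma=0.0, alpha=1.0, a=0.15, b=0.8, lam=3.0,
                        mu_U=0.0, sigma_U=0.0, lapse=0.0)
        obs = SyntheticObserver(type1=p, type2=Type2Params())
        for i in range(10):
            pmf = response_pmf_mc(p, bank.orientations[i], n_mc=5,
                                  seed=0).forced()
            choice, dec, _, _ = simulate_type1_trial(
                obs, bank.orientations[i], None, np.random.default_rng(0),
                cat=bank.cat_params,
            )
            assert pmf.prob(choice, dec) == pytest.approx(1.0)

    def test_single_sample_trial_matches_normal_tails(self):
        # T=1: P(cross at 1) is the mass of ell+eps outside +/-Lambda_1
        p = Type1Params(sigma=0.8, alpha=1.0, a=0.3, b=0.5, lam=2.0)
        theta = -0.3
        pmf = response_pmf_mc(p, [theta], n_mc=40_000, seed=7)
        ell = compute_evidence(theta)
        lim = bound_value(1, p.a, p.b, p.lam)
        p_up = 1 - norm.cdf((lim - ell) / p.sigma)
        p_dn = norm.cdf((-lim - ell) / p.sigma)
        assert pmf.prob(1, 1) == pytest.approx(p_up, abs=0.01)
        assert pmf.prob(2, 1) == pytest.approx(p_dn, abs=0.01)
        assert pmf.censor_mass == pytest.approx(1 - p_up - p_dn, abs=0.015)

    def test_deterministic_given_seed(self, type1, bank):
        a = response_pmf_mc(type1, bank.orientations[0], n_mc=500, seed=9)
        b = response_pmf_mc(type1, bank.orientations[0], n_mc=500, seed=9)
        np.testing.assert_array_equal(a.f, b.f)


class TestNondecisionConvolution:
    def test_identity_kernel(self, type1, bank):
        pmf = response_pmf_mc(type1, bank.orientations[1], n_mc=300, seed=1)
        out = convolve_nondecision(pmf, 0.0, 0.0)
        np.testing.assert_allclose(out.f, pmf.f)

    def test_pure_shift_moves_interior_mode(self, bank):
        p = Type1Params(sigma=0.3, alpha=1.0, a=0.15, b=0.8, lam=3.0)
        pmf = response_pmf_mc(p, bank.orientations[2], n_mc=500, seed=2)
        row = int(np.argmax(pmf.f.sum(axis=1)))
        mode = int(np.argmax(pmf.f[row]))
        out = convolve_nondecision(pmf, 2.0, 1e-9)
        assert int(np.argmax(out.f[row])) == min(mode + 2, pmf.T - 1)

    @pytest.mark.parametrize("mu,sd", [(0, 0.5), (2, 1.0), (5, 3.0), (-1, 0.7)])
    def test_mass_preserved(self, type1, bank, mu, sd):
        pmf = response_pmf_mc(type1, bank.orientations[3], n_mc=300, seed=4)
        out = convolve_nondecision(pmf, mu, sd)
        assert out.total_mass() == pytest.approx(pmf.total_mass(), abs=1e-9)

    def test_negative_sd_rejected(self, type1, bank):
        pmf = response_pmf_mc(type1, bank.orientations[0], n_mc=50, seed=0)
        with pytest.raises(ValueError):
            convolve_nondecision(pmf, 1.0, -0.5)


class TestAnalyticChoice:
    def test_symmetric_cases(self, type1):
        assert choice_prob_analytic(type1, [0.0, 0.0]) == pytest.approx(0.5)
        huge = Type1Params(sigma=5000.0, alpha=1.0, a=0.2, b=1.0, lam=3.0)
        assert choice_prob_analytic(huge, [-np.pi / 4] * 5) == pytest.approx(
            0.5, abs=1e-3
        )

    def test_zero_noise_step_function(self):
        p = Type1Params(sigma=0.0, alpha=1.0, a=0.2, b=1.0, lam=3.0,
                        lapse=0.0)
        assert choice_prob_analytic(p, [-np.pi / 4] * 3) == 1.0
        assert choice_prob_analytic(p, [np.pi / 4] * 3) == 0.0

    def test_monte_carlo_agrees_with_analytic(self, type1, bank):
        # unbounded fixed-length trials: MC frequencies vs the Gaussian form
        rng = np.random.default_rng(0)
        unbounded = Type1Params(sigma=type1.sigma, alpha=type1.alpha,
                                a=1e9, b=0.0, lam=3.0, lapse=type1.lapse)
        n_mc = 10_000
        for i in range(10):
            T = int(rng.integers(2, 20))
            ors = bank.orientations[i, :T]
            pa = choice_prob_analytic(type1, ors)
            rows = pd.DataFrame({
                "trial_id": [bank.trial_id[i]], "n_shown": [T],
                "choice": [1],
            })
            # the huge bound is never reached, so this exercises the
            # Monte-Carlo path on an effectively fixed-length trial
            nll = nll_replay(unbounded, Type2Params(sigma_c=0.0),
                             ModelVariant(covert_bound="absorbing",
                                          type2_coupling="same_z"),
                             rows, bank, n_mc=n_mc, seed=100 + i,
                             type1_only=True)
            pm = np.exp(-nll)
            se = max(np.sqrt(pa * (1 - pa) / n_mc), 1e-4)
            assert abs(pm - pa) <= 3 * se + 1e-3


class TestStoppingNLL:
    def _behaviour(self, obs, bank, n=60, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            choice, _, resp, _ = simulate_type1_trial(
                obs, bank.orientations[i % bank.n_trials], None, rng,
                cat=bank.cat_params,
            )
            rows.append({"condition": "85", "trial_id": i % bank.n_trials,
                         "choice": choice, "response_sample": resp})
        return pd.DataFrame(rows)

    def test_additivity_under_duplication(self, type1, observer, bank):
        beh = self._behaviour(observer, bank)
        single = nll_stopping(type1.with_lam({"85": 3.0}), beh, bank,
                              n_mc=200, seed=5)
        double = nll_stopping(type1.with_lam({"85": 3.0}),
                              pd.concat([beh, beh]), bank, n_mc=200, seed=5)
        assert double == pytest.approx(2 * single, rel=1e-9)

    def test_impossible_response_is_floored_not_infinite(self, bank):
        p = Type1Params(sigma=0.0, alpha=1.0, a=0.15, b=0.8, lam=3.0,
                        mu_U=0.0, sigma_U=0.0)
        beh = pd.DataFrame({
            "condition": ["85"], "trial_id": [0],
            "choice": [2], "response_sample": [1],
        })
        # force a response the deterministic model cannot produce
        nll = nll_stopping(p, beh, bank, n_mc=100, seed=0)
        assert np.isfinite(nll)
        assert nll > 5  # far less likely than any real response

    def test_common_random_numbers_make_nll_deterministic(self, type1, observer, bank):
        beh = self._behaviour(observer, bank)
        p = type1.with_lam({"85": 3.0})
        assert nll_stopping(p, beh, bank, n_mc=150, seed=3) == \
            nll_stopping(p, beh, bank, n_mc=150, seed=3)

    def test_unknown_trial_rejected(self, type1, bank):
        beh = pd.DataFrame({
            "condition": ["85"], "trial_id": [9999],
            "choice": [1], "response_sample": [5],
        })
        with pytest.raises(ValueError):
            nll_stopping(type1.with_lam({"85": 3.0}), beh, bank)

    def test_self_consistency_near_entropy(self, observer, bank):
        # NLL of data under its generating model is close to the entropy of
        # the model's own response distribution
        from metabound.likelihood import stopping_pmf_matrix, _frozen_uniform
        p = observer.type1
        beh = self._behaviour(observer, bank, n=400, seed=8)
        nll = nll_stopping(p, beh, bank, n_mc=600, seed=1)
        noise = _frozen_uniform(1, (600, bank.n_trials, 40))
        f = stopping_pmf_matrix(p, bank, None, noise)
        ent = -(f * np.log(np.maximum(f, 1e-12))).sum(axis=(1, 2))
        expected = ent[beh["trial_id"].to_numpy() % bank.n_trials].sum()
        assert nll == pytest.approx(expected, rel=0.15)


class TestReplayNLL:
    def _replay_behaviour(self, observer, bank, seed=0, n=150):
        from metabound import simulate_replay_trial
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            tid = i % bank.n_trials
            ns = int(rng.integers(2, 25))
            ch, cf = simulate_replay_trial(observer, bank.orientations[tid],
                                           ns, rng, cat=bank.cat_params)
            rows.append({"trial_id": tid, "n_shown": ns, "choice": ch,
                         "confidence": cf})
        return pd.DataFrame(rows)

    def test_joint_cells_sum_to_one(self, type1, type2, bank):
        n_shown = np.tile([3, 8, 20], 10)
        f = replay_joint_pmf(type1, type2, ModelVariant(), bank, n_shown,
                             n_mc=300, seed=0,
                             trial_index=np.arange(30))
        np.testing.assert_allclose(f.sum(axis=(1, 2)), 1.0, atol=1e-9)

    def test_type1_only_reduces_to_analytic(self, type1, type2, observer, bank):
        beh = self._replay_behaviour(observer, bank)
        v = ModelVariant(covert_bound="none")
        nll = nll_replay(type1, None, v, beh, bank, type1_only=True)
        direct = 0.0
        for _, r in beh.iterrows():
            p1 = choice_prob_analytic(
                type1, bank.orientations[int(r.trial_id), :int(r.n_shown)],
                cat=bank.cat_params,
            )
            direct -= np.log(p1 if r.choice == 1 else 1 - p1)
        assert nll == pytest.approx(direct, rel=1e-9)

    def test_samez_with_extra_noise_rejected(self, type1, type2, observer, bank):
        beh = self._replay_behaviour(observer, bank, n=10)
        v = ModelVariant(type2_coupling="same_z")
        with pytest.raises(ValueError):
            nll_replay(type1, type2, v, beh, bank, n_mc=50, seed=0)

    def test_degenerate_partition_ties_rating_to_choice_evidence(self, bank):
        # same_z, no noise anywhere, criteria so wide only rating 1 occurs
        p = Type1Params(sigma=0.0, alpha=1.0, a=1e9, b=0.0, lam=3.0,
                        lapse=0.0)
        t2 = Type2Params(sigma_c=0.0, a_c=1e9, b_c=0.0,
                         lam1=1.0, lam2=2.0, lam3=3.0)
        v = ModelVariant(covert_bound="none", type2_coupling="same_z")
        n_shown = np.full(10, 12)
        f = replay_joint_pmf(p, t2, v, bank, n_shown, n_mc=50, seed=0,
                             trial_index=np.arange(10))
        # all mass in rating 1 for the deterministic choice
        assert np.allclose(f[:, :, 1:].sum(), 0.0, atol=1e-9)
        for i in range(10):
            z = compute_evidence(bank.orientations[i, :12],
                                 bank.cat_params).sum()
            c = 0 if z > 0 else 1
            assert f[i, c, 0] == pytest.approx(1.0, abs=1e-9)
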