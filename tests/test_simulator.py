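"""Synthetic observers and the three-task behavioural protocol."""

import numpy as np
import pandas as pd
import pytest

from metabound import (
    CategoryParams,
    ModelVariant,
    SyntheticObserver,
    Type1Params,
    Type2Params,
    compute_evidence,
    generate_trial_bank,
    make_replay_conditions,
    map_confidence,
    run_protocol,
    simulate_replay_trial,
    simulate_type1_trial,
)
from metabound.simulator import TrialBank, draw_synthetic_observers


class TestTrialBank:
    def test_balanced_categories_and_shape(self, bank):
        assert bank.n_trials == 100
        assert bank.max_samples == 40
        assert (bank.category == 1).sum() == 50

    def test_odd_bank_rejected(self):
        with pytest.raises(ValueError):
            generate_trial_bank(n_trials=99)

    def test_deterministic_given_seed(self):
        b1 = generate_trial_bank(seed=9)
        b2 = generate_trial_bank(seed=9)
        np.testing.assert_array_equal(b1.orientations, b2.orientations)
        np.testing.assert_array_equal(b1.category, b2.category)

    def test_high_concentration_degenerates_to_category_mean(self):
        cat = CategoryParams(kappa=500.0)
        b = generate_trial_bank(n_trials=10, cat=cat, seed=0)
        ori1 = b.orientations[b.category == 1]
        assert np.allclose(ori1, -np.pi / 4, atol=0.1)

    def test_category1_evidence_positive_on_average(self, bank):
        ev = compute_evidence(bank.orientations[bank.category == 1])
        assert ev.mean() > 0.15

    def test_csv_roundtrip(self, bank, tmp_path):
        path = tmp_path / "bank.csv"
        bank.to_csv(path)
        back = TrialBank.from_csv(path)
        np.testing.assert_allclose(back.orientations, bank.orientations,
                                   atol=1e-10)
        np.testing.assert_array_equal(back.category, bank.category)


class TestType1Trial:
    def test_immediate_crossing_with_clean_evidence(self):
        # sigma=0, every sample worth +1, bound 0.5n: decision at sample 1
        p = Type1Params(sigma=0.0, alpha=1.0, a=0.5, b=0.0, lam=3.0,
                        mu_U=0.0, sigma_U=0.0, lapse=0.0)
        obs = SyntheticObserver(type1=p, type2=Type2Params())
        ors = np.full(40, -np.pi / 4)  # evidence +1 each
        choice, dec, resp, traj = simulate_type1_trial(
            obs, ors, None, np.random.default_rng(0)
        )
        assert (choice, dec, resp) == (1, 1, 1)
        assert traj[0] == pytest.approx(1.0)

    def test_unreachable_bound_forces_last_sample(self, bank):
        p = Type1Params(sigma=0.0, alpha=1.0, a=50.0, b=50.0, lam=3.0,
                        mu_U=0.0, sigma_U=0.0, lapse=0.0)
        obs = SyntheticObserver(type1=p, type2=Type2Params())
        ors = bank.orientations[0]
        choice, dec, resp, traj = simulate_type1_trial(
            obs, ors, None, np.random.default_rng(0)
        )
        assert dec == resp == 40
        expected = 1 if compute_evidence(ors).sum() > 0 else 2
        assert choice == expected

    def test_reproducible_given_rng(self, observer, bank):
        out1 = simulate_type1_trial(observer, bank.orientations[3], None,
                                    np.random.default_rng(5))
        out2 = simulate_type1_trial(observer, bank.orientations[3], None,
                                    np.random.default_rng(5))
        assert out1[:3] == out2[:3]

    def test_response_never_precedes_decision(self, observer, bank):
        rng = np.random.default_rng(0)
        for i in range(30):
            _, dec, resp, _ = simulate_type1_trial(
                observer, bank.orientations[i], None, rng
            )
            assert dec <= resp <= 40


class TestReplayTrial:
    def test_degenerate_coupling_shares_trajectory(self, bank):
        # same_z with no covert bound: confidence must equal the mapping of
        # the Type-I end-of-trial evidence
        p = Type1Params(sigma=0.4, alpha=1.0, a=0.15, b=0.8, lam=3.0,
                        lapse=0.0)
        t2 = Type2Params(sigma_c=0.0, alpha_c=1.0, a_c=0.15, b_c=0.8,
                         lam1=2.0, lam2=4.0, lam3=7.0)
        v = ModelVariant(covert_bound="none", type2_coupling="same_z")
        obs = SyntheticObserver(type1=p, type2=t2, variant=v)
        ors = bank.orientations[5]
        rng = np.random.default_rng(3)
        choice, conf = simulate_replay_trial(obs, ors, 12, rng)
        # replicate the shared trajectory with the same rng stream
        rng2 = np.random.default_rng(3)
        ell = compute_evidence(ors[:12])
        eps = rng2.normal(0.0, p.sigma, 12)
        z = np.cumsum(ell + eps)[-1]
        assert choice == (1 if z > 0 else 2)
        assert conf == map_confidence(z, 12, t2)

    def test_tiny_absorbing_bound_freezes_first_sample(self, bank):
        p = Type1Params(sigma=0.0, alpha=1.0, a=1e-6, b=0.0, lam=3.0,
                        lapse=0.0)
        t2 = Type2Params(sigma_c=0.0)
        v = ModelVariant(covert_bound="absorbing", type2_coupling="same_z")
        obs = SyntheticObserver(type1=p, type2=t2, variant=v)
        rng = np.random.default_rng(0)
        for i in range(20):
            ors = bank.orientations[i]
            choice, _ = simulate_replay_trial(obs, ors, 30, rng)
            first_sign = 1 if compute_evidence(ors[0]) > 0 else 2
            assert choice == first_sign

    def test_stronger_evidence_raises_ratings(self, observer, bank):
        # |Type-II z| grows with sequence length on average, so ratings
        # should be stochastically higher for longer sequences
        rng = np.random.default_rng(1)
        short, long_ = [], []
        for i in range(bank.n_trials):
            short.append(simulate_replay_trial(
                observer, bank.orientations[i], 3, rng)[1])
            long_.append(simulate_replay_trial(
                observer, bank.orientations[i], 35, rng)[1])
        assert np.mean(long_) > np.mean(short)


class TestReplayConditions:
    @pytest.mark.parametrize("free,expected", [
        ((4, 5, 10), (2, 5, 14)),
        ((3, 3, 3), (1, 3, 7)),
        ((1, 2, 40), (1, 2, 40)),
    ])
    def test_rule(self, free, expected):
        assert make_replay_conditions(free) == expected

    @pytest.mark.parametrize("bad", [(3, 3), (1, 2, 3, 4), (0, 3, 5)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            make_replay_conditions(bad)


class TestProtocols:
    def test_record_counts(self, observer, bank):
        stop = run_protocol(observer, bank, "stopping")
        free = run_protocol(observer, bank, "free", seed=1)
        replay = run_protocol(observer, bank, "replay", free_table=free,
                              seed=2)
        assert len(stop) == 600
        assert len(free) == 300
        assert len(replay) == 300
        assert stop["confidence"].isna().all()
        assert replay["confidence"].notna().all()
        assert replay.groupby("condition").size().to_dict() == {
            "less": 100, "more": 100, "same": 100
        }
        assert stop["response_sample"].between(1, 40).all()

    def test_replay_requires_free_run(self, observer, bank):
        with pytest.raises(ValueError):
            run_protocol(observer, bank, "replay")

    def test_median_response_grows_with_bound_decay(self, bank):
        # slower bound collapse (larger lam) -> later responses
        meds = []
        for lam in (1.0, 8.0):
            p = Type1Params(sigma=0.5, alpha=1.0, a=0.1, b=1.0, lam=lam,
                            mu_U=0.0, sigma_U=0.0)
            obs = SyntheticObserver(type1=p, type2=Type2Params(), seed=7)
            df = run_protocol(obs, bank, "free", seed=3)
            meds.append(df["response_sample"].median())
        assert meds[1] > meds[0]

    def test_replay_same_matches_free_accuracy_without_bound(self, bank):
        # a bound-free observer sees identical evidence in the Free task
        # and the Same replay condition, so accuracies should agree
        p = Type1Params(sigma=0.5, alpha=1.0, a=60.0, b=0.0, lam=3.0,
                        mu_U=0.0, sigma_U=0.0)
        t2 = Type2Params(sigma_c=0.3, a_c=0.1, b_c=0.6)
        obs = SyntheticObserver(
            type1=p, type2=t2,
            variant=ModelVariant(covert_bound="none"), seed=21,
        )
        free = run_protocol(obs, bank, "free", seed=5)
        replay = run_protocol(obs, bank, "replay", free_table=free, seed=6)
        same_acc = replay.loc[replay["condition"] == "same",
                              "correct"].mean()
        assert same_acc == pytest.approx(free["correct"].mean(), abs=0.08)

    def test_optimal_observer_upper_bounds_accuracy(self, bank):
        ell = bank.evidence()
        optimal = np.where(ell.sum(axis=1) > 0, 1, 2)
        opt_acc = (optimal == bank.category).mean()
        obs = draw_synthetic_observers(3, seed=4)
        for o in obs:
            df = run_protocol(o, bank, "free", seed=11)
            assert df["correct"].mean() <= opt_acc + 0.05


class TestObserverDraws:
    def test_empty_and_deterministic(self):
        assert draw_synthetic_observers(0, seed=1) == []
        a = draw_synthetic_observers(3, seed=2)
        b = draw_synthetic_observers(3, seed=2)
        assert [o.type1 for o in a] == [o.type1 for o in b]

    def test_lambda_ordering_and_ranges(self):
        from metabound.simulator import DEFAULT_OBSERVER_RANGES as R
        for o in draw_synthetic_observers(10, seed=3):
            lams = [o.type1.lam_for(c) for c in ("70", "85", "90")]
            assert lams[0] <= lams[1] <= lams[2]
            assert R["sigma"][0] <= o.type1.sigma <= R["sigma"][1]
            assert o.type2.lam1 <= o.type2.lam2 <= o.type2.lam3

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValueError):
            draw_synthetic_observers(2, ranges={}, seed=0)
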