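"""Behavioral analysis: r_MH inference, bounded MLE, randomization test,
model precision, and pairwise U-tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from mhng.analysis import (
    A_FLOOR,
    BehaviorLog,
    analyze_cohort,
    biased_bernoulli_loglik,
    binned_acceptance,
    empirical_p,
    fit_biased_bernoulli,
    game_log_to_behavior_logs,
    infer_rmh_for_log,
    model_precision,
    pairwise_u_tests,
    randomization_test_a,
    report_tables,
)
from mhng.participants import BehaviorModelSpec, simulate_cohort


def _toy_log(initial_c, initial_s, trial_rows, n_items=5):
    return BehaviorLog(
        participant_id="p1", pair_id="pair1", dataset_label="hard",
        trials=pd.DataFrame(trial_rows),
        initial_c=np.asarray(initial_c), initial_s=np.asarray(initial_s),
        n_items=n_items,
    )


def _trial(item, s_star, s_own, c_own, decision=0, c_after=None):
    return {
        "pass": 0, "item_id": item, "proposed_sign": s_star,
        "own_sign_before": s_own, "own_category": c_own, "decision": decision,
        "own_category_after": c_own if c_after is None else c_after,
    }


def _cohort_trials(model, n_pairs=10, datasets=("hard", "easy"), seed=11,
                   use_true=True):
    cohort = simulate_cohort(model, n_pairs=n_pairs, datasets=datasets, seed=seed)
    z, r_true, r_inf = [], [], []
    for name, logs in cohort.items():
        for i, g in enumerate(logs):
            for view in game_log_to_behavior_logs(g, pair_id=f"{name}p{i}").values():
                z.append(view.decisions())
                r_true.append(view.trials["r_mh_true"].to_numpy())
                if not use_true:
                    r_inf.append(infer_rmh_for_log(view)["r_mh"].to_numpy())
    out = [np.concatenate(z), np.concatenate(r_true)]
    if not use_true:
        out.append(np.concatenate(r_inf))
    return out


class TestInferRmh:
    def test_closed_form_dirichlet_oracle(self):
        # 5 items, all category 2 under sign 1; proposal sign 3:
        # theta_hat[1][2] = 5.1/5.5, theta_hat[3][2] = 0.1/0.5,
        # r = 0.2 * 5.5 / 5.1 = 1.1/5.1
        log = _toy_log([2] * 5, [1] * 5, [_trial(0, s_star=3, s_own=1, c_own=2)])
        inf = infer_rmh_for_log(log)
        assert inf["r_mh"].iloc[0] == pytest.approx(1.1 / 5.1, abs=1e-12)
        assert inf["p_num"].iloc[0] == pytest.approx(0.1 / 0.5, abs=1e-12)
        assert inf["p_den"].iloc[0] == pytest.approx(5.1 / 5.5, abs=1e-12)

    def test_identical_proposal_gives_one(self):
        log = _toy_log([2] * 5, [1] * 5, [_trial(0, s_star=1, s_own=1, c_own=2)])
        assert infer_rmh_for_log(log)["r_mh"].iloc[0] == 1.0

    def test_online_state_tracks_accepted_signs(self):
        # after an accepted proposal the item's sign changes, shifting the
        # counts used for the next trial's theta estimate
        rows = [
            _trial(0, s_star=3, s_own=1, c_own=2, decision=1),
            _trial(1, s_star=3, s_own=1, c_own=2, decision=0),
        ]
        inf = infer_rmh_for_log(_toy_log([2] * 5, [1] * 5, rows))
        # trial 2: item 0 now carries sign 3 -> theta[3][2] = 1.1/1.5,
        # theta[1][2] = 4.1/4.5
        assert inf["r_mh"].iloc[1] == pytest.approx((1.1 / 1.5) / (4.1 / 4.5))

    def test_label_permutation_invariance(self):
        # relabeling signs and categories consistently leaves r_MH unchanged
        rows = [
            _trial(0, s_star=3, s_own=1, c_own=2, decision=1),
            _trial(2, s_star=0, s_own=4, c_own=0, decision=0),
            _trial(1, s_star=2, s_own=2, c_own=4, decision=1),
        ]
        log = _toy_log([2, 0, 4, 1, 3], [1, 4, 0, 2, 3], rows)
        perm = np.array([4, 2, 0, 1, 3])
        rows_p = [
            _trial(int(r["item_id"]), int(perm[r["proposed_sign"]]),
                   int(perm[r["own_sign_before"]]), int(perm[r["own_category"]]),
                   int(r["decision"]), int(perm[r["own_category_after"]]))
            for r in rows
        ]
        log_p = _toy_log(perm[[2, 0, 4, 1, 3]], perm[[1, 4, 0, 2, 3]], rows_p)
        np.testing.assert_allclose(
            infer_rmh_for_log(log)["r_mh"], infer_rmh_for_log(log_p)["r_mh"]
        )

    def test_recovery_against_generator(self):
        # inferred r_MH tracks the generator's logged truth across a cohort
        z, r_true, r_inf = _cohort_trials(
            BehaviorModelSpec("mh"), n_pairs=10, datasets=("easy",),
            seed=5, use_true=False,
        )
        assert z.size == 900  # 45 trials x 20 participants
        assert np.corrcoef(r_true, r_inf)[0, 1] > 0.8

    def test_unknown_item_rejected(self):
        log = _toy_log([2] * 5, [1] * 5, [_trial(9, s_star=3, s_own=1, c_own=2)])
        with pytest.raises(ValueError):
            infer_rmh_for_log(log)

    def test_sampled_estimator_agrees_with_mean(self):
        log = _toy_log([2, 2, 1, 0, 2], [1, 1, 3, 0, 1],
                       [_trial(0, s_star=3, s_own=1, c_own=2)])
        r_mean = infer_rmh_for_log(log, estimator="mean")["r_mh"].iloc[0]
        r_samp = infer_rmh_for_log(log, estimator="sample", gibbs_iters=4000,
                                   seed=1)["r_mh"].iloc[0]
        # sampled-theta averaging is a different estimator of the same ratio;
        # they need only agree loosely (Jensen gap + Monte-Carlo error)
        assert abs(r_mean - r_samp) < 0.15


class TestFitBiasedBernoulli:
    def test_all_accept_boundary(self, rng):
        a, b, _, flag = fit_biased_bernoulli(np.ones(50), rng.random(50))
        assert (a, b) == (0.0, 1.0)
        assert not flag

    def test_identical_rates_unidentifiable(self):
        with pytest.warns(UserWarning):
            a, b, _, flag = fit_biased_bernoulli(
                np.array([1, 0, 1, 1]), np.full(4, 0.3)
            )
        assert a == 0.0 and flag
        assert b == pytest.approx(0.75)

    def test_parameter_recovery(self, rng):
        r = rng.choice([0.02, 0.1, 0.5, 0.9, 1.0], size=2000)
        z = (rng.random(2000) < 0.5 * r + 0.25).astype(int)
        a, b, _, _ = fit_biased_bernoulli(z, r)
        assert abs(a - 0.5) < 0.05 and abs(b - 0.25) < 0.05

    def test_matches_slsqp_oracle(self, rng):
        # independent constrained optimizer finds no higher likelihood
        for _ in range(5):
            n = 150
            r = rng.random(n)
            z = (rng.random(n) < np.clip(0.7 * r + 0.2, 0, 1)).astype(int)
            a, b, ll, _ = fit_biased_bernoulli(z, r)
            best = np.inf
            for start in [(0.1, 0.2), (0.5, 0.25), (0.0, 0.5), (0.8, 0.1)]:
                res = minimize(
                    lambda x: -biased_bernoulli_loglik(z, r, *x), start,
                    method="SLSQP",
                    constraints=[
                        {"type": "ineq", "fun": lambda x: x[1]},
                        {"type": "ineq", "fun": lambda x: 1 - x[0] - x[1]},
                        {"type": "ineq", "fun": lambda x: x[0] - A_FLOOR},
                    ],
                )
                best = min(best, res.fun)
            assert -ll <= best + 1e-4

    def test_null_model_is_nested(self, rng):
        # at (a, b) = (0, b_bar) the likelihood equals the constant model's
        z = (rng.random(300) < 0.6).astype(int)
        r = rng.random(300)
        b_bar = z.mean()
        ll = biased_bernoulli_loglik(z, r, 0.0, b_bar)
        expected = z.sum() * np.log(b_bar) + (z.size - z.sum()) * np.log(1 - b_bar)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_biased_bernoulli(np.array([0, 2]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            fit_biased_bernoulli(np.array([0, 1]), np.array([0.1, 1.2]))
        with pytest.raises(ValueError):
            fit_biased_bernoulli(np.array([]), np.array([]))


class TestRandomizationTest:
    def test_empirical_p_inclusive_extremes(self):
        null = np.array([0.1, 0.2, 0.3, 0.4])
        assert empirical_p(null, 0.1) == 1.0  # observed = min -> p = 1
        assert empirical_p(null, 0.5) == 0.0  # above every null sample
        assert empirical_p(null, 0.3) == 0.5

    def test_detects_true_association(self, rng):
        r = rng.choice([0.05, 0.5, 1.0], size=500)
        z = (rng.random(500) < np.clip(0.8 * r + 0.1, 0, 1)).astype(int)
        a_hat, p, null_a, _ = randomization_test_a(z, r, n_null=500, seed=1)
        assert a_hat > 0.5
        assert p < 0.01
        assert null_a.shape == (500,)

    def test_null_data_gives_large_p(self, rng):
        r = rng.choice([0.05, 0.5, 1.0], size=500)
        z = (rng.random(500) < 0.6).astype(int)
        _, p, _, _ = randomization_test_a(z, r, n_null=500, seed=2)
        assert p > 0.01

    def test_seeded_determinism(self, rng):
        r = rng.random(100)
        z = (rng.random(100) < 0.5).astype(int)
        out1 = randomization_test_a(z, r, n_null=50, seed=9)
        out2 = randomization_test_a(z, r, n_null=50, seed=9)
        assert out1[0] == out2[0] and out1[1] == out2[1]
        assert np.array_equal(out1[2], out2[2])


class TestModelPrecision:
    def test_perfect_model_has_unit_precision(self, rng):
        z = rng.integers(0, 2, 200)
        # mh model with probabilities exactly matching the decisions
        prec = model_precision(z, z.astype(float), z.astype(float),
                               z.astype(float), BehaviorModelSpec("mh"),
                               n_replicates=20, seed=0)
        assert np.all(prec == 1.0)

    def test_coin_flip_model_half_precision(self, rng):
        z = rng.integers(0, 2, 400)
        prec = model_precision(z, np.full(400, 0.5), np.full(400, 0.5),
                               np.full(400, 0.5),
                               BehaviorModelSpec("constant", b_bar=0.5),
                               n_replicates=200, seed=1)
        assert abs(prec.mean() - 0.5) < 0.02

    def test_constant_model_uses_observed_rate(self, rng):
        # the constant model's probability is the observed acceptance rate
        z = (rng.random(500) < 0.7).astype(int)
        model = BehaviorModelSpec("constant", b_bar=float(z.mean()))
        prec = model_precision(z, np.zeros(500), np.zeros(500), np.zeros(500),
                               model, n_replicates=400, seed=2)
        pbar = z.mean()
        expected = pbar**2 + (1 - pbar) ** 2
        assert abs(prec.mean() - expected) < 0.02


class TestPairwiseUTests:
    def test_identical_samples_not_rejected(self, rng):
        x = rng.random(100)
        p, rej, _ = pairwise_u_tests({"m1": x, "m2": x.copy()})
        assert p.loc["m1", "m2"] >= 0.05
        assert not rej.to_numpy().any()

    def test_complete_separation_tiny_p(self, rng):
        lo = rng.uniform(0.0, 0.4, 100)
        hi = rng.uniform(0.6, 1.0, 100)
        p, rej, _ = pairwise_u_tests({"hi": hi, "lo": lo})
        # oracle: U statistic is exactly 100*100 = 10,000; the asymptotic
        # one-sided tail at that extreme is far below 1e-6
        assert p.loc["hi", "lo"] < 1e-6
        assert rej.loc["hi", "lo"]
        assert p.loc["lo", "hi"] > 0.999

    def test_exact_enumeration_oracle_small_samples(self, rng):
        # brute-force permutation distribution of U for tiny replicate counts
        x = rng.random(6)
        y = rng.random(6)
        pooled = np.concatenate([x, y])
        u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        count = total = 0
        for idx in itertools.combinations(range(12), 6):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(12) if i not in idx]]
            u = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
            count += u >= u_obs
            total += 1
        p_exact = count / total
        p, _, _ = pairwise_u_tests({"x": x, "y": y})
        assert p.loc["x", "y"] == pytest.approx(p_exact, abs=0.05)

    def test_degenerate_all_tied_flagged(self):
        x = np.full(30, 0.8)
        p, rej, flagged = pairwise_u_tests({"m1": x, "m2": x.copy()})
        assert p.loc["m1", "m2"] == 0.5
        assert ("m1", "m2") in flagged
        assert not rej.to_numpy().any()

    def test_unequal_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_u_tests({"m1": rng.random(10), "m2": rng.random(9)})


class TestCohortAnalysis:
    def test_report_tables_and_binned_partition(self):
        cohort = simulate_cohort(BehaviorModelSpec("mh"), n_pairs=2,
                                 datasets=("easy",), seed=3)
        blogs = []
        for i, g in enumerate(cohort["easy"]):
            blogs.extend(game_log_to_behavior_logs(g, pair_id=f"p{i}").values())
        result = analyze_cohort(blogs, n_null=50, n_model_reps=50, seed=3)
        tables = report_tables(result)
        # one row per participant-dataset plus the pooled rows
        assert len(tables["fits"]) == len(result.per_participant) + len(result.pooled)
        assert tables["u_pvalues"].shape == (5, 5)
        binned = tables["binned_acceptance"]
        assert len(binned) == 10
        assert binned["bin_left"].iloc[0] == 0.0
        assert binned["bin_right"].iloc[-1] == 1.0
        assert binned["n_trials"].sum() == 4 * 45

    def test_mh_precision_beats_constant_on_mh_data(self):
        cohort = simulate_cohort(BehaviorModelSpec("mh"), n_pairs=3,
                                 datasets=("easy",), seed=8)
        blogs = []
        for i, g in enumerate(cohort["easy"]):
            blogs.extend(game_log_to_behavior_logs(g, pair_id=f"p{i}").values())
        result = analyze_cohort(blogs, n_null=50, n_model_reps=100, seed=8)
        pooled = result.precision["pooled"]
        assert pooled["mh"].mean() > pooled["constant"].mean()


def test_binned_acceptance_partition_property(rng):
    z = rng.integers(0, 2, 500)
    r = rng.random(500)
    binned = binned_acceptance(z, r)
    assert binned["n_trials"].sum() == 500
    assert (binned["n_accepted"] <= binned["n_trials"]).all()
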