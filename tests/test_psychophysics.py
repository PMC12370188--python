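"""2-IFC sessions, simulated observers, exclusion, reliability, and the
model-human correspondence statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from gaborpath import psychophysics as psy, stimuli


@pytest.fixture(scope="module")
def one_split(behavioral_set):
    return behavioral_set[behavioral_set["split"] == 0]


class TestBuildSession:
    def test_200_trials_with_exact_counterbalancing(self, one_split):
        for seed in (0, 1):
            sess = psy.build_session(one_split, seed=seed)
            assert len(sess) == 200
            per_cond = sess.groupby(["beta_deg", "present_interval"]).size()
            assert (per_cond == 20).all() and len(per_cond) == 10
            per_block = sess.groupby(["block", "beta_deg",
                                      "present_interval"]).size()
            assert (per_block == 4).all()
            per_mini = sess.groupby(["miniblock", "beta_deg",
                                     "present_interval"]).size()
            assert (per_mini == 2).all()

    def test_two_seeds_same_conditions_different_orders(self, one_split):
        a = psy.build_session(one_split, seed=0)
        b = psy.build_session(one_split, seed=1)
        assert sorted(a["pair_id"]) == sorted(b["pair_id"])
        assert not a["pair_id"].tolist() == b["pair_id"].tolist()

    def test_malformed_split_rejected(self, one_split):
        with pytest.raises(ValueError):
            psy.build_session(one_split.iloc[:150], seed=0)


class TestSimulateObservers:
    def _run(self, threshold, lapse, sd, one_split, n=30):
        sessions = {i: psy.build_session(one_split, seed=i) for i in range(n)}
        params = [psy.ObserverParams(weibull_threshold=threshold,
                                     weibull_slope=2.0, lapse_rate=lapse,
                                     trial_difficulty_sd=sd, seed=100 + i)
                  for i in range(n)]
        diffs = psy.make_trial_difficulties(one_split["pair_id"], sd,
                                            np.random.default_rng(0))
        return psy.simulate_observers(params, sessions, diffs)

    def test_infinite_threshold_no_lapse_gives_all_correct(self, one_split):
        resp = self._run(1e9, 0.0, 0.0, one_split, n=3)
        assert resp["correct"].all()

    def test_zero_threshold_limit_is_guessing(self, one_split):
        resp = self._run(1e-6, 0.0, 0.0, one_split, n=10)
        acc = resp["correct"].mean()
        se = math.sqrt(0.25 / len(resp))
        assert abs(acc - 0.5) < 4 * se

    def test_mean_accuracy_decreases_with_curvature(self, one_split):
        resp = self._run(45.0, 0.02, 0.5, one_split, n=40)
        by_beta = resp.groupby("beta_deg")["correct"].mean()
        assert by_beta.is_monotonic_decreasing
        # and tracks the closed-form psychometric mean within sampling error
        expected = psy.weibull_p(by_beta.index.to_numpy(), 45.0, 2.0, 0.02)
        np.testing.assert_allclose(by_beta.to_numpy(), expected, atol=0.06)


class TestFitPsychometric:
    def test_parameter_recovery_within_ten_percent(self):
        betas = np.array([15, 30, 45, 60, 75], dtype=float)
        rng = np.random.default_rng(1)
        p = psy.weibull_p(betas, 40.0, 2.5, 0.0)
        acc = rng.binomial(1000, p) / 1000.0
        fit = psy.fit_psychometric(betas, acc)
        assert not fit.flagged
        assert abs(fit.threshold - 40.0) / 40.0 <= 0.10

    def test_flat_chance_data_flagged_or_tiny_threshold(self):
        betas = [15, 30, 45, 60, 75]
        fit = psy.fit_psychometric(betas, [0.5] * 5)
        assert fit.flagged or fit.threshold < 15

    def test_flat_ceiling_data_flagged_or_huge_threshold(self):
        betas = [15, 30, 45, 60, 75]
        fit = psy.fit_psychometric(betas, [1.0] * 5)
        assert fit.flagged or fit.threshold > 75


class TestExclusion:
    def _cohort(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        betas = np.repeat([15, 30, 45, 60, 75], 40)
        pair_ids = [f"b{b}_{i}" for b, i in zip(betas, range(200))]
        rows = []
        p_by_beta = dict(zip([15, 30, 45, 60, 75],
                             [0.95, 0.85, 0.7, 0.6, 0.55]))
        for pid in range(n):
            p = np.array([p_by_beta[b] for b in betas])
            correct = (rng.random(200) < p).astype(int)
            rows.append(pd.DataFrame({
                "participant": pid, "pair_id": pair_ids,
                "beta_deg": betas.astype(float), "correct": correct}))
        return pd.concat(rows, ignore_index=True)

    def test_homogeneous_cohort_keeps_everyone(self):
        # identical deterministic response patterns: zero spread
        base = self._cohort(n=1, seed=3)
        df = pd.concat([base.assign(participant=i) for i in range(10)],
                       ignore_index=True)
        kept, audit = psy.exclude_participants(df)
        assert len(kept) == 10 and audit.empty

    def test_planted_low_accuracy_observer_removed_at_stage_1(self):
        df = self._cohort(n=50)
        bad = df[df["participant"] == 0].copy()
        bad["participant"] = 50
        bad["correct"] = (np.random.default_rng(9).random(len(bad)) < 0.1
                          ).astype(int)
        kept, audit = psy.exclude_participants(
            pd.concat([df, bad], ignore_index=True))
        assert 50 not in kept
        row = audit[audit["participant"] == 50].iloc[0]
        assert row["stage"] == 1

    def test_planted_inverted_profile_removed_at_stage_2(self):
        df = self._cohort(n=50)
        bad = df[df["participant"] == 0].copy()
        bad["participant"] = 50
        rng = np.random.default_rng(10)
        # inverted curvature profile, same overall accuracy (~0.73)
        p_by_beta = {15: 0.55, 30: 0.6, 45: 0.7, 60: 0.85, 75: 0.95}
        p = bad["beta_deg"].map(p_by_beta).to_numpy()
        bad["correct"] = (rng.random(len(bad)) < p).astype(int)
        kept, audit = psy.exclude_participants(
            pd.concat([df, bad], ignore_index=True))
        assert 50 not in kept
        row = audit[audit["participant"] == 50].iloc[0]
        assert row["stage"] == 2

    def test_exclusion_is_idempotent(self, cohort):
        resp = cohort["responses"]
        kept, _ = psy.exclude_participants(resp)
        again, audit2 = psy.exclude_participants(
            resp[resp["participant"].isin(kept)])
        assert sorted(again) == sorted(kept)
        assert audit2.empty

    def test_too_few_participants_aborts(self):
        df = self._cohort(n=2)
        with pytest.raises(psy.ExclusionAborted):
            psy.exclude_participants(df)


class TestReliability:
    def test_spearman_brown_closed_form(self):
        assert psy.spearman_brown(0.65) == pytest.approx(0.7879, abs=5e-4)
        assert psy.spearman_brown(1.0) == 1.0
        rs = np.linspace(0.05, 0.95, 10)
        sb = [psy.spearman_brown(r) for r in rs]
        assert all(b > a for a, b in zip(sb, sb[1:]))  # monotone
        assert all(s >= r for r, s in zip(rs, sb))  # >= r on (0, 1)

    def test_duplicated_cohort_has_unit_raw_reliability(self, one_split):
        sessions = {i: psy.build_session(one_split, seed=i % 4)
                    for i in range(8)}
        params = [psy.ObserverParams(seed=100 + (i % 4)) for i in range(8)]
        diffs = psy.make_trial_difficulties(one_split["pair_id"], 0.5,
                                            np.random.default_rng(0))
        resp = psy.simulate_observers(params, sessions, diffs)
        # participants 0-3 and 4-7 are exact clones; force the halving to
        # split clones apart by duplicating the frame with relabeled ids
        a = resp[resp["participant"] < 4]
        clones = a.copy()
        clones["participant"] += 4
        both = pd.concat([a, clones], ignore_index=True)
        both["split"] = 0
        raws = []
        rng = np.random.default_rng(5)
        for _ in range(20):
            half = rng.permutation(8)[:4]
            pa = both[both["participant"].isin(half)] \
                .groupby("pair_id")["correct"].mean()
            pb = both[~both["participant"].isin(half)] \
                .groupby("pair_id")["correct"].mean()
            r = np.corrcoef(pa, pb.loc[pa.index])[0, 1]
            raws.append(r)
        assert max(raws) == pytest.approx(1.0)  # clone-respecting halvings

    def test_cohort_reliability_matches_analytic_attenuation(self, cohort):
        resp = cohort["responses"]
        raw, corrected, ci = psy.split_half_reliability(resp, n_boot=200,
                                                        seed=3)
        beh = cohort["behavioral"]
        base = psy.weibull_p(beh["beta_deg"].to_numpy(), 45.0, 2.0, 0.02)
        from scipy.special import expit
        offs = cohort["difficulties"].reindex(beh["pair_id"]).to_numpy()
        p_t = expit(np.log(base / (1 - base)) + offs)
        pred_raw = psy.predicted_split_half_r(p_t, n_half=5)
        pred_corrected = psy.spearman_brown(pred_raw)
        assert ci[0] <= pred_corrected <= ci[1]


class TestSignalAndCorrespondence:
    def test_contour_signal_worked_examples(self):
        assert psy.contour_signal(0.9, 0.1) == pytest.approx(0.4)
        assert psy.contour_signal(0.3, 0.3) == 0.0
        assert psy.contour_signal(0.1, 0.9) == -psy.contour_signal(0.9, 0.1)
        with pytest.raises(ValueError):
            psy.contour_signal(np.nan, 0.1)

    def test_affine_signal_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        acc = pd.Series(rng.random(100), index=[f"p{i}" for i in range(100)])
        sig = 3.0 * acc + 1.0
        rep = psy.model_human_correlation(sig, acc)
        assert rep.pearson_r == pytest.approx(1.0)
        rep_neg = psy.model_human_correlation(-acc, acc)
        assert rep_neg.pearson_r == pytest.approx(-1.0)

    def test_independent_signal_ci_covers_zero(self):
        rng = np.random.default_rng(1)
        idx = [f"p{i}" for i in range(1000)]
        acc = pd.Series(rng.random(1000), index=idx)
        sig = pd.Series(rng.normal(size=1000), index=idx)
        rep = psy.model_human_correlation(sig, acc)
        # permutation oracle for the null spread
        perm = [np.corrcoef(rng.permutation(sig.values), acc.values)[0, 1]
                for _ in range(200)]
        assert abs(rep.pearson_r) < 3 * np.std(perm) + 1e-3
        assert rep.ci95_low <= 0.0 <= rep.ci95_high

    def test_fisher_interval_width_shrinks_with_n(self):
        lo1, hi1 = psy.fisher_ci(0.5, 50)
        lo2, hi2 = psy.fisher_ci(0.5, 5000)
        assert (hi2 - lo2) < (hi1 - lo1)
        assert lo1 < 0.5 < hi1


def test_end_to_end_latent_signal_recovery(cohort):
    """A 'model' whose signal is the generator's true per-trial success
    probability correlates with simulated percent correct at the analytic
    attenuation bound implied by the finite cohort size."""
    resp = cohort["responses"]
    kept, _ = psy.exclude_participants(resp)
    ta = psy.trial_accuracy(resp, kept).set_index("pair_id")
    acc = ta["percent_correct"]

    beh = cohort["behavioral"]
    base = psy.weibull_p(beh["beta_deg"].to_numpy(), 45.0, 2.0, 0.02)
    from scipy.special import expit
    offs = cohort["difficulties"].reindex(beh["pair_id"]).to_numpy()
    p_true = pd.Series(expit(np.log(base / (1 - base)) + offs),
                       index=beh["pair_id"])

    rep = psy.model_human_correlation(p_true, acc)
    n_bar = float(ta["n_responses"].mean())
    # corr(p, p + e) with Var(e) = E[p(1-p)]/n: sqrt of the split-half form
    expected = math.sqrt(
        psy.predicted_split_half_r(p_true.to_numpy(), n_bar))
    assert rep.pearson_r == pytest.approx(expected, abs=0.07)
    assert 0.0 < rep.pearson_r <= 1.0
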