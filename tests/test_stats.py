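import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

import prediarem as pr


def null_long_table(rng, n_per_group=30, effect=0.0):
    n = 2 * n_per_group
    subj = np.repeat(np.arange(n), 2)
    grp = np.repeat(["A"] * n_per_group + ["B"] * n_per_group, 2)
    tim = np.tile(["t0", "t1"], n)
    y = np.repeat(rng.normal(0, 1, n), 2) + rng.normal(0, 1, 2 * n)
    y[(grp == "B") & (tim == "t1")] += effect
    return pd.DataFrame({"subject_id": subj, "group": grp, "time": tim, "value": y})


class TestMixedModel:
    def test_balanced_zero_effect_estimate_near_zero(self):
        # perfectly symmetric data: the interaction contrast vanishes
        df = pd.DataFrame(
            {
                "subject_id": np.repeat(np.arange(8), 2),
                "group": np.repeat(["A"] * 4 + ["B"] * 4, 2),
                "time": np.tile(["t0", "t1"], 8),
                "value": np.tile([1.0, 2.0], 8),
            }
        )
        res = pr.fit_group_time_model(df)
        assert res.estimate == pytest.approx(0.0, abs=1e-8)
        assert res.within_group["A"]["estimate"] == pytest.approx(1.0, abs=1e-8)
        assert res.within_group["B"]["estimate"] == pytest.approx(1.0, abs=1e-8)

    def test_effect_recovery_and_ci_coverage(self):
        """Interaction effect of 1 residual SD at n = 50/group.  The analytic
        power of this design is ~0.94 (interaction SE = sqrt(4/50)); the
        Monte-Carlo thresholds leave ~3 sigma of sampling slack below that
        and below the nominal 95% CI coverage."""
        rng = np.random.default_rng(101)
        covered = rejected = 0
        reps = 120
        for _ in range(reps):
            df = null_long_table(rng, 50, effect=1.0)
            res = pr.fit_group_time_model(df)
            covered += res.ci_low <= 1.0 <= res.ci_high
            rejected += res.p_interaction < 0.05
        assert rejected / reps >= 0.87
        assert covered / reps >= 0.89

    def test_sensitivity_adjustment_changes_design(self):
        rng = np.random.default_rng(0)
        df = null_long_table(rng, 20)
        df["insulin_sensitivity"] = rng.normal(300, 30, len(df))
        r1 = pr.fit_group_time_model(df)
        r2 = pr.fit_group_time_model(df, adjust_for_sensitivity=True)
        assert r1.estimate != r2.estimate

    def test_too_few_subjects_rejected(self):
        df = null_long_table(np.random.default_rng(0), 1)
        with pytest.raises(ValueError):
            pr.fit_group_time_model(df)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert pr.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_textbook_example(self):
        np.testing.assert_allclose(
            pr.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_brute_force_definition(self):
        """adj_i = min over j with p_j >= p_i of min(1, p_j * m / rank_j)."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 20))
            m = len(p)
            order = np.argsort(p)
            brute = np.empty(m)
            vals = [min(1.0, p[order[j]] * m / (j + 1)) for j in range(m)]
            for j in range(m):
                brute[order[j]] = min(vals[j:])
            np.testing.assert_allclose(pr.bh_adjust(p), brute, atol=1e-12)

    def test_permutation_invariance_and_monotonicity(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(pr.bh_adjust(p)[perm], pr.bh_adjust(p[perm]))
        assert np.all(pr.bh_adjust(p) >= p - 1e-15)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            pr.bh_adjust([])
        with pytest.raises(ValueError):
            pr.bh_adjust([0.5, 1.2])


class TestRelativeRisk:
    def test_equal_risks(self):
        res = pr.relative_risk(10, 90, 10, 90)
        assert res.rr == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_hand_example(self):
        res = pr.relative_risk(10, 90, 20, 80)
        assert res.rr == pytest.approx(0.5)
        se = np.sqrt(1 / 10 - 1 / 100 + 1 / 20 - 1 / 100)
        assert res.ci_low == pytest.approx(0.5 * np.exp(-1.959963985 * se), rel=1e-6)
        assert res.ci_high == pytest.approx(0.5 * np.exp(1.959963985 * se), rel=1e-6)

    def test_group_swap_inverts(self):
        res = pr.relative_risk(7, 44, 46, 137)
        swapped = pr.relative_risk(46, 137, 7, 44)
        assert swapped.rr == pytest.approx(1.0 / res.rr)
        assert swapped.ci_low == pytest.approx(1.0 / res.ci_high)
        assert swapped.ci_high == pytest.approx(1.0 / res.ci_low)
        assert swapped.p_fisher == pytest.approx(res.p_fisher)

    def test_zero_reference_events_flagged(self):
        res = pr.relative_risk(3, 47, 0, 50)
        assert np.isinf(res.rr)
        assert np.isnan(res.ci_low)


def random_survival(rng, n=60):
    t = rng.exponential(5.0, n)
    c = rng.uniform(0, 8.0, n)
    return np.minimum(t, c) + 1e-9, t <= c


class TestKaplanMeierLogRank:
    def test_no_events_survival_one(self):
        tl, s = pr.km_estimate([1.0, 2.0, 3.0], [False, False, False])
        assert np.allclose(s, 1.0)

    def test_no_censoring_is_one_minus_ecdf(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        tl, s = pr.km_estimate(t, np.ones(5, bool))
        np.testing.assert_allclose(s, 1.0 - np.arange(1, 6) / 5.0)

    def test_matches_lifelines_on_random_censored_data(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            t, e = random_survival(rng)
            tl, s = pr.km_estimate(t, e)
            kmf = KaplanMeierFitter().fit(t, e)
            ref = kmf.survival_function_at_times(tl).to_numpy()
            np.testing.assert_allclose(s, ref, atol=1e-8)

    def test_logrank_matches_lifelines(self):
        rng = np.random.default_rng(78)
        for _ in range(100):
            t1, e1 = random_survival(rng, 40)
            t2, e2 = random_survival(rng, 55)
            t = np.concatenate([t1, t2])
            e = np.concatenate([e1, e2])
            g = np.array(["a"] * 40 + ["b"] * 55)
            chi2, p = pr.log_rank(t, e, g)
            ref = logrank_test(t1, t2, e1, e2)
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_logrank_null_calibration(self):
        """Equal exponential hazards: rejection near the nominal 5%."""
        rng = np.random.default_rng(79)
        rej = 0
        reps = 500
        for _ in range(reps):
            t, e = random_survival(rng, 80)
            g = np.where(rng.random(80) < 0.5, "a", "b")
            if len(np.unique(g)) < 2 or not e.any():
                continue
            _, p = pr.log_rank(t, e, g)
            rej += p < 0.05
        assert abs(rej / reps - 0.05) <= 0.02

    def test_no_events_flagged(self):
        chi2, p = pr.log_rank([1.0, 2.0], [False, False], ["a", "b"])
        assert np.isnan(chi2) and np.isnan(p)


class TestStratifiedRates:
    def test_all_responder_stratum(self):
        out = pr.stratified_remission_rates([1.0, 1.5], [True, True], [0, 2, 4])
        assert out.loc[0, "proportion"] == 1.0
        assert out.loc[1, "n"] == 0

    def test_wilson_interval_50_50(self):
        vals = np.concatenate([np.full(50, 0.5), np.full(50, 0.6)])
        resp = np.array([True] * 50 + [False] * 50)
        out = pr.stratified_remission_rates(vals, resp, [0.0, 1.0])
        assert out.loc[0, "proportion"] == 0.5
        assert out.loc[0, "ci_low"] == pytest.approx(0.404, abs=0.005)
        assert out.loc[0, "ci_high"] == pytest.approx(0.596, abs=0.005)

    def test_half_open_bin_convention(self):
        out = pr.stratified_remission_rates([1.0], [True], [0.0, 1.0, 2.0])
        assert out.loc[1, "n"] == 1  # boundary value goes to the upper bin
        assert out.loc[0, "n"] == 0


class TestImputation:
    def phenotype_frame(self, rng, n=150):
        liver = rng.normal(7, 2, n)
        vat = 2 + 0.3 * liver + rng.normal(0, 0.5, n)
        scat = 12 + 0.5 * vat + rng.normal(0, 1.0, n)
        return pd.DataFrame({"liver_fat_pct": liver, "vat_l": vat, "scat_l": scat})

    def test_no_missing_is_identity(self):
        df = self.phenotype_frame(np.random.default_rng(1))
        out = pr.impute_missing(df, ["vat_l"], m=3, seed=0)
        assert len(out) == 3
        for c in out:
            pd.testing.assert_frame_equal(c, df)

    def test_mcar_masking_recovers_means(self):
        """10% MCAR missingness: pooled mean within 1 SE of the complete-data
        mean."""
        rng = np.random.default_rng(4)
        df = self.phenotype_frame(rng)
        full_mean = df["vat_l"].mean()
        se = df["vat_l"].std() / np.sqrt(len(df))
        masked = df.copy()
        idx = rng.choice(len(df), size=15, replace=False)
        masked.loc[idx, "vat_l"] = np.nan
        completed = pr.impute_missing(masked, ["vat_l"], m=5, seed=11)
        pooled = np.mean([c["vat_l"].mean() for c in completed])
        assert abs(pooled - full_mean) <= se
        # observed entries are untouched
        keep = masked["vat_l"].notna()
        for c in completed:
            np.testing.assert_allclose(c.loc[keep, "vat_l"], df.loc[keep, "vat_l"])

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        df = self.phenotype_frame(rng)
        df.loc[:10, "vat_l"] = np.nan
        a = pr.impute_missing(df, ["vat_l"], m=2, seed=5)
        b = pr.impute_missing(df, ["vat_l"], m=2, seed=5)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_fully_missing_rejected(self):
        df = self.phenotype_frame(np.random.default_rng(1))
        df["vat_l"] = np.nan
        with pytest.raises(ValueError):
            pr.impute_missing(df, ["vat_l"])


class TestRubinPooling:
    def test_single_imputation_reduces_to_estimate(self):
        out = pr.pool_rubin([2.0], [0.25])
        assert out["estimate"] == 2.0
        assert out["se"] == pytest.approx(0.5)

    def test_between_variance_widens_interval(self):
        narrow = pr.pool_rubin([2.0, 2.0, 2.0], [0.25, 0.25, 0.25])
        wide = pr.pool_rubin([1.0, 2.0, 3.0], [0.25, 0.25, 0.25])
        assert wide["se"] > narrow["se"]
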