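"""Reliability (ICC), change models, stepwise AIC and exploratory contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pvskit import (
    CohortSimSpec,
    experience_correlations,
    fit_change_model,
    group_contrasts,
    icc3k,
    prepost_delta,
    reliability_gate,
    run_sans_contrast,
    simulate_cohort,
    stepwise_aic,
)
from pvskit.stats import gaussian_aic, metric_wide

from conftest import icc3k_oracle


class TestICC:
    def test_perfect_reliability(self):
        x = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0], "s2": [1.0, 2.0, 3.0, 4.0]})
        assert icc3k(x).icc3k == pytest.approx(1.0)

    def test_constructed_table_matches_hand_oracle(self):
        x = pd.DataFrame(
            {"s1": [9.0, 6.0, 8.0, 7.0], "s2": [10.0, 5.0, 9.0, 6.0]}
        )
        got = icc3k(x).icc3k
        assert got == pytest.approx(icc3k_oracle(x.to_numpy()), abs=1e-12)

    @pytest.mark.parametrize("n,k", [(4, 2), (6, 3), (10, 6), (5, 4)])
    def test_random_tables_match_oracle(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        x = pd.DataFrame(rng.normal(10, 3, (n, k)))
        assert icc3k(x).icc3k == pytest.approx(icc3k_oracle(x.to_numpy()), abs=1e-12)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(99)
        n, k = 12, 4
        x = rng.normal(0, 1, (n, k)) + rng.normal(0, 2, (n, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "session": np.tile(np.arange(k), n),
                "y": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            data=long, targets="subject", raters="session", ratings="y"
        )
        sel = ref["Type"].isin(["ICC3k", "ICC(C,k)"])
        ref3k = float(ref.loc[sel, "ICC"].iloc[0])
        got = icc3k(pd.DataFrame(x)).icc3k
        assert got == pytest.approx(ref3k, abs=1e-9)

    def test_pure_noise_icc_near_zero(self):
        # with k = 2 a single null table has sd(ICC) ~ 0.14, so test the
        # null expectation over replicates
        rng = np.random.default_rng(7)
        vals = [
            icc3k(pd.DataFrame(rng.normal(0, 1, (200, 2)))).icc3k
            for _ in range(12)
        ]
        assert abs(np.mean(vals)) < 0.1
        assert all(abs(v) < 0.5 for v in vals)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc3k(pd.DataFrame({"a": [1.0], "b": [2.0]}))

    def test_gate_excludes_unreliable_metric_in_either_cohort(self):
        spec = CohortSimSpec(seed=12)
        spec.metric_params = {
            "good": (10.0, 3.0, 0.3),
            "bad": (10.0, 0.1, 3.0),  # session noise swamps subjects
        }
        spec.group_effects = {"novice": {}, "experienced": {}}
        table = simulate_cohort(spec)
        report, retained, excluded = reliability_gate(table, ["good", "bad"])
        assert retained == ["good"]
        assert excluded == ["bad"]
        assert not report.loc[report["metric"] == "bad", "retained"].iloc[0]


class TestPrepostDelta:
    @pytest.fixture
    def table(self):
        rows = []
        for sid, vals in [
            ("A1", {"L-180": 1.5, "L-60": 2.0, "R+4": 2.5}),
            ("A2", {"L-180": 1.8, "R+4": 2.0}),  # missing primary baseline
            ("A3", {"L-180": 1.0, "L-60": 1.2}),  # missing post
        ]:
            for sess, v in vals.items():
                rows.append(
                    {
                        "subject_id": sid, "cohort": "astronaut",
                        "group": "novice", "sans": "unknown", "session": sess,
                        "m": v, "sex": "M", "age_at_launch_yr": 45.0,
                        "mission_duration_d": 180.0,
                        "days_landing_to_scan_d": 4.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_primary_baseline(self, table):
        delta, _ = prepost_delta(table, "m")
        assert delta.set_index("subject_id").loc["A1", "delta"] == pytest.approx(0.5)

    def test_fallback_baseline(self, table):
        delta, log = prepost_delta(table, "m")
        row = delta.set_index("subject_id").loc["A2"]
        assert row["delta"] == pytest.approx(0.2)
        assert row["baseline_fallback"]
        assert any("fallback" in e["reason"] for e in log)

    def test_missing_post_dropped_and_logged(self, table):
        delta, log = prepost_delta(table, "m")
        assert "A3" not in set(delta["subject_id"])
        assert any(e["subject_id"] == "A3" and "R+4" in e["reason"] for e in log)


def _delta_frame(values, groups=None, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    n = len(values)
    groups = groups or ["novice"] * n
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "delta": values,
            "group": groups,
            "sans": rng.permutation(["SANS", "no-SANS"] * (n // 2 + 1))[:n],
            "sex": rng.permutation(["M", "F"] * (n // 2 + 1))[:n],
            "age_at_launch_yr": rng.normal(47, 6, n),
            "mission_duration_d": rng.normal(190, 50, n),
            "days_landing_to_scan_d": rng.normal(4.5, 1, n),
        }
    )


class TestChangeModel:
    def test_degenerate_constant_outcome(self):
        d = _delta_frame([1.0, 1.0, 1.0, 1.0])
        res = fit_change_model(d)
        assert res.coef_table.loc["const", "estimate"] == pytest.approx(1.0)
        assert res.coef_table.loc["const", "se"] == pytest.approx(0.0, abs=1e-12)

    def test_intercept_only_equals_one_sample_t(self):
        rng = np.random.default_rng(20)
        vals = rng.normal(0.16, 0.06, 15)
        res = fit_change_model(_delta_frame(list(vals)))
        t, p = sps.ttest_1samp(vals, 0.0)
        assert res.coef_table.loc["const", "t"] == pytest.approx(t, abs=1e-10)
        assert res.coef_table.loc["const", "p"] == pytest.approx(p, abs=1e-10)

    def test_orthogonal_predictor_near_zero(self):
        rng = np.random.default_rng(21)
        n = 40
        d = _delta_frame(list(rng.normal(1.0, 0.5, n)))
        d["noise_cov"] = rng.normal(0, 1, n)
        res = fit_change_model(d, predictors=["noise_cov"])
        assert abs(res.coef_table.loc["noise_cov", "estimate"]) < 0.3
        assert res.coef_table.loc["const", "estimate"] == pytest.approx(
            d["delta"].mean(), abs=0.05
        )

    def test_group_coefficient_recovery_within_2se(self):
        # parameter recovery across replicates at the study's group structure
        hits = 0
        R = 60
        for rep in range(R):
            rng = np.random.default_rng(1000 + rep)
            groups = ["novice"] * 9 + ["experienced"] * 6
            truth = 0.16
            vals = [
                (truth if g == "novice" else 0.0) + rng.normal(0, 0.11)
                for g in groups
            ]
            d = _delta_frame(vals, groups=groups, rng_seed=rep)
            res = fit_change_model(d, predictors=["group"])
            est = res.coef_table.loc["novice", "estimate"]
            se = res.coef_table.loc["novice", "se"]
            if abs(est - truth) <= 2 * se:
                hits += 1
        assert hits / R >= 0.85

    def test_rank_deficient_design_rejected(self):
        d = _delta_frame(list(np.random.default_rng(3).normal(size=10)))
        d["dup"] = d["age_at_launch_yr"]
        with pytest.raises(ValueError, match="rank"):
            fit_change_model(d, predictors=["age_at_launch_yr", "dup"])


class TestStepwiseAIC:
    def test_aic_closed_form_on_small_dataset(self):
        y = np.array([1.0, 2.0, 2.5, 3.5, 5.0])
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ beta) ** 2).sum())
        assert gaussian_aic(rss, 5, 2) == pytest.approx(
            5 * math.log(rss / 5) + 4, abs=1e-12
        )

    def test_strong_predictor_retained(self):
        rng = np.random.default_rng(30)
        n = 100
        x = rng.normal(0, 1, n)
        d = _delta_frame(list(2.0 * x + rng.normal(0, 1, n)), rng_seed=30)
        d["signal"] = x
        for j in range(4):
            d[f"junk{j}"] = rng.normal(0, 1, n)
        res = stepwise_aic(
            d, predictors=["signal", "junk0", "junk1", "junk2", "junk3"]
        )
        assert "signal" in res.predictors

    def test_all_noise_mostly_intercept_only(self):
        kept = 0
        R = 50
        for rep in range(R):
            rng = np.random.default_rng(4000 + rep)
            n = 100
            d = _delta_frame(list(rng.normal(0, 1, n)), rng_seed=rep)
            for j in range(4):
                d[f"junk{j}"] = rng.normal(0, 1, n)
            res = stepwise_aic(d, predictors=[f"junk{j}" for j in range(4)])
            if res.predictors == []:
                kept += 1
        assert kept / R > 0.5

    def test_final_aic_never_worse_than_endpoints(self):
        rng = np.random.default_rng(31)
        n = 30
        d = _delta_frame(list(rng.normal(0, 1, n)), rng_seed=31)
        d["x1"] = rng.normal(0, 1, n)
        d["x2"] = d["delta"] * 0.5 + rng.normal(0, 1, n)
        res = stepwise_aic(d, predictors=["x1", "x2"])
        aics = dict(res.aic_trace)
        full = aics[tuple(sorted(["x1", "x2"]))]
        final = res.aic_trace[-1][1]
        intercept_only = stepwise_aic(d, predictors=[]).aic_trace[-1][1]
        assert final <= full + 1e-9
        assert final <= intercept_only + 1e-9

    def test_trace_is_monotone_decreasing(self):
        rng = np.random.default_rng(32)
        n = 40
        d = _delta_frame(list(rng.normal(0, 1, n)), rng_seed=32)
        for j in range(3):
            d[f"x{j}"] = rng.normal(0, 1, n)
        res = stepwise_aic(d, predictors=["x0", "x1", "x2"])
        aic_vals = [a for _, a in res.aic_trace]
        assert all(b < a + 1e-12 for a, b in zip(aic_vals, aic_vals[1:]))


class TestCorrelations:
    def _table(self, y_fn, n=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            days = float(50 + 60 * i)
            age = float(rng.normal(52, 4))
            y = y_fn(days, age, rng)
            for sess in ("L-180", "L-60"):
                rows.append(
                    {
                        "subject_id": f"E{i}", "cohort": "astronaut",
                        "group": "experienced", "session": sess, "m": y,
                        "prior_flight_days_d": days, "age_at_launch_yr": age,
                    }
                )
        return pd.DataFrame(rows)

    def test_perfect_linear_relation(self):
        t = self._table(lambda d, a, r: 0.01 * d + 1.0)
        rep = experience_correlations(t, "m")
        assert rep.r == pytest.approx(1.0)
        assert rep.df == 4

    def test_null_relation_large_n(self):
        t = self._table(lambda d, a, r: r.normal(), n=1000, seed=5)
        rep = experience_correlations(t, "m")
        assert abs(rep.r) < 0.1

    def test_degenerate_partial_flagged(self):
        t = self._table(lambda d, a, r: a)  # metric IS age
        rep = experience_correlations(t, "m")
        assert math.isnan(rep.partial_r) or abs(rep.partial_r) < 1e-6

    def test_partial_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        t = self._table(lambda d, a, r: 0.005 * d + 0.05 * a + r.normal(0, 0.3), n=12, seed=9)
        rep = experience_correlations(t, "m")
        per = t.groupby("subject_id").first()
        base = t.groupby("subject_id")["m"].mean()
        df = pd.DataFrame(
            {
                "x": per["prior_flight_days_d"],
                "y": base,
                "z": per["age_at_launch_yr"],
            }
        )
        ref = pg.partial_corr(data=df, x="x", y="y", covar="z")
        assert rep.partial_r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)

    def test_too_few_subjects_rejected(self):
        t = self._table(lambda d, a, r: 1.0, n=2)
        with pytest.raises(ValueError):
            experience_correlations(t, "m")


class TestGroupContrasts:
    def _table(self, ages_a, ages_b, sex_a, sex_b):
        rows = []
        for i, (age, sex) in enumerate(zip(ages_a, sex_a)):
            rows.append(
                {"subject_id": f"N{i}", "group": "novice", "sex": sex,
                 "age_at_launch_yr": age, "mission_duration_d": 180.0,
                 "days_landing_to_scan_d": 4.0}
            )
        for i, (age, sex) in enumerate(zip(ages_b, sex_b)):
            rows.append(
                {"subject_id": f"E{i}", "group": "experienced", "sex": sex,
                 "age_at_launch_yr": age, "mission_duration_d": 181.0,
                 "days_landing_to_scan_d": 4.0}
            )
        return pd.DataFrame(rows)

    def test_identical_groups_t_zero(self):
        ages = [40.0, 45.0, 50.0, 55.0]
        t = self._table(ages, ages, "MMFF", "MMFF")
        out = {c.variable: c for c in group_contrasts(t)}
        assert out["age_at_launch_yr"].statistic == pytest.approx(0.0, abs=1e-12)
        assert out["age_at_launch_yr"].p == pytest.approx(1.0)

    def test_identical_sex_split_chi2_zero(self):
        t = self._table([40, 45, 50, 55], [41, 46, 51, 56], "MMFF", "MMFF")
        out = {c.variable: c for c in group_contrasts(t)}
        assert out["sex"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_chi2_matches_hand_oracle(self):
        # 2x2 counts: novice 5M/5F, experienced 8M/2F
        t = self._table(
            list(np.linspace(40, 50, 10)), list(np.linspace(45, 55, 10)),
            "M" * 5 + "F" * 5, "M" * 8 + "F" * 2,
        )
        out = {c.variable: c for c in group_contrasts(t)}
        obs = np.array([[5, 5], [8, 2]], dtype=float)
        row, col, tot = obs.sum(1), obs.sum(0), obs.sum()
        exp = np.outer(row, col) / tot
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert out["sex"].statistic == pytest.approx(chi2, abs=1e-10)


class TestSANSContrast:
    def test_null_effect_near_zero(self):
        rng = np.random.default_rng(40)
        n = 40
        d = _delta_frame(list(rng.normal(0.0, 0.1, n)), rng_seed=40)
        res = run_sans_contrast(d)
        assert abs(res.coef_table.loc["sans_pos", "estimate"]) < 0.08

    def test_permutation_attenuates_real_effect(self):
        rng = np.random.default_rng(41)
        n = 60
        sans = ["SANS"] * (n // 2) + ["no-SANS"] * (n // 2)
        vals = [(0.5 if s == "SANS" else 0.0) + rng.normal(0, 0.1) for s in sans]
        d = _delta_frame(vals, rng_seed=41)
        d["sans"] = sans
        real = abs(run_sans_contrast(d).coef_table.loc["sans_pos", "estimate"])
        perm_estimates = []
        for rep in range(20):
            dp = d.copy()
            dp["sans"] = np.random.default_rng(rep).permutation(sans)
            perm_estimates.append(
                abs(run_sans_contrast(dp).coef_table.loc["sans_pos", "estimate"])
            )
        assert real > np.percentile(perm_estimates, 95)

    def test_unknown_sans_excluded(self):
        rng = np.random.default_rng(42)
        d = _delta_frame(list(rng.normal(0, 0.1, 12)), rng_seed=42)
        d.loc[:2, "sans"] = "unknown"
        res = run_sans_contrast(d)
        assert res.n == 9

    def test_single_level_rejected(self):
        d = _delta_frame(list(np.random.default_rng(2).normal(size=8)), rng_seed=2)
        d["sans"] = "SANS"
        with pytest.raises(ValueError):
            run_sans_contrast(d)


class TestMetricWide:
    def test_pivot_layout(self):
        table = simulate_cohort(CohortSimSpec(seed=1))
        ast = table[table["cohort"] == "astronaut"]
        wide = metric_wide(ast, "norm_total_pvs_volume", ["L-180", "L-60"])
        assert wide.shape == (15, 2)
        assert list(wide.columns) == ["L-180", "L-60"]
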