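import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from schemasim import stats as st


def _balanced(n_participants=8, effect_c=2.0, effect_d=1.0, noise=1.0,
              participant_sd=0.0, seed=0, interaction=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        offset = rng.normal(0, participant_sd)
        for c in ("c1", "c2"):
            for d in ("d1", "d2"):
                mu = 5 + effect_c * (c == "c1") + effect_d * (d == "d1")
                mu += interaction * ((c == "c1") and (d == "d1"))
                rows.append({
                    "participant": f"p{p:02d}",
                    "group": "A" if p < n_participants // 2 else "B",
                    "c": c, "d": d,
                    "y": mu + offset + rng.normal(0, noise),
                })
    return pd.DataFrame(rows)


SPEC = st.ModelSpec(response="y", factors=["c", "d"], group_slopes=False)


class TestFactorCoding:
    def test_sum_coding_columns(self):
        df = _balanced(2)
        coding = st.FactorCoding(df, ["c", "d"])
        X = coding.encode(df)
        assert X.shape[1] == 4  # intercept + c + d + c:d
        # sum coding: each main-effect column sums to zero under balance
        assert np.allclose(X[:, 1:].sum(axis=0), 0)
        assert set(coding.terms) == {"c", "d", "c:d"}

    def test_single_level_factor_rejected(self):
        df = _balanced(2).assign(c="c1")
        with pytest.raises(ValueError, match="single level"):
            st.FactorCoding(df, ["c", "d"])

    def test_unknown_level_rejected(self):
        df = _balanced(2)
        coding = st.FactorCoding(df, ["c", "d"])
        with pytest.raises(ValueError, match="unknown level"):
            coding.cell_row({"c": "zzz", "d": "d1"})


class TestFitMixedModel:
    def test_zero_random_variance_matches_anova_oracle(self):
        # large fixed effect, no participant variance: mixed F within 1% of
        # the ordinary one-way ANOVA F on the same factor
        rng = np.random.default_rng(1)
        rows = []
        for p in range(20):
            for c in ("c1", "c2"):
                for _ in range(3):
                    rows.append({"participant": f"p{p:03d}", "c": c,
                                 "y": 3.0 * (c == "c1") + rng.normal(0, 1)})
        df = pd.DataFrame(rows)
        res = st.fit_mixed_model(
            df, st.ModelSpec(response="y", factors=["c"], group_slopes=False)
        )
        F_mixed = res.anova.set_index("term").loc["c", "F"]
        g1 = df[df.c == "c1"]["y"]
        g2 = df[df.c == "c2"]["y"]
        F_oracle, _ = sp_stats.f_oneway(g1, g2)
        assert F_mixed == pytest.approx(F_oracle, rel=0.01)

    def test_constant_response_all_F_zero(self):
        df = _balanced(6, effect_c=0, effect_d=0, noise=0)
        df["y"] = 4.0
        res = st.fit_mixed_model(df, SPEC)
        assert (res.anova["F"] == 0.0).all()
        assert "OLS" in res.random_structure

    def test_missing_response_rejected(self):
        with pytest.raises(ValueError, match="response"):
            st.fit_mixed_model(_balanced(4), st.ModelSpec(response="zz", factors=["c", "d"]))

    def test_sqrt_transform_applied(self):
        df = _balanced(6, noise=0.1)
        df["y"] = df["y"].abs()
        spec = st.ModelSpec(response="y", factors=["c", "d"], transform="sqrt",
                            group_slopes=False)
        res = st.fit_mixed_model(df, spec)
        raw_mean = np.sqrt(df["y"]).mean()
        assert res.fitted.mean() == pytest.approx(raw_mean, rel=0.05)

    def test_sqrt_requires_nonnegative(self):
        df = _balanced(4)
        df.loc[0, "y"] = -10.0
        spec = st.ModelSpec(response="y", factors=["c", "d"], transform="sqrt",
                            group_slopes=False)
        with pytest.raises(ValueError, match="non-negative"):
            st.fit_mixed_model(df, spec)

    def test_power_against_generating_model(self):
        # with a known interaction and known noise, the rejection rate over
        # seeds tracks the analytic power of the balanced design
        n_rej = 0
        n_sims = 60
        effect, noise, n_part = 1.2, 1.0, 10
        for s in range(n_sims):
            df = _balanced(n_part, effect_c=0, effect_d=0, noise=noise,
                           interaction=effect, seed=100 + s)
            res = st.fit_mixed_model(df, SPEC)
            p = res.anova.set_index("term").loc["c:d", "p"]
            n_rej += p < 0.05
        # analytic power: interaction contrast = effect/4 per cell coding,
        # F(1, n-4) noncentrality lambda = n_obs * (effect/4)^2 / noise^2
        lam = 4 * n_part * (effect / 4) ** 2 / noise**2
        df_den = 4 * n_part - 4
        crit = sp_stats.f.ppf(0.95, 1, df_den)
        power = 1 - sp_stats.ncf.cdf(crit, 1, df_den, lam)
        se = np.sqrt(power * (1 - power) / n_sims)
        assert abs(n_rej / n_sims - power) < 4 * se + 0.02


class TestAssumptionChecks:
    def test_normal_homoskedastic_no_recommendations(self):
        df = _balanced(10, noise=1.0, seed=4)
        res = st.fit_mixed_model(df, SPEC)
        checks = st.assumption_checks(res)
        assert checks["normality"] == "normal"
        assert checks["heteroskedasticity"] == "homoskedastic"
        assert not checks["recommend_sqrt"] and not checks["recommend_weights"]

    def test_4x_variance_detected(self):
        rng = np.random.default_rng(4)
        rows = []
        for p in range(12):
            for c in ("c1", "c2"):
                for i in range(6):
                    rows.append({"participant": f"p{p}", "c": c,
                                 "d": "d1" if i % 2 else "d2",
                                 "y": rng.normal(0, 4.0 if c == "c1" else 1.0)})
        df = pd.DataFrame(rows)
        spec = st.ModelSpec(response="y", factors=["c", "d"], weight_by=["c"],
                            group_slopes=False)
        res = st.fit_mixed_model(df, spec)
        checks = st.assumption_checks(res)
        assert checks["heteroskedasticity"] == "heteroskedastic"
        assert checks["recommend_weights"]

    def test_skewed_response_triggers_sqrt_and_reduces_skew(self):
        rng = np.random.default_rng(5)
        df = _balanced(10, effect_c=0, effect_d=0, noise=0)
        df["y"] = rng.exponential(2.0, len(df)) ** 2  # strongly right-skewed
        spec = st.ModelSpec(response="y", factors=["c", "d"], group_slopes=False)
        result, log = st.run_model_with_checks(df, spec)
        steps = [l["step"] for l in log]
        assert "sqrt refit" in steps
        assert result.spec.transform == "sqrt"
        skew_before = sp_stats.skew(df["y"])
        skew_after = sp_stats.skew(np.sqrt(df["y"]))
        assert abs(skew_after) < abs(skew_before)

    def test_weight_refit_records_weights(self):
        rng = np.random.default_rng(6)
        rows = []
        for p in range(12):
            for c in ("c1", "c2"):
                for i in range(6):
                    rows.append({"participant": f"p{p}", "c": c,
                                 "d": "d1" if i % 2 else "d2",
                                 "y": 10 + rng.normal(0, 4.0 if c == "c1" else 1.0)})
        df = pd.DataFrame(rows)
        spec = st.ModelSpec(response="y", factors=["c", "d"], weight_by=["c"],
                            group_slopes=False)
        result, log = st.run_model_with_checks(df, spec)
        assert result.weights is not None
        assert any(l["step"] == "variance-weight refit" for l in log)


class TestEmmeans:
    def test_unbalanced_hand_example(self):
        # cells (a,x): {1,3}; (a,y): {10} -> EMM(a) = (2 + 10)/2 = 6.0,
        # whereas the raw mean of the a rows is 14/3 = 4.667
        df = pd.DataFrame({
            "participant": [f"p{i}" for i in range(7)],
            "f1": ["a", "a", "a", "b", "b", "b", "b"],
            "f2": ["x", "x", "y", "x", "y", "x", "y"],
            "y": [1.0, 3.0, 10.0, 2.0, 4.0, 2.0, 4.0],
        })
        res = st.fit_mixed_model(
            df, st.ModelSpec(response="y", factors=["f1", "f2"], group_slopes=False)
        )
        emm = st.emmeans(res, ["f1"]).set_index("margin")
        assert emm.loc["a", "emmean"] == pytest.approx(6.0, abs=1e-5)
        assert df[df.f1 == "a"]["y"].mean() == pytest.approx(14 / 3)

    def test_balanced_emm_equals_raw_cell_means(self):
        df = _balanced(8, seed=7)
        res = st.fit_mixed_model(df, SPEC)
        emm = st.emmeans(res).set_index("margin")
        raw = df.groupby(["c", "d"])["y"].mean()
        for (c, d), mean in raw.items():
            assert emm.loc[f"{c}/{d}", "emmean"] == pytest.approx(mean, abs=1e-5)

    def test_constant_response_all_emms_equal(self):
        df = _balanced(5, effect_c=0, effect_d=0, noise=0)
        df["y"] = 3.14
        res = st.fit_mixed_model(df, SPEC)
        emm = st.emmeans(res)
        assert np.allclose(emm["emmean"], 3.14, atol=1e-6)

    def test_unknown_margin_rejected(self):
        res = st.fit_mixed_model(_balanced(4), SPEC)
        with pytest.raises(ValueError, match="unknown margin"):
            st.emmeans(res, ["nope"])


class TestContrasts:
    def test_identical_margins_zero_estimate(self):
        df = _balanced(6, effect_c=0.0, effect_d=2.0, noise=0.0, seed=8)
        df["y"] = df["y"].round(10)
        res = st.fit_mixed_model(df, SPEC)
        ct = st.pairwise_contrasts(res, ["c"]).iloc[0]
        assert ct["estimate"] == pytest.approx(0.0, abs=1e-6)

    def test_antisymmetry_via_emm_differences(self):
        df = _balanced(8, seed=9)
        res = st.fit_mixed_model(df, SPEC)
        emm = st.emmeans(res, ["c"]).set_index("margin")
        ct = st.pairwise_contrasts(res, ["c"]).iloc[0]
        diff = emm.loc["c1", "emmean"] - emm.loc["c2", "emmean"]
        assert ct["estimate"] == pytest.approx(diff, abs=1e-10)
        # A-B equals the exact negative of B-A by construction
        assert ct["estimate"] == pytest.approx(
            -(emm.loc["c2", "emmean"] - emm.loc["c1", "emmean"]), abs=1e-12
        )

    def test_known_mean_difference_recovered(self):
        diffs = []
        for s in range(15):
            df = _balanced(10, effect_c=1.5, noise=1.0, seed=200 + s)
            res = st.fit_mixed_model(df, SPEC)
            ct = st.pairwise_contrasts(res, ["c"]).iloc[0]
            diffs.append(ct["estimate"])
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - 1.5) < 4 * se + 0.01


class TestMorey:
    def test_pure_between_subject_offset_gives_zero_se(self):
        df = pd.DataFrame({
            "participant": ["p1"] * 4 + ["p2"] * 4,
            "cond": ["a", "b", "c", "d"] * 2,
            "v": [1.0, 2.0, 3.0, 4.0, 11.0, 12.0, 13.0, 14.0],
        })
        out = st.morey_sem(df, "participant", "cond", "v")
        assert np.allclose(out["sem"], 0.0, atol=1e-12)

    def test_hand_worked_two_by_two(self):
        # participants (1,3) and (2,6): centered rows (-1,1), (-2,2);
        # + grand mean 3 -> columns {2,1} and {4,5}; sd = [sqrt(0.5), sqrt(0.5)]
        # SE = sd/sqrt(2); Morey factor sqrt(2/1) -> sem = sqrt(0.5)/sqrt(2)*sqrt(2)
        df = pd.DataFrame({
            "participant": ["p1", "p1", "p2", "p2"],
            "cond": ["A", "B", "A", "B"],
            "v": [1.0, 3.0, 2.0, 6.0],
        })
        out = st.morey_sem(df, "participant", "cond", "v").set_index("condition")
        manual = np.sqrt(0.5) / np.sqrt(2) * np.sqrt(2 / 1)
        assert out.loc["A", "sem"] == pytest.approx(manual)
        assert out.loc["B", "sem"] == pytest.approx(manual)
        assert out.loc["A", "mean"] == pytest.approx(1.5)

    def test_single_condition_plain_se_with_warning(self):
        df = pd.DataFrame({
            "participant": ["p1", "p2", "p3"],
            "cond": ["A"] * 3,
            "v": [1.0, 2.0, 3.0],
        })
        with pytest.warns(UserWarning, match="Morey"):
            out = st.morey_sem(df, "participant", "cond", "v")
        assert out["sem"].iloc[0] == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))

    def test_incomplete_participants_dropped_and_logged(self):
        df = pd.DataFrame({
            "participant": ["p1", "p1", "p2"],
            "cond": ["A", "B", "A"],
            "v": [1.0, 2.0, 5.0],
        })
        out = st.morey_sem(df, "participant", "cond", "v")
        assert out.attrs["dropped_participants"] == ["p2"]
        assert (out["n"] == 1).all()
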