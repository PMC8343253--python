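"""Age groups, de-duplication, filters, velocities and contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import growthkit as gk
from growthkit.cohort_pipeline import PipelineError


class TestAgeGroups:
    @pytest.mark.parametrize("age,group", [
        (0.2, 0), (0.49, 0), (0.5, 1), (1.49, 1), (1.5, 2),
        (6.1, 6), (17.49, 17), (17.5, 18), (19.0, 18),
    ])
    def test_rounded_age_allocation(self, age, group):
        assert gk.assign_age_group(age) == group

    def test_negative_age_rejected(self):
        with pytest.raises(PipelineError):
            gk.assign_age_group(-0.1)


class TestDedup:
    def test_first_per_group_kept(self):
        obs = pd.DataFrame({
            "child_id": ["a", "a", "a", "b"],
            "age_years": [6.4, 6.1, 7.1, 6.4],
        })
        obs["age_group"] = gk.assign_age_group(obs["age_years"])
        out = gk.dedup_first_per_group(obs)
        a_rows = out[out.child_id == "a"]
        assert sorted(a_rows.age_years) == [6.1, 7.1]
        assert len(out) == 3

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        obs = pd.DataFrame({
            "child_id": rng.integers(0, 30, 200).astype(str),
            "age_years": rng.uniform(0.5, 17, 200),
        })
        obs["age_group"] = gk.assign_age_group(obs["age_years"])
        once = gk.dedup_first_per_group(obs)
        twice = gk.dedup_first_per_group(once)
        pd.testing.assert_frame_equal(once, twice)


class TestInclusionFilters:
    def _toy(self):
        children = pd.DataFrame({
            "child_id": [f"c{i}" for i in range(1, 10)],
            "sex": "male",
            "gestational_age_weeks": [40, 40, 40, 36, 40, 40, 40, 40, 40],
            "flags": ["", "", "", "", "disease", "medication",
                      "metformin", "thyroxin", ""],
        })
        obs = pd.DataFrame({
            "child_id": ["c1", "c2", "c3", "c4", "c4", "c5", "c6", "c7",
                         "c8", "c9"],
            "age_years": [5, 5, 5, 1.5, 2.0, 5, 5, 5, 5, 5],
            "height_sds": [4.2, -2.6, 0, 0, 0, 0, 0, 0, 0, 0.5],
            "bmi_sds": [0, 0, -3.6, 0, 0, 0, 0, 0, 0, 0.2],
        })
        analytes = pd.DataFrame({
            "child_id": ["c7", "c7", "c8"],
            "age_years": [5, 5, 5],
            "analyte": ["insulin", "igf1", "tsh"],
            "value": [60.0, 200.0, 2.0],
        })
        return children, obs, analytes

    def test_each_rule_fires_once(self):
        children, obs, analytes = self._toy()
        filtered, ana, log = gk.apply_inclusion_filters(
            children, obs, analytes=analytes)
        assert log["height_sds_above_max"] == 1
        assert log["height_sds_below_min"] == 1
        assert log["bmi_sds_below_min"] == 1
        assert log["premature_below_age_2"] == 1
        assert log["disease_flag"] == 1
        assert log["medication_flag"] == 1
        assert log["metformin_analyte_rows"] == 1
        assert log["thyroxin_analyte_rows"] == 1
        # survivors: c4@2.0 (premature boundary), c7, c8, c9
        assert sorted(filtered.child_id) == ["c4", "c7", "c8", "c9"]
        assert filtered.loc[filtered.child_id == "c4", "age_years"].item() == 2.0
        # metformin child keeps non-insulin analytes
        assert list(ana.analyte) == ["igf1"]

    def test_boundary_values_retained(self):
        children = pd.DataFrame({"child_id": ["a"], "sex": ["female"],
                                 "gestational_age_weeks": [40.0],
                                 "flags": [""]})
        obs = pd.DataFrame({"child_id": ["a", "a"], "age_years": [5, 6],
                            "height_sds": [4.0, -2.5],
                            "bmi_sds": [-3.5, 0.0]})
        filtered, log = gk.apply_inclusion_filters(children, obs)
        assert len(filtered) == 2 and log["observations_removed"] == 0

    def test_requires_sds_columns(self):
        children = pd.DataFrame({"child_id": ["a"], "sex": ["male"],
                                 "flags": [""]})
        obs = pd.DataFrame({"child_id": ["a"], "age_years": [5.0]})
        with pytest.raises(PipelineError, match="reference"):
            gk.apply_inclusion_filters(children, obs)

    def test_order_independence(self):
        children, obs, _ = self._toy()
        filtered, _ = gk.apply_inclusion_filters(children, obs)
        shuffled = obs.sample(frac=1, random_state=0)
        filtered2, _ = gk.apply_inclusion_filters(children, shuffled)
        assert sorted(zip(filtered.child_id, filtered.age_years)) == \
            sorted(zip(filtered2.child_id, filtered2.age_years))


class TestVelocities:
    def _obs(self, rows):
        df = pd.DataFrame(rows, columns=["child_id", "age_years",
                                         "height_cm"])
        df["weight_category"] = "normal"
        df["sex"] = "male"
        return df

    def test_basic_velocity_and_group(self, refs):
        obs = self._obs([("a", 4.0, 100.0), ("a", 5.0, 106.0)])
        vel, log = gk.compute_velocities(obs, refs[gk.VELOCITY])
        assert len(vel) == 1
        rec = vel.iloc[0]
        assert rec.gv == pytest.approx(6.0)
        assert rec.mean_age == pytest.approx(4.5)
        assert rec.age_group == 5
        assert rec.interval == pytest.approx(1.0)

    def test_each_plausibility_rule(self, refs):
        obs = self._obs([
            ("short", 4.0, 100.0), ("short", 4.1, 101.0),     # interval 0.1
            ("long", 4.0, 100.0), ("long", 6.8, 112.0),       # interval 2.8
            ("neg", 4.0, 100.0), ("neg", 5.0, 99.0),          # gv -1
            ("slow", 9.5, 130.0), ("slow", 10.5, 130.5),      # gv 0.5, <14 y
            ("fast", 5.0, 100.0), ("fast", 6.0, 120.0),       # gv sds > 10
            ("young", 0.8, 72.0), ("young", 1.6, 78.0),       # mean age 1.2
            ("ok", 4.0, 100.0), ("ok", 5.0, 106.0),
        ])
        vel, log = gk.compute_velocities(obs, refs[gk.VELOCITY])
        assert log["interval_too_short"] == 1
        assert log["interval_too_long"] == 1
        assert log["gv_negative"] == 1
        assert log["gv_below_1_under_14"] == 1
        assert log["gv_sds_above_10"] == 1
        assert log["mean_age_below_1_5"] == 1
        assert log["records_out"] == 1
        assert list(vel.child_id) == ["ok"]

    def test_slow_growth_allowed_after_14(self, refs):
        obs = self._obs([("a", 14.5, 170.0), ("a", 15.5, 170.5)])
        vel, _ = gk.compute_velocities(obs, refs[gk.VELOCITY])
        assert len(vel) == 1 and vel.iloc[0].gv == pytest.approx(0.5)

    def test_weight_category_rules(self, refs):
        obs = self._obs([("a", 4.0, 100.0), ("a", 5.0, 106.0),
                         ("a", 6.0, 112.0)])
        obs["weight_category"] = ["normal", "obese", "obese"]
        vel, _ = gk.compute_velocities(obs, refs[gk.VELOCITY])
        assert list(vel.weight_category) == ["normal", "obese"]
        cfg = gk.VelocityConfig(weight_rule="child-first")
        vel2, _ = gk.compute_velocities(obs, refs[gk.VELOCITY], cfg)
        assert list(vel2.weight_category) == ["normal", "normal"]

    def test_unsorted_input_rejected(self, refs):
        obs = self._obs([("a", 5.0, 106.0), ("a", 4.0, 100.0)])
        with pytest.raises(PipelineError, match="sorted"):
            gk.compute_velocities(obs, refs[gk.VELOCITY])

    def test_missing_reference_skips_sds_filter(self):
        obs = self._obs([("fast", 5.0, 100.0), ("fast", 6.0, 120.0)])
        vel, log = gk.compute_velocities(obs, None)
        assert not log["sds_filter_applied"]
        assert len(vel) == 1 and np.isnan(vel.iloc[0].gv_sds)


def _brute_force_holm_sidak(p):
    """Independent step-down enumeration oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, min(val, 1.0))
        adj[idx] = running
    return adj


class TestHolmSidak:
    def test_single_p_unchanged(self):
        assert gk.holm_sidak([0.01]) == pytest.approx([0.01])

    def test_hand_computed_example(self):
        out = gk.holm_sidak([0.01, 0.04, 0.03])
        assert out == pytest.approx([0.0297, 0.0591, 0.0591], abs=5e-5)

    def test_degenerate_zeroes(self):
        assert gk.holm_sidak([0.0, 0.0, 0.0]) == pytest.approx([0, 0, 0])

    def test_smallest_p_gets_full_family(self):
        p = [0.2, 0.01, 0.6, 0.35]
        out = gk.holm_sidak(p)
        assert out[1] == pytest.approx(1 - (1 - 0.01) ** 4)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    def test_brute_force_agreement(self, p):
        assert gk.holm_sidak(p) == pytest.approx(_brute_force_holm_sidak(p))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_adjusted_at_least_raw(self, p):
        out = gk.holm_sidak(p)
        assert np.all(out >= np.asarray(p) - 1e-12)
        assert np.all(out <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(PipelineError):
            gk.holm_sidak([0.5, 1.2])


class TestCompareGroups:
    def _data(self, rng, mean_a=0.0, mean_b=0.0, n=200, n_groups=10):
        frames = []
        for g in range(1, n_groups + 1):
            frames.append(pd.DataFrame({
                "age_group": g,
                "weight_category": ["obese"] * n + ["normal"] * n,
                "value": np.concatenate([rng.normal(mean_a, 1, n),
                                         rng.normal(mean_b, 1, n)]),
            }))
        return pd.concat(frames, ignore_index=True)

    def test_planted_difference_all_significant(self, rng):
        data = self._data(rng, mean_a=1.0, n=200)
        res = gk.compare_groups(data, "value", "obese", "normal")
        assert res.table.significant.all()
        assert res.table["diff"].mean() == pytest.approx(1.0, abs=0.1)

    def test_small_stratum_suppressed_and_out_of_family(self, rng):
        data = self._data(rng, n=30, n_groups=4)
        drop = data[(data.age_group == 2) & (data.weight_category == "obese")
                    ].index[5:]
        data = data.drop(drop)  # group 2 obese n=5 < 6
        res = gk.compare_groups(data, "value", "obese", "normal")
        tab = res.table.set_index("age_group")
        assert tab.loc[2, "suppressed"]
        assert np.isnan(tab.loc[2, "p_raw"])
        # family excludes the suppressed stratum
        fam = tab[~tab.suppressed]
        assert gk.holm_sidak(fam.p_raw.to_numpy()) == pytest.approx(
            fam.p_adj.to_numpy())

    def test_zero_variance_flagged(self):
        data = pd.DataFrame({
            "age_group": [1] * 12,
            "weight_category": ["obese"] * 6 + ["normal"] * 6,
            "value": [1.0] * 12,
        })
        res = gk.compare_groups(data, "value", "obese", "normal")
        row = res.table.iloc[0]
        assert row.degenerate and np.isnan(row.p_raw)
        assert row["diff"] == pytest.approx(0.0)

    def test_welch_type_one_error(self, rng):
        # H0: equal normal populations, n=30/30, 2000 replicates
        n_rep, n = 2000, 30
        a = rng.normal(0, 1, (n_rep, n))
        b = rng.normal(0, 1, (n_rep, n))
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.01)

    def test_label_swap_negates_difference(self, rng):
        data = self._data(rng, mean_a=0.5, n=50, n_groups=3)
        r1 = gk.compare_groups(data, "value", "obese", "normal")
        r2 = gk.compare_groups(data, "value", "normal", "obese")
        assert r1.table["diff"].to_numpy() == pytest.approx(
            -r2.table["diff"].to_numpy())
        assert r1.table.p_raw.to_numpy() == pytest.approx(
            r2.table.p_raw.to_numpy())


class TestMaxGroupDifference:
    def _result(self, groups, diffs, means_b=None):
        tab = pd.DataFrame({
            "age_group": groups, "diff": diffs,
            "mean_b": means_b if means_b is not None else 1.0,
            "suppressed": False,
        })
        tab["pct_diff"] = 100 * tab["diff"] / tab["mean_b"]
        return gk.ComparisonResult("x", "a", "b", tab)

    def test_argmax(self):
        res = self._result([5, 7, 9], [0.2, 1.4, 0.9])
        assert gk.max_group_difference(res, "absolute") == (7, 1.4)

    def test_tie_goes_to_youngest(self):
        res = self._result([5, 7, 9], [1.0, 1.0, 1.0])
        assert gk.max_group_difference(res, "absolute")[0] == 5

    def test_percent_metric(self):
        res = self._result([3], [10.0], means_b=[100.0])
        assert gk.max_group_difference(res, "percent") == (3, 10.0)

    def test_window_and_all_suppressed(self):
        res = self._result([5, 7, 9], [0.2, 1.4, 0.9])
        assert gk.max_group_difference(res, "absolute", window=(8, 10)) == \
            (9, 0.9)
        res.table["suppressed"] = True
        with pytest.raises(PipelineError):
            gk.max_group_difference(res, "absolute")
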