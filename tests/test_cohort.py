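"""Breath-gas pipeline: normalization, fences, classification, comparisons."""

import numpy as np
import pandas as pd
import pytest

from butyrogen import (
    classify_methanogenic,
    compare_mg_groups,
    normalize_breath,
    subject_period_means,
    tukey_exclude,
)
from butyrogen.cohort import period_contrast


def breath_frame(rows):
    """rows: (subject, period, h2, ch4, co2[, semester])"""
    recs = []
    for r in rows:
        semester = r[5] if len(r) > 5 else "S1"
        recs.append({"subject": r[0], "period": r[1], "h2_ppm": r[2],
                     "ch4_ppm": r[3], "co2_pct": r[4], "semester": semester})
    return pd.DataFrame(recs)


class TestNormalizeBreath:
    def test_nominal_co2_is_identity(self):
        df = normalize_breath(breath_frame([("a", "before", 10.0, 8.0, 3.5)]))
        assert df["ch4_norm_ppm"].iloc[0] == pytest.approx(8.0)
        assert df["h2_norm_ppm"].iloc[0] == pytest.approx(10.0)

    def test_dilute_sample_scaled_up_and_rich_scaled_down(self):
        df = normalize_breath(breath_frame([("a", "before", 10.0, 8.0, 7.0),
                                            ("a", "before", 10.0, 8.0, 1.75)]))
        assert df["ch4_norm_ppm"].tolist() == pytest.approx([4.0, 16.0])

    def test_zero_gas_stays_zero(self):
        df = normalize_breath(breath_frame([("a", "before", 0.0, 0.0, 5.1)]))
        assert df["h2_norm_ppm"].iloc[0] == 0.0

    def test_doubling_co2_halves_normalized(self):
        df = normalize_breath(breath_frame([("a", "before", 12.0, 6.0, 2.0),
                                            ("a", "before", 12.0, 6.0, 4.0)]))
        assert df["h2_norm_ppm"].iloc[1] == pytest.approx(df["h2_norm_ppm"].iloc[0] / 2)

    def test_nonpositive_co2_rejected(self):
        with pytest.raises(ValueError, match="CO2"):
            normalize_breath(breath_frame([("a", "before", 10.0, 8.0, 0.0)]))


def brute_force_fences(values, k=3.0):
    """Independent quartile + fence computation (hand-coded interpolation)."""
    s = np.sort(np.asarray(values, float))
    n = len(s)

    def quantile(q):
        pos = q * (n - 1)
        lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        return s[lo] * (1 - frac) + s[hi] * frac

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


class TestTukeyExclude:
    def test_single_gross_outlier(self):
        res = tukey_exclude([1, 2, 3, 4, 5, 100])
        assert res.excluded.tolist() == [False] * 5 + [True]
        assert res.kept.tolist() == [1, 2, 3, 4, 5]

    def test_constant_series_keeps_everything(self):
        res = tukey_exclude([7.0] * 10)
        assert not res.excluded.any()

    def test_uniform_data_never_excluded_at_k3(self, rng):
        res = tukey_exclude(rng.uniform(0, 1, 500))
        assert not res.excluded.any()

    def test_empty_rejected_and_small_warned(self):
        with pytest.raises(ValueError):
            tukey_exclude([])
        with pytest.warns(UserWarning, match="weakly"):
            tukey_exclude([1.0, 2.0])

    def test_matches_brute_force_on_random_samples(self, rng):
        for _ in range(1000):
            n = rng.integers(4, 30)
            vals = rng.normal(0, 1, n) * rng.uniform(0.1, 10)
            if rng.random() < 0.3:
                vals[0] += 50  # inject an occasional gross outlier
            lo, hi = brute_force_fences(vals)
            res = tukey_exclude(vals)
            expected = (vals < lo) | (vals > hi)
            assert np.array_equal(res.excluded, expected)
            assert res.lower_fence == pytest.approx(lo)
            assert res.upper_fence == pytest.approx(hi)


class TestClassifyMethanogenic:
    def test_single_exceedance_makes_mg(self):
        df = breath_frame([("a", "before", 0, 2.0, 3.5),
                           ("a", "before", 0, 5.0, 3.5),
                           ("a", "before", 0, 3.0, 3.5)])
        out = classify_methanogenic(df)
        assert out["status"].iloc[0] == "MG"
        assert out["max_corrected_ch4_ppm"].iloc[0] == pytest.approx(5.0)

    def test_threshold_is_strict(self):
        df = breath_frame([("a", "before", 0, 4.0, 3.5)] * 3)
        assert classify_methanogenic(df)["status"].iloc[0] == "non-MG"

    def test_semester_baseline_subtraction(self):
        df = breath_frame([("a", "before", 0, 5.0, 3.5, "W16"),
                           ("a", "before", 0, 5.0, 3.5, "W16")])
        out = classify_methanogenic(df, baseline_semesters=["W16"])
        assert out["status"].iloc[0] == "non-MG"
        assert out["max_corrected_ch4_ppm"].iloc[0] == pytest.approx(4.0)
        assert out["baseline_applied_ppm"].iloc[0] == 1.0
        # without the baseline flag the same subject is MG
        assert classify_methanogenic(df)["status"].iloc[0] == "MG"

    def test_periods_classified_separately(self):
        df = breath_frame([("a", "before", 0, 1.0, 3.5),
                           ("a", "during", 0, 9.0, 3.5)])
        out = classify_methanogenic(df).set_index("period")
        assert out.loc["before", "status"] == "non-MG"
        assert out.loc["during", "status"] == "MG"

    def test_monotone_in_ch4(self, rng):
        base = breath_frame([("a", "before", 0, float(v), 3.5)
                             for v in rng.uniform(0, 6, 5)])
        was_mg = classify_methanogenic(base)["status"].iloc[0] == "MG"
        bumped = base.assign(ch4_ppm=base["ch4_ppm"] + 2.0)
        now_mg = classify_methanogenic(bumped)["status"].iloc[0] == "MG"
        assert now_mg or not was_mg  # raising CH4 never flips MG -> non-MG

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_methanogenic(breath_frame([]).reindex(
                columns=["subject", "period", "h2_ppm", "ch4_ppm", "co2_pct",
                         "semester"]))


class TestSubjectPeriodMeans:
    def test_simple_means(self):
        df = breath_frame([("a", "before", 2.0, 0, 3.5), ("a", "before", 4.0, 0, 3.5),
                           ("b", "before", 5.0, 0, 3.5), ("b", "before", 5.0, 0, 3.5)])
        df = normalize_breath(df)
        out = subject_period_means(df, "h2_norm_ppm").set_index("subject")
        assert out.loc["a", "mean"] == pytest.approx(3.0)
        assert out.loc["b", "mean"] == pytest.approx(5.0)

    def test_outlier_changes_mean_after_exclusion(self):
        rows = [("a", "before", v, 0, 3.5) for v in (1.0, 2.0, 3.0)]
        rows += [("b", "before", v, 0, 3.5) for v in (2.0, 3.0, 400.0)]
        df = normalize_breath(breath_frame(rows))
        out = subject_period_means(df, "h2_norm_ppm").set_index("subject")
        naive_b = np.mean([2.0, 3.0, 400.0])
        assert out.loc["b", "mean"] == pytest.approx(2.5)  # 400 fenced out
        assert out.loc["b", "mean"] != pytest.approx(naive_b)

    def test_fully_excluded_subject_dropped_with_warning(self):
        rows = [("a", "before", v, 0, 3.5) for v in (1.0, 1.5, 2.0, 2.5, 3.0)]
        rows += [("b", "before", 500.0, 0, 3.5)]
        df = normalize_breath(breath_frame(rows))
        with pytest.warns(UserWarning, match="excluded"):
            out = subject_period_means(df, "h2_norm_ppm")
        assert set(out["subject"]) == {"a"}


def status_frame(mg_subjects, nonmg_subjects, period="during"):
    rows = [{"subject": s, "period": period, "status": "MG"} for s in mg_subjects]
    rows += [{"subject": s, "period": period, "status": "non-MG"}
             for s in nonmg_subjects]
    return pd.DataFrame(rows)


def means_frame(values, period="during"):
    return pd.DataFrame([{"subject": s, "period": period, "mean": v}
                         for s, v in values.items()])


class TestCompareMgGroups:
    def test_identical_groups_p_one(self):
        means = means_frame({"a": 5.0, "b": 5.0, "c": 5.0, "d": 5.0})
        status = status_frame(["a", "b"], ["c", "d"])
        cmp_ = compare_mg_groups(means, status, "h2", "during")
        assert cmp_.p == 1.0 and cmp_.t == 0.0

    def test_programmed_separation_detected(self, rng):
        mg = {f"m{i}": rng.normal(5, 1) for i in range(20)}
        nm = {f"n{i}": rng.normal(10, 1) for i in range(20)}
        means = means_frame({**mg, **nm})
        status = status_frame(list(mg), list(nm))
        cmp_ = compare_mg_groups(means, status, "h2", "during")
        assert cmp_.p < 1e-6
        assert cmp_.row()["mean_MG"] < cmp_.row()["mean_nonMG"]
        assert "t=" in cmp_.summary()

    def test_explicit_exclusion_supported(self):
        means = means_frame({"a": 5.0, "b": 6.0, "c": 5.0, "d": 6.0, "e": 80.0})
        status = status_frame(["a", "b", "e"], ["c", "d"])
        with_e = compare_mg_groups(means, status, "h2", "during")
        without_e = compare_mg_groups(means, status, "h2", "during",
                                      exclude_subjects=["e"])
        assert with_e.row()["mean_MG"] > without_e.row()["mean_MG"]

    def test_one_subject_group_rejected(self):
        means = means_frame({"a": 5.0, "b": 6.0, "c": 5.0})
        status = status_frame(["a"], ["b", "c"])
        with pytest.raises(ValueError, match="degenerate"):
            compare_mg_groups(means, status, "h2", "during")


class TestPeriodContrast:
    def test_paired_detects_within_subject_shift(self, rng):
        rows = {}
        means = []
        for i in range(15):
            base = rng.normal(10, 3)
            means.append({"subject": f"s{i}", "period": "before", "mean": base})
            means.append({"subject": f"s{i}", "period": "during",
                          "mean": base + 4 + rng.normal(0, 1)})
        df = pd.DataFrame(means)
        t_paired, p_paired = period_contrast(df, paired=True)
        t_unpaired, p_unpaired = period_contrast(df, paired=False)
        assert p_paired < 0.001
        assert t_paired > 0
        # pairing removes the between-subject variance, so it is more sensitive
        assert p_paired < p_unpaired
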