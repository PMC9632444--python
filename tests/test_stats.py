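"""Paired comparisons, agreement analysis, age correction, ANOVA and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qsmsci import stats as qst
from qsmsci.segmentation import DepthMap, LesionPair, LesionROI


def make_pairs_with_means(mean_a, mean_b, n=20, spread=1.0, seed=0):
    """Paired samples whose group means equal the requested values exactly."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, spread, n)
    b = rng.normal(0, spread, n)
    return a - a.mean() + mean_a, b - b.mean() + mean_b


class TestPairedDelta:
    def test_printed_group_means_reproduce_delta(self):
        # lesion vs NAWM susceptibility: -0.0067 vs -0.0153 ppm -> +0.0086
        a, b = make_pairs_with_means(-0.0067, -0.0153, n=211, spread=0.01)
        out = qst.paired_delta(a, b)
        assert np.isclose(out["delta"], 0.0086, atol=1e-12)

    def test_hand_computed_t(self):
        out = qst.paired_delta([1, 2, 3], [2, 2, 5])
        assert np.isclose(out["delta"], -1.0)
        assert np.isclose(out["t"], -np.sqrt(3), atol=1e-4)  # -1.7321, df 2
        assert out["n"] == 3

    def test_identical_pairs_flagged_undefined(self):
        out = qst.paired_delta([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["delta"] == 0.0
        assert out["undefined"] and np.isnan(out["t"])

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=30), rng.normal(size=30)
        perm = rng.permutation(30)
        x, y = qst.paired_delta(a, b), qst.paired_delta(a[perm], b[perm])
        assert np.isclose(x["t"], y["t"])


class TestBlandAltman:
    def test_hand_computed_loa(self):
        # differences {1, -1}: bias 0, sd = sqrt(2), LOA = +/-2.7719
        out = qst.bland_altman([2.0, 1.0], [1.0, 2.0])
        assert out["bias"] == 0.0
        assert np.isclose(out["sd"], np.sqrt(2))
        assert np.isclose(out["loa_upper"], 1.96 * np.sqrt(2), atol=1e-12)
        assert np.isclose(out["loa_upper"], 2.7719, atol=1e-4)

    def test_equal_inputs(self):
        out = qst.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["bias"] == out["loa_lower"] == out["loa_upper"] == 0.0

    def test_bias_equals_paired_delta(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=25), rng.normal(size=25)
        assert np.isclose(qst.bland_altman(a, b)["bias"],
                          qst.paired_delta(a, b)["delta"])


class TestAgeCorrect:
    def test_age_independent_values_unchanged(self):
        vals = np.array([1.0, 2.0, 1.5, 1.8, 2.2, 0.8])
        ages = np.array([10.0, 20.0, 30.0, 15.0, 25.0, 40.0])
        # residualizing after removing any fitted slope: r with ln(age) ~ 0
        out = qst.age_correct(vals, ages)
        assert abs(np.corrcoef(out, np.log(ages))[0, 1]) < 1e-10
        assert np.isclose(out.mean(), vals.mean())

    def test_exact_log_trend_collapses_to_grand_mean(self):
        ages = np.array([8.0, 16.0, 32.0, 64.0])
        vals = 3.0 + 2.0 * np.log(ages)
        out = qst.age_correct(vals, ages)
        assert np.allclose(out, vals.mean())

    def test_confounded_group_difference_recovered(self):
        # shared age trend + true group offset: correction must recover the
        # generative offset within its simulation confidence interval
        rng = np.random.default_rng(3)
        n = 120
        ages = rng.uniform(8, 60, n)
        group = np.repeat([0, 1], n // 2)
        offset = 0.5
        vals = 2.0 * np.log(ages) + offset * group + rng.normal(0, 0.3, n)
        corrected = qst.age_correct(vals, ages)
        diff = corrected[group == 1].mean() - corrected[group == 0].mean()
        se = np.sqrt(2) * 0.3 / np.sqrt(n / 2)
        assert abs(diff - offset) < 3 * se + 0.1  # ln(age) imbalance slack

    def test_constant_ages_warns_identity(self):
        with pytest.warns(UserWarning):
            out = qst.age_correct([1.0, 2.0, 3.0], [20.0, 20.0, 20.0])
        assert np.allclose(out, [1.0, 2.0, 3.0])


class TestAnovaEffects:
    def test_single_factor_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "y": np.concatenate([rng.normal(0, 1, 12), rng.normal(1, 1, 12)]),
            "group": ["SCA"] * 12 + ["HC"] * 12,
        })
        table = qst.anova_effects(df, "y", factors=[("group", "C(group)", True)])
        t, _ = sps.ttest_ind(df[df.group == "SCA"].y, df[df.group == "HC"].y)
        assert np.isclose(table.loc["group", "F"], t ** 2, rtol=1e-10)

    def test_balanced_two_factor_matches_brute_force_ss(self):
        # sequential (type-I) sums of squares computed by explicit projections
        rng = np.random.default_rng(5)
        a = np.repeat([0, 1], 8)
        b = np.tile([0, 1], 8)
        y = 1.0 + 2.0 * a - 1.5 * b + rng.normal(0, 1, 16)
        df = pd.DataFrame({"y": y, "A": a.astype(str), "B": b.astype(str)})
        table = qst.anova_effects(
            df, "y", factors=[("A", "C(A)", True), ("B", "C(B)", True)])

        def rss(x_cols):
            x = np.column_stack([np.ones(16)] + x_cols)
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return ((y - x @ beta) ** 2).sum()

        ss_a = rss([]) - rss([a])
        ss_b = rss([a]) - rss([a, b])
        ss_res = rss([a, b])
        df_res = 16 - 3
        assert np.isclose(table.loc["A", "sum_sq"], ss_a, rtol=1e-10)
        assert np.isclose(table.loc["B", "sum_sq"], ss_b, rtol=1e-10)
        assert np.isclose(table.loc["A", "F"], ss_a / (ss_res / df_res), rtol=1e-10)

    def test_default_factor_order_runs_on_lesion_table(self):
        rng = np.random.default_rng(6)
        n = 60
        df = pd.DataFrame({
            "age_years": rng.uniform(8, 60, n),
            "group": rng.choice(["SCA", "HC"], n),
            "lobe": rng.choice(["frontal", "parietal"], n),
            "volume_mm3": rng.uniform(10, 500, n),
        })
        df["y"] = rng.normal(size=n)
        table = qst.anova_effects(df, "y")
        assert list(table.index[:4]) == ["ln_age", "group", "lobe", "ln_volume"]

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "group": ["SCA"] * 3})
        with pytest.raises(ValueError, match="fewer than 2"):
            qst.anova_effects(df, "y", factors=[("group", "C(group)", True)])


class TestGroupCompare:
    def test_identical_groups(self):
        df = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5,
                           "y": [1.0, 2, 3, 4, 5] * 2})
        out = qst.group_compare(df, "g", "y")
        assert np.isclose(out["p"], 1.0)
        assert out["means"]["a"] == out["means"]["b"]

    def test_power_on_separated_groups(self):
        # N(0,1) vs N(1,1), n=50 each: significant at 0.05 in >= 95% of reps
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            df = pd.DataFrame({
                "g": ["a"] * 50 + ["b"] * 50,
                "y": np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)]),
            })
            if qst.group_compare(df, "g", "y")["p"] < 0.05 :
                hits += 1
        assert hits >= 190

    def test_tukey_matches_hand_computation(self):
        # balanced 3-group fixture: MSE = 1, q(0.05, 3, 6) from the
        # studentized-range distribution gives the HSD half-width
        df = pd.DataFrame({
            "g": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            "y": [1.0, 2, 3, 2, 3, 4, 4, 5, 6],
        })
        out = qst.group_compare(df, "g", "y")
        assert out["test"] == "anova+tukey"
        tk = out["tukey"]
        diffs = dict(zip(zip(tk["group1"], tk["group2"]),
                         tk["meandiff"].astype(float)))
        assert np.isclose(diffs[("a", "b")], 1.0)
        assert np.isclose(diffs[("a", "c")], 3.0)
        q = sps.studentized_range.ppf(0.95, 3, 6)
        half = q * np.sqrt(1.0 / 3.0)
        rejected = {k: bool(v) for k, v in
                    zip(zip(tk["group1"], tk["group2"]), tk["reject"])}
        assert rejected[("a", "c")] == (3.0 > half)
        assert rejected[("a", "b")] == (1.0 > half)

    def test_small_group_dropped_with_warning(self):
        df = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5 + ["c"],
                           "y": np.arange(11, dtype=float)})
        with pytest.warns(UserWarning, match="n < 2"):
            out = qst.group_compare(df, "g", "y")
        assert set(out["means"]) == {"a", "b"}


class TestCorrelations:
    def test_perfect_linear_relation(self):
        s = pd.DataFrame({"mean_delta_chi": [0.1, 0.2, 0.3, 0.4],
                          "fsiq": [80.0, 90.0, 100.0, 110.0]})
        out = qst.cognition_correlate(s, "FSIQ")
        assert np.isclose(out["r"], 1.0)

    def test_hand_triple(self):
        out = qst.correlate_paired([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert np.isclose(out["r"], 0.5)

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError):
            qst.correlate_paired([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            qst.correlate_paired([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        s = pd.DataFrame({"mean_delta_chi": [0.1, 0.2, 0.3],
                          "fsiq": [90.0, 90.0, 90.0]})
        with pytest.raises(ValueError):
            qst.cognition_correlate(s, "FSIQ")
        with pytest.raises(ValueError):
            qst.cognition_correlate(s, "IQ")

    def test_shuffled_pairing_decorrelates(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=2000)
        paired = base + rng.normal(0, 0.1, 2000)
        assert qst.correlate_paired(base, paired)["r"] > 0.99
        assert abs(qst.correlate_paired(base, rng.permutation(paired))["r"]) < 0.08


class TestRoiMeans:
    def make_pair(self, shape=(12, 12, 12)):
        sci = np.zeros(shape, dtype=bool)
        sci[2:5, 2:5, 2:5] = True
        nawm = np.zeros(shape, dtype=bool)
        nawm[7:10, 2:5, 2:5] = True
        return LesionPair(sci=LesionROI(mask=sci, definition="FLAIR", lesion_id=0),
                          nawm=LesionROI(mask=nawm))

    def test_constant_map_gives_zero_delta(self):
        pair = self.make_pair()
        rec, rows = qst.roi_means(pair, chi_map=np.full((12, 12, 12), 3.0),
                                  r2star_map=np.full((12, 12, 12), 19.2))
        assert rec.mean_chi_sci == rec.mean_chi_nawm == 3.0
        assert rec.mean_r2s_sci == 19.2
        assert rows == []

    def test_depth_split_rows_match_hand_means(self):
        pair = self.make_pair()
        labels = np.full((12, 12, 12), 3, dtype=np.int8)  # deep
        labels[:, :, :3] = 1                              # juxtacortical slab
        depth = DepthMap(labels=labels, d_cortex=np.zeros((12, 12, 12)),
                         d_ventricle=np.zeros((12, 12, 12)))
        chi = np.zeros((12, 12, 12))
        chi[:, :, :3] = 1.0  # juxtacortical voxels carry chi 1
        rec, rows = qst.roi_means(pair, chi_map=chi, depth_map=depth)
        assert len(rows) == 2
        by_class = {r["depth_class"]: r for r in rows}
        assert by_class["juxtacortical"]["mean_chi_sci"] == 1.0
        assert by_class["deep"]["mean_chi_sci"] == 0.0
        # 3x3x3 SCI with one z-slab of 9 voxels juxtacortical
        assert by_class["juxtacortical"]["n_voxels"] == 9
        assert np.isclose(sum(rec.depth.values()), 1.0)

    def test_empty_mask_rejected(self):
        pair = self.make_pair()
        pair.nawm.mask[:] = False
        with pytest.raises(ValueError):
            qst.roi_means(pair, chi_map=np.zeros((12, 12, 12)))


class TestSubjectSummaries:
    def test_summaries_and_null_correlation(self):
        rng = np.random.default_rng(9)
        recs = []
        for s in range(12):
            for l in range(rng.integers(1, 4)):
                recs.append(qst.RoiRecord(
                    subject_id=f"s{s:02d}", lesion_id=l, definition="FLAIR",
                    group="SCA" if s % 2 else "HC", age_years=10.0 + s,
                    volume_mm3=50.0, n_voxels=30,
                    mean_chi_sci=rng.normal(0.01, 0.002),
                    mean_chi_nawm=rng.normal(0.0, 0.002),
                    mean_r2s_sci=16.7, mean_r2s_nawm=19.2))
        df = qst.records_to_dataframe(recs)
        cov = pd.DataFrame({"subject_id": [f"s{s:02d}" for s in range(12)],
                            "fsiq": rng.normal(90, 10, 12)})
        summ = qst.summarize_subjects(df, cov)
        assert len(summ) == 12
        assert np.allclose(summ["mean_delta_r2s"], -2.5)
        out = qst.cognition_correlate(summ, "FSIQ")
        assert out["n"] == 12
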