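"""Reliability (ICC) and group-comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from craniocurve.errors import DegenerateVariance, SingletonGroup, UndefinedICC
from craniocurve.stats import (
    compare_groups,
    games_howell,
    group_mean_curves,
    icc_2_1,
    reliability_report,
)


def anova_components_oracle(x: np.ndarray) -> float:
    """Independent ICC(2,1) oracle via explicit variance components."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (
        ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand) ** 2).sum()
        / ((n - 1) * (k - 1))
    )
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC21:
    def test_perfect_agreement_gives_one(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 3))
        assert icc_2_1(x) == pytest.approx(1.0, abs=1e-12)

    def test_matches_variance_components_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, size=(6, 3)) + rng.normal(0, 2, size=(6, 1))
        assert icc_2_1(x) == pytest.approx(anova_components_oracle(x), abs=1e-9)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        x = rng.normal(0, 1, size=(8, 3)) + rng.normal(0, 1.5, size=(8, 1))
        df = pd.DataFrame(x, columns=["r1", "r2", "r3"]).reset_index(names="target")
        long = df.melt(id_vars="target", var_name="rater", value_name="score")
        ref = pingouin.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        )
        # absolute agreement, single measures: labelled ICC2 or ICC(A,1)
        # depending on the pingouin version
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        ref_val = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc_2_1(x) == pytest.approx(ref_val, abs=1e-9)

    def test_pure_noise_gives_near_zero(self):
        rng = np.random.default_rng(99)
        x = rng.normal(0, 1, size=(1000, 3))
        assert abs(icc_2_1(x)) < 0.05

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(10, 2, size=(7, 4))
        base = icc_2_1(x)
        assert icc_2_1(x + 123.4) == pytest.approx(base, abs=1e-9)
        assert icc_2_1(x * 7.7) == pytest.approx(base, abs=1e-9)

    def test_systematic_rater_offset_lowers_absolute_agreement(self):
        rng = np.random.default_rng(2)
        truth = rng.normal(0, 5, size=(10, 1))
        x = np.tile(truth, (1, 3)) + rng.normal(0, 0.1, size=(10, 3))
        offset = x.copy()
        offset[:, 2] += 50.0
        assert icc_2_1(offset) < icc_2_1(x) - 0.5

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedICC):
            icc_2_1(np.full((5, 3), 2.5))


class TestReliabilityReport:
    @staticmethod
    def _ratings(jitter_sd=0.1, seed=0, n_subjects=26):
        rng = np.random.default_rng(seed)
        rows = []
        for lm in ("ex_left", "ex_right", "po_left", "po_right"):
            truth = rng.normal(0, 30, size=(n_subjects, 3))
            for rater in ("a", "b", "c"):
                for session in (1, 2, 3):
                    pts = truth + rng.normal(0, jitter_sd, size=truth.shape)
                    for i, p in enumerate(pts):
                        rows.append(
                            dict(subject=i, landmark=lm, rater=rater, session=session,
                                 x=p[0], y=p[1], z=p[2])
                        )
        return pd.DataFrame(rows)

    def test_small_jitter_gives_excellent_reliability(self):
        # 0.1 mm placement jitter over 26 targets: all ICCs near-perfect,
        # the regime reported for human raters on these landmarks
        report = reliability_report(self._ratings(jitter_sd=0.1))
        coord = report[report["axis"] != "r3d"]
        assert (coord["icc"] > 0.99).all()
        assert coord["acceptable"].all()

    def test_duplicated_rater_perfect_interrater(self):
        df = self._ratings(jitter_sd=0.0, seed=1, n_subjects=6)
        inter = reliability_report(df)
        inter = inter[(inter["kind"] == "inter") & (inter["axis"] == "x")]
        assert np.allclose(inter["icc"], 1.0)

    def test_report_covers_all_landmarks_axes_kinds(self):
        report = reliability_report(self._ratings(n_subjects=5))
        assert set(report["landmark"]) == {"ex_left", "ex_right", "po_left", "po_right"}
        assert set(report["axis"]) == {"x", "y", "z", "r3d"}
        assert set(report["kind"]) == {"intra", "inter"}


class TestGroupMeanCurves:
    def test_identical_curves_zero_range(self):
        curve = np.full(360, 1.0) + 0.1 * np.cos(np.deg2rad(np.arange(360)))
        summary = group_mean_curves({"g": [curve, curve.copy(), curve.copy()]})
        assert summary.range_mean["g"] == pytest.approx(0.0, abs=1e-15)
        assert summary.range_sd["g"] == pytest.approx(0.0, abs=1e-15)

    def test_constant_offset_gives_constant_range(self):
        base = np.full(360, 1.0)
        summary = group_mean_curves({"g": [base, base + 0.1]})
        assert summary.range_mean["g"] == pytest.approx(0.1)
        assert summary.range_sd["g"] == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(summary.mean_curves["g"], 1.05)

    def test_singleton_group_rejected(self):
        with pytest.raises(SingletonGroup):
            group_mean_curves({"g": [np.ones(360)]})


class TestGamesHowell:
    def test_two_groups_reduces_to_welch_t(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 3, 20)
        gh = games_howell({"a": a, "b": b})
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert gh["p"].iloc[0] == pytest.approx(p, abs=1e-6)
        assert gh["t"].iloc[0] == pytest.approx(abs(t), abs=1e-9)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(13)
        data = {
            "a": rng.normal(0, 1, 10),
            "b": rng.normal(0.8, 2, 14),
            "c": rng.normal(-0.5, 0.5, 8),
        }
        gh = games_howell(data)
        long = pd.concat(
            [pd.DataFrame({"y": v, "g": k}) for k, v in data.items()], ignore_index=True
        )
        ref = pingouin.pairwise_gameshowell(data=long, dv="y", between="g")
        merged = gh.merge(
            ref.rename(columns={"A": "group_a", "B": "group_b"}),
            on=["group_a", "group_b"],
        )
        np.testing.assert_allclose(merged["p"], merged["pval"], atol=1e-6)
        np.testing.assert_allclose(merged["df_x"], merged["df_y"], atol=1e-6)

    def test_p_monotone_in_mean_difference(self):
        rng = np.random.default_rng(21)
        base = rng.normal(0, 1, 15)
        shift_small = base + 0.5
        shift_big = base + 2.0
        p_small = games_howell({"a": base, "b": shift_small})["p"].iloc[0]
        p_big = games_howell({"a": base, "b": shift_big})["p"].iloc[0]
        assert p_big < p_small


class TestCompareGroups:
    def test_separated_group_flagged_null_pair_not(self):
        # one group shifted by 5 standard errors of a pairwise mean
        # difference: over seeded replicates the separated pairs are called,
        # the null pair is not
        hits_sep, hits_null = 0, 0
        n_rep = 200
        n = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            shift = 5.0 * np.sqrt(2.0 / n)
            report = compare_groups(
                {
                    "a": rng.normal(0, 1, n),
                    "b": rng.normal(0, 1, n),
                    "c": rng.normal(shift, 1, n),
                }
            )
            post = report.posthoc.set_index(["group_a", "group_b"])
            if post.loc[("a", "c"), "significant"] and post.loc[("b", "c"), "significant"]:
                hits_sep += 1
            if post.loc[("a", "b"), "significant"]:
                hits_null += 1
        assert hits_sep / n_rep >= 0.95
        assert hits_null / n_rep <= 0.05

    def test_type_one_error_within_monte_carlo_bounds(self):
        # identical distributions: the omnibus ANOVA should reject at the
        # nominal 5 % rate within 2 Monte-Carlo SE over 1000 replicates
        n_rep = 1000
        rng = np.random.default_rng(1234)
        data = rng.normal(0, 1, size=(n_rep, 3, 50))
        rejections = 0
        for rep in range(n_rep):
            _, p = sps.f_oneway(*data[rep])
            rejections += p < 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 2 * se + 1e-12

    def test_bonferroni_adjustment_applied(self):
        rng = np.random.default_rng(3)
        report = compare_groups(
            {k: rng.normal(i, 1 + i, 12) for i, k in enumerate("abc")}
        )
        assert report.n_comparisons == 3
        np.testing.assert_allclose(
            report.posthoc["p_bonferroni"],
            np.minimum(1.0, report.posthoc["p"] * 3),
        )
        assert "Levene" in report.to_text()

    def test_single_group_rejected(self):
        with pytest.raises(SingletonGroup):
            compare_groups({"a": np.arange(5.0)})

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateVariance):
            compare_groups({"a": np.ones(5), "b": np.full(5, 2.0)})
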