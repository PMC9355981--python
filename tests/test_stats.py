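"""Reliability and comparison statistics, cross-checked against pingouin."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from paraseg.stats import (assumption_checks, bland_altman, icc_2_1, mauchly,
                           paired_t, posthoc_best_vs_rest, rm_anova)


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 7.0])
        res = icc_2_1(x, x)
        assert res.value == pytest.approx(1.0)

    def test_constant_bias_penalized(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = icc_2_1(x, x + 10.0)
        assert res.value < 0.5  # absolute agreement punishes systematic offset

    def test_matches_pingouin_icc2(self, rng):
        x = rng.normal(10, 3, 20)
        y = x + rng.normal(0.5, 1.0, 20)
        mine = icc_2_1(x, y)
        df = pd.DataFrame({"t": np.r_[np.arange(20), np.arange(20)],
                           "r": ["a"] * 20 + ["b"] * 20, "v": np.r_[x, y]})
        ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="v")
        row = ref[ref.Type == "ICC(A,1)"].iloc[0] if (ref.Type == "ICC(A,1)").any() \
            else ref[ref.Type == "ICC2"].iloc[0]
        assert mine.value == pytest.approx(float(row.ICC), abs=1e-10)
        lo, hi = row.CI95 if "CI95" in ref.columns else row["CI95%"]
        assert mine.ci_low == pytest.approx(lo, abs=0.01)
        assert mine.ci_high == pytest.approx(hi, abs=0.01)

    def test_affine_rescale_invariance(self, rng):
        x = rng.normal(size=15)
        y = x + rng.normal(0, 0.3, 15)
        a = icc_2_1(x, y).value
        b = icc_2_1(5 * x + 2, 5 * y + 2).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_zero_variance(self):
        res = icc_2_1(np.ones(5), np.ones(5))
        assert res.degenerate and np.isnan(res.value)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            icc_2_1([1, 2], [1, 2])


class TestBlandAltman:
    def test_equal_measurements(self):
        bias, lo, hi = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_closed_form_two_diffs(self):
        bias, lo, hi = bland_altman([0.0, 2.0], [1.0, 1.0])
        sd = np.std([-1.0, 1.0], ddof=1)
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * sd)
        assert lo == pytest.approx(-1.96 * sd)

    def test_homogeneous_in_scale(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        b1, l1, h1 = bland_altman(x, y)
        b3, l3, h3 = bland_altman(3 * x, 3 * y)
        assert (b3, l3, h3) == pytest.approx((3 * b1, 3 * l1, 3 * h1))

    def test_limits_symmetric_about_bias(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        bias, lo, hi = bland_altman(x, y)
        assert hi - bias == pytest.approx(bias - lo)


class TestPairedT:
    def test_identical_samples(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_hand_formula(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(0.4, 0.8, 12)
        d = x - y
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = paired_t(x, y)
        assert t == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(expected), len(d) - 1), rel=1e-12)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=9)
        t1, p1 = paired_t(x, y)
        t2, p2 = paired_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestRMAnova:
    def test_null_structure_subject_offsets_only(self, rng):
        n, k = 10, 3
        base = rng.normal(size=(n, 1))
        vals = np.repeat(base, k, axis=1)
        df = pd.DataFrame({"subject": np.repeat(range(n), k),
                           "cond": list("abc") * n, "y": vals.ravel()})
        res = rm_anova(df, "y", ["cond"])
        assert res.SS[0] == pytest.approx(0.0, abs=1e-20)

    def test_two_conditions_equals_squared_paired_t(self, rng):
        n = 14
        df = pd.DataFrame({"subject": np.repeat(range(n), 2),
                           "cond": ["a", "b"] * n, "y": rng.normal(size=2 * n)})
        res = rm_anova(df, "y", ["cond"])
        wide = df.pivot(index="subject", columns="cond", values="y")
        t, p = paired_t(wide["a"], wide["b"])
        assert res.F[0] == pytest.approx(t**2, rel=1e-10)
        assert res.p[0] == pytest.approx(p, rel=1e-10)

    def test_matches_pingouin_two_factor(self, rng):
        n = 12
        df = pd.DataFrame({"subject": np.repeat(range(n), 6),
                           "a": np.tile(np.repeat(["a1", "a2"], 3), n),
                           "b": ["x", "y", "z"] * 2 * n,
                           "y": rng.normal(size=n * 6) + np.repeat(rng.normal(size=n), 6)})
        mine = rm_anova(df, "y", ["a", "b"]).set_index("effect")
        ref = pg.rm_anova(data=df, dv="y", within=["a", "b"], subject="subject").set_index("Source")
        for eff, src in (("a", "a"), ("b", "b"), ("a:b", "a * b")):
            assert mine.loc[eff, "F"] == pytest.approx(float(ref.loc[src, "F"]), rel=1e-8)
            assert mine.loc[eff, "p"] == pytest.approx(float(ref.loc[src, "p_unc"]), rel=1e-6)

    def test_total_ss_conservation(self, rng):
        # effect + error SS over all strata (incl. subject) equal total SS
        n = 8
        df = pd.DataFrame({"subject": np.repeat(range(n), 4),
                           "a": ["a1", "a1", "a2", "a2"] * n,
                           "b": ["x", "y"] * 2 * n, "y": rng.normal(size=4 * n)})
        res = rm_anova(df, "y", ["a", "b"])
        subj_means = df.groupby("subject")["y"].mean()
        ss_subject = 4 * ((subj_means - df.y.mean()) ** 2).sum()
        total = ((df.y - df.y.mean()) ** 2).sum()
        decomposed = res.SS.sum() + res.SS_error.sum() + ss_subject
        assert decomposed == pytest.approx(total, rel=1e-10)

    def test_planted_effect_detected(self, rng):
        n = 30
        effect = {"m1": 0.0, "m2": 0.08}
        rows = []
        for s in range(n):
            off = rng.normal(0, 0.05)
            for m in ("m1", "m2"):
                for mus in ("mf", "es", "pm"):
                    rows.append({"subject": s, "model": m, "muscle": mus,
                                 "y": 0.9 + off + effect[m] + rng.normal(0, 0.03)})
        res = rm_anova(pd.DataFrame(rows), "y", ["model", "muscle"]).set_index("effect")
        assert res.loc["model", "p"] < 0.01

    def test_incomplete_design_rejected(self, rng):
        df = pd.DataFrame({"subject": [0, 0, 1], "cond": ["a", "b", "a"],
                           "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            rm_anova(df, "y", ["cond"])


class TestPosthoc:
    def test_best_selected_and_compared(self, rng):
        n = 10
        df = pd.DataFrame({"subject": np.repeat(range(n), 3),
                           "cell": ["a", "b", "c"] * n,
                           "dice": np.r_[[0.9, 0.8, 0.7]].tolist() * n
                           + rng.normal(0, 1e-3, 3 * n)})
        res = posthoc_best_vs_rest(df, "dice", "cell")
        assert set(res.best) == {"a"}
        assert len(res) == 2
        assert (res.p < 0.01).all()


class TestAssumptionChecks:
    def test_normal_residuals(self, rng):
        r = rng.normal(size=500)
        out = assumption_checks(r)
        assert out["shapiro_p"] > 0.001
        assert abs(out["skewness"]) < 0.2
        assert len(out["qq"]["sample"]) == 500

    def test_exponential_skewness_near_two(self, rng):
        r = rng.exponential(size=4000)
        out = assumption_checks(r)
        assert out["skewness"] == pytest.approx(2.0, abs=0.4)

    def test_mauchly_matches_pingouin(self, rng):
        tab = rng.normal(size=(15, 4)) @ np.diag([1.0, 1.5, 0.7, 1.2])
        mine = mauchly(tab)
        df = pd.DataFrame({"subject": np.repeat(range(15), 4),
                           "cond": list("abcd") * 15, "y": tab.ravel()})
        ref = pg.sphericity(df, dv="y", within="cond", subject="subject")
        eps = float(pg.epsilon(df, dv="y", within="cond", subject="subject",
                               correction="gg"))
        assert mine["W"] == pytest.approx(float(ref.W), rel=1e-10)
        assert mine["chi2"] == pytest.approx(float(ref.chi2), rel=1e-10)
        assert mine["p"] == pytest.approx(float(ref.pval), rel=1e-8)
        assert mine["gg_epsilon"] == pytest.approx(eps, rel=1e-8)

    def test_two_conditions_skips_mauchly(self, rng):
        out = mauchly(rng.normal(size=(10, 2)))
        assert out["skipped"] and out["gg_epsilon"] == 1.0
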