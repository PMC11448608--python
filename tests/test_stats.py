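import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predosim.io import SurvivalRecord
from predosim.stats import (
    anova_multi,
    fold_change,
    km_fit,
    logrank,
    ratio_with_uncertainty,
    two_way_anova,
)


class TestFoldChange:
    @pytest.mark.parametrize(
        "a, b, fold, raw",
        [
            (260.4, 11.2, 23.0, 23.25),  # kidney cumulated activity, healthy
            (1615.0, 197.0, 8.0, 8.20),  # kidney cumulated activity, xenograft
            (60.03, 37.54, 1.6, 1.599),  # tumor MAD penalty of pretargeting
            (2.0, 0.4, 5.0, 5.0),  # kidney TI gain
            (60.03, 1.98, 30.0, 30.32),  # tumor MAD, FAP-low PDX vs xenograft
        ],
    )
    def test_reference_headline_folds(self, a, b, fold, raw):
        fc = fold_change(a, b)
        assert fc["fold"] == pytest.approx(fold)
        assert fc["raw"] == pytest.approx(raw, abs=0.01)

    def test_equal_inputs_unit_fold(self):
        fc = fold_change(7.0, 7.0)
        assert fc["fold"] == pytest.approx(1.0)
        assert fc["direction"] == "equal"

    def test_direction_recorded(self):
        assert fold_change(1.0, 10.0)["direction"] == "decrease"
        assert fold_change(10.0, 1.0)["direction"] == "increase"

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)


class TestRatioWithUncertainty:
    def test_tumor_to_kidney_pretargeting(self):
        # 404 +/- 41 over 197 +/- 31 -> 2.05 +/- 0.38, reported 2.0 +/- 0.4
        r = ratio_with_uncertainty(404.0, 41.0, 197.0, 31.0)
        assert r.ratio == pytest.approx(2.05, abs=0.01)
        assert r.sd == pytest.approx(0.38, abs=0.01)
        assert round(r.ratio, 1) == 2.1 or round(r.ratio, 1) == 2.0

    def test_tumor_to_kidney_conventional(self):
        # 662 +/- 60 over 1,615 +/- 185 -> 0.41 +/- 0.06
        r = ratio_with_uncertainty(662.0, 60.0, 1615.0, 185.0)
        assert r.ratio == pytest.approx(0.41, abs=0.005)
        assert r.sd == pytest.approx(0.06, abs=0.005)

    def test_zero_sd_gives_exact_unit_ratio(self):
        r = ratio_with_uncertainty(5.0, 0.0, 5.0, 0.0)
        assert r.ratio == 1.0 and r.sd == 0.0

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_cv_scale_invariance(self, c):
        base = ratio_with_uncertainty(404.0, 41.0, 197.0, 31.0)
        scaled = ratio_with_uncertainty(c * 404.0, c * 41.0, c * 197.0, c * 31.0)
        assert scaled.ratio == pytest.approx(base.ratio, rel=1e-9)
        assert scaled.sd / scaled.ratio == pytest.approx(base.sd / base.ratio, rel=1e-9)

    def test_non_positive_mean_rejected(self):
        with pytest.raises(ValueError):
            ratio_with_uncertainty(0.0, 1.0, 1.0, 1.0)


class TestAnova:
    def test_identical_groups_unit_pvalues(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = anova_multi(g, adjust="sidak")
        assert np.all(res.comparisons["p_adj"] == 1.0)
        res = anova_multi(g, adjust="dunnett", control="a")
        assert np.all(res.comparisons["p_adj"] == 1.0)

    def test_sidak_single_comparison_unadjusted(self):
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        res = anova_multi({"a": a, "b": b}, adjust="sidak")
        # m = 1 so p_adj equals the pooled-variance t-test p-value
        t, p = sps.ttest_ind(a, b)
        assert res.comparisons["p_adj"].iloc[0] == pytest.approx(p, rel=1e-9)

    def test_dunnett_matches_permutation_oracle(self):
        # independent max-|t| permutation null (1e5 draws) reproduces
        # the multivariate-t adjusted p within Monte-Carlo error
        rng = np.random.default_rng(11)
        n = 20
        groups = {
            "control": rng.normal(0.0, 1.0, n),
            "t1": rng.normal(0.7, 1.0, n),
            "t2": rng.normal(0.4, 1.0, n),
        }
        res = anova_multi(groups, adjust="dunnett", control="control")
        data = np.concatenate(list(groups.values()))
        N = 3 * n

        def tstats(x):
            g = x.reshape(*x.shape[:-1], 3, n)
            m = g.mean(-1)
            mse = ((g - m[..., None]) ** 2).sum((-1, -2)) / (N - 3)
            se = np.sqrt(mse * 2.0 / n)
            return (m[..., 1:] - m[..., :1]) / se[..., None]

        t_obs = tstats(data)
        idx = np.argsort(rng.random((100_000, N)), axis=1)
        t_max = np.abs(tstats(data[idx])).max(-1)
        for i, row in res.comparisons.iterrows():
            p_perm = float((t_max >= abs(t_obs[i])).mean())
            assert row["p_adj"] == pytest.approx(p_perm, abs=0.01)

    def test_exact_separation_flagged(self):
        g = {"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]}
        res = anova_multi(g, adjust="sidak")
        assert res.exact_separation

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            anova_multi({"a": [1.0], "b": [1.0, 2.0]}, adjust="sidak")

    def test_two_way_anova_table(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        rows = []
        for arm in ("pre", "conv"):
            for organ in ("kidney", "tumor"):
                mu = {"pre": 1.0, "conv": 3.0}[arm] + {"kidney": 0.0, "tumor": 1.0}[organ]
                for v in rng.normal(mu, 0.5, 5):
                    rows.append(dict(arm=arm, organ=organ, auc=v))
        table = two_way_anova(pd.DataFrame(rows), "auc", "arm", "organ")
        assert "C(arm)" in table.index and "C(arm):C(organ)" in table.index
        assert table.loc["C(arm)", "PR(>F)"] < 0.001


class TestKaplanMeier:
    def test_median_no_censoring(self):
        recs = [SurvivalRecord("g", float(t), 1) for t in range(1, 11)]
        km = km_fit(recs)
        # smallest t with S(t) <= 0.5
        assert km.median_d == pytest.approx(5.0)

    def test_all_censored_median_undefined(self):
        recs = [SurvivalRecord("g", float(t), 0) for t in range(1, 6)]
        assert np.isnan(km_fit(recs).median_d)

    def test_matches_hand_computed_product_limit(self, survival_toy):
        # events at 1, 3, 5 with censoring at 2, 4:
        # S(1) = 4/5, S(3) = 4/5 * 2/3, S(5) = 0
        km = km_fit(survival_toy)
        assert km.probability_at(1.0) == pytest.approx(0.8)
        assert km.probability_at(3.0) == pytest.approx(0.8 * 2.0 / 3.0)
        assert km.probability_at(5.0) == pytest.approx(0.0)
        assert km.probability_at(0.5) == 1.0

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(21)
        times = rng.exponential(30.0, 40)
        recs = [SurvivalRecord("g", float(t), 1) for t in times]
        km = km_fit(recs)
        for t in np.quantile(times, [0.1, 0.4, 0.6, 0.9]):
            assert km.probability_at(t) == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_survival_starts_at_one_and_non_increasing(self, survival_toy):
        km = km_fit(survival_toy)
        assert km.survival[0] == 1.0
        assert np.all(np.diff(km.survival) <= 0)


class TestLogrank:
    def test_identical_groups_null(self):
        a = [SurvivalRecord("a", float(t), 1) for t in (3, 5, 8, 13)]
        b = [SurvivalRecord("b", float(t), 1) for t in (3, 5, 8, 13)]
        res = logrank(a, b)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_hand_computed_oe_over_v(self):
        # independent Mantel-Cox oracle computed from the risk tables
        a = [SurvivalRecord("a", t, 1) for t in (1.0, 3.0, 5.0)]
        b = [SurvivalRecord("b", t, 1) for t in (2.0, 4.0, 6.0)]
        o_minus_e, var = 0.0, 0.0
        event_times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        for t in event_times:
            na = sum(1 for r in a if r.time_d >= t)
            nb = sum(1 for r in b if r.time_d >= t)
            da = sum(1 for r in a if r.time_d == t)
            db = sum(1 for r in b if r.time_d == t)
            n, d = na + nb, da + db
            o_minus_e += da - d * na / n
            if n > 1:
                var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
        chi2_oracle = o_minus_e**2 / var
        res = logrank(a, b)
        assert res["chi2"] == pytest.approx(chi2_oracle, rel=1e-9)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(31)
        a = [SurvivalRecord("a", float(t), int(e)) for t, e in
             zip(rng.exponential(20, 12), rng.integers(0, 2, 12))]
        b = [SurvivalRecord("b", float(t), int(e)) for t, e in
             zip(rng.exponential(35, 12), np.ones(12))]
        assert logrank(a, b)["chi2"] == pytest.approx(logrank(b, a)["chi2"], rel=1e-12)

    def test_zero_events_undefined(self):
        a = [SurvivalRecord("a", 3.0, 0)]
        b = [SurvivalRecord("b", 4.0, 0)]
        with pytest.raises(ValueError, match="zero observed events"):
            logrank(a, b)
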