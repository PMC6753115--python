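"""Statistical battery vs textbook oracles and calibration simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from snipegrade.stats import (
    anova_oneway,
    chi_square_counts,
    cohens_d,
    fdr_bh,
    fdr_scan,
    gradient_report,
    interaction_model,
    tukey_hsd,
)


def _force_moments(raw: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Rescale a sample so its (ddof=1) moments are exactly (mean, sd)."""
    z = (raw - raw.mean()) / raw.std(ddof=1)
    return mean + sd * z


class TestAnova:
    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        f, p_f = anova_oneway({"a": a, "b": b})
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_identical_groups_zero_f(self):
        g = np.array([1.0, 2.0, 3.0])
        f, p = anova_oneway({"a": g, "b": g.copy()})
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_decomposition(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(k_i, 1, 5 + k_i) for k_i, k in enumerate("abc")}
        f, _ = anova_oneway(groups)
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        k, n = len(groups), all_vals.size
        assert f == pytest.approx((ssb / (k - 1)) / (ssw / (n - k)), rel=1e-10)

    def test_null_pvalues_uniform(self):
        """Repeated null simulations give uniform p (KS test)."""
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(500):
            groups = {k: rng.normal(0, 1, 10) for k in "abc"}
            ps.append(anova_oneway(groups)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_guards(self):
        with pytest.raises(ValueError):
            anova_oneway({"a": np.array([1.0, 2.0])})
        with pytest.raises(ValueError):
            anova_oneway({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestTukey:
    def test_identical_groups_p_near_one(self):
        g = np.array([3.0, 4.0, 5.0, 6.0])
        out = tukey_hsd({"a": g, "b": g.copy(), "c": g.copy()})
        assert (out["p_adj"] > 0.99).all()

    def test_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(i * 0.4, 1, 8) for i, k in enumerate("abcd")}
        out = tukey_hsd(groups)
        for _, row in out.iterrows():
            _, p_raw = sps.ttest_ind(groups[row["group_a"]], groups[row["group_b"]])
            assert row["p_adj"] >= p_raw - 1e-12

    def test_matches_studentized_range_oracle(self):
        """Balanced 3-group example recomputed by direct SR evaluation."""
        g1 = np.array([10.0, 12, 11, 9, 13])
        groups = {"a": g1, "b": g1 + 2, "c": g1 + 5}
        out = tukey_hsd(groups).set_index(["group_a", "group_b"])
        k, n = 3, 5
        msw = np.mean([v.var(ddof=1) for v in groups.values()])
        for (na, nb), row in out.iterrows():
            q = abs(groups[na].mean() - groups[nb].mean()) / np.sqrt(msw / n)
            oracle = sps.studentized_range.sf(q, k, k * (n - 1))
            assert row["p_adj"] == pytest.approx(oracle, rel=1e-8)

    def test_covers_all_pairs(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(0, 1, 6) for k in "abcde"}
        assert len(tukey_hsd(groups)) == 10


class TestCohensD:
    def test_equal_samples_zero(self):
        g = np.array([1.0, 2, 3, 4])
        assert cohens_d(g, g.copy()) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a), rel=1e-14)

    def test_cognitive_screen_group_contrast(self):
        """Samples forced to the CH/AD cognitive-screen moments
        (28.0 +- 1.94, n=29 vs 17.2 +- 5.36, n=12) give the hand-computed
        pooled-SD effect size."""
        rng = np.random.default_rng(6)
        ch = _force_moments(rng.normal(size=29), 28.0, 1.94)
        ad = _force_moments(rng.normal(size=12), 17.2, 5.36)
        # oracle: pooled var = (28*1.94^2 + 11*5.36^2)/39, d = 10.8/sqrt(.)
        assert cohens_d(ch, ad) == pytest.approx(3.2855304, abs=1e-6)

    def test_matches_pooled_formula_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.normal(0, 2, int(rng.integers(2, 20)))
            b = rng.normal(1, 3, int(rng.integers(2, 20)))
            na, nb = len(a), len(b)
            sp = np.sqrt(
                (
                    ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
                )
                / (na + nb - 2)
            )
            assert cohens_d(a, b) == pytest.approx(
                (a.mean() - b.mean()) / sp, rel=1e-10
            )

    def test_zero_spread_flagged(self):
        with pytest.raises(FloatingPointError):
            cohens_d(np.ones(5), np.ones(4))


class TestFdr:
    def test_all_tiny_p_all_rejected(self):
        res = fdr_bh(np.full(10, 0.001), q=0.05)
        assert res.n_rejected == 10
        assert res.critical_index == 10

    def test_step_up_example(self):
        res = fdr_bh(np.array([0.01, 0.02, 0.2]), q=0.05)
        assert list(res.reject) == [True, True, False]

    def test_matches_definitional_oracle(self):
        """BH step-up re-derived from its definition on random p-vectors."""
        rng = np.random.default_rng(8)
        for _ in range(300):
            m = int(rng.integers(1, 25))
            p = rng.uniform(0, 1, m)
            res = fdr_bh(p, q=0.05)
            order = np.argsort(p)
            ps = p[order]
            kmax = 0
            for i in range(m):
                if ps[i] <= (i + 1) * 0.05 / m:
                    kmax = i + 1
            expected = np.zeros(m, dtype=bool)
            expected[order[:kmax]] = True
            assert np.array_equal(res.reject, expected)

    def test_rejections_monotone_in_q(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 40)
        r1 = fdr_bh(p, q=0.01).n_rejected
        r2 = fdr_bh(p, q=0.10).n_rejected
        assert r1 <= r2

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, np.nan]))
        with pytest.raises(ValueError):
            fdr_bh(np.array([1.5]))


class TestChiSquare:
    def test_sex_table_nonsignificant(self):
        """The five-group sex table is balanced: p ~ 0.963."""
        tab = [[17, 37, 11, 4, 6], [12, 29, 11, 4, 6]]
        x2, p = chi_square_counts(tab)
        assert p == pytest.approx(0.9627, abs=0.001)
        assert p > 0.05

    def test_proportional_table_zero(self):
        x2, p = chi_square_counts([[10, 20], [30, 60]])
        assert x2 == pytest.approx(0.0, abs=1e-12)

    def test_2x2_closed_form_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 40, 4)
            x2, _ = chi_square_counts([[a, b], [c, d]])
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert x2 == pytest.approx(closed, rel=1e-10)

    def test_degenerate_margins(self):
        with pytest.raises(ValueError):
            chi_square_counts([[0, 0], [3, 4]])


class TestInteraction:
    @staticmethod
    def _simulate(rng, beta_int: float, n0: int = 29, n1: int = 66):
        g = np.r_[np.zeros(n0), np.ones(n1)]
        s = rng.normal(0, 1, n0 + n1)
        y = 0.3 * g + 0.2 * s + beta_int * g * s + rng.normal(0, 1, n0 + n1)
        return y, g, s

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        hits = sum(
            interaction_model(*self._simulate(rng, 0.0)).p_value < 0.05
            for _ in range(500)
        )
        assert 0.03 <= hits / 500 <= 0.07

    def test_power_at_strong_interaction(self):
        rng = np.random.default_rng(12)
        hits = sum(
            interaction_model(*self._simulate(rng, 0.8)).p_value < 0.05
            for _ in range(500)
        )
        assert hits / 500 > 0.9

    def test_constant_symptom_dropped(self):
        y = np.random.default_rng(13).normal(size=40)
        g = np.r_[np.zeros(20), np.ones(20)]
        res = interaction_model(y, g, np.full(40, 3.0))
        assert res.dropped and np.isnan(res.p_value)

    def test_small_group_guard(self):
        y = np.zeros(15)
        g = np.r_[np.zeros(5), np.ones(10)]
        with pytest.raises(ValueError, match=">= 10"):
            interaction_model(y, g, y)


class TestReporters:
    @staticmethod
    def _table(rng, effect=1.0):
        rows = []
        for gi, (g, n) in enumerate(
            [("CH", 20), ("SCD", 20), ("eMCI", 15), ("lMCI", 10), ("AD", 10)]
        ):
            for _ in range(n):
                rows.append({"group": g, "m": -effect * gi + rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_ten_pairwise_rows_and_stars(self):
        rng = np.random.default_rng(14)
        rep = gradient_report(self._table(rng), ["m"])
        comp = rep["m"]
        assert len(comp.pairwise) == 10
        assert "AD" in comp.stars_vs_ref

    def test_missing_reference_errors(self):
        df = pd.DataFrame({"group": ["SCD"] * 4, "m": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="reference"):
            gradient_report(df, ["m"])

    def test_null_region_battery_rarely_fdr_positive(self):
        """78 null regions, CH vs SCD: BH yields any rejection in <10% of seeds."""
        n_false = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            df = pd.DataFrame({"group": ["CH"] * 29 + ["SCD"] * 66})
            for r in range(78):
                df[f"r{r}"] = rng.normal(0, 1, 95)
            scan = fdr_scan(df, [f"r{r}" for r in range(78)])
            n_false += scan["significant_fdr"].any()
        assert n_false / 50 < 0.10
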