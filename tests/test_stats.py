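"""Correlation CIs, sub-range scan, linear screens, and group tests."""

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from ueff.stats import (
    fisher_ci,
    fit_linear_models,
    holm_adjust,
    kruskal_wallis_dunn,
    pearson_with_ci,
    simple_linreg,
    subrange_correlation_scan,
)
from ueff.synthetic import generate_cohort, nafld_config


class TestPearsonWithCi:
    def test_matches_scipy_estimate_and_p(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = pearson_with_ci(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.rho == pytest.approx(ref_r, rel=1e-12)
        assert res.p_value == pytest.approx(ref_p, rel=1e-9)

    def test_perfect_linear_degenerate_ci(self):
        x = np.arange(10.0)
        res = pearson_with_ci(x, 2 * x + 1)
        assert res.rho == pytest.approx(1.0)
        assert (res.ci_low, res.ci_high) == (res.rho, res.rho)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci(np.ones(10), np.arange(10.0))

    def test_ci_shrinks_with_n(self):
        widths = []
        for n in (10, 30, 100, 500):
            lo, hi = fisher_ci(0.6, n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance_and_symmetry(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        base = pearson_with_ci(x, y)
        scaled = pearson_with_ci(a * x + b, y)
        swapped = pearson_with_ci(y, x)
        assert scaled.rho == pytest.approx(base.rho, abs=1e-9)
        assert swapped.rho == pytest.approx(base.rho, abs=1e-12)
        assert scaled.ci_low == pytest.approx(base.ci_low, abs=1e-9)


class TestSubrangeScan:
    def test_linear_data_returns_full_range(self, rng):
        x = np.sort(rng.uniform(0, 30, 40))
        y = 2 * x + 1
        res = subrange_correlation_scan(x, y, min_fraction=0.5)
        assert res.range_used == (x.min(), x.max())
        assert res.rho == pytest.approx(1.0)

    def test_min_fraction_one_equals_full_sample(self, rng):
        x = rng.uniform(0, 30, 40)
        y = x + rng.normal(0, 5, 40)
        scan = subrange_correlation_scan(x, y, min_fraction=1.0)
        full = pearson_with_ci(x, y)
        assert scan.rho == pytest.approx(full.rho, rel=1e-12)
        assert scan.n == 40

    def test_detects_knee(self, rng):
        # linear below a knee at 12, flat (saturated) above
        x = np.sort(rng.uniform(0, 30, 120))
        y = np.where(x < 12, x, 12.0) + rng.normal(0, 0.3, 120)
        res = subrange_correlation_scan(x, y, min_fraction=0.5)
        # a few saturated points may enter before they dilute the correlation,
        # so the detected endpoint sits at the knee plus a noise margin
        assert res.range_used[1] <= 18.0
        assert res.rho > pearson_with_ci(x, y).rho

    def test_no_admissible_interval(self):
        with pytest.raises(ValueError):
            subrange_correlation_scan([1.0, 2.0], [1.0, 2.0])


class TestSimpleLinreg:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, p = simple_linreg(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert p < 1e-10

    def test_constant_y(self):
        slope, intercept, p = simple_linreg(np.arange(10.0), np.full(10, 7.0))
        assert slope == 0.0
        assert intercept == pytest.approx(7.0)

    def test_matches_normal_equations(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        slope, intercept, _ = simple_linreg(x, y)
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert intercept == pytest.approx(beta[0], rel=1e-10, abs=1e-12)
        assert slope == pytest.approx(beta[1], rel=1e-10)


class TestLinearScreen:
    def test_noiseless_univariable_recovers_slope(self, rng):
        cohort = generate_cohort(nafld_config(seed=8))
        # overwrite pdff with an exact linear function of ac
        import dataclasses

        from ueff.cohort import Cohort

        recs = [
            dataclasses.replace(r, pdff=3.0 + 2.0 * r.ac) for r in cohort
        ]
        c = Cohort(recs)
        res = fit_linear_models(c)
        row = res.table[(res.table.analysis == "univariable") & (res.table.predictor == "ac")]
        assert row.beta.item() == pytest.approx(2.0, rel=1e-9)
        assert row.adj_r2.item() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_predictor_collinear(self):
        cohort = generate_cohort(nafld_config(seed=8))
        import dataclasses

        from ueff.cohort import Cohort

        recs = [dataclasses.replace(r, bmi=r.ac) for r in cohort]
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_models(Cohort(recs))

    def test_coefficients_match_normal_equations(self):
        cohort = generate_cohort(nafld_config(seed=9))
        res = fit_linear_models(cohort)
        y = cohort.column("pdff")
        X = np.column_stack(
            [np.ones(len(cohort))] + [cohort.column(p) for p in ("ac", "bscd", "ls", "bmi")]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        multi = res.table[res.table.analysis == "multivariable"]
        for i, p in enumerate(("ac", "bscd", "ls", "bmi")):
            assert multi[multi.predictor == p].beta.item() == pytest.approx(
                beta[i + 1], rel=1e-10, abs=1e-10
            )
        # multivariable rows share the joint model's adj R²
        assert multi.adj_r2.nunique() == 1


class TestHolm:
    def test_step_down_with_cummax(self):
        # raw (0.01, 0.04, 0.03): sorted 0.01->0.03, 0.03->0.06, 0.04->max(0.04, 0.06)
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=8)
        _, ref, _, _ = multipletests(p, method="holm")
        assert holm_adjust(p) == pytest.approx(ref, rel=1e-12)

    @given(p=st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=10))
    def test_monotone_and_at_least_raw(self, p):
        adj = holm_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestKruskalWallisDunn:
    def test_all_equal_convention(self):
        res = kruskal_wallis_dunn([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.h == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_h_two_groups(self):
        # ranks 1..6, R1 = 6, R2 = 15 -> H = 12/42*(12+75) - 21 = 27/7
        res = kruskal_wallis_dunn([1.0, 2.0, 3.0, 10.0, 11.0, 12.0], list("aaabbb"))
        assert res.h == pytest.approx(27.0 / 7.0)
        pair = res.pairwise.iloc[0]
        assert pair.p_holm < 0.06
        assert pair.p_holm >= pair.p_raw

    def test_matches_scipy_h(self, rng):
        values = rng.normal(size=30)
        groups = rng.choice(list("abc"), size=30)
        res = kruskal_wallis_dunn(values, groups)
        ref_h, ref_p = sps.kruskal(*[values[groups == g] for g in "abc"])
        assert res.h == pytest.approx(ref_h, rel=1e-12)
        assert res.p_value == pytest.approx(ref_p, rel=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        values = rng.normal(size=40)
        groups = rng.choice(list("abcd"), size=40)
        base = kruskal_wallis_dunn(values, groups)
        trans = kruskal_wallis_dunn(np.exp(values), groups)
        assert trans.h == pytest.approx(base.h, rel=1e-12)
        assert trans.pairwise.z.to_numpy() == pytest.approx(
            base.pairwise.z.to_numpy(), rel=1e-12
        )

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis_dunn([1.0, 2.0, 3.0], ["a", "a", "a"])
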