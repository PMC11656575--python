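"""Composite-null MaxP scan: regressions, mixture correction, FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from cpgmediate.mediation_scan import (
    DegenerateNullError,
    NullProportions,
    UndefinedProportionError,
    bh_fdr,
    corrected_pvalues,
    estimate_null_proportions,
    mediation_scan,
    proportion_mediated_single,
    scan_mediators,
)


def _naive_two_regressions(x, m_col, y, c):
    """Oracle: two independent statsmodels OLS fits for one CpG."""
    d1 = sm.add_constant(np.column_stack([x] + ([c] if c is not None else [])))
    f1 = sm.OLS(m_col, d1).fit()
    d2 = sm.add_constant(
        np.column_stack([x, m_col] + ([c] if c is not None else []))
    )
    f2 = sm.OLS(y, d2).fit()
    return f1.params[1], f1.pvalues[1], f2.params[2], f2.pvalues[2]


class TestScanMediators:
    def test_matches_naive_loop_oracle(self, rng):
        n, j = 120, 50
        x = rng.normal(size=n)
        c = rng.normal(size=(n, 3))
        m = pd.DataFrame(
            rng.uniform(0.2, 0.8, size=(n, j)),
            columns=[f"cg{k:03d}" for k in range(j)],
        )
        y = rng.normal(size=n)
        scan = scan_mediators(x, m, y, pd.DataFrame(c))
        for k in range(j):
            a, pa, b, pb = _naive_two_regressions(x, m.iloc[:, k].to_numpy(), y, c)
            row = scan.iloc[k]
            assert row["alpha_hat"] == pytest.approx(a, abs=1e-10)
            assert row["p_alpha"] == pytest.approx(pa, abs=1e-10)
            assert row["beta_hat"] == pytest.approx(b, abs=1e-10)
            assert row["p_beta"] == pytest.approx(pb, abs=1e-10)

    def test_noiseless_mediator_gives_exact_alpha(self, rng):
        n = 80
        x = rng.normal(size=n)
        m = pd.DataFrame({"cg1": 0.1 * x, "cg2": rng.uniform(size=n)})
        y = rng.normal(size=n)
        scan = scan_mediators(x, m, y)
        assert scan.loc[0, "alpha_hat"] == pytest.approx(0.1, abs=1e-12)
        assert scan.loc[0, "p_alpha"] < 1e-100

    def test_null_pvalues_uniform(self, rng):
        n, j = 100, 5000
        x = rng.normal(size=n)
        m = pd.DataFrame(rng.uniform(size=(n, j)),
                         columns=[f"cg{k}" for k in range(j)])
        y = rng.normal(size=n)
        scan = scan_mediators(x, m, y)
        assert stats.kstest(scan["p_alpha"], "uniform").pvalue > 0.01
        assert stats.kstest(scan["p_beta"], "uniform").pvalue > 0.01

    def test_constant_mediator_flagged_not_fatal(self, rng):
        n = 50
        x = rng.normal(size=n)
        m = pd.DataFrame({"cgA": np.full(n, 0.5), "cgB": rng.uniform(size=n)})
        scan = scan_mediators(x, m, rng.normal(size=n))
        assert bool(scan.loc[0, "degenerate"])
        assert np.isnan(scan.loc[0, "p_alpha"])
        assert not scan.loc[1, "degenerate"]

    def test_invariant_to_column_order_and_covariate_scaling(self, rng):
        n, j = 90, 20
        x = rng.normal(size=n)
        c = pd.DataFrame({"c1": rng.normal(size=n)})
        m = pd.DataFrame(rng.uniform(size=(n, j)),
                         columns=[f"cg{k:02d}" for k in range(j)])
        y = rng.normal(size=n)
        s1 = scan_mediators(x, m, y, c).set_index("cpg_id")
        s2 = scan_mediators(x, m[m.columns[::-1]], y, c * 50 + 3).set_index("cpg_id")
        pd.testing.assert_frame_equal(s1, s2.loc[s1.index], atol=1e-9, rtol=0)


class TestNullProportions:
    def test_complete_null_estimates_pi00_near_one(self, rng):
        j = 10_000
        props = estimate_null_proportions(rng.uniform(size=j), rng.uniform(size=j))
        assert abs(props.pi00 - 1.0) < 0.05
        assert props.pi01 < 0.05 and props.pi10 < 0.05

    def test_constructed_half_alpha_active_mixture(self, rng):
        j = 10_000
        p_alpha = np.concatenate([np.full(j // 2, 1e-12), rng.uniform(size=j // 2)])
        p_beta = rng.uniform(size=j)
        props = estimate_null_proportions(p_alpha, p_beta)
        assert props.pi10 == pytest.approx(0.5, abs=0.05)
        assert props.pi00 == pytest.approx(0.5, abs=0.05)
        assert props.pi01 == pytest.approx(0.0, abs=0.05)

    def test_invariant_to_permutation(self, rng):
        j = 500
        pa, pb = rng.uniform(size=j), rng.uniform(size=j)
        perm = rng.permutation(j)
        p1 = estimate_null_proportions(pa, pb)
        p2 = estimate_null_proportions(pa[perm], pb[perm])
        assert (p1.pi00, p1.pi10, p1.pi01) == (p2.pi00, p2.pi10, p2.pi01)

    def test_too_few_pvalues_raise(self, rng):
        from cpgmediate.mediation_scan import InsufficientDataError
        with pytest.raises(InsufficientDataError):
            estimate_null_proportions(rng.uniform(size=50), rng.uniform(size=50))


class TestCorrectedPvalues:
    @pytest.mark.parametrize(
        "props, t, expected",
        [
            (NullProportions(pi00=1.0, pi10=0.0, pi01=0.0), 0.1, 0.01),
            (NullProportions(pi00=0.0, pi10=0.0, pi01=1.0), 0.1, 0.1),
            (NullProportions(pi00=0.0, pi10=1.0, pi01=0.0), 0.1, 0.1),
            (NullProportions(pi00=0.5, pi10=0.25, pi01=0.25), 0.1, 0.055),
        ],
    )
    def test_mixture_cdf_values(self, props, t, expected):
        out = corrected_pvalues(np.array([t]), props)
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_maxp(self, rng):
        props = NullProportions(pi00=0.8, pi10=0.1, pi01=0.05)
        t = np.sort(rng.uniform(size=200))
        out = corrected_pvalues(t, props)
        assert (np.diff(out) >= 0).all()
        assert ((out > 0) & (out <= 1)).all()

    def test_zero_null_mass_raises(self):
        props = NullProportions(pi00=0.0, pi10=0.0, pi01=0.0)
        with pytest.raises(DegenerateNullError):
            corrected_pvalues(np.array([0.5]), props)


class TestBHFdr:
    def test_hand_computed_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    def test_single_pvalue_unchanged(self):
        assert bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), j=st.integers(2, 200))
    def test_stepup_monotone_and_dominates_p(self, seed, j):
        p = np.sort(np.random.default_rng(seed).uniform(size=j))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestProportionMediated:
    def test_arithmetic(self):
        assert proportion_mediated_single(0.5, 0.4, 1.0) == pytest.approx(0.20)
        assert proportion_mediated_single(0.0, 0.9, 2.0) == 0.0

    def test_zero_total_effect_raises(self):
        with pytest.raises(UndefinedProportionError):
            proportion_mediated_single(0.5, 0.4, 0.0)


class TestFullScan:
    def test_pure_double_null_corrected_p_uniform(self, rng):
        n, j = 200, 4000
        x = rng.normal(size=n)
        m = pd.DataFrame(rng.uniform(size=(n, j)),
                         columns=[f"cg{k}" for k in range(j)])
        y = rng.normal(size=n)
        scan, props = mediation_scan(x, m, y)
        assert props.pi00 > 0.9
        assert stats.kstest(scan["corrected_p"], "uniform").pvalue > 0.01

    def test_strong_single_mediator_detected(self, rng):
        n, j = 400, 300
        x = rng.normal(size=n)
        m = pd.DataFrame(rng.uniform(0.3, 0.7, size=(n, j)),
                         columns=[f"cg{k:03d}" for k in range(j)])
        m["cg000"] = 0.5 + 0.05 * x + rng.normal(0, 0.01, n)
        y = 5.0 * m["cg000"].to_numpy() + rng.normal(0, 0.3, n)
        scan, _ = mediation_scan(x, m, y, total_effect=0.25)
        row = scan.set_index("cpg_id").loc["cg000"]
        assert bool(row["significant"])
        assert row["proportion_mediated"] == pytest.approx(
            row["alpha_hat"] * row["beta_hat"] / 0.25
        )
        assert scan["significant"].sum() <= 3
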