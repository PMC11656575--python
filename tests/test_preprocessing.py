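"""Methylation and outcome preprocessing rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cpgmediate import preprocessing as pp
from cpgmediate import SimulationConfig, generate_methylation


class TestMeanImpute:
    def test_mean_of_observed_fills_missing(self):
        m = pd.DataFrame({"cg1": [0.2, np.nan, 0.4]})
        out = pp.mean_impute(m)
        np.testing.assert_allclose(out["cg1"], [0.2, 0.3, 0.4])

    def test_no_missing_is_identity(self):
        m = pd.DataFrame({"cg1": [0.1, 0.2], "cg2": [0.5, 0.6]})
        pd.testing.assert_frame_equal(pp.mean_impute(m), m)

    def test_column_mean_preserved(self, rng):
        vals = rng.uniform(0, 1, size=50)
        vals[rng.choice(50, 10, replace=False)] = np.nan
        m = pd.DataFrame({"cg1": vals})
        out = pp.mean_impute(m)
        assert out["cg1"].mean() == pytest.approx(np.nanmean(vals))

    def test_all_missing_column_raises(self):
        with pytest.raises(pp.UnprocessableColumnError):
            pp.mean_impute(pd.DataFrame({"cg1": [np.nan, np.nan]}))


class TestWinsorize:
    def test_zero_iqr_collapses_to_constant(self):
        v = np.array([0.5] * 10 + [0.1, 0.9])
        out = pp.winsorize_3iqr(v)
        np.testing.assert_allclose(out, 0.5)

    def test_outlier_clamped_to_hand_computed_fence(self, rng):
        v = np.concatenate([rng.uniform(0.4, 0.6, 99), [0.99]])
        q1, q3 = np.quantile(v, [0.25, 0.75])  # type-7, matches implementation
        hi = q3 + 3 * (q3 - q1)
        out = pp.winsorize_3iqr(v)
        assert out[-1] == pytest.approx(hi)
        np.testing.assert_allclose(out[:-1], v[:-1])

    def test_within_fence_vector_unchanged(self, rng):
        v = rng.uniform(0.3, 0.7, 50)
        np.testing.assert_array_equal(pp.winsorize_3iqr(v), v)

    def test_too_short_vector_raises(self):
        with pytest.raises(pp.DegenerateInputError):
            pp.winsorize_3iqr(np.array([0.1, 0.2, 0.3]))

    def test_matrix_version_matches_columnwise(self, rng):
        m = pd.DataFrame(rng.uniform(0, 1, size=(30, 4)),
                         columns=[f"cg{i}" for i in range(4)])
        out = pp.winsorize_matrix(m)
        for c in m.columns:
            np.testing.assert_allclose(out[c], pp.winsorize_3iqr(m[c].to_numpy()))


class TestResidualize:
    @pytest.fixture()
    def study(self):
        cfg = SimulationConfig(n_participants=150, n_mediators=30,
                               cell_effect_scale=0.3, seed=12)
        x = cfg.rng(9).standard_normal(150)
        meth, cells, _ = generate_methylation(cfg, x)
        return meth, cells

    def test_residuals_orthogonal_to_cell_proportions(self, study):
        meth, cells = study
        out = pp.residualize_methylation(meth, cells)
        vals = out.drop(columns=["plate", "position_row", "position_col"])
        for cell in cells.columns[:-1]:
            r = np.corrcoef(vals.T, cells[cell])[-1, :-1]
            assert np.max(np.abs(r)) < 1e-10

    def test_plate_mean_shift_absorbed(self, rng):
        n = 80
        plate = pd.Series(["A"] * 40 + ["B"] * 40)
        base = rng.normal(0.5, 0.02, n)
        m = pd.DataFrame({"cg1": base + np.where(plate == "A", 0.0, 0.3)})
        c1 = rng.uniform(0.2, 0.4, n)
        cells = pd.DataFrame({"c1": c1, "c2": 1 - c1})
        out = pp.residualize_methylation(m, cells, plate=plate)
        resid = out["cg1"]
        assert resid[plate == "A"].mean() == pytest.approx(
            resid[plate == "B"].mean(), abs=1e-10
        )

    def test_constant_cell_proportions_only_recenter(self, rng):
        n = 40
        m = pd.DataFrame({"cg1": rng.uniform(0.4, 0.6, n)})
        cells = pd.DataFrame({"c1": np.full(n, 0.25), "c2": np.full(n, 0.75)})
        with pytest.raises(pp.CollinearityError):
            # constant proportions duplicate the intercept
            pp.residualize_methylation(m, cells)

    def test_refit_on_same_design_gives_zero_coefficients(self, study):
        meth, cells = study
        out = pp.residualize_methylation(meth, cells)
        vals = out.drop(columns=["plate", "position_row", "position_col"]).to_numpy()
        d = np.column_stack([np.ones(len(vals)), cells.to_numpy()[:, :-1]])
        coef, *_ = np.linalg.lstsq(d, vals, rcond=None)
        assert np.max(np.abs(coef[1:])) < 1e-8

    def test_idempotent(self, study):
        meth, cells = study
        once = pp.residualize_methylation(meth, cells)
        twice = pp.residualize_methylation(once, cells)
        pd.testing.assert_frame_equal(once, twice, atol=1e-10, rtol=0)


class TestOutcomeOutliers:
    def test_no_outliers_no_exclusions(self, rng):
        v = pd.Series(rng.normal(100, 5, 50), index=[f"P{i}" for i in range(50)])
        kept, audit = pp.remove_outcome_outliers(v)
        assert audit.empty
        pd.testing.assert_series_equal(kept, v)

    def test_injected_extreme_value_excluded(self, rng):
        idx = [f"P{i}" for i in range(51)]
        v = pd.Series(np.append(rng.normal(100, 5, 50), 1000.0), index=idx)
        kept, audit = pp.remove_outcome_outliers(v)
        assert len(audit) == 1
        assert audit["participant_id"].iloc[0] == "P50"
        assert np.isnan(kept.iloc[-1])

    def test_exclusion_count_affine_invariant(self, rng):
        v = pd.Series(np.append(rng.normal(0, 1, 60), [15.0, -12.0]))
        _, audit1 = pp.remove_outcome_outliers(v)
        _, audit2 = pp.remove_outcome_outliers(v * 3.7 - 42.0)
        assert len(audit1) == len(audit2) > 0


class TestMedicationAdjustment:
    @pytest.fixture()
    def flags(self):
        return pd.DataFrame(
            {
                "antihypertensive_med": [True, False],
                "statin_med": [True, False],
                "diabetes_med": [True, False],
            }
        )

    @pytest.mark.parametrize(
        "outcome, raw, expected_on, expected_off",
        [
            ("SBP", 120.0, 135.0, 120.0),
            ("DBP", 80.0, 90.0, 80.0),
            ("LDL-C", 70.0, 100.0, 70.0),
            ("TC", 160.0, 200.0, 160.0),
            ("HDL-C", 55.0, 55.0, 55.0),
            ("TG", 140.0, 140.0, 140.0),
            ("BMI", 30.0, 30.0, 30.0),
        ],
    )
    def test_adjustment_rules(self, flags, outcome, raw, expected_on, expected_off):
        out = pp.adjust_medication(outcome, pd.Series([raw, raw]), flags)
        assert out["adjusted"].iloc[0] == pytest.approx(expected_on)
        assert out["adjusted"].iloc[1] == pytest.approx(expected_off)
        assert not out["excluded"].any()

    def test_glucose_excluded_not_adjusted_under_diabetes_meds(self, flags):
        out = pp.adjust_medication("glucose", pd.Series([110.0, 110.0]), flags)
        assert bool(out["excluded"].iloc[0])
        assert np.isnan(out["adjusted"].iloc[0])
        assert out["adjusted"].iloc[1] == pytest.approx(110.0)
        assert out["exclusion_reason"].iloc[0] == "diabetes_medication"

    def test_unknown_outcome_raises(self, flags):
        with pytest.raises(pp.SchemaError):
            pp.adjust_medication("ferritin", pd.Series([1.0, 2.0]), flags)


class TestLogTransform:
    def test_log_outcomes(self):
        assert pp.log_transform("CRP", pd.Series([1.0])).iloc[0] == pytest.approx(0.0)
        assert pp.log_transform("glucose", pd.Series([np.e**2])).iloc[0] == pytest.approx(2.0)

    def test_untransformed_outcome_identity(self):
        v = pd.Series([30.0])
        pd.testing.assert_series_equal(pp.log_transform("BMI", v), v)

    def test_nonpositive_value_raises_with_ids(self):
        v = pd.Series([1.0, -2.0], index=["P1", "P2"])
        with pytest.raises(pp.DomainError, match="P2"):
            pp.log_transform("CRP", v)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_winsorization_preserves_order_statistics(seed):
    v = np.random.default_rng(seed).normal(size=40)
    out = pp.winsorize_3iqr(v)
    assert (np.argsort(np.argsort(out)) == np.argsort(np.argsort(v))).all() or (
        # ties introduced at the fences are allowed; check monotonicity instead
        np.all(np.diff(out[np.argsort(v)]) >= -1e-12)
    )
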