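"""Index formulas: worked examples, properties, and missingness rules."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from irindices import (
    bmi,
    compute_panel,
    friedewald,
    glucose_mgdl_to_mmol,
    homa_ir,
    lap,
    ratios,
    tg_hdl_ratio,
    tyg,
)
from irindices.indices import InsulinResistanceIndices

from conftest import random_cohort_frame


class TestScalarFormulas:
    @pytest.mark.parametrize(
        "fpg, expected",
        [(90.0, 5.0), (0.0, 0.0), (100.298, 5.5721)],
    )
    def test_glucose_conversion(self, fpg, expected):
        assert glucose_mgdl_to_mmol(fpg) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "insulin, fpg, expected",
        [(10.0, 90.0, 2.2222), (0.0, 123.0, 0.0), (9.4, 100.298, 2.3279)],
    )
    def test_homa_ir(self, insulin, fpg, expected):
        assert homa_ir(insulin, fpg) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "tg, fpg, expected",
        [(150.0, 100.0, 4.8079), (1.0, 1.0, 0.0), (107.92, 81.99, 4.5440)],
    )
    def test_tyg(self, tg, fpg, expected):
        assert tyg(tg, fpg) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "tg, hdl, expected",
        [(150.0, 50.0, 3.0), (0.0, 40.0, 0.0), (170.79, 34.51, 4.949)],
    )
    def test_tg_hdl(self, tg, hdl, expected):
        assert tg_hdl_ratio(tg, hdl) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "sex, waist, tg, expected",
        [
            ("M", 65.0, 123.0, 0.0),
            ("F", 58.0, 88.0, 0.0),
            ("M", 95.0, 177.14, 60.00),
            ("F", 80.78, 107.92, 27.76),
        ],
    )
    def test_lap(self, sex, waist, tg, expected):
        assert lap(sex, waist, tg) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize(
        "weight, height, expected",
        [(80.0, 160.0, 31.25), (64.807, 167.607, 23.07), (0.0, 170.0, 0.0)],
    )
    def test_bmi(self, weight, height, expected):
        assert bmi(weight, height) == pytest.approx(expected, abs=5e-3)

    def test_ratios(self):
        assert ratios(80.0, 100.0, 160.0) == pytest.approx((0.8, 0.5))
        whr, _ = ratios(86.843, 91.514, 160.0)
        assert whr == pytest.approx(0.949, abs=5e-4)
        assert ratios(90.0, 90.0, 170.0)[0] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "tc, hdl, tg, ldl, vldl",
        [(200.0, 50.0, 150.0, 120.0, 30.0), (55.0, 55.0, 0.0, 0.0, 0.0), (188.33, 40.0, 170.79, None, 34.158)],
    )
    def test_friedewald(self, tc, hdl, tg, ldl, vldl):
        got_ldl, got_vldl = friedewald(tc, hdl, tg)
        assert got_vldl == pytest.approx(vldl, abs=5e-3)
        if ldl is not None:
            assert got_ldl == pytest.approx(ldl, abs=5e-3)

    def test_friedewald_invalid_above_tg_limit(self):
        ldl, vldl = friedewald(250.0, 40.0, 450.0)
        assert np.isnan(ldl) and vldl == pytest.approx(90.0)

    @pytest.mark.parametrize(
        "fn, args",
        [
            (glucose_mgdl_to_mmol, (-1.0,)),
            (homa_ir, (-2.0, 90.0)),
            (tyg, (0.0, 90.0)),
            (tyg, (100.0, -1.0)),
            (tg_hdl_ratio, (100.0, 0.0)),
            (lap, ("M", 0.0, 100.0)),
            (bmi, (70.0, 0.0)),
            (ratios, (80.0, 0.0, 160.0)),
            (friedewald, (200.0, -1.0, 100.0)),
        ],
    )
    def test_domain_errors(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


class TestProperties:
    @given(
        insulin=st.floats(0.1, 100), fpg=st.floats(1, 400), k=st.floats(1.01, 10)
    )
    def test_homa_ir_bilinear(self, insulin, fpg, k):
        base = homa_ir(insulin, fpg)
        assert homa_ir(k * insulin, fpg) == pytest.approx(k * base, rel=1e-12)
        assert homa_ir(insulin, k * fpg) == pytest.approx(k * base, rel=1e-12)

    @given(tg=st.floats(1, 500), fpg=st.floats(1, 400), a=st.floats(0.1, 10))
    def test_tyg_log_product_identity(self, tg, fpg, a):
        assert tyg(a * tg, fpg / a) == pytest.approx(tyg(tg, fpg), abs=1e-9)

    @given(tg=st.floats(1, 500), fpg=st.floats(1, 400))
    def test_tyg_increasing(self, tg, fpg):
        assert tyg(tg * 1.1, fpg) > tyg(tg, fpg)
        assert tyg(tg, fpg * 1.1) > tyg(tg, fpg)

    @given(waist=st.floats(66, 150), tg=st.floats(1, 500), sex=st.sampled_from(["M", "F"]))
    def test_lap_monotone_above_offset(self, waist, tg, sex):
        assert lap(sex, waist + 1.0, tg) > lap(sex, waist, tg)
        assert lap(sex, waist, tg * 1.1) > lap(sex, waist, tg)
        offset = 65.0 if sex == "M" else 58.0
        assert lap(sex, offset, tg) == 0.0


def _panel_oracle_row(row) -> dict:
    """Single-formula recomputation, written independently of the transformer."""
    h = row.height_cm / 100.0
    out = {
        "bmi": row.weight_kg / h**2,
        "whr": row.waist_cm / row.hip_cm,
        "whtr": row.waist_cm / row.height_cm,
        "homa_ir": row.insulin_uiu_ml * row.fpg_mgdl / 18.0 / 22.5,
        "tyg": np.log(row.tg_mgdl * row.fpg_mgdl) / 2.0,
        "tg_hdl": row.tg_mgdl / row.hdl_mgdl,
    }
    offset = 65.0 if row.sex == "M" else 58.0
    out["lap"] = (row.waist_cm - offset) * row.tg_mgdl / 88.57
    out["vldl_derived"] = row.tg_mgdl / 5.0
    out["ldl_derived"] = (
        row.tc_mgdl - row.hdl_mgdl - row.tg_mgdl / 5.0 if row.tg_mgdl < 400 else np.nan
    )
    return out


class TestPanel:
    def test_panel_matches_single_formula_oracle(self):
        rng = np.random.default_rng(42)
        cohort = random_cohort_frame(rng, 1000)
        panel = compute_panel(cohort)
        oracle = pd.DataFrame([_panel_oracle_row(r) for r in cohort.itertuples()])
        for col in oracle.columns:
            np.testing.assert_allclose(
                panel[col].to_numpy(), oracle[col].to_numpy(), atol=1e-9, err_msg=col
            )

    def test_group_mean_vectors_land_near_published_group_means(self):
        """Indices of group-mean inputs track the group means of the indices.

        A calibration smoke test, not an identity: means of nonlinear
        functions differ from functions of means, so 10% slack.
        """
        # (insulin, fpg, tg, hdl, waist/sex) group-mean inputs vs the
        # published group-level HOMA-IR / TyG / VLDL / LAP means
        mets = {"homa": homa_ir(9.4, 100.298), "tyg": tyg(170.79, 100.298),
                "vldl": friedewald(188.33, 40.0, 170.79)[1], "lap": lap("M", 95.29, 170.79)}
        non = {"homa": homa_ir(4.86, 81.99), "tyg": tyg(107.92, 81.99),
               "vldl": friedewald(160.33, 40.0, 107.92)[1], "lap": lap("F", 80.78, 107.92)}
        published_mets = {"homa": 2.32, "tyg": 4.83, "vldl": 34.15, "lap": 61.91}
        published_non = {"homa": 0.99, "tyg": 4.51, "vldl": 21.58, "lap": 26.2}
        for key in mets:
            assert mets[key] == pytest.approx(published_mets[key], rel=0.10)
            assert non[key] == pytest.approx(published_non[key], rel=0.10)

    def test_missingness_propagates_not_zero(self):
        rng = np.random.default_rng(0)
        cohort = random_cohort_frame(rng, 3)
        cohort["tg_mgdl"] = [100.0, 150.0, 200.0]  # keep Friedewald valid
        cohort.loc[1, "hdl_mgdl"] = np.nan
        panel = compute_panel(cohort)
        assert np.isnan(panel.loc[1, "tg_hdl"])
        assert np.isnan(panel.loc[1, "ldl_derived"])
        for col in ("bmi", "whr", "homa_ir", "tyg", "lap", "vldl_derived"):
            assert np.isfinite(panel.loc[1, col])
        assert panel.drop(index=1).notna().all().all()

    def test_measured_ldl_preferred_over_friedewald(self):
        rng = np.random.default_rng(1)
        cohort = random_cohort_frame(rng, 2)
        cohort.loc[0, "ldl_mgdl"] = 123.0
        panel = compute_panel(cohort)
        assert panel.loc[0, "ldl_derived"] == 123.0

    def test_transformer_is_sklearn_compatible(self):
        from sklearn.base import clone

        est = InsulinResistanceIndices(glucose_divisor=18.016)
        assert clone(est).get_params()["glucose_divisor"] == 18.016
        cohort = random_cohort_frame(np.random.default_rng(2), 5)
        panel = est.fit(cohort).transform(cohort)
        assert list(panel.columns)[:4] == ["bmi", "whr", "whtr", "homa_ir"]

    def test_missing_required_column_raises(self):
        cohort = random_cohort_frame(np.random.default_rng(3), 4).drop(columns=["hdl_mgdl"])
        with pytest.raises(ValueError, match="hdl_mgdl"):
            compute_panel(cohort)
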