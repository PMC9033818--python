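import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoplex.errors import DegenerateModelError, InsufficientControlsError
from mitoplex.mrc import (
    CategoryThresholds,
    ControlModel,
    classify_cells,
    compute_zscores,
    fit_control_model,
    score_cells,
    select_controls,
)
from mitoplex.simgen import ImageConfig, SimConfig, simulate_cell_population


def model_from_config(cfg: SimConfig, n: int = 0) -> ControlModel:
    return ControlModel(
        mu_T=cfg.mu_T, sd_T=cfg.sd_T,
        intercept_N=cfg.intercept_N, slope_N=cfg.slope_N, resid_sd_N=cfg.resid_sd_N,
        intercept_M=cfg.intercept_M, slope_M=cfg.slope_M, resid_sd_M=cfg.resid_sd_M,
        n_control=n,
    )


def cells_table(od_n, od_m, od_t):
    n = len(np.atleast_1d(od_n))
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "od_ndufb8": od_n,
            "od_mtco1": od_m,
            "od_tomm20": od_t,
        }
    )


class TestFitControlModel:
    def test_parameter_recovery_within_3se(self, control_cells):
        cells, cfg = control_cells
        n = 5000
        sub = cells.iloc[:n]
        model = fit_control_model(sub)
        # independent oracle: statsmodels OLS standard errors
        log_t = np.log10(sub["od_tomm20"])
        for dep, slope, intercept, resid_sd in (
            ("od_ndufb8", cfg.slope_N, cfg.intercept_N, cfg.resid_sd_N),
            ("od_mtco1", cfg.slope_M, cfg.intercept_M, cfg.resid_sd_M),
        ):
            fit = sm.OLS(np.log10(sub[dep]), sm.add_constant(log_t)).fit()
            se_int, se_slope = fit.bse
            m = "N" if dep == "od_ndufb8" else "M"
            assert abs(getattr(model, f"slope_{m}") - slope) <= 3 * se_slope
            assert abs(getattr(model, f"intercept_{m}") - intercept) <= 3 * se_int
            assert abs(getattr(model, f"resid_sd_{m}") - resid_sd) <= 0.1 * resid_sd
        assert abs(model.mu_T - cfg.mu_T) <= 3 * cfg.sd_T / np.sqrt(n)
        assert abs(model.sd_T - cfg.sd_T) <= 0.1 * cfg.sd_T

    def test_matches_statsmodels_exactly(self, control_cells):
        cells, _ = control_cells
        sub = cells.iloc[:2000]
        model = fit_control_model(sub)
        log_t = np.log10(sub["od_tomm20"])
        fit = sm.OLS(np.log10(sub["od_ndufb8"]), sm.add_constant(log_t)).fit()
        assert model.intercept_N == pytest.approx(fit.params.iloc[0], abs=1e-10)
        assert model.slope_N == pytest.approx(fit.params.iloc[1], abs=1e-10)
        assert model.resid_sd_N == pytest.approx(
            np.sqrt(fit.ssr / (len(sub) - 2)), abs=1e-10
        )

    def test_collinear_controls_degenerate(self):
        t = np.linspace(10, 100, 200)
        cells = cells_table(2.0 * t, 3.0 * t, t)  # exact log-log lines
        with pytest.raises(DegenerateModelError):
            fit_control_model(cells)

    def test_insufficient_controls(self):
        rng = np.random.default_rng(0)
        cells = cells_table(*rng.uniform(1, 10, (3, 99)))
        with pytest.raises(InsufficientControlsError):
            fit_control_model(cells, min_n=100)

    def test_nonpositive_ods_excluded(self):
        rng = np.random.default_rng(1)
        od = rng.uniform(1, 10, (3, 300))
        cells = cells_table(*od)
        cells.loc[:49, "od_ndufb8"] = 0.0
        model = fit_control_model(cells, min_n=100)
        assert model.n_control == 250

    def test_select_controls_filters_group_and_tissue(self, control_cells):
        cells, _ = control_cells
        cells = cells.copy()
        cells.loc[cells.index[:10], "tissue_class"] = "stromal"
        cells.loc[cells.index[10:20], "group"] = "tumour"
        sel = select_controls(cells)
        assert len(sel) == len(cells) - 20


class TestComputeZscores:
    def test_cell_on_both_lines_zero_z(self):
        model = ControlModel(2.0, 0.2, 0.5, 0.9, 0.05, 0.3, 0.95, 0.06, 100)
        od_t = 10.0**2.0
        od_n = 10.0 ** (0.5 + 0.9 * 2.0)
        od_m = 10.0 ** (0.3 + 0.95 * 2.0)
        z = compute_zscores(cells_table([od_n], [od_m], [od_t]), model)
        assert z["z_tomm20"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert z["z_ndufb8"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert z["z_mtco1"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_tomm20_arithmetic(self):
        model = ControlModel(2.0, 0.2, 0.5, 0.9, 0.05, 0.3, 0.95, 0.06, 100)
        z = compute_zscores(cells_table([1.0], [1.0], [10.0**2.4]), model)
        assert z["z_tomm20"].iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_self_scoring_standardised(self):
        cfg = SimConfig(
            seed=21,
            groups=("young_benign",),
            n_patients_per_group=1,
            rois_per_patient=1,
            cells_per_roi=10_000,
            stromal_fraction=0.0,
            deficiency_fractions={"young_benign": {}},
            image=ImageConfig(height=1200, width=1200),
        )
        cells, _ = simulate_cell_population(cfg)
        model = fit_control_model(cells)
        z = compute_zscores(cells, model)
        for col in ("z_ndufb8", "z_mtco1", "z_tomm20"):
            assert abs(z[col].mean()) <= 0.02
            assert abs(z[col].std(ddof=1) - 1.0) <= 0.02

    def test_drop_policy_counts(self):
        model = ControlModel(2.0, 0.2, 0.5, 0.9, 0.05, 0.3, 0.95, 0.06, 100)
        cells = cells_table([1.0, 0.0, 2.0], [1.0, 1.0, -1.0], [5.0, 5.0, 5.0])
        z = compute_zscores(cells, model, exclusion_policy="drop")
        assert len(z) == 1
        assert z.attrs["n_excluded"] == 2

    def test_floor_policy_keeps_all(self):
        model = ControlModel(2.0, 0.2, 0.5, 0.9, 0.05, 0.3, 0.95, 0.06, 100)
        cells = cells_table([1.0, 0.0], [1.0, 1.0], [5.0, 5.0])
        z = compute_zscores(cells, model, exclusion_policy="floor", floor_epsilon=1e-6)
        assert len(z) == 2
        assert np.isfinite(z["z_ndufb8"]).all()

    def test_monotonic_in_od_n(self):
        model = ControlModel(2.0, 0.2, 0.5, 0.9, 0.05, 0.3, 0.95, 0.06, 100)
        od_n = np.linspace(0.5, 50, 100)
        z = compute_zscores(
            cells_table(od_n, np.full(100, 5.0), np.full(100, 50.0)), model
        )
        assert (np.diff(z["z_ndufb8"]) > 0).all()


class TestClassifyCells:
    def zrec(self, z_n=0.0, z_m=0.0, z_t=0.0):
        return pd.DataFrame(
            {"cell_id": ["c"], "z_ndufb8": [z_n], "z_mtco1": [z_m], "z_tomm20": [z_t]}
        )

    @pytest.mark.parametrize(
        "z, cat, deficient",
        [
            (-6.5, "very_low", True),
            (-6.0, "low", True),  # very_low is strict z < -6
            (-4.0, "low", True),
            (-3.0, "normal", False),  # deficiency strict z < -3
            (-2.9999999, "normal", False),
            (0.0, "normal", False),
            (3.0, "normal", False),
            (3.0000001, "high", False),
        ],
    )
    def test_ndufb8_categories(self, z, cat, deficient):
        out = classify_cells(self.zrec(z_n=z))
        assert out["cat_ndufb8"].iloc[0] == cat
        assert bool(out["deficient_ndufb8"].iloc[0]) is deficient

    @pytest.mark.parametrize(
        "z, cat",
        [(-2.5, "low"), (-2.0, "normal"), (2.0, "normal"), (2.5, "high")],
    )
    def test_tomm20_categories(self, z, cat):
        out = classify_cells(self.zrec(z_t=z))
        assert out["cat_tomm20"].iloc[0] == cat

    def test_exhaustive_boundary_sweep_partition(self):
        eps = 1e-9
        zs = np.array(
            [s * b + d for b in (0.0, 2.0, 3.0, 6.0) for s in (-1, 1) for d in (-eps, 0.0, eps)]
        )
        frame = pd.DataFrame({"z_ndufb8": zs, "z_mtco1": zs, "z_tomm20": zs})
        out = classify_cells(frame)
        assert set(out["cat_ndufb8"]) <= {"very_low", "low", "normal", "high"}
        assert set(out["cat_tomm20"]) <= {"low", "normal", "high"}
        # each z gets exactly one category; spot-check the boundary policy
        by_z = dict(zip(zs, out["cat_ndufb8"]))
        assert by_z[-6.0 - eps] == "very_low"
        assert by_z[-6.0] == "low"
        assert by_z[-3.0] == "normal"
        assert by_z[-3.0 - eps] == "low"
        assert by_z[3.0] == "normal"
        assert by_z[3.0 + eps] == "high"
        by_z_t = dict(zip(zs, out["cat_tomm20"]))
        assert by_z_t[-2.0 - eps] == "low"
        assert by_z_t[-2.0] == "normal"
        assert by_z_t[2.0] == "normal"
        assert by_z_t[2.0 + eps] == "high"

    @given(z=st.floats(min_value=-50, max_value=50, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_category_partition_property(self, z):
        out = classify_cells(self.zrec(z_n=z, z_m=z, z_t=z))
        assert out["cat_ndufb8"].iloc[0] in {"very_low", "low", "normal", "high"}
        assert out["cat_mtco1"].iloc[0] in {"very_low", "low", "normal", "high"}
        assert out["cat_tomm20"].iloc[0] in {"low", "normal", "high"}
        assert bool(out["deficient_ndufb8"].iloc[0]) == (z < -3)

    def test_nonfinite_flagged_invalid(self):
        out = classify_cells(self.zrec(z_n=np.nan))
        assert out["cat_ndufb8"].iloc[0] == "invalid"
        assert not out["valid"].iloc[0]
        assert out.attrs["n_invalid"] == 1
        assert not out["deficient_ndufb8"].iloc[0]

    def test_custom_thresholds(self):
        t = CategoryThresholds(low=-2.0, deficient=-2.0)
        out = classify_cells(self.zrec(z_n=-2.5), t)
        assert out["cat_ndufb8"].iloc[0] == "low"
        assert out["deficient_ndufb8"].iloc[0]


class TestPhenotypeRecovery:
    def test_planted_deficiency_sensitivity_and_fpr(self):
        cfg = SimConfig(
            seed=33,
            groups=("young_benign", "tumour"),
            n_patients_per_group=1,
            rois_per_patient=1,
            cells_per_roi=8000,
            stromal_fraction=0.0,
            deficiency_fractions={
                "young_benign": {},
                "tumour": {"ndufb8": 0.2},
            },
            deficiency_shift=5.0,
            image=ImageConfig(height=1100, width=1100),
        )
        cells, truth = simulate_cell_population(cfg)
        z, _ = score_cells(cells)
        merged = z.merge(truth[["cell_id", "phenotype"]], on="cell_id")
        planted = merged["phenotype"] == "ndufb8_deficient"
        assert planted.sum() > 500
        sens = merged.loc[planted, "deficient_ndufb8"].mean()
        fpr_other = merged.loc[planted, "deficient_mtco1"].mean()
        assert sens >= 0.95
        assert fpr_other <= 0.01

    def test_control_tail_matches_normal(self):
        n = 100_000
        cfg = SimConfig(
            seed=44,
            groups=("young_benign",),
            n_patients_per_group=1,
            rois_per_patient=1,
            cells_per_roi=n,
            stromal_fraction=0.0,
            deficiency_fractions={"young_benign": {}},
            image=ImageConfig(height=3000, width=3000),
        )
        cells, _ = simulate_cell_population(cfg)
        model = model_from_config(cfg, n)
        z = classify_cells(compute_zscores(cells, model))
        from scipy.stats import norm

        p = norm.cdf(-3)
        bound = 3 * np.sqrt(p * (1 - p) / n)
        for marker in ("ndufb8", "mtco1"):
            frac = z[f"deficient_{marker}"].mean()
            assert abs(frac - p) <= bound


class TestModelSerialisation:
    def test_yaml_round_trip(self, tmp_path):
        model = ControlModel(2.0, 0.2, 0.5, 0.9, 0.05, 0.3, 0.95, 0.06, 1234)
        p = tmp_path / "model.yaml"
        model.to_yaml(p)
        assert ControlModel.from_yaml(p) == model

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateModelError):
            ControlModel(2.0, 0.0, 0.5, 0.9, 0.05, 0.3, 0.95, 0.06, 10)
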