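"""Control-cohort model fitting, per-cell Z-scores and abundance categories.

The control model is fitted on epithelial cells from young-benign patients:
log10-NDUFB8 and log10-MTCO1 are each regressed on log10-TOMM20 by ordinary
least squares, and the mean/SD of log10-TOMM20 is recorded. A cell's Z-score
is its deviation from the control expectation in SD units:

    z_tomm20 = (log10 OD_T - mu_T) / sd_T
    z_ndufb8 = (log10 OD_N - (intercept_N + slope_N * log10 OD_T)) / resid_sd_N
    z_mtco1  = (log10 OD_M - (intercept_M + slope_M * log10 OD_T)) / resid_sd_M

Categories (NDUFB8/MTCO1): very_low z < -6; low -6 <= z < -3;
normal -3 <= z <= 3; high z > 3. TOMM20: low z < -2; normal -2 <= z <= 2;
high z > 2. A cell is deficient in a marker iff z < -3 (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mitoplex.errors import (
    ConfigurationError,
    DegenerateModelError,
    InsufficientControlsError,
)
from mitoplex.panel import MITO_MARKERS

logger = logging.getLogger(__name__)

CONTROL_GROUP = "young_benign"
_EPS_SD = 1e-12


@dataclass
class ControlModel:
    """Parameters of the pooled control cohort."""

    mu_T: float
    sd_T: float
    intercept_N: float
    slope_N: float
    resid_sd_N: float
    intercept_M: float
    slope_M: float
    resid_sd_M: float
    n_control: int

    def __post_init__(self) -> None:
        for f in (
            "mu_T", "sd_T", "intercept_N", "slope_N", "resid_sd_N",
            "intercept_M", "slope_M", "resid_sd_M",
        ):
            setattr(self, f, float(getattr(self, f)))
        self.n_control = int(self.n_control)
        if self.sd_T <= _EPS_SD or self.resid_sd_N <= _EPS_SD or self.resid_sd_M <= _EPS_SD:
            raise DegenerateModelError(
                "control model has (near) zero spread in at least one marker"
            )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ControlModel":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class CategoryThresholds:
    """Z-score category boundaries (SD units)."""

    very_low: float = -6.0
    low: float = -3.0
    high: float = 3.0
    tomm20_low: float = -2.0
    tomm20_high: float = 2.0
    deficient: float = -3.0


def select_controls(cells: pd.DataFrame, control_group: str = CONTROL_GROUP) -> pd.DataFrame:
    """Epithelial cells from the control patient group."""
    sel = cells["group"] == control_group
    if "tissue_class" in cells.columns:
        sel &= cells["tissue_class"] == "epithelial"
    return cells.loc[sel]


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and residual SD (n-2 denominator) of y ~ x."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx <= _EPS_SD:
        raise DegenerateModelError("regressor log10-TOMM20 has zero variance")
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    resid_sd = float(np.sqrt((resid**2).sum() / (n - 2)))
    return slope, intercept, resid_sd


def fit_control_model(control_cells: pd.DataFrame, min_n: int = 100) -> ControlModel:
    """Fit the control model by OLS on log10-transformed ODs.

    Cells with any nonpositive marker OD are excluded before the transform;
    the exclusion count is logged. Raises if fewer than ``min_n`` usable
    cells remain, or if any fitted spread is (near) zero.
    """
    od = control_cells[["od_ndufb8", "od_mtco1", "od_tomm20"]].to_numpy(dtype=float)
    usable = np.isfinite(od).all(axis=1) & (od > 0).all(axis=1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("fit_control_model: excluded %d cells with nonpositive ODs", n_dropped)
    od = od[usable]
    n = len(od)
    if n < min_n:
        raise InsufficientControlsError(
            f"{n} usable control cells, need at least {min_n}"
        )
    log_n, log_m, log_t = np.log10(od[:, 0]), np.log10(od[:, 1]), np.log10(od[:, 2])
    mu_t = float(log_t.mean())
    sd_t = float(log_t.std(ddof=1))
    slope_n, intercept_n, resid_sd_n = _ols(log_t, log_n)
    slope_m, intercept_m, resid_sd_m = _ols(log_t, log_m)
    return ControlModel(
        mu_T=mu_t,
        sd_T=sd_t,
        intercept_N=intercept_n,
        slope_N=slope_n,
        resid_sd_N=resid_sd_n,
        intercept_M=intercept_m,
        slope_M=slope_m,
        resid_sd_M=resid_sd_m,
        n_control=n,
    )


def compute_zscores(
    cells: pd.DataFrame,
    model: ControlModel,
    exclusion_policy: str = "drop",
    floor_epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Per-cell Z-scores for the three mitochondrial markers.

    ``exclusion_policy`` controls cells with nonpositive ODs: "drop" removes
    them (count recorded in ``result.attrs['n_excluded']``), "floor" replaces
    nonpositive ODs by ``floor_epsilon`` before the log transform.
    """
    if exclusion_policy not in ("drop", "floor"):
        raise ConfigurationError(f"unknown exclusion_policy {exclusion_policy!r}")
    od = cells[["od_ndufb8", "od_mtco1", "od_tomm20"]].to_numpy(dtype=float)
    bad = ~(np.isfinite(od).all(axis=1) & (od > 0).all(axis=1))
    n_excluded = 0
    out = cells.copy()
    if exclusion_policy == "drop":
        n_excluded = int(bad.sum())
        if n_excluded:
            logger.info("compute_zscores: dropped %d cells with nonpositive ODs", n_excluded)
        out = out.loc[~bad].copy()
        od = od[~bad]
    else:
        od = np.where(np.isfinite(od) & (od > 0), od, floor_epsilon)

    log_n, log_m, log_t = np.log10(od[:, 0]), np.log10(od[:, 1]), np.log10(od[:, 2])
    out["z_tomm20"] = (log_t - model.mu_T) / model.sd_T
    out["z_ndufb8"] = (log_n - (model.intercept_N + model.slope_N * log_t)) / model.resid_sd_N
    out["z_mtco1"] = (log_m - (model.intercept_M + model.slope_M * log_t)) / model.resid_sd_M
    out.attrs["n_excluded"] = n_excluded
    return out


def _categorise(z: np.ndarray, t: CategoryThresholds) -> np.ndarray:
    """NDUFB8/MTCO1 categories; precedence very_low > low, normal closed."""
    cat = np.full(len(z), "normal", dtype=object)
    cat[z > t.high] = "high"
    cat[z < t.low] = "low"
    cat[z < t.very_low] = "very_low"
    cat[~np.isfinite(z)] = "invalid"
    return cat


def _categorise_tomm20(z: np.ndarray, t: CategoryThresholds) -> np.ndarray:
    cat = np.full(len(z), "normal", dtype=object)
    cat[z > t.tomm20_high] = "high"
    cat[z < t.tomm20_low] = "low"
    cat[~np.isfinite(z)] = "invalid"
    return cat


def classify_cells(
    zcells: pd.DataFrame, thresholds: CategoryThresholds | None = None
) -> pd.DataFrame:
    """Attach abundance categories and deficiency flags to scored cells.

    Cells with non-finite Z-scores get category "invalid" and are excluded
    from downstream proportions; the count lands in
    ``result.attrs['n_invalid']``.
    """
    t = thresholds or CategoryThresholds()
    out = zcells.copy()
    z_n = out["z_ndufb8"].to_numpy(dtype=float)
    z_m = out["z_mtco1"].to_numpy(dtype=float)
    z_t = out["z_tomm20"].to_numpy(dtype=float)
    out["cat_ndufb8"] = _categorise(z_n, t)
    out["cat_mtco1"] = _categorise(z_m, t)
    out["cat_tomm20"] = _categorise_tomm20(z_t, t)
    out["deficient_ndufb8"] = np.isfinite(z_n) & (z_n < t.deficient)
    out["deficient_mtco1"] = np.isfinite(z_m) & (z_m < t.deficient)
    invalid = ~(np.isfinite(z_n) & np.isfinite(z_m) & np.isfinite(z_t))
    out["valid"] = ~invalid
    out.attrs["n_invalid"] = int(invalid.sum())
    if invalid.any():
        logger.warning("classify_cells: %d cells with non-finite z flagged invalid", invalid.sum())
    return out


def score_cells(
    cells: pd.DataFrame,
    model: ControlModel | None = None,
    control_group: str = CONTROL_GROUP,
    min_n: int = 100,
    thresholds: CategoryThresholds | None = None,
    exclusion_policy: str = "drop",
) -> tuple[pd.DataFrame, ControlModel]:
    """Convenience wrapper: fit (if needed), score and classify in one call.

    Only epithelial cells enter the output when a tissue_class column exists,
    matching the analysis population.
    """
    if "tissue_class" in cells.columns:
        cells = cells.loc[cells["tissue_class"] == "epithelial"]
    if model is None:
        model = fit_control_model(select_controls(cells, control_group), min_n=min_n)
    z = compute_zscores(cells, model, exclusion_policy=exclusion_policy)
    return classify_cells(z, thresholds), model


def marker_z_columns() -> dict[str, str]:
    return {m: f"z_{m}" for m in MITO_MARKERS}
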