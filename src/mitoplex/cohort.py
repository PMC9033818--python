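"""Group-level statistics: category proportions, deltas, chi-square and
Kruskal-Wallis comparisons.

Proportions are pooled over cells within a grouping cell (not averaged over
patients); the patient-stratified view is obtained by grouping on
patient_id. Chi-square uses the Pearson statistic without continuity
correction; Kruskal-Wallis applies the standard tie correction and a
chi-square approximation with k-1 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mitoplex.errors import ConfigurationError
from mitoplex.panel import MITO_MARKERS

CATEGORIES = {
    "ndufb8": ("very_low", "low", "normal", "high"),
    "mtco1": ("very_low", "low", "normal", "high"),
    "tomm20": ("low", "normal", "high"),
}


@dataclass
class ComparisonResult:
    contrast: str
    marker: str
    category: str
    p_a: float | None = None
    p_b: float | None = None
    delta_pp: float | None = None
    statistic: float = float("nan")
    df: int = 0
    p_value: float = float("nan")
    test_name: str = ""
    low_expected_warning: bool = False
    extras: dict = field(default_factory=dict)


def category_proportions(
    zcells: pd.DataFrame, grouping: list[str] | str = "group"
) -> pd.DataFrame:
    """Long-format summary: one row per grouping cell x marker x category.

    Columns: grouping keys, marker, category, n_cells, count, percentage,
    mean_z. Invalid cells (non-finite z) are excluded; empty grouping cells
    are omitted with a warning.
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    missing = [g for g in grouping if g not in zcells.columns]
    if missing:
        raise ConfigurationError(f"grouping keys not in table: {missing}")
    data = zcells
    if "valid" in data.columns:
        n_invalid = int((~data["valid"]).sum())
        if n_invalid:
            warnings.warn(f"excluding {n_invalid} invalid cells", stacklevel=2)
        data = data.loc[data["valid"]]

    rows = []
    for keys, sub in data.groupby(grouping, sort=True, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        n = len(sub)
        if n == 0:
            warnings.warn(f"empty grouping cell {keys}; omitted", stacklevel=2)
            continue
        for marker in MITO_MARKERS:
            counts = sub[f"cat_{marker}"].value_counts()
            mean_z = float(sub[f"z_{marker}"].mean())
            for cat in CATEGORIES[marker]:
                c = int(counts.get(cat, 0))
                rows.append(
                    {
                        **dict(zip(grouping, keys)),
                        "marker": marker,
                        "category": cat,
                        "n_cells": n,
                        "count": c,
                        "percentage": 100.0 * c / n,
                        "mean_z": mean_z,
                    }
                )
    return pd.DataFrame(rows)


def deficient_proportions(
    zcells: pd.DataFrame, grouping: list[str] | str = "group"
) -> pd.DataFrame:
    """Per-grouping-cell counts and percentages of deficient cells (z < -3)."""
    if isinstance(grouping, str):
        grouping = [grouping]
    data = zcells.loc[zcells["valid"]] if "valid" in zcells.columns else zcells
    rows = []
    for keys, sub in data.groupby(grouping, sort=True, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for marker in ("ndufb8", "mtco1"):
            c = int(sub[f"deficient_{marker}"].sum())
            rows.append(
                {
                    **dict(zip(grouping, keys)),
                    "marker": marker,
                    "n_cells": len(sub),
                    "n_deficient": c,
                    "percentage": 100.0 * c / len(sub) if len(sub) else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def proportion_delta(p_a: float, p_b: float) -> float:
    """Percentage-point difference p_a - p_b, reported to 2 decimal places.

    Both inputs are percentages in [0, 100].
    """
    for p in (p_a, p_b):
        if not np.isfinite(p) or not 0.0 <= p <= 100.0:
            raise ConfigurationError(f"proportion {p} outside [0, 100]")
    return round(float(p_a) - float(p_b), 2)


def chisq_proportions(
    count_table: np.ndarray | list,
    contrast: str = "",
    marker: str = "",
    category: str = "",
) -> ComparisonResult:
    """Pearson chi-square test on an r x k table of cell counts.

    No continuity correction; df = (r-1)(k-1); p from the chi-square upper
    tail. Any expected count below 5 sets ``low_expected_warning``.
    """
    obs = np.asarray(count_table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ConfigurationError("count table must be at least 2 x 2")
    if np.any(obs < 0) or not np.all(np.isfinite(obs)):
        raise ConfigurationError("counts must be finite and nonnegative")
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    if np.any(row_tot == 0) or np.any(col_tot == 0):
        raise ConfigurationError("zero marginal total in count table")
    total = obs.sum()
    expected = np.outer(row_tot, col_tot) / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    res = ComparisonResult(
        contrast=contrast,
        marker=marker,
        category=category,
        statistic=chi2,
        df=df,
        p_value=p,
        test_name="chi-square",
        low_expected_warning=bool((expected < 5).any()),
    )
    if obs.shape == (2, 2):
        res.p_a = 100.0 * obs[0, 0] / row_tot[0]
        res.p_b = 100.0 * obs[1, 0] / row_tot[1]
        res.delta_pp = res.p_a - res.p_b
    return res


def compare_deficiency(
    zcells: pd.DataFrame,
    key: str,
    group_a: str,
    group_b: str,
    marker: str = "ndufb8",
) -> ComparisonResult:
    """Chi-square comparison of deficient-vs-not proportions between two
    values of a grouping column (e.g. group or region)."""
    col = f"deficient_{marker}"
    data = zcells.loc[zcells["valid"]] if "valid" in zcells.columns else zcells
    table = []
    for g in (group_a, group_b):
        sub = data.loc[data[key] == g, col]
        table.append([int(sub.sum()), int((~sub).sum())])
    res = chisq_proportions(
        table, contrast=f"{key}:{group_a} vs {key}:{group_b}", marker=marker,
        category="deficient",
    )
    return res


def kruskal_wallis(
    values_by_group: dict[str, np.ndarray | list],
    contrast: str = "",
    marker: str = "",
) -> ComparisonResult:
    """Kruskal-Wallis H test across >= 2 groups of ROI-level values.

    H uses the standard rank-sum form with tie correction; p comes from the
    chi-square approximation with k-1 degrees of freedom.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ConfigurationError("Kruskal-Wallis needs at least 2 groups")
    for k, v in groups.items():
        if len(v) == 0:
            raise ConfigurationError(f"group {k!r} has no values")
    pooled = np.concatenate(list(groups.values()))
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for v in groups.values():
        r = ranks[start : start + len(v)]
        h += r.sum() ** 2 / len(v)
        start += len(v)
    h = 12.0 / (n_tot * (n_tot + 1)) * h - 3.0 * (n_tot + 1)
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    denom = 1.0 - tie_term / (n_tot**3 - n_tot) if n_tot > 1 else 1.0
    if denom <= 0:  # all values identical
        h = 0.0
    else:
        h /= denom
    df = len(groups) - 1
    p = float(stats.chi2.sf(h, df))
    return ComparisonResult(
        contrast=contrast or " vs ".join(groups),
        marker=marker,
        category="roi_mean_z",
        statistic=float(h),
        df=df,
        p_value=p,
        test_name="kruskal-wallis",
    )


def roi_mean_z(zcells: pd.DataFrame, marker: str) -> pd.DataFrame:
    """Unweighted mean z per ROI (epithelial cells), with group and region."""
    col = f"z_{marker}"
    if col not in zcells.columns:
        raise ConfigurationError(f"marker {marker!r} not scored")
    data = zcells.loc[zcells["valid"]] if "valid" in zcells.columns else zcells
    keep = [c for c in ("group", "patient_id", "region") if c in data.columns]
    agg = data.groupby("roi_id", observed=True).agg(
        **{f"mean_z_{marker}": (col, "mean"), "n_cells": (col, "size")},
        **{c: (c, "first") for c in keep},
    )
    return agg.reset_index()


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "contrast": r.contrast,
                "marker": r.marker,
                "category": r.category,
                "p_a": r.p_a,
                "p_b": r.p_b,
                "delta_pp": None if r.delta_pp is None else round(r.delta_pp, 2),
                "statistic": r.statistic,
                "df": r.df,
                "p_value": r.p_value,
                "test_name": r.test_name,
                "low_expected_warning": r.low_expected_warning,
            }
        )
    return pd.DataFrame(rows)
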