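"""Visual outputs: MRC scatter graphs, pseudo-colour Z-score images and ROI
heatmaps.

Every figure has a machine-readable twin (a CSV of the exact values that
were drawn); tests and downstream consumers read the twin, never pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.colors import Normalize

from mitoplex.errors import ConfigurationError


@dataclass
class PlotStyle:
    cmap: str = "coolwarm"
    z_clip: float = 6.0
    reference_sd: float = 3.0
    spot_scale: float = 0.15  # points^2 per pixel of cell area
    background_rgb: tuple[float, float, float] = (0.85, 0.85, 0.85)
    missing_rgb: tuple[float, float, float] = (1.0, 0.0, 1.0)
    dpi: int = 120
    axis_limit: float = 12.0
    density: bool = False


def _twin_path(figure_path: str | Path) -> Path:
    p = Path(figure_path)
    return p.with_suffix(".csv")


def mrc_graph(
    zcells: pd.DataFrame,
    figure_path: str | Path,
    style: PlotStyle | None = None,
) -> pd.DataFrame:
    """MRC graph: scatter of z_ndufb8 (y) against z_mtco1 (x), one spot per
    cell, spot radius proportional to sqrt(cell area) so spot area tracks
    cell area. Reference lines at +/- reference_sd on both axes.

    Returns (and writes alongside the figure) the plotted-point table with
    columns x, y, size.
    """
    style = style or PlotStyle()
    if len(zcells) == 0:
        raise ConfigurationError("no cells to plot")
    data = zcells.loc[
        np.isfinite(zcells["z_mtco1"]) & np.isfinite(zcells["z_ndufb8"])
    ].copy()
    if len(data) == 0:
        raise ConfigurationError("no cells with finite z-scores to plot")
    area = data["area_px"].to_numpy(dtype=float) if "area_px" in data else np.full(len(data), 50.0)
    points = pd.DataFrame(
        {
            "cell_id": data["cell_id"].to_numpy() if "cell_id" in data else np.arange(len(data)),
            "x": data["z_mtco1"].to_numpy(dtype=float),
            "y": data["z_ndufb8"].to_numpy(dtype=float),
            "size": style.spot_scale * area,
        }
    )

    fig, ax = plt.subplots(figsize=(5, 5), dpi=style.dpi)
    if style.density:
        ax.hexbin(points["x"], points["y"], gridsize=60, cmap="viridis", mincnt=1)
    else:
        ax.scatter(points["x"], points["y"], s=points["size"], alpha=0.5, lw=0, c="#444444")
    for v in (-style.reference_sd, style.reference_sd):
        ax.axvline(v, color="tab:red", lw=0.8, ls="--")
        ax.axhline(v, color="tab:red", lw=0.8, ls="--")
    lim = style.axis_limit
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("MTCO1 Z-score")
    ax.set_ylabel("NDUFB8 Z-score")
    fig.tight_layout()
    fig.savefig(figure_path)
    plt.close(fig)
    points.to_csv(_twin_path(figure_path), index=False)
    return points


def pseudo_image(
    mask: np.ndarray,
    zcells: pd.DataFrame,
    marker: str,
    figure_path: str | Path,
    style: PlotStyle | None = None,
    label_column: str = "label",
) -> pd.DataFrame:
    """Pseudo-colour Z-score image: each cell footprint filled with a
    diverging colour mapped from its z (blue low, red high), clipped at
    +/- z_clip; background a fixed neutral colour; cells present in the mask
    but absent from the score table get the 'missing' colour and a warning.

    Returns (and writes) the per-cell colour table (label, z, r, g, b).
    """
    style = style or PlotStyle()
    zcol = f"z_{marker}"
    if zcol not in zcells.columns:
        raise ConfigurationError(f"marker {marker!r} not scored")
    if label_column not in zcells.columns:
        raise ConfigurationError(f"score table lacks a {label_column!r} column")

    cmap = colormaps[style.cmap]
    norm = Normalize(vmin=-style.z_clip, vmax=style.z_clip)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    by_label = zcells.set_index(label_column)[zcol].to_dict()

    rows = []
    n_missing = 0
    lut = np.zeros((int(mask.max()) + 1, 3))
    lut[0] = style.background_rgb
    for lab in labels:
        z = by_label.get(int(lab), np.nan)
        if np.isfinite(z):
            zc = float(np.clip(z, -style.z_clip, style.z_clip))
            rgb = cmap(norm(zc))[:3]
        else:
            n_missing += 1
            rgb = style.missing_rgb
        lut[int(lab)] = rgb
        rows.append({"label": int(lab), "z": z, "r": rgb[0], "g": rgb[1], "b": rgb[2]})
    if n_missing:
        warnings.warn(f"{n_missing} mask cells missing from score table", stacklevel=2)

    rgb_img = lut[mask]
    fig, ax = plt.subplots(figsize=(5, 5), dpi=style.dpi)
    ax.imshow(rgb_img, interpolation="nearest")
    ax.set_axis_off()
    ax.set_title(f"{marker} Z-score")
    fig.tight_layout()
    fig.savefig(figure_path)
    plt.close(fig)
    table = pd.DataFrame(rows)
    table.to_csv(_twin_path(figure_path), index=False)
    return table


def roi_heatmap(
    roi_means: pd.DataFrame,
    markers: list[str],
    figure_path: str | Path,
    sort_by: str | None = None,
    sort_group: str | None = None,
    style: PlotStyle | None = None,
) -> pd.DataFrame:
    """ROI x marker matrix of mean Z-scores rendered as a heatmap.

    ``roi_means`` must carry one row per ROI with ``mean_z_<marker>``
    columns (see cohort.roi_mean_z). Rows can be sorted by one marker's mean
    z (``sort_by``) and, before that, by a categorical column such as a
    histopathological subgroup (``sort_group``). The matrix is written as
    the CSV twin.
    """
    style = style or PlotStyle()
    cols = []
    for m in markers:
        col = f"mean_z_{m}"
        if col not in roi_means.columns:
            raise ConfigurationError(f"marker {m!r} absent from ROI summary")
        cols.append(col)
    mat = roi_means.copy()
    sort_keys = []
    if sort_group is not None:
        if sort_group not in mat.columns:
            raise ConfigurationError(f"sort_group column {sort_group!r} absent")
        sort_keys.append(sort_group)
    if sort_by is not None:
        if f"mean_z_{sort_by}" not in mat.columns:
            raise ConfigurationError(f"marker {sort_by!r} absent from ROI summary")
        sort_keys.append(f"mean_z_{sort_by}")
    if sort_keys:
        mat = mat.sort_values(sort_keys, kind="mergesort")
    matrix = mat.set_index("roi_id")[cols]

    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * len(cols), 1 + 0.18 * len(matrix)), dpi=style.dpi
    )
    im = ax.imshow(
        matrix.to_numpy(),
        cmap=style.cmap,
        vmin=-style.z_clip,
        vmax=style.z_clip,
        aspect="auto",
        interpolation="nearest",
    )
    ax.set_xticks(range(len(cols)), markers)
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="mean Z-score")
    fig.tight_layout()
    fig.savefig(figure_path)
    plt.close(fig)
    matrix.to_csv(_twin_path(figure_path))
    return matrix
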