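"""End-to-end orchestration: simulate -> unmix -> quantify -> score ->
compare -> report, from a single configuration."""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from mitoplex import cohort, io, report, segquant
from mitoplex.mrc import score_cells
from mitoplex.panel import MITO_MARKERS
from mitoplex.simgen import (
    SimConfig,
    make_spectral_library,
    render_tissue_cube,
    simulate_cell_population,
)
from mitoplex.unmix import unmix_cube

logger = logging.getLogger(__name__)


def run_pipeline(
    config: SimConfig,
    out_dir: str | Path,
    use_truth_masks: bool = False,
    save_cubes: bool = False,
) -> dict[str, Path]:
    """Run the full synthetic pipeline; returns a dict of output paths.

    With ``use_truth_masks`` the rendered ground-truth masks replace
    segmentation, which makes the statistical stages independent of
    segmentation quality.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    figs = out_dir / "figs"
    figs.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    config.validate()
    library = make_spectral_library()
    io.write_library(out_dir / "library.yaml", library)
    paths["library"] = out_dir / "library.yaml"

    cells_true, truth = simulate_cell_population(config)
    io.write_cells(out_dir / "cells_true.csv", cells_true)
    io.write_cells(out_dir / "truth.csv", truth)
    paths["cells_true"] = out_dir / "cells_true.csv"
    paths["truth"] = out_dir / "truth.csv"

    roi_meta = (
        cells_true[["roi_id", "patient_id", "group", "region"]]
        .drop_duplicates("roi_id")
        .set_index("roi_id")
    )
    ck_threshold = math.sqrt(config.ck_epithelial * config.ck_stromal)

    tables = []
    first_masks: dict[str, tuple[np.ndarray, pd.DataFrame]] = {}
    for i, (roi_id, meta) in enumerate(roi_meta.iterrows()):
        truth_roi = truth.loc[truth["roi_id"] == roi_id]
        cube, mask_true = render_tissue_cube(
            truth_roi, library, config, noise_seed=config.seed + 7919 * (i + 1)
        )
        if save_cubes:
            cube_dir = out_dir / "cubes"
            cube_dir.mkdir(exist_ok=True)
            io.write_cube(cube_dir / f"{roi_id}.tif", cube)
            io.write_mask(cube_dir / f"{roi_id}_mask.tif", mask_true)
        components = unmix_cube(cube, library)
        mask = mask_true if use_truth_masks else segquant.segment_cells(components)
        tissue = segquant.classify_tissue(components, mask, threshold=ck_threshold)
        table = segquant.quantify_cells(
            components,
            mask,
            annotations=meta.to_dict() | {"roi_id": roi_id},
            tissue_class=tissue,
        )
        tables.append(table)
        if not first_masks:
            first_masks[roi_id] = (mask, table)

    cells = pd.concat(tables, ignore_index=True)
    io.write_cells(out_dir / "cells.csv", cells)
    paths["cells"] = out_dir / "cells.csv"

    zcells, model = score_cells(cells)
    model.to_yaml(out_dir / "model.yaml")
    io.write_cells(out_dir / "z.csv", zcells)
    paths["model"] = out_dir / "model.yaml"
    paths["z"] = out_dir / "z.csv"

    by_group = cohort.category_proportions(zcells, "group")
    by_patient = cohort.category_proportions(zcells, ["group", "patient_id"])
    by_group.to_csv(out_dir / "summary_by_group.csv", index=False)
    by_patient.to_csv(out_dir / "summary_by_patient.csv", index=False)
    paths["summary_by_group"] = out_dir / "summary_by_group.csv"
    paths["summary_by_patient"] = out_dir / "summary_by_patient.csv"

    comparisons = []
    if {"tumour", "aged_benign"} <= set(zcells["group"]):
        for marker in ("ndufb8", "mtco1"):
            comparisons.append(
                cohort.compare_deficiency(zcells, "group", "tumour", "aged_benign", marker)
            )
    tumour_cells = zcells.loc[zcells["group"] == "tumour"]
    if {"tumour", "benign_adjacent"} <= set(tumour_cells["region"]):
        for marker in ("ndufb8", "mtco1"):
            comparisons.append(
                cohort.compare_deficiency(
                    tumour_cells, "region", "tumour", "benign_adjacent", marker
                )
            )
    if comparisons:
        cohort.comparisons_to_frame(comparisons).to_csv(
            out_dir / "comparisons.csv", index=False
        )
        paths["comparisons"] = out_dir / "comparisons.csv"

    roi_frames = [cohort.roi_mean_z(zcells, m) for m in MITO_MARKERS]
    roi_means = roi_frames[0]
    for f in roi_frames[1:]:
        roi_means = roi_means.merge(
            f[["roi_id", f.columns[1]]], on="roi_id", how="outer"
        )
    roi_means.to_csv(out_dir / "roi_means.csv", index=False)
    paths["roi_means"] = out_dir / "roi_means.csv"

    kw = [
        cohort.kruskal_wallis(
            {
                g: sub[f"mean_z_{m}"].to_numpy()
                for g, sub in roi_means.groupby("group", observed=True)
            },
            marker=m,
        )
        for m in MITO_MARKERS
        if roi_means["group"].nunique() >= 2
    ]
    if kw:
        cohort.comparisons_to_frame(kw).to_csv(out_dir / "kruskal_wallis.csv", index=False)
        paths["kruskal_wallis"] = out_dir / "kruskal_wallis.csv"

    report.mrc_graph(zcells, figs / "mrc.png")
    paths["mrc_graph"] = figs / "mrc.png"
    roi_id, (mask, table) = next(iter(first_masks.items()))
    ztab = zcells.loc[zcells["roi_id"] == roi_id]
    for marker in MITO_MARKERS:
        report.pseudo_image(mask, ztab, marker, figs / f"pseudo_{marker}.png")
        paths[f"pseudo_{marker}"] = figs / f"pseudo_{marker}.png"
    report.roi_heatmap(
        roi_means, list(MITO_MARKERS), figs / "roi_heatmap.png", sort_by="ndufb8"
    )
    paths["roi_heatmap"] = figs / "roi_heatmap.png"
    logger.info("pipeline complete: %d cells quantified", len(cells))
    return paths
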