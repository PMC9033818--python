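"""Cell segmentation, tissue classification and per-cell quantification.

Nuclei are detected on the DAPI component plane (Gaussian smoothing,
thresholding, distance-transform watershed); each nucleus is then expanded
into a cytoplasmic ring bounded by the cytokeratin-positive support and by
neighbouring cells. A trainable commercial segmenter is deliberately
replaced by this transparent parameterised algorithm, and ground-truth
masks can be used in place of segmentation throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, relabel_sequential, watershed

from mitoplex.errors import ConfigurationError
from mitoplex.panel import FLUOR_TO_MARKER
from mitoplex.spectra import ComponentImages


@dataclass
class SegmentationParams:
    dapi_sigma: float = 1.0
    dapi_threshold: float | None = None  # None -> Otsu
    min_nucleus_distance: int = 3
    min_nucleus_area: int = 4
    cytoplasm_expand_px: int = 3
    ck_threshold: float | None = None  # None -> Otsu on the CK plane
    restrict_to_ck: bool = True


def segment_cells(
    components: ComponentImages, params: SegmentationParams | None = None
) -> np.ndarray:
    """Segment cells; returns an integer label mask (0 = background)."""
    params = params or SegmentationParams()
    if "DAPI" not in components.planes:
        raise ConfigurationError("DAPI plane required for segmentation")
    dapi = components["DAPI"]
    if not dapi.any():
        warnings.warn("blank DAPI plane: emitting empty mask", stacklevel=2)
        return np.zeros(dapi.shape, dtype=np.int32)

    smooth = gaussian(dapi, sigma=params.dapi_sigma, preserve_range=True)
    thr = params.dapi_threshold
    if thr is None:
        thr = threshold_otsu(smooth)
    fg = smooth > thr
    if not fg.any():
        warnings.warn("no DAPI foreground above threshold", stacklevel=2)
        return np.zeros(dapi.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=params.min_nucleus_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    nuclei = watershed(-dist, markers, mask=fg)

    sizes = np.bincount(nuclei.ravel())
    small = np.flatnonzero(sizes < params.min_nucleus_area)
    nuclei[np.isin(nuclei, small[small > 0])] = 0

    cells = expand_labels(nuclei, distance=params.cytoplasm_expand_px)
    if params.restrict_to_ck and "Opal690" in components.planes:
        ck = components["Opal690"]
        ck_thr = params.ck_threshold
        if ck_thr is None:
            ck_thr = threshold_otsu(ck) if ck.any() else np.inf
        support = (nuclei > 0) | (ck > ck_thr)
        cells = np.where(support, cells, 0)

    cells, _, _ = relabel_sequential(cells)
    return cells.astype(np.int32)


def classify_tissue(
    components: ComponentImages,
    mask: np.ndarray,
    threshold: float | None = None,
) -> pd.Series:
    """Per-cell epithelial/stromal call from mean cytokeratin intensity.

    With ``threshold=None`` an automatic bimodal (Otsu) split of the per-cell
    log-mean intensities is used; if the split is degenerate (one side empty,
    i.e. effectively unimodal) a threshold must be supplied instead. A cell
    is epithelial iff its mean strictly exceeds the threshold.
    """
    if "Opal690" not in components.planes:
        raise ConfigurationError("cytokeratin (Opal690) plane required")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if len(labels) == 0:
        return pd.Series(dtype=object)
    means = ndi.mean(components["Opal690"], labels=mask, index=labels)

    if threshold is None:
        log_means = np.log10(np.asarray(means) + 1e-12)
        if np.ptp(log_means) < 1e-12:
            raise ConfigurationError(
                "cytokeratin per-cell means are unimodal; supply a threshold"
            )
        log_thr = threshold_otsu(log_means)
        threshold = 10.0**log_thr
        epithelial = means > threshold
        if epithelial.all() or not epithelial.any():
            raise ConfigurationError(
                "automatic cytokeratin threshold produced a one-sided split; "
                "supply a threshold"
            )
    else:
        epithelial = means > threshold

    return pd.Series(
        np.where(epithelial, "epithelial", "stromal"), index=pd.Index(labels, name="label")
    )


def quantify_cells(
    components: ComponentImages,
    mask: np.ndarray,
    annotations: dict | None = None,
    tissue_class: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-cell mean component intensity table (one row per mask label).

    ``annotations`` supplies the ROI-level labels (patient_id, group, roi_id,
    region); a missing annotation yields region "n/a" with a warning. Cells
    touching the image border are kept and flagged ``edge=True``.
    """
    if mask.shape != components.shape:
        raise ConfigurationError("mask and component planes disagree on shape")
    if annotations is None:
        warnings.warn("no annotations supplied; region set to 'n/a'", stacklevel=2)
        annotations = {}
    patient_id = annotations.get("patient_id", "n/a")
    group = annotations.get("group", "n/a")
    roi_id = annotations.get("roi_id", "n/a")
    region = annotations.get("region", "n/a")

    labels = np.unique(mask)
    labels = labels[labels > 0]
    h, w = mask.shape
    records: dict[str, np.ndarray | list] = {}
    means = {}
    for fluor, marker in FLUOR_TO_MARKER.items():
        if fluor in components.planes:
            means[f"od_{marker}"] = ndi.mean(
                components[fluor], labels=mask, index=labels
            )

    areas = ndi.sum_labels(np.ones_like(mask), labels=mask, index=labels).astype(int)
    com = ndi.center_of_mass(np.ones_like(mask, dtype=float), labels=mask, index=labels)
    com = np.atleast_2d(np.asarray(com, dtype=float))

    edge = np.zeros(len(labels), dtype=bool)
    border = np.concatenate([mask[0, :], mask[-1, :], mask[:, 0], mask[:, -1]])
    edge_labels = set(np.unique(border[border > 0]).tolist())
    for i, lab in enumerate(labels):
        edge[i] = int(lab) in edge_labels

    records = {
        "patient_id": patient_id,
        "group": group,
        "roi_id": roi_id,
        "region": region,
        "cell_id": [f"{roi_id}_{int(lab):05d}" for lab in labels],
        "label": labels.astype(int),
        "area_px": areas,
        **{k: np.asarray(v) for k, v in means.items()},
        "x": com[:, 1] if len(labels) else np.array([]),
        "y": com[:, 0] if len(labels) else np.array([]),
        "edge": edge,
    }
    table = pd.DataFrame(records)
    if tissue_class is not None:
        table["tissue_class"] = (
            table["label"].map(tissue_class).fillna("stromal").astype(str)
        )
    return table


def match_to_ground_truth(
    mask: np.ndarray, truth_roi: pd.DataFrame
) -> pd.DataFrame:
    """Match segmented labels to ground-truth centroids.

    Returns the truth table with a ``matched_label`` column: the mask label
    under each true centroid (0 when the centroid falls on background).
    """
    out = truth_roi.copy()
    ys = out["y"].to_numpy(dtype=int)
    xs = out["x"].to_numpy(dtype=int)
    out["matched_label"] = mask[ys, xs]
    return out


def segmentation_scores(mask: np.ndarray, truth_roi: pd.DataFrame) -> dict[str, float]:
    """Centroid-based recall/precision of a segmentation against ground truth.

    A true cell is recovered iff exactly its own mask label sits under its
    centroid and no other true centroid claims the same label (1:1 match).
    """
    matched = match_to_ground_truth(mask, truth_roi)["matched_label"].to_numpy()
    hits = matched[matched > 0]
    unique_hits = len(np.unique(hits))
    n_truth = len(truth_roi)
    n_pred = len(np.unique(mask)) - (1 if (mask == 0).any() else 0)
    recall = unique_hits / n_truth if n_truth else 0.0
    precision = unique_hits / n_pred if n_pred else 0.0
    return {"recall": recall, "precision": precision, "n_pred": n_pred, "n_truth": n_truth}
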