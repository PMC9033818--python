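"""Synthetic cell populations, spectral libraries and multispectral tissue cubes.

The generative model mirrors the fitting model used downstream so that
parameter- and phenotype-recovery are exact in expectation:

* log10-TOMM20 ~ Normal(mu_T, sd_T)
* log10-NDUFB8 = intercept_N + slope_N * log10-TOMM20 + Normal(0, resid_sd_N)
* log10-MTCO1  = intercept_M + slope_M * log10-TOMM20 + Normal(0, resid_sd_M)

Deficient phenotypes shift the named marker's residual downward by
``deficiency_shift`` residual SDs; the high-TOMM20 phenotype shifts
log10-TOMM20 upward by ``high_tomm20_shift`` SDs; "combined" does all three.
Deficient cells are placed in spatially contiguous clones within an ROI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mitoplex.errors import ConfigurationError
from mitoplex.panel import AF_NAME, FLUOROPHORES, MARKER_TO_FLUOR
from mitoplex.spectra import MultispectralCube, SpectralLibrary

GROUPS = ("young_benign", "aged_benign", "tumour")
PHENOTYPES = ("normal", "ndufb8_deficient", "mtco1_deficient", "high_tomm20", "combined")

#: default emission peak (nm) per fluorophore on the 440-720 nm grid
DEFAULT_PEAKS = {
    "DAPI": 460.0,
    "Opal520": 520.0,
    "Opal570": 570.0,
    "Opal620": 620.0,
    "Opal690": 690.0,
}
DEFAULT_EMISSION_WIDTH_NM = 25.0


def make_spectral_library(
    band_start_nm: float = 440.0,
    band_end_nm: float = 720.0,
    band_step_nm: float = 20.0,
    peak_positions: dict[str, float] | None = None,
    emission_width_nm: float = DEFAULT_EMISSION_WIDTH_NM,
    af_peak_nm: float = 530.0,
    af_width_nm: float = 90.0,
) -> SpectralLibrary:
    """Build a synthetic spectral library of Gaussian emission curves.

    The grid runs from ``band_start_nm`` to ``band_end_nm`` inclusive in steps
    of ``band_step_nm``; every endmember is unit-peak normalised. The
    autofluorescence spectrum is a broad Gaussian, also unit peak.
    """
    if band_start_nm >= band_end_nm:
        raise ConfigurationError("band_start_nm must be below band_end_nm")
    if band_step_nm <= 0:
        raise ConfigurationError("band_step_nm must be positive")
    span = band_end_nm - band_start_nm
    n_steps = span / band_step_nm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ConfigurationError(
            f"band step {band_step_nm} nm does not divide range {span} nm"
        )
    wavelengths = band_start_nm + band_step_nm * np.arange(int(round(n_steps)) + 1)

    if peak_positions is None:
        peaks = dict(DEFAULT_PEAKS)
    else:
        names = list(peak_positions)
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate fluorophore names in peak_positions")
        peaks = {str(k): float(v) for k, v in peak_positions.items()}
    for name, peak in peaks.items():
        if not (band_start_nm <= peak <= band_end_nm):
            raise ConfigurationError(
                f"peak for {name!r} ({peak} nm) outside band range"
            )

    def gaussian(peak: float, width: float) -> np.ndarray:
        spec = np.exp(-((wavelengths - peak) ** 2) / (2.0 * width**2))
        return spec / spec.max()

    endmembers = {name: gaussian(peak, emission_width_nm) for name, peak in peaks.items()}
    af = gaussian(af_peak_nm, af_width_nm)
    return SpectralLibrary(wavelengths=wavelengths, endmembers=endmembers, autofluorescence=af)


@dataclass
class ImageConfig:
    """Raster geometry and camera noise model for rendered ROI cubes."""

    height: int = 192
    width: int = 192
    nucleus_radius: int = 2
    cytoplasm_radius: int = 4
    noise_model: str = "none"  # none | poisson | poisson_read
    gain: float = 100.0  # photons per intensity unit
    read_noise_sd: float = 0.0  # intensity units
    autofluorescence_level: float = 0.0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ConfigurationError("image dimensions must be >= 1")
        if self.nucleus_radius < 1 or self.cytoplasm_radius < self.nucleus_radius:
            raise ConfigurationError(
                "need cytoplasm_radius >= nucleus_radius >= 1"
            )
        if self.noise_model not in ("none", "poisson", "poisson_read"):
            raise ConfigurationError(f"unknown noise_model {self.noise_model!r}")
        if self.gain <= 0:
            raise ConfigurationError("gain must be positive")
        if self.read_noise_sd < 0 or self.autofluorescence_level < 0:
            raise ConfigurationError("noise levels must be nonnegative")


def _default_fractions() -> dict[str, dict[str, float]]:
    return {
        "young_benign": {"ndufb8": 0.0, "mtco1": 0.0, "high_tomm20": 0.0, "combined": 0.0},
        "aged_benign": {"ndufb8": 0.005, "mtco1": 0.045, "high_tomm20": 0.04, "combined": 0.0},
        "tumour": {"ndufb8": 0.15, "mtco1": 0.013, "high_tomm20": 0.11, "combined": 0.005},
    }


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic cohort.

    ``deficiency_fractions`` maps group -> phenotype fraction for the keys
    ``ndufb8``, ``mtco1``, ``high_tomm20`` and ``combined``; per group the
    fractions must sum to at most 1 (the remainder is phenotypically normal).
    """

    seed: int = 0
    groups: tuple[str, ...] = GROUPS
    n_patients_per_group: int = 2
    rois_per_patient: int = 4
    cells_per_roi: int = 200
    stromal_fraction: float = 0.2
    # control model (log10 scale)
    mu_T: float = 2.0
    sd_T: float = 0.2
    intercept_N: float = 0.5
    slope_N: float = 0.9
    resid_sd_N: float = 0.05
    intercept_M: float = 0.3
    slope_M: float = 0.95
    resid_sd_M: float = 0.06
    # phenotype planting
    deficiency_fractions: dict[str, dict[str, float]] = field(default_factory=_default_fractions)
    deficiency_shift: float = 5.0  # residual-SD units, downward
    high_tomm20_shift: float = 3.0  # sd_T units, upward
    clonal_cluster_size: float = 8.0  # mean cells per deficient clone
    # non-mitochondrial channels (linear OD units)
    ck_epithelial: float = 50.0
    ck_stromal: float = 0.5
    ck_log_sd: float = 0.1
    dapi_level: float = 80.0
    dapi_log_sd: float = 0.1
    image: ImageConfig = field(default_factory=ImageConfig)

    def validate(self) -> None:
        if self.n_patients_per_group < 1 or self.rois_per_patient < 1 or self.cells_per_roi < 1:
            raise ConfigurationError("counts must be >= 1")
        for name in ("sd_T", "resid_sd_N", "resid_sd_M"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if not 0 <= self.stromal_fraction <= 1:
            raise ConfigurationError("stromal_fraction must be in [0, 1]")
        if self.clonal_cluster_size < 1:
            raise ConfigurationError("clonal_cluster_size must be >= 1")
        for group in self.groups:
            fracs = self.deficiency_fractions.get(group, {})
            unknown = set(fracs) - {"ndufb8", "mtco1", "high_tomm20", "combined"}
            if unknown:
                raise ConfigurationError(f"unknown phenotype keys {unknown} for {group!r}")
            for k, f in fracs.items():
                if not 0 <= f <= 1:
                    raise ConfigurationError(f"fraction {k}={f} for {group!r} not in [0, 1]")
            if sum(fracs.values()) > 1 + 1e-12:
                raise ConfigurationError(
                    f"phenotype fractions for {group!r} sum to {sum(fracs.values()):.3f} > 1"
                )
        self.image.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["groups"] = list(self.groups)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "image" in d:
            d["image"] = ImageConfig(**d["image"])
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _grid_positions(n: int, img: ImageConfig) -> tuple[np.ndarray, np.ndarray]:
    """Row-major lattice of n cell centres that keeps footprints inside the
    frame and non-overlapping. Contiguous indices are spatial neighbours,
    which is what makes clone runs spatially contiguous."""
    r = img.cytoplasm_radius
    n_cols = max(1, int(math.ceil(math.sqrt(n * img.width / img.height))))
    n_rows = int(math.ceil(n / n_cols))
    pitch_x = (img.width - 2 * r - 2) / max(n_cols - 1, 1) if n_cols > 1 else 0.0
    pitch_y = (img.height - 2 * r - 2) / max(n_rows - 1, 1) if n_rows > 1 else 0.0
    min_pitch = 2 * r + 1
    if (n_cols > 1 and pitch_x < min_pitch) or (n_rows > 1 and pitch_y < min_pitch):
        raise ConfigurationError(
            f"{n} cells of radius {r} do not fit in a "
            f"{img.height}x{img.width} frame without overlap"
        )
    idx = np.arange(n)
    row, col = idx // n_cols, idx % n_cols
    x = r + 1 + col * pitch_x
    y = r + 1 + row * pitch_y
    return np.round(x).astype(int), np.round(y).astype(int)


def _assign_phenotypes(
    n: int, fractions: dict[str, float], mean_clone: float, rng: np.random.Generator
) -> np.ndarray:
    """Assign phenotypes to n cells of one ROI, clustering non-normal cells
    into contiguous index runs (clones) of geometric mean size ``mean_clone``.

    Each cell's marginal probability of carrying phenotype p is fractions[p];
    clones only correlate assignments spatially.
    """
    labels = np.array(["normal"] * n, dtype=object)
    order = ("combined", "ndufb8", "mtco1", "high_tomm20")
    pheno_name = {
        "ndufb8": "ndufb8_deficient",
        "mtco1": "mtco1_deficient",
        "high_tomm20": "high_tomm20",
        "combined": "combined",
    }
    p_clone = 1.0 / mean_clone
    for key in order:
        f = fractions.get(key, 0.0)
        if f <= 0:
            continue
        target = rng.binomial(n, f)
        placed = 0
        attempts = 0
        while placed < target and attempts < 20 * n:
            attempts += 1
            size = min(rng.geometric(p_clone), target - placed)
            start = rng.integers(0, n)
            run = np.arange(start, min(start + size, n))
            free = run[labels[run] == "normal"]
            labels[free] = pheno_name[key]
            placed += len(free)
    return labels


def simulate_cell_population(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full cohort; returns (cell table, ground truth).

    The cell table has the canonical CellTable columns; the ground truth table
    is keyed by cell_id and adds the phenotype label, per-fluorophore true
    abundances and the mask label id each cell will receive when its ROI is
    rendered. Identical config (including seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    img = config.image
    rows_c: list[pd.DataFrame] = []
    rows_g: list[pd.DataFrame] = []
    nuc_area, cyt_area = _disk_areas(img)

    cell_counter = 0
    for group in config.groups:
        fractions = config.deficiency_fractions.get(group, {})
        for p in range(config.n_patients_per_group):
            patient_id = f"{group[:2].upper()}{p + 1:02d}"
            for r in range(config.rois_per_patient):
                roi_id = f"{patient_id}_roi{r + 1:02d}"
                if group == "tumour":
                    region = "tumour" if r % 2 == 0 else "benign_adjacent"
                else:
                    region = "n/a"
                n = config.cells_per_roi
                x, y = _grid_positions(n, img)
                phenotype = _assign_phenotypes(
                    n, fractions, config.clonal_cluster_size, rng
                )
                stromal = rng.random(n) < config.stromal_fraction

                log_t = rng.normal(config.mu_T, config.sd_T, n)
                log_t = log_t + np.where(
                    np.isin(phenotype, ("high_tomm20", "combined")),
                    config.high_tomm20_shift * config.sd_T,
                    0.0,
                )
                eps_n = rng.normal(0.0, config.resid_sd_N, n)
                eps_n -= np.where(
                    np.isin(phenotype, ("ndufb8_deficient", "combined")),
                    config.deficiency_shift * config.resid_sd_N,
                    0.0,
                )
                eps_m = rng.normal(0.0, config.resid_sd_M, n)
                eps_m -= np.where(
                    np.isin(phenotype, ("mtco1_deficient", "combined")),
                    config.deficiency_shift * config.resid_sd_M,
                    0.0,
                )
                log_n = config.intercept_N + config.slope_N * log_t + eps_n
                log_m = config.intercept_M + config.slope_M * log_t + eps_m
                od_t, od_n, od_m = 10.0**log_t, 10.0**log_n, 10.0**log_m

                ck_base = np.where(stromal, config.ck_stromal, config.ck_epithelial)
                od_ck = 10.0 ** (np.log10(ck_base) + rng.normal(0, config.ck_log_sd, n))
                od_dapi = 10.0 ** (
                    np.log10(config.dapi_level) + rng.normal(0, config.dapi_log_sd, n)
                )

                cell_ids = np.array(
                    [f"c{cell_counter + i:07d}" for i in range(n)], dtype=object
                )
                cell_counter += n
                rows_c.append(
                    pd.DataFrame(
                        {
                            "patient_id": patient_id,
                            "group": group,
                            "roi_id": roi_id,
                            "region": region,
                            "cell_id": cell_ids,
                            "area_px": cyt_area,
                            "od_ndufb8": od_n,
                            "od_mtco1": od_m,
                            "od_tomm20": od_t,
                            "od_ck": od_ck,
                            "od_dapi": od_dapi,
                            "tissue_class": np.where(stromal, "stromal", "epithelial"),
                            "x": x,
                            "y": y,
                        }
                    )
                )
                rows_g.append(
                    pd.DataFrame(
                        {
                            "cell_id": cell_ids,
                            "roi_id": roi_id,
                            "label": np.arange(1, n + 1),
                            "phenotype": phenotype,
                            "x": x,
                            "y": y,
                            "abund_DAPI": od_dapi,
                            "abund_Opal520": od_n,
                            "abund_Opal570": od_t,
                            "abund_Opal620": od_m,
                            "abund_Opal690": od_ck,
                            "nucleus_area_px": nuc_area,
                            "area_px": cyt_area,
                        }
                    )
                )
    cells = pd.concat(rows_c, ignore_index=True)
    truth = pd.concat(rows_g, ignore_index=True)
    return cells, truth


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    inside = dy**2 + dx**2 <= radius**2
    return dy[inside], dx[inside]


def _disk_areas(img: ImageConfig) -> tuple[int, int]:
    return len(_disk_offsets(img.nucleus_radius)[0]), len(
        _disk_offsets(img.cytoplasm_radius)[0]
    )


def render_tissue_cube(
    truth_roi: pd.DataFrame,
    library: SpectralLibrary,
    config: SimConfig,
    noise_seed: int | None = None,
) -> tuple[MultispectralCube, np.ndarray]:
    """Render one ROI's ground-truth cells into a multispectral cube + mask.

    Per-pixel spectrum is the nonnegative linear combination
    ``sum_f A_f(px) * endmember_f + af(px) * autofluorescence`` plus the
    configured noise. DAPI abundance is painted on the nucleus disk only;
    every other fluorophore uniformly over the full cell footprint, so the
    per-cell mean of each marker plane equals the planted abundance exactly.

    Overlapping cells resolve deterministically: the lower label id wins,
    with a warning when any pixel contends.
    """
    img = config.image
    h, w = img.height, img.width
    mask = np.zeros((h, w), dtype=np.int32)
    planes = {name: np.zeros((h, w)) for name in library.endmembers}
    missing = [f for f in FLUOROPHORES if f not in library.endmembers]
    if missing:
        raise ConfigurationError(f"library missing fluorophores: {missing}")

    dy_c, dx_c = _disk_offsets(img.cytoplasm_radius)
    dy_n, dx_n = _disk_offsets(img.nucleus_radius)

    overlap = 0
    for row in truth_roi.sort_values("label").itertuples():
        yy, xx = row.y + dy_c, row.x + dx_c
        keep = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        yy, xx = yy[keep], xx[keep]
        free = mask[yy, xx] == 0
        overlap += int((~free).sum())
        yy, xx = yy[free], xx[free]
        mask[yy, xx] = row.label
        for fluor in ("Opal520", "Opal570", "Opal620", "Opal690"):
            planes[fluor][yy, xx] = getattr(row, f"abund_{fluor}")
        yn, xn = row.y + dy_n, row.x + dx_n
        keep = (yn >= 0) & (yn < h) & (xn >= 0) & (xn < w)
        yn, xn = yn[keep], xn[keep]
        own = mask[yn, xn] == row.label
        planes["DAPI"][yn[own], xn[own]] = row.abund_DAPI
    if overlap:
        warnings.warn(
            f"{overlap} overlapping cell pixels; precedence by ascending label id",
            stacklevel=2,
        )

    af_plane = np.full((h, w), float(img.autofluorescence_level))
    cube = np.zeros((h, w, library.n_bands))
    for name, plane in planes.items():
        cube += plane[:, :, None] * library.endmembers[name][None, None, :]
    cube += af_plane[:, :, None] * library.autofluorescence[None, None, :]

    if img.noise_model != "none":
        nrng = np.random.default_rng(config.seed if noise_seed is None else noise_seed)
        cube = nrng.poisson(np.clip(cube, 0, None) * img.gain) / img.gain
        if img.noise_model == "poisson_read" and img.read_noise_sd > 0:
            cube = cube + nrng.normal(0.0, img.read_noise_sd, cube.shape)
        cube = np.clip(cube, 0.0, None)

    return MultispectralCube(data=cube, wavelengths=library.wavelengths), mask
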