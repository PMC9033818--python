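import numpy as np
import pytest

from mitoplex.simgen import (
    ImageConfig,
    SimConfig,
    make_spectral_library,
    render_tissue_cube,
    simulate_cell_population,
)


@pytest.fixture(scope="session")
def library():
    return make_spectral_library()


def small_config(**overrides) -> SimConfig:
    """One-patient-per-group noiseless config used across tests."""
    defaults = dict(
        seed=42,
        n_patients_per_group=1,
        rois_per_patient=1,
        cells_per_roi=60,
        stromal_fraction=0.2,
        image=ImageConfig(height=128, width=128, noise_model="none"),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture()
def noiseless_config():
    return small_config()


@pytest.fixture(scope="session")
def noiseless_scene(library):
    """A rendered noiseless single-ROI scene: (cube, mask, truth_roi, config)."""
    cfg = small_config()
    _, truth = simulate_cell_population(cfg)
    roi = truth["roi_id"].iloc[0]
    truth_roi = truth.loc[truth["roi_id"] == roi].reset_index(drop=True)
    cube, mask = render_tissue_cube(truth_roi, library, cfg)
    return cube, mask, truth_roi, cfg


@pytest.fixture(scope="session")
def control_cells():
    """A pure-control cohort large enough for stable model fits."""
    cfg = SimConfig(
        seed=7,
        groups=("young_benign",),
        n_patients_per_group=2,
        rois_per_patient=1,
        cells_per_roi=3000,
        stromal_fraction=0.0,
        deficiency_fractions={"young_benign": {}},
        image=ImageConfig(height=700, width=700),
    )
    cells, _ = simulate_cell_population(cfg)
    return cells, cfg


def expected_planes(mask: np.ndarray, truth_roi, fluor: str) -> np.ndarray:
    """Reconstruct a marker plane from the mask + ground truth table alone
    (independent of the renderer's painting code path)."""
    lut = np.zeros(int(mask.max()) + 1)
    for row in truth_roi.itertuples():
        lut[row.label] = getattr(row, f"abund_{fluor}")
    return lut[mask]
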