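"""File I/O: multi-page TIFF cubes, label masks, YAML libraries/models, CSV tables.

Cubes are written one band per TIFF page with the wavelength recorded in the
page description as JSON (``{"wavelength_nm": 540.0}``). Masks are single-page
integer TIFFs. Everything else is YAML or CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from mitoplex.errors import ConfigurationError
from mitoplex.spectra import MultispectralCube, SpectralLibrary


def write_cube(path: str | Path, cube: MultispectralCube) -> None:
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for b in range(cube.n_bands):
            tif.write(
                cube.data[:, :, b].astype(np.float32),
                description=json.dumps({"wavelength_nm": float(cube.wavelengths[b])}),
                contiguous=False,
            )


def read_cube(path: str | Path) -> MultispectralCube:
    path = Path(path)
    bands, wavelengths = [], []
    with tifffile.TiffFile(path) as tif:
        for page in tif.pages:
            bands.append(page.asarray())
            desc = page.tags.get("ImageDescription")
            if desc is None:
                raise ConfigurationError(f"{path}: page missing wavelength metadata")
            try:
                wavelengths.append(float(json.loads(desc.value)["wavelength_nm"]))
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ConfigurationError(
                    f"{path}: cannot parse wavelength metadata: {desc.value!r}"
                ) from exc
    data = np.stack(bands, axis=2).astype(float)
    return MultispectralCube(data=data, wavelengths=np.asarray(wavelengths), cube_id=path.stem)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=np.int32))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int64)


def write_library(path: str | Path, library: SpectralLibrary) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(library.to_dict(), fh, sort_keys=False)


def read_library(path: str | Path) -> SpectralLibrary:
    with open(path) as fh:
        return SpectralLibrary.from_dict(yaml.safe_load(fh))


def write_cells(path: str | Path, cells: pd.DataFrame) -> None:
    cells.to_csv(path, index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_component_planes(out_dir: str | Path, components) -> dict[str, Path]:
    """One single-page float TIFF per component plane; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, plane in components.planes.items():
        p = out_dir / f"{name}.tif"
        tifffile.imwrite(p, plane.astype(np.float32))
        paths[name] = p
    if components.residual is not None:
        p = out_dir / "residual.tif"
        tifffile.imwrite(p, components.residual.astype(np.float32))
        paths["residual"] = p
    return paths


def read_component_planes(paths: dict[str, str | Path]):
    from mitoplex.spectra import ComponentImages

    planes = {}
    residual = None
    for name, p in paths.items():
        arr = tifffile.imread(Path(p)).astype(float)
        if name == "residual":
            residual = arr
        else:
            planes[name] = arr
    return ComponentImages(planes=planes, residual=residual)
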