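"""Core spectral data containers: wavelength grids, libraries and image cubes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitoplex.errors import ConfigurationError
from mitoplex.panel import AF_NAME


@dataclass
class SpectralLibrary:
    """A wavelength grid plus one emission spectrum per fluorophore and an
    autofluorescence spectrum.

    Endmember spectra are unit-peak normalised; the autofluorescence spectrum
    is stored as-is (it may be a raw mean spectrum from a reference slide).
    """

    wavelengths: np.ndarray
    endmembers: dict[str, np.ndarray]
    autofluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.ndim != 1 or len(self.wavelengths) < 2:
            raise ConfigurationError("wavelength grid needs at least 2 bands")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        b = len(self.wavelengths)
        self.endmembers = {k: np.asarray(v, dtype=float) for k, v in self.endmembers.items()}
        for name, spec in self.endmembers.items():
            if spec.shape != (b,):
                raise ConfigurationError(
                    f"endmember {name!r} has {spec.shape} bands, expected {b}"
                )
            if np.any(spec < 0):
                raise ConfigurationError(f"endmember {name!r} has negative values")
        self.autofluorescence = np.asarray(self.autofluorescence, dtype=float)
        if self.autofluorescence.shape != (b,):
            raise ConfigurationError("autofluorescence spectrum length mismatch")
        if np.any(self.autofluorescence < 0):
            raise ConfigurationError("autofluorescence spectrum has negative values")

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths)

    @property
    def names(self) -> list[str]:
        """Component names in matrix order: fluorophores then autofluorescence."""
        return list(self.endmembers) + [AF_NAME]

    def matrix(self) -> np.ndarray:
        """(B, K) matrix of all components including autofluorescence."""
        cols = list(self.endmembers.values()) + [self.autofluorescence]
        return np.stack(cols, axis=1)

    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": [float(w) for w in self.wavelengths],
            "endmembers": {k: [float(x) for x in v] for k, v in self.endmembers.items()},
            "autofluorescence": [float(x) for x in self.autofluorescence],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralLibrary":
        return cls(
            wavelengths=np.asarray(d["wavelengths_nm"], dtype=float),
            endmembers={k: np.asarray(v, dtype=float) for k, v in d["endmembers"].items()},
            autofluorescence=np.asarray(d["autofluorescence"], dtype=float),
        )


@dataclass
class MultispectralCube:
    """H x W x B nonnegative intensity array with its wavelength axis."""

    data: np.ndarray
    wavelengths: np.ndarray
    cube_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("cube must be H x W x B")
        if self.data.shape[2] != len(self.wavelengths):
            raise ConfigurationError(
                f"cube has {self.data.shape[2]} bands but "
                f"{len(self.wavelengths)} wavelengths"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def mean_spectrum(self) -> np.ndarray:
        return self.data.reshape(-1, self.n_bands).mean(axis=0)


@dataclass
class ComponentImages:
    """Named nonnegative abundance plane per spectral component.

    The autofluorescence plane is carried but flagged non-marker: it is
    excluded from downstream marker quantification.
    """

    planes: dict[str, np.ndarray]
    residual: np.ndarray | None = None
    library_id: str = ""
    cube_id: str = ""
    af_name: str = field(default=AF_NAME)

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) > 1:
            raise ConfigurationError(f"component planes disagree on shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    @property
    def marker_names(self) -> list[str]:
        return [n for n in self.planes if n != self.af_name]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.planes[name]
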