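"""Spectral library construction and nonnegative linear unmixing.

Per pixel, the observed spectrum is decomposed by nonnegativity-constrained
least squares against all fluorophore endmembers plus the autofluorescence
spectrum. The autofluorescence abundance is estimated jointly but its plane
is flagged non-marker, which is how its contribution is removed from
downstream marker quantification.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls

from mitoplex.errors import CollinearLibraryError, ConfigurationError, NoSignalError
from mitoplex.panel import AF_NAME
from mitoplex.spectra import ComponentImages, MultispectralCube, SpectralLibrary

_COLLINEAR_COS = 1.0 - 1e-10


def build_library_from_singleplex(
    singleplex_cubes: dict[str, MultispectralCube],
    autofluorescence_cube: MultispectralCube,
    bright_fraction: float = 0.02,
) -> SpectralLibrary:
    """Derive a spectral library from single-stain reference cubes.

    For each fluorophore the mean spectrum of the brightest ``bright_fraction``
    of pixels (by total band sum) is taken, the autofluorescence reference
    spectrum (mean spectrum of the autofluorescence cube) is subtracted,
    negatives are clipped to zero and the result is unit-peak normalised.
    The autofluorescence entry is stored as the raw mean spectrum.
    """
    if not 0 < bright_fraction <= 0.5:
        raise ConfigurationError("bright_fraction must be in (0, 0.5]")
    wl = autofluorescence_cube.wavelengths
    for name, cube in singleplex_cubes.items():
        if not np.array_equal(cube.wavelengths, wl):
            raise ConfigurationError(
                f"singleplex cube {name!r} wavelength grid differs from "
                "the autofluorescence cube"
            )
    af_ref = autofluorescence_cube.mean_spectrum()

    endmembers: dict[str, np.ndarray] = {}
    for name, cube in singleplex_cubes.items():
        flat = cube.data.reshape(-1, cube.n_bands)
        totals = flat.sum(axis=1)
        if totals.max() <= 0:
            raise NoSignalError(f"no signal in singleplex cube {name!r}")
        cutoff = np.quantile(totals, 1.0 - bright_fraction)
        bright = flat[totals >= cutoff]
        spec = np.clip(bright.mean(axis=0) - af_ref, 0.0, None)
        if spec.max() <= 0:
            raise NoSignalError(
                f"singleplex cube {name!r} has no signal above autofluorescence"
            )
        endmembers[name] = spec / spec.max()
    return SpectralLibrary(wavelengths=wl, endmembers=endmembers, autofluorescence=af_ref)


def _check_rank(library: SpectralLibrary) -> np.ndarray:
    e = library.matrix()
    norms = np.linalg.norm(e, axis=0)
    if np.any(norms == 0):
        idx = int(np.argmin(norms))
        raise ConfigurationError(f"component {library.names[idx]!r} is all zero")
    unit = e / norms
    gram = unit.T @ unit
    k = gram.shape[0]
    iu = np.triu_indices(k, 1)
    worst = np.argmax(np.abs(gram[iu]))
    if np.abs(gram[iu][worst]) >= _COLLINEAR_COS or np.linalg.matrix_rank(e) < k:
        i, j = iu[0][worst], iu[1][worst]
        raise CollinearLibraryError((library.names[i], library.names[j]))
    return e


def unmix_cube(cube: MultispectralCube, library: SpectralLibrary) -> ComponentImages:
    """Unmix a cube into per-component abundance planes plus a residual plane.

    Fast path: the unconstrained least-squares solution is computed for all
    pixels at once; pixels whose solution is already nonnegative are accepted
    (clipping tiny negative round-off), the rest are re-solved with NNLS.
    The result is identical to per-pixel NNLS for a full-column-rank library.
    """
    if not np.array_equal(cube.wavelengths, library.wavelengths):
        raise ConfigurationError("cube band grid does not match library grid")
    e = _check_rank(library)
    h, w, b = cube.shape
    k = e.shape[1]
    flat = cube.data.reshape(-1, b)

    coefs = np.zeros((flat.shape[0], k))
    nonzero = flat.any(axis=1)
    if nonzero.any():
        sol, *_ = np.linalg.lstsq(e, flat[nonzero].T, rcond=None)
        sol = sol.T
        ok = sol.min(axis=1) >= -1e-10
        out = np.clip(sol, 0.0, None)
        redo = np.flatnonzero(nonzero)[~ok]
        coefs[nonzero] = out
        for i in redo:
            coefs[i], _ = nnls(e, flat[i])

    resid = np.linalg.norm(flat - coefs @ e.T, axis=1).reshape(h, w)
    names = library.names
    planes = {name: coefs[:, j].reshape(h, w) for j, name in enumerate(names)}
    return ComponentImages(
        planes=planes, residual=resid, cube_id=cube.cube_id, af_name=AF_NAME
    )
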