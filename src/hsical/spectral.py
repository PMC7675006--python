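"""Core spectral types and wavelength-grid arithmetic.

Everything in the calibration chain that is a function of wavelength --
tile reflectance, illumination power, sensor band responses -- is carried
as a :class:`SpectralCurve`: a sampled, nonnegative function on a strictly
increasing wavelength grid in nanometres.  The instrument geometry (band
centers, FWHMs, mosaic layout) is described by :class:`BandSet`, whose
packaged constants for the three supported setups are loaded from a JSON
resource with :func:`load_band_table`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "WORKING_GRID",
    "CHART_GRID",
    "SpectralCurve",
    "BandDef",
    "BandSet",
    "SensorResponseSet",
    "ReferenceChart",
    "resample_curve",
    "gaussian_band_response",
    "load_band_table",
    "available_setups",
    "exposure_table",
    "scale_factor_table",
]

#: Common internal working grid, 390-1000 nm at 1 nm.  Band FWHMs go down to
#: 4 nm, so response/illumination integrals need sub-FWHM sampling.
WORKING_GRID = np.arange(390.0, 1000.0 + 0.5, 1.0)

#: Reference-chart I/O grid, 390-1000 nm at 10 nm (62 samples).
CHART_GRID = np.arange(390.0, 1000.0 + 5.0, 10.0)

# Gaussian FWHM = 2*sqrt(2*ln 2) * sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _as_grid(wavelengths) -> np.ndarray:
    grid = np.asarray(wavelengths, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("wavelength grid must be 1-D with at least 2 samples")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    return grid


@dataclass(frozen=True)
class SpectralCurve:
    """A sampled function of wavelength (nm) to a nonnegative value."""

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "wavelengths_nm", _as_grid(self.wavelengths_nm))
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.wavelengths_nm.shape:
            raise ValueError("values and wavelengths must have equal length")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("curve values must be finite and >= 0")
        object.__setattr__(self, "values", vals)

    def __call__(self, wavelengths_nm) -> np.ndarray:
        """Linear interpolation within the curve's support (no extrapolation)."""
        w = np.asarray(wavelengths_nm, dtype=float)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if np.any(w < lo) or np.any(w > hi):
            raise ValueError(
                f"requested wavelengths outside support [{lo}, {hi}] nm"
            )
        return np.interp(w, self.wavelengths_nm, self.values)

    def resample(self, grid) -> "SpectralCurve":
        grid = _as_grid(grid)
        return SpectralCurve(grid, self(grid))

    def integral(self) -> float:
        """Trapezoidal integral over the curve's support (value * nm)."""
        return float(np.trapezoid(self.values, self.wavelengths_nm))


def resample_curve(curve: SpectralCurve, grid) -> SpectralCurve:
    """Resample ``curve`` onto ``grid`` by linear interpolation.

    The grid must lie within the curve's support; extrapolation raises
    ``ValueError``.  At shared sample points the result is exact.
    """
    return curve.resample(grid)


def gaussian_band_response(center_nm: float, fwhm_nm: float, grid) -> SpectralCurve:
    """Unit-peak Gaussian band response with the given center and FWHM."""
    if fwhm_nm <= 0:
        raise ValueError("fwhm_nm must be > 0")
    grid = _as_grid(grid)
    sigma = fwhm_nm * _FWHM_TO_SIGMA
    vals = np.exp(-0.5 * ((grid - center_nm) / sigma) ** 2)
    return SpectralCurve(grid, vals)


@dataclass(frozen=True)
class BandDef:
    """One spectral band: center, FWHM, and its position on the sensor.

    ``sensor_index`` is the band's physical position (row-major cell index
    within the mosaic period for snapshot cameras, wheel slot for the
    filter-wheel); ``sorted_index`` is its rank by ascending center
    wavelength.  The two orderings generally differ.
    """

    center_nm: float
    fwhm_nm: float
    sensor_index: int
    sorted_index: int

    def __post_init__(self):
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be > 0")


@dataclass(frozen=True)
class BandSet:
    """The band layout of one acquisition setup."""

    setup_name: str
    bands: tuple
    pattern: int

    _EXPECTED = {"filter_wheel": 19, "cam4x4": 16, "cam5x5": 25}

    def __post_init__(self):
        bands = tuple(self.bands)
        object.__setattr__(self, "bands", bands)
        centers = [b.center_nm for b in bands]
        if len(set(centers)) != len(centers):
            raise ValueError("band centers must be unique")
        if self.setup_name in self._EXPECTED:
            want = self._EXPECTED[self.setup_name]
            if len(bands) != want:
                raise ValueError(
                    f"{self.setup_name} must have {want} bands, got {len(bands)}"
                )
        if self.pattern < 1:
            raise ValueError("pattern must be >= 1")
        if self.pattern > 1 and self.pattern ** 2 < len(bands):
            raise ValueError("mosaic period too small for band count")
        ranks = {b.sorted_index for b in bands}
        if ranks != set(range(len(bands))):
            raise ValueError("sorted_index must be a permutation rank")

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def is_mosaic(self) -> bool:
        return self.pattern > 1

    @property
    def centers_nm(self) -> np.ndarray:
        """Band centers in ascending (sorted_index) order."""
        return np.array([b.center_nm for b in self.sorted_bands()])

    @property
    def fwhms_nm(self) -> np.ndarray:
        return np.array([b.fwhm_nm for b in self.sorted_bands()])

    def sorted_bands(self) -> list:
        return sorted(self.bands, key=lambda b: b.sorted_index)

    def sensor_to_sorted(self) -> dict:
        """Map sensor_index -> sorted_index."""
        return {b.sensor_index: b.sorted_index for b in self.bands}


@dataclass(frozen=True)
class SensorResponseSet:
    """Per-band sensor response curves on a common wavelength grid."""

    bandset: BandSet
    grid: np.ndarray
    responses: tuple  # SpectralCurve per band, in sorted_index order

    def __post_init__(self):
        grid = _as_grid(self.grid)
        object.__setattr__(self, "grid", grid)
        responses = tuple(self.responses)
        object.__setattr__(self, "responses", responses)
        if len(responses) != self.bandset.n_bands:
            raise ValueError("one response per band required")
        for r in responses:
            if r.wavelengths_nm.shape != grid.shape or not np.allclose(
                r.wavelengths_nm, grid
            ):
                raise ValueError("all responses must share the common grid")
            if np.any(r.values > 1.0 + 1e-12):
                raise ValueError("response values must lie in [0, 1]")

    def matrix(self) -> np.ndarray:
        """Responses stacked as a (bands x wavelengths) matrix, sorted order."""
        return np.stack([r.values for r in self.responses])


@dataclass(frozen=True)
class ReferenceChart:
    """24-tile reference chart: known reflectance and per-wavelength SD.

    18 colored plus 6 gray tiles, each with a calibrated reflectance
    spectrum on the 390-1000 nm / 10 nm grid and a per-wavelength
    measurement SD.
    """

    tile_names: tuple
    reflectance: dict  # name -> SpectralCurve on CHART_GRID
    sd: dict  # name -> ndarray, same length as CHART_GRID

    def __post_init__(self):
        names = tuple(self.tile_names)
        object.__setattr__(self, "tile_names", names)
        if len(names) != 24:
            raise ValueError("a reference chart has exactly 24 tiles")
        for name in names:
            curve = self.reflectance[name]
            if curve.wavelengths_nm.shape != CHART_GRID.shape or not np.allclose(
                curve.wavelengths_nm, CHART_GRID
            ):
                raise ValueError("chart curves must be on the 390-1000/10 nm grid")
            if np.any(curve.values > 1.0 + 1e-12):
                raise ValueError("reflectance must lie in [0, 1]")
            sd = np.asarray(self.sd[name], dtype=float)
            if sd.shape != CHART_GRID.shape or np.any(sd < 0):
                raise ValueError("sd must be nonnegative, one value per wavelength")

    @property
    def grid(self) -> np.ndarray:
        return CHART_GRID


def _load_tables() -> dict:
    text = resources.files("hsical.data").joinpath("band_tables.json").read_text()
    return json.loads(text)


def available_setups() -> list:
    return sorted(_load_tables()["setups"])


def load_band_table(setup_name: str) -> BandSet:
    """Load the packaged band constants for one setup.

    filter_wheel: 19 bands, 400-700 nm step 20 (FWHM 10) plus 750/800/850
    (FWHM 25).  cam4x4: 16 bands, 463-638 nm.  cam5x5: 25 bands, 693-966 nm.
    """
    tables = _load_tables()["setups"]
    if setup_name not in tables:
        raise ValueError(
            f"unknown setup {setup_name!r}; expected one of {sorted(tables)}"
        )
    entry = tables[setup_name]
    raw = entry["bands"]
    order = np.argsort([b["center_nm"] for b in raw])
    rank = np.empty(len(raw), dtype=int)
    rank[order] = np.arange(len(raw))
    bands = tuple(
        BandDef(
            center_nm=b["center_nm"],
            fwhm_nm=b["fwhm_nm"],
            sensor_index=int(b["sensor_index"]),
            sorted_index=int(rank[i]),
        )
        for i, b in enumerate(raw)
    )
    return BandSet(setup_name=setup_name, bands=bands, pattern=int(entry["pattern"]))


def exposure_table() -> dict:
    """Per-(setup, illumination) optimal frame exposure times in ms."""
    out = {}
    for setup, entry in _load_tables()["exposure_ms"].items():
        for illum, ms in entry.items():
            out[(setup, illum)] = float(ms)
    return out


def scale_factor_table() -> dict:
    """Per-(setup, illumination) identified intensity-correction factors alpha."""
    out = {}
    for setup, entry in _load_tables()["scale_factors"].items():
        for illum, a in entry.items():
            out[(setup, illum)] = float(a)
    return out
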