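"""Forward model of both acquisition setups.

The simulator renders raw sensor frames from a known scene so that every
stage of the calibration chain can be checked against ground truth.  It
emulates the physics that matter to calibration -- broadband or
narrowband illumination, Gaussian band responses with optional secondary
peaks, radial vignetting, dark offset, read and shot noise, exposure
scaling, and full-well saturation -- and deliberately nothing else (no
PSF, no chromatic aberration, no thermal drift).

Two acquisition geometries are supported:

* snapshot mosaic cameras (4x4 or 5x5 filter period on the sensor), where
  one exposure yields a single 2-D :class:`MosaicFrame`;
* the filter-wheel microscope, where the *illumination* is narrowband and
  a panchromatic sensor records one frame per band (:class:`FrameStack`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectral import (
    CHART_GRID,
    WORKING_GRID,
    BandSet,
    ReferenceChart,
    SensorResponseSet,
    SpectralCurve,
    gaussian_band_response,
)

__all__ = [
    "IlluminationSpectrum",
    "SceneModel",
    "AcquisitionParams",
    "MosaicFrame",
    "FrameStack",
    "make_reference_chart",
    "make_illumination",
    "make_sensor_responses",
    "default_secondary_peaks",
    "render_mosaic_frame",
    "render_filterwheel_stack",
    "render_reference_frames",
    "chart_scene",
    "tile_masks",
    "make_two_region_cube",
    "GRAY_LEVELS",
    "WHITE_BOARD_REFLECTANCE",
]

#: Fixed reflectance levels of the six gray tiles.
GRAY_LEVELS = (0.90, 0.59, 0.36, 0.19, 0.09, 0.03)

#: Reflectance of the white calibration board.
WHITE_BOARD_REFLECTANCE = 0.95


@dataclass(frozen=True)
class IlluminationSpectrum:
    """Relative radiometric power of a light source."""

    kind: str  # xenon | led | flat
    curve: SpectralCurve

    def __post_init__(self):
        if self.kind in ("xenon", "led"):
            below = self.curve.wavelengths_nm < 400.0
            if np.any(self.curve.values[below] > 0):
                raise ValueError(f"{self.kind} illumination must be zero below 400 nm")


@dataclass(frozen=True)
class SceneModel:
    """A labeled scene: per-pixel tile label plus label -> reflectance."""

    tile_map: np.ndarray  # int labels, (H, W)
    label_spectra: dict  # label -> SpectralCurve

    def __post_init__(self):
        tm = np.asarray(self.tile_map)
        if tm.ndim != 2:
            raise ValueError("tile_map must be 2-D")
        object.__setattr__(self, "tile_map", tm)
        for lab in np.unique(tm):
            if int(lab) not in self.label_spectra:
                raise ValueError(f"no spectrum for label {lab}")
        for curve in self.label_spectra.values():
            if np.any(curve.values > 1.0 + 1e-12):
                raise ValueError("scene reflectance must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.tile_map.shape[0]

    @property
    def width(self) -> int:
        return self.tile_map.shape[1]


@dataclass(frozen=True)
class AcquisitionParams:
    """Exposure, sensor and noise settings for one acquisition.

    ``gain_counts`` converts integrated in-band radiance (relative power x
    reflectance x response, integrated over nm) times exposure (ms) into
    sensor counts.  The default full well of 4095 corresponds to a 12-bit
    readout.
    """

    exposure_ms: float
    full_well_counts: float = 4095.0
    dark_offset_counts: float = 100.0
    read_noise_sd_counts: float = 0.0
    shot_noise: bool = False
    vignetting_strength: float = 0.0
    gain_counts: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be > 0")
        if not 0 <= self.vignetting_strength < 1:
            raise ValueError("vignetting_strength must be in [0, 1)")
        if self.dark_offset_counts >= self.full_well_counts:
            raise ValueError("dark offset must be below full well")
        if self.read_noise_sd_counts < 0:
            raise ValueError("read_noise_sd_counts must be >= 0")

    @property
    def noiseless(self) -> bool:
        return self.read_noise_sd_counts == 0 and not self.shot_noise


@dataclass(frozen=True)
class MosaicFrame:
    """Raw 2-D snapshot readout with its mosaic band layout."""

    pixels: np.ndarray
    bandset: BandSet
    exposure_ms: float

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("mosaic frame must be 2-D")
        p = self.bandset.pattern
        if p < 2:
            raise ValueError("mosaic frame requires a mosaic bandset (pattern > 1)")
        if px.shape[0] % p or px.shape[1] % p:
            raise ValueError("frame dimensions must be multiples of the pattern")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class FrameStack:
    """Sequential filter-wheel readout: one 2-D frame per band."""

    frames: np.ndarray  # (bands, H, W)
    bandset: BandSet
    exposure_ms: float

    def __post_init__(self):
        fr = np.asarray(self.frames, dtype=float)
        if fr.ndim != 3:
            raise ValueError("frames must be a (bands, H, W) array")
        if fr.shape[0] != self.bandset.n_bands:
            raise ValueError("frame count must equal band count")
        object.__setattr__(self, "frames", fr)


# ---------------------------------------------------------------------------
# scene and instrument generators
# ---------------------------------------------------------------------------

def _smooth_random_reflectance(rng: np.random.Generator) -> np.ndarray:
    """One colored tile: 2-4 Gaussian bumps, scaled into [0.03, 0.95]."""
    n_bumps = rng.integers(2, 5)
    vals = np.full_like(CHART_GRID, 0.05)
    for _ in range(n_bumps):
        center = rng.uniform(400.0, 980.0)
        width = rng.uniform(40.0, 120.0)
        height = rng.uniform(0.2, 1.0)
        vals = vals + height * np.exp(-0.5 * ((CHART_GRID - center) / width) ** 2)
    lo, hi = vals.min(), vals.max()
    span = rng.uniform(0.4, 0.92)
    base = rng.uniform(0.03, 0.9 - span * 0.9)
    vals = base + span * (vals - lo) / (hi - lo)
    return np.clip(vals, 0.03, 0.95)


def _sd_envelope(rng: np.random.Generator) -> np.ndarray:
    """Per-wavelength SD growing from ~0.002 (visible) to ~0.11 (NIR)."""
    x = (CHART_GRID - 780.0) / 60.0
    envelope = 0.002 + 0.108 / (1.0 + np.exp(-x))
    scale = rng.uniform(0.5, 1.0)
    return envelope * scale


def make_reference_chart(seed: int = 0) -> ReferenceChart:
    """Synthesize a 24-tile reference chart with smooth, known spectra.

    18 colored tiles are random smooth Gaussian-bump mixtures; 6 gray
    tiles are flat at fixed levels.  Each tile carries a per-wavelength
    SD envelope that grows from the visible into the NIR, mimicking the
    behaviour of spectroradiometer chart calibrations.  Gray tiles are
    seed-independent; colored tiles vary with the seed.
    """
    rng = np.random.default_rng(seed)
    names, refl, sd = [], {}, {}
    for i in range(18):
        name = f"color_{i:02d}"
        names.append(name)
        refl[name] = SpectralCurve(CHART_GRID, _smooth_random_reflectance(rng))
        sd[name] = _sd_envelope(rng)
    for i, level in enumerate(GRAY_LEVELS):
        name = f"gray_{i}"
        names.append(name)
        refl[name] = SpectralCurve(CHART_GRID, np.full_like(CHART_GRID, level))
        sd[name] = _sd_envelope(rng)
    return ReferenceChart(tile_names=tuple(names), reflectance=refl, sd=sd)


def make_illumination(kind: str, grid=None) -> IlluminationSpectrum:
    """Reference illumination spectra.

    ``xenon``: near-flat from 400 nm up, with two narrow emission peaks
    between 810 and 845 nm.  ``led``: strong 460 nm peak, elevated
    525-680 nm plateau, rapidly decaying above 680 nm, hence very little
    NIR power.  ``flat``: unit power everywhere (for tests).
    """
    grid = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    if kind == "flat":
        return IlluminationSpectrum("flat", SpectralCurve(grid, np.ones_like(grid)))
    if kind == "xenon":
        vals = np.ones_like(grid)
        # gentle roll-off beyond the 850 nm design interval
        vals = np.where(grid > 850.0, 1.0 - 0.4 * (grid - 850.0) / 150.0, vals)
        for peak, height in ((818.0, 1.2), (838.0, 1.6)):
            vals = vals + height * np.exp(-0.5 * ((grid - peak) / 4.0) ** 2)
        vals[grid < 400.0] = 0.0
        return IlluminationSpectrum("xenon", SpectralCurve(grid, vals))
    if kind == "led":
        peak = 1.0 * np.exp(-0.5 * ((grid - 460.0) / 12.0) ** 2)
        plateau = 0.55 / (1.0 + np.exp(-(grid - 505.0) / 12.0))
        plateau = plateau / (1.0 + np.exp((grid - 690.0) / 9.0))
        vals = peak + plateau + 0.002
        vals[grid < 400.0] = 0.0
        return IlluminationSpectrum("led", SpectralCurve(grid, vals))
    raise ValueError(f"unknown illumination kind {kind!r}")


def default_secondary_peaks(bandset: BandSet) -> list:
    """Default secondary-response contamination for the NIR snapshot camera.

    Two 5x5-camera bands receive an additive secondary Gaussian roughly
    150 nm below their primary, with 30% of the primary height,
    emulating the dual peak responses such mosaic sensors exhibit.  The
    secondary center snaps to the nearest band center (872 -> 732 nm,
    932 -> 784 nm): second-order response peaks contaminate wavelengths
    the sensor is otherwise sensitive to, which is also what makes them
    correctable from the other bands' signals.  Other setups default to
    clean unimodal responses.
    """
    if bandset.setup_name != "cam5x5":
        return []
    centers = bandset.centers_nm
    out = []
    for rank in (13, 19):  # bands at 872 and 932 nm
        band = bandset.sorted_bands()[rank]
        nearest = centers[np.argmin(np.abs(centers - (band.center_nm - 150.0)))]
        out.append((rank, float(nearest), 0.3))
    return out


def _peak_heights(bandset: BandSet) -> np.ndarray:
    if bandset.setup_name == "cam4x4":
        heights = np.full(bandset.n_bands, 0.2)
        heights[3] = 0.1  # one low-response band
        return heights
    if bandset.setup_name == "cam5x5":
        heights = np.full(bandset.n_bands, 0.1)
        # outer bands respond weaker than the central block
        heights[:5] = 0.05
        heights[15:] = 0.05
        return heights
    return np.ones(bandset.n_bands)


def make_sensor_responses(
    bandset: BandSet,
    secondary_peaks=None,
    grid=None,
) -> SensorResponseSet:
    """Gaussian primary responses at the packaged band centers/FWHMs.

    Peak heights are ~0.2 for the 4x4 camera (one band at 0.1) and ~0.1
    or lower for the 5x5 camera, reproducing the per-band response gaps
    of real mosaic sensors.  ``secondary_peaks`` is a list of
    ``(sorted_band_index, center_nm, relative_height)`` adding a secondary
    Gaussian (same FWHM as the primary) to selected bands; relative
    heights must stay below 1.
    """
    grid = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    heights = _peak_heights(bandset)
    curves = []
    for band, h in zip(bandset.sorted_bands(), heights):
        curves.append(h * gaussian_band_response(band.center_nm, band.fwhm_nm, grid).values)
    if secondary_peaks:
        sorted_bands = bandset.sorted_bands()
        centers = np.array([b.center_nm for b in sorted_bands])
        for rank, center, rel in secondary_peaks:
            if rel >= 1.0:
                raise ValueError("secondary peak height must be below the primary")
            # a secondary leak has the spectral shape of the band structure
            # it leaks through: use the FWHM of the nearest band
            nearest = sorted_bands[int(np.argmin(np.abs(centers - center)))]
            sec = gaussian_band_response(center, nearest.fwhm_nm, grid).values
            curves[rank] = curves[rank] + rel * heights[rank] * sec
    responses = tuple(SpectralCurve(grid, np.clip(c, 0.0, 1.0)) for c in curves)
    return SensorResponseSet(bandset=bandset, grid=grid, responses=responses)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _vignetting_profile(height: int, width: int, strength: float) -> np.ndarray:
    """Radial quartic falloff, 1 at center, 1 - strength at the corners."""
    if strength == 0:
        return np.ones((height, width))
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    y = (np.arange(height) - cy) / max(cy, 0.5)
    x = (np.arange(width) - cx) / max(cx, 0.5)
    r2 = (y[:, None] ** 2 + x[None, :] ** 2) / 2.0  # corner -> 1
    return 1.0 - strength * r2 ** 2


def _band_signals(
    scene: SceneModel,
    weights: np.ndarray,
    grid: np.ndarray,
    acq: AcquisitionParams,
) -> dict:
    """Per-label, per-band noiseless signal above dark (counts).

    ``weights`` is a (bands x wavelengths) matrix of illumination x
    response products on ``grid``; the per-band signal is the Riemann sum
    against the label's reflectance, scaled by exposure and gain.
    """
    dlam = np.gradient(grid)
    out = {}
    for lab, curve in scene.label_spectra.items():
        refl = curve(np.clip(grid, curve.wavelengths_nm[0], curve.wavelengths_nm[-1]))
        out[lab] = acq.exposure_ms * acq.gain_counts * (weights * refl * dlam).sum(axis=1)
    return out


def _add_noise(
    signal: np.ndarray, acq: AcquisitionParams, rng: np.random.Generator
) -> np.ndarray:
    counts = signal
    if acq.shot_noise:
        counts = rng.poisson(np.clip(counts, 0.0, None)).astype(float)
    counts = counts + acq.dark_offset_counts
    if acq.read_noise_sd_counts > 0:
        counts = counts + rng.normal(0.0, acq.read_noise_sd_counts, counts.shape)
    return np.clip(counts, 0.0, acq.full_well_counts)


def render_mosaic_frame(
    scene: SceneModel,
    illumination: IlluminationSpectrum,
    responses: SensorResponseSet,
    acq: AcquisitionParams,
    rng: np.random.Generator | None = None,
) -> MosaicFrame:
    """Render one raw snapshot frame of ``scene``.

    Each pixel integrates illumination x reflectance x band response over
    wavelength for the band sitting at its mosaic position, scaled by
    exposure and gain, attenuated by the vignetting profile, offset by
    the dark level, and degraded by the configured noise before clipping
    to the full well.
    """
    bandset = responses.bandset
    p = bandset.pattern
    if p < 2:
        raise ValueError("render_mosaic_frame requires a mosaic bandset")
    if scene.height % p or scene.width % p:
        raise ValueError("scene dimensions must be multiples of the mosaic pattern")
    if rng is None:
        rng = np.random.default_rng(acq.seed)

    grid = responses.grid
    illum = illumination.curve(np.clip(grid, *illumination.curve.wavelengths_nm[[0, -1]]))
    weights = responses.matrix() * illum  # sorted-band order
    signals = _band_signals(scene, weights, grid, acq)

    # band (sorted index) at each pixel from its mosaic cell position
    sensor_to_sorted = bandset.sensor_to_sorted()
    cell = np.empty((p, p), dtype=int)
    for b in bandset.bands:
        cell[b.sensor_index // p, b.sensor_index % p] = b.sorted_index
    # unused mosaic cells (pattern^2 > bands) repeat the last band
    band_map = cell[np.arange(scene.height)[:, None] % p, np.arange(scene.width)[None, :] % p]

    signal = np.empty((scene.height, scene.width))
    for lab, per_band in signals.items():
        mask = scene.tile_map == lab
        signal[mask] = per_band[band_map[mask]]
    signal = signal * _vignetting_profile(scene.height, scene.width, acq.vignetting_strength)
    counts = _add_noise(signal, acq, rng)
    return MosaicFrame(pixels=counts, bandset=bandset, exposure_ms=acq.exposure_ms)


def render_filterwheel_stack(
    scene: SceneModel,
    bandset: BandSet,
    acq: AcquisitionParams,
    illumination: IlluminationSpectrum | None = None,
    rng: np.random.Generator | None = None,
) -> FrameStack:
    """Render the sequential filter-wheel acquisition of ``scene``.

    The wheel places a Gaussian band filter (packaged center/FWHM) in the
    illumination path of the broadband source, and a panchromatic sensor
    (flat quantum efficiency) records one frame per band.
    """
    if bandset.setup_name != "filter_wheel":
        raise ValueError("render_filterwheel_stack requires the filter_wheel bandset")
    if illumination is None:
        illumination = make_illumination("xenon")
    if rng is None:
        rng = np.random.default_rng(acq.seed)

    grid = WORKING_GRID
    envelope = illumination.curve(np.clip(grid, *illumination.curve.wavelengths_nm[[0, -1]]))
    weights = np.stack(
        [
            gaussian_band_response(b.center_nm, b.fwhm_nm, grid).values * envelope
            for b in bandset.sorted_bands()
        ]
    )
    signals = _band_signals(scene, weights, grid, acq)

    vig = _vignetting_profile(scene.height, scene.width, acq.vignetting_strength)
    frames = np.empty((bandset.n_bands, scene.height, scene.width))
    for k in range(bandset.n_bands):
        signal = np.empty((scene.height, scene.width))
        for lab, per_band in signals.items():
            signal[scene.tile_map == lab] = per_band[k]
        frames[k] = _add_noise(signal * vig, acq, rng)
    return FrameStack(frames=frames, bandset=bandset, exposure_ms=acq.exposure_ms)


def _uniform_scene(height: int, width: int, reflectance: float) -> SceneModel:
    curve = SpectralCurve(WORKING_GRID, np.full_like(WORKING_GRID, reflectance))
    return SceneModel(tile_map=np.zeros((height, width), dtype=int), label_spectra={0: curve})


def render_reference_frames(
    acq: AcquisitionParams,
    illumination: IlluminationSpectrum,
    responses_or_bandset,
    n_dark: int,
    shape: tuple,
    white_exposure_ms: float | None = None,
):
    """Render the calibration references: a dark series and a white frame.

    Dark frames are signal-free renders (illumination off) sharing the
    acquisition's noise settings.  The white frame images a uniform
    0.95-reflectance calibration board, acquired with its own exposure
    (``white_exposure_ms``, default the acquisition exposure), which is
    recorded in the returned frame's metadata.

    Returns ``(dark_frames, white)`` where ``dark_frames`` is a list of
    2-D arrays and ``white`` a :class:`MosaicFrame` or :class:`FrameStack`
    matching the setup geometry.
    """
    if n_dark < 1:
        raise ValueError("n_dark must be >= 1")
    height, width = shape
    rng = np.random.default_rng(acq.seed)
    zero = np.zeros((height, width))
    dark_frames = [_add_noise(zero, acq, rng) for _ in range(n_dark)]

    white_exp = acq.exposure_ms if white_exposure_ms is None else white_exposure_ms
    white_acq = replace(acq, exposure_ms=white_exp)
    board = _uniform_scene(height, width, WHITE_BOARD_REFLECTANCE)
    if isinstance(responses_or_bandset, SensorResponseSet):
        white = render_mosaic_frame(board, illumination, responses_or_bandset, white_acq, rng=rng)
    else:
        white = render_filterwheel_stack(board, responses_or_bandset, white_acq,
                                         illumination=illumination, rng=rng)
    return dark_frames, white


# ---------------------------------------------------------------------------
# scene helpers
# ---------------------------------------------------------------------------

def chart_scene(
    chart: ReferenceChart,
    tile_px: int,
    n_rows: int = 4,
    n_cols: int = 6,
) -> SceneModel:
    """Lay the 24 chart tiles out as an ``n_rows x n_cols`` grid scene."""
    if n_rows * n_cols != len(chart.tile_names):
        raise ValueError("grid must hold exactly the chart's tiles")
    tile_map = np.zeros((n_rows * tile_px, n_cols * tile_px), dtype=int)
    spectra = {}
    for idx, name in enumerate(chart.tile_names):
        r, c = divmod(idx, n_cols)
        tile_map[r * tile_px:(r + 1) * tile_px, c * tile_px:(c + 1) * tile_px] = idx
        spectra[idx] = chart.reflectance[name]
    return SceneModel(tile_map=tile_map, label_spectra=spectra)


def tile_masks(tile_map: np.ndarray, factor: int = 1, margin: int = 1) -> dict:
    """Per-label boolean masks at ``1/factor`` resolution, edges eroded.

    ``factor`` is the mosaic pattern for demosaiced cubes (the cube pixel
    (i, j) samples the full-resolution block at (i*factor, j*factor)).
    ``margin`` drops that many boundary pixels of each tile region to keep
    the mask clear of tile borders.
    """
    sub = tile_map[::factor, ::factor]
    masks = {}
    for lab in np.unique(tile_map):
        m = sub == lab
        for _ in range(margin):
            inner = np.zeros_like(m)
            inner[1:-1, 1:-1] = (
                m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
            )
            m = inner
        if not m.any():  # tiny tiles: fall back to the uneroded region
            m = sub == lab
        masks[int(lab)] = m
    return masks


def make_two_region_cube(
    bandset: BandSet,
    shape: tuple = (40, 40),
    interval_nm: tuple = (460.0, 480.0),
    contrast: float = 0.05,
    noise_sd: float = 0.01,
    brightness_sd: float = 0.1,
    base_level: float = 0.5,
    seed: int = 0,
):
    """Two-tissue reflectance cube for enhancement experiments.

    Both regions share a flat base spectrum modulated by a smooth
    per-pixel brightness field (the dominant variance, as global shading
    is in clinical scenes).  Region B additionally raises the bands whose
    centers fall inside ``interval_nm`` by ``contrast``; iid Gaussian
    noise of ``noise_sd`` is added everywhere.  Returns
    ``(data, region_b_mask)`` with ``data`` of shape (bands, H, W).
    """
    rng = np.random.default_rng(seed)
    height, width = shape
    centers = bandset.centers_nm
    n = bandset.n_bands

    yy, xx = np.meshgrid(np.linspace(-1, 1, height), np.linspace(-1, 1, width),
                         indexing="ij")
    coeff = rng.normal(0.0, 1.0, 5)
    field = (coeff[0] * yy + coeff[1] * xx + coeff[2] * yy * xx
             + coeff[3] * (yy ** 2 - 0.5) + coeff[4] * (xx ** 2 - 0.5))

    region_b = np.zeros((height, width), dtype=bool)
    region_b[:, width // 2:] = True

    # shading must carry no label information: equalize its region means so
    # the only systematic region difference is the in-interval contrast
    field[region_b] -= field[region_b].mean()
    field[~region_b] -= field[~region_b].mean()
    field = 1.0 + brightness_sd * field / max(field.std(), 1e-12)

    in_interval = (centers >= interval_nm[0]) & (centers <= interval_nm[1])
    data = base_level * field[None, :, :] * np.ones((n, 1, 1))
    data[in_interval[:, None, None] & region_b[None, :, :]] += contrast
    data = data + rng.normal(0.0, noise_sd, data.shape)
    return np.clip(data, 0.0, None), region_b
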