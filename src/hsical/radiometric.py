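"""Radiometric calibration: flat field, dark/white reflectance, SNR, alpha.

The chain converts raw sensor counts into physically comparable
reflectance:

1. flat-field / vignetting correction -- per band, a gain map
   ``I_ref / I_meas`` estimated from a dark-subtracted image of a
   spatially uniform target, where ``I_ref`` is the mean over a small
   window at the sensor center;
2. one-point reflectance conversion --
   ``I_res = (I_raw - I_dark) / (I_white - I_dark_white) * (e_white / e_raw)``
   with per-acquisition exposures ``e``;
3. SNR bookkeeping from the temporal statistics of a shielded-sensor
   dark series (``SNR = A_signal / sigma_noise``);
4. a single scalar intensity correction ``I_final = alpha * I_res`` per
   setup/illumination, fitted by least squares through the origin against
   a reference chart, excluding wavelengths above a NIR cutoff
   (default 850 nm) where reference and signal quality degrade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectral import BandSet, ReferenceChart, SpectralCurve

__all__ = [
    "DarkReference",
    "WhiteReference",
    "FlatFieldGain",
    "BandCube",
    "ScaleCorrection",
    "ValidationReport",
    "average_dark",
    "estimate_flat_field",
    "apply_flat_field",
    "to_reflectance",
    "compute_snr",
    "fit_alpha",
    "apply_alpha",
    "validate_against_chart",
    "REGION_BREAKS_NM",
]

#: Validation region breakpoints: visible / red-NIR transition / deep NIR.
REGION_BREAKS_NM = (680.0, 850.0)


@dataclass(frozen=True)
class BandCube:
    """Band-indexed image cube with band metadata and a unit tag.

    ``data`` is (bands, H, W) with bands in ascending-wavelength
    (sorted_index) order.  ``unit`` is ``"counts"`` or ``"reflectance"``;
    the only allowed transition is counts -> reflectance.  ``provenance``
    records the calibration steps applied, in order.
    """

    data: np.ndarray
    bandset: BandSet
    unit: str = "counts"
    provenance: tuple = ()
    exposure_ms: float | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("cube data must be (bands, H, W)")
        if data.shape[0] != self.bandset.n_bands:
            raise ValueError(
                f"cube has {data.shape[0]} planes but bandset defines "
                f"{self.bandset.n_bands} bands"
            )
        if self.unit not in ("counts", "reflectance"):
            raise ValueError("unit must be 'counts' or 'reflectance'")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    def with_data(self, data, step: str, unit: str | None = None) -> "BandCube":
        unit = self.unit if unit is None else unit
        if self.unit == "reflectance" and unit == "counts":
            raise ValueError("unit may only move from counts to reflectance")
        return BandCube(
            data=data,
            bandset=self.bandset,
            unit=unit,
            provenance=self.provenance + (step,),
            exposure_ms=self.exposure_ms,
        )


@dataclass(frozen=True)
class DarkReference:
    """Temporal statistics of a shielded-sensor dark series."""

    mean_frame: np.ndarray  # (H, W) or (bands, H, W)
    noise_sd: np.ndarray  # same shape
    exposure_ms: float
    n_frames: int

    def __post_init__(self):
        mean = np.asarray(self.mean_frame, dtype=float)
        sd = np.asarray(self.noise_sd, dtype=float)
        if sd.shape != mean.shape:
            raise ValueError("noise_sd must match mean_frame shape")
        if np.any(sd < 0):
            raise ValueError("noise_sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        object.__setattr__(self, "mean_frame", mean)
        object.__setattr__(self, "noise_sd", sd)

    @property
    def sd_valid(self) -> bool:
        """False when the series was too short to estimate temporal SD."""
        return self.n_frames > 1


@dataclass(frozen=True)
class WhiteReference:
    """White calibration board acquisition, with its own exposure."""

    frame: np.ndarray  # (H, W) or (bands, H, W)
    exposure_ms: float
    board_reflectance: float = 0.95

    def __post_init__(self):
        frame = np.asarray(self.frame, dtype=float)
        if not 0 < self.board_reflectance <= 1:
            raise ValueError("board_reflectance must be in (0, 1]")
        object.__setattr__(self, "frame", frame)


@dataclass(frozen=True)
class FlatFieldGain:
    """Per-band multiplicative gain map normalizing the sensor center to 1."""

    gain: np.ndarray  # (bands, H, W)
    center_window_px: int
    invalid: np.ndarray = None  # (bands, H, W) bool, masked pixels

    def __post_init__(self):
        gain = np.asarray(self.gain, dtype=float)
        if gain.ndim != 3:
            raise ValueError("gain must be (bands, H, W)")
        invalid = self.invalid
        if invalid is None:
            invalid = np.zeros(gain.shape, dtype=bool)
        object.__setattr__(self, "gain", gain)
        object.__setattr__(self, "invalid", np.asarray(invalid, dtype=bool))


@dataclass(frozen=True)
class ScaleCorrection:
    """The scalar intensity-correction factor alpha for one configuration."""

    alpha: float
    setup_name: str = ""
    illumination_kind: str = ""
    lambda_max_nm: float = 850.0

    def __post_init__(self):
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError("alpha must be positive and finite")


@dataclass(frozen=True)
class ValidationReport:
    """Chart-validation result: per-tile differences and regional RMSE.

    ``difference`` maps tile name -> (reconstructed - reference) at the
    measured band centers; ``within_sd`` flags points whose |difference|
    lies inside the chart's stated SD envelope.  ``rmse_by_region`` keys
    are ``visible`` (lambda <= 680), ``red_nir`` (680-850) and
    ``deep_nir`` (> 850).
    """

    wavelengths_nm: np.ndarray
    difference: dict
    within_sd: dict
    rmse_by_region: dict
    reconstructed: dict = field(default_factory=dict)
    reference: dict = field(default_factory=dict)

    def mean_difference(self) -> float:
        return float(np.mean([d.mean() for d in self.difference.values()]))

    def overall_rmse(self, lambda_min=None, lambda_max=None) -> float:
        w = self.wavelengths_nm
        sel = np.ones_like(w, dtype=bool)
        if lambda_min is not None:
            sel &= w >= lambda_min
        if lambda_max is not None:
            sel &= w <= lambda_max
        if not sel.any():
            raise ValueError("no bands in requested wavelength window")
        sq = [d[sel] ** 2 for d in self.difference.values()]
        return float(np.sqrt(np.mean(np.concatenate(sq))))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def average_dark(frames, exposure_ms: float) -> DarkReference:
    """Temporal mean and SD of a dark-frame series.

    With a single frame the SD is zero and the result is flagged
    (``sd_valid`` False).
    """
    stack = np.stack([np.asarray(f, dtype=float) for f in frames])
    if stack.shape[0] < 1:
        raise ValueError("need at least one dark frame")
    mean = stack.mean(axis=0)
    if stack.shape[0] == 1:
        sd = np.zeros_like(mean)
        warnings.warn("single dark frame: temporal SD unavailable", stacklevel=2)
    else:
        sd = stack.std(axis=0, ddof=1)
    return DarkReference(
        mean_frame=mean, noise_sd=sd, exposure_ms=exposure_ms,
        n_frames=stack.shape[0],
    )


def estimate_flat_field(
    uniform_cube: BandCube,
    center_window_px: int = 10,
    min_fraction: float = 1e-3,
) -> FlatFieldGain:
    """Estimate per-band flat-field gain from a uniform-target cube.

    The input must be a dark-subtracted render of a spatially uniform
    target (normally the white board).  Per band, ``I_ref`` is the mean
    over the ``(2w+1)^2`` center window and the gain is ``I_ref/I_meas``
    per pixel.  Pixels below ``min_fraction * I_ref`` are masked (gain 1)
    rather than producing unbounded gains.
    """
    data = uniform_cube.data
    _, height, width = data.shape
    w = center_window_px
    if 2 * w + 1 > height or 2 * w + 1 > width:
        raise ValueError("center window exceeds image size")
    cy, cx = height // 2, width // 2
    win = (slice(cy - w, cy + w + 1), slice(cx - w, cx + w + 1))

    gain = np.ones_like(data)
    invalid = np.zeros(data.shape, dtype=bool)
    for b in range(data.shape[0]):
        i_ref = data[b][win].mean()
        if i_ref <= 0:
            raise ValueError(f"band {b}: nonpositive center reference intensity")
        bad = data[b] <= min_fraction * i_ref
        invalid[b] = bad
        gain[b][~bad] = i_ref / data[b][~bad]
    frac = invalid.mean()
    if frac >= 0.05:
        warnings.warn(
            f"flat field: {frac:.1%} of pixels masked as near-zero", stacklevel=2
        )
    return FlatFieldGain(gain=gain, center_window_px=w, invalid=invalid)


def apply_flat_field(cube: BandCube, gain: FlatFieldGain) -> BandCube:
    """Apply the per-band flat-field gain (element-wise multiplication)."""
    if gain.gain.shape != cube.data.shape:
        raise ValueError("gain shape does not match cube")
    return cube.with_data(cube.data * gain.gain, "flat_field")


def _dark_for(cube_shape, dark: DarkReference) -> np.ndarray:
    mean = dark.mean_frame
    if mean.ndim == 2:
        return mean[None, :, :]
    return mean


def to_reflectance(
    raw: BandCube,
    dark: DarkReference,
    white: WhiteReference,
    white_dark: DarkReference | None = None,
    apply_board_reflectance: bool = False,
) -> BandCube:
    """One-point conversion of raw counts to reflectance.

    ``I_res = (I_raw - I_dark) / (I_white - I_dark_white) * (e_white/e_raw)``.
    Pixels whose white denominator is <= 0 are set to NaN (invalid).
    Negative results (noise below the dark level) are kept, not clipped,
    so that region averages stay unbiased.  By default the white board's
    own 0.95 reflectance is *not* divided out (the scalar it leaves
    behind is absorbed by the alpha correction); pass
    ``apply_board_reflectance=True`` to multiply by the board reflectance
    and obtain absolute reflectance directly.
    """
    if raw.unit != "counts":
        raise ValueError("input cube must be in counts")
    if white_dark is None:
        white_dark = dark
    if raw.exposure_ms is None or raw.exposure_ms <= 0:
        raise ValueError("missing exposure metadata on raw cube")
    if white.exposure_ms is None or white.exposure_ms <= 0:
        raise ValueError("missing exposure metadata on white reference")

    num = raw.data - _dark_for(raw.data.shape, dark)
    wframe = white.frame if white.frame.ndim == 3 else white.frame[None, :, :]
    den = wframe - _dark_for(wframe.shape, white_dark)
    ratio = white.exposure_ms / raw.exposure_ms
    with np.errstate(divide="ignore", invalid="ignore"):
        res = num / den * ratio
    res = np.where(den > 0, res, np.nan)
    if apply_board_reflectance:
        res = res * white.board_reflectance
    return raw.with_data(res, "reflectance_conversion", unit="reflectance")


def compute_snr(signal_amplitude, dark: DarkReference) -> np.ndarray:
    """Per-band SNR = A_signal / sigma_noise.

    ``sigma_noise`` per band is the spatial median of the dark series'
    per-pixel temporal SD.  A zero sigma (e.g. a single-frame dark
    series) is an error: the SNR is undefined.
    """
    amp = np.atleast_1d(np.asarray(signal_amplitude, dtype=float))
    sd = dark.noise_sd
    if sd.ndim == 2:
        sigma = np.full(amp.shape, float(np.median(sd)))
    else:
        sigma = np.array([float(np.median(sd[b])) for b in range(sd.shape[0])])
        if sigma.shape != amp.shape:
            raise ValueError("signal amplitude count must match band count")
    if np.any(sigma <= 0):
        raise ZeroDivisionError("sigma_noise is zero: SNR undefined")
    return amp / sigma


def _pool_measured(measured_tile_spectra, chart, lambda_max_nm):
    m_all, r_all = [], []
    for name, curve in measured_tile_spectra.items():
        ref = chart.reflectance[name]
        w = curve.wavelengths_nm
        sel = w <= lambda_max_nm
        sel &= (w >= ref.wavelengths_nm[0]) & (w <= ref.wavelengths_nm[-1])
        vals = np.asarray(curve.values, dtype=float)
        ok = sel & np.isfinite(vals)
        if not ok.any():
            continue
        m_all.append(vals[ok])
        r_all.append(ref(w[ok]))
    if not m_all:
        raise ValueError("no usable (tile, wavelength) points below the cutoff")
    return np.concatenate(m_all), np.concatenate(r_all)


def fit_alpha(
    measured_tile_spectra: dict,
    chart: ReferenceChart,
    lambda_max_nm: float = 850.0,
    setup_name: str = "",
    illumination_kind: str = "",
) -> ScaleCorrection:
    """Fit the scalar intensity correction by least squares through origin.

    ``measured_tile_spectra`` maps tile name -> measured
    :class:`SpectralCurve` at the band centers.  Pooling all tiles and
    wavelengths at or below ``lambda_max_nm``, the estimate is

        alpha = sum(m * r) / sum(m * m)

    which minimizes ``sum (alpha*m - r)^2``.  Wavelengths above the
    cutoff (unreliable NIR) never enter the fit.
    """
    m, r = _pool_measured(measured_tile_spectra, chart, lambda_max_nm)
    denom = float(np.dot(m, m))
    if denom == 0:
        raise ValueError("all measured values are zero: alpha fit degenerate")
    alpha = float(np.dot(m, r) / denom)
    if alpha <= 0:
        raise ValueError(f"degenerate alpha fit: alpha={alpha}")
    return ScaleCorrection(
        alpha=alpha,
        setup_name=setup_name,
        illumination_kind=illumination_kind,
        lambda_max_nm=lambda_max_nm,
    )


def apply_alpha(cube: BandCube, sc: ScaleCorrection) -> BandCube:
    """Apply the intensity correction ``I_final = alpha * I_res``."""
    if cube.unit != "reflectance":
        raise ValueError("alpha correction applies to reflectance cubes")
    return cube.with_data(cube.data * sc.alpha, f"alpha={sc.alpha:.6g}")


def extract_tile_spectra(cube: BandCube, tile_masks: dict, tile_names) -> dict:
    """Spatial mean spectrum per tile at the cube's band centers."""
    centers = cube.bandset.centers_nm
    out = {}
    for label, name in enumerate(tile_names):
        mask = tile_masks[label]
        if not np.any(mask):
            raise ValueError(f"empty mask for tile {name}")
        spec = np.nanmean(cube.data[:, mask], axis=1)
        out[name] = SpectralCurve(centers, np.clip(spec, 0.0, None))
    return out


def validate_against_chart(
    cube: BandCube,
    chart: ReferenceChart,
    tile_masks: dict,
    region_breaks_nm: tuple = REGION_BREAKS_NM,
) -> ValidationReport:
    """Compare a calibrated cube against the reference chart.

    For each tile the spatial mean spectrum at the measured band centers
    is compared to the chart reflectance resampled onto those centers:
    ``d = reconstructed - reference``.  Points are flagged as inside the
    chart's SD envelope, and RMSE is summarized per spectral region
    (defaults: <= 680 nm, 680-850 nm, > 850 nm).
    """
    centers = cube.bandset.centers_nm
    lo, hi = chart.grid[0], chart.grid[-1]
    usable = (centers >= lo) & (centers <= hi)
    if not usable.any():
        raise ValueError("no band centers fall inside the chart grid")
    w = centers[usable]

    measured = extract_tile_spectra(cube, tile_masks, chart.tile_names)
    diff, within, recon, refer = {}, {}, {}, {}
    for name in chart.tile_names:
        rec = np.asarray(measured[name].values)[usable]
        ref = chart.reflectance[name](w)
        sd = np.interp(w, chart.grid, chart.sd[name])
        d = rec - ref
        diff[name] = d
        within[name] = np.abs(d) <= np.maximum(sd, 1e-12)
        recon[name] = rec
        refer[name] = ref

    b1, b2 = region_breaks_nm
    regions = {
        "visible": w <= b1,
        "red_nir": (w > b1) & (w <= b2),
        "deep_nir": w > b2,
    }
    rmse = {}
    for rname, sel in regions.items():
        if sel.any():
            sq = np.concatenate([diff[n][sel] ** 2 for n in chart.tile_names])
            rmse[rname] = float(np.sqrt(np.mean(sq)))
        else:
            rmse[rname] = float("nan")
    return ValidationReport(
        wavelengths_nm=w,
        difference=diff,
        within_sd=within,
        rmse_by_region=rmse,
        reconstructed=recon,
        reference=refer,
    )
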