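"""Mosaic demosaicing and the spectral crosstalk correction matrix.

Snapshot mosaic sensors measure each band through a filter whose response
overlaps its neighbours and may carry secondary peaks, so the per-band
signal mixes light from other wavelengths.  This module extracts the
band planes from the raw mosaic (one sample per pattern cell, no
interpolation) and builds a correction matrix ``C`` such that applying
``I_cor = I_res . C`` per pixel behaves like a deconvolution of the
spectral bands: the corrected signal approximates what nearly ideal
narrowband Gaussian filters at the nominal centers/FWHMs would have
measured.  This step applies only to the snapshot-camera path; the
filter-wheel setup selects wavelengths on the illumination side and
needs no spectral correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radiometric import BandCube
from .simulate import MosaicFrame
from .spectral import BandSet, SensorResponseSet, gaussian_band_response

__all__ = [
    "CorrectionMatrix",
    "demosaic",
    "build_correction_matrix",
    "apply_spectral_correction",
]


@dataclass(frozen=True)
class CorrectionMatrix:
    """Band-in x band-out crosstalk correction matrix."""

    matrix: np.ndarray
    ridge: float
    target_bandset: BandSet

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or not np.all(np.isfinite(m)):
            raise ValueError("correction matrix must be 2-D and finite")
        object.__setattr__(self, "matrix", m)


def demosaic(frame: MosaicFrame) -> BandCube:
    """Extract band planes from a raw mosaic frame.

    Plane ``k`` collects the pixels whose position within the mosaic
    period holds band ``k``; planes are ordered by ascending center
    wavelength, not by sensor position.  The output spatial size is the
    input divided by the pattern; no interpolation is performed.
    """
    p = frame.bandset.pattern
    h, w = frame.pixels.shape
    planes = np.empty((frame.bandset.n_bands, h // p, w // p))
    for band in frame.bandset.bands:
        r, c = divmod(band.sensor_index, p)
        planes[band.sorted_index] = frame.pixels[r::p, c::p]
    return BandCube(
        data=planes,
        bandset=frame.bandset,
        unit="counts",
        provenance=("demosaic",),
        exposure_ms=frame.exposure_ms,
    )


def build_correction_matrix(
    responses: SensorResponseSet,
    target: BandSet | None = None,
    ridge: float = 1e-4,
    normalize: str | None = "flat",
) -> CorrectionMatrix:
    """Compute the crosstalk correction matrix from measured responses.

    Let ``R`` be the measured band responses and ``T`` ideal unit-area
    Gaussian targets at the nominal centers/FWHMs, both normalized to
    unit integral (matching the white-reference normalization each
    reflectance band has already received).  Scene reflectance is smooth
    on the scale of the band spacing, so the deconvolution is solved on
    a smooth scene-spectrum basis ``Phi`` (Gaussians at the band
    centers, widths set by the local band spacing) rather than over the
    full wavelength space: with ``A = R Phi`` and ``B = T Phi`` the band
    responses to each basis spectrum, ``C`` solves the
    Tikhonov-regularized least squares

        min_C || C^T A - B ||^2 + ridge * || C ||^2

    via the band-overlap Gram matrix: ``C = (A A^T + ridge I)^-1 A B^T``.
    Working in this basis is what lets an isolated secondary response
    peak be cancelled out of its band using the signals of the bands
    covering the contaminating wavelengths.  With ``normalize="flat"``
    the columns are rescaled so a flat input spectrum maps exactly to a
    flat output (the least-squares solution already satisfies this
    approximately); ``normalize=None`` returns the raw least-squares
    solution (``Phi`` is an orthonormal target basis in the textbook
    two-band case, where the solution is the inverse of the band-overlap
    matrix).
    """
    if target is None:
        target = responses.bandset
    if target.n_bands != responses.bandset.n_bands:
        raise ValueError("responses and target band counts must match")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")

    grid = responses.grid
    dlam = np.gradient(grid)

    def unit_area(rows):
        areas = (rows * dlam).sum(axis=1)
        if np.any(areas <= 0):
            raise ValueError("every band response must have positive area")
        return rows / areas[:, None]

    R = unit_area(responses.matrix())
    T = unit_area(
        np.stack(
            [
                gaussian_band_response(b.center_nm, b.fwhm_nm, grid).values
                for b in target.sorted_bands()
            ]
        )
    )

    # smooth scene basis: one Gaussian per target band, width ~ local spacing
    centers = target.centers_nm
    gaps = np.diff(centers)
    width = np.empty_like(centers)
    width[0] = gaps[0]
    width[-1] = gaps[-1]
    width[1:-1] = np.maximum(gaps[:-1], gaps[1:])
    width = np.maximum(width, 2.0)
    Phi = np.stack(
        [np.exp(-0.5 * ((grid - c) / w) ** 2) for c, w in zip(centers, width)]
    )

    A = (R * dlam) @ Phi.T  # (bands x basis) responses to smooth spectra
    B = (T * dlam) @ Phi.T
    G = A @ A.T  # band-overlap Gram matrix on the smooth basis
    n = G.shape[0]
    if ridge == 0:
        cond = np.linalg.cond(G)
        if cond > 1e12:
            raise np.linalg.LinAlgError(
                f"band-overlap Gram matrix is ill-conditioned (cond={cond:.2e}); "
                "use ridge > 0"
            )
        C = np.linalg.solve(G, A @ B.T)
    else:
        scale = np.trace(G) / n
        C = np.linalg.solve(G + ridge * scale * np.eye(n), A @ B.T)

    if normalize == "flat":
        colsum = C.sum(axis=0)
        if np.any(np.abs(colsum) < 1e-12):
            raise ValueError("flat normalization degenerate: zero column sum")
        C = C / colsum[None, :]
    elif normalize is not None:
        raise ValueError("normalize must be 'flat' or None")
    return CorrectionMatrix(matrix=C, ridge=ridge, target_bandset=target)


def apply_spectral_correction(cube: BandCube, C: CorrectionMatrix) -> BandCube:
    """Apply ``I_cor = I_res . C`` to every pixel spectrum."""
    if cube.n_bands != C.matrix.shape[0]:
        raise ValueError(
            f"cube has {cube.n_bands} bands, matrix expects {C.matrix.shape[0]}"
        )
    corrected = np.einsum("bhw,bk->khw", cube.data, C.matrix)
    return cube.with_data(corrected, "spectral_correction")
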