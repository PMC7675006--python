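"""Spatial registration and assembly of the joint hypercube.

Sequential filter-wheel frames, and the cubes of the two snapshot
cameras, are aligned by integer translation maximizing normalized cross
correlation (NCC) on the valid-overlap region, then cropped to the
common field and merged into a single cube whose bands are sorted by
center wavelength.  Registration is translation-only: view-angle or
deformable misalignment is out of scope and must be handled upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radiometric import BandCube
from .spectral import BandDef, BandSet

__all__ = [
    "ShiftVector",
    "ncc_score",
    "register_translation",
    "shift_and_crop",
    "concat_bandsets",
    "assemble_hypercube",
]


@dataclass(frozen=True)
class ShiftVector:
    """Integer pixel offset (dy, dx) with the NCC score at the optimum."""

    dy: int
    dx: int
    score: float

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.score <= 1.0 + 1e-9:
            raise ValueError("NCC score must lie in [-1, 1]")


def ncc_score(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean, unit-variance normalized cross correlation of two images.

    Invariant under positive-gain affine intensity maps of either image.
    Constant images have undefined correlation and raise ``ValueError``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have equal shape")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("NCC undefined for a constant image")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _overlap(ref: np.ndarray, mov: np.ndarray, dy: int, dx: int):
    """Valid-overlap views for candidate displacement (dy, dx).

    The moving image content is displaced by (dy, dx) relative to the
    reference: mov[y, x] corresponds to ref[y - dy, x - dx].
    """
    dy, dx = -dy, -dx
    h, w = ref.shape
    ry0, ry1 = max(dy, 0), min(h, h + dy)
    rx0, rx1 = max(dx, 0), min(w, w + dx)
    my0, my1 = max(-dy, 0), min(h, h - dy)
    mx0, mx1 = max(-dx, 0), min(w, w - dx)
    return ref[ry0:ry1, rx0:rx1], mov[my0:my1, mx0:mx1]


def register_translation(
    ref: np.ndarray, moving: np.ndarray, max_shift: int = 16
) -> ShiftVector:
    """Find the integer shift of ``moving`` relative to ``ref`` by NCC.

    Exhaustive search over the ``(2*max_shift+1)^2`` window, scoring each
    candidate on the valid-overlap region only (no zero padding).  Ties
    are broken by the smallest Euclidean shift norm, then row-major
    order.  The overlap at the largest shift must keep at least 16x16
    pixels.
    """
    ref = np.asarray(ref, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if ref.shape != moving.shape:
        raise ValueError("images must have equal shape")
    h, w = ref.shape
    if h - max_shift < 16 or w - max_shift < 16:
        raise ValueError("overlap window at max_shift smaller than 16x16")

    best = None
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            r, m = _overlap(ref, moving, dy, dx)
            try:
                score = ncc_score(r, m)
            except ValueError:
                continue
            key = (-score, dy * dy + dx * dx, dy, dx)
            if best is None or key < best[0]:
                best = (key, ShiftVector(dy=dy, dx=dx, score=score))
    if best is None:
        raise ValueError("no valid shift candidate (constant images?)")
    return best[1]


def shift_and_crop(planes: np.ndarray, shifts) -> np.ndarray:
    """Undo per-plane integer shifts and crop all planes to the common field.

    ``shifts[k] = (dy, dx)`` is plane k's content displacement relative
    to the reference (``plane[y, x] = ref[y - dy, x - dx]``); the plane
    is translated back by (-dy, -dx) and the stack is cropped to the
    region where every plane has valid data.
    """
    shifts = [(int(dy), int(dx)) for dy, dx in shifts]
    h, w = planes.shape[-2:]
    y0 = max(0, max(-dy for dy, _ in shifts))
    y1 = min(h, min(h - dy for dy, _ in shifts))
    x0 = max(0, max(-dx for _, dx in shifts))
    x1 = min(w, min(w - dx for _, dx in shifts))
    if y1 - y0 <= 0 or x1 - x0 <= 0:
        raise ValueError("no common valid region after shifting")
    out = np.empty((planes.shape[0], y1 - y0, x1 - x0))
    for k, (dy, dx) in enumerate(shifts):
        out[k] = planes[k, y0 + dy:y1 + dy, x0 + dx:x1 + dx]
    return out


def concat_bandsets(*bandsets: BandSet, name: str | None = None) -> BandSet:
    """Concatenate bandsets into one, re-ranked by ascending center."""
    defs = []
    for bs in bandsets:
        defs.extend(bs.sorted_bands())
    centers = [b.center_nm for b in defs]
    if len(set(centers)) != len(centers):
        raise ValueError("concatenated bandsets must have unique centers")
    order = np.argsort(centers)
    rank = np.empty(len(defs), dtype=int)
    rank[order] = np.arange(len(defs))
    bands = tuple(
        BandDef(b.center_nm, b.fwhm_nm, sensor_index=i, sorted_index=int(rank[i]))
        for i, b in enumerate(defs)
    )
    if name is None:
        name = "+".join(bs.setup_name for bs in bandsets)
    return BandSet(setup_name=name, bands=bands, pattern=1)


def assemble_hypercube(
    cubes,
    ref_band_per_cube=None,
    max_shift: int = 8,
    register: bool = True,
) -> BandCube:
    """Register band planes and merge cubes into one sorted hypercube.

    Every band of every cube is registered (integer translation, NCC) to
    the reference band of the first cube -- by default its
    mid-wavelength band, which typically has the best SNR.  Shifted
    planes are cropped to the common valid region and the merged bands
    are sorted by center wavelength; the joint 4x4 + 5x5 snapshot cube
    has 41 bands.  Band provenance keeps a per-band source tag.
    """
    cubes = list(cubes)
    if not cubes:
        raise ValueError("need at least one cube")
    shape = cubes[0].data.shape[-2:]
    for c in cubes[1:]:
        if c.data.shape[-2:] != shape:
            raise ValueError("cubes must share spatial size")
    units = {c.unit for c in cubes}
    if len(units) > 1:
        raise ValueError("cubes must share a unit")
    if ref_band_per_cube is None:
        ref_band_per_cube = [c.n_bands // 2 for c in cubes]
    ref_plane = cubes[0].data[ref_band_per_cube[0]]

    planes = np.concatenate([c.data for c in cubes], axis=0)
    sources = []
    for c in cubes:
        sources.extend([c.bandset.setup_name] * c.n_bands)

    if register:
        shifts = []
        for plane in planes:
            try:
                s = register_translation(ref_plane, plane, max_shift=max_shift)
                shifts.append((s.dy, s.dx))
            except ValueError:
                shifts.append((0, 0))
        planes = shift_and_crop(planes, shifts)

    merged = concat_bandsets(*(c.bandset for c in cubes))
    order = np.argsort([b.center_nm for c in cubes for b in c.bandset.sorted_bands()])
    cube = BandCube(
        data=planes[order],
        bandset=merged,
        unit=cubes[0].unit,
        provenance=tuple(step for c in cubes for step in c.provenance)
        + ("assemble_hypercube",),
        exposure_ms=cubes[0].exposure_ms,
    )
    # per-band source tag rides along as an extra (frozen-safe) attribute
    object.__setattr__(cube, "band_sources", tuple(np.asarray(sources)[order]))
    return cube
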