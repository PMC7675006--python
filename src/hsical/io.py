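"""Readers and writers for the pipeline's on-disk formats.

Cubes travel as multi-page TIFF (one page per band, ascending
wavelength) with a JSON sidecar (``<path>.json``) carrying the band
definitions, unit tag, exposure and step provenance -- a lossless,
inspectable container.  Spectra (reference charts, sensor responses,
tile measurements) travel as CSV with a ``wavelength_nm`` column, one
column per named curve and optional ``<name>_sd`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .radiometric import BandCube
from .spectral import (
    BandDef,
    BandSet,
    ReferenceChart,
    SensorResponseSet,
    SpectralCurve,
)

__all__ = [
    "write_cube",
    "read_cube",
    "write_spectra_csv",
    "read_spectra_csv",
    "read_chart_csv",
    "write_chart_csv",
    "read_responses_csv",
    "write_responses_csv",
]


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def _bandset_to_dict(bs: BandSet) -> dict:
    return {
        "setup_name": bs.setup_name,
        "pattern": bs.pattern,
        "bands": [
            {
                "center_nm": b.center_nm,
                "fwhm_nm": b.fwhm_nm,
                "sensor_index": b.sensor_index,
                "sorted_index": b.sorted_index,
            }
            for b in bs.bands
        ],
    }


def _bandset_from_dict(d: dict) -> BandSet:
    bands = tuple(
        BandDef(
            center_nm=b["center_nm"],
            fwhm_nm=b["fwhm_nm"],
            sensor_index=b["sensor_index"],
            sorted_index=b["sorted_index"],
        )
        for b in d["bands"]
    )
    return BandSet(setup_name=d["setup_name"], bands=bands, pattern=d["pattern"])


def write_cube(cube: BandCube, path) -> None:
    """Write a cube as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, cube.data.astype(np.float32), photometric="minisblack")
    meta = {
        "bandset": _bandset_to_dict(cube.bandset),
        "unit": cube.unit,
        "exposure_ms": cube.exposure_ms,
        "provenance": list(cube.provenance),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_cube(path) -> BandCube:
    """Read a cube written by :func:`write_cube` (lossless round trip)."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    bandset = _bandset_from_dict(meta["bandset"])
    if data.shape[0] != bandset.n_bands:
        raise ValueError(
            f"cube file has {data.shape[0]} pages but sidecar defines "
            f"{bandset.n_bands} bands"
        )
    return BandCube(
        data=data,
        bandset=bandset,
        unit=meta["unit"],
        provenance=tuple(meta.get("provenance", ())),
        exposure_ms=meta.get("exposure_ms"),
    )


def _curves_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError("spectra CSV must have a 'wavelength_nm' column")
    w = df["wavelength_nm"].to_numpy(dtype=float)
    if not np.all(np.diff(w) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    return df


def write_spectra_csv(path, curves: dict, sd: dict | None = None) -> None:
    """Write named curves (all on one grid) with optional SD columns."""
    names = list(curves)
    grid = curves[names[0]].wavelengths_nm
    cols = {"wavelength_nm": grid}
    for name in names:
        curve = curves[name]
        if not np.array_equal(curve.wavelengths_nm, grid):
            raise ValueError("all curves must share one wavelength grid")
        cols[name] = curve.values
        if sd is not None and name in sd:
            cols[f"{name}_sd"] = np.asarray(sd[name], dtype=float)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_spectra_csv(path):
    """Read named curves; returns ``(curves, sd)`` dicts.

    SD columns (``<name>_sd``) are optional and default to zero.
    """
    df = _curves_frame(path)
    w = df["wavelength_nm"].to_numpy(dtype=float)
    names = [c for c in df.columns if c != "wavelength_nm" and not c.endswith("_sd")]
    curves, sd = {}, {}
    for name in names:
        curves[name] = SpectralCurve(w, df[name].to_numpy(dtype=float))
        col = f"{name}_sd"
        sd[name] = (
            df[col].to_numpy(dtype=float) if col in df.columns else np.zeros_like(w)
        )
    return curves, sd


def write_chart_csv(path, chart: ReferenceChart) -> None:
    write_spectra_csv(path, chart.reflectance, chart.sd)


def read_chart_csv(path) -> ReferenceChart:
    curves, sd = read_spectra_csv(path)
    return ReferenceChart(tile_names=tuple(curves), reflectance=curves, sd=sd)


def write_responses_csv(path, responses: SensorResponseSet) -> None:
    curves = {
        f"band_{i:02d}": r for i, r in enumerate(responses.responses)
    }
    write_spectra_csv(path, curves)


def read_responses_csv(path, bandset: BandSet) -> SensorResponseSet:
    curves, _ = read_spectra_csv(path)
    if len(curves) != bandset.n_bands:
        raise ValueError("response column count must match the bandset")
    names = sorted(curves)
    grid = curves[names[0]].wavelengths_nm
    return SensorResponseSet(
        bandset=bandset, grid=grid, responses=tuple(curves[n] for n in names)
    )
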