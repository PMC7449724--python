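"""File formats: two-column trace CSVs with JSON sidecars, HDF5 raster
containers, and CSV/JSON output for spectra, optical constants and
normalized images."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import Geometry
from .imaging import NormalizedImage
from .spectroscopy import ComplexSpectrum, OpticalConstants, TimeTrace
from .synthetic import ImageRaster

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_raster_h5",
    "read_raster_h5",
    "write_spectrum_csv",
    "write_optical_constants_csv",
    "write_normalized_image",
    "read_normalized_image",
    "geometry_to_dict",
    "geometry_from_dict",
]


def geometry_to_dict(geometry: Geometry) -> dict:
    d = asdict(geometry)
    for key in ("n_quartz", "n_air"):
        z = complex(d[key])
        d[key] = [z.real, z.imag]
    return d


def geometry_from_dict(d: dict) -> Geometry:
    kwargs = dict(d)
    for key in ("n_quartz", "n_air"):
        if key in kwargs and isinstance(kwargs[key], (list, tuple)):
            re, im = kwargs[key]
            kwargs[key] = complex(re, im)
    return Geometry(**kwargs)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace_csv(
    trace: TimeTrace, path, geometry: Geometry | None = None
) -> Path:
    """Write a trace as two-column CSV (time_ps, amplitude) with a JSON
    sidecar carrying the role and, optionally, the geometry."""
    path = Path(path)
    pd.DataFrame({"time_ps": trace.t, "amplitude": trace.e}).to_csv(
        path, index=False
    )
    meta = {"role": trace.role}
    if geometry is not None:
        meta["geometry"] = geometry_to_dict(geometry)
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_trace_csv(path) -> tuple[TimeTrace, Geometry | None]:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    geometry = (
        geometry_from_dict(meta["geometry"]) if "geometry" in meta else None
    )
    trace = TimeTrace(
        df["time_ps"].to_numpy(),
        df["amplitude"].to_numpy(),
        role=meta.get("role", "sample"),
    )
    return trace, geometry


def write_raster_h5(raster: ImageRaster, path) -> Path:
    """HDF5 raster container: time axis, 3-D trace cube, shared reference
    and baseline traces; pitch/group/replicate as attributes."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("time_ps", data=raster.t)
        h5.create_dataset("traces", data=raster.traces)
        h5.create_dataset("air_reference", data=raster.air_reference.e)
        h5.create_dataset("baseline", data=raster.baseline.e)
        h5.attrs["pitch_mm"] = raster.pitch_mm
        if raster.group is not None:
            h5.attrs["group"] = raster.group
        if raster.replicate is not None:
            h5.attrs["replicate"] = raster.replicate
    return path


def read_raster_h5(path) -> ImageRaster:
    with h5py.File(path, "r") as h5:
        t = h5["time_ps"][()]
        return ImageRaster(
            t=t,
            traces=h5["traces"][()],
            air_reference=TimeTrace(
                t, h5["air_reference"][()], role="air_reference"
            ),
            baseline=TimeTrace(t, h5["baseline"][()], role="baseline"),
            pitch_mm=float(h5.attrs["pitch_mm"]),
            group=str(h5.attrs["group"]) if "group" in h5.attrs else None,
            replicate=(
                int(h5.attrs["replicate"])
                if "replicate" in h5.attrs
                else None
            ),
        )


def write_spectrum_csv(spec: ComplexSpectrum, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"f_THz": spec.f, "real": spec.v.real, "imag": spec.v.imag}
    ).to_csv(path, index=False)
    return path


def write_optical_constants_csv(constants: OpticalConstants, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "f_THz": constants.f,
            "n": constants.n,
            "k": constants.k,
            "alpha_cm-1": constants.alpha,
        }
    ).to_csv(path, index=False)
    return path


def write_normalized_image(img: NormalizedImage, path) -> Path:
    """CSV matrix of |M|_norm plus a JSON sidecar (f_eval, ROI, reference)."""
    path = Path(path)
    np.savetxt(path, img.grid, delimiter=",")
    ri, rj = img.roi
    meta = {
        "f_eval_THz": img.f_eval,
        "m_before_bar": img.m_before_bar,
        "roi_rows": [ri.start, ri.stop],
        "roi_cols": [rj.start, rj.stop],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_normalized_image(path) -> NormalizedImage:
    path = Path(path)
    grid = np.loadtxt(path, delimiter=",")
    meta = json.loads(_sidecar(path).read_text())
    roi = (slice(*meta["roi_rows"]), slice(*meta["roi_cols"]))
    return NormalizedImage(
        grid=grid,
        m_before_bar=meta["m_before_bar"],
        roi=roi,
        f_eval=meta["f_eval_THz"],
    )
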