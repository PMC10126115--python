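"""Scan-container, vessel-annotation and results I/O.

The scan container is an HDF5 file with datasets ``/fringes``
(``[n_bscans, n_alines, n_samples]``), ``/wavelength_nm`` and
``/background_fringe`` plus root attributes ``axial_pixel_um``,
``lateral_pixel_um``, ``scan_type``, ``n_bscans`` and ``n_alines``.
Vessel annotations are a JSON array; results are written as CSV/JSON twins.
Datasets are written with ``track_times=False`` so a seeded simulation
produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

WAVELENGTH_MIN_NM = 500.0
WAVELENGTH_MAX_NM = 620.0


@dataclass
class RawScan:
    """A stack of spectral fringes with its wavelength calibration."""

    fringes: np.ndarray           # (n_bscans, n_alines, n_samples)
    wavelength_nm: np.ndarray     # (n_samples,), strictly increasing
    background_fringe: np.ndarray  # (n_samples,), sample arm blocked
    axial_pixel_um: float          # physical depth pixel in tissue
    lateral_pixel_um: float = 0.8
    scan_type: str = "raster"

    def __post_init__(self):
        self.fringes = np.asarray(self.fringes)
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.background_fringe = np.asarray(self.background_fringe, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.fringes.ndim != 3:
            raise ValidationError("fringes must be a 3-D [bscan, aline, sample] array")
        if self.fringes.shape[2] != self.wavelength_nm.size:
            raise ValidationError("fringe sample count must match wavelength vector")
        if self.background_fringe.size != self.wavelength_nm.size:
            raise ValidationError("background fringe length mismatch")
        d = np.diff(self.wavelength_nm)
        if not np.all(d > 0):
            raise ValidationError("wavelength calibration must be strictly increasing")
        if self.wavelength_nm.min() < WAVELENGTH_MIN_NM or \
                self.wavelength_nm.max() > WAVELENGTH_MAX_NM:
            raise ValidationError("wavelength calibration outside 500-620 nm")
        if not self.axial_pixel_um > 0:
            raise ValidationError("axial_pixel_um must be positive")
        if not self.lateral_pixel_um > 0:
            raise ValidationError("lateral_pixel_um must be positive")

    @property
    def n_bscans(self) -> int:
        return self.fringes.shape[0]

    @property
    def n_alines(self) -> int:
        return self.fringes.shape[1]


def write_scan(scan: RawScan, path) -> None:
    """Write a scan container (HDF5)."""
    with h5py.File(path, "w", track_order=True) as f:
        for name, data in (("fringes", scan.fringes),
                           ("wavelength_nm", scan.wavelength_nm),
                           ("background_fringe", scan.background_fringe)):
            f.create_dataset(name, data=data, track_times=False)
        f.attrs["axial_pixel_um"] = float(scan.axial_pixel_um)
        f.attrs["lateral_pixel_um"] = float(scan.lateral_pixel_um)
        f.attrs["scan_type"] = scan.scan_type
        f.attrs["n_bscans"] = scan.n_bscans
        f.attrs["n_alines"] = scan.n_alines


def read_scan(path) -> RawScan:
    """Read and validate a scan container."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"scan container not found: {path}")
    with h5py.File(path, "r") as f:
        for name in ("fringes", "wavelength_nm", "background_fringe"):
            if name not in f:
                raise FormatError(f"container missing dataset /{name}")
        return RawScan(
            fringes=f["fringes"][()],
            wavelength_nm=f["wavelength_nm"][()],
            background_fringe=f["background_fringe"][()],
            axial_pixel_um=float(f.attrs.get("axial_pixel_um", 0.0)),
            lateral_pixel_um=float(f.attrs.get("lateral_pixel_um", 0.8)),
            scan_type=str(f.attrs.get("scan_type", "raster")),
        )


@dataclass
class VesselAnnotation:
    """Approximate lateral bounds of a vessel, as drawn by an annotator."""

    vessel_id: str
    a_line_left: int
    a_line_right: int
    vessel_type: str = "vein"          # "artery" | "vein"
    b_scan_range: tuple = None          # (first, last+1); None = all

    def __post_init__(self):
        if self.a_line_right <= self.a_line_left:
            raise ValidationError("a_line_right must exceed a_line_left")


def write_annotations(annotations, path) -> None:
    payload = []
    for a in annotations:
        d = dataclasses.asdict(a)
        d["b_scan_range"] = list(a.b_scan_range) if a.b_scan_range else None
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path) -> list:
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise FormatError(f"cannot read annotations: {e}") from e
    out = []
    for d in payload:
        rng = d.get("b_scan_range")
        out.append(VesselAnnotation(
            vessel_id=str(d["vessel_id"]),
            a_line_left=int(d["a_line_left"]),
            a_line_right=int(d["a_line_right"]),
            vessel_type=d.get("vessel_type", "vein"),
            b_scan_range=tuple(rng) if rng else None,
        ))
    return out


ADS_SSF_RANGE = (0.02, 0.10)

_RESULT_FIELDS = ["vessel_id", "so2_fraction", "r_squared", "ssf",
                  "diameter_um", "depth_um", "window_z0_px", "window_dz_px",
                  "n_bscans_used", "method_tag"]


@dataclass
class ResultRecord:
    """One per-vessel oximetry result row."""

    vessel_id: str
    so2_fraction: float
    r_squared: float
    ssf: float
    diameter_um: float
    depth_um: float
    window_z0_px: int
    window_dz_px: int
    n_bscans_used: int
    method_tag: str = "ADS"   # "ADS" | "FA"

    def __post_init__(self):
        if not (np.isnan(self.so2_fraction) or 0.0 <= self.so2_fraction <= 1.0):
            raise ValidationError("so2_fraction must lie in [0, 1]")
        if self.method_tag == "ADS" and not np.isnan(self.ssf) and \
                not ADS_SSF_RANGE[0] <= self.ssf <= ADS_SSF_RANGE[1]:
            raise ValidationError("adaptive-method SSF outside [0.02, 0.10]")
        if self.method_tag not in ("ADS", "FA"):
            raise ValidationError("method_tag must be 'ADS' or 'FA'")


def results_frame(records) -> pd.DataFrame:
    rows = [{k: getattr(r, k) for k in _RESULT_FIELDS} for r in records]
    return pd.DataFrame(rows, columns=_RESULT_FIELDS)


def write_results(records, path_stem) -> None:
    """Write result records as CSV and JSON twins ``<stem>.csv/<stem>.json``."""
    stem = Path(path_stem)
    if stem.suffix in (".csv", ".json"):
        stem = stem.with_suffix("")
    df = results_frame(records)
    df.to_csv(stem.with_suffix(".csv"), index=False, float_format="%.12g")
    stem.with_suffix(".json").write_text(
        json.dumps(df.to_dict(orient="records"), indent=1))


def read_results(path) -> list:
    """Read result records back from the CSV (or JSON) twin."""
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        df = pd.read_csv(path)
        rows = df.to_dict(orient="records")
    out = []
    for r in rows:
        out.append(ResultRecord(
            vessel_id=str(r["vessel_id"]),
            so2_fraction=float(r["so2_fraction"]),
            r_squared=float(r["r_squared"]),
            ssf=float(r["ssf"]),
            diameter_um=float(r["diameter_um"]),
            depth_um=float(r["depth_um"]),
            window_z0_px=int(r["window_z0_px"]),
            window_dz_px=int(r["window_dz_px"]),
            n_bscans_used=int(r["n_bscans_used"]),
            method_tag=str(r["method_tag"]),
        ))
    return out
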