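"""Reading and writing motor-map tables, reference points and reports.

The neutral motor-map table is a CSV with header ``x_mm,y_mm,z_mm,mep_uv``:
one stimulation event per row, scanner-space millimetre coordinates
(+x left→right, +y posterior→anterior, +z inferior→superior) and the
peak-to-peak MEP amplitude in μV. An optional JSON sidecar
(``<stem>.json``) carries the reference point and a session label.
Vendor neuronavigation exports (Nexstim, BrainSight) are proprietary and
undocumented; this schema is the package's own interchange format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import EmptyFileError, SchemaError

__all__ = [
    "MotorMapDataset",
    "ReferencePoint",
    "MeasurementReport",
    "read_motor_map",
    "write_motor_map",
    "read_report",
    "write_report",
]

_COLUMNS = ("x_mm", "y_mm", "z_mm", "mep_uv")

_REFERENCE_SOURCES = ("imported", "centroid_default", "user_set")


@dataclass(frozen=True)
class ReferencePoint:
    """A 3D anatomical reference (mm) against which positions are reported."""

    x: float
    y: float
    z: float
    source: str = "imported"

    def __post_init__(self) -> None:
        if self.source not in _REFERENCE_SOURCES:
            raise ValueError(f"unknown reference source {self.source!r}")
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("reference point coordinates must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class MotorMapDataset:
    """Stimulation events of one mapping session.

    Parameters
    ----------
    points : (N, 3) float array
        Event positions in scanner millimetres.
    values : (N,) float array
        Peak-to-peak MEP amplitudes in μV (non-negative).
    reference_point : ReferencePoint, optional
        Shared anatomical reference; absent means "use the head centroid".
    session_label : str
        Free-text identifier of the recording session.
    """

    points: np.ndarray
    values: np.ndarray
    reference_point: Optional[ReferencePoint] = None
    session_label: str = ""
    units: tuple[str, str] = field(default=("mm", "uV"), repr=False)

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("points must have shape (N, 3)")
        if values.shape != (points.shape[0],):
            raise ValueError("values must have shape (N,)")
        if points.shape[0] < 1:
            raise ValueError("a motor map needs at least one event")
        if not np.all(np.isfinite(points)):
            raise ValueError("event coordinates must be finite")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("MEP values must be finite and non-negative")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.points.shape[0]

    def with_points(self, points: np.ndarray) -> "MotorMapDataset":
        return replace(self, points=np.asarray(points, dtype=float))

    def with_values(self, values: np.ndarray) -> "MotorMapDataset":
        return replace(self, values=np.asarray(values, dtype=float))

    def equals(self, other: "MotorMapDataset") -> bool:
        """Field-for-field equality (exact array comparison)."""
        if not np.array_equal(self.points, other.points):
            return False
        if not np.array_equal(self.values, other.values):
            return False
        if (self.reference_point is None) != (other.reference_point is None):
            return False
        if self.reference_point is not None and other.reference_point is not None:
            if not np.array_equal(self.reference_point.xyz, other.reference_point.xyz):
                return False
            if self.reference_point.source != other.reference_point.source:
                return False
        return self.session_label == other.session_label


@dataclass(frozen=True)
class MeasurementReport:
    """Single-map measurements and their distances to the reference point.

    Units: positions mm, peak value μV, surface area mm², volume integral
    μV·mm², distances mm (signed right→left / posterior→anterior /
    inferior→superior components plus the Euclidean norm).
    """

    cog: tuple[float, float, float]
    peak_position: tuple[float, float, float]
    peak_value: float
    surface_area: float
    volume_integral: float
    cog_distance: tuple[float, float, float, float]
    peak_distance: tuple[float, float, float, float]
    reference_point: Optional[ReferencePoint] = None
    session_label: str = ""

    def __post_init__(self) -> None:
        if self.surface_area < 0:
            raise ValueError("surface area must be non-negative")

    def to_dict(self) -> dict:
        d = {
            "session_label": self.session_label,
            "cog_x_mm": self.cog[0],
            "cog_y_mm": self.cog[1],
            "cog_z_mm": self.cog[2],
            "peak_x_mm": self.peak_position[0],
            "peak_y_mm": self.peak_position[1],
            "peak_z_mm": self.peak_position[2],
            "peak_value_uv": self.peak_value,
            "surface_area_mm2": self.surface_area,
            "volume_integral_uv_mm2": self.volume_integral,
            "cog_dx_mm": self.cog_distance[0],
            "cog_dy_mm": self.cog_distance[1],
            "cog_dz_mm": self.cog_distance[2],
            "cog_euclidean_mm": self.cog_distance[3],
            "peak_dx_mm": self.peak_distance[0],
            "peak_dy_mm": self.peak_distance[1],
            "peak_dz_mm": self.peak_distance[2],
            "peak_euclidean_mm": self.peak_distance[3],
        }
        if self.reference_point is not None:
            d["reference_x_mm"] = self.reference_point.x
            d["reference_y_mm"] = self.reference_point.y
            d["reference_z_mm"] = self.reference_point.z
            d["reference_source"] = self.reference_point.source
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementReport":
        reference = None
        if "reference_x_mm" in d:
            reference = ReferencePoint(
                d["reference_x_mm"],
                d["reference_y_mm"],
                d["reference_z_mm"],
                d.get("reference_source", "imported"),
            )
        return cls(
            cog=(d["cog_x_mm"], d["cog_y_mm"], d["cog_z_mm"]),
            peak_position=(d["peak_x_mm"], d["peak_y_mm"], d["peak_z_mm"]),
            peak_value=d["peak_value_uv"],
            surface_area=d["surface_area_mm2"],
            volume_integral=d["volume_integral_uv_mm2"],
            cog_distance=(
                d["cog_dx_mm"],
                d["cog_dy_mm"],
                d["cog_dz_mm"],
                d["cog_euclidean_mm"],
            ),
            peak_distance=(
                d["peak_dx_mm"],
                d["peak_dy_mm"],
                d["peak_dz_mm"],
                d["peak_euclidean_mm"],
            ),
            reference_point=reference,
            session_label=d.get("session_label", ""),
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_motor_map(path, format: str = "neutral_csv") -> MotorMapDataset:
    """Read a motor-map table from the neutral CSV schema.

    Raises
    ------
    SchemaError
        If a required column is missing.
    EmptyFileError
        If the file has no data rows.
    ValueError
        On non-numeric or negative MEP values.
    """
    if format != "neutral_csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path, header=0, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyFileError(f"{path} is empty") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path} is missing required column(s): {', '.join(missing)}")
    if len(frame) == 0:
        raise EmptyFileError(f"{path} has a header but no data rows")
    try:
        points = frame[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        values = frame["mep_uv"].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric entry in motor-map table") from exc

    reference = None
    label = ""
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("session_label", "")
        if "reference_point" in meta:
            r = meta["reference_point"]
            reference = ReferencePoint(
                r["x_mm"], r["y_mm"], r["z_mm"], r.get("source", "imported")
            )
    return MotorMapDataset(points, values, reference_point=reference, session_label=label)


def write_motor_map(dataset: MotorMapDataset, path) -> Path:
    """Write a dataset in the neutral CSV schema (+ JSON sidecar if needed)."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "x_mm": dataset.points[:, 0],
            "y_mm": dataset.points[:, 1],
            "z_mm": dataset.points[:, 2],
            "mep_uv": dataset.values,
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")
    meta: dict = {}
    if dataset.session_label:
        meta["session_label"] = dataset.session_label
    if dataset.reference_point is not None:
        meta["reference_point"] = {
            "x_mm": dataset.reference_point.x,
            "y_mm": dataset.reference_point.y,
            "z_mm": dataset.reference_point.z,
            "source": dataset.reference_point.source,
        }
    sidecar = _sidecar_path(path)
    if meta:
        sidecar.write_text(json.dumps(meta, indent=2))
    elif sidecar.exists():
        sidecar.unlink()
    return path


def write_report(report: MeasurementReport, path) -> Path:
    """Write a measurement report as JSON (and a CSV twin alongside).

    ``path`` names the JSON file; a CSV rendering with units embedded in
    the column headers is written next to it with the ``.csv`` suffix.
    """
    path = Path(path)
    d = report.to_dict()
    try:
        path.write_text(json.dumps(d, indent=2))
        pd.DataFrame([d]).to_csv(path.with_suffix(".csv"), index=False)
    except OSError as exc:
        raise IOError(f"cannot write report to {path}") from exc
    return path


def read_report(path) -> MeasurementReport:
    """Read a JSON measurement report written by :func:`write_report`."""
    return MeasurementReport.from_dict(json.loads(Path(path).read_text()))
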