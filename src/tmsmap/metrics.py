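"""Motor-map measurements: COG, peak, surface area, volume integral.

Center of gravity and peak are computed from the raw events and need no
fitted surface; the COG is the value-weighted mean position

    X_COG = Σ x_i·v_i / Σ v_i   (and likewise Y, Z)

Surface area and volume integral are discrete integrals over the dense
angular grid of the fitted surface. For every grid cell (θ, φ) whose
value is strictly above the threshold, the three corners (θ, φ),
(θ+s, φ) and (θ, φ+s) are mapped onto the scalp ellipsoid; with edge
vectors p and q the patch contributes ‖p × q‖ mm² to SA and
‖p × q‖·v μV·mm² to VI. Cells where the surface is undefined (outside
the training hull) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .errors import NoPeakError, ZeroMassError
from .geometry import AngularGrid, ScalpEllipsoid, cartesian_to_angular
from .io import MeasurementReport, MotorMapDataset, ReferencePoint
from .surfaces import SurfaceModel

__all__ = [
    "CogResult",
    "PeakRegion",
    "center_of_gravity",
    "discretize_peaks",
    "default_measurement_grid",
    "measure_map",
    "peak",
    "position_report",
    "surface_area",
    "surface_peak",
    "volume_integral",
]

#: Default μV threshold above which a cell counts toward SA/VI.
DEFAULT_SA_THRESHOLD_UV = 0.0


@dataclass(frozen=True)
class CogResult:
    """Value-weighted mean position of the map (mm)."""

    x: float
    y: float
    z: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def center_of_gravity(dataset: MotorMapDataset) -> CogResult:
    """Center of gravity of the raw events (value-weighted mean position).

    Raises
    ------
    ZeroMassError
        If all values are zero.
    """
    total = dataset.values.sum()
    if total <= 0:
        raise ZeroMassError("all map values are zero; COG undefined")
    cog = (dataset.points * dataset.values[:, None]).sum(axis=0) / total
    return CogResult(*cog)


def peak(dataset: MotorMapDataset):
    """Position and value of the absolute maximum raw measurement.

    Ties resolve to the lowest event index.
    """
    i = int(np.argmax(dataset.values))
    return dataset.points[i].copy(), float(dataset.values[i])


def position_report(point, reference: ReferencePoint):
    """Signed per-axis components and Euclidean distance to the reference.

    Components are (right→left, posterior→anterior, inferior→superior),
    i.e. point − reference per axis, in mm.
    """
    d = np.asarray(point, dtype=float) - reference.xyz
    return float(d[0]), float(d[1]), float(d[2]), float(np.linalg.norm(d))


def default_measurement_grid(
    surface: SurfaceModel, spacing: float = np.pi / 512
) -> AngularGrid:
    """Grid covering the surface's training hull at the given spacing."""
    return AngularGrid.around(
        surface.sites[:, 0], surface.sites[:, 1], spacing=spacing, margin=spacing
    )


def _grid_values(surface: SurfaceModel, grid: AngularGrid) -> np.ndarray:
    th, ph = grid.mesh()
    return surface(th, ph)


def _patch_areas(model: ScalpEllipsoid, grid: AngularGrid) -> np.ndarray:
    """‖p × q‖ per grid cell, p and q the θ- and φ-edge vectors (mm²)."""
    th, ph = grid.mesh()
    s = grid.spacing
    p0 = model.to_cartesian(th, ph)
    p_theta = model.to_cartesian(th + s, ph) - p0
    p_phi = model.to_cartesian(th, ph + s) - p0
    return np.linalg.norm(np.cross(p_theta, p_phi), axis=-1)


def surface_area(
    surface: SurfaceModel,
    model: ScalpEllipsoid,
    grid: Optional[AngularGrid] = None,
    threshold: float = DEFAULT_SA_THRESHOLD_UV,
) -> float:
    """Map surface area (mm²): total patch area where value > threshold."""
    if grid is None:
        grid = default_measurement_grid(surface)
    values = _grid_values(surface, grid)
    mask = np.isfinite(values) & (values > threshold)
    if not mask.any():
        return 0.0
    return float(_patch_areas(model, grid)[mask].sum())


def volume_integral(
    surface: SurfaceModel,
    model: ScalpEllipsoid,
    grid: Optional[AngularGrid] = None,
    threshold: float = DEFAULT_SA_THRESHOLD_UV,
) -> float:
    """Volume integral (μV·mm²): patch areas weighted by the map value."""
    if grid is None:
        grid = default_measurement_grid(surface)
    values = _grid_values(surface, grid)
    mask = np.isfinite(values) & (values > threshold)
    if not mask.any():
        return 0.0
    areas = _patch_areas(model, grid)
    return float((areas[mask] * values[mask]).sum())


def surface_peak(
    surface: SurfaceModel,
    model: ScalpEllipsoid,
    grid: Optional[AngularGrid] = None,
):
    """Argmax and max of the fitted surface over its dense grid.

    Returns ``(position_mm, value)``; the position is the scalp point of
    the maximising grid cell.
    """
    if grid is None:
        grid = default_measurement_grid(surface)
    values = _grid_values(surface, grid)
    if not np.isfinite(values).any():
        raise NoPeakError("surface undefined over the whole grid")
    flat = np.where(np.isfinite(values), values, -np.inf)
    i, j = np.unravel_index(int(np.argmax(flat)), values.shape)
    pos = model.to_cartesian(grid.theta[i], grid.phi[j])
    return np.asarray(pos), float(values[i, j])


def measure_map(
    dataset: MotorMapDataset,
    surface: SurfaceModel,
    model: ScalpEllipsoid,
    grid: Optional[AngularGrid] = None,
    sa_threshold: float = DEFAULT_SA_THRESHOLD_UV,
    reference: Optional[ReferencePoint] = None,
) -> MeasurementReport:
    """Full measurement report for one motor map.

    COG and peak come from the raw events; SA and VI from the fitted
    surface. The reference defaults to the dataset's own, then to the
    head centroid.
    """
    if grid is None:
        grid = default_measurement_grid(surface)
    if reference is None:
        reference = dataset.reference_point
    if reference is None:
        cx, cy, cz = model.centroid
        reference = ReferencePoint(cx, cy, cz, "centroid_default")
    cog = center_of_gravity(dataset)
    peak_pos, peak_val = peak(dataset)
    return MeasurementReport(
        cog=(cog.x, cog.y, cog.z),
        peak_position=tuple(peak_pos),
        peak_value=peak_val,
        surface_area=surface_area(surface, model, grid, sa_threshold),
        volume_integral=volume_integral(surface, model, grid, sa_threshold),
        cog_distance=position_report(cog.xyz, reference),
        peak_distance=position_report(peak_pos, reference),
        reference_point=reference,
        session_label=dataset.session_label,
    )


@dataclass(frozen=True)
class PeakRegion:
    """One discretized hotspot of the map on the angular grid."""

    label: int
    mask: np.ndarray  # boolean, (n_theta, n_phi)
    cog: np.ndarray  # (3,) mm, area-and-value-weighted over region cells
    peak_position: np.ndarray  # (3,) mm
    peak_value: float
    surface_area: float
    volume_integral: float
    boundary: tuple  # contours in (row, col) grid coordinates


def discretize_peaks(
    surface: SurfaceModel,
    model: ScalpEllipsoid,
    grid: Optional[AngularGrid] = None,
    threshold: float = DEFAULT_SA_THRESHOLD_UV,
    min_prominence: float = 0.1,
) -> list[PeakRegion]:
    """Split the map into individual hotspots and measure each alone.

    Local maxima with prominence ≥ ``min_prominence`` × the global
    maximum seed a watershed of the negated surface; each watershed
    basin, intersected with the strictly-above-threshold set, becomes a
    region whose COG, peak, SA and VI are computed from within-region
    cells only.

    Raises
    ------
    NoPeakError
        If no grid cell exceeds the threshold.
    """
    if grid is None:
        grid = default_measurement_grid(surface)
    values = _grid_values(surface, grid)
    above = np.isfinite(values) & (values > threshold)
    if not above.any():
        raise NoPeakError("no grid cell above the threshold")
    vmax = float(values[above].max())
    filled = np.where(np.isfinite(values), values, values[above].min())
    h = max(min_prominence * vmax, np.finfo(float).tiny)
    seeds = h_maxima(filled, h) & above
    markers, n_seeds = ndimage.label(seeds)
    if n_seeds == 0:  # flat above-threshold plateau: one region
        markers[above] = 1
    basins = watershed(-filled, markers=markers, mask=above)

    areas = _patch_areas(model, grid)
    th, ph = grid.mesh()
    cell_pos = model.to_cartesian(th, ph)

    regions = []
    for lab in range(1, int(basins.max()) + 1):
        mask = basins == lab
        if not mask.any():
            continue
        v = values[mask]
        a = areas[mask]
        pos = cell_pos[mask]
        weights = v * a
        total = weights.sum()
        cog = (
            (pos * weights[:, None]).sum(axis=0) / total
            if total > 0
            else pos.mean(axis=0)
        )
        k = int(np.argmax(v))
        regions.append(
            PeakRegion(
                label=lab,
                mask=mask,
                cog=cog,
                peak_position=pos[k],
                peak_value=float(v[k]),
                surface_area=float(a.sum()),
                volume_integral=float((a * v).sum()),
                boundary=tuple(find_contours(mask.astype(float), 0.5)),
            )
        )
    regions.sort(key=lambda r: -r.peak_value)
    return regions
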