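"""Head geometry: segmentation, angular coordinates, the scalp ellipsoid.

Stimulation sites live on the scalp, a 2D manifold in scanner space, so
the pipeline works in *angular coordinates*: inclination θ ∈ [0, π]
(measured from the +z axis) and azimuth φ ∈ (−π, π], taken about the
centroid of the head segmentation. A smooth map back to 3D is provided
by an ellipsoid-like surface whose radial term is a fourth-order
polynomial in (θ, φ), fitted per Cartesian axis by least squares to a
point cloud sampled from the head mask:

    x − x_o = w1 + (w2 + w3·θ + w4·φ + w5·θ² + w6·φ² + w7·θ³ + w8·φ³
                    + w9·θ⁴ + w10·φ⁴) · sin θ cos φ

and likewise for y (factor sin θ sin φ) and z (factor cos θ), ten
weights per axis. For a sphere of radius R about the centroid the exact
solution is w2 = R with all other weights zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .errors import (
    DegenerateCogError,
    DegeneratePointError,
    InsufficientForegroundError,
    InsufficientPointsError,
    NoForegroundError,
    SingularDesignError,
)
from .io import MotorMapDataset, ReferencePoint

__all__ = [
    "AngularGrid",
    "ScalpEllipsoid",
    "angular_to_cartesian",
    "cartesian_to_angular",
    "compute_centroid",
    "fit_scalp_ellipsoid",
    "render_topographic",
    "sample_point_cloud",
    "segment_head",
    "snap_cog_to_equator",
]

#: Number of radial polynomial weights per Cartesian axis.
N_ELLIPSOID_TERMS = 10

#: Default voxel stride when converting a head mask into a point cloud.
DEFAULT_CLOUD_STRIDE = 25


def segment_head(volume: np.ndarray, closing_radius: int = 2) -> np.ndarray:
    """Segment the head from a grayscale volume into a binary mask.

    Otsu threshold, morphological closing, interior hole fill, then the
    largest connected component. The result separates head from
    background; it is not a brain extraction.

    Raises
    ------
    NoForegroundError
        If thresholding leaves no foreground voxel.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.size == 0:
        raise ValueError("empty volume")
    vmin, vmax = volume.min(), volume.max()
    if vmax <= vmin:
        raise NoForegroundError("volume is constant; no foreground found")
    mask = volume > threshold_otsu(volume)
    if not mask.any():
        raise NoForegroundError("no voxel above the Otsu threshold")
    if closing_radius > 0:
        mask = ndimage.binary_closing(mask, structure=ball(closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise NoForegroundError("no foreground component after morphology")
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def sample_point_cloud(
    mask: np.ndarray,
    voxel_spacing=(1.0, 1.0, 1.0),
    stride: int = DEFAULT_CLOUD_STRIDE,
) -> np.ndarray:
    """Convert a binary mask into a point cloud in mm.

    Takes every ``stride``-th foreground voxel in fixed raster (C) order;
    coordinates are voxel index × spacing.

    Raises
    ------
    InsufficientForegroundError
        If the mask has fewer than ``stride`` foreground voxels.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = np.argwhere(np.asarray(mask, dtype=bool))
    if idx.shape[0] < stride:
        raise InsufficientForegroundError(
            f"mask has {idx.shape[0]} foreground voxels; need at least {stride}"
        )
    spacing = np.asarray(voxel_spacing, dtype=float)
    return idx[::stride].astype(float) * spacing


def compute_centroid(points: np.ndarray) -> np.ndarray:
    """Coordinate-wise arithmetic mean of a point cloud (mm)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 1:
        raise ValueError("need at least one point")
    return points.mean(axis=0)


def cartesian_to_angular(points: np.ndarray, centroid: np.ndarray):
    """Convert 3D points to angular coordinates about ``centroid``.

    Returns ``(theta, phi)``: inclination ``theta = arccos(dz / r)`` in
    [0, π] and azimuth ``phi = atan2(dy, dx)`` in (−π, π].

    Raises
    ------
    DegeneratePointError
        If a point coincides with the centroid.
    """
    points = np.asarray(points, dtype=float)
    squeeze = points.ndim == 1
    points = np.atleast_2d(points)
    d = points - np.asarray(centroid, dtype=float)
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise DegeneratePointError("point coincides with the centroid")
    theta = np.arccos(np.clip(d[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    if squeeze:
        return theta[0], phi[0]
    return theta, phi


def _radial_design(theta: np.ndarray, phi: np.ndarray, n_terms: int) -> list[np.ndarray]:
    """Per-axis design matrices for the polynomial ellipsoid.

    Column 1 is the constant offset; columns 2..n multiply the axis trig
    factor by [1, θ, φ, θ², φ², θ³, φ³, θ⁴, φ⁴] in that order.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float).ravel()
    monomials = [
        np.ones_like(theta), theta, phi,
        theta**2, phi**2, theta**3, phi**3, theta**4, phi**4,
    ]
    trig = [
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(theta),
    ]
    designs = []
    for t in trig:
        cols = [np.ones_like(theta)] + [t * m for m in monomials]
        designs.append(np.column_stack(cols[:n_terms]))
    return designs


@dataclass(frozen=True)
class ScalpEllipsoid:
    """Fitted scalp surface: angular coordinates → 3D Cartesian mm.

    ``weights`` has one row of ``n_terms`` coefficients per Cartesian
    axis (x, y, z); ``centroid`` is the origin of the angular system.
    """

    weights: np.ndarray
    centroid: np.ndarray
    rms_residual: float = 0.0
    residuals: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0), repr=False)

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.ndim != 2 or weights.shape[0] != 3:
            raise ValueError("weights must have shape (3, n_terms)")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))

    @property
    def n_terms(self) -> int:
        return self.weights.shape[1]

    def to_cartesian(self, theta, phi) -> np.ndarray:
        """Evaluate the surface at angular coordinates; returns (..., 3) mm."""
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        shape = np.broadcast_shapes(theta.shape, phi.shape)
        th = np.broadcast_to(theta, shape).ravel()
        ph = np.broadcast_to(phi, shape).ravel()
        designs = _radial_design(th, ph, self.n_terms)
        xyz = np.column_stack(
            [design @ w for design, w in zip(designs, self.weights)]
        )
        xyz += self.centroid
        return xyz.reshape(shape + (3,))

    @classmethod
    def exact_sphere(cls, radius: float, centroid=(0.0, 0.0, 0.0)) -> "ScalpEllipsoid":
        """The sphere of given radius as an exact member of the model family."""
        weights = np.zeros((3, N_ELLIPSOID_TERMS))
        weights[:, 1] = radius
        return cls(weights=weights, centroid=np.asarray(centroid, dtype=float))

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "centroid_mm": list(self.centroid),
                    "weights": [list(row) for row in self.weights],
                    "rms_residual_mm": self.rms_residual,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path) -> "ScalpEllipsoid":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            centroid=np.asarray(d["centroid_mm"], dtype=float),
            rms_residual=d.get("rms_residual_mm", 0.0),
        )


def fit_scalp_ellipsoid(
    points: np.ndarray,
    centroid: Optional[np.ndarray] = None,
    n_terms: int = N_ELLIPSOID_TERMS,
) -> ScalpEllipsoid:
    """Least-squares fit of the polynomial ellipsoid to a point cloud.

    Each Cartesian axis is regressed independently onto the radial
    design evaluated at the cloud's angular coordinates.

    Raises
    ------
    InsufficientPointsError
        If the cloud has fewer points than weights per axis.
    SingularDesignError
        If the design matrix is rank deficient.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if centroid is None:
        centroid = compute_centroid(points)
    centroid = np.asarray(centroid, dtype=float)
    if points.shape[0] < n_terms:
        raise InsufficientPointsError(
            f"{points.shape[0]} points < {n_terms} parameters per axis"
        )
    theta, phi = cartesian_to_angular(points, centroid)
    designs = _radial_design(theta, phi, n_terms)
    target = points - centroid
    weights = np.zeros((3, n_terms))
    residuals = []
    for axis in range(3):
        w, _, rank, _ = np.linalg.lstsq(designs[axis], target[:, axis], rcond=None)
        if rank < n_terms:
            raise SingularDesignError(
                f"design matrix rank {rank} < {n_terms} for axis {'xyz'[axis]}"
            )
        weights[axis] = w
        resid = designs[axis] @ w - target[:, axis]
        residuals.append(float(np.sqrt(np.mean(resid**2))))
    model = ScalpEllipsoid(
        weights=weights,
        centroid=centroid,
        rms_residual=float(np.sqrt(np.mean(np.square(residuals)))),
        residuals=tuple(residuals),
    )
    return model


def angular_to_cartesian(theta, phi, model: ScalpEllipsoid) -> np.ndarray:
    """Map angular coordinates onto the fitted scalp surface (mm)."""
    return model.to_cartesian(theta, phi)


@dataclass(frozen=True)
class AngularGrid:
    """A regular (θ, φ) raster with a single pixel spacing in radians.

    Cell origins are ``min + i·s``; the default covers the full sphere,
    θ ∈ [0, π] × φ ∈ (−π, π], at 512 × 1024 pixels (s = π/512).
    """

    spacing: float = np.pi / 512
    theta_min: float = 0.0
    theta_max: float = np.pi
    phi_min: float = -np.pi
    phi_max: float = np.pi

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.theta_max <= self.theta_min or self.phi_max <= self.phi_min:
            raise ValueError("grid extents must be non-empty")

    @property
    def n_theta(self) -> int:
        return max(1, int(np.floor((self.theta_max - self.theta_min) / self.spacing + 0.5)))

    @property
    def n_phi(self) -> int:
        return max(1, int(np.floor((self.phi_max - self.phi_min) / self.spacing + 0.5)))

    @property
    def theta(self) -> np.ndarray:
        return self.theta_min + self.spacing * np.arange(self.n_theta)

    @property
    def phi(self) -> np.ndarray:
        return self.phi_min + self.spacing * np.arange(self.n_phi)

    def mesh(self):
        """Meshgrid of cell-origin coordinates, shape (n_theta, n_phi)."""
        return np.meshgrid(self.theta, self.phi, indexing="ij")

    @classmethod
    def around(cls, theta, phi, spacing: float, margin: float = 0.0) -> "AngularGrid":
        """Smallest grid covering the given angular sites, plus a margin."""
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        return cls(
            spacing=spacing,
            theta_min=max(0.0, float(theta.min()) - margin),
            theta_max=min(np.pi, float(theta.max()) + margin + spacing),
            phi_min=max(-np.pi, float(phi.min()) - margin),
            phi_max=min(np.pi, float(phi.max()) + margin + spacing),
        )


def render_topographic(
    volume: np.ndarray,
    model: ScalpEllipsoid,
    grid: Optional[AngularGrid] = None,
    voxel_spacing=(1.0, 1.0, 1.0),
    background: float = 0.0,
) -> np.ndarray:
    """Globe-like topographic projection of a scan onto the scalp surface.

    For every grid cell the scan intensity is sampled at the ellipsoid
    surface point by nearest-voxel lookup; surface points outside the
    volume take the background value. Returns an (n_theta, n_phi) image.
    """
    if grid is None:
        grid = AngularGrid()
    volume = np.asarray(volume)
    spacing = np.asarray(voxel_spacing, dtype=float)
    th, ph = grid.mesh()
    xyz = model.to_cartesian(th, ph).reshape(-1, 3)
    idx = np.round(xyz / spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(volume.shape)), axis=1)
    image = np.full(idx.shape[0], float(background))
    ii = idx[inside]
    image[inside] = volume[ii[:, 0], ii[:, 1], ii[:, 2]]
    return image.reshape(grid.n_theta, grid.n_phi)


def _weighted_cog(dataset: MotorMapDataset) -> np.ndarray:
    total = dataset.values.sum()
    if total > 0:
        return (dataset.points * dataset.values[:, None]).sum(axis=0) / total
    return dataset.points.mean(axis=0)


def snap_cog_to_equator(
    dataset: MotorMapDataset,
    cloud: np.ndarray,
    centroid: np.ndarray,
    rotate_reference: bool = True,
):
    """Rigidly rotate data and cloud so the data COG sits on the equator.

    The topographic projection distorts least near inclination π/2, so a
    single minimal rotation about the centroid takes the direction of the
    data's center of gravity to the equatorial plane: rotation axis =
    COG direction × its equatorial projection. The same rotation is
    applied to the head point cloud (and, by default, the reference
    point) so that all pairwise distances are preserved.

    Returns ``(rotated_dataset, rotated_cloud, rotation)``.

    Raises
    ------
    DegenerateCogError
        If the COG coincides with the centroid, or lies on the pole axis
        (no minimal rotation is defined there).
    """
    centroid = np.asarray(centroid, dtype=float)
    cloud = np.atleast_2d(np.asarray(cloud, dtype=float))
    cog = _weighted_cog(dataset)
    u = cog - centroid
    norm_u = np.linalg.norm(u)
    if norm_u == 0:
        raise DegenerateCogError("data COG coincides with the centroid")
    u = u / norm_u
    equatorial = np.array([u[0], u[1], 0.0])
    norm_eq = np.linalg.norm(equatorial)
    if norm_eq < 1e-12:
        raise DegenerateCogError("data COG lies on the pole axis")
    t = equatorial / norm_eq
    axis = np.cross(u, t)
    sin_angle = np.linalg.norm(axis)
    cos_angle = float(np.dot(u, t))
    angle = np.arctan2(sin_angle, cos_angle)
    if sin_angle < 1e-15:
        rotation = Rotation.identity()
    else:
        rotation = Rotation.from_rotvec(axis / sin_angle * angle)

    def apply(pts: np.ndarray) -> np.ndarray:
        return rotation.apply(pts - centroid) + centroid

    new_points = apply(dataset.points)
    reference = dataset.reference_point
    if reference is not None and rotate_reference:
        rx, ry, rz = apply(reference.xyz[None, :])[0]
        reference = ReferencePoint(rx, ry, rz, reference.source)
    rotated = MotorMapDataset(
        new_points,
        dataset.values,
        reference_point=reference,
        session_label=dataset.session_label,
    )
    return rotated, apply(cloud), rotation
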