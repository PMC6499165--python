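"""Synthetic head phantoms and motor maps with known ground truth.

The phantom is a solid ellipsoid of uniform foreground intensity in a
grayscale volume, optionally with additive Gaussian noise, together
with its exact mask — the oracle for segmentation tests.

The synthetic motor map emulates a grid-sampled TMS mapping session: a
rectangular grid of stimulation sites at 5–10 mm spacing laid over the
fitted scalp surface, each stimulated 1–4 times, with MEP amplitudes
drawn from an isotropic Gaussian response field

    v(θ, φ) = A · exp(−d(θ, φ; θ_c, φ_c)² / (2 w²))

where d is the great-circle angular distance to the field center. MEP
variability is modelled as multiplicative log-normal noise (unit mean,
configurable coefficient of variation) plus an additive Gaussian floor,
truncated at zero; coil repositioning error is a small isotropic
positional jitter. Ground-truth COG, peak, SA and VI are integrated
numerically from the noiseless field on a fine angular grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import AngularGrid, ScalpEllipsoid, cartesian_to_angular
from .io import MotorMapDataset

__all__ = [
    "PhantomSpec",
    "SyntheticMapSpec",
    "make_head_phantom",
    "make_gaussian_map",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Ellipsoidal head phantom parameters.

    Defaults give an adult-head-sized ellipsoid (radii 80/90/75 mm) in a
    64³ volume at 3 mm isotropic spacing.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    center: Optional[tuple[float, float, float]] = None  # mm; default = volume center
    radii: tuple[float, float, float] = (80.0, 90.0, 75.0)
    foreground: float = 1000.0
    background: float = 0.0
    noise_sigma: float = 0.0  # absolute intensity units
    seed: int = 0

    def center_mm(self) -> np.ndarray:
        if self.center is not None:
            return np.asarray(self.center, dtype=float)
        return (np.asarray(self.shape, dtype=float) - 1) / 2 * np.asarray(
            self.voxel_spacing
        )


def make_head_phantom(spec: PhantomSpec = PhantomSpec()):
    """Build an ellipsoid phantom volume and its exact foreground mask.

    Returns ``(volume, mask)``.

    Raises
    ------
    ValueError
        Non-positive radii, or an ellipsoid that exceeds the volume.
    """
    radii = np.asarray(spec.radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("phantom radii must be positive")
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    extent = (np.asarray(spec.shape, dtype=float) - 1) * spacing
    center = spec.center_mm()
    if np.any(center - radii < 0) or np.any(center + radii > extent):
        raise ValueError("phantom ellipsoid exceeds the volume bounds")
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(spec.shape, spacing)], indexing="ij"
    )
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    mask = q <= 1.0
    volume = np.where(mask, spec.foreground, spec.background).astype(float)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        volume = volume + rng.normal(0.0, spec.noise_sigma, size=volume.shape)
    return volume, mask


@dataclass(frozen=True)
class SyntheticMapSpec:
    """Grid-sampled Gaussian MEP field parameters.

    Defaults emulate a dense repeated-measures protocol: a 0.5 cm grid,
    three stimuli per site, a ~1000 μV hotspot and 10 % multiplicative
    MEP variability.
    """

    grid_spacing_mm: float = 5.0
    grid_extent_mm: float = 40.0  # full side length of the square grid
    center_theta: float = np.pi / 2
    center_phi: float = 0.0
    amplitude_uv: float = 1000.0
    width_rad: float = 0.12  # Gaussian σ of the field, radians
    repeats: int = 3
    noise_cv: float = 0.1  # multiplicative log-normal coefficient of variation
    noise_floor_uv: float = 0.0  # additive Gaussian σ
    position_jitter_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_uv < 0:
            raise ValueError("amplitude must be non-negative")
        if self.repeats < 1:
            raise ValueError("need at least one stimulus per site")
        if self.grid_spacing_mm <= 0 or self.grid_extent_mm <= 0:
            raise ValueError("grid spacing and extent must be positive")


def _angular_distance(theta, phi, theta_c, phi_c):
    """Great-circle distance on the unit sphere (radians)."""
    cosd = np.cos(theta_c) * np.cos(theta) + np.sin(theta_c) * np.sin(theta) * np.cos(
        phi - phi_c
    )
    return np.arccos(np.clip(cosd, -1.0, 1.0))


def field_value(spec: SyntheticMapSpec, theta, phi) -> np.ndarray:
    """Noiseless Gaussian MEP field evaluated at angular coordinates (μV)."""
    d = _angular_distance(theta, phi, spec.center_theta, spec.center_phi)
    return spec.amplitude_uv * np.exp(-(d**2) / (2 * spec.width_rad**2))


def _ground_truth(
    model: ScalpEllipsoid, spec: SyntheticMapSpec, threshold: float, fine: float
) -> dict:
    # numerical integration of the noiseless field on a fine grid,
    # restricted to where the field is non-negligible
    half = 6 * spec.width_rad
    grid = AngularGrid(
        spacing=fine,
        theta_min=max(0.0, spec.center_theta - half),
        theta_max=min(np.pi, spec.center_theta + half),
        phi_min=max(-np.pi, spec.center_phi - half),
        phi_max=min(np.pi, spec.center_phi + half),
    )
    th, ph = grid.mesh()
    v = field_value(spec, th, ph)
    p0 = model.to_cartesian(th, ph)
    p_t = model.to_cartesian(th + fine, ph) - p0
    p_p = model.to_cartesian(th, ph + fine) - p0
    areas = np.linalg.norm(np.cross(p_t, p_p), axis=-1)
    above = v > threshold
    weights = v * areas
    total = weights.sum()
    cog = (p0 * weights[..., None]).sum(axis=(0, 1)) / total if total > 0 else None
    return {
        "cog_mm": cog,
        "peak_position_mm": np.asarray(
            model.to_cartesian(spec.center_theta, spec.center_phi)
        ),
        "peak_value_uv": spec.amplitude_uv,
        "surface_area_mm2": float(areas[above].sum()),
        "volume_integral_uv_mm2": float((areas * v)[above].sum()),
        "sa_threshold_uv": threshold,
    }


def make_gaussian_map(
    model: ScalpEllipsoid,
    spec: SyntheticMapSpec = SyntheticMapSpec(),
    sa_threshold: float = 0.0,
    ground_truth_spacing: float = 0.002,
    compute_ground_truth: bool = True,
):
    """Sample a synthetic grid-mapped session from the Gaussian field.

    Returns ``(dataset, truth)`` where ``truth`` carries the noiseless
    field's COG, peak, above-threshold surface area and volume integral
    (``None`` when ``compute_ground_truth`` is off — the truth depends
    only on the field and grid parameters, never on the seed, so it can
    be computed once and shared across seeded replicates).
    All randomness derives from ``spec.seed``; identical specs yield
    identical datasets.

    Raises
    ------
    ValueError
        If the field center sits on a pole of the angular system (the
        azimuth step is undefined there).
    """
    rng = np.random.default_rng(spec.seed)
    sin_c = np.sin(spec.center_theta)
    if sin_c < 1e-6:
        raise ValueError("field center must not sit on a pole")
    center_pos = np.asarray(model.to_cartesian(spec.center_theta, spec.center_phi))
    radius = float(np.linalg.norm(center_pos - model.centroid))
    d_theta = spec.grid_spacing_mm / radius
    d_phi = d_theta / sin_c
    n_side = int(np.floor(spec.grid_extent_mm / spec.grid_spacing_mm)) + 1
    offsets = (np.arange(n_side) - (n_side - 1) / 2)
    thetas = spec.center_theta + offsets * d_theta
    phis = spec.center_phi + offsets * d_phi
    th, ph = np.meshgrid(thetas, phis, indexing="ij")
    site_pos = model.to_cartesian(th, ph).reshape(-1, 3)
    # the fitted surface is not exactly radial about the centroid, so a
    # site's angular coordinates as re-derived from its 3D position differ
    # slightly from the nominal grid angles; the field is defined over the
    # angular working space, so evaluate it at the derived coordinates
    site_th, site_ph = cartesian_to_angular(site_pos, model.centroid)
    site_values = field_value(spec, site_th, site_ph)

    points = []
    values = []
    sigma_log = np.sqrt(np.log1p(spec.noise_cv**2))
    for pos, v in zip(site_pos, site_values):
        for _ in range(spec.repeats):
            jitter = rng.normal(0.0, spec.position_jitter_mm, size=3)
            noisy = v
            if spec.noise_cv > 0:
                noisy = noisy * rng.lognormal(-sigma_log**2 / 2, sigma_log)
            if spec.noise_floor_uv > 0:
                noisy = noisy + rng.normal(0.0, spec.noise_floor_uv)
            points.append(pos + jitter)
            values.append(max(0.0, noisy))
    dataset = MotorMapDataset(
        np.asarray(points),
        np.asarray(values),
        session_label=f"synthetic-seed-{spec.seed}",
    )
    truth = (
        _ground_truth(model, spec, sa_threshold, ground_truth_spacing)
        if compute_ground_truth
        else None
    )
    return dataset, truth
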