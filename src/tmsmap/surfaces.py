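"""Non-parametric surface fitting of consolidated maps in angular space.

Fits a continuous function value = S(θ, φ) to scattered consolidated
sites. Four algorithms are available:

piecewise_cubic
    C1 piecewise-cubic (Clough–Tocher) interpolation on a Delaunay
    triangulation — smooth patches over triples of data points joined
    continuously.
piecewise_linear
    Barycentric linear interpolation on the same triangulation.
biharmonic_v4
    Biharmonic-spline interpolation: one Green's-function kernel
    g(r) = r²(ln r − 1) per data site, coefficients from the dense
    linear system, plus a constant offset term that makes predictions
    exactly equivariant under value shifts. Duplicate sites are
    collapsed by averaging before the solve.
lowess
    Locally weighted first-order regression with tricube weights over
    the nearest ``span`` fraction of sites (span fixed at 0.25 by
    default). Smoothing: does not interpolate the training values.

All algorithms are undefined outside the convex hull of the training
sites (queries there evaluate to NaN); no extrapolation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator, LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError

from .errors import DegenerateGeometryError, SingularSystemError

__all__ = [
    "SURFACE_ALGORITHMS",
    "DEFAULT_LOWESS_SPAN",
    "SurfaceModel",
    "evaluate_surface",
    "fit_surface",
]

SURFACE_ALGORITHMS = ("piecewise_cubic", "piecewise_linear", "biharmonic_v4", "lowess")

#: Fraction of sites entering each local lowess regression.
DEFAULT_LOWESS_SPAN = 0.25


def _greens(r: np.ndarray) -> np.ndarray:
    """Biharmonic-spline kernel g(r) = r^2 (ln r - 1), with g(0) = 0."""
    out = np.zeros_like(r)
    pos = r > 0
    rp = r[pos]
    out[pos] = rp**2 * (np.log(rp) - 1.0)
    return out


def _collapse_duplicates(sites: np.ndarray, values: np.ndarray):
    """Average values over exactly coincident sites."""
    uniq, inverse = np.unique(sites, axis=0, return_inverse=True)
    if uniq.shape[0] == sites.shape[0]:
        return sites, values
    summed = np.zeros(uniq.shape[0])
    counts = np.zeros(uniq.shape[0])
    np.add.at(summed, inverse, values)
    np.add.at(counts, inverse, 1.0)
    return uniq, summed / counts


@dataclass(frozen=True)
class SurfaceModel:
    """A fitted surface S(θ, φ) → value, evaluable on any angular grid."""

    algorithm: str
    sites: np.ndarray  # (N, 2) training (theta, phi)
    values: np.ndarray  # (N,)
    units: str = "uV"
    lowess_span: float = DEFAULT_LOWESS_SPAN
    _state: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[0]

    @property
    def hull(self) -> Optional[Delaunay]:
        return self._state.get("hull")

    def in_hull(self, theta, phi) -> np.ndarray:
        """Boolean mask of queries inside the training convex hull."""
        q = np.column_stack(
            [np.asarray(theta, dtype=float).ravel(), np.asarray(phi, dtype=float).ravel()]
        )
        hull = self.hull
        if hull is None:
            # degenerate geometry (biharmonic on < 3 sites): everywhere defined
            return np.ones(q.shape[0], dtype=bool)
        return hull.find_simplex(q) >= 0

    def __call__(self, theta, phi) -> np.ndarray:
        """Predicted values at angular coordinates; NaN outside the hull."""
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        shape = np.broadcast_shapes(theta.shape, phi.shape)
        th = np.broadcast_to(theta, shape).ravel()
        ph = np.broadcast_to(phi, shape).ravel()
        out = np.full(th.shape, np.nan)
        mask = self.in_hull(th, ph)
        if mask.any():
            out[mask] = self._predict(th[mask], ph[mask])
        return out.reshape(shape) if shape else float(out[0])

    def _predict(self, th: np.ndarray, ph: np.ndarray) -> np.ndarray:
        if self.algorithm in ("piecewise_cubic", "piecewise_linear"):
            return self._state["interpolator"](np.column_stack([th, ph]))
        if self.algorithm == "biharmonic_v4":
            sites = self._state["solve_sites"]
            coef = self._state["coef"]
            r = np.sqrt(
                (th[:, None] - sites[:, 0]) ** 2 + (ph[:, None] - sites[:, 1]) ** 2
            )
            return _greens(r) @ coef[:-1] + coef[-1]
        return self._lowess_predict(th, ph)

    def _lowess_predict(self, th: np.ndarray, ph: np.ndarray) -> np.ndarray:
        sites, values = self.sites, self.values
        n = sites.shape[0]
        k = max(3, int(np.ceil(self.lowess_span * n)))
        if k > n:
            # too few sites for a local fit: one global linear regression
            return self._global_linear(th, ph)
        out = np.empty(th.shape)
        for i, (t, p) in enumerate(zip(th, ph)):
            d = np.hypot(sites[:, 0] - t, sites[:, 1] - p)
            order = np.argsort(d, kind="stable")[:k]
            dk = d[order[-1]]
            if dk == 0:  # all in-span sites coincide with the query
                out[i] = values[order].mean()
                continue
            w = (1.0 - np.clip(d[order] / dk, 0.0, 1.0) ** 3) ** 3
            if np.count_nonzero(w) < 3:
                out[i] = self._global_linear(np.array([t]), np.array([p]))[0]
                continue
            design = np.column_stack(
                [np.ones(k), sites[order, 0] - t, sites[order, 1] - p]
            )
            wsqrt = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(
                design * wsqrt[:, None], values[order] * wsqrt, rcond=None
            )
            out[i] = beta[0]
        return out

    def _global_linear(self, th: np.ndarray, ph: np.ndarray) -> np.ndarray:
        design = np.column_stack(
            [np.ones(self.n_sites), self.sites[:, 0], self.sites[:, 1]]
        )
        beta, *_ = np.linalg.lstsq(design, self.values, rcond=None)
        return beta[0] + beta[1] * th + beta[2] * ph


def fit_surface(
    theta,
    phi,
    values,
    algorithm: str = "piecewise_cubic",
    units: str = "uV",
    lowess_span: float = DEFAULT_LOWESS_SPAN,
) -> SurfaceModel:
    """Fit a surface to scattered angular sites.

    Parameters
    ----------
    theta, phi : array-like
        Angular coordinates of the consolidated sites (radians).
    values : array-like
        Consolidated map values (μV, μV² or % depending on the
        consolidation operator).
    algorithm : {"piecewise_cubic", "piecewise_linear", "biharmonic_v4", "lowess"}

    Raises
    ------
    DegenerateGeometryError
        Collinear or duplicate sites where a triangulation is required.
    SingularSystemError
        Singular biharmonic system.
    """
    if algorithm not in SURFACE_ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; expected one of {SURFACE_ALGORITHMS}"
        )
    sites = np.column_stack(
        [np.asarray(theta, dtype=float).ravel(), np.asarray(phi, dtype=float).ravel()]
    )
    values = np.asarray(values, dtype=float).ravel()
    if sites.shape[0] != values.shape[0]:
        raise ValueError("theta/phi and values must have the same length")
    if sites.shape[0] < 1:
        raise ValueError("need at least one site")
    state: dict = {}

    try:
        state["hull"] = Delaunay(sites)
    except QhullError:
        state["hull"] = None

    if algorithm in ("piecewise_cubic", "piecewise_linear"):
        if sites.shape[0] < 3 or state["hull"] is None:
            raise DegenerateGeometryError(
                "triangulation requires at least 3 non-collinear sites"
            )
        if np.unique(sites, axis=0).shape[0] != sites.shape[0]:
            raise DegenerateGeometryError("duplicate sites are not triangulable")
        cls = (
            CloughTocher2DInterpolator
            if algorithm == "piecewise_cubic"
            else LinearNDInterpolator
        )
        state["interpolator"] = cls(state["hull"], values)
    elif algorithm == "biharmonic_v4":
        solve_sites, solve_values = _collapse_duplicates(sites, values)
        n = solve_sites.shape[0]
        r = np.sqrt(
            (solve_sites[:, 0][:, None] - solve_sites[:, 0]) ** 2
            + (solve_sites[:, 1][:, None] - solve_sites[:, 1]) ** 2
        )
        # Green's-function system bordered with a constant offset row so
        # that adding c to all values shifts every prediction by c.
        system = np.zeros((n + 1, n + 1))
        system[:n, :n] = _greens(r)
        system[:n, n] = 1.0
        system[n, :n] = 1.0
        rhs = np.concatenate([solve_values, [0.0]])
        try:
            coef = np.linalg.solve(system, rhs)
        except np.linalg.LinAlgError as exc:
            raise SingularSystemError("biharmonic system is singular") from exc
        state["solve_sites"] = solve_sites
        state["coef"] = coef
    else:  # lowess
        if sites.shape[0] < 3:
            raise DegenerateGeometryError("lowess requires at least 3 sites")

    return SurfaceModel(
        algorithm=algorithm,
        sites=sites,
        values=values,
        units=units,
        lowess_span=lowess_span,
        _state=state,
    )


def evaluate_surface(model: SurfaceModel, theta, phi) -> np.ndarray:
    """Evaluate a fitted surface on angular coordinates (grid or points).

    ``theta`` and ``phi`` may be 1D axes (evaluated as their outer grid)
    or broadcastable arrays. Returns NaN outside the training hull.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if theta.ndim == 1 and phi.ndim == 1 and theta.shape != phi.shape:
        theta, phi = np.meshgrid(theta, phi, indexing="ij")
    return model(theta, phi)
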