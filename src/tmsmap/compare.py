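"""Comparison of two motor maps from the same subject.

Continuous mode fits both datasets with one algorithm and reports the
shifts in COG and peak, the SA and VI differences, a difference grid
over the overlap of the two training hulls, and the RMSE

    RMSE = sqrt( Σ (P_i − O_i)² / n )

where O_i are the raw values of dataset 1 and P_i the predictions of
dataset 2's surface at the same locations. RMSE is only meaningful when
the maps sample the same scalp region; with no overlap it is reported
as unavailable.

Categorical mode quantifies map stability: a probability-consolidated
map of session 1 (the training set) predicts, at every location, the
probability that a stimulus elicits an MEP above the binarization
threshold. Testing events from session 2 are binarized at that same
threshold, the model's predictions are binarized at a sweep of cutoffs
from 0 to 100 %, and each cutoff yields a confusion count
(A, B, C, D) = (TP, FP, FN, TN) with

    TPR = A / (A + C),    FPR = 1 − D / (D + B)

The ROC curve is (FPR, TPR) over the sweep and the AUC its trapezoidal
integral: 1 = always right, 0 = always inverted, 0.5 = chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .clustering import DEFAULT_BINARIZATION_THRESHOLD_UV, binarize
from .errors import DegenerateTestError, FrameMismatchError, NoOverlapError
from .geometry import AngularGrid, ScalpEllipsoid, cartesian_to_angular
from .io import MeasurementReport, MotorMapDataset
from .metrics import DEFAULT_SA_THRESHOLD_UV, measure_map
from .surfaces import SurfaceModel, fit_surface

__all__ = [
    "ContinuousComparison",
    "RocResult",
    "compare_continuous",
    "rmse",
    "roc_auc",
]

#: Number of evenly spaced percentage cutoffs in the ROC sweep.
DEFAULT_N_CUTOFFS = 1001


def rmse(surface_b: SurfaceModel, dataset_a: MotorMapDataset, model: ScalpEllipsoid) -> float:
    """Root mean square error of B's surface predicting A's raw events.

    Events of A outside B's training hull are dropped.

    Raises
    ------
    NoOverlapError
        If no event of A lies inside B's hull.
    """
    theta, phi = cartesian_to_angular(dataset_a.points, model.centroid)
    predicted = surface_b(theta, phi)
    inside = np.isfinite(predicted)
    if not inside.any():
        raise NoOverlapError("no raw point of dataset A inside B's training hull")
    diff = predicted[inside] - dataset_a.values[inside]
    return float(np.sqrt(np.mean(diff**2)))


@dataclass(frozen=True)
class ContinuousComparison:
    """Continuous-mode comparison of two maps (differences are B − A)."""

    report_a: MeasurementReport
    report_b: MeasurementReport
    delta_cog: tuple[float, float, float, float]  # dx, dy, dz, Euclidean (mm)
    delta_peak: tuple[float, float, float, float]
    delta_surface_area: float  # mm²
    delta_volume_integral: float  # μV·mm²
    difference: np.ndarray  # (n_theta, n_phi) grid of S_B − S_A, NaN off-overlap
    grid: AngularGrid
    rmse: Optional[float]  # μV; None when the maps do not overlap
    rmse_note: str = ""

    def to_dict(self) -> dict:
        return {
            "delta_cog_mm": list(self.delta_cog),
            "delta_peak_mm": list(self.delta_peak),
            "delta_surface_area_mm2": self.delta_surface_area,
            "delta_volume_integral_uv_mm2": self.delta_volume_integral,
            "rmse_uv": self.rmse,
            "rmse_note": self.rmse_note,
            "map_a": self.report_a.to_dict(),
            "map_b": self.report_b.to_dict(),
        }


def _check_frames(a: MotorMapDataset, b: MotorMapDataset) -> None:
    ra, rb = a.reference_point, b.reference_point
    if ra is not None and rb is not None:
        if not np.allclose(ra.xyz, rb.xyz, atol=1e-9):
            raise FrameMismatchError(
                "datasets declare different reference points; align them first"
            )


def compare_continuous(
    dataset_a: MotorMapDataset,
    dataset_b: MotorMapDataset,
    model: ScalpEllipsoid,
    fit_algorithm: str = "piecewise_cubic",
    sa_threshold: float = DEFAULT_SA_THRESHOLD_UV,
    grid: Optional[AngularGrid] = None,
) -> ContinuousComparison:
    """Fit both maps with one algorithm and report all difference metrics.

    Raises
    ------
    FrameMismatchError
        If the datasets declare different reference points.
    """
    _check_frames(dataset_a, dataset_b)
    surfaces = []
    for ds in (dataset_a, dataset_b):
        theta, phi = cartesian_to_angular(ds.points, model.centroid)
        surfaces.append(fit_surface(theta, phi, ds.values, algorithm=fit_algorithm))
    surface_a, surface_b = surfaces

    if grid is None:
        sites = np.vstack([surface_a.sites, surface_b.sites])
        grid = AngularGrid.around(
            sites[:, 0], sites[:, 1], spacing=np.pi / 512, margin=np.pi / 512
        )
    report_a = measure_map(dataset_a, surface_a, model, grid, sa_threshold)
    report_b = measure_map(dataset_b, surface_b, model, grid, sa_threshold)

    th, ph = grid.mesh()
    difference = surface_b(th, ph) - surface_a(th, ph)

    try:
        err = rmse(surface_b, dataset_a, model)
        note = ""
    except NoOverlapError:
        err = None
        note = (
            "no overlap: RMSE is only meaningful when both maps sample "
            "the same region"
        )

    d_cog = np.subtract(report_b.cog, report_a.cog)
    d_peak = np.subtract(report_b.peak_position, report_a.peak_position)
    return ContinuousComparison(
        report_a=report_a,
        report_b=report_b,
        delta_cog=(*map(float, d_cog), float(np.linalg.norm(d_cog))),
        delta_peak=(*map(float, d_peak), float(np.linalg.norm(d_peak))),
        delta_surface_area=report_b.surface_area - report_a.surface_area,
        delta_volume_integral=report_b.volume_integral - report_a.volume_integral,
        difference=difference,
        grid=grid,
        rmse=err,
        rmse_note=note,
    )


@dataclass(frozen=True)
class RocResult:
    """ROC curve and AUC of a probabilistic map against a testing set."""

    cutoffs: np.ndarray  # %, including a > 100 % endpoint forcing (0, 0)
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    binarization_threshold: float  # μV
    n_test: int
    n_dropped: int  # testing events outside the training hull

    def curve(self) -> np.ndarray:
        """(n, 2) array of (FPR, TPR) sorted by FPR."""
        order = np.lexsort((self.tpr, self.fpr))
        return np.column_stack([self.fpr[order], self.tpr[order]])


def roc_auc(
    training_surface: SurfaceModel,
    testing_set: MotorMapDataset,
    model: ScalpEllipsoid,
    binarization_threshold: float = DEFAULT_BINARIZATION_THRESHOLD_UV,
    n_cutoffs: int = DEFAULT_N_CUTOFFS,
) -> RocResult:
    """ROC/AUC of a probability-consolidated map predicting a testing set.

    The training surface must be in probability units (0–100 %). Testing
    events are binarized at the μV threshold; model predictions are
    binarized at each percentage cutoff as predicted-positive iff
    prediction ≥ cutoff (so cutoff 0 marks everything positive). Events
    outside the training hull are dropped and counted.

    Raises
    ------
    NoOverlapError
        If every testing event falls outside the training hull.
    DegenerateTestError
        If the retained testing labels are all positive or all negative.
    """
    theta, phi = cartesian_to_angular(testing_set.points, model.centroid)
    predictions = training_surface(theta, phi)
    inside = np.isfinite(predictions)
    n_dropped = int((~inside).sum())
    if not inside.any():
        raise NoOverlapError("no testing event inside the training hull")
    predictions = predictions[inside]
    labels = binarize(testing_set.values[inside], binarization_threshold)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateTestError(
            f"testing set is all-{'positive' if n_neg == 0 else 'negative'}; "
            "TPR or FPR is undefined"
        )
    cutoffs = np.linspace(0.0, 100.0, n_cutoffs)
    # extra cutoffs beyond every prediction force the curve to reach its
    # (0, 0) and (1, 1) endpoints even when numerical round-off pushes a
    # prediction marginally outside [0, 100]
    cutoffs = np.concatenate([
        [min(0.0, float(predictions.min())) - 1.0],
        cutoffs,
        [max(100.0, float(predictions.max())) + 1.0],
    ])
    pred_pos = predictions[None, :] >= cutoffs[:, None]
    positive = labels.astype(bool)[None, :]
    tp = (pred_pos & positive).sum(axis=1)
    fp = (pred_pos & ~positive).sum(axis=1)
    fn = n_pos - tp
    tn = n_neg - fp
    tpr = tp / (tp + fn)
    fpr = 1.0 - tn / (tn + fp)
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocResult(
        cutoffs=cutoffs,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        binarization_threshold=binarization_threshold,
        n_test=int(labels.size),
        n_dropped=n_dropped,
    )
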