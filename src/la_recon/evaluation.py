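"""Technical and biological evaluation of LA reconstructions.

Technical: dice overlap, symmetric surface-to-surface distance (STSD),
sensitivity, specificity.  Biological: LA diameter (maximum in-slice row sum
along the anterior-posterior axis), LA volume (voxel count x voxel volume),
and their percent errors against ground truth.  Coverage is the fraction of
surface voxels represented by the point cloud.  A cohort-level correlation
analysis relates coverage to every accuracy metric (Pearson r, two-sided p,
line of best fit).

"Surface" throughout means foreground voxels with at least one background
6-neighbor.  STSD uses Euclidean distance transforms of each surface set and
is reported in voxel units ("pixels"); multiply by the spacing for mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import LAGeometry, PointCloud, surface_voxels

__all__ = [
    "EvalReport",
    "dice_score",
    "stsd",
    "sensitivity_specificity",
    "la_diameter",
    "la_volume",
    "coverage",
    "error_map",
    "ErrorMap",
    "evaluate_case",
    "coverage_correlation",
    "CorrelationResult",
    "cohort_table",
    "plot_coverage_correlation",
]


def dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Smoothed dice overlap of two binary masks (1.0 when identical)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    num = 2.0 * float(np.logical_and(pred, truth).sum()) + 1.0
    den = float(pred.sum()) + float(truth.sum()) + 1.0
    return num / den


def _surface_distances(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(distances of pred-surface voxels to truth surface, and vice versa), voxels."""
    surf_p = surface_voxels(pred)
    surf_t = surface_voxels(truth)
    if not surf_p.any() or not surf_t.any():
        raise ValueError("both masks must be non-empty to measure surface distance")
    dt_to_t = ndimage.distance_transform_edt(~surf_t)
    dt_to_p = ndimage.distance_transform_edt(~surf_p)
    return dt_to_t[surf_p], dt_to_p[surf_t]


def stsd(pred: np.ndarray, truth: np.ndarray, spacing_mm: float = 1.0) -> float:
    """Average symmetric surface-to-surface distance.

    Sum of each prediction-surface voxel's distance to the truth surface and
    each truth-surface voxel's distance to the prediction surface, divided by
    the total number of surface voxels.  Returned in voxel units when
    ``spacing_mm`` is 1 (the convention used for reporting), otherwise mm.
    """
    d_pt, d_tp = _surface_distances(np.asarray(pred, bool), np.asarray(truth, bool))
    return float((d_pt.sum() + d_tp.sum()) / (len(d_pt) + len(d_tp)) * spacing_mm)


def sensitivity_specificity(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)) over voxels; NaN where undefined."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = float(np.logical_and(pred, truth).sum())
    fn = float(np.logical_and(~pred, truth).sum())
    tn = float(np.logical_and(~pred, ~truth).sum())
    fp = float(np.logical_and(pred, ~truth).sum())
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return sens, spec


def la_diameter(mask: np.ndarray, spacing_mm: float, ap_axis: int = 1) -> float:
    """Maximum LA diameter (mm): the largest row sum along the
    anterior-posterior axis over all slices of the volume.

    ``ap_axis`` maps the anatomical A-P direction onto an array axis for the
    dataset's orientation (default axis 1 of the synthetic frame).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    return float(mask.sum(axis=ap_axis).max()) * spacing_mm


def la_volume(mask: np.ndarray, spacing_mm: float) -> float:
    """LA volume in cm^3: foreground voxel count x voxel volume."""
    return float(np.asarray(mask, bool).sum()) * spacing_mm**3 / 1000.0


def coverage(pc: PointCloud | np.ndarray, la: LAGeometry) -> float:
    """Fraction of the LA surface represented by the point cloud.

    Points are snapped to the voxel grid and deduplicated; the result is the
    unique voxel count divided by the number of LA surface voxels (capped at
    1.0, since jittered points can land on voxels off the surface).
    Accepts a PointCloud or a bare (N, 3) array (N may be 0).
    """
    m = int(la.surface.sum())
    if m == 0:
        raise ValueError("LA has no surface voxels")
    points = pc.points if isinstance(pc, PointCloud) else np.asarray(pc, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return 0.0
    idx = np.floor((points - la.origin) / la.spacing_mm).astype(np.int64)
    n = len(np.unique(idx, axis=0))
    return min(1.0, n / m)


@dataclass
class ErrorMap:
    """Per-surface-voxel distance fields between two segmentations."""

    pred_to_truth: np.ndarray  # volume; distance (mm) at pred-surface voxels, 0 elsewhere
    truth_to_pred: np.ndarray
    pred_surface: np.ndarray  # boolean surface masks
    truth_surface: np.ndarray
    spacing_mm: float

    @property
    def mean_symmetric(self) -> float:
        """Mean over both direction fields; equals stsd (x spacing)."""
        s = self.pred_to_truth[self.pred_surface].sum() + self.truth_to_pred[self.truth_surface].sum()
        n = int(self.pred_surface.sum()) + int(self.truth_surface.sum())
        return float(s / n)

    def save(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag([self.spacing_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.pred_to_truth.astype(np.float32), affine), str(path))


def error_map(pred: np.ndarray, truth: np.ndarray, spacing_mm: float = 1.0) -> ErrorMap:
    """Surface-distance error maps in both directions (units: voxels x spacing)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    surf_p = surface_voxels(pred)
    surf_t = surface_voxels(truth)
    if not surf_p.any() or not surf_t.any():
        raise ValueError("both masks must be non-empty")
    field_p = np.zeros(pred.shape, dtype=np.float64)
    field_t = np.zeros(truth.shape, dtype=np.float64)
    field_p[surf_p] = ndimage.distance_transform_edt(~surf_t)[surf_p] * spacing_mm
    field_t[surf_t] = ndimage.distance_transform_edt(~surf_p)[surf_t] * spacing_mm
    return ErrorMap(field_p, field_t, surf_p, surf_t, spacing_mm)


@dataclass
class EvalReport:
    """All per-case metrics for one reconstruction."""

    dice: float
    stsd_px: float
    sensitivity: float
    specificity: float
    diameter_mm: float
    volume_cm3: float
    diameter_error_pct: float
    volume_error_pct: float
    coverage: float
    case_id: str = ""

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "dice": self.dice,
            "stsd_px": self.stsd_px,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "diameter_mm": self.diameter_mm,
            "volume_cm3": self.volume_cm3,
            "diameter_error_pct": self.diameter_error_pct,
            "volume_error_pct": self.volume_error_pct,
            "coverage": self.coverage,
        }


def evaluate_case(
    pred: LAGeometry,
    truth: LAGeometry,
    cloud: PointCloud | None = None,
    case_id: str = "",
    ap_axis: int = 1,
) -> EvalReport:
    """Full technical + biological evaluation of one predicted geometry.

    Percent errors are |pred - truth| / truth x 100.  Coverage is computed
    from the supplied point cloud against the *truth* geometry (NaN when no
    cloud is given).
    """
    if pred.mask.shape != truth.mask.shape:
        raise ValueError(f"shape mismatch: {pred.mask.shape} vs {truth.mask.shape}")
    sens, spec = sensitivity_specificity(pred.mask, truth.mask)
    d_pred = la_diameter(pred.mask, truth.spacing_mm, ap_axis=ap_axis)
    d_true = la_diameter(truth.mask, truth.spacing_mm, ap_axis=ap_axis)
    v_pred = la_volume(pred.mask, truth.spacing_mm)
    v_true = la_volume(truth.mask, truth.spacing_mm)
    return EvalReport(
        dice=dice_score(pred.mask, truth.mask),
        stsd_px=stsd(pred.mask, truth.mask),
        sensitivity=sens,
        specificity=spec,
        diameter_mm=d_pred,
        volume_cm3=v_pred,
        diameter_error_pct=abs(d_pred - d_true) / d_true * 100.0 if d_true else float("nan"),
        volume_error_pct=abs(v_pred - v_true) / v_true * 100.0 if v_true else float("nan"),
        coverage=coverage(cloud, truth) if cloud is not None else float("nan"),
        case_id=case_id,
    )


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    degenerate: bool = False


_CORR_METRICS = ("dice", "stsd_px", "sensitivity", "diameter_error_pct", "volume_error_pct")


def coverage_correlation(reports: list[EvalReport]) -> dict[str, CorrelationResult]:
    """Pearson correlation of coverage with each accuracy metric.

    Requires at least 3 reports.  Metrics with zero variance (or degenerate
    coverage) are flagged rather than raising.
    """
    if len(reports) < 3:
        raise ValueError(f"need >= 3 reports, got {len(reports)}")
    df = pd.DataFrame([r.as_dict() for r in reports])
    cov = df["coverage"].to_numpy(dtype=float)
    out: dict[str, CorrelationResult] = {}
    for metric in _CORR_METRICS:
        y = df[metric].to_numpy(dtype=float)
        ok = np.isfinite(cov) & np.isfinite(y)
        if ok.sum() < 3 or np.var(cov[ok]) == 0 or np.var(y[ok]) == 0:
            out[metric] = CorrelationResult(float("nan"), float("nan"), float("nan"), float("nan"), True)
            continue
        r, p = stats.pearsonr(cov[ok], y[ok])
        fit = stats.linregress(cov[ok], y[ok])
        out[metric] = CorrelationResult(float(r), float(p), float(fit.slope), float(fit.intercept))
    return out


def cohort_table(reports: list[EvalReport]) -> pd.DataFrame:
    """Per-case rows plus a mean +/- SD summary row appended last."""
    df = pd.DataFrame([r.as_dict() for r in reports])
    numeric = df.drop(columns="case_id")
    summary = numeric.mean().to_frame().T
    summary.insert(0, "case_id", "mean")
    sd = numeric.std().to_frame().T
    sd.insert(0, "case_id", "sd")
    return pd.concat([df, summary, sd], ignore_index=True)


def plot_coverage_correlation(
    reports: list[EvalReport], metric: str, path: str | Path
) -> CorrelationResult:
    """Scatter of coverage vs a metric with the best-fit line; saved as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    result = coverage_correlation(reports)[metric]
    df = pd.DataFrame([r.as_dict() for r in reports])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df["coverage"], df[metric], s=18, alpha=0.8)
    if not result.degenerate:
        xs = np.linspace(df["coverage"].min(), df["coverage"].max(), 50)
        ax.plot(xs, result.slope * xs + result.intercept, "r-", lw=1.5)
        ax.set_title(f"r = {result.r:.2f}, p = {result.p_value:.2g}")
    ax.set_xlabel("point-cloud coverage")
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return result
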