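"""Shim-quality metrics and the incremental-database convergence study.

NRMSE over a region is defined against the region-mean-calibrated target:
with the relative flip angle normalised so its region mean is 1,

    NRMSE = 100 * sqrt( mean_region( (alpha(r) - 1)^2 ) )  [percent]

which coincides numerically with the coefficient of variation when the
calibration and evaluation regions are the same mask.  The headline
aggregate across validation subjects is the median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import ChannelFieldMap, flip_angle_map
from .grid import CoilGeometry
from .shim import (
    CostSpec,
    ShimConstraints,
    ShimVector,
    apply_shim,
    cp_mode,
    optimize_subject,
    optimize_universal,
)

logger = logging.getLogger(__name__)

HISTOGRAM_RANGE = (0.0, 2.0)
HISTOGRAM_BINS = 50
LOW_B1_THRESHOLD = 0.5


def nrmse(flip_map: np.ndarray, roi: np.ndarray) -> float:
    """Percent RMS deviation of the relative flip angle from 1 over the ROI."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    alpha = np.asarray(flip_map, dtype=float)[roi]
    return 100.0 * float(np.sqrt(np.mean((alpha - 1.0) ** 2)))


def coefficient_of_variation(flip_map: np.ndarray, mask: np.ndarray) -> float:
    """Percent std/mean of the flip angle over a mask (scale-free)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(flip_map, dtype=float)[mask]
    mean = float(vals.mean())
    if mean == 0.0:
        raise ValueError("zero mean flip angle on the mask")
    return 100.0 * float(vals.std() / mean)


def field_distributions(
    flip_map: np.ndarray,
    roi: np.ndarray,
    brain_mask: np.ndarray,
    n_bins: int = HISTOGRAM_BINS,
    low_threshold: float = LOW_B1_THRESHOLD,
) -> dict:
    """Relative-B1+ distributions within ROI, outside ROI, and whole brain.

    Histograms share the fixed range [0, 2] in relative units and are
    normalised to sum to 1; each region also reports the fraction of voxels
    below ``low_threshold`` (quantifying very low B1+ regions).  The
    outside-ROI histogram is empty (and flagged) when the ROI covers the
    whole brain.
    """
    roi = np.asarray(roi, dtype=bool)
    brain = np.asarray(brain_mask, dtype=bool)
    if np.any(roi & ~brain):
        raise ValueError("ROI must be a subset of the brain mask")
    flip = np.asarray(flip_map, dtype=float)
    regions = {
        "within_roi": flip[roi],
        "outside_roi": flip[brain & ~roi],
        "whole_brain": flip[brain],
    }
    edges = np.linspace(*HISTOGRAM_RANGE, n_bins + 1)
    out: dict = {"bin_edges": edges}
    for name, vals in regions.items():
        counts, _ = np.histogram(vals, bins=edges)
        total = counts.sum()
        out[name] = {
            "density": counts / total if total else counts.astype(float),
            "n_voxels": int(vals.size),
            "low_fraction": float((vals < low_threshold).mean()) if vals.size else 0.0,
            "empty": vals.size == 0,
        }
    return out


@dataclass
class ConvergenceCurve:
    """Median validation NRMSE versus training-database size."""

    training_counts: np.ndarray
    median_validation_nrmse: np.ndarray
    cp_reference: float
    subject_specific_reference: float
    failed_counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.training_counts = np.asarray(self.training_counts, dtype=int)
        self.median_validation_nrmse = np.asarray(self.median_validation_nrmse, dtype=float)
        if self.training_counts.size != self.median_validation_nrmse.size:
            raise ValueError("curve length mismatch")
        if np.any(np.diff(self.training_counts) <= 0):
            raise ValueError("training counts must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.training_counts,
                "median_nrmse_pct": self.median_validation_nrmse,
                "cp_ref_pct": self.cp_reference,
                "subject_specific_ref_pct": self.subject_specific_reference,
            }
        )


def _validation_median_nrmse(shim, validation, constraints) -> float:
    vals = []
    for ds in validation:
        alpha, _ = apply_shim(ds.field_map, shim, ds.phantom.roi_mask, constraints)
        vals.append(nrmse(alpha, ds.phantom.roi_mask))
    return float(np.median(vals))


def convergence_study(
    training,
    validation,
    constraints: ShimConstraints | None = None,
    cost_spec: CostSpec | None = None,
    seed: int = 0,
    n_restarts: int = 2,
    subject_n_restarts: int = 4,
    geometry: CoilGeometry | None = None,
) -> ConvergenceCurve:
    """Universal-shim convergence over an expanding training database.

    For k = 1..N_train a universal shim is fitted on the first k training
    datasets (in acquisition order, warm-started from the k-1 solution) and
    applied to every validation subject; the curve records the median
    validation NRMSE per k.  CP-mode and per-subject subject-specific
    medians are computed as reference lines.  A failed optimisation at some
    k is logged and flagged, not fatal.
    """
    if len(training) < 1 or len(validation) < 1:
        raise ValueError("both databases must be nonempty")
    constraints = constraints or ShimConstraints()
    cost_spec = cost_spec or CostSpec()
    geometry = geometry or getattr(training, "geometry", None)

    counts, medians, failed = [], [], []
    warm: tuple = ()
    for k in range(1, len(training) + 1):
        try:
            res = optimize_universal(
                training.first(k), constraints, cost_spec,
                n_restarts=n_restarts, seed=seed, geometry=geometry,
                warm_starts=warm,
            )
            warm = (res.shim.weights,)
            medians.append(_validation_median_nrmse(res.shim.weights, validation, constraints))
        except Exception:  # noqa: BLE001 - per-k failures are recorded, not fatal
            logger.exception("universal optimisation failed at k=%d", k)
            medians.append(np.nan)
            failed.append(k)
        counts.append(k)

    if geometry is not None:
        cp_ref = _validation_median_nrmse(cp_mode(geometry).weights, validation, constraints)
    else:
        cp_ref = float("nan")

    subj_vals = []
    for i, ds in enumerate(validation):
        res = optimize_subject(
            ds.field_map, ds.phantom.roi_mask, constraints, cost_spec,
            n_restarts=subject_n_restarts, seed=seed + i, geometry=geometry,
        )
        alpha, _ = apply_shim(ds.field_map, res.shim.weights, ds.phantom.roi_mask, constraints)
        subj_vals.append(nrmse(alpha, ds.phantom.roi_mask))

    return ConvergenceCurve(
        training_counts=np.asarray(counts),
        median_validation_nrmse=np.asarray(medians),
        cp_reference=cp_ref,
        subject_specific_reference=float(np.median(subj_vals)),
        failed_counts=failed,
    )


def strategy_comparison(
    validation,
    shims: dict,
    constraints: ShimConstraints | None = None,
) -> pd.DataFrame:
    """Tidy per-strategy, per-subject NRMSE table on ROI and whole brain.

    ``shims`` maps a strategy label to either a single shim (applied to all
    subjects, e.g. CP mode or a universal solution) or a sequence of
    per-subject shims (e.g. subject-specific solutions).  Whole-brain rows
    are re-calibrated to the whole-brain mean (calibration column "self");
    ROI rows keep ROI calibration ("roi").
    """
    constraints = constraints or ShimConstraints()
    n_subjects = len(validation)
    rows = []
    for label, shim in shims.items():
        per_subject = _as_per_subject(shim, n_subjects)
        for i, ds in enumerate(validation):
            w = np.asarray(per_subject[i], dtype=complex)
            if w.size != ds.field_map.n_channels:
                raise ValueError(
                    f"strategy {label!r}: shim has {w.size} weights, "
                    f"field map has {ds.field_map.n_channels} channels"
                )
            alpha_roi = flip_angle_map(ds.field_map, w, ds.phantom.roi_mask)
            alpha_brain = flip_angle_map(ds.field_map, w, ds.phantom.brain_mask)
            rows.append({
                "strategy": label, "subject": ds.subject_id, "region": "roi",
                "calibration": "roi",
                "nrmse_pct": nrmse(alpha_roi, ds.phantom.roi_mask),
                "cv_pct": coefficient_of_variation(alpha_roi, ds.phantom.roi_mask),
            })
            rows.append({
                "strategy": label, "subject": ds.subject_id, "region": "brain",
                "calibration": "self",
                "nrmse_pct": nrmse(alpha_brain, ds.phantom.brain_mask),
                "cv_pct": coefficient_of_variation(alpha_brain, ds.phantom.brain_mask),
            })
    return pd.DataFrame(rows)


def _as_per_subject(shim, n_subjects: int) -> list:
    if isinstance(shim, ShimVector):
        return [shim.weights] * n_subjects
    if isinstance(shim, np.ndarray) and shim.ndim == 1:
        return [shim] * n_subjects
    shims = list(shim)
    if len(shims) != n_subjects:
        raise ValueError(f"expected {n_subjects} per-subject shims, got {len(shims)}")
    return [np.asarray(s, dtype=complex) for s in shims]
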