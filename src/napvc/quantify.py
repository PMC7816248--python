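"""Bias-field normalization, reference calibration and ROI statistics.

The sodium image is acquired in arbitrary units; absolute tissue sodium
concentration (mM) is obtained by linear scaling against a reference
region of known concentration -- ventricular CSF, assumed to be 138 mM.
Before that, the coil sensitivity profile is divided out (bias-field
correction), with a floor on the normalized sensitivity so that
near-zero-sensitivity voxels are zeroed instead of amplified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import LabelMask, Volume3D

__all__ = [
    "CalibrationSpec",
    "bias_correct",
    "calibrate_tsc",
    "delta_tsc",
    "roi_summary",
]


@dataclass(frozen=True)
class CalibrationSpec:
    """Reference-region calibration: scale so the reference mean equals
    ``reference_value`` (mM)."""

    reference_value: float = 138.0

    def __post_init__(self) -> None:
        if self.reference_value <= 0:
            raise ValueError("reference_value must be > 0")


def bias_correct(
    vol: Volume3D,
    sensitivity: Volume3D,
    brain_mask: np.ndarray,
    floor: float = 0.05,
) -> tuple[Volume3D, np.ndarray]:
    """Divide out the coil sensitivity, normalized to its brain-mask mean.

    Voxels whose normalized sensitivity falls below ``floor`` are set to 0
    and returned in the low-sensitivity QC mask (division there would only
    amplify noise).
    """
    if vol.shape != sensitivity.shape:
        raise ValueError("volume and sensitivity must share one grid")
    if (sensitivity.data < 0).any():
        raise ValueError("sensitivity must be non-negative")
    ref = float(sensitivity.data[brain_mask].mean())
    if ref <= 0:
        raise ValueError("sensitivity is zero over the brain mask")
    norm = sensitivity.data / ref
    low = norm < floor
    out = np.where(low, 0.0, vol.data / np.where(low, 1.0, norm))
    return vol.like(out), low


def calibrate_tsc(
    vol: Volume3D,
    reference_mask: np.ndarray,
    cal: CalibrationSpec = CalibrationSpec(),
) -> Volume3D:
    """Scale the image so the reference-region mean equals the assumed TSC.

    Scale-equivariant: calibrating a * vol gives the same output as
    calibrating vol.
    """
    if reference_mask.shape != vol.shape:
        raise ValueError("reference mask must live on the volume grid")
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    ref_mean = float(vol.data[reference_mask].mean())
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference mean ({ref_mean})")
    return vol.like(vol.data * (cal.reference_value / ref_mean))


def delta_tsc(
    ground_truth: Volume3D,
    corrected: Volume3D,
    roi: np.ndarray,
) -> tuple[float, float, float]:
    """Mean/SD of (ground truth - corrected) over an ROI, plus percent.

    The percent difference uses the ground-truth ROI mean as denominator
    (an 'underestimated by 20%' convention).
    """
    if ground_truth.shape != corrected.shape or roi.shape != ground_truth.shape:
        raise ValueError("ground truth, corrected map and ROI must share one grid")
    if not roi.any():
        raise ValueError("empty ROI")
    diff = ground_truth.data[roi] - corrected.data[roi]
    gt_mean = float(ground_truth.data[roi].mean())
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    pct = 100.0 * mean / gt_mean if gt_mean != 0 else float("nan")
    return mean, sd, pct


def roi_summary(
    tsc: Volume3D,
    rois: dict[str, np.ndarray],
    exclude: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean / sample SD / CoV (%) per ROI; flagged voxels can be excluded.

    CoV = 100 * SD / mean; empty ROIs yield NaN rows.
    """
    rows = []
    for name, sel in rois.items():
        if exclude is not None:
            sel = sel & ~exclude
        vals = tsc.data[sel]
        if vals.size == 0:
            rows.append({"roi": name, "n": 0, "mean": np.nan, "sd": np.nan, "cov": np.nan})
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        cov = 100.0 * sd / mean if mean != 0 else np.nan
        rows.append({"roi": name, "n": int(vals.size), "mean": mean, "sd": sd, "cov": cov})
    return pd.DataFrame(rows)
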