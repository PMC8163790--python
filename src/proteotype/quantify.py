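"""Calibration-curve fitting and absolute quantification.

Each assay's external calibration curve relates the light/heavy peak-area
ratio y to the spiked light-peptide concentration x (fmol/uL) by a straight
line fitted with 1/x^e weighting (default e = 2, the standard bioanalytical
choice that equalises relative error across a curve spanning three decades).
Endogenous concentrations are back-calculated by inverting the line and
censored against the assay's LLOQ/ULOQ; the LLOQ boundary itself counts as
in range.  Curves are fitted once from the plate-1 standards and applied to
all plates; plate-to-plate drift is handled downstream by pooled-reference
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AssayDefinition,
    ConcentrationMatrix,
    TransitionRecord,
    ValidationError,
    records_to_frame,
)

logger = logging.getLogger(__name__)


class DegenerateDesignError(ValueError):
    """Calibration design cannot identify a line (e.g. all x identical)."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Weighted least-squares line ratio = slope * conc + intercept."""

    protein_id: str
    slope: float
    intercept: float
    weighting_exponent: int
    r_squared: float
    n_points: int
    lloq: float
    uloq: float
    rejected: bool = False  # slope <= 0: curve unusable for back-calculation


@dataclass(frozen=True)
class QcSummary:
    """Pooled-reference precision for one assay (CV over in-range values)."""

    protein_id: str
    n_pooled: int
    mean_conc: float
    cv_percent: float


def fit_calibration(
    points: Sequence[tuple[float, float]],
    weighting_exponent: int = 2,
    *,
    protein_id: str = "",
    lloq: float = np.nan,
    uloq: float = np.nan,
) -> CalibrationCurve:
    """Fit (slope, intercept) minimising sum w_i (y_i - a x_i - b)^2, w_i = 1/x_i^e.

    Solved by the weighted normal equations.  A non-positive slope marks the
    curve ``rejected`` (flagged, not raised) so callers can report it.
    """
    if len(points) < 2:
        raise ValidationError("calibration needs >= 2 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.any(x <= 0):
        raise ValidationError("calibration concentrations must be > 0")
    if np.allclose(x, x[0]):
        raise DegenerateDesignError("all calibration concentrations identical")
    w = 1.0 / x**weighting_exponent
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_res = (w * (y - slope * x - intercept) ** 2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    rejected = not slope > 0
    if rejected:
        logger.warning("calibration slope <= 0 for %s; curve rejected", protein_id)
    return CalibrationCurve(
        protein_id=protein_id,
        slope=float(slope),
        intercept=float(intercept),
        weighting_exponent=weighting_exponent,
        r_squared=float(r2),
        n_points=len(points),
        lloq=float(lloq),
        uloq=float(uloq),
        rejected=rejected,
    )


def back_calculate(ratio: float, curve: CalibrationCurve) -> tuple[float, str]:
    """Invert the curve: concentration = (ratio - intercept) / slope.

    Negative back-calculations clamp to 0 (concentrations are physical) and
    flag ``below_lloq``.  The LLOQ/ULOQ boundaries are inclusive in-range.
    """
    if curve.rejected or not curve.slope > 0:
        raise ValidationError(
            f"curve for {curve.protein_id!r} is rejected (slope <= 0)"
        )
    conc = (ratio - curve.intercept) / curve.slope
    if conc < 0:
        return 0.0, "below_lloq"
    if conc < curve.lloq:
        return conc, "below_lloq"
    if conc > curve.uloq:
        return conc, "above_uloq"
    return conc, "in_range"


def fit_all_curves(
    records: Iterable[TransitionRecord] | pd.DataFrame,
    assays: Iterable[AssayDefinition],
    weighting_exponent: int = 2,
) -> dict[str, CalibrationCurve]:
    """Fit one curve per assay from the calibration_standard records."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    cal = frame[frame["role"] == "calibration_standard"]
    curves: dict[str, CalibrationCurve] = {}
    for assay in assays:
        rows = cal[cal["protein_id"] == assay.protein_id]
        if rows.empty:
            raise ValidationError(f"no calibration standards for {assay.protein_id}")
        pts = list(
            zip(
                rows["nominal_conc"].astype(float),
                rows["light_area"].astype(float) / rows["heavy_area"].astype(float),
            )
        )
        curves[assay.protein_id] = fit_calibration(
            pts,
            weighting_exponent,
            protein_id=assay.protein_id,
            lloq=assay.lloq,
            uloq=assay.uloq,
        )
    return curves


@dataclass
class QuantificationResult:
    study: ConcentrationMatrix
    pooled: ConcentrationMatrix
    #: plate of each pooled-reference sample (index = pooled sample id)
    pooled_plates: pd.Series
    #: plate of each study sample
    study_plates: pd.Series
    #: per-protein pooled-reference QC across all plates
    qc: list[QcSummary]
    #: per (plate, protein) pooled CV table
    qc_by_plate: pd.DataFrame


def _pivot(frame: pd.DataFrame, curves: Mapping[str, CalibrationCurve],
           proteins: list[str]) -> ConcentrationMatrix:
    ratio = frame["light_area"].astype(float) / frame["heavy_area"].astype(float)
    conc = np.empty(len(frame))
    flag = np.empty(len(frame), dtype=object)
    for i, (pid, r) in enumerate(zip(frame["protein_id"], ratio)):
        conc[i], flag[i] = back_calculate(r, curves[pid])
    tmp = frame[["sample_id", "protein_id"]].copy()
    tmp["conc"] = conc
    tmp["flag"] = flag
    dup = tmp.duplicated(["sample_id", "protein_id"])
    if dup.any():
        raise ValidationError(
            "duplicate (sample, protein) measurement: "
            + repr(tmp.loc[dup, ["sample_id", "protein_id"]].iloc[0].tolist())
        )
    order = pd.unique(tmp["sample_id"])
    values = tmp.pivot(index="sample_id", columns="protein_id", values="conc")
    flags = tmp.pivot(index="sample_id", columns="protein_id", values="flag")
    values = values.reindex(index=order, columns=proteins)
    flags = flags.reindex(index=order, columns=proteins)
    flags = flags.where(values.notna(), "missing")
    values.index.name = values.columns.name = None
    flags.index.name = flags.columns.name = None
    return ConcentrationMatrix(values, flags)


def quantify_dataset(
    records: Iterable[TransitionRecord] | pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    assays: Iterable[AssayDefinition],
) -> QuantificationResult:
    """Back-calculate every study and pooled-reference record.

    Returns the study sample x protein matrix, the pooled-reference matrix
    (used for plate normalization), and pooled-reference QC summaries.
    Proteins with no record for a sample become missing cells (logged).
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    proteins = [a.protein_id for a in assays]
    for pid in proteins:
        if pid not in curves:
            raise ValidationError(f"no calibration curve for {pid}")
    study_frame = frame[frame["role"] == "study"]
    pooled_frame = frame[frame["role"] == "pooled_reference"]
    study = _pivot(study_frame, curves, proteins)
    pooled = _pivot(pooled_frame, curves, proteins)
    n_missing = int(study.values.isna().sum().sum())
    if n_missing:
        logger.warning("study matrix has %d missing cells", n_missing)
    all_missing = study.values.columns[study.values.isna().all(axis=0)]
    for pid in all_missing:
        logger.warning("protein %s has no study measurements at all", pid)
    study_plates = (
        study_frame.drop_duplicates("sample_id").set_index("sample_id")["plate_id"]
    )
    pooled_plates = (
        pooled_frame.drop_duplicates("sample_id").set_index("sample_id")["plate_id"]
    )
    qc = []
    for pid in proteins:
        vals = pooled.values[pid][pooled.flags[pid] == "in_range"].dropna()
        cv = compute_cv(vals.to_numpy()) if len(vals) >= 2 else np.nan
        qc.append(
            QcSummary(
                protein_id=pid,
                n_pooled=int(len(vals)),
                mean_conc=float(vals.mean()) if len(vals) else np.nan,
                cv_percent=cv,
            )
        )
    rows = []
    for plate, sample_ids in pooled_plates.groupby(pooled_plates).groups.items():
        for pid in proteins:
            sub = pooled.values.loc[list(sample_ids), pid]
            ok = pooled.flags.loc[list(sample_ids), pid] == "in_range"
            vals = sub[ok].dropna().to_numpy()
            rows.append(
                {
                    "plate_id": plate,
                    "protein_id": pid,
                    "n_pooled": len(vals),
                    "mean_conc": float(np.mean(vals)) if len(vals) else np.nan,
                    "cv_percent": compute_cv(vals) if len(vals) >= 2 else np.nan,
                }
            )
    return QuantificationResult(
        study=study,
        pooled=pooled,
        pooled_plates=pooled_plates,
        study_plates=study_plates,
        qc=qc,
        qc_by_plate=pd.DataFrame(rows),
    )


def compute_cv(values: np.ndarray | Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sd / mean (sd with n-1)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValidationError("CV needs >= 2 values")
    m = v.mean()
    if m == 0:
        logger.warning("CV undefined: mean is 0")
        return float("nan")
    return float(100.0 * v.std(ddof=1) / m)
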