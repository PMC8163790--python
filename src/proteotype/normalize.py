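"""Plate-wise pooled-reference normalization and the LLOQ filtering cascade.

Normalization rescales each plate per protein so that the plate's pooled
references match the grand (all-plate) pooled median.  When more than half
of a plate's pooled references fall below the assay LLOQ the pooled median
is untrustworthy and the original values are kept unchanged (factor 1) —
the below-LLOQ exception.  The filtering cascade then classifies proteins:
detectable (at least one in-range measurement), quantifiable (>= 5% of all
measurements in range), and final (fully in range in every member of at
least one strain x sex group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import ConcentrationMatrix, SampleAnnotation, ValidationError, annotations_to_frame

logger = logging.getLogger(__name__)


def _recensor(values: pd.DataFrame, flags: pd.DataFrame, lloqs: pd.Series,
              uloqs: pd.Series) -> pd.DataFrame:
    """Recompute range flags against LLOQ/ULOQ; missing cells stay missing."""
    out = pd.DataFrame("in_range", index=values.index, columns=values.columns)
    out = out.where(~values.lt(lloqs, axis=1), "below_lloq")
    out = out.where(~values.gt(uloqs, axis=1), "above_uloq")
    return out.where(values.notna(), "missing")


def normalize_plates(
    matrix: ConcentrationMatrix,
    pooled: ConcentrationMatrix,
    pooled_plates: pd.Series,
    study_plates: pd.Series,
    lloqs: pd.Series,
    uloqs: pd.Series | None = None,
) -> tuple[ConcentrationMatrix, ConcentrationMatrix, pd.DataFrame]:
    """Scale study (and pooled) values per (plate, protein) to the grand pooled median.

    Returns (normalized study matrix, normalized pooled matrix, report).
    The report has one row per (plate, protein) with the factor applied,
    the number of in-range pooled references, and whether the below-LLOQ
    exception fired.  Censor flags are recomputed after scaling.
    """
    lloqs = lloqs.reindex(matrix.proteins)
    if uloqs is None:
        uloqs = lloqs * 1000.0
    uloqs = uloqs.reindex(matrix.proteins)
    plates = sorted(pooled_plates.unique())
    for plate in sorted(study_plates.unique()):
        if plate not in plates:
            raise ValidationError(f"plate {plate!r} has zero pooled references")

    pv = pooled.values
    factors = pd.DataFrame(1.0, index=plates, columns=matrix.proteins)
    rows = []
    for pid in matrix.proteins:
        lloq = lloqs[pid]
        col = pv[pid]
        below = col < lloq  # LLOQ boundary inclusive: == LLOQ is in range
        in_range_vals = col[~below & col.notna()]
        plate_of = pooled_plates.reindex(col.index)
        exception: dict[str, bool] = {}
        plate_median: dict[str, float] = {}
        for plate in plates:
            on_plate = plate_of == plate
            n_total = int((on_plate & col.notna()).sum())
            n_below = int((on_plate & below).sum())
            exc = n_total == 0 or n_below > n_total / 2.0
            exception[plate] = exc
            vals = in_range_vals[plate_of[~below & col.notna()] == plate]
            plate_median[plate] = float(vals.median()) if len(vals) else np.nan
        grand = float(in_range_vals.median()) if len(in_range_vals) else np.nan
        for plate in plates:
            if exception[plate] or not np.isfinite(grand) or not np.isfinite(
                plate_median[plate]
            ) or plate_median[plate] == 0:
                f = 1.0
                exc = True
            else:
                f = grand / plate_median[plate]
                exc = False
            factors.loc[plate, pid] = f
            rows.append(
                {
                    "plate_id": plate,
                    "protein_id": pid,
                    "factor": f,
                    "n_pooled_in_range": int(
                        (in_range_vals.index.map(plate_of) == plate).sum()
                    ),
                    "exception_applied": exc,
                }
            )
    report = pd.DataFrame(rows)

    def _apply(m: ConcentrationMatrix, plate_map: pd.Series) -> ConcentrationMatrix:
        fac = factors.loc[plate_map.reindex(m.samples)].to_numpy()
        values = m.values * fac
        flags = _recensor(values, m.flags, lloqs, uloqs)
        return ConcentrationMatrix(values, flags)

    return _apply(matrix, study_plates), _apply(pooled, pooled_plates), report


@dataclass
class FilterReport:
    n_measured: int
    n_detectable: int
    n_quantifiable: int
    n_final: int
    #: per-protein disposition: protein_id, stage survived, reason if dropped
    disposition: pd.DataFrame

    def __post_init__(self) -> None:
        if not (
            self.n_measured >= self.n_detectable >= self.n_quantifiable >= self.n_final
        ):
            raise ValidationError("filter counts must be monotone non-increasing")


def filter_cascade(
    matrix: ConcentrationMatrix,
    annotations: list[SampleAnnotation] | pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[ConcentrationMatrix, FilterReport]:
    """Three-stage protein filter: detectable, quantifiable, final.

    Stage 1 (detectable): >= 1 in-range measurement anywhere.
    Stage 2 (quantifiable): fraction of all measurements in range >= the
    configured minimum (default 5%).
    Stage 3 (final): at least one strain x sex group in which every
    member's value is in range.
    """
    config = config or PipelineConfig()
    ann = (
        annotations
        if isinstance(annotations, pd.DataFrame)
        else annotations_to_frame(annotations)
    )
    ann = ann.reindex(matrix.samples)
    in_range = matrix.flags == "in_range"
    n_samples = len(matrix.samples)

    detectable = in_range.any(axis=0)
    frac = in_range.sum(axis=0) / max(n_samples, 1)
    quantifiable = detectable & (frac >= config.detect_min_fraction)

    group_key = ann["strain"].astype(str) + "|" + ann["sex"].astype(str)
    full_group = pd.Series(False, index=matrix.proteins)
    for _, idx in in_range.groupby(group_key).groups.items():
        full_group |= in_range.loc[idx].all(axis=0)
    final = quantifiable & full_group

    reasons = pd.Series("retained", index=matrix.proteins, dtype=object)
    reasons[~full_group] = "no strain/sex group fully in range"
    reasons[~quantifiable] = f"< {config.detect_min_fraction:.0%} of measurements in range"
    reasons[~detectable] = "no in-range measurement"
    stage = pd.Series("final", index=matrix.proteins, dtype=object)
    stage[~final] = "quantifiable"
    stage[~quantifiable] = "detectable"
    stage[~detectable] = "measured"
    disposition = pd.DataFrame(
        {"protein_id": matrix.proteins, "stage": stage.to_numpy(), "reason": reasons.to_numpy()}
    )
    keep = list(final[final].index)
    reduced = ConcentrationMatrix(matrix.values[keep].copy(), matrix.flags[keep].copy())
    report = FilterReport(
        n_measured=len(matrix.proteins),
        n_detectable=int(detectable.sum()),
        n_quantifiable=int(quantifiable.sum()),
        n_final=int(final.sum()),
        disposition=disposition,
    )
    logger.info(
        "filter cascade: %d measured -> %d detectable -> %d quantifiable -> %d final",
        report.n_measured,
        report.n_detectable,
        report.n_quantifiable,
        report.n_final,
    )
    return reduced, report
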