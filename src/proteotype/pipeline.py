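"""End-to-end orchestration: simulate/load -> quantify -> normalize -> filter.

Convenience layer used by the CLI ``run-all`` subcommand and by scripted
analyses; each stage remains callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import PipelineConfig
from .io import AssayDefinition, ConcentrationMatrix, SampleAnnotation
from .normalize import FilterReport, filter_cascade, normalize_plates
from .quantify import QuantificationResult, fit_all_curves, quantify_dataset
from .simulate import SimulatedDataset


@dataclass
class PipelineRun:
    quant: QuantificationResult
    normalized: ConcentrationMatrix
    normalized_pooled: ConcentrationMatrix
    normalization_report: pd.DataFrame
    filtered: ConcentrationMatrix
    filter_report: FilterReport


def run_pipeline(
    transitions: pd.DataFrame,
    annotations: list[SampleAnnotation] | pd.DataFrame,
    assays: list[AssayDefinition],
    config: PipelineConfig | None = None,
) -> PipelineRun:
    """Quantify, plate-normalize and filter one transition-level dataset."""
    config = config or PipelineConfig()
    curves = fit_all_curves(transitions, assays, config.weighting_exponent)
    quant = quantify_dataset(transitions, curves, assays)
    lloqs = pd.Series({a.protein_id: a.lloq for a in assays})
    uloqs = pd.Series({a.protein_id: a.uloq for a in assays})
    normalized, normalized_pooled, norm_report = normalize_plates(
        quant.study,
        quant.pooled,
        quant.pooled_plates,
        quant.study_plates,
        lloqs,
        uloqs,
    )
    filtered, filt_report = filter_cascade(normalized, annotations, config)
    return PipelineRun(
        quant=quant,
        normalized=normalized,
        normalized_pooled=normalized_pooled,
        normalization_report=norm_report,
        filtered=filtered,
        filter_report=filt_report,
    )


def run_simulated(
    dataset: SimulatedDataset, config: PipelineConfig | None = None
) -> PipelineRun:
    return run_pipeline(
        dataset.transitions, dataset.annotations, dataset.assays, config
    )
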