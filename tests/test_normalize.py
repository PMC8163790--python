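"""Plate normalization (with the below-LLOQ exception) and filtering cascade."""

import numpy as np
import pandas as pd
import pytest

from proteotype.config import PipelineConfig
from proteotype.io import ConcentrationMatrix, SampleAnnotation, ValidationError
from proteotype.normalize import FilterReport, filter_cascade, normalize_plates
from proteotype.pipeline import run_simulated
from proteotype.simulate import SimulationDesign, TruthConfig, simulate_dataset


def _matrix(values: dict, lloq=1.0, uloq=1000.0):
    v = pd.DataFrame(values).T  # rows = samples
    flags = pd.DataFrame("in_range", index=v.index, columns=v.columns)
    flags = flags.where(~(v < lloq), "below_lloq").where(~(v > uloq), "above_uloq")
    flags = flags.where(v.notna(), "missing")
    return ConcentrationMatrix(v.astype(float), flags)


def _norm(study, pooled, pooled_plates, study_plates, lloq=1.0):
    lloqs = pd.Series(lloq, index=study.proteins)
    return normalize_plates(
        study, pooled, pd.Series(pooled_plates), pd.Series(study_plates), lloqs
    )


class TestNormalizePlates:
    def test_equal_plate_medians_give_unit_factors(self):
        pooled = _matrix({"Q1": [100.0], "Q2": [100.0], "Q3": [100.0], "Q4": [100.0]})
        study = _matrix({"S1": [50.0], "S2": [70.0]})
        norm, _, report = _norm(
            study,
            pooled,
            {"Q1": "A", "Q2": "A", "Q3": "B", "Q4": "B"},
            {"S1": "A", "S2": "B"},
        )
        assert (report["factor"] == 1.0).all()
        pd.testing.assert_frame_equal(norm.values, study.values)

    def test_low_plate_scaled_to_grand_median(self):
        # plate A pooled median 50, plate B 150 -> grand median 100 -> A x2
        pooled = _matrix(
            {"Q1": [50.0], "Q2": [50.0], "Q3": [150.0], "Q4": [150.0]}
        )
        study = _matrix({"S1": [40.0], "S2": [60.0]})
        norm, _, report = _norm(
            study,
            pooled,
            {"Q1": "A", "Q2": "A", "Q3": "B", "Q4": "B"},
            {"S1": "A", "S2": "B"},
        )
        fa = report.query("plate_id == 'A'")["factor"].iloc[0]
        assert fa == pytest.approx(2.0)
        assert norm.values.loc["S1"].iloc[0] == pytest.approx(80.0)

    def test_below_lloq_majority_triggers_exception(self):
        # 7 of 12 pooled values below LLOQ on plate A -> factor 1
        vals = {f"Q{i}": [0.5 if i <= 7 else 50.0] for i in range(1, 13)}
        vals.update({f"R{i}": [100.0] for i in range(1, 10)})
        pooled = _matrix(vals)
        study = _matrix({"S1": [40.0]})
        plates = {f"Q{i}": "A" for i in range(1, 13)}
        plates.update({f"R{i}": "B" for i in range(1, 10)})
        _, _, report = _norm(study, pooled, plates, {"S1": "A"})
        row = report.query("plate_id == 'A'").iloc[0]
        assert row["exception_applied"]
        assert row["factor"] == 1.0

    def test_zero_pooled_references_on_a_plate_rejected(self):
        pooled = _matrix({"Q1": [100.0], "Q2": [100.0]})
        study = _matrix({"S1": [40.0]})
        with pytest.raises(ValidationError):
            _norm(study, pooled, {"Q1": "A", "Q2": "A"}, {"S1": "B"})

    def test_idempotent_on_simulated_data(self, small_dataset, small_run):
        lloqs = pd.Series({a.protein_id: a.lloq for a in small_dataset.assays})
        uloqs = pd.Series({a.protein_id: a.uloq for a in small_dataset.assays})
        quant = small_run.quant
        again = normalize_plates(
            small_run.normalized,
            small_run.normalized_pooled,
            quant.pooled_plates,
            quant.study_plates,
            lloqs,
            uloqs,
        )
        np.testing.assert_allclose(again[2]["factor"].to_numpy(), 1.0, atol=1e-12)

    def test_noise_free_plate_bias_recovered_exactly(self):
        """kappa = 0 with real plate biases: normalization must return the
        bias-free truth for every non-exception protein."""
        design = SimulationDesign(
            n_strains=0, n_controls_per_sex=6, n_proteins=30, pooled_refs_per_plate=9
        )
        tc = TruthConfig(
            cv=0.0,
            biological_cv=0.0,
            n_sex_effects=0,
            n_secondary_ko_effects=0,
            plate_bias_sd=0.15,
            contamination_fraction=0.0,
        )
        ds = simulate_dataset(design, tc, seed=9)
        run = run_simulated(ds)
        expected = ds.truth.baselines[run.normalized.proteins]
        exceptions = set(
            run.normalization_report.query("exception_applied")["protein_id"]
        )
        check = [p for p in run.normalized.proteins if p not in exceptions]
        for sid in run.normalized.samples:
            np.testing.assert_allclose(
                run.normalized.values.loc[sid, check].to_numpy(),
                expected[check].to_numpy(),
                rtol=1e-9,
            )


ANN = [
    SampleAnnotation("S1", "KO1", "HOM", "F", "A"),
    SampleAnnotation("S2", "KO1", "HOM", "F", "A"),
    SampleAnnotation("S3", "KO1", "HOM", "F", "A"),
    SampleAnnotation("S4", "WT", "WT", "M", "A"),
    SampleAnnotation("S5", "WT", "WT", "M", "A"),
    SampleAnnotation("S6", "WT", "WT", "M", "A"),
]


class TestFilterCascade:
    def _run(self, flags_by_protein):
        proteins = list(flags_by_protein)
        samples = [a.sample_id for a in ANN]
        flags = pd.DataFrame(
            {p: flags_by_protein[p] for p in proteins}, index=samples
        )
        values = pd.DataFrame(10.0, index=samples, columns=proteins).where(
            flags != "missing"
        )
        matrix = ConcentrationMatrix(values, flags)
        return filter_cascade(matrix, ANN)

    def test_fully_in_range_protein_survives_all_stages(self):
        _, report = self._run({"P1": ["in_range"] * 6})
        assert report.n_final == 1

    def test_low_fraction_dropped_at_quantifiable_stage(self):
        flags = ["in_range"] + ["below_lloq"] * 5  # 1/6 = 17% > 5% -> survives
        _, report = self._run({"P1": flags})
        assert report.n_quantifiable == 1
        assert report.n_final == 0  # but no complete strain/sex group

    def test_four_percent_in_range_dropped_at_stage_two(self):
        ann = [
            SampleAnnotation(f"T{i:02d}", "WT", "WT", "F", "A") for i in range(25)
        ]
        samples = [a.sample_id for a in ann]
        flags = pd.DataFrame(
            {"P1": ["in_range"] + ["below_lloq"] * 24}, index=samples
        )
        values = pd.DataFrame(10.0, index=samples, columns=["P1"])
        _, report = filter_cascade(ConcentrationMatrix(values, flags), ann)
        assert report.n_detectable == 1
        assert report.n_quantifiable == 0

    def test_never_in_range_not_detectable(self):
        _, report = self._run({"P1": ["below_lloq"] * 6})
        assert report.n_detectable == 0

    def test_one_complete_group_is_enough_for_final(self):
        flags = ["in_range"] * 3 + ["below_lloq"] * 3  # all 3 KO1/F mice
        _, report = self._run({"P1": flags})
        assert report.n_final == 1

    def test_incomplete_group_fails_final(self):
        flags = ["in_range", "in_range", "below_lloq"] * 2
        _, report = self._run({"P1": flags})
        assert report.n_quantifiable == 1
        assert report.n_final == 0

    def test_counts_monotone(self, default_run):
        r = default_run.filter_report
        assert r.n_measured >= r.n_detectable >= r.n_quantifiable >= r.n_final

    def test_adding_in_range_measurement_never_drops_a_survivor(self):
        flags = ["in_range"] * 3 + ["below_lloq"] * 3
        reduced_before, _ = self._run({"P1": flags, "P2": ["in_range"] * 6})
        flags2 = ["in_range"] * 4 + ["below_lloq"] * 2
        reduced_after, _ = self._run({"P1": flags2, "P2": ["in_range"] * 6})
        assert set(reduced_before.proteins) <= set(reduced_after.proteins)

    def test_report_rejects_non_monotone_counts(self):
        with pytest.raises(ValidationError):
            FilterReport(1, 2, 0, 0, pd.DataFrame())
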