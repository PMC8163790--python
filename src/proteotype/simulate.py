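"""Synthetic transition-level datasets with known ground truth.

The generator emulates the structure of a multi-plate MRM plasma
proteotyping study: 30 knockout strains x 2 sexes x 3 mice plus 19 + 19
wild-type controls (218 study samples) randomized over 3 plates with
pooled references on every plate, an 8-point calibration curve on plate 1
spanning 1-1000x LLOQ, curve QC standards on every plate, ~226 assays with
baselines spanning five orders of magnitude (0.3 to 6e4 fmol/uL), ~9%
multiplicative measurement CV, per-protein plate biases, sparse additive
erythrocyte contamination shared across a 12-protein panel (plus one
extension candidate), per-protein sex effects, and per-strain knockout
effects including full ablation of the knocked-out protein.

Every draw flows from one seeded generator, so identical (design, truth
config, seed) produce bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ConfigError
from .io import (
    AssayDefinition,
    PanelDefinition,
    SampleAnnotation,
    TRANSITION_COLUMNS,
)

logger = logging.getLogger(__name__)

#: erythrocyte-specific intracellular proteins used as the simulated panel
ERYTHROCYTE_PANEL = (
    "BPGM", "CA1", "CA2", "BLVRB", "HBA", "HBB-B1",
    "HBZ", "PRDX2", "PRDX6", "SOD1", "CAT", "ESD",
)
#: intracellular protein sharing the contamination loading but absent from
#: the shipped panel — the planted panel-extension candidate
EXTENSION_CANDIDATE = "ISG15"
PLATELET_PANEL = (
    "PF4", "PPBP", "THBS1", "SELP", "ITGA2B",
    "ITGB3", "VWF", "FLNA", "TLN1", "MYH9",
)


@dataclass(frozen=True)
class SimulationDesign:
    """Study layout; defaults reproduce 30*2*3 + 2*19 = 218 study samples."""

    n_strains: int = 30
    mice_per_strain_per_sex: int = 3
    n_controls_per_sex: int = 19
    n_plates: int = 3
    pooled_refs_per_plate: int = 11
    n_proteins: int = 226
    calibration_levels: Sequence[float] = (1, 2, 5, 10, 50, 100, 500, 1000)
    qc_levels: Sequence[float] = (3.0, 30.0, 300.0)

    def __post_init__(self) -> None:
        if not 9 <= self.pooled_refs_per_plate <= 12:
            raise ConfigError("pooled_refs_per_plate must be in [9, 12]")
        if len(self.calibration_levels) < 2:
            raise ConfigError("need >= 2 calibration levels")

    @property
    def n_study_samples(self) -> int:
        return (
            self.n_strains * 2 * self.mice_per_strain_per_sex
            + 2 * self.n_controls_per_sex
        )


@dataclass(frozen=True)
class TruthConfig:
    """Effect-size and noise settings for the generative model."""

    #: protein baselines drawn log-uniform over this range (fmol/uL)
    baseline_range: tuple[float, float] = (0.3, 6.0e4)
    #: multiplicative measurement CV (0.09 = 9%)
    cv: float = 0.09
    #: between-mouse biological CV on study concentrations (pooled
    #: references and standards are unaffected)
    biological_cv: float = 0.15
    #: number of sex-dimorphic proteins and |log2 FC| range
    n_sex_effects: int = 20
    sex_effect_range: tuple[float, float] = (1.0, 2.0)
    #: secondary (non-target) affected proteins per knockout strain
    n_secondary_ko_effects: int = 3
    ko_effect_range: tuple[float, float] = (1.0, 2.0)
    #: log2 effect on the strain's own protein in heterozygotes
    het_target_log2fc: float = -1.0
    #: sd of the per-protein-per-plate log-normal bias (median-centred
    #: across plates so plate normalization is exactly invertible)
    plate_bias_sd: float = 0.04
    #: fraction of study samples carrying erythrocyte contamination
    contamination_fraction: float = 0.25
    #: contamination loading scale relative to the protein baseline
    contamination_scale: float = 2.0
    #: blank signal for absent/ablated proteins, as a multiple of LLOQ
    blank_level: float = 0.1
    #: assay LLOQ depth below baseline: lloq = baseline / 10^U(range)
    lloq_depth_range: tuple[float, float] = (1.0, 2.5)
    heavy_area_mean: float = 1.0e5
    heavy_area_cv: float = 0.3
    #: planted phenotype tests (protein-linked, sex-only, pure noise)
    n_planted_phenotypes: int = 2

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ConfigError("cv must be >= 0")
        if not 0 <= self.contamination_fraction <= 1:
            raise ConfigError("contamination_fraction must be in [0, 1]")


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated dataset."""

    baselines: pd.Series
    lloqs: pd.Series
    sex_log2fc: pd.Series  # log2(male/female); 0 for null proteins
    ko_effects: dict[str, dict[str, float]]  # strain -> protein -> log2 FC (-inf = ablated)
    strain_targets: dict[str, str]
    strain_zygosity: dict[str, str]
    plate_bias: pd.DataFrame  # plate x protein multiplicative bias
    contamination: pd.Series  # per study sample contamination level c_s
    loadings: pd.Series  # per contaminated protein additive loading (fmol/uL)
    cv: float
    phenotype_links: dict[str, str]  # test name -> driving protein ("" if none)


@dataclass
class SimulatedDataset:
    transitions: pd.DataFrame
    annotations: list[SampleAnnotation]
    assays: list[AssayDefinition]
    panels: list[PanelDefinition]
    phenotypes: pd.DataFrame
    truth: SimulationTruth


def _protein_ids(n: int) -> list[str]:
    special = [*ERYTHROCYTE_PANEL, EXTENSION_CANDIDATE, *PLATELET_PANEL]
    if n < len(special) + 1:
        raise ConfigError(f"n_proteins must be >= {len(special) + 1}")
    generic = [f"P{i:03d}" for i in range(1, n - len(special) + 1)]
    return generic + special


def simulate_dataset(
    design: SimulationDesign | None = None,
    truth_config: TruthConfig | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Generate a full transition-level dataset plus its ground truth."""
    design = design or SimulationDesign()
    tc = truth_config or TruthConfig()
    rng = np.random.default_rng(seed)

    proteins = _protein_ids(design.n_proteins)
    n_prot = len(proteins)
    n_special = len(ERYTHROCYTE_PANEL) + 1 + len(PLATELET_PANEL)
    generic = proteins[: n_prot - n_special]
    contam_proteins = [*ERYTHROCYTE_PANEL, EXTENSION_CANDIDATE]

    # --- per-protein truth ------------------------------------------------
    lo, hi = np.log10(tc.baseline_range[0]), np.log10(tc.baseline_range[1])
    baselines = pd.Series(
        10.0 ** rng.uniform(lo, hi, n_prot), index=proteins, name="baseline"
    )
    depth = rng.uniform(*tc.lloq_depth_range, n_prot)
    lloqs = pd.Series(baselines.to_numpy() / 10.0**depth, index=proteins, name="lloq")

    strains = [f"KO{i:02d}" for i in range(1, design.n_strains + 1)]
    if design.n_strains > len(generic):
        raise ConfigError("more knockout strains than available target proteins")
    strain_targets = dict(zip(strains, generic[: design.n_strains]))
    strain_zygosity = {
        s: ("HOM" if i % 2 == 0 else "HET") for i, s in enumerate(strains)
    }

    eligible = [p for p in generic if p not in set(strain_targets.values())]
    if tc.n_sex_effects > len(eligible):
        raise ConfigError("more sex-dimorphic proteins requested than available")
    sex_affected = list(rng.choice(eligible, size=tc.n_sex_effects, replace=False))
    sex_log2fc = pd.Series(0.0, index=proteins)
    mags = rng.uniform(*tc.sex_effect_range, tc.n_sex_effects)
    signs = rng.choice([-1.0, 1.0], tc.n_sex_effects)
    sex_log2fc[sex_affected] = mags * signs

    secondary_pool = [p for p in eligible if p not in set(sex_affected)]
    if tc.n_secondary_ko_effects > len(secondary_pool):
        raise ConfigError("more secondary knockout effects requested than available")
    ko_effects: dict[str, dict[str, float]] = {}
    for s in strains:
        eff: dict[str, float] = {
            strain_targets[s]: (
                -np.inf if strain_zygosity[s] == "HOM" else tc.het_target_log2fc
            )
        }
        picks = rng.choice(secondary_pool, size=tc.n_secondary_ko_effects, replace=False)
        mags = rng.uniform(*tc.ko_effect_range, tc.n_secondary_ko_effects)
        signs = rng.choice([-1.0, 1.0], tc.n_secondary_ko_effects)
        for p, m, sg in zip(picks, mags, signs):
            eff[str(p)] = float(m * sg)
        ko_effects[s] = eff

    plates = [f"plate{i}" for i in range(1, design.n_plates + 1)]
    if tc.plate_bias_sd > 0:
        bias = np.exp(rng.normal(0.0, tc.plate_bias_sd, (design.n_plates, n_prot)))
        bias /= np.median(bias, axis=0, keepdims=True)  # exact median-1 anchor
    else:
        bias = np.ones((design.n_plates, n_prot))
    plate_bias = pd.DataFrame(bias, index=plates, columns=proteins)

    # --- samples ----------------------------------------------------------
    records: list[tuple[str, str, str, str]] = []  # sample, strain, zygosity, sex
    i = 0
    for s in strains:
        for sex in ("F", "M"):
            for _ in range(design.mice_per_strain_per_sex):
                i += 1
                records.append((f"S{i:03d}", s, strain_zygosity[s], sex))
    for sex in ("F", "M"):
        for _ in range(design.n_controls_per_sex):
            i += 1
            records.append((f"S{i:03d}", "WT", "WT", sex))
    sample_ids = [r[0] for r in records]
    n_study = len(sample_ids)
    perm = rng.permutation(n_study)
    plate_of = np.empty(n_study, dtype=object)
    for k, chunk in enumerate(np.array_split(perm, design.n_plates)):
        plate_of[chunk] = plates[k]
    annotations = [
        SampleAnnotation(sid, strain, zyg, sex, plate)
        for (sid, strain, zyg, sex), plate in zip(records, plate_of)
    ]

    active = rng.random(n_study) < tc.contamination_fraction
    c_s = np.where(active, rng.lognormal(0.0, 0.5, n_study), 0.0)
    contamination = pd.Series(c_s, index=sample_ids, name="contamination")
    loadings = pd.Series(
        tc.contamination_scale
        * baselines[contam_proteins].to_numpy()
        * rng.uniform(0.8, 1.2, len(contam_proteins)),
        index=contam_proteins,
        name="loading",
    )

    assays = [
        AssayDefinition(protein_id=p, peptide_id=f"pep_{p}", lloq=float(lloqs[p]))
        for p in proteins
    ]
    heavy_spike = 100.0 * lloqs.to_numpy()
    sigma = float(np.sqrt(np.log1p(tc.cv**2)))

    def noise(shape: tuple[int, ...]) -> np.ndarray:
        if sigma == 0:
            return np.ones(shape)
        return rng.lognormal(-0.5 * sigma**2, sigma, shape)

    def heavy(shape: tuple[int, ...]) -> np.ndarray:
        s = float(np.sqrt(np.log1p(tc.heavy_area_cv**2)))
        mu = np.log(tc.heavy_area_mean) - 0.5 * s**2
        return rng.lognormal(mu, s, shape)

    # --- study block ------------------------------------------------------
    base = np.tile(baselines.to_numpy(), (n_study, 1))
    male = np.array([r[3] == "M" for r in records], dtype=float)[:, None]
    base = base * 2.0 ** (sex_log2fc.to_numpy()[None, :] * male)
    pidx = {p: j for j, p in enumerate(proteins)}
    for si, (sid, strain, _, _) in enumerate(records):
        if strain == "WT":
            continue
        for p, d in ko_effects[strain].items():
            base[si, pidx[p]] = 0.0 if np.isinf(d) else base[si, pidx[p]] * 2.0**d
    if tc.biological_cv > 0:
        s_bio = float(np.sqrt(np.log1p(tc.biological_cv**2)))
        base = base * rng.lognormal(-0.5 * s_bio**2, s_bio, base.shape)
    bias_rows = plate_bias.loc[list(plate_of)].to_numpy()
    t_study = base * bias_rows
    contam_cols = np.array([pidx[p] for p in contam_proteins])
    t_study[:, contam_cols] += c_s[:, None] * loadings.to_numpy()[None, :]
    t_study = np.maximum(t_study, tc.blank_level * lloqs.to_numpy()[None, :])

    blocks: list[pd.DataFrame] = []

    def block(sample_ids_, plate_ids_, role, t_or_nominal, nominal=None):
        """Emit one long-format block; t_or_nominal is true conc (fmol/uL)."""
        n_s = len(sample_ids_)
        ratio = (t_or_nominal / heavy_spike[None, :]) * noise((n_s, n_prot))
        h = heavy((n_s, n_prot))
        df = pd.DataFrame(
            {
                "sample_id": np.repeat(sample_ids_, n_prot),
                "protein_id": np.tile(proteins, n_s),
                "peptide_id": np.tile([f"pep_{p}" for p in proteins], n_s),
                "light_area": (ratio * h).ravel(),
                "heavy_area": h.ravel(),
                "plate_id": np.repeat(plate_ids_, n_prot),
                "role": role,
                "nominal_conc": np.nan
                if nominal is None
                else np.asarray(nominal).ravel(),
            }
        )
        blocks.append(df)

    block(sample_ids, list(plate_of), "study", t_study)

    # --- pooled references ------------------------------------------------
    for plate in plates:
        ids = [
            f"POOL_{plate}_{j}" for j in range(1, design.pooled_refs_per_plate + 1)
        ]
        t = np.tile(
            baselines.to_numpy() * plate_bias.loc[plate].to_numpy(), (len(ids), 1)
        )
        block(ids, [plate] * len(ids), "pooled_reference", t)

    # --- calibration standards (plate 1 only) ------------------------------
    cal_levels = np.asarray(design.calibration_levels, dtype=float)
    cal_ids = [f"CAL_L{int(l)}" for l in cal_levels]
    nominal = cal_levels[:, None] * lloqs.to_numpy()[None, :]
    block(cal_ids, [plates[0]] * len(cal_ids), "calibration_standard", nominal, nominal)

    # --- curve QC standards (every plate) ----------------------------------
    qc_levels = np.asarray(design.qc_levels, dtype=float)
    for plate in plates:
        ids = [f"QC_{plate}_L{int(l)}" for l in qc_levels]
        nominal = qc_levels[:, None] * lloqs.to_numpy()[None, :]
        block(ids, [plate] * len(ids), "curve_qc", nominal, nominal)

    transitions = pd.concat(blocks, ignore_index=True)[TRANSITION_COLUMNS]

    panels = [
        PanelDefinition(
            "erythrocyte", frozenset(ERYTHROCYTE_PANEL), "erythrocyte"
        ),
        PanelDefinition("platelet", frozenset(PLATELET_PANEL), "platelet"),
    ]

    # --- phenotype table with planted correlations --------------------------
    pheno_links: dict[str, str] = {}
    pheno = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    # link phenotype tests to effect-free proteins so the association is
    # carried by between-mouse variation, not by a shared group effect
    used = set(strain_targets.values()) | set(map(str, sex_affected))
    for eff in ko_effects.values():
        used |= set(eff)
    link_pool = [p for p in generic if p not in used] or list(generic)
    for j in range(tc.n_planted_phenotypes):
        p = str(link_pool[j % len(link_pool)])
        name = f"test_linked_{j + 1}"
        pheno[name] = 2.0 * np.log10(t_study[:, pidx[p]]) + rng.normal(
            0.0, 0.1, n_study
        )
        pheno_links[name] = p
    pheno["test_sex_only"] = male.ravel() * 2.0 + rng.normal(0.0, 0.3, n_study)
    pheno_links["test_sex_only"] = ""
    pheno["test_noise"] = rng.normal(0.0, 1.0, n_study)
    pheno_links["test_noise"] = ""

    truth = SimulationTruth(
        baselines=baselines,
        lloqs=lloqs,
        sex_log2fc=sex_log2fc,
        ko_effects=ko_effects,
        strain_targets=strain_targets,
        strain_zygosity=strain_zygosity,
        plate_bias=plate_bias,
        contamination=contamination,
        loadings=loadings,
        cv=tc.cv,
        phenotype_links=pheno_links,
    )
    return SimulatedDataset(
        transitions=transitions,
        annotations=annotations,
        assays=assays,
        panels=panels,
        phenotypes=pheno,
        truth=truth,
    )


def truth_report(truth: SimulationTruth) -> pd.DataFrame:
    """Tabulate all non-null planted effects: (protein, contrast, true log2 effect).

    Ablations are reported with the sentinel string ``"ablated"``; proteins
    with no planted effect do not appear.
    """
    rows = []
    for p, d in truth.sex_log2fc.items():
        if d != 0.0:
            rows.append({"protein_id": p, "contrast": "sex", "true_log2_effect": d})
    for strain, effects in truth.ko_effects.items():
        for p, d in effects.items():
            rows.append(
                {
                    "protein_id": p,
                    "contrast": f"strain:{strain}",
                    "true_log2_effect": "ablated" if np.isinf(d) else d,
                }
            )
    return pd.DataFrame(rows, columns=["protein_id", "contrast", "true_log2_effect"])
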