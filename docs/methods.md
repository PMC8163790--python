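# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic data can and cannot establish.

## Quantification model

Each assay quantifies one protein through one surrogate peptide (multiple
peptides per protein are rejected at read time; the pipeline's contract
starts at integrated peak areas, after any upstream peak-integration
review). The measurement is the light/heavy peak-area ratio, with the
heavy internal standard spiked at 100× the assay LLOQ.

The calibration curve is linear in ratio vs spiked concentration, fitted
by weighted least squares with weights 1/x^e, e = 2 by default. 1/x²
weighting is the standard bioanalytical choice for curves spanning several
decades: it makes relative (not absolute) residuals comparable across the
1–1000× LLOQ range. The fit is the closed-form solution of the weighted
normal equations; a weighted R² is reported. A non-positive slope marks
the curve rejected rather than raising, so a batch run can report which
assays failed. Calibration standards sit on the first plate only;
the curves are applied to all plates and plate drift is handled by
normalization, mirroring how multi-plate MRM batches are usually run.

Back-calculation inverts the line. Conventions, fixed and documented:

- negative back-calculations clamp to 0 (concentrations are physical);
  the `below_lloq` flag preserves the information;
- range boundaries are inclusive: a value exactly at the LLOQ or ULOQ is
  `in_range`;
- censored values are *retained* with their flags, never imputed or
  dropped; the downstream rank tests tolerate them, and the censoring
  fraction is what the filter cascade consumes.

The coefficient of variation is 100·sd/mean with the n−1 denominator,
computed over in-range pooled-reference values only.

## Plate normalization

For each (plate, protein), study values are multiplied by
(grand median of pooled-reference values across all plates) / (median
within the plate). Medians, not means: pooled values occasionally censor,
and the median is robust to one or two stragglers. Below-LLOQ pooled
values are excluded from the medians. When more than half of a plate's
pooled values for a protein fall below the LLOQ, the plate median is
untrustworthy and the factor is forced to 1 (the exception is recorded in
the report). The grand median is an arbitrary but global anchor; any
global constant cancels in all downstream two-group contrasts. Censor
flags are recomputed after scaling. Normalization is idempotent: applied
to its own output (study and pooled matrices both rescaled), all factors
are 1 to machine precision.

## Filtering cascade

Three nested stages per protein: *detectable* = at least one in-range
measurement anywhere; *quantifiable* = at least 5% of all measurements in
range; *final* = at least one strain × sex group in which **every**
member is in range. "Detectable" has no universal definition; the ≥ 1
in-range reading is the weakest defensible one and the per-protein
disposition table makes the choice auditable. The counts are monotone by
construction and the report enforces that invariant.

## Contamination screening

Erythrocyte carry-over is modeled (and detected) as a sample-level scalar
multiplied by per-protein loadings, which makes the affected assays
strongly correlated across samples. Detection thresholds an absolute
Pearson correlation at 0.8 and takes **connected components** of the
resulting graph, not cliques — the weakest defensible reading of a
thresholded correlation matrix; users who want tighter clusters can raise
the threshold. Panel extension proposes non-panel proteins whose *median*
|r| to the panel reaches the threshold (median, so a single spurious pair
cannot promote a protein).

A significantly differential panel protein is called
`contaminant_origin` when at least 50% of the other measured panel
members shift with the same sign and |log2 FC| ≥ 0.5 in the same
contrast, `biological` otherwise, and `indeterminate` with fewer than 3
other members measured. Both knobs are config-exposed; the qualitative
rule ("do the other panel members trend the same way?") is standard
practice and the quantitative operationalisation is ours. Platelet
proteins are clustered and reported but never auto-flagged: platelet-rich
plasma legitimately contains them.

## Differential testing

The primary test is the two-sided Mann–Whitney–Wilcoxon. For
n_a + n_b ≤ 12 the p-value is exact: the U distribution is enumerated
over all C(n_a+n_b, n_a) labelings of the observed midranks, and the
two-sided p is the probability of a U at least as far from n_a·n_b/2 as
observed. This handles ties exactly, which off-the-shelf exact
implementations do not. Larger groups use the normal approximation with
midranks, tie correction and a 0.5 continuity correction.

Benjamini–Hochberg runs within one contrast (not pooled across strains,
since each strain comparison stands alone). Fold change is the ratio of
group means; a zero mean on one side — or a group entirely below LLOQ
against a fully quantified other group — yields the *ablated* sentinel
and is significant by absence, which is how a complete knockout of a
measured protein manifests.

Knockout contrasts default to the strain's 6 mice (both sexes) versus all
38 controls at BH-adjusted p < 0.05 and twofold change. With 3 vs 3 the
smallest exact two-sided rank p is 2/20 = 0.1, so per-sex knockout
contrasts cannot reach p < 0.05 by rank test and are optional. The sex
contrast uses raw p < 0.01 with twofold change by default (BH values are
reported alongside); both thresholds are configurable.

LASSO discriminator selection: features are log10-transformed (with a
positivity floor one decade below the smallest positive value),
mean-imputed, standardised *within each cross-validation fold* (scaling
on the full data would leak the held-out sample, which at these group
sizes inflates apparent generalisation badly), and fitted by L1-penalised
logistic regression over a descending 20-point penalty grid. The penalty
is chosen by leave-one-out deviance with the one-standard-error rule
(glmnet's `lambda.1se`): at n ≈ 6–44 the deviance minimum alone is noisy
and systematically favours overfitting, while the 1-SE rule keeps the
selected set minimal; an empty selection is a legitimate outcome. The
classifier C-statistic uses effectively unpenalised (ridge-stabilised,
penalty 1e−6) logistic regression over stratified k folds (default 5),
scaling fit on each training fold, and reports the mean held-out ROC AUC.

PCA operates on log10-transformed, mean-imputed, standardised
concentrations; constant proteins are dropped with a warning before
scaling.

## Over-representation analysis

One-sided hypergeometric enrichment only (no depletion, no ranked GSEA).
Sets are intersected with the background — the quantified protein
universe — before testing; sets with fewer than 3 background members are
skipped; BH runs across the sets tested within one collection. Identifier
mapping (e.g. mouse → human ortholog for disease resources) is an
explicit two-column input applied before testing; the package embeds no
knowledgebase.

## Phenotype correlation

Spearman is the default headline method (robust to the monotone
nonlinearities typical of clinical assays); Pearson is available in the
same record. Sex adjustment removes the per-sex mean from both variables
— exactly equivalent to regressing each on a sex indicator and
correlating residuals, and to the partial correlation given a binary
covariate — and per-sex stratified correlations are reported alongside.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design: 30 strains × 2 sexes × 3 mice
+ 19 + 19 controls = 218 study samples randomized over 3 plates, 11
pooled references per plate (33 total), an 8-point calibration curve at
(1, 2, 5, 10, 50, 100, 500, 1000)× LLOQ on plate 1, and QC standards at
(3, 30, 300)× LLOQ on every plate.

Generative model, per protein p and sample s:

- baseline µ_p log-uniform over [0.3, 6×10⁴] fmol/µL (five orders of
  magnitude);
- LLOQ set 10–300× below baseline (log-uniform depth), heavy spike =
  100× LLOQ, ULOQ = 1000× LLOQ;
- true concentration T = µ_p · 2^(δ_sex·[male]) · 2^(δ_ko) · bio ·
  b_plate + λ_p·c_s for erythrocyte-panel proteins, floored at the blank
  level 0.1× LLOQ;
- 20 sex-dimorphic proteins with |log2 FC| in [1, 2]; each strain ablates
  its own target protein (homozygotes; δ = −∞ → blank signal) or halves
  it (heterozygotes), plus 3 secondary effects with |log2 FC| in [1, 2];
- plate biases log-normal (σ = 0.04), median-centred across plates per
  protein so that median-anchored normalization is exactly invertible —
  a deliberate generator choice that makes the noise-free recovery test
  sharp rather than approximate;
- contamination: 25% of samples carry a log-normal level c_s shared
  across the 12 erythrocyte markers plus one extension candidate
  (ISG15), with loadings ≈ 2× baseline; platelet markers carry no
  contamination component;
- noise: multiplicative log-normal with σ = √ln(1+κ²), κ = 0.09
  (measurement, all roles) and 0.15 (between-mouse biological, study
  samples only); heavy areas log-normal around 10⁵ counts with 30% CV;
  the observed ratio is (T / heavy_spike)·ε and light = ratio · heavy.

Everything derives from one seeded generator, so identical inputs give
bit-identical output.

Not emulated: chromatographic peak shapes, interference and
transition-level artifacts, assay-specific calibration nonlinearity,
missing-at-random dropout, correlated biological variation between
proteins (each mouse's biological deviations are independent per
protein), and real inter-protein covariance structure. Passing
recovery tests therefore demonstrates that the *pipeline logic* is
correct under the study's design and noise magnitudes — not that the
thresholds are optimal for any particular real dataset.

## Problem sizes in tests

The test suite exercises the full 218 × 226 study shape for the
end-to-end, recovery and contamination checks (10 seeds each for the
recovery criteria) and a 36-sample × 40-protein design for unit-level
fixtures. The acceptance script uses the full shape with a 3-seed median
for the stochastic recovery quantities. Oracle comparisons run the
complete N ≤ 30 hypergeometric grid, all Mann–Whitney group sizes with
n_a + n_b ≤ 10, and 1000 random calibration designs.

## Known limitations

- The below-LLOQ exception keys on the plate's pooled references only; a
  plate whose *study* samples censor heavily but whose pool does not is
  still rescaled.
- Connected-component clustering can chain unrelated proteins through a
  single bridge at the threshold; the cluster report includes mean |r|
  so such chains are visible.
- The exact Mann–Whitney path is O(C(n_a+n_b, n_a)) and capped at
  n_a + n_b = 12 by default.
- `correlate_all` computes one pair at a time; for very large phenotype
  batteries a vectorised path would be preferable.
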