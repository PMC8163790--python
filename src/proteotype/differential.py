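"""Two-group differential abundance and signature analysis.

Contrasts (female vs male, or one knockout strain vs all wild-type
controls) are tested per protein with the two-sided Mann-Whitney-Wilcoxon
rank test — exact by full labeling enumeration for small groups, normal
approximation with midranks, tie and continuity correction otherwise —
followed by Benjamini-Hochberg adjustment within the contrast and fold
change of group means.  Knockout-ablated proteins (quantified in controls,
blank in the knockout) are reported with an ablation sentinel and count as
significant by absence.  Signature tools: L1-penalised logistic regression
(LASSO) for minimal discriminator sets, PCA projection, and a stratified
cross-validated logistic-regression C-statistic.

Knockout contrasts default to the strain's 6 mice versus all 38 controls:
with only 3 vs 3 littermates the smallest exact two-sided rank-test p is
0.1, so no protein could pass p < 0.05 in a per-sex contrast.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .config import PipelineConfig
from .io import ConcentrationMatrix, ValidationError

logger = logging.getLogger(__name__)

#: group sizes up to this total use exact enumeration of all labelings
EXACT_LIMIT = 12
ABLATED = "ablated"


@dataclass(frozen=True)
class Contrast:
    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    p_threshold: float = 0.05
    fold_threshold: float = 2.0
    use_adjusted_p: bool = True

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValidationError("contrast groups must be disjoint")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValidationError("each contrast group needs >= 2 samples")


@dataclass(frozen=True)
class ClassifierReport:
    contrast: str
    features: tuple[str, ...]
    fold_c_statistics: tuple[float, ...]
    mean_c_statistic: float


def _u_statistic(pooled_ranks: np.ndarray, a_idx: np.ndarray, n_a: int) -> float:
    return pooled_ranks[a_idx].sum() - n_a * (n_a + 1) / 2.0


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test; returns (U of group a, p).

    Exact when n_a + n_b <= 12: the U null distribution is built from all
    C(n_a + n_b, n_a) group labelings of the observed (midranked) values,
    and p is the probability of a U at least as far from the null mean
    n_a*n_b/2 as observed.  Larger samples use the normal approximation
    with midranks, tie correction and a 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    u_obs = _u_statistic(ranks, np.arange(n_a), n_a)
    if np.all(pooled == pooled[0]):
        return u_obs, 1.0
    center = n_a * n_b / 2.0
    if n_a + n_b <= EXACT_LIMIT:
        dev = abs(u_obs - center)
        hits = total = 0
        for idx in combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks, np.array(idx), n_a)
            total += 1
            if abs(u - center) >= dev - 1e-9:
                hits += 1
        return u_obs, hits / total
    # normal approximation with tie correction
    n = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - center) - 0.5) / math.sqrt(var)
    return u_obs, float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjustment; adjusted values returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


@dataclass(frozen=True)
class FoldChange:
    fc: float
    log_fc: float
    status: str  # ok | ablated | undefined

    @property
    def is_ablated(self) -> bool:
        return self.status == ABLATED


def fold_change(
    a: Sequence[float], b: Sequence[float], log_base: float = 2.0
) -> FoldChange:
    """Fold change of means, b relative to a, with ablation sentinel.

    A zero mean on exactly one side marks ablation (the protein is present
    in one group and absent in the other); zero on both sides is undefined.
    """
    mean_a = float(np.mean(np.asarray(a, dtype=float)))
    mean_b = float(np.mean(np.asarray(b, dtype=float)))
    if mean_a == 0 and mean_b == 0:
        return FoldChange(math.nan, math.nan, "undefined")
    if mean_a == 0:
        return FoldChange(math.inf, math.inf, ABLATED)
    if mean_b == 0:
        return FoldChange(0.0, -math.inf, ABLATED)
    fc = mean_b / mean_a
    return FoldChange(fc, math.log(fc, log_base), "ok")


def sex_contrast(
    annotations: pd.DataFrame, config: PipelineConfig | None = None
) -> Contrast:
    """Female (a) vs male (b) across all study samples."""
    config = config or PipelineConfig()
    return Contrast(
        name="sex",
        group_a=tuple(annotations.index[annotations["sex"] == "F"]),
        group_b=tuple(annotations.index[annotations["sex"] == "M"]),
        p_threshold=config.sex_p_threshold,
        fold_threshold=config.sex_fold_threshold,
        use_adjusted_p=config.sex_use_adjusted_p,
    )


def strain_contrast(
    annotations: pd.DataFrame, strain: str, config: PipelineConfig | None = None
) -> Contrast:
    """Wild-type controls (a) vs one knockout strain, both sexes (b)."""
    config = config or PipelineConfig()
    ko = annotations.index[annotations["strain"] == strain]
    wt = annotations.index[annotations["strain"] == "WT"]
    if len(ko) == 0:
        raise ValidationError(f"strain {strain!r} not found in annotations")
    return Contrast(
        name=f"strain:{strain}",
        group_a=tuple(wt),
        group_b=tuple(ko),
        p_threshold=config.ko_p_threshold,
        fold_threshold=config.ko_fold_threshold,
        use_adjusted_p=config.ko_use_adjusted_p,
    )


def run_contrast(
    matrix: ConcentrationMatrix,
    contrast: Contrast,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-protein MWW test, BH adjustment and fold change for one contrast.

    A protein is significant when its selected p (raw or BH-adjusted, per
    the contrast) is below threshold and |log2 FC| reaches the fold
    threshold — or when it carries the ablation sentinel: all of one
    group censored below LLOQ while the other group is fully quantified,
    or a group mean of exactly zero.  Proteins missing in more than half
    of either group are excluded (logged).
    """
    config = config or PipelineConfig()
    idx_a = [s for s in contrast.group_a if s in matrix.values.index]
    idx_b = [s for s in contrast.group_b if s in matrix.values.index]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValidationError(f"contrast {contrast.name!r} groups unresolvable")
    log2_fold_min = math.log2(contrast.fold_threshold)
    rows = []
    for pid in matrix.proteins:
        va = matrix.values.loc[idx_a, pid].dropna()
        vb = matrix.values.loc[idx_b, pid].dropna()
        if len(va) < len(idx_a) / 2.0 or len(vb) < len(idx_b) / 2.0:
            logger.info(
                "protein %s excluded from %s: missing in > half of a group",
                pid,
                contrast.name,
            )
            continue
        fa = matrix.flags.loc[idx_a, pid]
        fb = matrix.flags.loc[idx_b, pid]
        u, p = mann_whitney(va, vb)
        fc = fold_change(va, vb, config.log_base)
        absent_b = (fb == "below_lloq").all() and (fa == "in_range").all()
        absent_a = (fa == "below_lloq").all() and (fb == "in_range").all()
        ablated = fc.is_ablated or absent_a or absent_b
        log2_fc = fc.log_fc
        if ablated and math.isfinite(log2_fc):
            log2_fc = -math.inf if absent_b else math.inf
        rows.append(
            {
                "protein_id": pid,
                "u_statistic": u,
                "p_raw": p,
                "mean_a": float(va.mean()),
                "mean_b": float(vb.mean()),
                "fold_change": fc.fc,
                "log2_fc": log2_fc,
                "ablated": ablated,
            }
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return pd.DataFrame(
            columns=[
                "protein_id", "u_statistic", "p_raw", "p_adjusted", "mean_a",
                "mean_b", "fold_change", "log2_fc", "ablated", "significant",
            ]
        )
    res["p_adjusted"] = (
        benjamini_hochberg(res["p_raw"].to_numpy())
        if config.bh_adjust
        else res["p_raw"]
    )
    p_sel = res["p_adjusted"] if contrast.use_adjusted_p else res["p_raw"]
    effect = res["log2_fc"].abs() >= log2_fold_min
    res["significant"] = ((p_sel < contrast.p_threshold) & effect) | res["ablated"]
    return res[
        [
            "protein_id", "u_statistic", "p_raw", "p_adjusted", "mean_a",
            "mean_b", "fold_change", "log2_fc", "ablated", "significant",
        ]
    ]


def optional_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sided t test, reported alongside MWW as a comparator.

    Identical groups give (0, 1); zero pooled variance with unequal means
    is degenerate and returns p = 0 (guarded, not raised).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _log10_impute(values: pd.DataFrame) -> pd.DataFrame:
    """log10-transform with a positivity floor, then mean-impute missing."""
    pos = values.to_numpy()
    floor = np.nanmin(np.where(pos > 0, pos, np.nan))
    floor = floor / 10.0 if np.isfinite(floor) else 1e-12
    x = np.log10(np.maximum(np.nan_to_num(pos, nan=np.nan), floor))
    x = pd.DataFrame(x, index=values.index, columns=values.columns)
    return x.fillna(x.mean())


def lasso_select(
    values: pd.DataFrame,
    labels: Sequence[int] | Sequence[bool],
    seed: int = 0,
    n_penalties: int = 20,
) -> list[str]:
    """Minimal discriminator set via L1-penalised logistic regression.

    Features are log10-transformed then standardised; the penalty is chosen
    by leave-one-out cross-validated deviance over a descending penalty
    grid, taking the strongest penalty within one standard error of the
    deviance minimum (the glmnet ``lambda.1se`` convention, which keeps
    the set minimal).  Selected proteins are those with nonzero
    coefficients; an empty selection is a valid outcome.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("labels must contain both classes")
    if len(y) < 4:
        raise ValidationError("need >= 4 samples for selection")
    x_raw = _log10_impute(values).to_numpy()
    cs = np.logspace(1.5, -2, n_penalties)  # descending C = increasing penalty
    eps = 1e-12
    contrib = np.full((len(cs), len(y)), np.inf)
    folds = [
        (train, test)
        for train, test in LeaveOneOut().split(x_raw)
        if len(np.unique(y[train])) == 2
    ]
    # standardise inside each fold: the held-out sample must not leak
    # through the feature means/scales
    scaled = []
    for train, test in folds:
        scaler = StandardScaler().fit(x_raw[train])
        scaled.append(
            (
                np.nan_to_num(scaler.transform(x_raw[train])),
                np.nan_to_num(scaler.transform(x_raw[test])),
            )
        )
    for ci, c in enumerate(cs):
        for (train, test), (xt, xv) in zip(folds, scaled):
            clf = LogisticRegression(
                l1_ratio=1.0, C=c, solver="liblinear", random_state=seed
            )
            clf.fit(xt, y[train])
            prob = clf.predict_proba(xv)[0, 1]
            prob = min(max(prob, eps), 1 - eps)
            i = test[0]
            contrib[ci, i] = -2.0 * (
                y[i] * math.log(prob) + (1 - y[i]) * math.log(1 - prob)
            )
    totals = contrib.sum(axis=1)
    best = int(np.argmin(totals))
    # one-standard-error rule: take the strongest penalty whose deviance is
    # within one SE of the minimum, which keeps the selection minimal
    se = float(contrib[best].std(ddof=1)) * math.sqrt(len(y))
    chosen = best
    for ci in range(len(cs) - 1, best, -1):
        if totals[ci] <= totals[best] + se:
            chosen = ci
            break
    clf = LogisticRegression(
        l1_ratio=1.0, C=cs[chosen], solver="liblinear", random_state=seed
    )
    clf.fit(np.nan_to_num(StandardScaler().fit_transform(x_raw)), y)
    coef = clf.coef_.ravel()
    return [p for p, c in zip(values.columns, coef) if c != 0.0]


def pca_project(
    values: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA scores on log10-transformed, standardised concentrations.

    Missing cells are mean-imputed after the transform; constant proteins
    are dropped with a warning before scaling.  Returns (scores, fraction
    of variance per component).
    """
    if values.shape[0] < 3 or values.shape[1] < 2:
        raise ValidationError("PCA needs >= 3 samples and >= 2 proteins")
    x = _log10_impute(values)
    constant = x.columns[x.std(ddof=0) == 0]
    if len(constant):
        logger.warning("dropping %d constant protein(s) before PCA", len(constant))
        x = x.drop(columns=list(constant))
    if x.shape[1] < 2:
        raise ValidationError("fewer than 2 non-constant proteins for PCA")
    z = StandardScaler().fit_transform(x)
    n_components = min(n_components, min(z.shape) - 0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=values.index, columns=cols),
        pca.explained_variance_ratio_,
    )


def cv_logistic_cstat(
    values: pd.DataFrame,
    labels: Sequence[int] | Sequence[bool],
    k: int = 5,
    seed: int = 0,
) -> ClassifierReport:
    """Mean held-out ROC AUC of a logistic model over stratified folds.

    The model is effectively unpenalised (ridge-stabilised, penalty 1e-6)
    logistic regression on standardised log10 features; the C-statistic is
    the area under the ROC curve of the held-out decision scores.
    """
    y = np.asarray(labels, dtype=int)
    if k > min(np.bincount(y)):
        raise ValidationError("k exceeds the smaller class size")
    x_all = _log10_impute(values)
    aucs = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train, test in skf.split(x_all, y):
        scaler = StandardScaler().fit(x_all.iloc[train])
        xt = np.nan_to_num(scaler.transform(x_all.iloc[train]))
        xv = np.nan_to_num(scaler.transform(x_all.iloc[test]))
        clf = LogisticRegression(C=1e6, max_iter=5000, random_state=seed)
        clf.fit(xt, y[train])
        score = clf.decision_function(xv)
        if len(np.unique(y[test])) < 2:
            continue  # fold without both classes carries no ROC information
        aucs.append(float(roc_auc_score(y[test], score)))
    if not aucs:
        raise ValidationError("no fold contained both classes")
    return ClassifierReport(
        contrast="",
        features=tuple(values.columns),
        fold_c_statistics=tuple(aucs),
        mean_c_statistic=float(np.mean(aucs)),
    )
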