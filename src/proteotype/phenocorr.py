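"""Correlation of protein concentrations with clinical phenotyping tests.

Sexual dimorphism confounds plasma protein / clinical-test associations,
so alongside the plain pairwise-complete correlation each record carries a
sex-adjusted residual correlation: both variables are mean-centred within
each sex (equivalent to regressing on a sex indicator) before correlating
the residuals.  Per-sex stratified correlations are reported as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConcentrationMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationRecord:
    protein_id: str
    test: str
    method: str
    r: float
    n: int
    sex_adjusted_r: float


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValidationError(f"unknown correlation method {method!r}")


def sex_adjusted_correlation(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    sex: np.ndarray | pd.Series,
    method: str = "spearman",
) -> tuple[float, dict[str, float]]:
    """Residual correlation after removing per-sex means from both variables.

    Returns (residual r, per-sex stratified correlations).  With one sex
    absent the unadjusted correlation is returned with a warning; if either
    variable is constant within every sex the residual correlation is
    undefined (NaN, warned).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sex = np.asarray(sex)
    levels = pd.unique(sex)
    stratified = {}
    for lv in levels:
        m = sex == lv
        stratified[str(lv)] = (
            _corr(x[m], y[m], method) if m.sum() >= 3 else float("nan")
        )
    if len(levels) < 2:
        logger.warning("only one sex present; returning unadjusted correlation")
        return _corr(x, y, method), stratified
    xr, yr = x.astype(float).copy(), y.astype(float).copy()
    for lv in levels:
        m = sex == lv
        xr[m] -= xr[m].mean()
        yr[m] -= yr[m].mean()
    if np.std(xr) == 0 or np.std(yr) == 0:
        logger.warning("variable constant within each sex; residual correlation undefined")
        return float("nan"), stratified
    return _corr(xr, yr, method), stratified


def correlate_all(
    matrix: ConcentrationMatrix,
    phenotypes: pd.DataFrame,
    sex: pd.Series | None = None,
    method: str = "spearman",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete correlation of every (protein, test) pair.

    Records with fewer than ``min_pairs`` complete pairs are skipped (with
    a count).  Results are sortable by |r|; when ``sex`` is given each
    record also carries the sex-adjusted residual correlation.
    """
    common = [s for s in matrix.samples if s in phenotypes.index]
    values = matrix.values.loc[common]
    pheno = phenotypes.loc[common]
    n_skipped = 0
    rows = []
    for test in pheno.columns:
        t = pheno[test]
        for pid in values.columns:
            v = values[pid]
            ok = v.notna() & t.notna()
            n = int(ok.sum())
            if n < min_pairs:
                n_skipped += 1
                continue
            r = _corr(v[ok].to_numpy(), t[ok].to_numpy(), method)
            if sex is not None:
                adj, _ = sex_adjusted_correlation(
                    v[ok].to_numpy(), t[ok].to_numpy(), sex.loc[ok.index[ok]].to_numpy(), method
                )
            else:
                adj = float("nan")
            rows.append(
                {
                    "protein_id": pid,
                    "test": test,
                    "method": method,
                    "r": r,
                    "n": n,
                    "sex_adjusted_r": adj,
                }
            )
    if n_skipped:
        logger.warning("%d (protein, test) pairs skipped: < %d complete pairs", n_skipped, min_pairs)
    out = pd.DataFrame(rows, columns=["protein_id", "test", "method", "r", "n", "sex_adjusted_r"])
    if not out.empty:
        out = out.reindex(out["r"].abs().sort_values(ascending=False).index).reset_index(
            drop=True
        )
    return out
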