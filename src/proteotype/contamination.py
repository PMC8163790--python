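"""Blood-cell contamination screening.

Variable carry-over of erythrocyte (and platelet) content during plasma
collection injects a shared, sample-level component into every marker
protein of the affected cell type, so contaminated assays form tight
correlation clusters across samples.  This module finds those clusters at
a |Pearson r| threshold (default 0.8), proposes panel extensions (proteins
co-correlating with the known panel), and classifies significantly
differential panel proteins as contamination-originated when the rest of
the panel co-trends.  Platelet proteins are clustered and reported but are
never auto-flagged: platelet-rich plasma legitimately contains them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import ConcentrationMatrix, ValidationError


@dataclass(frozen=True)
class CorrelationCluster:
    members: tuple[str, ...]
    panel_overlap: int
    mean_abs_r: float


@dataclass(frozen=True)
class ContaminationVerdict:
    protein_id: str
    contrast: str
    verdict: str  # contaminant_origin | biological | indeterminate
    co_trending_fraction: float
    n_other_members: int


def correlation_matrix(
    matrix: ConcentrationMatrix | pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Protein x protein correlation over pairwise-complete observations.

    Pairs with fewer than 3 complete observations are left missing; the
    diagonal is exactly 1.
    """
    values = matrix.values if isinstance(matrix, ConcentrationMatrix) else matrix
    corr = values.corr(method=method, min_periods=3)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def cluster_by_threshold(
    corr: pd.DataFrame,
    threshold: float = 0.8,
    panel: Iterable[str] | None = None,
) -> list[CorrelationCluster]:
    """Connected components of the |r| >= threshold graph (>= 2 members).

    Components, not cliques: a thresholded correlation matrix defines edges,
    and chained correlation is treated as shared origin.  Singletons are
    omitted.  ``panel`` (optional) fills in the overlap count per cluster.
    """
    panel = frozenset(panel or ())
    g = nx.Graph()
    g.add_nodes_from(corr.columns)
    a = corr.abs().to_numpy()
    cols = list(corr.columns)
    iu, ju = np.triu_indices(len(cols), k=1)
    mask = np.nan_to_num(a[iu, ju]) >= threshold
    g.add_edges_from((cols[i], cols[j]) for i, j in zip(iu[mask], ju[mask]))
    clusters = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        members = tuple(sorted(comp))
        sub = corr.loc[list(members), list(members)].abs().to_numpy()
        off = sub[np.triu_indices(len(members), k=1)]
        clusters.append(
            CorrelationCluster(
                members=members,
                panel_overlap=len(panel & set(members)),
                mean_abs_r=float(np.nanmean(off)),
            )
        )
    clusters.sort(key=lambda c: (-len(c.members), c.members))
    return clusters


def propose_panel_extension(
    corr: pd.DataFrame,
    panel: Iterable[str],
    threshold: float = 0.8,
) -> pd.Series:
    """Non-panel proteins whose median |r| to the panel reaches the threshold.

    Returns a Series (protein -> median |r|) sorted descending; the panel's
    own members are never proposed.
    """
    panel = [p for p in panel if p in corr.columns]
    if not panel:
        raise ValidationError("no panel member present in the correlation grid")
    others = [p for p in corr.columns if p not in set(panel)]
    med = corr.loc[others, panel].abs().median(axis=1)
    out = med[med >= threshold].sort_values(ascending=False)
    out.name = "median_abs_r_to_panel"
    return out


def flag_differential_contaminants(
    results: pd.DataFrame,
    panel: Iterable[str],
    panel_log2fc: pd.Series,
    contrast: str = "",
    co_trend_fraction: float = 0.5,
    min_abs_log2fc: float = 0.5,
) -> list[ContaminationVerdict]:
    """Classify significantly altered panel proteins in one contrast.

    ``results`` is a differential-result table (columns ``protein_id``,
    ``significant``, ``log2_fc``); ``panel_log2fc`` carries the log2 fold
    changes of every measured panel member in the same contrast.  A panel
    protein whose shift is echoed (same sign, |log2 FC| >= ``min_abs_log2fc``)
    by at least ``co_trend_fraction`` of the other measured members is
    ``contaminant_origin``; with fewer than 3 other members measured the
    verdict is ``indeterminate``; otherwise ``biological``.  Non-panel
    proteins are never flagged.
    """
    panel = frozenset(panel)
    verdicts = []
    sig = results[results["significant"].astype(bool)]
    for row in sig.itertuples(index=False):
        pid = row.protein_id
        if pid not in panel:
            continue
        fc = float(row.log2_fc)
        others = panel_log2fc.drop(labels=[pid], errors="ignore").dropna()
        others = others[np.isfinite(others)]
        if len(others) < 3:
            verdicts.append(
                ContaminationVerdict(pid, contrast, "indeterminate", np.nan, len(others))
            )
            continue
        co = ((np.sign(others) == np.sign(fc)) & (others.abs() >= min_abs_log2fc)).mean()
        verdict = "contaminant_origin" if co >= co_trend_fraction else "biological"
        verdicts.append(
            ContaminationVerdict(pid, contrast, verdict, float(co), len(others))
        )
    return verdicts
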