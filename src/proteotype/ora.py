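"""Over-representation analysis against gene-set collections.

One-sided hypergeometric enrichment of a protein list against each set in
a GMT collection, with the quantified protein panel as the background
universe.  Sets are intersected with the background before testing, and
BH adjustment runs across the sets tested within one collection.
Identifier mapping (e.g. mouse protein to human ortholog) is applied
through an explicit two-column table before testing; no live knowledgebase
queries are performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats

from .differential import benjamini_hochberg
from .io import GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OraResult:
    set_name: str
    background_size: int  # N
    annotated_in_background: int  # K
    list_size: int  # n
    overlap: int  # x
    p_raw: float
    p_adjusted: float
    overlapping_ids: tuple[str, ...]


def hypergeometric_tail(n_background: int, n_annotated: int, n_list: int, x: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    X counts annotated proteins in a size-``n_list`` draw without
    replacement from ``n_background`` proteins of which ``n_annotated``
    are annotated.  Evaluated in log space via the survival function for
    numerical stability.
    """
    if not (0 <= x <= n_list <= n_background and 0 <= n_annotated <= n_background):
        raise ValidationError(
            f"invalid hypergeometric arguments N={n_background}, K={n_annotated}, "
            f"n={n_list}, x={x}"
        )
    if x > n_annotated:
        raise ValidationError("overlap cannot exceed the annotated count")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, n_background, n_annotated, n_list))


def run_ora(
    protein_list: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    min_set_size: int = 3,
    id_map: Mapping[str, str] | None = None,
) -> list[OraResult]:
    """Test every collection set for over-representation of the list.

    The background is the quantified protein universe; list members not in
    the background are dropped with a warning count.  Sets whose overlap
    with the background is below ``min_set_size`` are skipped.  BH runs
    across the tested sets.
    """
    if id_map is not None:
        protein_list = [id_map[p] for p in protein_list if p in id_map]
        background = [id_map[p] for p in background if p in id_map]
    lst = set(protein_list)
    bg = set(background)
    if not lst:
        raise ValidationError("protein list is empty")
    dropped = lst - bg
    if dropped:
        logger.warning("%d list member(s) not in background; dropped", len(dropped))
    lst &= bg
    if not lst:
        raise ValidationError("protein list has no overlap with the background")
    n_bg, n_list = len(bg), len(lst)
    tested = []
    for s in collection.sets.values():
        members = s.members & bg
        if len(members) < min_set_size:
            continue
        overlap = tuple(sorted(lst & members))
        tested.append((s.name, len(members), overlap))
    p_raw = [
        hypergeometric_tail(n_bg, k, n_list, len(ov)) for _, k, ov in tested
    ]
    p_adj = benjamini_hochberg(p_raw) if tested else []
    return [
        OraResult(
            set_name=name,
            background_size=n_bg,
            annotated_in_background=k,
            list_size=n_list,
            overlap=len(ov),
            p_raw=float(pr),
            p_adjusted=float(pa),
            overlapping_ids=ov,
        )
        for (name, k, ov), pr, pa in zip(tested, p_raw, p_adj)
    ]
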