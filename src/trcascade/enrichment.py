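"""Per-stage GO over-representation analysis.

Each stage column is tested one set at a time against a flat annotation
map with a one-sided Fisher's exact test (over-representation), the
p-values are Bonferroni-corrected over the number of tested terms, and
significant terms are ranked by fold enrichment.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .dataset import ExpressionDataset, normalize_symbol
from .io import AnnotationMap

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_pvalue",
    "enrich_stage",
    "enrich_all_stages",
    "expressed_universe",
]

_COLUMNS = ["term", "label", "k", "n", "K", "N", "fold", "p", "p_adj"]


def fisher_pvalue(k: int, n: int, big_k: int, big_n: int) -> float:
    """One-sided Fisher's exact p for over-representation.

    Probability of drawing at least ``k`` annotated genes when ``n`` genes
    are sampled without replacement from a universe of ``big_n`` genes of
    which ``big_k`` carry the annotation — the hypergeometric upper tail
    P(X >= k).
    """
    if not (0 <= k <= min(n, big_k) and n <= big_n and big_k <= big_n):
        raise ValueError(
            f"inconsistent 2x2 table: k={k}, n={n}, K={big_k}, N={big_n}"
        )
    return float(min(1.0, hypergeom.sf(k - 1, big_n, big_k, n)))


def enrich_stage(
    stage_genes: Iterable[str],
    annotations: AnnotationMap,
    universe: Iterable[str],
    alpha: float = 0.05,
    full: bool = False,
) -> pd.DataFrame:
    """Fisher's exact over-representation of annotation terms in one stage.

    For a term annotated to ``K`` of the ``N`` universe genes and ``k``
    of the ``n`` stage genes, the one-sided p-value is the hypergeometric
    upper tail P(X >= k).  Only terms overlapping the stage set (k >= 1)
    are tested; the Bonferroni factor is the number of tested terms.
    Returns terms with adjusted p below ``alpha`` sorted by fold
    enrichment descending then p ascending (the full table with
    ``full=True``).

    Columns: term, label, k, n, K, N, fold = (k/n)/(K/N), p, p_adj.
    """
    universe = {normalize_symbol(g) for g in universe}
    if not universe:
        raise ValueError("empty annotation universe")
    stage_set = {normalize_symbol(g) for g in stage_genes}
    outside = stage_set - universe
    if outside:
        logger.warning(
            "%d stage gene(s) outside the universe dropped: %s",
            len(outside), sorted(outside)[:5],
        )
        stage_set &= universe
    n = len(stage_set)
    big_n = len(universe)

    rows = []
    for term in sorted(annotations.term_to_genes):
        term_genes = annotations.term_to_genes[term] & universe
        k = len(term_genes & stage_set)
        if k == 0:
            continue
        big_k = len(term_genes)
        p = fisher_pvalue(k, n, big_k, big_n)
        fold = (k / n) / (big_k / big_n)
        rows.append(
            {"term": term, "label": annotations.name(term), "k": k, "n": n,
             "K": big_k, "N": big_n, "fold": fold, "p": p}
        )
    table = pd.DataFrame(rows, columns=_COLUMNS[:-1])
    m = len(table)
    table["p_adj"] = (table["p"] * m).clip(upper=1.0) if m else []
    table = table.sort_values(
        ["fold", "p", "term"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if full:
        return table
    return table[table["p_adj"] < alpha].reset_index(drop=True)


def enrich_all_stages(
    assignment,
    annotations: AnnotationMap,
    universe: Iterable[str],
    alpha: float = 0.05,
    full: bool = False,
) -> pd.DataFrame:
    """Run :func:`enrich_stage` for every cascade column; adds a stage column."""
    universe = {normalize_symbol(g) for g in universe}
    parts = []
    for stage, col in assignment.stages:
        res = enrich_stage(
            [g for g, _ in col], annotations, universe, alpha=alpha, full=full
        )
        res.insert(0, "stage", stage)
        parts.append(res)
    if not parts:
        return pd.DataFrame(columns=["stage", *_COLUMNS])
    return pd.concat(parts, ignore_index=True)


def expressed_universe(
    ds: ExpressionDataset, annotations: AnnotationMap, min_e: float
) -> frozenset[str]:
    """Default enrichment universe: detectably expressed, annotated genes.

    Conditions on the same minE floor the cascade applies, so enrichment
    compares stage sets against genes that *could* have been picked.
    """
    expressed = {g for g, mx in ds.max_per_gene().items() if mx > min_e}
    return frozenset(expressed & annotations.annotated_genes())
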