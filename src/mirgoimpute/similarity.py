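"""Set-level similarity: terms -> genes -> miRNAs.

A gene is a set of GO terms; a miRNA is a set of target genes.  Each lifting
step scores the rectangular matrix of constituent similarities with one of
four strategies:

``max``    global maximum (1 as soon as one constituent matches perfectly)
``avg``    global mean (self-similarity < 1 for non-trivial sets)
``rcmax``  max of the two directional best-match averages
``bma``    best-match average — row maxima plus column maxima over k + s

The default two-step pipeline applies ``bma`` at both levels, producing the
miRNA functional-similarity matrix H.  A one-step ``pooled`` variant that
merges every target's terms into a single redundant set per miRNA is offered
as an alternative.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import filter_annotations, read_annotations, read_targets  # noqa: F401  (module surface)
from .ontology import OntologyGraph, TermSimilarityModel, term_similarity

logger = logging.getLogger(__name__)

STRATEGIES = ("max", "avg", "rcmax", "bma")


class _TermPairCache:
    """Memoises unordered term pairs across an H computation."""

    def __init__(self, model: TermSimilarityModel, graph: OntologyGraph):
        self.model = model
        self.graph = graph
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        try:
            return self._cache[key]
        except KeyError:
            sim = term_similarity(self.model, self.graph, t1, t2)
            self._cache[key] = sim
            return sim


def pairwise_term_matrix(
    model: TermSimilarityModel,
    graph: OntologyGraph,
    terms1: Sequence[str],
    terms2: Sequence[str],
    _cache: _TermPairCache | None = None,
) -> np.ndarray:
    """k x s matrix of term similarities between two term collections."""
    sim = _cache if _cache is not None else _TermPairCache(model, graph)
    terms1, terms2 = list(terms1), list(terms2)
    out = np.empty((len(terms1), len(terms2)))
    for i, t1 in enumerate(terms1):
        for j, t2 in enumerate(terms2):
            out[i, j] = sim(t1, t2)
    return out


def set_similarity(pairwise: np.ndarray, strategy: str = "bma") -> float:
    """Collapse a rectangular constituent-similarity matrix to one score.

    An empty matrix (either set empty) yields 0 with a logged warning: an
    unannotated entity degrades gracefully to expression-only distance
    downstream rather than aborting the run.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    pairwise = np.asarray(pairwise, dtype=float)
    if pairwise.size == 0:
        logger.warning("set similarity of an empty set requested; returning 0")
        return 0.0
    if pairwise.ndim != 2:
        raise ValueError("pairwise matrix must be 2-dimensional")
    if strategy == "max":
        return float(pairwise.max())
    if strategy == "avg":
        return float(pairwise.mean())
    row_max = pairwise.max(axis=1)
    col_max = pairwise.max(axis=0)
    if strategy == "rcmax":
        return float(max(row_max.mean(), col_max.mean()))
    k, s = pairwise.shape
    return float((row_max.sum() + col_max.sum()) / (k + s))


def gene_similarity_matrix(
    model: TermSimilarityModel,
    graph: OntologyGraph,
    annotations: Mapping[str, set[str]],
    genes: Sequence[str] | None = None,
    strategy: str = "bma",
) -> pd.DataFrame:
    """Symmetric gene x gene similarity from the genes' GO-term sets.

    Genes missing from *annotations* (or annotated only with filtered-out
    terms) contribute a zero row/column.  Each unordered pair is computed
    once; term-pair similarities are shared across all pairs.
    """
    if genes is None:
        genes = list(annotations)
    genes = list(genes)
    term_sets = {g: sorted(annotations.get(g, ())) for g in genes}
    missing = [g for g in genes if not term_sets[g]]
    if missing:
        logger.warning("%d gene(s) have no usable annotation: %s",
                       len(missing), ", ".join(missing[:10]))
    cache = _TermPairCache(model, graph)
    n = len(genes)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            pw = pairwise_term_matrix(model, graph, term_sets[genes[i]],
                                      term_sets[genes[j]], _cache=cache)
            values[i, j] = values[j, i] = set_similarity(pw, strategy)
    return pd.DataFrame(values, index=genes, columns=genes)


def mirna_similarity_matrix(
    gene_sim: pd.DataFrame,
    targets: Mapping[str, set[str]],
    mirnas: Sequence[str] | None = None,
    strategy: str = "bma",
) -> pd.DataFrame:
    """The functional-similarity matrix H: second step of the two-step lift.

    Entry (i, j) applies *strategy* to the rectangular block of *gene_sim*
    between the two miRNAs' target sets.  Target genes not indexed in
    *gene_sim* are dropped with a warning; a miRNA left without usable
    targets gets a zero row (off-diagonal), so its combined distance reduces
    to plain expression distance.
    """
    if mirnas is None:
        mirnas = list(targets)
    mirnas = list(mirnas)
    known = set(gene_sim.index)
    gene_lists: dict[str, list[str]] = {}
    for m in mirnas:
        tg = sorted(targets.get(m, ()))
        usable = [g for g in tg if g in known]
        if len(usable) < len(tg):
            logger.warning("miRNA %s: dropped %d target gene(s) absent from the gene "
                           "similarity matrix", m, len(tg) - len(usable))
        if not usable:
            logger.warning("miRNA %s has no usable target genes; similarity row set to 0", m)
        gene_lists[m] = usable
    n = len(mirnas)
    values = np.zeros((n, n))
    gs = gene_sim.to_numpy()
    pos = {g: i for i, g in enumerate(gene_sim.index)}
    for i in range(n):
        gi = [pos[g] for g in gene_lists[mirnas[i]]]
        for j in range(i, n):
            gj = [pos[g] for g in gene_lists[mirnas[j]]]
            block = gs[np.ix_(gi, gj)] if gi and gj else np.empty((0, 0))
            values[i, j] = values[j, i] = set_similarity(block, strategy)
    return pd.DataFrame(values, index=mirnas, columns=mirnas)


def functional_similarity(
    model: TermSimilarityModel,
    graph: OntologyGraph,
    annotations: Mapping[str, set[str]],
    targets: Mapping[str, set[str]],
    mirnas: Sequence[str] | None = None,
    gene_strategy: str = "bma",
    mirna_strategy: str = "bma",
) -> pd.DataFrame:
    """End-to-end H computation from ontology + annotations + targets.

    ``mirna_strategy="pooled"`` switches to the one-step redundant-set
    variant: each miRNA's terms are the union over its targets' annotations
    and ``gene_strategy`` scores the term-level block directly.
    """
    annotations = filter_annotations(annotations, graph)
    if mirnas is None:
        mirnas = list(targets)
    if mirna_strategy == "pooled":
        cache = _TermPairCache(model, graph)
        pooled = {
            m: sorted(set().union(*(annotations.get(g, set()) for g in targets.get(m, set()))))
            if targets.get(m) else []
            for m in mirnas
        }
        n = len(mirnas)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                pw = pairwise_term_matrix(model, graph, pooled[mirnas[i]],
                                          pooled[mirnas[j]], _cache=cache)
                values[i, j] = values[j, i] = set_similarity(pw, gene_strategy)
        return pd.DataFrame(values, index=list(mirnas), columns=list(mirnas))
    used_genes = sorted(set().union(*(targets.get(m, set()) for m in mirnas)) & set(annotations))
    gene_sim = gene_similarity_matrix(model, graph, annotations, used_genes, gene_strategy)
    return mirna_similarity_matrix(gene_sim, targets, mirnas, mirna_strategy)
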