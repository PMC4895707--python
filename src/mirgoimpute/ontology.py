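"""Gene Ontology parsing and term-level semantic similarity.

The ontology is held as a directed acyclic graph with edges pointing from a
child (more specific) term to its parents, restricted to ``is_a`` and
``part_of`` relations.  Two term-similarity backends are provided:

``structural``
    The semantic-contribution recursion used by G-SESAME / GOSemSim ("Wang"
    method): each ancestor *a* of a term *t* receives an S-value
    ``S_t(t) = 1`` and ``S_t(a) = max over children c of a on paths to t of
    w_rel * S_t(c)``, with per-relation contribution factors ``w_is_a = 0.8``
    and ``w_part_of = 0.6`` by default.  The similarity of two terms is the
    summed S-values over their common ancestors, normalised by the two
    semantic totals:

        sim(t1, t2) = sum_{a in anc(t1) ∩ anc(t2)} (S_t1(a) + S_t2(a))
                      / (SV(t1) + SV(t2)),   SV(t) = sum_{a in anc(t)} S_t(a)

``information_content``
    Annotation-frequency based.  ``IC(x) = -ln(|G_x| / |G_root|)`` where
    ``G_x`` is the set of genes associated with *x* or any of its ontology
    descendants.  Pair similarity is the IC of the most informative common
    ancestor normalised to [0, 1] as ``2 IC(mica) / (IC(t1) + IC(t2))``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

DEFAULT_CONTRIBUTION_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}

#: OBO namespace name -> GAF aspect letter
NAMESPACE_ASPECT = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}


class OntologyError(ValueError):
    """Structural problem with the ontology (cycles, unknown terms...)."""


class OboParseError(OntologyError):
    """The OBO file is syntactically malformed."""


class OntologyGraph:
    """A single-namespace GO DAG.

    Parameters
    ----------
    graph : networkx.MultiDiGraph
        Edges point child -> parent; the edge key is the relation
        (``is_a`` or ``part_of``).
    namespace : str or None
        Namespace the graph was restricted to, if any.
    obsolete : iterable of str
        Identifiers of obsolete terms.  They are recorded but carry no edges
        and take no part in traversals.
    """

    def __init__(
        self,
        graph: nx.MultiDiGraph,
        namespace: str | None = None,
        obsolete: Iterable[str] = (),
    ):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"ontology contains a relation cycle: {cycle}")
        self.graph = graph
        self.namespace = namespace
        self.obsolete = frozenset(obsolete)

    # -- basic queries ---------------------------------------------------
    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> list[str]:
        """Terms with no parent, one per connected namespace."""
        return sorted(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def _require(self, term: str) -> None:
        if term not in self.graph:
            raise OntologyError(f"unknown term {term!r}")

    def parents(self, term: str) -> list[tuple[str, str]]:
        """``(parent, relation)`` pairs of a term."""
        self._require(term)
        return [(p, rel) for _, p, rel in self.graph.out_edges(term, keys=True)]

    def term_namespace(self, term: str) -> str | None:
        self._require(term)
        return self.graph.nodes[term].get("namespace", self.namespace)

    def ancestors(self, term: str) -> set[str]:
        """The term together with every term reachable via parent edges."""
        self._require(term)
        return {term} | nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """The term together with every term that specialises it."""
        self._require(term)
        return {term} | nx.ancestors(self.graph, term)


def ancestors(graph: OntologyGraph, term: str) -> set[str]:
    """Ancestor closure of *term* (inclusive); see :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term)


def _prescan_obo(path) -> None:
    # obonet does not report line numbers; catch gross syntax errors here so
    # the error can name the offending line.
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!")[0].strip()
            if not line:
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise OboParseError(f"{path}: malformed stanza header at line {lineno}: {raw!r}")
                continue
            if ":" not in line:
                raise OboParseError(f"{path}: malformed tag-value pair at line {lineno}: {raw!r}")


def read_obo(path, namespace: str | None = "molecular_function") -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Only ``is_a`` and ``relationship: part_of`` edges are retained.  The graph
    is restricted to *namespace* (terms that declare no namespace, as in toy
    fixtures, are kept); pass ``namespace=None`` to keep every term.  Obsolete
    terms are recorded in :attr:`OntologyGraph.obsolete` and excluded from the
    graph.

    Raises
    ------
    OboParseError
        If the file is syntactically malformed (the message names the line).
    OntologyError
        If the retained relations contain a cycle.
    """
    _prescan_obo(path)
    try:
        raw = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - obonet raises ValueError
        raise OboParseError(f"{path}: {exc}") from exc

    obsolete = {
        n for n, data in raw.nodes(data=True)
        if str(data.get("is_obsolete", "false")).lower() == "true"
    }

    keep: set[str] = set()
    for node, data in raw.nodes(data=True):
        if node in obsolete:
            continue
        ns = data.get("namespace")
        if namespace is None or ns is None or ns == namespace:
            keep.add(node)

    g = nx.MultiDiGraph()
    for node in keep:
        g.add_node(node, **raw.nodes[node])
    for child, parent, rel in raw.edges(keys=True):
        if rel in ("is_a", "part_of") and child in keep and parent in keep:
            g.add_edge(child, parent, key=rel)
    return OntologyGraph(g, namespace=namespace, obsolete=obsolete)


@dataclass
class TermSimilarityModel:
    """Configuration of the term-level similarity backend.

    Parameters
    ----------
    backend : {"structural", "information_content"}
        ``structural`` is the graph-location method (default, used throughout
        the imputation pipeline); ``information_content`` scores pairs by
        their most informative common ancestor and requires *annotations*.
    contribution_weights : mapping relation -> factor in (0, 1)
        Semantic-contribution factor per edge type for the structural backend.
    annotations : mapping gene -> set of terms, optional
        Required by the ``information_content`` backend.
    """

    backend: str = "structural"
    contribution_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTRIBUTION_WEIGHTS)
    )
    annotations: Mapping[str, set] | None = None

    def __post_init__(self):
        if self.backend not in ("structural", "information_content"):
            raise ValueError(f"unknown backend {self.backend!r}")
        for rel, w in self.contribution_weights.items():
            if not 0.0 < w < 1.0:
                raise ValueError(
                    f"contribution factor for {rel!r} must lie strictly in (0, 1); got {w}"
                )
        if self.backend == "information_content" and not self.annotations:
            raise ValueError("information_content backend requires annotations")
        self._ic_cache: dict[str, float] = {}


def semantic_values(
    graph: OntologyGraph, term: str, weights: Mapping[str, float] | None = None
) -> dict[str, float]:
    """S-values of *term*'s ancestors under the semantic-contribution recursion.

    ``S[term] = 1``; walking child -> parent, each parent keeps the best
    weighted contribution over its children that lie on a path from *term*.
    """
    if weights is None:
        weights = DEFAULT_CONTRIBUTION_WEIGHTS
    anc = graph.ancestors(term)
    sub = graph.graph.subgraph(anc)
    s = {term: 1.0}
    # children before parents: edges run child -> parent
    for node in nx.topological_sort(sub):
        if node not in s:  # unreachable side-branch inside the closure
            continue
        for _, parent, rel in sub.out_edges(node, keys=True):
            w = weights.get(rel)
            if w is None:
                continue
            cand = w * s[node]
            if cand > s.get(parent, 0.0):
                s[parent] = cand
    return s


def _structural_similarity(model, graph, t1, t2) -> float:
    s1 = semantic_values(graph, t1, model.contribution_weights)
    s2 = semantic_values(graph, t2, model.contribution_weights)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    num = sum(s1[a] + s2[a] for a in common)
    return num / (sum(s1.values()) + sum(s2.values()))


def _annotation_sets(graph: OntologyGraph, annotations: Mapping[str, set]) -> dict[str, set]:
    """Direct gene sets per term, restricted to terms present in the graph."""
    direct: dict[str, set] = {}
    for gene, terms in annotations.items():
        for t in terms:
            if t in graph:
                direct.setdefault(t, set()).add(gene)
    return direct


def information_content(
    graph: OntologyGraph, annotations: Mapping[str, set], term: str
) -> float:
    """``IC(x) = -ln(|G_x| / |G_root|)``, association-based.

    ``G_x`` contains every gene annotated to *term* or to any of its
    descendants; ``G_root`` is every gene the DAG annotates at all.  The root
    therefore has IC 0, and IC never decreases walking child-ward.

    Raises
    ------
    OntologyError
        If *term* is not in the graph, the annotation map is empty, or no gene
        is associated with *term* (IC undefined).
    """
    graph._require(term)
    if not annotations:
        raise OntologyError("annotation map is empty; IC is undefined")
    direct = _annotation_sets(graph, annotations)
    g_root: set = set().union(*direct.values()) if direct else set()
    if not g_root:
        raise OntologyError("no annotated gene maps to any graph term")
    g_x: set = set()
    for t in graph.descendants(term):
        g_x |= direct.get(t, set())
    if not g_x:
        raise OntologyError(f"term {term!r} annotates no gene; IC is undefined")
    return -math.log(len(g_x) / len(g_root))


def _ic_similarity(model, graph, t1, t2) -> float:
    if t1 == t2:
        return 1.0
    cache = model._ic_cache

    def ic(t):
        if t not in cache:
            cache[t] = information_content(graph, model.annotations, t)
        return cache[t]

    ic1, ic2 = ic(t1), ic(t2)
    if ic1 + ic2 == 0.0:  # two distinct roots
        return 0.0
    common = graph.ancestors(t1) & graph.ancestors(t2)
    mica = 0.0
    for a in common:
        try:
            mica = max(mica, ic(a))
        except OntologyError:
            continue  # ancestor annotating nothing cannot occur on a valid DAG
    return min(1.0, 2.0 * mica / (ic1 + ic2))


def term_similarity(
    model: TermSimilarityModel, graph: OntologyGraph, t1: str, t2: str
) -> float:
    """Similarity in [0, 1] of two same-namespace terms under *model*'s backend.

    Symmetric, with ``term_similarity(t, t) == 1``.
    """
    graph._require(t1)
    graph._require(t2)
    ns1, ns2 = graph.term_namespace(t1), graph.term_namespace(t2)
    if ns1 is not None and ns2 is not None and ns1 != ns2:
        raise OntologyError(
            f"cannot compare terms across namespaces: {t1!r} ({ns1}) vs {t2!r} ({ns2})"
        )
    if t1 == t2:
        return 1.0
    if model.backend == "structural":
        return _structural_similarity(model, graph, t1, t2)
    return _ic_similarity(model, graph, t1, t2)
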