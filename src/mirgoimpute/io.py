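"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices are tab/comma-delimited with the first column holding
miRNA identifiers and a header row of sample identifiers; empty cells or any
of the usual NA markers denote missing values.  Annotation and target tables
are 2-column delimited text; GAF 2.x is accepted for annotations, and target
tables may carry a third score column (e.g. mirSVR) with a keep-threshold.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping

import numpy as np
import pandas as pd

from .ontology import NAMESPACE_ASPECT, OntologyGraph

logger = logging.getLogger(__name__)

_SPLIT = re.compile(r"[\t,]| +")


# -- expression matrices ------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a miRNA x sample expression matrix (NaN = missing)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df = df.astype(float)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate miRNA identifiers in {path}: {dup}")
    return df


def write_expression(expr: pd.DataFrame, path, sep: str = "\t") -> None:
    expr.to_csv(path, sep=sep, na_rep="NA")


# -- annotations --------------------------------------------------------

def _parse_two_column(path, what: str) -> list[tuple[str, ...]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "!")):
                continue
            parts = [p for p in _SPLIT.split(line) if p]
            if len(parts) < 2:
                raise ValueError(
                    f"{path}: line {lineno} of the {what} table has fewer than 2 columns"
                )
            rows.append(tuple(parts))
    return rows


def read_annotations(
    path,
    graph: OntologyGraph | None = None,
    aspect: str | None = None,
) -> dict[str, set[str]]:
    """Read a gene -> GO-term map.

    Accepts 2-column delimited text ``(gene_id, term_id)`` or GAF 2.x (columns
    2 and 5 extracted; rows filtered to *aspect* — a letter F/P/C or a
    namespace name — when given).  If *graph* is supplied, terms absent from
    the graph are dropped with a logged warning, as are genes whose term set
    becomes empty.
    """
    if aspect is not None:
        aspect = NAMESPACE_ASPECT.get(aspect, aspect)
    annotations: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "!")):
                continue
            tabs = line.split("\t")
            if len(tabs) >= 15:  # GAF 2.x row
                if aspect is not None and tabs[8] != aspect:
                    continue
                gene, term = tabs[1], tabs[4]
            else:
                parts = [p for p in _SPLIT.split(line) if p]
                if len(parts) < 2:
                    raise ValueError(f"{path}: annotation row has fewer than 2 columns: {line!r}")
                gene, term = parts[0], parts[1]
            annotations.setdefault(gene, set()).add(term)
    if graph is not None:
        annotations = filter_annotations(annotations, graph)
    return annotations


def filter_annotations(
    annotations: Mapping[str, set[str]], graph: OntologyGraph
) -> dict[str, set[str]]:
    """Drop terms not in *graph*, then genes left with no terms (warning each)."""
    out: dict[str, set[str]] = {}
    dropped_terms = 0
    dropped_genes = []
    for gene, terms in annotations.items():
        kept = {t for t in terms if t in graph}
        dropped_terms += len(terms) - len(kept)
        if kept:
            out[gene] = kept
        else:
            dropped_genes.append(gene)
    if dropped_terms:
        logger.warning("dropped %d annotation term(s) absent from the ontology", dropped_terms)
    if dropped_genes:
        logger.warning(
            "dropped %d gene(s) with no usable annotation: %s",
            len(dropped_genes), ", ".join(sorted(dropped_genes)[:10]),
        )
    return out


def write_annotations(annotations: Mapping[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in annotations:
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


# -- miRNA target tables ------------------------------------------------

def read_targets(path, score_threshold: float | None = None) -> dict[str, set[str]]:
    """Read a miRNA -> target-gene map.

    2-column delimited text ``(mirna_id, gene_id)``; an optional third numeric
    column is a prediction score, kept only when ``score <= score_threshold``
    (the mirSVR convention: more negative = more confident).  Rows without a
    score are always kept.
    """
    targets: dict[str, set[str]] = {}
    for parts in _parse_two_column(path, "target"):
        mirna, gene = parts[0], parts[1]
        if score_threshold is not None and len(parts) >= 3:
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric score {parts[2]!r}") from exc
            if score > score_threshold:
                continue
        targets.setdefault(mirna, set()).add(gene)
    return targets


def write_targets(targets: Mapping[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna in targets:
            for gene in sorted(targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


# -- square labelled matrices (H, D, C) ---------------------------------

def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path, sep: str = "\t") -> None:
    matrix.to_csv(path, sep=sep, na_rep="NA")


# -- missingness masks ---------------------------------------------------

def write_mask(mask: np.ndarray, expr: pd.DataFrame, path) -> None:
    """Write masked cells as 3-column text ``(mirna_id, sample_id, 1)``."""
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    with open(path, "w", encoding="utf-8") as fh:
        for r, c in zip(rows, cols):
            fh.write(f"{expr.index[r]}\t{expr.columns[c]}\t1\n")


def read_mask(path, expr: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(expr.shape, dtype=bool)
    ridx = {m: i for i, m in enumerate(expr.index)}
    cidx = {s: j for j, s in enumerate(expr.columns)}
    for parts in _parse_two_column(path, "mask"):
        mask[ridx[parts[0]], cidx[parts[1]]] = True
    return mask


# -- OBO writing (for synthetic ontologies) ------------------------------

def write_obo(ontology: OntologyGraph, path) -> None:
    """Serialise an :class:`OntologyGraph` to a minimal OBO 1.2 file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: synthetic\n")
        if ontology.namespace:
            fh.write(f"default-namespace: {ontology.namespace}\n")
        fh.write("\n")
        for term in sorted(ontology.graph.nodes):
            data = ontology.graph.nodes[term]
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            if data.get("namespace"):
                fh.write(f"namespace: {data['namespace']}\n")
            for parent, rel in sorted(ontology.parents(term)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            fh.write("\n")
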