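"""Scoring alignments against a reference with m-to-n clustered counting.

Reference alignments (OAEI Alignment-format RDF) may contain m-to-n
groups of equivalences and uncertain cells marked "?".  "?" cells count
as positives.  The m-to-n cells are clustered into connected components
of the bipartite entity graph; a system is credited once per cluster the
first time it hits any cell of it, further hits on the same cluster are
ignored (reported separately as duplicate hits, counting toward neither
tp nor fp).  Recall is clusters-hit / clusters; precision is
tp / (tp + fp) where fp are predictions hitting no cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import rdflib

ALIGN_NS = rdflib.Namespace("http://knowledgeweb.semanticweb.org/heterogeneity/alignment")


@dataclass(frozen=True)
class ReferenceCell:
    entity1: str
    entity2: str
    relation: str = "="
    uncertain: bool = False  # the "?" marker


@dataclass
class ReferenceAlignment:
    cells: list[ReferenceCell]
    clusters: list[set[tuple[str, str]]] = field(default_factory=list)

    def __post_init__(self):
        if not self.clusters and self.cells:
            self.clusters = cluster_mn(self.cells)


@dataclass
class EvalResult:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    duplicate_hits: int

    def as_dict(self) -> dict:
        return {
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "tp": self.tp, "fp": self.fp, "duplicate_hits": self.duplicate_hits,
        }


def load_reference(path: str | Path) -> ReferenceAlignment:
    """Parse Cell elements of an Alignment-format RDF file.

    Cells whose relation is "?" (or whose entities are missing) are the
    uncertain mappings; they are flagged and still treated as positive.
    Malformed cells are skipped.
    """
    g = rdflib.Graph()
    g.parse(str(path), format="xml")
    cells: list[ReferenceCell] = []
    for cell in set(g.subjects(ALIGN_NS.entity1, None)) | {
        s for s, _, _ in g.triples((None, rdflib.RDF.type, ALIGN_NS.Cell))
    }:
        e1 = g.value(cell, ALIGN_NS.entity1)
        e2 = g.value(cell, ALIGN_NS.entity2)
        if e1 is None or e2 is None:
            continue
        rel = g.value(cell, ALIGN_NS.relation)
        rel_s = str(rel).strip() if rel is not None else "="
        cells.append(ReferenceCell(str(e1), str(e2), rel_s, uncertain=rel_s == "?"))
    cells.sort(key=lambda c: (c.entity1, c.entity2))
    return ReferenceAlignment(cells)


def cluster_mn(cells: Sequence[ReferenceCell]) -> list[set[tuple[str, str]]]:
    """Connected components of the bipartite graph of reference cells.

    A 1-to-1 cell is its own cluster; cells sharing an entity on either
    side merge (union-find over entity nodes).
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for c in cells:
        l, r = "L:" + c.entity1, "R:" + c.entity2
        parent.setdefault(l, l)
        parent.setdefault(r, r)
        union(l, r)

    groups: dict[str, set[tuple[str, str]]] = {}
    for c in cells:
        groups.setdefault(find("L:" + c.entity1), set()).add((c.entity1, c.entity2))
    return sorted(groups.values(), key=lambda s: sorted(s)[0])


def score(
    predictions: Sequence[tuple[str, str]],
    reference: ReferenceAlignment,
) -> EvalResult:
    """Count cluster hits: first hit on a cluster is a tp, further hits on
    an already-hit cluster are ignored, misses are fp."""
    if not reference.cells:
        raise ValueError("empty reference alignment")
    cell_to_cluster: dict[tuple[str, str], int] = {}
    for ci, cluster in enumerate(reference.clusters):
        for cell in cluster:
            cell_to_cluster[cell] = ci

    hit: set[int] = set()
    fp = 0
    dup = 0
    for pair in predictions:
        ci = cell_to_cluster.get(tuple(pair))
        if ci is None:
            fp += 1
        elif ci in hit:
            dup += 1
        else:
            hit.add(ci)
    tp = len(hit)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / len(reference.clusters)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalResult(precision, recall, f1, tp, fp, dup)
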