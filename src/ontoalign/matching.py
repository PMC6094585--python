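"""Alignment as stable marriage over cosine-distance preferences.

Both ontologies rank the other side's terms by increasing cosine distance
of their phrase embeddings.  The Gale–Shapley procedure (in the
McVitie–Wilson extension to unequal sets, the smaller side proposing)
yields a one-to-one matching with no blocking pair: no cross pair exists
in which both terms prefer each other to their assigned partners.  Two
threshold filters follow: ``t1`` on the retrofitted-embedding distance,
then ``t2`` on the DAE hidden-code distance (the outlier score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
from xml.sax.saxutils import escape

import numpy as np

from .dae import DAEParams, dae_distance
from .embeddings import WordVectorTable, sentence_embedding
from .ontology_io import Ontology

log = logging.getLogger(__name__)


@dataclass
class PreferenceMatrix:
    """m x n cosine distances plus the row/column term ids."""

    distances: np.ndarray
    row_ids: list[str]
    col_ids: list[str]


@dataclass(frozen=True)
class Correspondence:
    """An equivalence correspondence ``(e, =, e', confidence)``."""

    source_id: str
    target_id: str
    confidence: float
    relation: str = "="


@dataclass
class AlignmentSet:
    correspondences: list[Correspondence] = field(default_factory=list)
    scbow_distance: dict[tuple[str, str], float] = field(default_factory=dict)
    dae_distance: dict[tuple[str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.correspondences)

    def pairs(self) -> list[tuple[str, str]]:
        return [(c.source_id, c.target_id) for c in self.correspondences]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for c in self.correspondences:
                key = (c.source_id, c.target_id)
                fh.write(
                    f"{c.source_id}\t{c.target_id}\t{c.confidence:.6f}"
                    f"\t{self.scbow_distance.get(key, float('nan')):.6f}"
                    f"\t{self.dae_distance.get(key, float('nan')):.6f}\n"
                )

    def write_rdf(self, path: str | Path) -> None:
        """Serialise in the Alignment-format RDF dialect used by OAEI."""
        lines = [
            '<?xml version="1.0" encoding="utf-8"?>',
            '<rdf:RDF xmlns="http://knowledgeweb.semanticweb.org/heterogeneity/alignment"',
            '         xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#">',
            "<Alignment>",
            "  <xml>yes</xml>",
            "  <level>0</level>",
            "  <type>11</type>",
        ]
        for c in self.correspondences:
            lines += [
                "  <map><Cell>",
                f'    <entity1 rdf:resource="{escape(c.source_id, {chr(34): "&quot;"})}"/>',
                f'    <entity2 rdf:resource="{escape(c.target_id, {chr(34): "&quot;"})}"/>',
                f"    <relation>{escape(c.relation)}</relation>",
                f"    <measure rdf:datatype=\"http://www.w3.org/2001/XMLSchema#float\">{c.confidence:.6f}</measure>",
                "  </Cell></map>",
            ]
        lines += ["</Alignment>", "</rdf:RDF>", ""]
        Path(path).write_text("\n".join(lines), encoding="utf-8")


def build_preference_matrix(
    source_embeds: dict[str, np.ndarray],
    target_embeds: dict[str, np.ndarray],
) -> PreferenceMatrix:
    """Pairwise cosine distances between the two sides' embeddings.

    Ids are ordered lexicographically; zero embeddings are excluded with a
    warning (they have no direction).
    """
    def usable(embeds: dict[str, np.ndarray]) -> list[str]:
        ids = []
        for k in sorted(embeds):
            if np.linalg.norm(embeds[k]) == 0.0:
                log.warning("excluding %s: zero embedding", k)
            else:
                ids.append(k)
        return ids

    rows = usable(source_embeds)
    cols = usable(target_embeds)
    A = np.stack([source_embeds[r] for r in rows]) if rows else np.zeros((0, 1))
    B = np.stack([target_embeds[c] for c in cols]) if cols else np.zeros((0, 1))
    if rows and cols:
        An = A / np.linalg.norm(A, axis=1, keepdims=True)
        Bn = B / np.linalg.norm(B, axis=1, keepdims=True)
        D = 1.0 - np.clip(An @ Bn.T, -1.0, 1.0)
    else:
        D = np.zeros((len(rows), len(cols)))
    return PreferenceMatrix(D, rows, cols)


def stable_marriage(pref: PreferenceMatrix) -> list[tuple[str, str]]:
    """Gale–Shapley on unequal sets; the smaller side proposes.

    Preference orders come from sorting distances ascending with ties
    broken by term id.  The result has ``min(m, n)`` pairs and no blocking
    pair under the usual instability condition (a cross pair who both
    prefer each other to their partners).
    """
    m, n = pref.distances.shape
    if m == 0 or n == 0:
        return []
    transposed = m > n
    D = pref.distances.T if transposed else pref.distances
    p_ids = pref.col_ids if transposed else pref.row_ids
    r_ids = pref.row_ids if transposed else pref.col_ids
    P, R = D.shape  # P <= R

    # proposer k's preference list: receiver indices, best first
    pref_lists = [
        sorted(range(R), key=lambda j: (D[k, j], r_ids[j])) for k in range(P)
    ]
    # receiver j ranks proposers: lower is better
    rank = np.empty((R, P), dtype=np.int64)
    for j in range(R):
        order = sorted(range(P), key=lambda k: (D[k, j], p_ids[k]))
        for pos, k in enumerate(order):
            rank[j, k] = pos

    next_choice = [0] * P
    engaged_to: dict[int, int] = {}  # receiver -> proposer
    free = list(range(P - 1, -1, -1))
    while free:
        k = free.pop()
        j = pref_lists[k][next_choice[k]]
        next_choice[k] += 1
        cur = engaged_to.get(j)
        if cur is None:
            engaged_to[j] = k
        elif rank[j, k] < rank[j, cur]:
            engaged_to[j] = k
            free.append(cur)
        else:
            free.append(k)

    pairs = [(p_ids[k], r_ids[j]) for j, k in engaged_to.items()]
    if transposed:
        pairs = [(b, a) for a, b in pairs]
    return sorted(pairs)


def filter_by_threshold(
    alignments: AlignmentSet, distance_field: str, t: float
) -> AlignmentSet:
    """Keep correspondences whose named distance is <= t (pairs strictly
    greater are discarded); order preserved."""
    if distance_field not in ("scbow_distance", "dae_distance"):
        raise ValueError(f"unknown distance field {distance_field!r}")
    dists: dict[tuple[str, str], float] = getattr(alignments, distance_field)
    kept = [
        c for c in alignments.correspondences
        if dists.get((c.source_id, c.target_id), float("inf")) <= t
    ]
    keys = {(c.source_id, c.target_id) for c in kept}
    return AlignmentSet(
        kept,
        {k: v for k, v in alignments.scbow_distance.items() if k in keys},
        {k: v for k, v in alignments.dae_distance.items() if k in keys},
    )


def align_ontologies(
    onto_a: Ontology,
    onto_b: Ontology,
    table: WordVectorTable,
    dae_params: DAEParams | None = None,
    t1: float = 0.2,
    t2: float = 0.2,
    oov: dict[str, np.ndarray] | None = None,
) -> AlignmentSet:
    """Full matching stage: stable marriage, then the t1 filter on the
    phrase-embedding distance, then (when a DAE is given) the t2 filter on
    the hidden-code distance.

    Confidence is ``max(0, 1 - scbow_distance)`` — the clamped cosine
    similarity actually used for the matching decision.
    """
    def embeds(onto: Ontology) -> dict[str, np.ndarray]:
        out = {}
        for rec in onto.terms:
            if rec.degenerate:
                log.warning("excluding degenerate term %s", rec.term_id)
                continue
            try:
                out[rec.term_id] = sentence_embedding(rec.tokens, table, oov)
            except ValueError:
                log.warning("excluding %s: no usable word vectors", rec.term_id)
        return out

    ea, eb = embeds(onto_a), embeds(onto_b)
    pref = build_preference_matrix(ea, eb)
    pairs = stable_marriage(pref)

    aln = AlignmentSet()
    for s, t in pairs:
        d1 = pref.distances[pref.row_ids.index(s), pref.col_ids.index(t)]
        aln.correspondences.append(Correspondence(s, t, max(0.0, 1.0 - d1)))
        aln.scbow_distance[(s, t)] = float(d1)
        if dae_params is not None:
            aln.dae_distance[(s, t)] = dae_distance(ea[s], eb[t], dae_params)
    aln = filter_by_threshold(aln, "scbow_distance", t1)
    if dae_params is not None:
        aln = filter_by_threshold(aln, "dae_distance", t2)
    return aln
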