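"""Ontology parsing and textual preprocessing.

Each ontology class is reduced to a bag of lowercase tokens taken either
from its (first) ``rdfs:label`` or from the fragment of its IRI.  The
preprocessing mirrors what is usual for biomedical terminologies:
case-folding, tokenisation, removal of English stopwords and of words that
co-appear in the vast majority of terms (e.g. "structure" in SNOMED-style
naming conventions).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import rdflib
from rdflib.namespace import OWL, RDF, RDFS

log = logging.getLogger(__name__)

LabelPolicy = Literal["rdfs_label", "rdf_about"]

_TOKEN_SPLIT = re.compile(r"[^0-9a-zA-Z]+")
_CAMEL = re.compile(r"(?<=[a-z0-9])(?=[A-Z])|(?<=[A-Z])(?=[A-Z][a-z])")


@dataclass(frozen=True)
class TermRecord:
    """A single ontology term: its IRI, raw text and preprocessed tokens."""

    term_id: str
    raw_text: str
    tokens: tuple[str, ...]
    degenerate: bool = False  # True when preprocessing left no tokens


@dataclass
class Ontology:
    name: str
    terms: list[TermRecord]
    label_policy: LabelPolicy = "rdfs_label"
    #: alternate rdfs:label strings per term_id (first label is raw_text)
    extra_labels: dict[str, list[str]] = field(default_factory=dict)
    #: number of classes skipped because no usable text was found
    skipped: int = 0

    def collapse_groups(self) -> list[list[str]]:
        """Groups of distinct term_ids whose token bags collapsed to the
        same phrase after preprocessing (reported, matched independently)."""
        by_bag: dict[tuple[str, ...], list[str]] = {}
        for t in self.terms:
            by_bag.setdefault(t.tokens, []).append(t.term_id)
        return [ids for ids in by_bag.values() if len(ids) > 1]


def default_stopwords() -> frozenset[str]:
    """The English stopword list shipped with the package."""
    text = resources.files("ontoalign").joinpath("data/stopwords_en.txt").read_text("utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def tokenize(raw_text: str, split_camel: bool = False) -> list[str]:
    """Lowercase and split on whitespace, hyphens, underscores and punctuation.

    ``split_camel`` additionally splits camelCase boundaries before
    lowercasing, which IRI fragments commonly use.
    """
    if split_camel:
        raw_text = _CAMEL.sub(" ", raw_text)
    return [t.lower() for t in _TOKEN_SPLIT.split(raw_text) if t]


def preprocess_tokens(
    raw_text: str,
    stopwords: Iterable[str] = (),
    high_df: Iterable[str] = (),
    *,
    split_camel: bool = False,
) -> list[str]:
    """Tokenise and drop stopwords and high-document-frequency words.

    Order of the surviving tokens is preserved (contiguous-subsequence
    queries depend on it).  An empty result is not an error: callers flag
    the record as degenerate.
    """
    drop = set(stopwords) | set(high_df)
    return [t for t in tokenize(raw_text, split_camel=split_camel) if t not in drop]


def compute_high_df_words(terms: Sequence[Sequence[str]], df_fraction: float = 0.90) -> set[str]:
    """Words whose term-level document frequency is >= ``df_fraction``.

    ``df_fraction`` defaults to 0.90: high enough to single out naming
    boilerplate that co-appears in nearly every term without touching
    mid-frequency domain words.
    """
    if not 0.0 < df_fraction <= 1.0:
        raise ValueError(f"df_fraction must be in (0, 1], got {df_fraction}")
    if not terms:
        raise ValueError("terms must be non-empty")
    df: dict[str, int] = {}
    for toks in terms:
        for w in set(toks):
            df[w] = df.get(w, 0) + 1
    cutoff = df_fraction * len(terms)
    return {w for w, n in df.items() if n >= cutoff}


def _iri_fragment(iri: str) -> str:
    frag = iri.rsplit("#", 1)[-1]
    if frag == iri:
        frag = iri.rstrip("/").rsplit("/", 1)[-1]
    return frag


def parse_ontology(
    path: str | Path,
    label_policy: LabelPolicy = "rdfs_label",
    *,
    name: str | None = None,
    stopwords: Iterable[str] | None = None,
    df_fraction: float | None = 0.90,
) -> Ontology:
    """Parse an OWL/RDF file into one :class:`TermRecord` per ``owl:Class``.

    ``rdfs_label`` policy: the lexicographically first label is the term
    text; any further labels are kept in ``extra_labels`` so the lexicon
    stage can turn them into paraphrase pairs.  ``rdf_about`` policy: the
    IRI fragment is split on delimiters and camelCase.

    High-document-frequency words are computed on this ontology's own
    token bags and removed in a second pass; pass ``df_fraction=None`` to
    skip that step.
    """
    path = Path(path)
    g = rdflib.Graph()
    fmt = "turtle" if path.suffix in {".ttl", ".n3"} else "xml"
    try:
        g.parse(path, format=fmt)
    except Exception as exc:  # rdflib raises various parser errors
        raise ValueError(f"cannot parse ontology file {path}: {exc}") from exc

    sw = default_stopwords() if stopwords is None else frozenset(stopwords)

    classes = sorted(set(g.subjects(RDF.type, OWL.Class)), key=str)
    raw: list[tuple[str, str, list[str]]] = []  # (iri, raw_text, extra labels)
    skipped = 0
    for cls in classes:
        if not isinstance(cls, rdflib.URIRef):
            continue  # anonymous class expressions carry no usable text
        iri = str(cls)
        labels = sorted(str(o) for o in g.objects(cls, RDFS.label))
        if label_policy == "rdfs_label":
            if not labels:
                skipped += 1
                log.warning("class %s has no rdfs:label; skipped", iri)
                continue
            raw.append((iri, labels[0], labels[1:]))
        else:
            frag = _iri_fragment(iri)
            if not frag:
                skipped += 1
                log.warning("class %s has empty IRI fragment; skipped", iri)
                continue
            raw.append((iri, frag, labels[1:] if len(labels) > 1 else []))

    split_camel = label_policy == "rdf_about"
    bags = [preprocess_tokens(text, sw, (), split_camel=split_camel) for _, text, _ in raw]
    high_df: set[str] = set()
    if df_fraction is not None and bags:
        high_df = compute_high_df_words([b for b in bags if b], df_fraction)

    terms: list[TermRecord] = []
    for (iri, text, _extra), bag in zip(raw, bags):
        toks = tuple(t for t in bag if t not in high_df)
        terms.append(TermRecord(iri, text, toks, degenerate=not toks))

    onto = Ontology(
        name=name or path.stem,
        terms=terms,
        label_policy=label_policy,
        extra_labels={iri: extra for iri, _t, extra in raw if extra},
        skipped=skipped,
    )
    groups = onto.collapse_groups()
    if groups:
        log.info("%s: %d collapse groups after preprocessing", onto.name, len(groups))
    return onto
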