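"""Paraphrase supply: synonym-lexicon querying and ontology-internal labels.

Positive training examples (semantically similar phrases) come from two
sources: a local synonym lexicon queried with every contiguous subsequence
of a term's tokens, and alternate ``rdfs:label`` values of the same class.
A sub-span lexicon hit is spliced back into the term in place of the span
it matched, so the surrounding context words are preserved (e.g. a hit on
"heart muscle" inside "left heart muscle" yields "left cardiac muscle
tissue").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .ontology_io import Ontology, TermRecord, preprocess_tokens

log = logging.getLogger(__name__)

Tokens = tuple[str, ...]


@dataclass
class SynonymLexicon:
    """Map from a normalised phrase to its set of paraphrase phrases."""

    entries: dict[Tokens, set[Tokens]] = field(default_factory=dict)
    skipped_rows: int = 0

    def add(self, phrase: Tokens, paraphrase: Tokens) -> None:
        if phrase and paraphrase and phrase != paraphrase:
            self.entries.setdefault(phrase, set()).add(paraphrase)

    def lookup(self, phrase: Tokens) -> set[Tokens]:
        return self.entries.get(phrase, set())

    def merge(self, other: "SynonymLexicon") -> None:
        for k, vs in other.entries.items():
            for v in vs:
                self.add(k, v)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ParaphrasePair:
    left: Tokens
    right: Tokens
    source: str = "lexicon"  # "lexicon" | "ontology_label"


def contiguous_subsequences(tokens: Iterable[str]) -> list[Tokens]:
    """All m(m+1)/2 contiguous spans, longest first, then left-to-right."""
    toks = tuple(tokens)
    m = len(toks)
    out: list[Tokens] = []
    for length in range(m, 0, -1):
        for i in range(m - length + 1):
            out.append(toks[i : i + length])
    return out


def harvest_paraphrases(
    term: TermRecord | Tokens,
    lex: SynonymLexicon,
    max_paraphrases: int = 20,
) -> set[Tokens]:
    """Paraphrases of a full term obtained by querying every contiguous
    subsequence of its tokens against the lexicon.

    A hit on the full token sequence is returned as-is; a hit on a proper
    sub-span is spliced into the span's position.  Longest spans are
    queried first and the result is capped at ``max_paraphrases`` (longer
    span hits therefore win when the cap binds).  The original token
    sequence itself is never returned.
    """
    toks: Tokens = tuple(term.tokens) if isinstance(term, TermRecord) else tuple(term)
    out: set[Tokens] = set()
    for span in contiguous_subsequences(toks):
        for repl in lex.lookup(span):
            # locate the (first) position of this span; splice in place
            for i in range(len(toks) - len(span) + 1):
                if toks[i : i + len(span)] == span:
                    cand = toks[:i] + repl + toks[i + len(span):]
                    if cand != toks:
                        out.add(cand)
                    break
        if len(out) >= max_paraphrases:
            break
    if len(out) > max_paraphrases:
        out = set(sorted(out)[:max_paraphrases])
    return out


def ontology_label_synonyms(
    ontology: Ontology,
    stopwords: Iterable[str] = (),
    high_df: Iterable[str] = (),
) -> list[ParaphrasePair]:
    """One pair per (preferred label, alternate label) of a class.

    Both sides go through the same preprocessing as term text; pairs whose
    sides collapse to equal token bags (e.g. labels differing only in
    case) are dropped.
    """
    by_id: Mapping[str, TermRecord] = {t.term_id: t for t in ontology.terms}
    pairs: list[ParaphrasePair] = []
    for term_id, extras in ontology.extra_labels.items():
        rec = by_id.get(term_id)
        if rec is None or rec.degenerate:
            continue
        for alt in extras:
            alt_toks = tuple(preprocess_tokens(alt, stopwords, high_df))
            if alt_toks and alt_toks != rec.tokens:
                pairs.append(ParaphrasePair(rec.tokens, alt_toks, source="ontology_label"))
    return pairs


def load_lexicon_tsv(
    path: str | Path,
    stopwords: Iterable[str] = (),
    high_df: Iterable[str] = (),
) -> SynonymLexicon:
    """Load a two-column ``phrase<TAB>paraphrase`` UTF-8 TSV.

    Both columns are preprocessed with the same pipeline as ontology
    terms; malformed rows are skipped and counted.
    """
    lex = SynonymLexicon()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                lex.skipped_rows += 1
                log.warning("%s:%d: expected 2 tab-separated columns; skipped", path, lineno)
                continue
            left = tuple(preprocess_tokens(parts[0], stopwords, high_df))
            right = tuple(preprocess_tokens(parts[1], stopwords, high_df))
            if not left or not right or left == right:
                lex.skipped_rows += 1
                continue
            lex.add(left, right)
    return lex
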