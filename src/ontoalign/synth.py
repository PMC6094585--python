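"""Self-contained synthetic fixtures for every pipeline stage.

The generator emulates the situation the matcher is built for: two
ontologies naming the same set of latent concepts with disjoint phrases,
a synonym lexicon connecting some of those phrases, and a "pre-trained"
word-vector table in which synonym words cluster around a latent concept
direction — and in which, for a configurable fraction of concepts, a
*distinct* concept's words are planted near the same direction, the way
descriptively associated terms (horse/harness) coalesce with semantically
similar ones in corpus-trained vectors.

Every artefact is serialised in exactly the external formats the real
pipeline reads (OWL RDF/XML, TSV, word2vec text, Alignment-format RDF),
so fixtures double as format-integration tests.  Same seed, same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

from .embeddings import WordVectorTable
from .lexicon import SynonymLexicon
from .matching import AlignmentSet, Correspondence
from .ontology_io import Ontology, TermRecord

Tokens = tuple[str, ...]


@dataclass
class FixtureConfig:
    """Knobs of the planted-structure generator.

    ``similarity_noise`` is the per-component Gaussian sigma added to a
    unit concept direction when drawing a word vector; 0.12 at dim 16
    keeps synonym phrases coherent while spreading cross-concept cosines.
    ``confounder_cos`` / ``confounder_cos_hard`` set how close a
    confounded concept's direction is planted to its partner's; easy-class
    pairs additionally share a generic head word, so their surface
    confusion does not depend on the angular offset.  ``oov_fraction``
    plants concepts whose phrase on one side is missing from the vector
    table entirely — the rare-word failure mode that makes retrofitting
    worthwhile in the first place.
    """

    n_concepts: int = 40
    dim: int = 16
    phrases_per_concept: int = 2  # split alternately between the two sides
    words_per_phrase: int = 2
    confounder_fraction: float = 0.0
    similarity_noise: float = 0.12
    #: rank of the subspace concept directions are drawn from; word noise
    #: stays full-dimensional
    concept_rank: int = 8
    confounder_cos: float = 0.93
    #: planted cosine for confounded pairs within the hard class — deep
    #: coalescence: close enough that the two concepts' phrases genuinely
    #: interleave, the way horse/harness-type associations sit among
    #: synonyms in corpus vectors
    confounder_cos_hard: float = 0.97
    #: fraction of concepts whose two sides share no word at all (the rest
    #: share a head word, as most real cross-ontology matches do)
    hard_fraction: float = 0.35
    #: concepts (drawn from the hard class) whose phrase on one side is
    #: missing from the vector table — the rare-word failure mode
    oov_fraction: float = 0.2
    lexicon_coverage: float = 0.95      # easy concepts: common phrases, well covered
    lexicon_coverage_hard: float = 0.6  # rare terms: poorly covered by general lexicons
    #: per-side fraction of extra concepts with NO counterpart in the other
    #: ontology; each A-side leftover is descriptively associated (shared
    #: generic head + related direction) with a B-side leftover, the way
    #: partially overlapping ontologies leave related-but-distinct strays
    unmatched_fraction: float = 0.15
    bridges_per_concept: int = 2        # lexicon-only paraphrase phrases per concept
    vocab_size: int | None = None       # extra filler words beyond what phrases need
    seed: int = 0

    def __post_init__(self):
        if self.dim < 4:
            raise ValueError("dim must be >= 4")
        if self.phrases_per_concept < 2:
            raise ValueError("each concept needs at least 2 phrases (one per side)")
        if self.words_per_phrase < 2:
            raise ValueError("phrases need at least 2 words")
        if not 0.0 <= self.confounder_fraction < 1.0:
            raise ValueError("confounder_fraction must be in [0, 1)")
        if self.oov_fraction > self.hard_fraction:
            raise ValueError("oov concepts are drawn from the hard class")
        k = int(round(self.confounder_fraction * self.n_concepts))
        if k > self.n_concepts - k:
            raise ValueError("confounder_fraction too large to pair distinct concepts")
        if self.vocab_size is not None and self.vocab_size < 2 * self.n_concepts:
            raise ValueError("vocab_size must be at least 2 * n_concepts")


@dataclass
class Fixture:
    config: FixtureConfig
    ontology_a: Ontology
    ontology_b: Ontology
    lexicon: SynonymLexicon
    table: WordVectorTable
    ground_truth: list[tuple[str, str]]
    lexicon_rows: list[tuple[str, str]] = field(default_factory=list)
    #: planted structure, for construction checks: concept index -> partner
    confounder_partner: dict[int, int] = field(default_factory=dict)
    hard_concepts: set[int] = field(default_factory=set)
    oov_concepts: set[int] = field(default_factory=set)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Serialise all artefacts; deterministic byte-for-byte."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ontology_a": out / "ontoA.owl",
            "ontology_b": out / "ontoB.owl",
            "lexicon": out / "lexicon.tsv",
            "vectors": out / "vectors.txt",
            "reference": out / "reference.rdf",
        }
        _write_owl(self.ontology_a, paths["ontology_a"])
        _write_owl(self.ontology_b, paths["ontology_b"])
        with open(paths["lexicon"], "w", encoding="utf-8") as fh:
            for left, right in self.lexicon_rows:
                fh.write(f"{left}\t{right}\n")
        from .embeddings import save_word_vectors

        save_word_vectors(self.table, paths["vectors"])
        ref = AlignmentSet(
            [Correspondence(a, b, 1.0) for a, b in self.ground_truth]
        )
        ref.write_rdf(paths["reference"])
        return paths


def _write_owl(onto: Ontology, path: Path) -> None:
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"',
        '         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"',
        '         xmlns:owl="http://www.w3.org/2002/07/owl#">',
        f'  <owl:Ontology rdf:about="http://example.org/fixture/{escape(onto.name)}"/>',
    ]
    for rec in sorted(onto.terms, key=lambda t: t.term_id):
        lines.append(f'  <owl:Class rdf:about="{escape(rec.term_id)}">')
        lines.append(f"    <rdfs:label>{escape(rec.raw_text)}</rdfs:label>")
        for extra in sorted(onto.extra_labels.get(rec.term_id, [])):
            lines.append(f"    <rdfs:label>{escape(extra)}</rdfs:label>")
        lines.append("  </owl:Class>")
    lines += ["</rdf:RDF>", ""]
    path.write_text("\n".join(lines), encoding="utf-8")


def _orthonormal_noise(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    w = rng.normal(size=u.shape)
    w -= (w @ u) * u
    n = np.linalg.norm(w)
    return w / n


def generate_fixture(config: FixtureConfig, out_dir: str | Path | None = None) -> Fixture:
    """Build a matched ontology pair with planted synonym and confounder
    structure; optionally serialise it under ``out_dir``.

    Per concept ``c``: a unit direction ``u_c``; each phrase of the
    concept gets fresh words drawn as ``u_c + noise``; phrases alternate
    between ontology A (even ranks, rank 0 the preferred label) and B.
    One extra "bridge" phrase per covered concept appears only in the
    lexicon, mapped from both sides' full phrases — so the lexicon links
    the two sides only transitively, never exposing a ground-truth pair.
    For the confounded concepts, a distinct partner concept's direction
    is re-planted at cosine ``confounder_cos`` to theirs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_concepts, cfg.dim

    # concept classes: "easy" concepts share a head word across all their
    # phrases (most real cross-ontology matches share tokens); "hard" ones
    # share nothing and are held together only by vector geometry and the
    # lexicon; rare-word (oov) concepts — drawn from the hard class — have
    # one ontology phrase built entirely from words missing from the
    # table, emulating domain terms the pre-training corpus barely saw
    # (they receive the random OOV initialisation downstream)
    perm = rng.permutation(n)
    n_hard = int(round(cfg.hard_fraction * n))
    hard_concepts = set(perm[:n_hard].tolist())
    oov_concepts = set(perm[: int(round(cfg.oov_fraction * n))].tolist())

    # concept directions live in a low-rank semantic subspace (word-vector
    # spaces confine a domain's terms to a cone of modest rank) while word
    # noise is isotropic in the full space — the separation the DAE's
    # hidden representation exploits
    r = min(cfg.concept_rank, d)
    basis, _ = np.linalg.qr(rng.normal(size=(d, r)))
    basis = basis.T  # r x d, orthonormal rows

    def subspace_dir(vec_r: np.ndarray) -> np.ndarray:
        return (vec_r / np.linalg.norm(vec_r)) @ basis

    U = np.stack([subspace_dir(rng.normal(size=r)) for _ in range(n)])
    # plant confounders within each class (a hard concept's descriptive
    # associate is itself a hard concept, at the deeper planted cosine)
    k = int(round(cfg.confounder_fraction * n))
    raw_hard = perm[:n_hard].tolist()
    n_oov = int(round(cfg.oov_fraction * n))
    # interleave rare-word and ordinary hard concepts so confounding hits
    # both kinds of anchor (rare-word terms re-embedded by retrofitting
    # next to an associate are the filter stage's hardest cases)
    hard_list = [c for pair in zip(raw_hard[:n_oov], raw_hard[n_oov:]) for c in pair]
    hard_list += [c for c in raw_hard if c not in hard_list]
    easy_list = perm[n_hard:].tolist()
    k_hard = min(int(round(k * n_hard / n)), len(hard_list) // 2)
    k_easy = min(k - k_hard, len(easy_list) // 2)
    confounder_partner: dict[int, int] = {}
    for pool, kc, cc in (
        (hard_list, k_hard, cfg.confounder_cos_hard),
        (easy_list, k_easy, cfg.confounder_cos),
    ):
        for idx in range(kc):
            i, j = pool[idx], pool[len(pool) - 1 - idx]
            u_r = basis @ U[i]
            w_r = rng.normal(size=r)
            w_r -= (w_r @ u_r) * u_r
            w_r /= np.linalg.norm(w_r)
            U[j] = (cc * u_r + np.sqrt(1.0 - cc**2) * w_r) @ basis
            confounder_partner[i] = j

    wpp = cfg.words_per_phrase
    n_phr = cfg.phrases_per_concept + cfg.bridges_per_concept
    vocab: dict[str, int] = {}
    rows: list[np.ndarray] = []

    def draw_word(concept: int, name: str, in_table: bool) -> str:
        word = f"c{concept:03d}{name}"
        if in_table:
            vocab[word] = len(rows)
            rows.append(U[concept] + rng.normal(0.0, cfg.similarity_noise, size=d))
        else:
            rng.normal(0.0, cfg.similarity_noise, size=d)  # keep the stream aligned
        return word

    # easy-class confounded pairs share their head word outright — the
    # "tract"/"joint"/"muscle" pattern: one generic surface token used by
    # two distinct concepts, with a vector pulled toward both (its corpus
    # contexts mix the two).  Such pairs stay lexically close through
    # retrofitting and are the outlier filter's natural prey.
    shared_head: dict[int, str] = {}
    for idx in range(k_easy):
        i, j = easy_list[idx], easy_list[len(easy_list) - 1 - idx]
        word = f"g{i:03d}head"
        mid = U[i] + U[j]
        vocab[word] = len(rows)
        rows.append(mid / np.linalg.norm(mid) + rng.normal(0.0, cfg.similarity_noise, size=d))
        shared_head[i] = word
        shared_head[j] = word

    phrases: list[list[Tokens]] = []
    for c in range(n):
        hard = c in hard_concepts
        oov_side = (c % 2) if c in oov_concepts else None
        if hard:
            head = None
        else:
            head = shared_head.get(c) or draw_word(c, "head", True)
        ph: list[Tokens] = []
        for p in range(n_phr):
            side = p % 2  # phrases alternate between the A (0) and B (1) side
            in_table = oov_side is None or side != oov_side or p >= cfg.phrases_per_concept
            fill = wpp - (0 if hard else 1)
            toks = tuple(draw_word(c, f"p{p}w{q}", in_table) for q in range(fill))
            if hard:
                # hard-concept bridges borrow their side's first phrase word,
                # the way real lexicon paraphrases share surface tokens
                if p >= cfg.phrases_per_concept:
                    toks = (ph[side][0],) + toks[1:]
            else:
                toks = (head,) + toks
            ph.append(toks)
        phrases.append(ph)

    # leftover concepts present on one side only, in cross-side
    # descriptively-associated pairs (shared generic head, related
    # directions); stable marriage will be forced to pair them up
    n_unmatched = int(round(cfg.unmatched_fraction * n))
    stray_phrases: dict[int, dict[str, Tokens]] = {}
    for x in range(n_unmatched):
        v1_r = rng.normal(size=r)
        v1_r /= np.linalg.norm(v1_r)
        w_r = rng.normal(size=r)
        w_r -= (w_r @ v1_r) * v1_r
        w_r /= np.linalg.norm(w_r)
        v2_r = cfg.confounder_cos * v1_r + np.sqrt(1.0 - cfg.confounder_cos**2) * w_r
        v1, v2 = v1_r @ basis, v2_r @ basis
        head = f"s{x:03d}head"
        mid = v1 + v2
        vocab[head] = len(rows)
        rows.append(mid / np.linalg.norm(mid) + rng.normal(0.0, cfg.similarity_noise, size=d))
        toks = {}
        for side, v in (("A", v1), ("B", v2)):
            spec = f"s{x:03d}{side.lower()}"
            vocab[spec] = len(rows)
            rows.append(v + rng.normal(0.0, cfg.similarity_noise, size=d))
            toks[side] = (head, spec)
        stray_phrases[x] = toks

    # filler vocabulary nowhere used in terms, as in any real vector table
    need = len(rows)
    extra = (cfg.vocab_size - need) if cfg.vocab_size else max(0, 2 * n - need)
    for x in range(extra):
        word = f"filler{x:04d}"
        vocab[word] = len(rows)
        v = rng.normal(size=d)
        rows.append(v / np.linalg.norm(v))

    table = WordVectorTable(vocab, np.asarray(rows))

    def make_onto(name: str, parity: int) -> Ontology:
        terms, extras = [], {}
        for c in range(n):
            own = [phrases[c][p] for p in range(cfg.phrases_per_concept) if p % 2 == parity]
            iri = f"http://example.org/fixture/{name}#concept_{c:03d}"
            text = " ".join(own[0])
            terms.append(TermRecord(iri, text, own[0]))
            if len(own) > 1:
                extras[iri] = [" ".join(p) for p in own[1:]]
        for x, toks in stray_phrases.items():
            iri = f"http://example.org/fixture/{name}#stray_{x:03d}"
            terms.append(TermRecord(iri, " ".join(toks[name]), toks[name]))
        return Ontology(name=name, terms=terms, label_policy="rdfs_label", extra_labels=extras)

    onto_a = make_onto("A", 0)
    onto_b = make_onto("B", 1)
    # strays are deliberately absent from the ground truth: they have no
    # counterpart, so any pairing involving them is a false positive
    ground_truth = [
        (
            f"http://example.org/fixture/A#concept_{c:03d}",
            f"http://example.org/fixture/B#concept_{c:03d}",
        )
        for c in range(n)
    ]

    easy = [c for c in range(n) if c not in hard_concepts]
    hard = sorted(hard_concepts)
    covered = set()
    for pool, frac in ((easy, cfg.lexicon_coverage), (hard, cfg.lexicon_coverage_hard)):
        take = int(round(frac * len(pool)))
        covered.update(np.asarray(pool)[rng.permutation(len(pool))[:take]].tolist())
    lexicon = SynonymLexicon()
    lexicon_rows: list[tuple[str, str]] = []
    for c in sorted(covered):
        for bi in range(cfg.bridges_per_concept):
            bridge = phrases[c][cfg.phrases_per_concept + bi]
            for p in range(cfg.phrases_per_concept):
                left, right = " ".join(phrases[c][p]), " ".join(bridge)
                lexicon.add(phrases[c][p], bridge)
                lexicon_rows.append((left, right))

    fixture = Fixture(
        cfg, onto_a, onto_b, lexicon, table, ground_truth, lexicon_rows,
        confounder_partner, hard_concepts, oov_concepts,
    )
    if out_dir is not None:
        fixture.write(out_dir)
    return fixture
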