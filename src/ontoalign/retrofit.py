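"""Phrase retrofitting: Siamese CBOW with tempered softmax + distillation.

Pre-trained word vectors ``V`` are adjusted into ``V'`` by minimising

    kappa_S * L_S(V') + kappa_LD * L_KD(V, V')

where ``L_S`` is the categorical cross-entropy between a tempered softmax
over an anchor phrase's cosine similarities to its positive (paraphrase)
and negative (descriptively associated) examples and a target that puts
uniform mass on the positives, and ``L_KD`` is the cross-entropy against
the "soft targets" produced by the *initial* vectors — a knowledge
distillation regulariser that penalises large departures from the
pre-trained semantics.

Negative examples are the nearest terms of the two ontologies under the
initial vectors, skipping the ``n_star`` closest (likely true matches);
they are sampled once before training starts.

Gradients are derived analytically and optimised with Adam; only the
vectors of words that occur in some instance are ever touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .embeddings import WordVectorTable, sentence_embedding
from .lexicon import SynonymLexicon, harvest_paraphrases
from .ontology_io import TermRecord

log = logging.getLogger(__name__)

Tokens = tuple[str, ...]
_EPS = 1e-12  # clamp inside logs


@dataclass(frozen=True)
class TrainingInstance:
    """Anchor phrase with its paraphrases (S+) and descriptively
    associated terms (S-); examples are ordered positives first."""

    anchor: Tokens
    positives: tuple[Tokens, ...]
    negatives: tuple[Tokens, ...]

    def __post_init__(self):
        if not self.positives:
            raise ValueError("instance needs at least one positive example")
        pos, neg = set(self.positives), set(self.negatives)
        if self.anchor in pos or self.anchor in neg:
            raise ValueError("anchor must not appear among its examples")
        if pos & neg:
            raise ValueError("positives and negatives must be disjoint")

    @property
    def examples(self) -> tuple[Tokens, ...]:
        return self.positives + self.negatives


@dataclass
class RetrofitConfig:
    """Hyperparameters; defaults are the tuned values of the method."""

    kappa_s: float = 1e6
    kappa_ld: float = 1e3
    temperature: float = 2.0
    n_star: int = 2
    n_neg: int = 7
    epochs: int = 15
    learning_rate: float = 0.01
    grad_clip: float = 1.0
    batch_size: int = 32
    seed: int = 0
    softmax_form: Literal["standard", "literal"] = "standard"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


# ---------------------------------------------------------------------------
# losses


def target_distribution(n_pos: int, n_neg: int) -> np.ndarray:
    """Uniform 1/|S+| over positive slots, 0 over negative slots."""
    if n_pos < 1:
        raise ValueError("an instance without positive examples is unusable")
    if n_neg < 0:
        raise ValueError("n_neg must be >= 0")
    p = np.zeros(n_pos + n_neg)
    p[:n_pos] = 1.0 / n_pos
    return p


def _logits(cosines: np.ndarray, T: float, form: str) -> np.ndarray:
    if T <= 0:
        raise ValueError("temperature must be > 0")
    c = np.asarray(cosines, dtype=np.float64)
    if form == "standard":
        return c / T
    if form == "literal":
        # printed form cos^(1/T); undefined for cos < 0, clamped to 0
        return np.clip(c, 0.0, None) ** (1.0 / T)
    raise ValueError(f"unknown softmax form {form!r}")


def tempered_softmax(
    anchor_emb: np.ndarray,
    example_embs: Sequence[np.ndarray],
    T: float = 2.0,
    form: str = "standard",
) -> np.ndarray:
    """Probability over examples from the softmax of tempered cosines.

    Default semantics divide the cosine by the temperature, ``exp(cos/T)``
    (flattening the distribution, so small-logit information counts); the
    ``literal`` form ``exp(max(cos,0)^(1/T))`` is kept for comparison.
    """
    a = np.asarray(anchor_emb, dtype=np.float64)
    na = np.linalg.norm(a)
    if na == 0.0:
        raise ValueError("zero anchor embedding")
    cos = np.empty(len(example_embs))
    for j, e in enumerate(example_embs):
        e = np.asarray(e, dtype=np.float64)
        ne = np.linalg.norm(e)
        if ne == 0.0:
            raise ValueError("zero example embedding")
        cos[j] = float(a @ e) / (na * ne)
    z = _logits(cos, T, form)
    z = z - z.max()  # shift-invariant, numerically safe
    ez = np.exp(z)
    return ez / ez.sum()


def cross_entropy(target: np.ndarray, predicted: np.ndarray) -> float:
    """``-sum(target * log(predicted))`` with an epsilon clamp in the log."""
    return float(-np.sum(np.asarray(target) * np.log(np.clip(predicted, _EPS, None))))


def _instance_embeddings(inst: TrainingInstance, table: WordVectorTable):
    a = sentence_embedding(inst.anchor, table)
    es = [sentence_embedding(e, table) for e in inst.examples]
    return a, es


def _predicted(inst: TrainingInstance, table: WordVectorTable, T: float, form: str) -> np.ndarray:
    a, es = _instance_embeddings(inst, table)
    return tempered_softmax(a, es, T, form)


def similarity_loss(
    inst: TrainingInstance,
    table: WordVectorTable,
    T: float = 2.0,
    form: str = "standard",
) -> float:
    """Cross-entropy of the model distribution against the uniform-on-
    positives target; bounded below by the target's entropy."""
    q = target_distribution(len(inst.positives), len(inst.negatives))
    return cross_entropy(q, _predicted(inst, table, T, form))


def distillation_loss(
    inst: TrainingInstance,
    table: WordVectorTable,
    initial_table: WordVectorTable,
    T: float = 2.0,
    form: str = "standard",
) -> float:
    """Cross-entropy against the soft targets of the initial vectors."""
    q = _predicted(inst, initial_table, T, form)
    return cross_entropy(q, _predicted(inst, table, T, form))


def total_objective(
    instances: Sequence[TrainingInstance],
    table: WordVectorTable,
    initial_table: WordVectorTable,
    config: RetrofitConfig,
    soft_targets: Sequence[np.ndarray] | None = None,
) -> float:
    """``kappa_S * L_S + kappa_LD * L_KD`` averaged over the instances."""
    if not instances:
        raise ValueError("no training instances")
    ls = 0.0
    lkd = 0.0
    for k, inst in enumerate(instances):
        p = _predicted(inst, table, config.temperature, config.softmax_form)
        q = target_distribution(len(inst.positives), len(inst.negatives))
        qi = (
            soft_targets[k]
            if soft_targets is not None
            else _predicted(inst, initial_table, config.temperature, config.softmax_form)
        )
        ls += cross_entropy(q, p)
        lkd += cross_entropy(qi, p)
    n = len(instances)
    return config.kappa_s * ls / n + config.kappa_ld * lkd / n


# ---------------------------------------------------------------------------
# negative sampling & instance construction


def sample_negatives(
    anchor: Tokens,
    candidates: Sequence[TermRecord],
    table: WordVectorTable,
    n_star: int = 2,
    n_neg: int = 7,
) -> list[Tokens]:
    """The ``n_neg`` terms nearest to the anchor under the *initial*
    vectors, skipping the ``n_star`` closest (possible true alignments).

    Candidates are ranked by increasing cosine distance of their averaged
    embeddings to the anchor's, ties broken by term_id; ranks
    ``[n_star, n_star + n_neg)`` are returned.  Run once before training.
    """
    a = sentence_embedding(anchor, table)
    na = np.linalg.norm(a)
    scored: list[tuple[float, str, Tokens]] = []
    for rec in candidates:
        if rec.degenerate:
            continue
        try:
            e = sentence_embedding(rec.tokens, table)
        except ValueError:
            continue
        ne = np.linalg.norm(e)
        if ne == 0.0 or na == 0.0:
            continue
        dist = 1.0 - float(a @ e) / (na * ne)
        scored.append((dist, rec.term_id, tuple(rec.tokens)))
    scored.sort(key=lambda t: (t[0], t[1]))
    window = scored[n_star : n_star + n_neg]
    if len(window) < n_neg:
        log.warning(
            "only %d candidates beyond rank %d for anchor %s (wanted %d)",
            len(window), n_star, " ".join(anchor), n_neg,
        )
    return [toks for _, _, toks in window]


def build_training_instances(
    terms: Sequence[TermRecord],
    lexicon: SynonymLexicon,
    initial_table: WordVectorTable,
    config: RetrofitConfig | None = None,
    max_paraphrases: int = 20,
) -> list[TrainingInstance]:
    """One instance per term with at least one paraphrase.

    ``terms`` should contain the terms of *both* ontologies: every term is
    a negative-sampling candidate, but only terms the lexicon covers
    become anchors.  Negatives that coincide with the anchor or one of its
    positives are dropped (they would violate the instance invariants).
    """
    cfg = config or RetrofitConfig()
    out: list[TrainingInstance] = []
    for rec in terms:
        if rec.degenerate:
            continue
        pos = harvest_paraphrases(rec, lexicon, max_paraphrases)
        pos.discard(tuple(rec.tokens))
        if not pos:
            continue
        # a term is not a descriptive associate of itself: the n_star
        # exclusion window is meant for the closest *potential alignments*
        candidates = [t for t in terms if t.term_id != rec.term_id]
        try:
            neg = sample_negatives(
                tuple(rec.tokens), candidates, initial_table, cfg.n_star, cfg.n_neg
            )
        except ValueError:
            log.warning("no usable vectors for anchor %s; instance skipped", rec.term_id)
            continue
        positives = tuple(sorted(pos))
        seen = set(positives) | {tuple(rec.tokens)}
        negatives = []
        for nt in neg:
            if nt not in seen:
                negatives.append(nt)
                seen.add(nt)
        out.append(TrainingInstance(tuple(rec.tokens), positives, tuple(negatives)))
    return out


# ---------------------------------------------------------------------------
# training


@dataclass
class RetrofitResult:
    table: WordVectorTable
    #: full-data objective before training and after each epoch
    objective_history: list[float] = field(default_factory=list)


def _instance_gradient(
    inst: TrainingInstance,
    table: WordVectorTable,
    soft_target: np.ndarray,
    cfg: RetrofitConfig,
    grads: dict[int, np.ndarray],
) -> float:
    """Accumulate d(kappa_S*CE(q,p) + kappa_LD*CE(qI,p))/dV' into ``grads``
    (keyed by vocab row); returns the instance's weighted loss."""
    a, es = _instance_embeddings(inst, table)
    na = np.linalg.norm(a)
    nes = [np.linalg.norm(e) for e in es]
    cos = np.array([float(a @ e) / (na * ne) for e, ne in zip(es, nes)])
    z = _logits(cos, cfg.temperature, cfg.softmax_form)
    zs = z - z.max()
    ez = np.exp(zs)
    p = ez / ez.sum()

    q = target_distribution(len(inst.positives), len(inst.negatives))
    loss = cfg.kappa_s * cross_entropy(q, p) + cfg.kappa_ld * cross_entropy(soft_target, p)

    # softmax + cross-entropy: dL/dz_j = sum of (p - target) terms
    dz = cfg.kappa_s * (p - q) + cfg.kappa_ld * (p - soft_target)
    if cfg.softmax_form == "standard":
        dc = dz / cfg.temperature
    else:  # literal: z = max(c,0)^(1/T)
        invT = 1.0 / cfg.temperature
        dc = np.where(cos > 0.0, invT * np.clip(cos, _EPS, None) ** (invT - 1.0), 0.0) * dz

    da = np.zeros_like(a)
    for j, (e, ne) in enumerate(zip(es, nes)):
        if dc[j] == 0.0:
            continue
        da += dc[j] * (e / (na * ne) - cos[j] * a / (na * na))
        de = dc[j] * (a / (na * ne) - cos[j] * e / (ne * ne))
        m = len(inst.examples[j])
        for w in inst.examples[j]:
            if w in table.vocab:
                r = table.vocab[w]
                g = grads.get(r)
                if g is None:
                    grads[r] = de / m
                else:
                    g += de / m
    m = len(inst.anchor)
    for w in inst.anchor:
        if w in table.vocab:
            r = table.vocab[w]
            g = grads.get(r)
            if g is None:
                grads[r] = da / m
            else:
                g += da / m
    return loss


def train_retrofit(
    instances: Sequence[TrainingInstance],
    initial_table: WordVectorTable,
    config: RetrofitConfig | None = None,
) -> RetrofitResult:
    """Minimise the retrofitting objective with Adam.

    Soft targets are computed once from the initial table and reused every
    epoch.  Updates are sparse: a word absent from every instance keeps
    its pre-trained vector bit-identically.  The per-minibatch global
    gradient norm is clipped at ``config.grad_clip``.
    """
    cfg = config or RetrofitConfig()
    if not instances:
        raise ValueError("no training instances")
    table = initial_table.copy()

    soft_targets = [
        _predicted(inst, initial_table, cfg.temperature, cfg.softmax_form) for inst in instances
    ]

    n_rows, dim = table.matrix.shape
    m1 = np.zeros((n_rows, dim))
    m2 = np.zeros((n_rows, dim))
    step = np.zeros(n_rows, dtype=np.int64)  # lazy per-row Adam step count

    rng = np.random.default_rng(cfg.seed)
    history = [total_objective(instances, table, initial_table, cfg, soft_targets)]
    order = np.arange(len(instances))
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            grads: dict[int, np.ndarray] = {}
            for k in batch:
                _instance_gradient(instances[k], table, soft_targets[k], cfg, grads)
            if not grads:
                continue
            inv = 1.0 / len(batch)
            gnorm = np.sqrt(sum(float(g @ g) for g in grads.values())) * inv
            scale = inv if gnorm <= cfg.grad_clip else inv * cfg.grad_clip / gnorm
            for r, g in grads.items():
                g = g * scale
                if not np.all(np.isfinite(g)):
                    raise FloatingPointError(
                        "NaN/inf gradient during retrofitting; lower the learning rate"
                    )
                step[r] += 1
                t = step[r]
                m1[r] = cfg.adam_beta1 * m1[r] + (1 - cfg.adam_beta1) * g
                m2[r] = cfg.adam_beta2 * m2[r] + (1 - cfg.adam_beta2) * g * g
                mhat = m1[r] / (1 - cfg.adam_beta1 ** t)
                vhat = m2[r] / (1 - cfg.adam_beta2 ** t)
                table.matrix[r] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.adam_eps)
        obj = total_objective(instances, table, initial_table, cfg, soft_targets)
        if not np.isfinite(obj):
            raise FloatingPointError("objective became non-finite; lower the learning rate")
        history.append(obj)
        log.info("retrofit epoch %d/%d: objective %.6g", epoch + 1, cfg.epochs, obj)
    return RetrofitResult(table, history)
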