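"""End-to-end pipeline: parse -> lexicon -> retrofit -> DAE -> match -> evaluate.

A single run seed is expanded into per-stage seeds (base, base+1, base+2
for OOV initialisation, retrofitting and DAE respectively) so each stage
is independently reproducible with one knob.  A run manifest (config
snapshot, per-stage seeds, SHA-256 digests of the inputs, package
version, timings) is written next to the artefacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._version import __version__ as _version
from .dae import DAEConfig, DAEParams, train_dae
from .embeddings import (
    WordVectorTable,
    init_oov,
    load_word_vectors,
    save_word_vectors,
    sentence_embedding,
)
from .evaluation import EvalResult, load_reference, score
from .lexicon import SynonymLexicon, load_lexicon_tsv, ontology_label_synonyms
from .matching import AlignmentSet, align_ontologies
from .ontology_io import Ontology, parse_ontology
from .retrofit import RetrofitConfig, build_training_instances, train_retrofit

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    source: str = ""
    target: str = ""
    vectors: str = ""
    lexicons: list[str] = field(default_factory=list)
    reference: str | None = None
    label_policy: str = "rdfs_label"
    df_fraction: float = 0.90
    t1: float = 0.2
    t2: float = 0.2
    use_dae: bool = True
    seed: int = 0
    out_dir: str | None = None
    retrofit: RetrofitConfig = field(default_factory=RetrofitConfig)
    dae: DAEConfig = field(default_factory=DAEConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        rf = RetrofitConfig(**raw.pop("retrofit", {}))
        da = DAEConfig(**raw.pop("dae", {}))
        return cls(**raw, retrofit=rf, dae=da)


@dataclass
class PipelineResult:
    alignment: AlignmentSet
    manifest: dict
    evaluation: EvalResult | None = None


def run_ablation(fixture, seed: int, dae_hidden_dim: int = 8) -> dict[str, "EvalResult"]:
    """Feature-ablation study on a generated fixture.

    Runs the matching three ways — pre-trained vectors only ("w2v"),
    retrofitted vectors ("scbow"), retrofitted vectors plus the DAE
    outlier filter ("scbow_dae") — and scores each against the fixture's
    planted ground truth.  All three share the fixture and the seed, so
    differences isolate the contribution of each component.
    """
    from .evaluation import ReferenceAlignment, ReferenceCell

    reference = ReferenceAlignment(
        [ReferenceCell(a, b) for a, b in fixture.ground_truth]
    )
    variants = {
        "w2v": dict(use_dae=False, retrofit=RetrofitConfig(epochs=0)),
        "scbow": dict(use_dae=False, retrofit=RetrofitConfig()),
        "scbow_dae": dict(use_dae=True, retrofit=RetrofitConfig()),
    }
    out = {}
    for name, kw in variants.items():
        cfg = PipelineConfig(seed=seed, dae=DAEConfig(hidden_dim=dae_hidden_dim), **kw)
        res = run_pipeline(
            cfg,
            source=fixture.ontology_a,
            target=fixture.ontology_b,
            table=fixture.table,
            lexicon=fixture.lexicon,
        )
        out[name] = score(res.alignment.pairs(), reference)
    return out


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    *,
    source: Ontology | None = None,
    target: Ontology | None = None,
    table: WordVectorTable | None = None,
    lexicon: SynonymLexicon | None = None,
) -> PipelineResult:
    """Execute the full matching pipeline in its stated stage order.

    Inputs may be passed pre-parsed (fixture objects) or referenced by
    path through the config; every intermediate artefact is persisted
    when ``config.out_dir`` is set.
    """
    manifest: dict = {
        "version": _version,
        "seed": config.seed,
        "stage_seeds": {"oov": config.seed, "retrofit": config.seed + 1, "dae": config.seed + 2},
        "config": {
            **{k: v for k, v in asdict(config).items() if k not in ("retrofit", "dae")},
            "retrofit": asdict(config.retrofit),
            "dae": asdict(config.dae),
        },
        "inputs": {},
        "timings": {},
        "stages_completed": [],
    }
    t0 = time.perf_counter()

    def done(stage: str) -> None:
        manifest["timings"][stage] = round(time.perf_counter() - t0, 4)
        manifest["stages_completed"].append(stage)

    # --- parse -------------------------------------------------------------
    if source is None:
        source = parse_ontology(
            config.source, config.label_policy, df_fraction=config.df_fraction
        )
        manifest["inputs"]["source"] = _digest(config.source)
    if target is None:
        target = parse_ontology(
            config.target, config.label_policy, df_fraction=config.df_fraction
        )
        manifest["inputs"]["target"] = _digest(config.target)
    done("parse")

    # --- lexicon -----------------------------------------------------------
    if lexicon is None:
        lexicon = SynonymLexicon()
        for p in config.lexicons:
            lexicon.merge(load_lexicon_tsv(p))
            manifest["inputs"][f"lexicon:{p}"] = _digest(p)
    else:
        lexicon = SynonymLexicon({k: set(v) for k, v in lexicon.entries.items()})
    # ontology-internal multi-label synonyms, both directions
    for onto in (source, target):
        for pair in ontology_label_synonyms(onto):
            lexicon.add(pair.left, pair.right)
            lexicon.add(pair.right, pair.left)
    done("lexicon")

    # --- vectors + OOV -----------------------------------------------------
    if table is None:
        table = load_word_vectors(config.vectors)
        manifest["inputs"]["vectors"] = _digest(config.vectors)
    table = table.copy()
    term_words = sorted(
        {w for onto in (source, target) for t in onto.terms for w in t.tokens}
    )
    missing = [w for w in term_words if w not in table.vocab]
    if missing:
        log.info("initialising %d out-of-vocabulary word vectors", len(missing))
        for w, v in init_oov(missing, table.dim, config.seed).items():
            table.add(w, v)
    manifest["oov_words"] = len(missing)
    initial_table = table
    done("vectors")

    # --- training instances ------------------------------------------------
    all_terms = [t for onto in (source, target) for t in onto.terms]
    rf_cfg = RetrofitConfig(**{**asdict(config.retrofit), "seed": config.seed + 1})
    instances = build_training_instances(all_terms, lexicon, initial_table, rf_cfg)
    manifest["n_instances"] = len(instances)
    done("instances")

    # --- retrofit ----------------------------------------------------------
    if instances and rf_cfg.epochs > 0:
        result = train_retrofit(instances, initial_table, rf_cfg)
        retrofitted = result.table
        manifest["retrofit_objective"] = [float(x) for x in result.objective_history]
    else:
        retrofitted = initial_table
        log.warning("no training instances (or 0 epochs); using initial vectors")
    done("retrofit")

    # --- DAE ---------------------------------------------------------------
    dae_params: DAEParams | None = None
    if config.use_dae and instances:
        pairs = []
        for inst in instances:
            a = sentence_embedding(inst.anchor, retrofitted)
            for pos in inst.positives:
                try:
                    pairs.append((a, sentence_embedding(pos, retrofitted)))
                except ValueError:
                    continue
        # the DAE sees only paraphrase pairs: its hidden code models the
        # manifold of synonym-pair embeddings, and terms far from that
        # manifold (no paraphrase support) are exactly the ones the
        # outlier score should flag
        if pairs:
            dae_cfg = DAEConfig(**{**asdict(config.dae), "seed": config.seed + 2})
            dae_params, dae_hist = train_dae(pairs, dae_cfg)
            manifest["dae_loss"] = [float(x) for x in dae_hist]
    done("dae")

    # --- match + filter ----------------------------------------------------
    alignment = align_ontologies(
        source, target, retrofitted, dae_params, config.t1, config.t2
    )
    manifest["n_alignments"] = len(alignment)
    done("match")

    # --- evaluate ----------------------------------------------------------
    evaluation: EvalResult | None = None
    if config.reference:
        reference = load_reference(config.reference)
        manifest["inputs"]["reference"] = _digest(config.reference)
        evaluation = score(alignment.pairs(), reference)
        manifest["evaluation"] = evaluation.as_dict()
        done("evaluate")

    # --- persist -----------------------------------------------------------
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        alignment.write_tsv(out / "alignment.tsv")
        alignment.write_rdf(out / "alignment.rdf")
        save_word_vectors(retrofitted, out / "retrofitted_vectors.txt")
        if dae_params is not None:
            dae_params.save(out / "dae.npz")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(alignment, manifest, evaluation)
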