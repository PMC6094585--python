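"""Train the denoising autoencoder and score pairs with its hidden code.

The DAE reconstructs both a phrase embedding and one of its paraphrases
from a corrupted input; the cosine distance between two terms' hidden
codes is an outlier score for a proposed correspondence.
"""

import numpy as np

from ontoalign import FixtureConfig, generate_fixture
from ontoalign.dae import DAEConfig, dae_distance, train_dae
from ontoalign.embeddings import init_oov, sentence_embedding
from ontoalign.retrofit import RetrofitConfig, build_training_instances, train_retrofit

fx = generate_fixture(FixtureConfig(n_concepts=20, confounder_fraction=0.4, seed=7))
terms = {t.term_id: t for o in (fx.ontology_a, fx.ontology_b) for t in o.terms}

table = fx.table.copy()
missing = [w for w in sorted({w for t in terms.values() for w in t.tokens}) if w not in table.vocab]
for w, v in init_oov(missing, table.dim, seed=7).items():
    table.add(w, v)

cfg = RetrofitConfig(seed=8)
instances = build_training_instances(list(terms.values()), fx.lexicon, table, cfg)
retrofitted = train_retrofit(instances, table, cfg).table

pairs = []
for inst in instances:
    anchor = sentence_embedding(inst.anchor, retrofitted)
    for pos in inst.positives:
        pairs.append((anchor, sentence_embedding(pos, retrofitted)))
print(f"training the DAE on {len(pairs)} paraphrase-embedding pairs")
params, history = train_dae(pairs, DAEConfig(hidden_dim=8, seed=9))
print(f"mean reconstruction loss: {history[1]:.2f} -> {history[-1]:.2f}")


def emb(tid):
    return sentence_embedding(terms[tid].tokens, retrofitted)


same = [dae_distance(emb(a), emb(b), params) for a, b in fx.ground_truth
        if all(w in retrofitted.vocab for w in terms[a].tokens + terms[b].tokens)]
conf = []
for i, j in fx.confounder_partner.items():
    a = f"http://example.org/fixture/A#concept_{i:03d}"
    b = f"http://example.org/fixture/B#concept_{j:03d}"
    if all(w in retrofitted.vocab for w in terms[a].tokens + terms[b].tokens):
        conf.append(dae_distance(emb(a), emb(b), params))

print(f"\nhidden-code distance, matched pairs:    mean {np.mean(same):.3f}")
print(f"hidden-code distance, confounder pairs: mean {np.mean(conf):.3f}")
# Matched pairs should score lower on average than planted confounder
# pairs: the code has absorbed what paraphrases share.
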