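# ontoalign

Ontology alignment through representation learning: retrofit pre-trained
word vectors so that averaged phrase embeddings capture *semantic
similarity* rather than mere descriptive association, match two
ontologies' terms by casting the problem as a stable marriage over cosine
distances, and prune misalignments with a denoising-autoencoder outlier
detector.

The package is aimed at terminology-integration work — aligning two
overlapping biomedical (or other domain) ontologies whose classes carry
textual labels — and at anyone studying the similarity-vs-relatedness
problem in phrase embeddings.  It ships a synthetic benchmark generator,
so every stage can be exercised end to end without external downloads.

## The method

Each ontology class is a bag of tokens `sen_i = {w_1 … w_m}` (from
`rdfs:label` or the IRI fragment, after case-folding, stopword and
high-document-frequency-word removal).  Its embedding `s_i` is the mean
of the word vectors; distances are `dis(s_i, s_j) = 1 − cos(s_i, s_j)`.

**Phrase retrofitting.**  Pre-trained vectors `V` are adjusted into `V′`
by minimising

    κ_S · L_S(V′) + κ_LD · L_KD(V, V′)

where, per training instance (an anchor term, its paraphrase set `S⁺`
from a synonym lexicon and multi-label synonyms, and a set `S⁻` of
descriptively associated terms sampled once from the nearest terms of
both ontologies, skipping the `n*` closest),

* `L_S` is the categorical cross-entropy between a tempered softmax
  `p_θ(s_i, s_j) ∝ exp(cos(s_i, s_j)/T)` over `S⁺ ∪ S⁻` and the target
  that puts `1/|S⁺|` on each paraphrase and 0 on each associate, and
* `L_KD` is a knowledge-distillation term: cross-entropy against the
  "soft targets" the *initial* vectors produce, penalising large
  departures from the pre-trained semantics.

Defaults: `κ_S = 10⁶`, `κ_LD = 10³`, `T = 2`, `n* = 2`, `n = 7`,
15 epochs of Adam (lr 0.01, gradient clipping at 1).  Out-of-vocabulary
words are initialised from Normal(0, 0.01).

**Matching.**  The two term sets rank each other by embedding distance
and the Gale–Shapley procedure (unequal-set extension, smaller side
proposing) returns a one-to-one matching with no blocking pair.
Correspondences with distance above `t1 = 0.2` are discarded;
confidence is the clamped cosine similarity.

**Outlier filtering.**  A denoising autoencoder
(`h = relu(Wx̃ + b)`, `z = sigmoid(W′h + b′)`, hidden size 32,
corruption `v = 0.4`, 15 epochs of Adadelta) is trained — after
retrofitting — to reconstruct both a phrase embedding and one of its
paraphrases from a corrupted input.  The cosine distance between two
terms' hidden codes is the outlier score; pairs above `t2 = 0.2` are
discarded.

## Worked example

```
$ python examples/05_ablation_study.py
variant      precision    recall        F1
w2v              0.564     0.550     0.557
scbow            0.722     0.650     0.684
scbow_dae        0.735     0.625     0.676
```

On a generated 40-concept benchmark with 40 % planted
descriptively-associated confounders, matching with raw pre-trained
vectors (`w2v`) reaches F1 0.557: terms built from rare words the
vector table lacks cannot be matched at all, and confounded concepts
cross-match.  Retrofitting (`scbow`) pulls rare-word terms to their
paraphrases and separates planted associates, lifting F1 to 0.684.
The DAE filter (`scbow_dae`) trades a little recall for precision
(0.722 → 0.735) on the surviving pairs.

The other examples show each capability in isolation: fixture
generation (`01`), retrofitting distances before/after (`02`),
hidden-code outlier scores (`03`), and the full pipeline with
clustered evaluation (`04`).

A thin CLI mirrors the library:

```
ontoalign make-fixture --n-concepts 40 --confounders 0.4 --seed 7 --out fix/
ontoalign align --source fix/ontoA.owl --target fix/ontoB.owl \
    --vectors fix/vectors.txt --t1 0.2 --t2 0.2 --out aln.rdf
ontoalign evaluate --alignment aln.rdf --reference fix/reference.rdf
```

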