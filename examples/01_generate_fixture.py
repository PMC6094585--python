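"""Generate a synthetic ontology-matching benchmark.

Builds two small ontologies that name the same 20 latent concepts with
disjoint phrases, a synonym lexicon linking some of those phrases, and a
"pre-trained" word-vector table in which 40% of concepts have a planted
descriptively-associated partner (the horse/harness pattern).  All five
artefacts are written in the standard formats the pipeline reads.
"""

from pathlib import Path

from ontoalign import FixtureConfig, generate_fixture

out = Path("scratch/example_fixture")
cfg = FixtureConfig(n_concepts=20, dim=16, confounder_fraction=0.4, seed=7)
fx = generate_fixture(cfg, out)

print(f"ontology A: {len(fx.ontology_a.terms)} terms (incl. unmatched strays)")
print(f"ontology B: {len(fx.ontology_b.terms)} terms")
print(f"lexicon:    {len(fx.lexicon)} phrases with paraphrases")
print(f"vectors:    {len(fx.table)} words, dim {fx.table.dim}")
print(f"ground truth: {len(fx.ground_truth)} one-to-one equivalences")
print(f"planted confounder pairs: {sorted(fx.confounder_partner.items())}")
print(f"rare-word (OOV) concepts: {sorted(fx.oov_concepts)}")
print(f"files written under {out}/")
# The confounder pairs are concepts whose words were deliberately placed
# near each other's directions: a matcher that trusts raw vector
# similarity will confuse them; the OOV concepts have one side's phrase
# missing from the vector table entirely.
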