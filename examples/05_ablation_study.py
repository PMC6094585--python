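"""Component ablation: pre-trained vectors vs retrofitting vs + outlier filter.

Reproduces the package's headline comparison on one fixture seed: the
matcher run with raw pre-trained vectors (w2v), with retrofitted vectors
(scbow), and with retrofitted vectors plus the DAE outlier filter
(scbow_dae).
"""

from ontoalign import FixtureConfig, generate_fixture, run_ablation

fx = generate_fixture(FixtureConfig(n_concepts=40, confounder_fraction=0.4, seed=1))
results = run_ablation(fx, seed=1, dae_hidden_dim=8)

print(f"{'variant':<12}{'precision':>10}{'recall':>10}{'F1':>10}")
for name, res in results.items():
    print(f"{name:<12}{res.precision:>10.3f}{res.recall:>10.3f}{res.f1:>10.3f}")
# The retrofitted variant recovers rare-word terms the baseline cannot
# match and separates planted descriptive associates, so its F1 should
# clearly exceed the raw-vector baseline; the DAE filter then trades a
# little recall for precision on the surviving pairs.
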