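import math

import numpy as np
import pytest

from ontoalign.embeddings import WordVectorTable, sentence_embedding
from ontoalign.ontology_io import TermRecord
from ontoalign.retrofit import (
    RetrofitConfig,
    TrainingInstance,
    cross_entropy,
    distillation_loss,
    sample_negatives,
    similarity_loss,
    target_distribution,
    tempered_softmax,
    total_objective,
    train_retrofit,
)


def entropy(p):
    p = np.asarray(p)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


class TestTargetDistribution:
    def test_two_pos_two_neg(self):
        assert np.array_equal(target_distribution(2, 2), [0.5, 0.5, 0.0, 0.0])

    def test_single_positive(self):
        assert np.array_equal(target_distribution(1, 0), [1.0])

    def test_four_pos_three_neg(self):
        assert np.array_equal(target_distribution(4, 3), [0.25] * 4 + [0.0] * 3)

    def test_no_positive_is_error(self):
        with pytest.raises(ValueError):
            target_distribution(0, 3)

    @pytest.mark.parametrize("n_pos,n_neg", [(1, 1), (3, 7), (5, 0)])
    def test_sums_to_one(self, n_pos, n_neg):
        assert target_distribution(n_pos, n_neg).sum() == pytest.approx(1.0)


class TestTemperedSoftmax:
    def test_equal_cosines_uniform(self):
        a = np.array([1.0, 0.0])
        embs = [np.array([1.0, 0.0])] * 4
        assert np.allclose(tempered_softmax(a, embs, T=2.0), 0.25)

    def test_t1_is_standard_softmax(self):
        a = np.array([1.0, 0.0])
        embs = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        p = tempered_softmax(a, embs, T=1.0)
        want = np.exp([1.0, 0.0]) / np.exp([1.0, 0.0]).sum()
        assert np.allclose(p, want)

    def test_t2_halves_logits(self):
        a = np.array([1.0, 0.0])
        embs = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        p = tempered_softmax(a, embs, T=2.0)
        want = np.exp([0.5, 0.0]) / np.exp([0.5, 0.0]).sum()
        assert np.allclose(p, want)

    def test_literal_form_clamps_negative_cosines(self):
        a = np.array([1.0, 0.0])
        embs = [np.array([-1.0, 0.0]), np.array([0.0, 1.0])]
        p = tempered_softmax(a, embs, T=2.0, form="literal")
        # both logits clamp to 0 -> uniform
        assert np.allclose(p, 0.5)

    def test_zero_embedding_error(self):
        with pytest.raises(ValueError):
            tempered_softmax(np.zeros(2), [np.ones(2)])

    def test_sums_to_one_tightly(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(size=6)
            embs = [rng.normal(size=6) for _ in range(9)]
            assert abs(tempered_softmax(a, embs).sum() - 1.0) < 1e-9


@pytest.fixture()
def toy_world():
    """Deterministic word vectors plus one instance: 2 positives, 2 negatives."""
    rng = np.random.default_rng(7)
    words = [f"w{i}" for i in range(10)]
    table = WordVectorTable({w: i for i, w in enumerate(words)}, rng.normal(size=(10, 6)))
    inst = TrainingInstance(
        anchor=("w0", "w1"),
        positives=(("w2",), ("w3", "w4")),
        negatives=(("w5",), ("w6", "w7")),
    )
    return table, inst


class TestLosses:
    def test_similarity_loss_at_least_target_entropy(self, toy_world):
        table, inst = toy_world
        q = target_distribution(2, 2)
        assert similarity_loss(inst, table) >= entropy(q) - 1e-12

    def test_cross_entropy_equality_iff_match(self):
        q = np.array([0.5, 0.5, 0.0, 0.0])
        assert cross_entropy(q, q) == pytest.approx(math.log(2))
        assert cross_entropy(q, np.array([0.4, 0.4, 0.1, 0.1])) > math.log(2)

    def test_uniform_prediction_single_positive(self):
        q = np.zeros(5)
        q[0] = 1.0
        p = np.full(5, 0.2)
        assert cross_entropy(q, p) == pytest.approx(math.log(5))

    def test_distillation_equals_entropy_at_initial_params(self, toy_world):
        table, inst = toy_world
        from ontoalign.retrofit import _predicted

        p_init = _predicted(inst, table, 2.0, "standard")
        assert distillation_loss(inst, table, table) == pytest.approx(entropy(p_init))

    def test_distillation_gibbs_inequality(self, toy_world):
        table, inst = toy_world
        from ontoalign.retrofit import _predicted

        p_init = _predicted(inst, table, 2.0, "standard")
        floor = entropy(p_init)
        rng = np.random.default_rng(12)
        for _ in range(20):
            other = table.copy()
            other.matrix = other.matrix + rng.normal(0, 0.5, other.matrix.shape)
            assert distillation_loss(inst, other, table) >= floor - 1e-9

    def test_total_objective_recombines_components(self, toy_world):
        table, inst = toy_world
        cfg = RetrofitConfig(kappa_s=1e6, kappa_ld=1e3)
        got = total_objective([inst], table, table, cfg)
        want = 1e6 * similarity_loss(inst, table) + 1e3 * distillation_loss(inst, table, table)
        assert got == pytest.approx(want, rel=1e-12)

    def test_kappa_s_zero_minimized_at_initial(self, toy_world):
        table, inst = toy_world
        cfg = RetrofitConfig(kappa_s=0.0, kappa_ld=1.0)
        at_init = total_objective([inst], table, table, cfg)
        rng = np.random.default_rng(3)
        for _ in range(10):
            other = table.copy()
            other.matrix = other.matrix + rng.normal(0, 0.3, other.matrix.shape)
            assert total_objective([inst], other, table, cfg) >= at_init - 1e-9

    def test_moving_positives_closer_reduces_similarity_loss(self):
        table = WordVectorTable(
            {"a": 0, "p": 1, "n": 2},
            np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]]),
        )
        inst = TrainingInstance(("a",), (("p",),), (("n",),))
        before = similarity_loss(inst, table)
        closer = table.copy()
        closer.matrix[1] = [0.9, 0.1]  # positive rotated toward the anchor
        assert similarity_loss(inst, closer) < before


class TestInstanceInvariants:
    def test_anchor_not_among_examples(self):
        with pytest.raises(ValueError):
            TrainingInstance(("a",), (("a",),), ())

    def test_positive_negative_disjoint(self):
        with pytest.raises(ValueError):
            TrainingInstance(("a",), (("b",),), (("b",),))

    def test_requires_positive(self):
        with pytest.raises(ValueError):
            TrainingInstance(("a",), (), (("b",),))


class TestSampleNegatives:
    def _records(self, table):
        return [TermRecord(f"http://x#{w}", w, (w,)) for w in table.vocab]

    def test_rank_window(self, tiny_table):
        recs = self._records(tiny_table)
        anchor = ("alpha",)
        a = sentence_embedding(list(anchor), tiny_table)
        # brute-force oracle: sort all candidates by distance, ids break ties
        from ontoalign.embeddings import cosine_distance

        ranked = sorted(
            recs, key=lambda r: (cosine_distance(a, tiny_table.vector(r.raw_text)), r.term_id)
        )
        got = sample_negatives(anchor, recs, tiny_table, n_star=2, n_neg=3)
        assert got == [tuple(r.tokens) for r in ranked[2:5]]

    def test_nstar_zero_all_candidates(self, tiny_table):
        recs = self._records(tiny_table)
        got = sample_negatives(("beta",), recs, tiny_table, n_star=0, n_neg=len(recs))
        assert len(got) == len(recs)

    def test_too_few_candidates_returns_remainder(self, tiny_table):
        recs = self._records(tiny_table)[:3]
        got = sample_negatives(("beta",), recs, tiny_table, n_star=2, n_neg=7)
        assert len(got) == 1


class TestTraining:
    def test_zero_epochs_identity(self, toy_world):
        table, inst = toy_world
        cfg = RetrofitConfig(epochs=0, seed=1)
        out = train_retrofit([inst], table, cfg)
        assert np.array_equal(out.table.matrix, table.matrix)

    def test_objective_decreases_on_toy(self, toy_world):
        table, inst = toy_world
        cfg = RetrofitConfig(epochs=15, seed=1)
        out = train_retrofit([inst], table, cfg)
        assert out.objective_history[-1] < out.objective_history[0]

    def test_untouched_word_bit_identical(self, toy_world):
        table, inst = toy_world
        cfg = RetrofitConfig(epochs=5, seed=1)
        out = train_retrofit([inst], table, cfg)
        untouched = table.vocab["w9"]  # w8/w9 appear in no instance
        assert np.array_equal(out.table.matrix[untouched], table.matrix[untouched])
        touched = table.vocab["w0"]
        assert not np.array_equal(out.table.matrix[touched], table.matrix[touched])

    def test_deterministic_given_seed(self, toy_world):
        table, inst = toy_world
        cfg = RetrofitConfig(epochs=3, seed=9)
        a = train_retrofit([inst], table, cfg)
        b = train_retrofit([inst], table, cfg)
        assert np.array_equal(a.table.matrix, b.table.matrix)

    def test_empty_instances_error(self, toy_world):
        table, _ = toy_world
        with pytest.raises(ValueError):
            train_retrofit([], table)
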