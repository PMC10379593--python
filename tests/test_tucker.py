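"""Tucker scoring, Bernoulli loss and training behaviour."""

import math

import numpy as np
import pytest

from birads_tensor import (
    TrainConfig,
    TuckerModel,
    bernoulli_nll,
    predict_label,
    predict_malignancy,
    score_all_tails,
    score_triple,
    train,
)
from birads_tensor.graph import build_graph
from birads_tensor.tucker import _fit  # noqa: F401 (exercised via train)


def _random_model(rng, n_ent=5, n_rel=3, d_e=3, d_r=2):
    return TuckerModel(
        entity_embeddings=rng.normal(size=(n_ent, d_e)),
        relation_embeddings=rng.normal(size=(n_rel, d_r)),
        core=rng.normal(size=(d_e, d_r, d_e)),
        entities=[f"e{i}" for i in range(n_ent)],
        relations=[f"r{i}" for i in range(n_rel)],
    )


def _loop_score(core, h, r, t):
    """Independent brute-force contraction: three nested loops."""
    total = 0.0
    for i in range(core.shape[0]):
        for j in range(core.shape[1]):
            for k in range(core.shape[2]):
                total += core[i, j, k] * h[i] * r[j] * t[k]
    return total


class TestScoreTriple:
    def test_one_hot_contraction_reads_core_entry(self):
        m = _random_model(np.random.default_rng(0))
        m.entity_embeddings[:] = 0.0
        m.relation_embeddings[:] = 0.0
        m.core[:] = 0.0
        m.core[0, 0, 0] = 2.0
        m.entity_embeddings[0, 0] = 1.0
        m.relation_embeddings[0, 0] = 1.0
        assert score_triple(m, 0, 0, 0) == pytest.approx(2.0)

    def test_zero_head_scores_zero(self, rng):
        m = _random_model(rng)
        m.entity_embeddings[1] = 0.0
        for r in range(3):
            for t in range(5):
                assert score_triple(m, 1, r, t) == 0.0

    def test_matches_nested_loop_oracle(self, rng):
        for _ in range(100):
            m = _random_model(rng, d_e=3, d_r=2)
            h, r, t = rng.integers(5), rng.integers(3), rng.integers(5)
            expected = _loop_score(
                m.core,
                m.entity_embeddings[h],
                m.relation_embeddings[r],
                m.entity_embeddings[t],
            )
            assert abs(score_triple(m, h, r, t) - expected) < 1e-10

    def test_contraction_order_invariance(self, rng):
        """Applying the three mode products in any order gives the same phi."""
        m = _random_model(rng)
        h = m.entity_embeddings[2]
        r = m.relation_embeddings[1]
        t = m.entity_embeddings[4]
        orders = [
            np.einsum("ijk,i,j,k->", m.core, h, r, t),
            ((m.core @ t) @ r) @ h,  # mode-3 then mode-2 then mode-1
            np.tensordot(np.tensordot(m.core, h, axes=(0, 0)), r, axes=(0, 0)) @ t,
        ]
        assert np.allclose(orders, score_triple(m, 2, 1, 4), atol=1e-10)

    def test_entity_permutation_leaves_scores_unchanged(self, rng):
        m = _random_model(rng)
        perm = rng.permutation(5)
        pm = TuckerModel(
            entity_embeddings=m.entity_embeddings[perm],
            relation_embeddings=m.relation_embeddings,
            core=m.core,
            entities=[m.entities[i] for i in perm],
            relations=m.relations,
        )
        inv = np.argsort(perm)
        for h in range(5):
            for t in range(5):
                assert score_triple(m, h, 0, t) == pytest.approx(
                    score_triple(pm, inv[h], 0, inv[t])
                )


class TestScoreAllTails:
    def test_matches_elementwise_single_scores(self, rng):
        m = _random_model(rng)
        vec = score_all_tails(m, 1, 2)
        for t in range(5):
            assert vec[t] == pytest.approx(score_triple(m, 1, 2, t), abs=1e-12)

    def test_zero_core_all_zero(self, rng):
        m = _random_model(rng)
        m.core[:] = 0.0
        assert np.all(score_all_tails(m, 0, 0) == 0.0)

    def test_linear_in_head(self, rng):
        m = _random_model(rng)
        base = score_all_tails(m, 3, 1).copy()
        m.entity_embeddings[3] *= 2.5
        scaled = score_all_tails(m, 3, 1)
        mask = np.arange(5) != 3
        assert np.allclose(scaled[mask], 2.5 * base[mask])
        # entity 3 is both head and tail of its own entry: quadratic
        assert scaled[3] == pytest.approx(2.5**2 * base[3])


class TestBernoulliNLL:
    def test_perfect_prediction_is_zero(self):
        assert bernoulli_nll([1.0], [1]) == pytest.approx(0.0, abs=1e-6)

    def test_coin_flip_is_log_two(self):
        assert bernoulli_nll([0.5, 0.5], [1, 0]) == pytest.approx(math.log(2), abs=1e-12)

    def test_hand_evaluated_three_samples(self):
        expected = -(math.log(0.9) + math.log(0.8) + math.log(0.7)) / 3
        assert bernoulli_nll([0.9, 0.2, 0.7], [1, 0, 1]) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bernoulli_nll([0.5], [1, 0])

    def test_nonnegative_on_random_inputs(self, rng):
        p = rng.uniform(0.01, 0.99, 50)
        y = rng.integers(0, 2, 50)
        assert bernoulli_nll(p, y) >= 0.0


class TestTraining:
    def _fit_tiny(self, graph, seed=0, n_epochs=400):
        cfg = TrainConfig(d_e=8, d_r=8, n_epochs=n_epochs, batch_size=16, seed=seed)
        return train(graph.triples, graph, cfg)

    def test_loss_trace_finite_and_descending(self, tiny_separable_graph):
        result = self._fit_tiny(tiny_separable_graph)
        assert all(np.isfinite(result.loss_trace))
        assert result.loss_trace[-1] <= result.loss_trace[0]

    def test_overfit_recovery_ranks_true_pathology_first(self, tiny_separable_graph):
        """With ample epochs on the separable toy graph, every training
        pathology query puts its true tail at rank 1 over all entities."""
        g = tiny_separable_graph
        result = self._fit_tiny(g)
        model = result.model
        ri = model.relation_index["pathology"]
        for triple in g.triples:
            if triple.relation != "pathology":
                continue
            scores = score_all_tails(model, model.entity_index[triple.head], ri)
            assert model.entities[int(np.argmax(scores))] == triple.tail
            assert predict_label(model, triple.head) == triple.tail

    def test_same_seed_identical_parameters(self, tiny_separable_graph):
        a = self._fit_tiny(tiny_separable_graph, seed=7, n_epochs=50)
        b = self._fit_tiny(tiny_separable_graph, seed=7, n_epochs=50)
        assert np.array_equal(a.model.core, b.model.core)
        assert np.array_equal(a.model.entity_embeddings, b.model.entity_embeddings)
        assert a.loss_trace == b.loss_trace

    def test_empty_training_set_rejected(self, tiny_separable_graph):
        with pytest.raises(ValueError):
            train([], tiny_separable_graph)

    def test_grid_search_selects_from_grid(self, tiny_separable_graph):
        cfg = TrainConfig(
            d_e=6, d_r=6, n_epochs=30, batch_size=16, seed=1,
            grid={"learning_rate": [1e-3, 1e-2]},
        )
        result = train(tiny_separable_graph.triples, tiny_separable_graph, cfg)
        assert result.config.learning_rate in (1e-3, 1e-2)
        assert result.config.grid is None


class TestPrediction:
    def test_probability_in_open_unit_interval(self, tiny_separable_graph):
        cfg = TrainConfig(d_e=6, d_r=6, n_epochs=30, batch_size=16, seed=0)
        model = train(tiny_separable_graph.triples, tiny_separable_graph, cfg).model
        for head in ("a::0", "b::0", "c::0", "d::0"):
            p = predict_malignancy(model, head)
            assert 0.0 < p < 1.0

    def test_exact_tie_goes_to_benign(self, rng):
        m = _random_model(rng)
        m.entities[0:3] = ["p::0", "malignant", "benign"]
        m.relations[0] = "pathology"
        m.core[:] = 0.0  # all scores zero -> tie
        assert predict_label(m, "p::0") == "benign"

    def test_unknown_entity_rejected(self, tiny_separable_graph, rng):
        m = _random_model(rng)
        m.relations[0] = "pathology"
        with pytest.raises(KeyError):
            predict_malignancy(m, "nobody")
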