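"""Highway layer and BiLSTM(-Highway)-CRF training tests."""

import numpy as np
import pytest

from mammokg.corpus_io import TagSet
from mammokg.ner import predict, train_neural
from mammokg.ner.crf import crf_nll_and_grads, viterbi_decode
from mammokg.ner.neural import (
    HighwayParams,
    NeuralTagger,
    _init_params,
    highway_forward,
)

TOY_TAGSET = TagSet(["Mass", "Size"])
TOY_CORPUS = [
    ("块块大", ["B-Mass", "I-Mass", "B-Size"]),
    ("大块块", ["B-Size", "B-Mass", "I-Mass"]),
    ("块块", ["B-Mass", "I-Mass"]),
    ("大大", ["B-Size", "I-Size"]),
    ("块大大", ["B-Mass", "B-Size", "I-Size"]),
    ("见块块。", ["O", "B-Mass", "I-Mass", "O"]),
]


class TestHighwayLayer:
    def test_hand_computed_two_dimensional_example(self):
        params = HighwayParams(np.eye(2), np.zeros(2), np.zeros((2, 2)),
                               np.zeros(2))
        y = highway_forward(np.array([1.0, 0.0]), params)
        expected = np.array([0.5 * np.tanh(1.0) + 0.5, 0.0])
        assert np.allclose(y, expected, atol=1e-9)

    def test_open_transfer_gate_passes_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5)
        params = HighwayParams(rng.normal(size=(5, 5)), rng.normal(size=5),
                               np.zeros((5, 5)), np.full(5, 40.0))
        y = highway_forward(x, params)
        assert np.allclose(y, np.tanh(x @ params.W_H + params.b_H), atol=1e-9)

    def test_closed_transfer_gate_carries_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5)
        params = HighwayParams(rng.normal(size=(5, 5)), rng.normal(size=5),
                               np.zeros((5, 5)), np.full(5, -40.0))
        assert np.allclose(highway_forward(x, params), x, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        params = HighwayParams(np.eye(3), np.zeros(3), np.eye(3), np.zeros(3))
        with pytest.raises(ValueError):
            highway_forward(np.zeros(2), params)


def _tiny_model(arch, seed=1):
    tagset = TagSet(["Mass"])
    rng = np.random.default_rng(seed)
    params = _init_params(arch, vocab_size=5, d=4, h=3, K=len(tagset),
                          rng=rng, gate_bias=-1.0, embedding_vectors=None)
    vocab = {c: i for i, c in enumerate("块大见。")}
    vocab["<unk>"] = 4
    return NeuralTagger(arch, tagset, vocab, params, {})


class TestBackpropagation:
    @pytest.mark.parametrize("arch", ["bilstm_crf", "bilstm_highway_crf"])
    def test_gradients_match_finite_differences(self, arch):
        model = _tiny_model(arch)
        params = model.params
        idx = np.array([0, 2, 1, 3])
        tags = np.array([0, 1, 2, 0])

        def loss():
            em, _ = model._forward(idx)
            return crf_nll_and_grads(em, params["trans"], tags)[0]

        em, cache = model._forward(idx)
        nll, d_em, _ = crf_nll_and_grads(em, params["trans"], tags)
        grads = model._backward(d_em, cache)
        eps = 1e-6
        for name, g in grads.items():
            flat = params[name].ravel()
            for t in range(0, flat.size, max(1, flat.size // 6)):
                old = flat[t]
                flat[t] = old + eps
                fd = (loss() - nll) / eps
                flat[t] = old
                assert fd == pytest.approx(g.ravel()[t], abs=1e-4), name


class TestTraining:
    @pytest.mark.parametrize("arch", ["bilstm_crf", "bilstm_highway_crf"])
    def test_toy_corpus_reaches_perfect_held_in_f1(self, arch):
        hp = {"embedding_dim": 12, "hidden_dim": 12, "epochs": 60,
              "batch_size": 2, "learning_rate": 0.01, "dropout": 0.0}
        model = train_neural(arch, TOY_CORPUS, hp, seed=2, tagset=TOY_TAGSET)
        for text, tags in TOY_CORPUS:
            assert model.predict_tags(text) == tags

    def test_loss_halves_on_twenty_report_toy_set(self, small_bundle):
        from mammokg.ner import as_tagged

        tagged = as_tagged(small_bundle.reports[:20])
        hp = {"embedding_dim": 16, "hidden_dim": 16, "epochs": 30,
              "batch_size": 4, "learning_rate": 3e-3}
        model = train_neural("bilstm_highway_crf", tagged, hp, seed=3)
        assert model.loss_history[-1] <= 0.5 * model.loss_history[0]

    def test_fixed_seed_reproducible_final_loss(self):
        hp = {"embedding_dim": 8, "hidden_dim": 8, "epochs": 5,
              "batch_size": 2}
        a = train_neural("bilstm_crf", TOY_CORPUS, hp, seed=4, tagset=TOY_TAGSET)
        b = train_neural("bilstm_crf", TOY_CORPUS, hp, seed=4, tagset=TOY_TAGSET)
        assert a.loss_history == pytest.approx(b.loss_history, rel=1e-12)

    def test_invalid_architecture_rejected(self):
        with pytest.raises(ValueError, match="architecture"):
            train_neural("transformer", TOY_CORPUS)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_neural("bilstm_crf", [])


class TestPrediction:
    def test_closed_gate_suppresses_bilstm_path(self):
        model = _tiny_model("bilstm_highway_crf", seed=5)
        model.params["b_T"][:] = -10.0  # carry-dominated limit
        text = "块大见。"
        idx = model._indices(text)
        X = model.params["E"][idx]
        carry_emissions = X @ model.params["Wo"] + model.params["bo"]
        expected = viterbi_decode(carry_emissions, model.params["trans"])
        assert model.predict_tags(text) == [model.tagset.tags[t] for t in expected]

    def test_empty_text_gives_empty_spans(self):
        model = _tiny_model("bilstm_crf")
        assert predict(model, "") == []

    def test_prediction_deterministic(self):
        model = _tiny_model("bilstm_highway_crf")
        assert model.predict_tags("块大块大") == model.predict_tags("块大块大")
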