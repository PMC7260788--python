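"""Generative models: likelihoods, attention, training, sampling."""

import math

import numpy as np
import pytest

from scaffdec.autodiff import Tensor
from scaffdec.chemio import build_vocabulary
from scaffdec.model import (
    Decorator,
    GeneratorConfig,
    NllValue,
    ScaffoldGenerator,
    attention_step,
    decoration_nll,
    load_checkpoint,
    sample_decoration_batch,
    sample_scaffold_batch,
    sample_sequence,
    save_checkpoint,
    scaffold_nll,
    train_decorator,
    train_scaffold_generator,
)
from scaffdec.slicer import ScaffoldDecorationTuple, TupleDataset
from scaffdec.chemio import AttachmentSmiles


def tiny_config(corpus, hidden=12, embedding=6, layers=1):
    return GeneratorConfig(vocabulary=build_vocabulary(corpus),
                           embedding_dim=embedding, hidden_dim=hidden,
                           n_layers=layers, dropout=0.0)


# ---------------------------------------------------------------------------
# independent forward pass (pure NumPy, loop-per-token, no Tensor machinery)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _lstm_forward(stack, x_seq):
    """Run a 1-sequence LSTM stack on a list of input vectors."""
    H = stack.config.hidden_dim
    states = [(np.zeros(H), np.zeros(H)) for _ in stack.layers]
    outputs = []
    for x in x_seq:
        inp = x
        for li, layer in enumerate(stack.layers):
            h, c = states[li]
            gates = inp @ layer["Wx"].data + h @ layer["Wh"].data + layer["b"].data
            i, f, g, o = (gates[:H], gates[H:2 * H], gates[2 * H:3 * H],
                          gates[3 * H:])
            c = _sigmoid(f) * c + _sigmoid(i) * np.tanh(g)
            h = _sigmoid(o) * np.tanh(c)
            states[li] = (h, c)
            inp = h
        outputs.append(inp)
    return outputs, states


def _log_softmax(z):
    z = z - z.max()
    return z - np.log(np.exp(z).sum())


def reference_scaffold_nll(model, smiles):
    """Stepwise NLL oracle for the scaffold generator."""
    ids = model.vocabulary.encode(smiles)
    xs = [model.embedding.data[i] for i in ids[:-1]]
    outs, _ = _lstm_forward(model.lstm, xs)
    nll = 0.0
    for out, target in zip(outs, ids[1:]):
        logits = out @ model.W_out.data + model.b_out.data
        nll -= _log_softmax(logits)[target]
    return nll


def reference_decoration_nll(model, scaffold, decoration):
    """Stepwise NLL oracle for the decorator, attention included."""
    s_ids = model.vocabulary.encode(scaffold)
    d_ids = model.vocabulary.encode(decoration)
    xs = [model.embedding.data[i] for i in s_ids]
    fwd, fwd_states = _lstm_forward(model.enc_fwd, xs)
    bwd_rev, bwd_states = _lstm_forward(model.enc_bwd, xs[::-1])
    bwd = bwd_rev[::-1]
    enc = np.stack([f + b for f, b in zip(fwd, bwd)])
    H = model.config.hidden_dim
    states = [(hf + hb, cf + cb) for (hf, cf), (hb, cb)
              in zip(fwd_states, bwd_states)]
    nll = 0.0
    for x_id, target in zip(d_ids[:-1], d_ids[1:]):
        inp = model.embedding.data[x_id]
        for li, layer in enumerate(model.decoder.layers):
            h, c = states[li]
            gates = (inp @ layer["Wx"].data + h @ layer["Wh"].data
                     + layer["b"].data)
            i, f, g, o = (gates[:H], gates[H:2 * H], gates[2 * H:3 * H],
                          gates[3 * H:])
            c = _sigmoid(f) * c + _sigmoid(i) * np.tanh(g)
            h = _sigmoid(o) * np.tanh(c)
            states[li] = (h, c)
            inp = h
        scores = enc @ inp / np.sqrt(H)
        weights = np.exp(_log_softmax(scores))
        context = weights @ enc
        out = np.tanh(np.concatenate([inp, context]) @ model.W_att.data
                      + model.b_att.data)
        logits = out @ model.W_out.data + model.b_out.data
        nll -= _log_softmax(logits)[target]
    return nll


# ---------------------------------------------------------------------------


class TestScaffoldNll:
    def test_uniform_model_gives_t_log_v(self):
        config = tiny_config(["CCO"])
        model = ScaffoldGenerator(config, rng_seed=0)
        model.W_out.data[:] = 0.0
        model.b_out.data[:] = 0.0
        nll = scaffold_nll(model, "CCO")
        assert nll.n_tokens == 4  # three tokens plus the end marker
        assert nll.value == pytest.approx(4 * math.log(len(config.vocabulary)),
                                          rel=1e-9)

    def test_matches_stepwise_oracle(self):
        model = ScaffoldGenerator(tiny_config(["c1ccccc1CCO", "CCN"]), rng_seed=3)
        for s in ["c1ccccc1CCO", "CCN", "CC"]:
            assert scaffold_nll(model, s).value == pytest.approx(
                reference_scaffold_nll(model, s), abs=1e-9)

    def test_out_of_vocabulary_token_named(self):
        model = ScaffoldGenerator(tiny_config(["CC"]), rng_seed=0)
        with pytest.raises(Exception, match="Cl"):
            scaffold_nll(model, "CCl")

    def test_nonnegative_contract(self):
        with pytest.raises(ValueError):
            NllValue(value=-1.0, n_tokens=3)


class TestAttention:
    def test_single_position_gets_full_weight(self):
        rng = np.random.default_rng(0)
        enc = rng.normal(size=(1, 8))
        step = attention_step(rng.normal(size=8), enc)
        assert step.weights == pytest.approx([1.0])
        assert np.allclose(step.context.data, enc[0])

    def test_identical_positions_give_uniform_weights(self):
        enc = np.tile(np.arange(6.0), (4, 1))
        step = attention_step(np.ones(6), enc)
        assert np.allclose(step.weights, 0.25)

    def test_closed_form_small_matrices(self):
        rng = np.random.default_rng(5)
        enc = rng.normal(size=(5, 8))
        dec = rng.normal(size=8)
        step = attention_step(dec, enc)
        z = enc @ dec / np.sqrt(8)
        expected = np.exp(z) / np.exp(z).sum()
        assert np.abs(step.weights - expected).max() < 1e-6
        assert np.abs(step.context.data - expected @ enc).max() < 1e-6

    def test_weights_normalize_and_pads_get_zero(self):
        rng = np.random.default_rng(6)
        enc = rng.normal(size=(2, 7, 8))
        dec = rng.normal(size=(2, 8))
        mask = np.array([[1, 1, 1, 0, 0, 0, 0], [1, 1, 1, 1, 1, 1, 0]],
                        dtype=float)
        step = attention_step(dec, enc, mask)
        assert np.allclose(step.weights.sum(axis=1), 1.0)
        assert np.abs(step.weights[mask == 0]).max() < 1e-12

    def test_projection_output_shape_and_range(self):
        rng = np.random.default_rng(7)
        W = Tensor(rng.normal(size=(16, 8)))
        step = attention_step(rng.normal(size=8), rng.normal(size=(5, 8)), W=W)
        assert step.output.data.shape == (8,)
        assert np.abs(step.output.data).max() <= 1.0

    def test_all_masked_raises(self):
        with pytest.raises(ValueError, match="unmasked"):
            attention_step(np.ones(4), np.ones((3, 4)), mask=np.zeros(3))


class TestDecorationNll:
    def test_matches_stepwise_oracle(self):
        corpus = ["[*]c1ccccc1", "[*]CCO", "[*]CC"]
        model = Decorator(tiny_config(corpus), rng_seed=2)
        for dec in ["[*]CCO", "[*]CC"]:
            assert decoration_nll(model, "[*]c1ccccc1", dec).value == pytest.approx(
                reference_decoration_nll(model, "[*]c1ccccc1", dec), abs=1e-9)

    def test_randomized_scaffold_forms_give_finite_nlls(self):
        corpus = ["[*]c1ccc(C)cc1", "c1cc(C)ccc1[*]", "[*]CCO"]
        model = Decorator(tiny_config(corpus), rng_seed=2)
        for scaf in corpus[:2]:
            nll = decoration_nll(model, scaf, "[*]CCO")
            assert math.isfinite(nll.value) and nll.value >= 0

    def test_scaffold_without_attachment_rejected(self):
        model = Decorator(tiny_config(["[*]CC", "CC"]), rng_seed=0)
        with pytest.raises(ValueError, match="attachment"):
            decoration_nll(model, "CC", "[*]C")


class TestTraining:
    def _one_pair_dataset(self):
        tup = ScaffoldDecorationTuple(
            AttachmentSmiles.from_smiles("[*]c1ccccc1"),
            (AttachmentSmiles.from_smiles("[*]CCO"),), "OCCc1ccccc1")
        return TupleDataset(tuples=[tup, tup])

    def test_deterministic_given_seed(self):
        ds = self._one_pair_dataset()
        _, trace1 = train_decorator(ds, epochs=5, rng_seed=11)
        _, trace2 = train_decorator(ds, epochs=5, rng_seed=11)
        assert trace1 == trace2

    def test_loss_trace_finite_and_decreasing(self):
        ds = self._one_pair_dataset()
        _, trace = train_decorator(ds, epochs=30, rng_seed=1, lr=5e-3)
        assert all(math.isfinite(v) for v in trace)
        assert trace[-1] < trace[0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_decorator(TupleDataset(), epochs=1)
        with pytest.raises(ValueError):
            train_scaffold_generator([], epochs=1)

    def test_fixture_overfit_nll_collapses(self, trained_multi):
        _, trace = trained_multi
        assert trace[-1] < 0.05 * trace[0]

    def test_overfit_single_sequence_memorizes(self):
        ds = self._one_pair_dataset()
        model, _ = train_decorator(ds, epochs=200, rng_seed=3, lr=5e-3,
                                   randomize=False)
        target_nll = decoration_nll(model, "[*]c1ccccc1", "[*]CCO")
        assert target_nll.value < 0.01 * target_nll.n_tokens * 10
        samples = sample_decoration_batch(model, "[*]c1ccccc1", 100,
                                          np.random.default_rng(0))
        hits = sum(1 for s in samples if s.smiles == "[*]CCO")
        assert hits >= 95


class TestSampling:
    def test_softmax_probabilities_match_sample_frequencies(self):
        # hand-set logits over a 2-real-token vocabulary; first-step token
        # frequencies at n = 10,000 must match softmax within 3 sigma
        config = tiny_config(["CO"], hidden=4, embedding=3)
        model = ScaffoldGenerator(config, rng_seed=0)
        vocab = config.vocabulary
        model.W_out.data[:] = 0.0
        logits = np.full(len(vocab), -30.0)
        c_idx, o_idx = vocab.index("C"), vocab.index("O")
        logits[c_idx], logits[o_idx] = 1.0, 0.0
        model.b_out.data[:] = logits
        n = 10_000
        samples = sample_scaffold_batch(model, n, np.random.default_rng(9),
                                        max_length=1)
        first = [s.tokens.tokens[0] if s.tokens.tokens else "$" for s in samples]
        p_c = math.exp(1.0) / (math.exp(1.0) + 1.0)
        freq = first.count("C") / n
        sigma = math.sqrt(p_c * (1 - p_c) / n)
        assert abs(freq - p_c) < 3 * sigma

    def test_reported_nll_is_self_consistent(self):
        model = ScaffoldGenerator(tiny_config(["CCO"]), rng_seed=1)
        sample = sample_sequence(model, rng_seed=4, max_length=20)
        if not sample.truncated:
            recomputed = scaffold_nll(model, sample.tokens)
            assert sample.nll == pytest.approx(recomputed.value, abs=1e-9)
        dec = Decorator(tiny_config(["[*]CC", "[*]CCO"]), rng_seed=1)
        sample = sample_sequence(dec, conditioning="[*]CC", rng_seed=4,
                                 max_length=20)
        if not sample.truncated:
            recomputed = decoration_nll(dec, "[*]CC", sample.tokens)
            assert sample.nll == pytest.approx(recomputed.value, abs=1e-9)

    def test_fixed_seed_reproducible(self):
        model = ScaffoldGenerator(tiny_config(["CCO", "CCN"]), rng_seed=1)
        a = sample_scaffold_batch(model, 16, np.random.default_rng(5))
        b = sample_scaffold_batch(model, 16, np.random.default_rng(5))
        assert [s.smiles for s in a] == [s.smiles for s in b]

    def test_length_cap_flags_truncation(self):
        config = tiny_config(["CC"], hidden=4)
        model = ScaffoldGenerator(config, rng_seed=0)
        # make the end token unreachable
        model.b_out.data[:] = -30.0
        model.b_out.data[config.vocabulary.index("C")] = 30.0
        model.W_out.data[:] = 0.0
        sample = sample_sequence(model, rng_seed=0, max_length=10)
        assert sample.truncated
        assert len(sample.tokens) == 10

    def test_pad_and_begin_never_emitted(self):
        model = ScaffoldGenerator(tiny_config(["CCO"], hidden=4), rng_seed=2)
        for s in sample_scaffold_batch(model, 50, np.random.default_rng(1),
                                       max_length=30):
            assert "<pad>" not in s.tokens.tokens
            assert "^" not in s.tokens.tokens


class TestCheckpoint:
    def test_roundtrip_preserves_likelihoods(self, tmp_path):
        corpus = ["[*]c1ccccc1", "[*]CCO"]
        model = Decorator(tiny_config(corpus), rng_seed=8, mode="single")
        path = tmp_path / "model.json"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.mode == "single"
        want = decoration_nll(model, "[*]c1ccccc1", "[*]CCO").value
        got = decoration_nll(loaded, "[*]c1ccccc1", "[*]CCO").value
        assert got == pytest.approx(want, abs=1e-12)
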