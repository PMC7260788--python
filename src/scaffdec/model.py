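"""Recurrent generative models for scaffolds and decorations.

Two models share one architecture family (embedding -> stacked LSTM cells ->
linear + softmax over the vocabulary):

* the *scaffold generator*, an unconditional language model over scaffold
  SMILES, and
* the *decorator*, an encoder-decoder: a bidirectional LSTM stack encodes a
  randomized scaffold SMILES (the hidden and cell states of the two directions
  are summed and seed the decoder), and a unidirectional decoder generates the
  decoration token by token with a global attention mechanism — a scaled dot
  product of the decoder output against every encoder position, a masked
  softmax, and a tanh projection of [decoder output ; attention context].

Both are trained with teacher forcing on the negative log-likelihood (in
nats, summed over sequence tokens). Sampling is multinomial from the softmax
at each step until the end token or a length cap.

The multi-step decorator is trained on (partially decorated scaffold, next
decoration) pairs — one random decoration order per tuple per epoch, with the
partial molecule re-randomized at every step so the first-``[*]``-in-string
target policy matches the sampler. The single-step variant is trained on
(scaffold, dec_1|...|dec_c) pairs with decorations ordered by attachment
appearance in that particular randomized scaffold string.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .autodiff import Adam, Tensor, concat, stack
from .chemio import (
    ATTACHMENT_TOKEN,
    SEPARATOR_TOKEN,
    TokenSequence,
    Vocabulary,
    build_vocabulary,
    detokenize,
    mol_from_smiles,
    mol_to_smiles,
    randomize_smiles,
    strip_attachment_labels,
)
from .slicer import TupleDataset, _attach

__all__ = [
    "GeneratorConfig",
    "NllValue",
    "AttentionStep",
    "attention_step",
    "ScaffoldGenerator",
    "Decorator",
    "scaffold_nll",
    "decoration_nll",
    "train_scaffold_generator",
    "train_decorator",
    "build_training_pairs",
    "sample_sequence",
    "SampledSequence",
    "save_checkpoint",
    "load_checkpoint",
]

MAX_SEQUENCE_LENGTH = 256


@dataclass(frozen=True)
class GeneratorConfig:
    """Hyperparameters shared by the scaffold generator and the decorator.

    The full-scale configuration is 512 hidden units, 3 LSTM layers and
    dropout 0.2; desk-scale presets shrink hidden size and depth.
    """

    vocabulary: Vocabulary
    embedding_dim: int = 128
    hidden_dim: int = 512
    n_layers: int = 3
    dropout: float = 0.2

    def __post_init__(self):
        if self.hidden_dim <= 0 or self.embedding_dim <= 0:
            raise ValueError("embedding_dim and hidden_dim must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


@dataclass(frozen=True)
class NllValue:
    """A negative log-likelihood in nats, summed over the sequence tokens."""

    value: float
    n_tokens: int

    def __post_init__(self):
        if self.value < -1e-9:
            raise ValueError("NLL must be nonnegative")


@dataclass
class AttentionStep:
    """One attention evaluation: weights over encoder positions, context, output."""

    weights: np.ndarray
    context: Tensor
    output: Optional[Tensor]


def attention_step(decoder_out, encoder_outs, mask=None, W: Optional[Tensor] = None,
                   bias: Optional[Tensor] = None) -> AttentionStep:
    """Scaled-dot-product global attention for one decoder step.

    ``decoder_out`` is (H,) or (B, H); ``encoder_outs`` is (L, H) or (B, L, H);
    ``mask`` marks valid (non-pad) encoder positions with 1. Weights are
    softmax(decoder_out . encoder_outs^T / sqrt(d)) with masked positions sent
    to -inf before the softmax; the context is the weighted sum over encoder
    positions; when a projection ``W`` (2H, H) is given, the output is
    tanh(W [decoder_out ; context]).
    """
    dec = decoder_out if isinstance(decoder_out, Tensor) else Tensor(decoder_out)
    enc = encoder_outs if isinstance(encoder_outs, Tensor) else Tensor(encoder_outs)
    squeeze = dec.data.ndim == 1
    if squeeze:
        dec = dec.reshape(1, -1)
    if enc.data.ndim == 2:
        enc = enc.reshape(1, *enc.data.shape)
    B, L, H = enc.data.shape
    if mask is None:
        mask = np.ones((B, L))
    mask = np.asarray(mask, dtype=np.float64).reshape(B, L)
    if np.any(mask.sum(axis=1) == 0):
        raise ValueError("attention has no attendable (unmasked) position")
    scale = 1.0 / np.sqrt(H)
    scores = dec.attn_scores(enc) * scale
    scores = scores + Tensor((mask - 1.0) * 1e9)
    weights = scores.log_softmax(axis=-1).exp()
    context = weights.attn_context(enc)
    output = None
    if W is not None:
        pre = concat([dec, context], axis=-1).matmul(W)
        if bias is not None:
            pre = pre + bias
        output = pre.tanh()
    if squeeze:
        return AttentionStep(weights=weights.data[0],
                             context=context.reshape(-1),
                             output=None if output is None else output.reshape(-1))
    return AttentionStep(weights=weights.data, context=context, output=output)


# ---------------------------------------------------------------------------
# parameter containers


def _uniform(rng, shape, scale=0.08):
    return Tensor(rng.uniform(-scale, scale, shape), requires_grad=True)


class _LSTMStack:
    """Stacked LSTM cells with mask-aware batched steps."""

    def __init__(self, config: GeneratorConfig, rng, input_dim: int):
        self.config = config
        self.layers = []
        dim = input_dim
        for _ in range(config.n_layers):
            self.layers.append({
                "Wx": _uniform(rng, (dim, 4 * config.hidden_dim)),
                "Wh": _uniform(rng, (config.hidden_dim, 4 * config.hidden_dim)),
                "b": Tensor(np.concatenate([
                    np.zeros(config.hidden_dim),
                    np.ones(config.hidden_dim),  # forget-gate bias
                    np.zeros(2 * config.hidden_dim)]), requires_grad=True),
            })
            dim = config.hidden_dim

    def parameters(self):
        for layer in self.layers:
            yield from layer.values()

    def initial_state(self, batch: int):
        H = self.config.hidden_dim
        zero = lambda: Tensor(np.zeros((batch, H)))
        return [(zero(), zero()) for _ in self.layers]

    def step(self, x: Tensor, states, mask_t: Optional[np.ndarray] = None,
             train: bool = False, dropout_rng=None):
        """One timestep. ``mask_t`` (B,) freezes the state where 0 (padding)."""
        H = self.config.hidden_dim
        new_states = []
        inp = x
        m = None if mask_t is None else Tensor(mask_t.reshape(-1, 1))
        keep = None if m is None else Tensor(1.0 - m.data)
        for li, layer in enumerate(self.layers):
            if train and self.config.dropout > 0:
                inp = _dropout(inp, self.config.dropout, dropout_rng)
            h_prev, c_prev = states[li]
            gates = inp.matmul(layer["Wx"]) + h_prev.matmul(layer["Wh"]) + layer["b"]
            i = gates.narrow(1, 0, H).sigmoid()
            f = gates.narrow(1, H, H).sigmoid()
            g = gates.narrow(1, 2 * H, H).tanh()
            o = gates.narrow(1, 3 * H, H).sigmoid()
            c = f * c_prev + i * g
            h = o * c.tanh()
            if m is not None:
                h = m * h + keep * h_prev
                c = m * c + keep * c_prev
            new_states.append((h, c))
            inp = h
        return inp, new_states


def _dropout(x: Tensor, p: float, rng) -> Tensor:
    keep = (rng.random(x.data.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(keep)


class ScaffoldGenerator:
    """Unconditional SMILES language model (embedding -> LSTM stack -> linear)."""

    kind = "scaffold"

    def __init__(self, config: GeneratorConfig, rng_seed: int = 0):
        rng = np.random.default_rng(rng_seed)
        self.config = config
        self.vocabulary = config.vocabulary
        V = len(config.vocabulary)
        self.embedding = _uniform(rng, (V, config.embedding_dim))
        self.lstm = _LSTMStack(config, rng, config.embedding_dim)
        self.W_out = _uniform(rng, (config.hidden_dim, V))
        self.b_out = Tensor(np.zeros(V), requires_grad=True)

    def parameters(self):
        yield self.embedding
        yield from self.lstm.parameters()
        yield self.W_out
        yield self.b_out

    # -- likelihood --------------------------------------------------------

    def batch_nll(self, ids: np.ndarray, mask: np.ndarray, train: bool = False,
                  rng=None) -> Tuple[Tensor, np.ndarray]:
        """Teacher-forced NLL. ids (B, T) padded with 0; mask (B, T) 1 = real.

        Returns (scalar loss Tensor = summed NLL over the batch, per-sequence
        NLL array).
        """
        B, T = ids.shape
        states = self.lstm.initial_state(B)
        total = Tensor(np.zeros(B))
        for t in range(T - 1):
            x = self.embedding.embed(ids[:, t])
            out, states = self.lstm.step(x, states, mask[:, t], train=train,
                                         dropout_rng=rng)
            if train and self.config.dropout > 0:
                out = _dropout(out, self.config.dropout, rng)
            logits = out.matmul(self.W_out) + self.b_out
            logp = logits.log_softmax().gather_rows(ids[:, t + 1])
            total = total + logp * Tensor(-mask[:, t + 1])
        return total.sum(), total.data.copy()


class Decorator:
    """Encoder-decoder with global attention over a scaffold SMILES."""

    kind = "decorator"

    def __init__(self, config: GeneratorConfig, rng_seed: int = 0,
                 mode: str = "multi"):
        if mode not in ("multi", "single"):
            raise ValueError("mode must be 'multi' or 'single'")
        rng = np.random.default_rng(rng_seed)
        self.config = config
        self.vocabulary = config.vocabulary
        self.mode = mode
        V = len(config.vocabulary)
        H = config.hidden_dim
        self.embedding = _uniform(rng, (V, config.embedding_dim))
        self.enc_fwd = _LSTMStack(config, rng, config.embedding_dim)
        self.enc_bwd = _LSTMStack(config, rng, config.embedding_dim)
        self.decoder = _LSTMStack(config, rng, config.embedding_dim)
        self.W_att = _uniform(rng, (2 * H, H))
        self.b_att = Tensor(np.zeros(H), requires_grad=True)
        self.W_out = _uniform(rng, (H, V))
        self.b_out = Tensor(np.zeros(V), requires_grad=True)

    def parameters(self):
        yield self.embedding
        for stack_ in (self.enc_fwd, self.enc_bwd, self.decoder):
            yield from stack_.parameters()
        yield self.W_att
        yield self.b_att
        yield self.W_out
        yield self.b_out

    # -- encoder -----------------------------------------------------------

    def encode(self, ids: np.ndarray, mask: np.ndarray, train: bool = False,
               rng=None):
        """Bidirectional encoding of scaffold token ids (B, T).

        Returns (encoder outputs (B, T, H) Tensor with forward+backward
        summed, initial decoder states with per-direction h/c summed).
        """
        B, T = ids.shape
        fwd_states = self.enc_fwd.initial_state(B)
        bwd_states = self.enc_bwd.initial_state(B)
        fwd_outs, bwd_outs = [], [None] * T
        for t in range(T):
            x = self.embedding.embed(ids[:, t])
            out, fwd_states = self.enc_fwd.step(x, fwd_states, mask[:, t],
                                                train=train, dropout_rng=rng)
            fwd_outs.append(out)
        for t in range(T - 1, -1, -1):
            x = self.embedding.embed(ids[:, t])
            out, bwd_states = self.enc_bwd.step(x, bwd_states, mask[:, t],
                                                train=train, dropout_rng=rng)
            bwd_outs[t] = out
        summed = [f + b for f, b in zip(fwd_outs, bwd_outs)]
        enc_out = stack(summed, axis=1)
        init = [(hf + hb, cf + cb) for (hf, cf), (hb, cb)
                in zip(fwd_states, bwd_states)]
        return enc_out, init

    # -- decoder -----------------------------------------------------------

    def _decode_step(self, token_ids, states, enc_out, enc_mask,
                     train=False, rng=None):
        x = self.embedding.embed(token_ids)
        out, states = self.decoder.step(x, states, None, train=train,
                                        dropout_rng=rng)
        att = attention_step(out, enc_out, enc_mask, self.W_att, self.b_att)
        final = att.output
        if train and self.config.dropout > 0:
            final = _dropout(final, self.config.dropout, rng)
        logits = final.matmul(self.W_out) + self.b_out
        return logits, states, att

    def batch_nll(self, scaffold_ids: np.ndarray, scaffold_mask: np.ndarray,
                  dec_ids: np.ndarray, dec_mask: np.ndarray,
                  train: bool = False, rng=None) -> Tuple[Tensor, np.ndarray]:
        """Teacher-forced conditional NLL of decorations given scaffolds."""
        B, T = dec_ids.shape
        enc_out, states = self.encode(scaffold_ids, scaffold_mask, train, rng)
        total = Tensor(np.zeros(B))
        for t in range(T - 1):
            logits, states, _ = self._decode_step(dec_ids[:, t], states,
                                                  enc_out, scaffold_mask,
                                                  train=train, rng=rng)
            logp = logits.log_softmax().gather_rows(dec_ids[:, t + 1])
            total = total + logp * Tensor(-dec_mask[:, t + 1])
        return total.sum(), total.data.copy()


# ---------------------------------------------------------------------------
# public likelihood operations


def _encode_batch(vocab: Vocabulary, sequences: Sequence) -> Tuple[np.ndarray, np.ndarray]:
    """Pad encoded sequences to a (B, T) id array and 0/1 mask."""
    encoded = []
    for seq in sequences:
        if isinstance(seq, TokenSequence):
            encoded.append(vocab.encode(list(seq)))
        else:
            encoded.append(vocab.encode(seq))
    T = max(len(e) for e in encoded)
    ids = np.full((len(encoded), T), vocab.pad_index, dtype=np.int64)
    mask = np.zeros((len(encoded), T))
    for i, e in enumerate(encoded):
        ids[i, :len(e)] = e
        mask[i, :len(e)] = 1.0
    return ids, mask


def scaffold_nll(model: ScaffoldGenerator, sequence) -> NllValue:
    """NLL of one SMILES (string or TokenSequence) under the scaffold generator."""
    ids, mask = _encode_batch(model.vocabulary, [sequence])
    _, per_seq = model.batch_nll(ids, mask)
    return NllValue(value=float(per_seq[0]), n_tokens=int(mask[0].sum()) - 1)


def decoration_nll(model: Decorator, scaffold_seq, decoration_seq) -> NllValue:
    """Conditional NLL of a decoration sequence given a scaffold sequence."""
    scaffold_str = (detokenize(scaffold_seq)
                    if isinstance(scaffold_seq, TokenSequence) else scaffold_seq)
    if ATTACHMENT_TOKEN not in scaffold_str:
        raise ValueError(
            f"scaffold has no attachment points: {scaffold_str!r}")
    s_ids, s_mask = _encode_batch(model.vocabulary, [scaffold_seq])
    d_ids, d_mask = _encode_batch(model.vocabulary, [decoration_seq])
    _, per_seq = model.batch_nll(s_ids, s_mask, d_ids, d_mask)
    return NllValue(value=float(per_seq[0]), n_tokens=int(d_mask[0].sum()) - 1)


# ---------------------------------------------------------------------------
# sampling


@dataclass
class SampledSequence:
    tokens: TokenSequence
    smiles: str
    nll: float
    truncated: bool


def _multinomial(rng, probs: np.ndarray) -> np.ndarray:
    """Vectorized multinomial draw per row of a (B, V) probability matrix."""
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0 + 1e-12
    draws = rng.random((probs.shape[0], 1))
    return (draws > cum).sum(axis=1).astype(np.int64)


def _forbidden_mask(vocab: Vocabulary) -> np.ndarray:
    """Log-space mask that bars pad/begin tokens from ever being sampled."""
    bar = np.zeros(len(vocab))
    bar[vocab.pad_index] = -1e9
    bar[vocab.begin_index] = -1e9
    return bar


def sample_scaffold_batch(model: ScaffoldGenerator, n: int, rng,
                          max_length: int = MAX_SEQUENCE_LENGTH) -> List[SampledSequence]:
    vocab = model.vocabulary
    bar = _forbidden_mask(vocab)
    states = model.lstm.initial_state(n)
    current = np.full(n, vocab.begin_index, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    nll = np.zeros(n)
    sampled_tokens: List[List[str]] = [[] for _ in range(n)]
    for _ in range(max_length):
        x = model.embedding.embed(current)
        out, states = model.lstm.step(x, states, None)
        logits = out.matmul(model.W_out) + model.b_out
        logp_raw = logits.log_softmax().data
        logp = (logits + Tensor(bar)).log_softmax().data
        nxt = _multinomial(rng, np.exp(logp))
        # report the model's own NLL of the drawn token (pad/begin barring
        # only gates the draw; their probability mass is negligible once
        # trained, and this keeps the reported NLL recomputable)
        step_nll = -logp_raw[np.arange(n), nxt]
        for i in range(n):
            if done[i]:
                continue
            nll[i] += step_nll[i]
            if nxt[i] == vocab.end_index:
                done[i] = True
            else:
                sampled_tokens[i].append(vocab.token(int(nxt[i])))
        current = np.where(done, vocab.end_index, nxt)
        if done.all():
            break
    return [SampledSequence(tokens=TokenSequence(tuple(toks)),
                            smiles="".join(toks), nll=float(nll[i]),
                            truncated=not done[i])
            for i, toks in enumerate(sampled_tokens)]


def sample_decoration_batch(model: Decorator, scaffold: str, n: int, rng,
                            max_length: int = MAX_SEQUENCE_LENGTH) -> List[SampledSequence]:
    """Sample ``n`` decoration sequences conditioned on one scaffold string."""
    vocab = model.vocabulary
    bar = _forbidden_mask(vocab)
    s_ids, s_mask = _encode_batch(vocab, [scaffold])
    s_ids = np.repeat(s_ids, n, axis=0)
    s_mask = np.repeat(s_mask, n, axis=0)
    enc_out, states = model.encode(s_ids, s_mask)
    current = np.full(n, vocab.begin_index, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    nll = np.zeros(n)
    sampled_tokens: List[List[str]] = [[] for _ in range(n)]
    for _ in range(max_length):
        logits, states, _ = model._decode_step(current, states, enc_out, s_mask)
        logp_raw = logits.log_softmax().data
        logp = (logits + Tensor(bar)).log_softmax().data
        nxt = _multinomial(rng, np.exp(logp))
        step_nll = -logp_raw[np.arange(n), nxt]
        for i in range(n):
            if done[i]:
                continue
            nll[i] += step_nll[i]
            if nxt[i] == vocab.end_index:
                done[i] = True
            else:
                sampled_tokens[i].append(vocab.token(int(nxt[i])))
        current = np.where(done, vocab.end_index, nxt)
        if done.all():
            break
    return [SampledSequence(tokens=TokenSequence(tuple(toks)),
                            smiles="".join(toks), nll=float(nll[i]),
                            truncated=not done[i])
            for i, toks in enumerate(sampled_tokens)]


def sample_sequence(model, conditioning: Optional[str] = None, rng_seed=0,
                    max_length: int = MAX_SEQUENCE_LENGTH) -> SampledSequence:
    """Sample one sequence; unconditioned = scaffold generator, conditioned = decorator."""
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    if conditioning is None:
        if not isinstance(model, ScaffoldGenerator):
            raise TypeError("unconditioned sampling requires a ScaffoldGenerator")
        return sample_scaffold_batch(model, 1, rng, max_length)[0]
    if not isinstance(model, Decorator):
        raise TypeError("conditioned sampling requires a Decorator")
    cond = (detokenize(conditioning)
            if isinstance(conditioning, TokenSequence) else conditioning)
    return sample_decoration_batch(model, cond, 1, rng, max_length)[0]


# ---------------------------------------------------------------------------
# training-pair construction


_LABELLED = re.compile(r"\[(\d+)\*\]")


def _label_attachments(smiles: str):
    """Replace the n-th [*] with [n*] (n starting at 1) and parse."""
    counter = [0]

    def sub(_match):
        counter[0] += 1
        return f"[{counter[0]}*]"

    labelled = re.sub(r"\[\*\]", sub, smiles)
    return mol_from_smiles(labelled), counter[0]


def _first_labelled_dummy(randomized: str) -> int:
    match = _LABELLED.search(randomized)
    if match is None:
        raise ValueError(f"no labelled attachment in {randomized!r}")
    return int(match.group(1))


def _labels_in_order(randomized: str) -> List[int]:
    return [int(m) for m in _LABELLED.findall(randomized)]


def build_training_pairs(dataset: TupleDataset, mode: str, rng,
                         randomize: bool = True,
                         randomize_targets: bool = False) -> List[Tuple[str, str]]:
    """Expand tuples into (scaffold input, target) training pairs for one epoch.

    multi mode: each c-attachment tuple yields c pairs tracing one random
    decoration order, the partial molecule re-randomized at each step, and the
    target always the decoration at the first ``[*]`` of the input string.
    single mode: one pair per tuple, target = decorations joined with ``|`` in
    the order their attachment points appear in the randomized scaffold.

    Scaffold inputs are randomized (that is what the sampler feeds the model);
    decoration targets stay canonical by default, which keeps the target
    entropy at the chemistry rather than spending it on string variants —
    pass ``randomize_targets=True`` for full two-sided augmentation.
    """
    pairs = []
    for tup in dataset:
        dec_strings = [d.smiles for d in tup.decorations]
        if randomize and randomize_targets:
            dec_strings = [randomize_smiles(d, rng) for d in dec_strings]
        if mode == "single":
            mol, n = _label_attachments(tup.scaffold.smiles)
            rand = randomize_smiles(mol_to_smiles(mol, canonical=False), rng) \
                if randomize else mol_to_smiles(mol)
            order = _labels_in_order(rand)
            target = SEPARATOR_TOKEN.join(dec_strings[lbl - 1] for lbl in order)
            pairs.append((strip_attachment_labels(rand), target))
            continue
        # multi mode: walk one random decoration order
        mol, n = _label_attachments(tup.scaffold.smiles)
        remaining = n
        while remaining > 0:
            smiles = mol_to_smiles(mol, canonical=False)
            rand = randomize_smiles(smiles, rng) if randomize else smiles
            label = _first_labelled_dummy(rand)
            target = dec_strings[label - 1]
            pairs.append((strip_attachment_labels(rand), target))
            # join that decoration at the labelled site and continue
            rand_mol = mol_from_smiles(rand)
            dummy = next(a.GetIdx() for a in rand_mol.GetAtoms()
                         if a.GetAtomicNum() == 0 and a.GetIsotope() == label)
            dec_mol = mol_from_smiles(tup.decorations[label - 1].smiles)
            joined = _attach(Chem.RWMol(rand_mol), dummy, dec_mol).GetMol()
            Chem.SanitizeMol(joined)
            mol = joined
            remaining -= 1
    return pairs


# ---------------------------------------------------------------------------
# training loops


def _vocabulary_from_dataset(dataset: TupleDataset, rng,
                             n_randomizations: int = 10) -> Vocabulary:
    """Vocabulary covering canonical and randomized forms of all tuple strings."""
    strings = []
    for tup in dataset:
        strings.append(tup.scaffold.smiles)
        strings.extend(d.smiles for d in tup.decorations)
    augmented = list(strings)
    for s in strings:
        for _ in range(n_randomizations):
            augmented.append(randomize_smiles(s, rng))
    return build_vocabulary(augmented)


def train_scaffold_generator(corpus: Sequence[str], config: Optional[GeneratorConfig] = None,
                             epochs: int = 100, rng_seed: int = 0,
                             batch_size: int = 128, lr: float = 1e-3,
                             randomize: bool = True,
                             model: Optional[ScaffoldGenerator] = None):
    """Train a scaffold generator on a SMILES corpus; returns (model, loss trace)."""
    if not corpus:
        raise ValueError("cannot train on an empty corpus")
    rng = np.random.default_rng(rng_seed)
    if model is None:
        if config is None:
            augmented = list(corpus)
            for s in corpus:
                for _ in range(10):
                    augmented.append(randomize_smiles(s, rng))
            config = GeneratorConfig(vocabulary=build_vocabulary(augmented),
                                     embedding_dim=32, hidden_dim=64,
                                     n_layers=1, dropout=0.0)
        model = ScaffoldGenerator(config, rng_seed=rng_seed)
    optimizer = Adam(model.parameters(), lr=lr)
    trace = []
    for _epoch in range(epochs):
        strings = [randomize_smiles(s, rng) if randomize else s for s in corpus]
        order = rng.permutation(len(strings))
        epoch_nll, n_seq = 0.0, 0
        for start in range(0, len(order), batch_size):
            batch = [strings[i] for i in order[start:start + batch_size]]
            ids, mask = _encode_batch(model.vocabulary, batch)
            optimizer.zero_grad()
            loss, per_seq = model.batch_nll(ids, mask, train=True, rng=rng)
            loss.backward()
            optimizer.step()
            epoch_nll += float(per_seq.sum())
            n_seq += len(batch)
        trace.append(epoch_nll / n_seq)
        if not np.isfinite(trace[-1]):
            raise FloatingPointError(f"training diverged at epoch {_epoch}")
    return model, trace


def train_decorator(dataset: TupleDataset, mode: str = "multi",
                    config: Optional[GeneratorConfig] = None,
                    epochs: int = 100, rng_seed: int = 0, batch_size: int = 128,
                    lr: float = 1e-3, randomize: bool = True,
                    model: Optional[Decorator] = None):
    """Train a decorator (multi- or single-step) on a tuple dataset.

    Returns (model, per-epoch mean NLL trace). Deterministic for a fixed seed.
    """
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    rng = np.random.default_rng(rng_seed)
    if model is None:
        if config is None:
            config = GeneratorConfig(vocabulary=_vocabulary_from_dataset(dataset, rng),
                                     embedding_dim=32, hidden_dim=64,
                                     n_layers=1, dropout=0.0)
        model = Decorator(config, rng_seed=rng_seed, mode=mode)
    elif model.mode != mode:
        raise ValueError(f"model mode {model.mode!r} does not match {mode!r}")
    optimizer = Adam(model.parameters(), lr=lr)
    trace = []
    for _epoch in range(epochs):
        pairs = build_training_pairs(dataset, mode, rng, randomize=randomize)
        order = rng.permutation(len(pairs))
        epoch_nll, n_seq = 0.0, 0
        for start in range(0, len(order), batch_size):
            chunk = [pairs[i] for i in order[start:start + batch_size]]
            s_ids, s_mask = _encode_batch(model.vocabulary, [p[0] for p in chunk])
            d_ids, d_mask = _encode_batch(model.vocabulary, [p[1] for p in chunk])
            optimizer.zero_grad()
            loss, per_seq = model.batch_nll(s_ids, s_mask, d_ids, d_mask,
                                            train=True, rng=rng)
            loss.backward()
            optimizer.step()
            epoch_nll += float(per_seq.sum())
            n_seq += len(chunk)
        trace.append(epoch_nll / n_seq)
        if not np.isfinite(trace[-1]):
            raise FloatingPointError(f"training diverged at epoch {_epoch}")
    return model, trace


# ---------------------------------------------------------------------------
# checkpoints


_CHECKPOINT_VERSION = 1


def save_checkpoint(model, path) -> None:
    """Serialize a model (parameters + config + vocabulary) to a JSON file."""
    named = _named_parameters(model)
    payload = {
        "version": _CHECKPOINT_VERSION,
        "kind": model.kind,
        "mode": getattr(model, "mode", None),
        "config": {
            "embedding_dim": model.config.embedding_dim,
            "hidden_dim": model.config.hidden_dim,
            "n_layers": model.config.n_layers,
            "dropout": model.config.dropout,
        },
        "vocabulary": model.vocabulary.tokens(),
        "parameters": {name: p.data.tolist() for name, p in named},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_checkpoint(path):
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("version") != _CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version: {payload.get('version')}")
    vocab = Vocabulary.__new__(Vocabulary)
    vocab._tokens = payload["vocabulary"]
    vocab._index = {tok: i for i, tok in enumerate(vocab._tokens)}
    config = GeneratorConfig(vocabulary=vocab, **payload["config"])
    if payload["kind"] == "scaffold":
        model = ScaffoldGenerator(config)
    else:
        model = Decorator(config, mode=payload["mode"] or "multi")
    for name, p in _named_parameters(model):
        p.data = np.asarray(payload["parameters"][name], dtype=np.float64)
    return model


def _named_parameters(model):
    named = []

    def add_stack(prefix, stack_):
        for li, layer in enumerate(stack_.layers):
            for key, tensor in layer.items():
                named.append((f"{prefix}.{li}.{key}", tensor))

    named.append(("embedding", model.embedding))
    if isinstance(model, ScaffoldGenerator):
        add_stack("lstm", model.lstm)
    else:
        add_stack("enc_fwd", model.enc_fwd)
        add_stack("enc_bwd", model.enc_bwd)
        add_stack("decoder", model.decoder)
        named.append(("W_att", model.W_att))
        named.append(("b_att", model.b_att))
    named.append(("W_out", model.W_out))
    named.append(("b_out", model.b_out))
    return named
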