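"""Relational-memory autoregressive generator for sleep-stage sequences.

The model carries a memory matrix ``M_t`` (1 slot x 128 units by default,
organized as 2 attention heads of size 64) across time steps.  One step:

    e_t  = embed(token)                                  (memory_size,)
    A    = LayerNorm(M_t + MHA(q=M_t, kv=[M_t; e_t]))    attention block
    PA   = LayerNorm(A + MLP(A))                         post-attention
    f    = sigmoid(W_f e_t + U_f tanh(M_t) + b_f)        forget gate
    i    = sigmoid(W_i e_t + U_i tanh(M_t) + b_i)        input gate
    M_t1 = f * M_t + i * tanh(PA)
    O_t  = softmax(W_o flatten(M_t1) + b_o)              next-stage dist.

Training is purely supervised maximum likelihood with teacher forcing:
inputs are (start, I_1 .. I_{T-1}) and targets (I_1 .. I_T), loss the mean
negative log-likelihood of the next stage.  Generation rolls the model
forward from the start token, sampling each next stage from ``O_t``
(temperature-scaled) and feeding it back.  The vocabulary is the five
stage symbols plus a start token that is never emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .signal import STAGE_INDEX, STAGES

START_TOKEN = 5  # index of the start symbol in the 6-token vocabulary
N_STAGES = len(STAGES)


@dataclass(frozen=True)
class RmConfig:
    """Hyperparameters of the relational-memory generator and its training."""

    memory_slots: int = 1
    n_heads: int = 2
    head_size: int = 64
    mlp_layers: int = 2
    mlp_hidden: int = 128
    seq_length: int = 180
    batch_size: int = 64
    epochs: int = 200
    lr: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)

    @property
    def memory_size(self) -> int:
        return self.n_heads * self.head_size

    def with_overrides(self, **kw) -> "RmConfig":
        return replace(self, **kw)


class RelationalMemory(nn.Module):
    """The recurrent cell plus embedding and readout."""

    def __init__(self, config: RmConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        H = config.memory_size
        self.embed = nn.Embedding(N_STAGES + 1, H, rng)
        # attention projections (queries from memory, keys/values from [M; e])
        self.wq = nn.Linear(H, H, rng)
        self.wk = nn.Linear(H, H, rng)
        self.wv = nn.Linear(H, H, rng)
        self.wo = nn.Linear(H, H, rng)
        self.ln1_g = Tensor(np.ones(H), requires_grad=True)
        self.ln1_b = Tensor(np.zeros(H), requires_grad=True)
        hidden = [config.mlp_hidden] * (config.mlp_layers - 1) + [H]
        dims = [H] + hidden
        self.mlp = [nn.Linear(a, b, rng) for a, b in zip(dims, dims[1:])]
        self.ln2_g = Tensor(np.ones(H), requires_grad=True)
        self.ln2_b = Tensor(np.zeros(H), requires_grad=True)
        self.w_f = nn.Linear(H, H, rng)
        self.u_f = nn.Linear(H, H, rng)
        self.w_i = nn.Linear(H, H, rng)
        self.u_i = nn.Linear(H, H, rng)
        self.readout = nn.Linear(config.memory_slots * H, N_STAGES, rng)

    def initial_memory(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.config.memory_slots, self.config.memory_size)))

    # ------------------------------------------------------------------ step
    def step(self, memory: Tensor, tokens: np.ndarray) -> tuple[Tensor, Tensor]:
        """One recurrence.  ``tokens``: int array (B,); returns
        (log-probabilities over the 5 stages (B, 5), next memory)."""
        tokens = np.asarray(tokens)
        if tokens.min() < 0 or tokens.max() > START_TOKEN:
            raise ValueError(f"token index outside the 6-symbol vocabulary: {tokens}")
        cfg = self.config
        B = tokens.shape[0]
        H, nh, hs = cfg.memory_size, cfg.n_heads, cfg.head_size
        e = self.embed(tokens)                             # (B, H)
        e_row = e.reshape((B, 1, H))
        kv_in = ad.concat([memory, e_row], axis=1)         # (B, S+1, H)

        q = self.wq(memory).reshape((B, cfg.memory_slots, nh, hs)).swapaxes(1, 2)
        k = self.wk(kv_in).reshape((B, -1, nh, hs)).swapaxes(1, 2)
        v = self.wv(kv_in).reshape((B, -1, nh, hs)).swapaxes(1, 2)
        scores = ad.matmul(q, k.swapaxes(2, 3)) * (1.0 / np.sqrt(hs))
        attn = nn.softmax(scores, axis=-1)
        ctx = ad.matmul(attn, v).swapaxes(1, 2).reshape((B, cfg.memory_slots, H))
        a = nn.layer_norm(memory + self.wo(ctx), self.ln1_g, self.ln1_b)

        h = a
        for layer in self.mlp[:-1]:
            h = ad.relu(layer(h))
        pa = nn.layer_norm(a + self.mlp[-1](h), self.ln2_g, self.ln2_b)

        mt = ad.tanh(memory)
        f = ad.sigmoid(self.w_f(e_row) + self.u_f(mt))
        i = ad.sigmoid(self.w_i(e_row) + self.u_i(mt))
        new_memory = f * memory + i * ad.tanh(pa)

        logits = self.readout(new_memory.reshape((B, cfg.memory_slots * H)))
        return nn.log_softmax(logits, axis=-1), new_memory


def rm_step(model: RelationalMemory, memory: Tensor, token: int):
    """Single-sequence convenience wrapper: returns the next-stage
    probability vector (length 5, sums to 1) and the updated memory."""
    logp, new_mem = model.step(memory, np.array([token]))
    return np.exp(logp.data[0]), new_mem


# -------------------------------------------------------------------- losses
def mle_loss(step_probs, targets) -> float:
    """Mean negative log-likelihood of the observed next stages.

    ``step_probs``: (T, 5) next-stage distributions O_0..O_{T-1};
    ``targets``: the observed stages I_1..I_T (symbols or indices).  A
    zero probability at a target yields ``inf`` (reported, not masked).
    """
    probs = np.asarray(step_probs, dtype=np.float64)
    idx = encode(targets)
    if probs.shape[0] != idx.shape[0]:
        raise ValueError(f"length mismatch: {probs.shape[0]} outputs vs {idx.shape[0]} targets")
    p = probs[np.arange(len(idx)), idx]
    with np.errstate(divide="ignore"):
        return float(np.mean(-np.log(p)))


def encode(tokens) -> np.ndarray:
    """Stage symbols (or already-integer indices) -> int indices."""
    arr = np.asarray(tokens)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    try:
        return np.array([STAGE_INDEX[t] for t in tokens], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown stage symbol {exc.args[0]!r}") from exc


# ------------------------------------------------------------------ training
@dataclass
class TrainedRm:
    model: RelationalMemory
    config: RmConfig
    loss_trace: list[float] = field(default_factory=list)


def _batch_nll(model: RelationalMemory, batch_idx: np.ndarray) -> Tensor:
    """Teacher-forced mean NLL over a (B, T) batch of stage indices."""
    B, T = batch_idx.shape
    inputs = np.concatenate([np.full((B, 1), START_TOKEN), batch_idx[:, :-1]], axis=1)
    memory = model.initial_memory(B)
    total = None
    for t in range(T):
        logp, memory = model.step(memory, inputs[:, t])
        picked = logp[np.arange(B), batch_idx[:, t]]
        total = picked if total is None else total + picked
    return -ad.mean(total) * (1.0 / T)


def train_mle(sequences, config: RmConfig = RmConfig(), seed: int = 0) -> TrainedRm:
    """Supervised training on a corpus of stage sequences.

    Sequences are bucketed by length; each epoch shuffles the corpus and
    runs Adam on teacher-forced batches.  The recorded trace is the mean
    per-epoch training loss.
    """
    if not sequences:
        raise ValueError("empty training corpus")
    encoded = [encode(s) for s in sequences]
    if any(len(s) < 2 for s in encoded):
        raise ValueError("every training sequence needs length >= 2")
    rng = np.random.default_rng(seed)
    model = RelationalMemory(config, rng)
    opt = nn.Adam([{"params": model.parameters(), "lr": config.lr}], betas=config.adam_betas)
    by_len: dict[int, list[np.ndarray]] = {}
    for s in encoded:
        by_len.setdefault(len(s), []).append(s)
    buckets = [np.stack(v) for v in by_len.values()]

    trace: list[float] = []
    for _ in range(config.epochs):
        epoch_losses = []
        for bucket in buckets:
            order = rng.permutation(len(bucket))
            for start in range(0, len(bucket), config.batch_size):
                batch = bucket[order[start : start + config.batch_size]]
                loss = _batch_nll(model, batch)
                opt.zero_grad()
                ad.backward(loss)
                opt.step()
                epoch_losses.append(loss.item())
        trace.append(float(np.mean(epoch_losses)))
    return TrainedRm(model=model, config=config, loss_trace=trace)


# ---------------------------------------------------------------- generation
def generate_sequence(
    trained: TrainedRm | RelationalMemory,
    length: int = 180,
    seed: int = 0,
    temperature: float = 1.0,
    greedy: bool = False,
) -> list[str]:
    """Free-running rollout from the start token.

    Each step samples the next stage from the temperature-scaled output
    distribution (or takes the argmax when ``greedy``) and feeds it back
    as the next input.  Returns exactly ``length`` stage symbols.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    model = trained.model if isinstance(trained, TrainedRm) else trained
    rng = np.random.default_rng(seed)
    out: list[int] = []
    with ad.no_grad():
        memory = model.initial_memory(1)
        token = START_TOKEN
        for _ in range(length):
            logp, memory = model.step(memory, np.array([token]))
            if greedy:
                token = int(np.argmax(logp.data[0]))
            else:
                logits = logp.data[0] / temperature
                p = np.exp(logits - logits.max())
                p /= p.sum()
                token = int(rng.choice(N_STAGES, p=p))
            out.append(token)
    return [STAGES[t] for t in out]


def conditional_distributions(
    trained: TrainedRm | RelationalMemory, n_steps: int = 10000, seed: int = 0
) -> np.ndarray:
    """Empirical one-step transition matrix of the generator, estimated
    from a single long sampled rollout (row-normalized bigram counts)."""
    seq = generate_sequence(trained, length=n_steps, seed=seed)
    from .fixtures import empirical_transition_matrix

    return empirical_transition_matrix(seq)
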