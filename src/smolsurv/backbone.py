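"""Recurrent encoder: RNN over visits, temporal attention, FNN head.

The encoder maps a subject's ragged visit history to a real vector of
length ``L + p`` consumed by the monotone output layer:

1. a recurrent cell (GRU by default, LSTM selectable) consumes, per visit,
   the concatenation ``[z; x_j; m_j; dtau_j]`` and yields hidden states
   ``h_j`` plus an affine read-out ``x_hat_{j+1}`` predicting the next
   visit's covariates (used only by the reconstruction penalty);
2. temporal attention pools the hidden states of all but the last visit,
   scored by a two-layer scorer against the latest measurement; a subject
   with a single visit gets a zero context vector;
3. a feed-forward head consumes ``[context; z; x_last; m_last]`` and emits
   the output vector.

All computation runs through :mod:`smolsurv.autodiff`, so the same code path
serves training (gradients) and prediction (values only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concatenate, constant
from .data import HistoryBatch

__all__ = ["BackboneConfig", "init_params", "rnn_step", "temporal_attention", "encode_history"]

@dataclass
class BackboneConfig:
    """Architecture of the encoder.

    ``out_dim`` must equal the ``L + p`` of the attached output layer.
    ``include_dtau`` appends the inter-visit gap to the recurrent input;
    irregular visit spacing is the motivation for feeding it, but the
    original input list omits it, so both variants are supported.
    """

    hidden_size: int = 32
    cell: str = "gru"  # "gru" or "lstm"
    attn_hidden: int = 32
    fnn_hidden: tuple = (32,)
    dropout: float = 0.0
    out_dim: int = 13
    include_dtau: bool = True

    def __post_init__(self):
        if self.cell not in ("gru", "lstm"):
            raise ValueError(f"unknown recurrent cell {self.cell!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def init_params(config: BackboneConfig, d_z: int, d_x: int,
                rng: np.random.Generator) -> dict:
    """Seeded uniform fan-in initialisation of all weights; biases zero."""
    d_in = d_z + d_x + (d_z + d_x) + (1 if config.include_dtau else 0)
    H = config.hidden_size
    params: dict[str, Tensor] = {}

    def add(name, fan_in, fan_out, bias=True):
        params[name] = ad.parameter(_glorot(rng, fan_in, fan_out))
        if bias:
            params[name + "_b"] = ad.parameter(np.zeros(fan_out))

    gates = ("a", "c", "h") if config.cell == "gru" else ("i", "f", "o", "g")
    for g in gates:
        add(f"W{g}h", H, H, bias=False)  # the gate bias sits on the input map
        add(f"W{g}y", d_in, H)
    add("Wxh", H, d_x)  # next-visit read-out

    attn_in = H + d_z + d_x + (d_z + d_x)
    add("Wattn1", attn_in, config.attn_hidden)
    add("Wattn2", config.attn_hidden, 1)

    fnn_in = H + d_z + d_x + (d_z + d_x)
    prev = fnn_in
    for i, width in enumerate(config.fnn_hidden):
        add(f"Wfnn{i}", prev, width)
        prev = width
    add("Wout", prev, config.out_dim)
    return params


def _affine(v: Tensor, params: dict, name: str) -> Tensor:
    return v @ params[name] + params[name + "_b"]


def rnn_step(params: dict, config: BackboneConfig, h_prev: Tensor, v: Tensor,
             c_prev: Tensor | None = None):
    """One recurrent update on a batch of input rows ``v``.

    GRU: update gate ``a``, reset gate ``c``, candidate ``h~``, convex
    combination ``h = (1 - a) * h_prev + a * h~``.  LSTM keeps an extra cell
    state.  Returns ``(h, c, x_hat_next)`` where ``x_hat_next`` is the affine
    read-out of the new hidden state predicting the *next* visit's
    covariates.
    """
    if config.cell == "gru":
        a = (h_prev @ params["Wah"] + _affine(v, params, "Way")).sigmoid()
        c = (h_prev @ params["Wch"] + _affine(v, params, "Wcy")).sigmoid()
        h_tilde = ((c * h_prev) @ params["Whh"] + _affine(v, params, "Why")).tanh()
        h = (1.0 - a) * h_prev + a * h_tilde
        c_new = None
    else:
        i = (h_prev @ params["Wih"] + _affine(v, params, "Wiy")).sigmoid()
        f = (h_prev @ params["Wfh"] + _affine(v, params, "Wfy")).sigmoid()
        o = (h_prev @ params["Woh"] + _affine(v, params, "Woy")).sigmoid()
        g = (h_prev @ params["Wgh"] + _affine(v, params, "Wgy")).tanh()
        c_new = f * c_prev + i * g
        h = o * c_new.tanh()
    x_hat = _affine(h, params, "Wxh")
    return h, c_new, x_hat


def temporal_attention(params: dict, H_stack: Tensor, z_feat: np.ndarray,
                       past_mask: np.ndarray) -> Tensor:
    """Softmax-weighted pooling of past hidden states.

    ``H_stack`` is ``(n, Jmax, H)``; ``z_feat`` carries the constant scorer
    features ``[z, x_last, m_last]`` per subject; ``past_mask`` (n, Jmax) is
    one for hidden states that precede the last visit.  Subjects with no
    past state (single visit) receive a zero context vector.
    """
    n, Jmax, H = H_stack.shape
    feat_dim = z_feat.shape[1]
    flat_h = H_stack.reshape(n * Jmax, H)
    flat_feat = constant(np.repeat(z_feat, Jmax, axis=0))
    scorer_in = concatenate([flat_h, flat_feat], axis=1)
    s1 = _affine(scorer_in, params, "Wattn1").relu()
    scores = _affine(s1, params, "Wattn2").reshape(n, Jmax)
    # masked softmax; the max-shift is detached (constant) which leaves
    # gradients unchanged, and masked entries are pushed far negative before
    # exponentiation so they underflow to exactly zero instead of overflowing
    shift = np.where(past_mask > 0, scores.value, -np.inf).max(axis=1, keepdims=True)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    shift = shift + 1e3 * (1.0 - past_mask)
    w = (scores - constant(shift)).exp() * constant(past_mask)
    # the max-shift makes the largest unmasked weight exactly 1, so valid rows
    # have denom >= 1 and the floor only guards all-masked (single-visit) rows
    denom = w.sum(axis=1, keepdims=True) + 1e-12
    attn = w / denom
    context = (attn.reshape(n, Jmax, 1) * H_stack).sum(axis=1)
    return context


def encode_history(params: dict, config: BackboneConfig, batch: HistoryBatch,
                   rng: np.random.Generator | None = None, train: bool = False):
    """Run the full encoder on a padded batch.

    Returns ``(o, x_hat)`` where ``o`` is the ``(n, L + p)`` output tensor
    and ``x_hat`` is an ``(n, Jmax - 1, d_x)`` tensor of next-visit
    predictions (``x_hat[:, j - 1]`` predicts visit ``j``, 0-based), or
    ``None`` when every subject has a single visit.  With dropout disabled
    the pass is deterministic given the weights.
    """
    n, Jmax, d_x = batch.x.shape
    d_z = batch.z.shape[1]
    H = config.hidden_size

    h = constant(np.zeros((n, H)))
    c = constant(np.zeros((n, H))) if config.cell == "lstm" else None
    h_list, xhat_list = [], []
    for j in range(Jmax):
        parts = [batch.z, batch.x[:, j], batch.m[:, j]]
        if config.include_dtau:
            parts.append(batch.dtau[:, j:j + 1])
        v = constant(np.concatenate(parts, axis=1))
        h_new, c_new, x_hat = rnn_step(params, config, h, v, c)
        keep = constant(batch.valid[:, j:j + 1])
        h = keep * h_new + (1.0 - keep) * h
        if config.cell == "lstm":
            c = keep * c_new + (1.0 - keep) * c
        h_list.append(h.reshape(n, 1, H))
        if j < Jmax - 1:
            xhat_list.append(x_hat.reshape(n, 1, d_x))

    H_stack = concatenate(h_list, axis=1)
    z_feat = np.concatenate([batch.z, batch.x_last, batch.m_last], axis=1)
    past_mask = (np.arange(Jmax)[None, :] < (batch.J - 1)[:, None]).astype(float)
    context = temporal_attention(params, H_stack, z_feat, past_mask)

    f = concatenate([context, constant(z_feat)], axis=1)
    for i in range(len(config.fnn_hidden)):
        f = _affine(f, params, f"Wfnn{i}").relu()
        if train and config.dropout > 0:
            mask = (rng.random(f.shape) >= config.dropout) / (1 - config.dropout)
            f = f * constant(mask)
    o = _affine(f, params, "Wout")

    x_hat = concatenate(xhat_list, axis=1) if xhat_list else None
    return o, x_hat
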