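"""Mini-batch Adam training of the monotone-output survival network.

All randomness (weight initialisation, mini-batch partition, dropout) flows
from a single seed, and numpy in single-threaded mode is deterministic, so
two runs with the same seed produce bit-identical histories.  The mini-batch
partition is drawn once and reused across epochs, which lets the spline
constants of the likelihood and the pairwise ranking penalty be precomputed
per batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import BackboneConfig, encode_history, init_params
from .bspline import second_derivative_gram
from .data import HistoryBatch, LongitudinalCohort, build_batch
from .objective import (LikelihoodConstants, LossWeights, likelihood_constants,
                        pairwise_constants, total_loss)
from .smol import SmolHead, survival

__all__ = ["TrainConfig", "Adam", "train", "predict_survival"]


@dataclass
class TrainConfig:
    """Optimisation settings.

    ``batch_size`` must be at least 2 because the ranking penalty needs
    pairs; early stopping watches the validation total loss.
    """

    lr: float = 1e-2
    batch_size: int = 256
    epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (the ranking penalty needs pairs)")
        if self.epochs < 1 or self.patience < 1:
            raise ValueError("epochs and patience must be positive")


class Adam:
    """Adaptive-moment optimiser over a dict of parameter tensors."""

    def __init__(self, params: dict, lr: float = 1e-2, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _subset_batch(batch: HistoryBatch, rows: np.ndarray) -> HistoryBatch:
    return HistoryBatch(z=batch.z[rows], x=batch.x[rows], m=batch.m[rows],
                        dtau=batch.dtau[rows], times=batch.times[rows],
                        valid=batch.valid[rows], J=batch.J[rows],
                        index=batch.index[rows])


def _prepare_batches(cohort: LongitudinalCohort, head: SmolHead,
                     batch_size: int, rng: np.random.Generator,
                     need_pairs: bool) -> list:
    full = build_batch(cohort)
    order = rng.permutation(full.n)
    out = []
    for lo in range(0, full.n, batch_size):
        rows = order[lo: lo + batch_size]
        if len(rows) < 2:
            continue  # a singleton batch has no ranking pairs
        sub = _subset_batch(full, rows)
        lc = likelihood_constants(cohort, head, index=sub.index)
        pc = pairwise_constants(lc, head) if need_pairs else None
        out.append((sub, lc, pc))
    return out


def _epoch_loss(batches, params, bconfig, head, weights, binary_x, gram,
                d_z, rng=None, opt: Adam | None = None) -> float:
    total, n_total = 0.0, 0
    for sub, lc, pc in batches:
        train = opt is not None
        o, x_hat = encode_history(params, bconfig, sub, rng=rng, train=train)
        loss, parts = total_loss(o, x_hat, lc, pc, sub, head, weights,
                                 binary_x, gram=gram, d_z=d_z)
        if not np.isfinite(loss.value):
            bad = [k for k, v in parts.items() if not np.isfinite(v)]
            raise FloatingPointError(f"non-finite loss component(s): {bad}")
        if opt is not None:
            opt.zero_grad()
            loss.backward()
            opt.step()
        total += float(loss.value) * sub.n
        n_total += sub.n
    return total / n_total


def train(train_cohort: LongitudinalCohort, head: SmolHead,
          bconfig: BackboneConfig, weights: LossWeights, tc: TrainConfig,
          val_cohort: LongitudinalCohort | None = None,
          params: dict | None = None) -> tuple[dict, dict]:
    """Fit the network; returns ``(params, history)``.

    ``history`` holds per-epoch training loss and, when a validation cohort
    is given, validation loss; the weights achieving the best validation
    loss are restored before returning.
    """
    rng = np.random.default_rng(tc.seed)
    if params is None:
        params = init_params(bconfig, train_cohort.d_z, train_cohort.d_x, rng)
    need_pairs = weights.lambda1 > 0
    batches = _prepare_batches(train_cohort, head, tc.batch_size, rng, need_pairs)
    val_batches = None
    if val_cohort is not None:
        val_batches = _prepare_batches(val_cohort, head, tc.batch_size,
                                       np.random.default_rng(tc.seed + 1), need_pairs)
    gram = second_derivative_gram(head.ks) if weights.lambda3 > 0 else None
    opt = Adam(params, lr=tc.lr)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, stall = np.inf, None, 0
    for epoch in range(tc.epochs):
        tr = _epoch_loss(batches, params, bconfig, head, weights,
                         train_cohort.binary_x, gram, train_cohort.d_z,
                         rng=rng, opt=opt)
        history["train_loss"].append(tr)
        if val_batches is not None:
            vl = _epoch_loss(val_batches, params, bconfig, head, weights,
                             train_cohort.binary_x, gram, train_cohort.d_z)
            history["val_loss"].append(vl)
            if vl < best_val - 1e-9:
                best_val, stall = vl, 0
                best_state = {k: p.value.copy() for k, p in params.items()}
            else:
                stall += 1
                if stall >= tc.patience:
                    break
    if best_state is not None:
        for k, p in params.items():
            p.value = best_state[k]
    return params, history


def predict_survival(params: dict, bconfig: BackboneConfig, head: SmolHead,
                     cohort: LongitudinalCohort, t: float, s_grid) -> tuple:
    """Conditional survival curves ``S(s | history up to t)``.

    Returns ``(S, index)`` where ``S`` has one row per included subject and
    one column per ``s``; subjects without a visit at or before ``t`` are
    skipped (their positions are absent from ``index``).
    """
    s_grid = np.atleast_1d(np.asarray(s_grid, dtype=float))
    batch = build_batch(cohort, t=t)
    o, _ = encode_history(params, bconfig, batch)
    o_val = o.value
    S = np.column_stack([
        np.atleast_1d(survival(s, t, o_val, head)) for s in s_grid
    ])
    return S, batch.index
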