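"""Time-dependent concordance, the static Cox baseline, experiment harness.

``C(s|t)`` measures how well predicted conditional survival probabilities at
evaluation time ``s``, issued at prediction time ``t``, order the observed
outcomes: among ordered pairs where the first subject has an observed event
in ``(t, s]`` and the second outlives them, the index counts pairs whose
predicted survival orders the other way (lower survival for the earlier
event).  Ties in predicted survival count as discordant (strict inequality);
tied observed times are not comparable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import LongitudinalCohort

__all__ = [
    "EvalGrid",
    "time_dependent_cindex",
    "fit_cph_baseline",
    "cph_conditional_survival",
    "random_search",
    "run_experiment",
]


@dataclass(frozen=True)
class EvalGrid:
    """Pairs of (prediction time t, evaluation time s) with ``t < s``."""

    pairs: tuple

    def __post_init__(self):
        pairs = tuple((float(t), float(s)) for t, s in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        for t, s in pairs:
            if not t < s:
                raise ValueError(f"need t < s, got ({t}, {s})")
            if t < 0:
                raise ValueError("times must be nonnegative")

    def __iter__(self):
        return iter(self.pairs)


def time_dependent_cindex(scores, T, delta, t: float, s: float) -> float:
    """Concordance of predicted survival ``scores = S(s | t)`` with outcomes.

    Numerator: ordered pairs ``(i1, i2)`` with ``delta_{i1} = 1``,
    ``t < T_{i1} <= s``, ``T_{i1} < T_{i2}`` and ``score_{i1} < score_{i2}``.
    Denominator: the same pairs without the score condition.  Raises
    ``ValueError`` when no pair is comparable.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    T = np.asarray(T, dtype=float)
    delta = np.asarray(delta, dtype=int)
    if scores.shape != T.shape:
        raise ValueError("scores and observed times must align")
    ev = np.where((delta == 1) & (T > t) & (T <= s))[0]
    num = den = 0
    for i1 in ev:
        comp = T > T[i1]
        den += int(comp.sum())
        num += int(((scores[i1] < scores) & comp).sum())
    if den == 0:
        raise ValueError(f"no comparable pairs for (t, s) = ({t}, {s})")
    return num / den


def fit_cph_baseline(cohort: LongitudinalCohort, penalizer: float = 0.0):
    """Cox proportional-hazards fit on initial-visit covariates only.

    Returns a fitted :class:`smolsurv.estimators.CoxBaselineSurvival` (which
    keeps the Breslow cumulative baseline hazard for conditional survival
    ratios).
    """
    from .estimators import CoxBaselineSurvival

    return CoxBaselineSurvival(penalizer=penalizer).fit(cohort)


def cph_conditional_survival(model, cohort: LongitudinalCohort,
                             t: float, s) -> np.ndarray:
    """Conditional survival ``S(s)/S(t)`` from a fitted baseline Cox model."""
    S, _ = model.predict_survival(cohort, t, s)
    return S


def random_search(space: dict, budget: int, rng, evaluate=None):
    """Uniform random search over a hyperparameter space.

    ``space`` maps names either to a list/tuple of candidate values (sampled
    uniformly) or to a dict ``{"log10_low": a, "log10_high": b}`` sampled
    log-uniformly.  With an ``evaluate`` callable (config -> score, higher
    better) the best-scoring sampled config is returned; otherwise the list
    of sampled configs.
    """
    if not space:
        raise ValueError("empty hyperparameter space")
    if budget < 1:
        raise ValueError("budget must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    configs = []
    for _ in range(budget):
        cfg = {}
        for name, spec in space.items():
            if isinstance(spec, dict):
                lo, hi = float(spec["log10_low"]), float(spec["log10_high"])
                cfg[name] = 10.0 ** rng.uniform(lo, hi)
            else:
                cfg[name] = spec[rng.integers(len(spec))]
        configs.append(cfg)
    if evaluate is None:
        return configs
    scores = [evaluate(cfg) for cfg in configs]
    return configs[int(np.argmax(scores))]


def _split_indices(n: int, test_frac: float, rng) -> tuple:
    perm = rng.permutation(n)
    n_test = int(round(n * test_frac))
    return perm[n_test:], perm[:n_test]


def run_experiment(make_cohort, model_factory, grid: EvalGrid,
                   n_splits: int = 20, test_frac: float = 0.2,
                   val_frac: float = 0.2, seed: int = 0,
                   search_space: dict | None = None, budget: int = 30) -> pd.DataFrame:
    """Repeated-split evaluation of a model on (simulated) cohorts.

    Per split: a fresh cohort from ``make_cohort(split_seed)`` is divided
    into training (64%), validation (16%) and test (20%) subjects; when a
    ``search_space`` is given, hyperparameters are chosen by random search
    scored by the mean validation ``C(s|t)`` over the grid; the selected
    model is evaluated on the held-out test set.  Returns a tidy table of
    mean and standard deviation (both scaled by 100) per grid cell.
    """
    cells = {pair: [] for pair in grid}
    for split in range(n_splits):
        split_seed = seed + split
        rng = np.random.default_rng(split_seed)
        cohort = make_cohort(split_seed)
        trainval_idx, test_idx = _split_indices(cohort.n, test_frac, rng)
        n_val = int(round(len(trainval_idx) * val_frac))
        val_idx, train_idx = trainval_idx[:n_val], trainval_idx[n_val:]
        train_c = cohort.subset(train_idx)
        val_c = cohort.subset(val_idx)
        test_c = cohort.subset(test_idx)

        def fit_and_score(config, eval_cohort):
            model = model_factory(**(config or {}))
            model.fit(train_c)
            out = {}
            for t, s in grid:
                S, index = model.predict_survival(eval_cohort, t, s)
                try:
                    out[(t, s)] = time_dependent_cindex(
                        S[:, 0], eval_cohort.T[index],
                        eval_cohort.delta[index], t, s)
                except ValueError:
                    out[(t, s)] = np.nan
            return out

        config = None
        if search_space:
            config = random_search(
                search_space, budget, np.random.default_rng(split_seed + 7919),
                evaluate=lambda cfg: np.nanmean(
                    list(fit_and_score(cfg, val_c).values())),
            )
        scores = fit_and_score(config, test_c)
        for pair, c in scores.items():
            cells[pair].append(c)

    rows = []
    for (t, s), vals in cells.items():
        vals = np.asarray(vals, dtype=float)
        ok = np.isfinite(vals)
        rows.append({
            "t": t, "s": s, "n_splits": int(ok.sum()),
            "mean": 100 * np.nanmean(vals) if ok.any() else np.nan,
            "sd": 100 * np.nanstd(vals, ddof=1) if ok.sum() > 1 else np.nan,
        })
    return pd.DataFrame(rows)
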