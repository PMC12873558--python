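"""Estimator interfaces: the monotone-output survival network and the
static Cox baseline.

Both follow the scikit-learn convention — constructor parameters mirror
attribute names, ``fit`` returns ``self``, fitted state carries a trailing
underscore — and consume :class:`~smolsurv.data.LongitudinalCohort` objects
rather than flat design matrices, since the input is a ragged longitudinal
history per subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .backbone import BackboneConfig
from .data import LongitudinalCohort
from .evaluation import time_dependent_cindex
from .objective import LossWeights
from .smol import SmolHead
from .trainer import TrainConfig, predict_survival, train

__all__ = ["SmolSurvivalNet", "CoxBaselineSurvival"]


class SmolSurvivalNet(BaseEstimator):
    """Dynamic survival prediction with a smooth monotone spline output.

    A recurrent encoder with temporal attention summarises each subject's
    visit history into a vector; cumulative sums of its positively mapped
    entries act as B-spline coefficients, yielding a strictly increasing
    differentiable function of time whose exponentiated differences are
    conditional survival probabilities.  Training minimises the penalized
    negative log-likelihood (ranking, reconstruction and curvature
    penalties) with Adam.

    Parameters
    ----------
    L, p : int
        Interior segment count and spline degree of the output basis.
    t_max : float
        Upper end of the follow-up window in years.
    lambda1, lambda2, lambda3 : float
        Weights of the ranking, reconstruction and curvature penalties.
    val_fraction : float
        Fraction of training subjects held out for early stopping.

    Attributes
    ----------
    params_ : dict
        Trained weight tensors.
    head_ : SmolHead
        Knot sequence and positivity shift of the output layer.
    history_ : dict
        Per-epoch training / validation losses.
    """

    def __init__(self, L=10, p=3, t_max=30.0, eps_phi=1e-8,
                 hidden_size=32, cell="gru", attn_hidden=32, fnn_hidden=(32,),
                 dropout=0.0, include_dtau=True,
                 lambda1=1.0, lambda2=0.1, lambda3=10.0, eps_zeta=1e-8,
                 lr=1e-2, batch_size=256, epochs=100, patience=10,
                 val_fraction=0.2, random_state=0):
        self.L = L
        self.p = p
        self.t_max = t_max
        self.eps_phi = eps_phi
        self.hidden_size = hidden_size
        self.cell = cell
        self.attn_hidden = attn_hidden
        self.fnn_hidden = fnn_hidden
        self.dropout = dropout
        self.include_dtau = include_dtau
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda3 = lambda3
        self.eps_zeta = eps_zeta
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, cohort: LongitudinalCohort, y=None):
        """Train on a cohort; ``y`` is ignored (survival data live in the
        cohort)."""
        head = SmolHead.create(self.L, self.p, self.t_max, self.eps_phi)
        bconfig = BackboneConfig(
            hidden_size=self.hidden_size, cell=self.cell,
            attn_hidden=self.attn_hidden, fnn_hidden=tuple(self.fnn_hidden),
            dropout=self.dropout, out_dim=head.n_basis,
            include_dtau=self.include_dtau,
        )
        weights = LossWeights(self.lambda1, self.lambda2, self.lambda3, self.eps_zeta)
        tc = TrainConfig(lr=self.lr, batch_size=self.batch_size,
                         epochs=self.epochs, patience=self.patience,
                         seed=self.random_state)
        val_cohort = None
        train_cohort = cohort
        if self.val_fraction and self.val_fraction > 0:
            rng = np.random.default_rng(self.random_state)
            perm = rng.permutation(cohort.n)
            n_val = int(round(cohort.n * self.val_fraction))
            if n_val >= 2 and cohort.n - n_val >= 2:
                val_cohort = cohort.subset(perm[:n_val])
                train_cohort = cohort.subset(perm[n_val:])
        self.params_, self.history_ = train(train_cohort, head, bconfig,
                                            weights, tc, val_cohort=val_cohort)
        self.head_ = head
        self.bconfig_ = bconfig
        self.n_features_in_ = cohort.d_z + cohort.d_x
        return self

    def predict_survival(self, cohort: LongitudinalCohort, t: float, s):
        """Conditional survival ``S(s | history up to t)``.

        Returns ``(S, index)``: one row per subject with at least one visit
        at or before ``t`` (positions in ``index``), one column per ``s``.
        """
        self._check_fitted()
        return predict_survival(self.params_, self.bconfig_, self.head_,
                                cohort, t, s)

    def score(self, cohort: LongitudinalCohort, t: float = 2.0, s: float = 4.0):
        """Time-dependent concordance ``C(s|t)`` on a cohort."""
        S, index = self.predict_survival(cohort, t, s)
        return time_dependent_cindex(S[:, 0], cohort.T[index],
                                     cohort.delta[index], t, s)

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted; call fit first")


class CoxBaselineSurvival(BaseEstimator):
    """Static proportional-hazards baseline on initial-visit covariates.

    Fits a Cox model (Breslow baseline) to the time-invariant covariates
    plus the covariate values measured at each subject's first visit, and
    issues conditional survival as the ratio ``S(s)/S(t)`` of the subject's
    estimated survival curve.  Non-dynamic by construction: later visits are
    ignored.
    """

    def __init__(self, penalizer: float = 0.0):
        self.penalizer = penalizer

    @staticmethod
    def _design(cohort: LongitudinalCohort) -> pd.DataFrame:
        x0 = np.vstack([x[0] for x in cohort.x])
        cols = {f"z{k+1}": cohort.z[:, k] for k in range(cohort.d_z)}
        cols.update({f"x{k+1}": x0[:, k] for k in range(cohort.d_x)})
        return pd.DataFrame(cols)

    def fit(self, cohort: LongitudinalCohort, y=None):
        from lifelines import CoxPHFitter
        from lifelines.exceptions import ConvergenceError

        df = self._design(cohort)
        df["time"] = cohort.T
        df["event"] = cohort.delta
        model = CoxPHFitter(penalizer=self.penalizer)
        try:
            model.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as err:
            raise RuntimeError(f"Cox baseline failed to converge: {err}") from err
        self.model_ = model
        self.coef_ = model.params_.to_numpy()
        self.n_features_in_ = df.shape[1] - 2
        return self

    def predict_survival(self, cohort: LongitudinalCohort, t: float, s):
        """Conditional survival ratio ``S(s)/S(t)`` per subject.

        Returns ``(S, index)`` with ``index`` covering every subject (the
        baseline model never excludes anyone).  Raises when ``S(t)`` is
        numerically zero for some subject.
        """
        self._check_fitted()
        s_grid = np.atleast_1d(np.asarray(s, dtype=float))
        times = np.unique(np.concatenate([[t], s_grid]))
        sf = self.model_.predict_survival_function(self._design(cohort), times=times)
        St = sf.loc[t].to_numpy()
        if np.any(St <= 0):
            raise ZeroDivisionError("estimated S(t) is zero for some subject")
        S = np.column_stack([sf.loc[si].to_numpy() / St for si in s_grid])
        return np.minimum(S, 1.0), np.arange(cohort.n)

    def score(self, cohort: LongitudinalCohort, t: float = 2.0, s: float = 4.0):
        S, index = self.predict_survival(cohort, t, s)
        return time_dependent_cindex(S[:, 0], cohort.T[index],
                                     cohort.delta[index], t, s)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")
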