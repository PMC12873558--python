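"""Longitudinal time-to-event cohorts: containers, ingestion, batching.

A cohort couples, per subject, time-invariant covariates ``z`` (length
``d_z``), ragged per-visit time-varying covariates ``x`` (length ``d_x``)
with binary missingness masks (1 = missing), visit times aligned so the
first visit is at 0, and right-censored survival data ``(T, delta)``.

On disk a cohort is two delimited text files: a visits table (one row per
subject-visit) and a subjects table (one row per subject).  Missing
covariate cells may be left empty; they are imputed with column means
(continuous) or zeros (binary) and flagged in the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LongitudinalCohort", "HistoryBatch", "read_cohort", "write_cohort", "build_batch"]


@dataclass
class LongitudinalCohort:
    """In-memory longitudinal cohort.

    Attributes
    ----------
    z : (n, d_z) array of baseline covariates (imputed where masked).
    z_mask : (n, d_z) binary array, 1 where the entry was missing.
    times : list of n arrays of visit times, each starting at 0, increasing.
    x : list of n ``(J_i, d_x)`` arrays of time-varying covariates.
    x_mask : list of n ``(J_i, d_x)`` binary missingness arrays.
    T : (n,) observed times ``min(event, censoring)``.
    delta : (n,) event indicators.
    binary_x : (d_x,) booleans marking binary time-varying covariates
        (cross-entropy instead of squared error in the reconstruction
        penalty).
    ids : (n,) subject identifiers.
    """

    z: np.ndarray
    z_mask: np.ndarray
    times: list
    x: list
    x_mask: list
    T: np.ndarray
    delta: np.ndarray
    binary_x: np.ndarray = None
    ids: np.ndarray = None

    def __post_init__(self):
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        self.z_mask = np.atleast_2d(np.asarray(self.z_mask, dtype=float))
        self.T = np.asarray(self.T, dtype=float)
        self.delta = np.asarray(self.delta, dtype=int)
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        self.x = [np.atleast_2d(np.asarray(v, dtype=float)) for v in self.x]
        self.x_mask = [np.atleast_2d(np.asarray(v, dtype=float)) for v in self.x_mask]
        if self.binary_x is None:
            self.binary_x = np.zeros(self.d_x, dtype=bool)
        self.binary_x = np.asarray(self.binary_x, dtype=bool)
        if self.ids is None:
            self.ids = np.arange(self.n)
        self.ids = np.asarray(self.ids)
        for i, t in enumerate(self.times):
            if len(t) == 0:
                raise ValueError(f"subject {self.ids[i]} has no visits")
            if abs(t[0]) > 1e-9:
                raise ValueError(f"subject {self.ids[i]}: first visit must be at time 0")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"subject {self.ids[i]}: visit times must be increasing")
            if t[-1] > self.T[i] + 1e-9:
                raise ValueError(f"subject {self.ids[i]}: visit after observed time")

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def d_z(self) -> int:
        return self.z.shape[1]

    @property
    def d_x(self) -> int:
        return self.x[0].shape[1]

    def n_visits(self, t: float | None = None) -> np.ndarray:
        """``J_i(t)``: number of visits at or before ``t`` (all if None)."""
        if t is None:
            return np.array([len(v) for v in self.times])
        return np.array([int(np.sum(v <= t + 1e-9)) for v in self.times])

    def last_visit_time(self) -> np.ndarray:
        return np.array([v[-1] for v in self.times])

    def subset(self, idx) -> "LongitudinalCohort":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.where(idx)[0]
        return LongitudinalCohort(
            z=self.z[idx], z_mask=self.z_mask[idx],
            times=[self.times[i] for i in idx],
            x=[self.x[i] for i in idx],
            x_mask=[self.x_mask[i] for i in idx],
            T=self.T[idx], delta=self.delta[idx],
            binary_x=self.binary_x, ids=self.ids[idx],
        )

    # -- serialisation ----------------------------------------------------
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Long-format (visits, subjects) tables; masked cells become NaN."""
        rows = []
        for i in range(self.n):
            for j, tau in enumerate(self.times[i]):
                vals = self.x[i][j].copy()
                vals[self.x_mask[i][j] > 0] = np.nan
                rows.append([self.ids[i], tau, *vals])
        visits = pd.DataFrame(rows, columns=["id", "visit_time",
                                             *(f"x{k+1}" for k in range(self.d_x))])
        zvals = self.z.copy()
        zvals[self.z_mask > 0] = np.nan
        subjects = pd.DataFrame(
            np.column_stack([self.ids, zvals, self.T, self.delta]),
            columns=["id", *(f"z{k+1}" for k in range(self.d_z)), "time", "event"],
        )
        return visits, subjects


def write_cohort(cohort: LongitudinalCohort, visits_path, subjects_path) -> None:
    visits, subjects = cohort.to_frames()
    visits.to_csv(visits_path, index=False)
    subjects.to_csv(subjects_path, index=False)


def _impute(values: np.ndarray, mask: np.ndarray, binary: np.ndarray) -> np.ndarray:
    """Column means for continuous entries, zeros for binary ones."""
    out = values.copy()
    for k in range(values.shape[1]):
        miss = mask[:, k] > 0
        if not miss.any():
            continue
        if binary[k]:
            fill = 0.0
        else:
            obs = values[~miss, k]
            fill = float(obs.mean()) if len(obs) else 0.0
        out[miss, k] = fill
    return out


def _infer_binary(values: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.array([
            np.all(np.isin(values[~np.isnan(values[:, k]), k], (0.0, 1.0)))
            and len(np.unique(values[~np.isnan(values[:, k]), k])) <= 2
            for k in range(values.shape[1])
        ])


def read_cohort(visits_path, subjects_path, binary_x=None) -> LongitudinalCohort:
    """Build a cohort from the two delimited text tables.

    Missingness is taken from empty cells; masks are 1 where a value was
    absent.  Validation rejects duplicate (id, time) rows, visits after the
    observed time, and non-binary event indicators, listing offending rows.
    """
    visits = pd.read_csv(visits_path)
    subjects = pd.read_csv(subjects_path)
    xcols = [c for c in visits.columns if c not in ("id", "visit_time")]
    zcols = [c for c in subjects.columns if c not in ("id", "time", "event")]

    dup = visits.duplicated(subset=["id", "visit_time"])
    if dup.any():
        raise ValueError(f"duplicate (id, visit_time) rows: {list(visits.index[dup])}")
    if not set(visits["id"]).issubset(set(subjects["id"])):
        orphans = sorted(set(visits["id"]) - set(subjects["id"]))
        raise ValueError(f"visit rows reference unknown subjects: {orphans}")
    bad_event = ~subjects["event"].isin([0, 1])
    if bad_event.any():
        raise ValueError(f"non-binary event indicator rows: {list(subjects.index[bad_event])}")

    zvals = subjects[zcols].to_numpy(dtype=float)
    z_mask = np.isnan(zvals).astype(float)
    xall = visits[xcols].to_numpy(dtype=float)
    if binary_x is None:
        binary_x = _infer_binary(xall)
    binary_x = np.asarray(binary_x, dtype=bool)
    z = _impute(zvals, z_mask, _infer_binary(zvals))

    xg = visits.sort_values(["id", "visit_time"]).groupby("id", sort=False)
    times, x, x_mask = {}, {}, {}
    for sid, grp in xg:
        tau = grp["visit_time"].to_numpy(dtype=float)
        vals = grp[xcols].to_numpy(dtype=float)
        mask = np.isnan(vals).astype(float)
        times[sid], x[sid], x_mask[sid] = tau, vals, mask

    ids = subjects["id"].to_numpy()
    T = subjects["time"].to_numpy(dtype=float)
    delta = subjects["event"].to_numpy()
    order_times, order_x, order_m = [], [], []
    bad = []
    for sid, Ti in zip(ids, T):
        if sid not in times:
            bad.append(sid)
            continue
        if times[sid][-1] > Ti + 1e-9:
            raise ValueError(f"subject {sid}: visit at {times[sid][-1]} after observed time {Ti}")
        order_times.append(times[sid])
        order_x.append(x[sid])
        order_m.append(x_mask[sid])
    if bad:
        raise ValueError(f"subjects without visit rows: {bad}")

    # impute time-varying covariates with global column means / zeros
    stacked = np.vstack(order_x)
    smask = np.vstack(order_m)
    imputed = _impute(stacked, smask, binary_x)
    out_x, pos = [], 0
    for arr in order_x:
        out_x.append(imputed[pos: pos + len(arr)])
        pos += len(arr)

    return LongitudinalCohort(z=z, z_mask=z_mask, times=order_times, x=out_x,
                              x_mask=order_m, T=T, delta=delta,
                              binary_x=binary_x, ids=ids)


@dataclass
class HistoryBatch:
    """Padded view of the histories used by the recurrent encoder.

    ``m`` concatenates the baseline and per-visit masks (Eq-style indicator
    convention, 1 = missing); ``dtau`` holds inter-visit gaps with the first
    gap zero; ``valid`` marks real (non-padding) visits.
    """

    z: np.ndarray          # (n, d_z)
    x: np.ndarray          # (n, Jmax, d_x)
    m: np.ndarray          # (n, Jmax, d_z + d_x)
    dtau: np.ndarray       # (n, Jmax)
    times: np.ndarray      # (n, Jmax)
    valid: np.ndarray      # (n, Jmax) float 0/1
    J: np.ndarray          # (n,) number of visits
    index: np.ndarray      # positions of included subjects in the cohort

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def x_last(self) -> np.ndarray:
        i = np.arange(self.n)
        return self.x[i, self.J - 1]

    @property
    def m_last(self) -> np.ndarray:
        i = np.arange(self.n)
        return self.m[i, self.J - 1]


def build_batch(cohort: LongitudinalCohort, t: float | None = None) -> HistoryBatch:
    """Pad histories up to prediction time ``t`` (all visits if None).

    Subjects with no visit at or before ``t`` are excluded with a warning;
    ``index`` maps the batch rows back to cohort positions.
    """
    J = cohort.n_visits(t)
    keep = np.where(J >= 1)[0]
    if len(keep) < cohort.n:
        warnings.warn(
            f"excluded {cohort.n - len(keep)} subject(s) with no visits before t={t}"
        )
    J = J[keep]
    Jmax = int(J.max())
    n, d_x, d_z = len(keep), cohort.d_x, cohort.d_z
    x = np.zeros((n, Jmax, d_x))
    m = np.ones((n, Jmax, d_z + d_x))
    dtau = np.zeros((n, Jmax))
    times = np.zeros((n, Jmax))
    valid = np.zeros((n, Jmax))
    for r, i in enumerate(keep):
        j = J[r]
        x[r, :j] = cohort.x[i][:j]
        m[r, :j, :d_z] = cohort.z_mask[i]
        m[r, :j, d_z:] = cohort.x_mask[i][:j]
        tt = cohort.times[i][:j]
        times[r, :j] = tt
        dtau[r, 1:j] = np.diff(tt)
        valid[r, :j] = 1.0
    return HistoryBatch(z=cohort.z[keep], x=x, m=m, dtau=dtau, times=times,
                        valid=valid, J=J, index=keep)
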