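"""Parcel-level first-level GLM for the sustained-attention task.

The design follows the six-EV layout used for locating task states:

* EV1 ``vigilance``  - boxcar over non-target trial periods
* EV2 ``target``     - boxcar over target trial periods
* EV3 ``probe_window`` - unit boxcar over the 6 s preceding each probe
* EV4-EV6 ``thought_1..3`` - the probe-window boxcar scaled by that probe's
  component score, scores mean-centered within run (parametric regressors)

All EVs are convolved with a gamma HRF (mean lag 6 s, sd 3 s); confound
columns (motion parameters and friends) enter unconvolved and are excluded
from contrasts.  Estimation is plain OLS per parcel with an optional AR(1)
Cochrane-Orcutt correction; run-level results combine across runs by
inverse-variance (fixed-effects) averaging.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gamma_hrf",
    "build_design",
    "highpass",
    "fit_glm",
    "fixed_effects_average",
    "DesignMatrix",
    "GLMResult",
    "ParcelGLM",
]

#: Gamma HRF shape: mean lag 6 s, standard deviation 3 s.
HRF_MEAN_LAG = 6.0
HRF_SD = 3.0
HRF_LENGTH = 32.0

EV_NAMES = ("vigilance", "target", "probe_window")


class DesignError(ValueError):
    pass


class RankDeficientError(DesignError):
    pass


def gamma_hrf(tr: float, length: float = HRF_LENGTH) -> np.ndarray:
    """Gamma-density HRF kernel sampled at ``tr``, normalized to unit sum.

    Shape/scale are chosen so the density has mean lag 6 s and sd 3 s
    (shape 4, scale 1.5 s); the kernel covers at least ``length`` seconds.
    A unit-sum kernel leaves constant signals unchanged after burn-in.
    """
    if tr <= 0:
        raise DesignError("tr must be positive")
    shape = (HRF_MEAN_LAG / HRF_SD) ** 2
    scale = HRF_SD**2 / HRF_MEAN_LAG
    n = int(np.ceil(length / tr)) + 1
    t = np.arange(n) * tr
    h = stats.gamma.pdf(t, a=shape, scale=scale)
    return h / h.sum()


@dataclasses.dataclass
class DesignMatrix:
    """A volumes x regressors design with metadata.

    ``task_columns`` are the HRF-convolved EVs eligible for contrasts;
    ``confound_columns`` entered unconvolved and are excluded from them.
    """

    frame: pd.DataFrame
    tr: float
    task_columns: tuple[str, ...]
    confound_columns: tuple[str, ...]
    convolved: bool = True

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    def matrix(self, intercept: bool = True) -> pd.DataFrame:
        X = self.frame.copy()
        if intercept:
            X.insert(0, "intercept", 1.0)
        return X


def _occupancy(onsets, durations, tr: float, n_volumes: int) -> np.ndarray:
    """Fraction of each TR occupied by the given intervals (boxcar sampling)."""
    box = np.zeros(n_volumes)
    edges = np.arange(n_volumes + 1) * tr
    for onset, dur in zip(onsets, durations):
        start, stop = max(onset, 0.0), min(onset + dur, n_volumes * tr)
        if stop <= start:
            continue
        lo = int(np.floor(start / tr))
        hi = int(np.ceil(stop / tr))
        for v in range(lo, min(hi, n_volumes)):
            overlap = min(stop, edges[v + 1]) - max(start, edges[v])
            box[v] += max(overlap, 0.0) / tr
    return box


def build_design(
    events: pd.DataFrame,
    scores: pd.DataFrame | None,
    tr: float,
    n_volumes: int,
    probe_window: float = 6.0,
    confounds: pd.DataFrame | None = None,
    convolve: bool = True,
) -> DesignMatrix:
    """Build the six-EV first-level design for one run.

    Parameters
    ----------
    events : DataFrame with columns onset, duration, event_type
        ``event_type`` in {non_target, target, probe}.
    scores : DataFrame or None
        One row per probe (in onset order) with columns ``score_1..k``;
        scores are mean-centered within the run before scaling the
        probe-window boxcar.  ``None`` builds a three-EV design.
    probe_window : seconds
        Pre-probe window modeled by EV3 and the parametric EVs.  A probe
        whose window would extend before the run start is truncated with a
        warning.
    """
    events = events.sort_values("onset")
    probes = events[events["event_type"] == "probe"]
    run_len = n_volumes * tr
    if len(events) and (events["onset"] + events["duration"]).max() > run_len + 1e-9:
        raise DesignError("events extend beyond the run duration")

    cols: dict[str, np.ndarray] = {}
    for name, etype in (("vigilance", "non_target"), ("target", "target")):
        sel = events[events["event_type"] == etype]
        cols[name] = _occupancy(sel["onset"].to_numpy(), sel["duration"].to_numpy(), tr, n_volumes)

    # pre-probe window snapped to whole volumes (2 volumes at TR 3 s):
    # support ends at the volume containing the probe onset (exclusive)
    n_win = max(int(round(probe_window / tr)), 1)
    win_volumes = []
    truncated = False
    for onset in probes["onset"].to_numpy(float):
        end_vol = int(np.floor(onset / tr + 1e-9))
        start_vol = end_vol - n_win
        if start_vol < 0:
            truncated = True
            start_vol = 0
        win_volumes.append(np.arange(start_vol, min(end_vol, n_volumes)))
    if truncated:
        warnings.warn("probe window truncated at run start", stacklevel=2)
    ev3 = np.zeros(n_volumes)
    for vols in win_volumes:
        ev3[vols] += 1.0
    cols["probe_window"] = ev3

    task_names = list(EV_NAMES)
    if scores is not None:
        score_cols = [c for c in scores.columns if c.startswith("score_")]
        if len(scores) != len(probes):
            raise DesignError(
                f"{len(probes)} probes but {len(scores)} score rows (missing scores?)"
            )
        centered = scores[score_cols] - scores[score_cols].mean()
        for j, sc in enumerate(score_cols, start=1):
            ev = np.zeros(n_volumes)
            for vols, s in zip(win_volumes, centered[sc]):
                ev[vols] += s
            name = f"thought_{j}"
            cols[name] = ev
            task_names.append(name)

    if convolve:
        kernel = gamma_hrf(tr)
        frame = pd.DataFrame(
            {name: np.convolve(col, kernel)[:n_volumes] for name, col in cols.items()}
        )
    else:
        frame = pd.DataFrame(cols)
    for name in EV_NAMES:
        if not frame[name].any():
            raise DesignError(f"EV {name!r} is identically zero")

    confound_names: tuple[str, ...] = ()
    if confounds is not None:
        confounds = confounds.reset_index(drop=True)
        if len(confounds) != n_volumes:
            raise DesignError("confound length does not match n_volumes")
        for c in confounds.columns:
            frame[c] = confounds[c].to_numpy(float)
        confound_names = tuple(confounds.columns)

    return DesignMatrix(
        frame=frame,
        tr=tr,
        task_columns=tuple(task_names),
        confound_columns=confound_names,
        convolved=convolve,
    )


def _gaussian_line_smoother(n: int, tr: float, sigma: float) -> np.ndarray:
    """N x N matrix evaluating a Gaussian-weighted local linear fit at each t."""
    t = np.arange(n) * tr
    S = np.empty((n, n))
    for i in range(n):
        w = np.exp(-0.5 * ((t - t[i]) / sigma) ** 2)
        tc = t - t[i]
        s0, s1, s2 = w.sum(), (w * tc).sum(), (w * tc**2).sum()
        det = s0 * s2 - s1**2
        # fitted value at t_i is the local intercept of the weighted line
        S[i] = (s2 * w - s1 * w * tc) / det
    return S


def highpass(timeseries: pd.DataFrame | np.ndarray, sigma: float, tr: float) -> pd.DataFrame:
    """High-pass filter by subtracting a Gaussian-weighted running line.

    At each timepoint a straight line is fitted by weighted least squares
    (Gaussian weights, sd ``sigma`` seconds) and its local value subtracted.
    Any global linear trend is removed exactly; series length is preserved.
    """
    arr = np.asarray(timeseries, float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    n = arr.shape[0]
    if n < 3:
        raise DesignError("series too short to filter (need >= 3 volumes)")
    if sigma <= tr:
        raise DesignError("sigma must exceed the TR")
    S = _gaussian_line_smoother(n, tr, sigma)
    filtered = arr - S @ arr
    if isinstance(timeseries, pd.DataFrame):
        return pd.DataFrame(filtered, index=timeseries.index, columns=timeseries.columns)
    return filtered[:, 0] if squeeze else filtered


@dataclasses.dataclass
class GLMResult:
    """Per-parcel contrast estimates at run or subject level."""

    beta: pd.DataFrame  # parcels x contrasts
    var: pd.DataFrame
    t: pd.DataFrame | None
    z: pd.DataFrame
    dof: int
    level: str  # "run" or "subject"

    def map_for(self, contrast: str) -> pd.Series:
        """The z-stat parcel map for one contrast."""
        return self.z[contrast]


def _z_from_t(t: np.ndarray, dof: float) -> np.ndarray:
    """Convert t to z by exact two-sided tail matching (sign-preserving)."""
    with np.errstate(invalid="ignore"):
        tail = stats.t.sf(np.abs(t), dof)
    tail = np.clip(tail, 1e-300, None)
    return np.sign(t) * stats.norm.isf(tail)


class ParcelGLM:
    """OLS estimator for parcel timeseries against a task design.

    sklearn-style: ``fit(timeseries)`` stores ``beta_``, ``sigma2_``,
    ``dof_``; ``contrast_results(contrasts)`` yields a :class:`GLMResult`.
    ``ar1=True`` applies a one-step Cochrane-Orcutt correction before the
    final fit (synthetic noise is white by default, so plain OLS is the
    default path).
    """

    def __init__(self, design: DesignMatrix, ar1: bool = False):
        self.design = design
        self.ar1 = ar1

    def fit(self, timeseries: pd.DataFrame) -> "ParcelGLM":
        X = self.design.matrix(intercept=True)
        if len(timeseries) != len(X):
            raise DesignError("timeseries length does not match design")
        Xv = X.to_numpy(float)
        rank = np.linalg.matrix_rank(Xv)
        if rank < Xv.shape[1]:
            # name the collinear columns via QR pivoting on the gram matrix
            _, R = np.linalg.qr(Xv)
            bad = [X.columns[j] for j in range(Xv.shape[1]) if abs(R[j, j]) < 1e-8]
            raise RankDeficientError(f"design is rank deficient; collinear columns: {bad}")
        Y = timeseries.to_numpy(float)
        if self.ar1:
            Xv, Y = self._prewhiten(Xv, Y)
        XtX_inv = np.linalg.inv(Xv.T @ Xv)
        B = XtX_inv @ Xv.T @ Y
        resid = Y - Xv @ B
        dof = Xv.shape[0] - Xv.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        self.columns_ = list(X.columns)
        self.parcels_ = timeseries.columns
        self.beta_ = pd.DataFrame(B.T, index=self.parcels_, columns=self.columns_)
        self.xtx_inv_ = XtX_inv
        self.sigma2_ = pd.Series(sigma2, index=self.parcels_)
        self.dof_ = dof
        return self

    def _prewhiten(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        B = np.linalg.lstsq(X, Y, rcond=None)[0]
        resid = Y - X @ B
        num = (resid[1:] * resid[:-1]).sum()
        den = (resid[:-1] ** 2).sum()
        rho = 0.0 if den == 0 else float(np.clip(num / den, -0.99, 0.99))
        return X[1:] - rho * X[:-1], Y[1:] - rho * Y[:-1]

    def contrast_results(self, contrasts: Mapping[str, Mapping[str, float]]) -> GLMResult:
        """Evaluate named contrasts (weights over task columns) per parcel.

        A weight on a confound column is rejected; an all-zero contrast
        yields beta 0 with the z flagged undefined (NaN) rather than
        propagating a 0/0.
        """
        betas, vars_, ts, zs = {}, {}, {}, {}
        for name, weights in contrasts.items():
            bad = set(weights) - set(self.design.task_columns)
            if bad:
                raise DesignError(f"contrast {name!r} weights non-task columns {sorted(bad)}")
            c = np.array([float(weights.get(col, 0.0)) for col in self.columns_])
            cb = self.beta_.to_numpy() @ c
            quad = float(c @ self.xtx_inv_ @ c)
            v = quad * self.sigma2_.to_numpy()
            betas[name] = cb
            vars_[name] = v
            if quad == 0.0:
                warnings.warn(f"contrast {name!r} is null; z undefined", stacklevel=2)
                ts[name] = np.full(len(cb), np.nan)
                zs[name] = np.full(len(cb), np.nan)
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = cb / np.sqrt(v)
                ts[name] = t
                zs[name] = _z_from_t(t, self.dof_)
        idx = self.parcels_
        return GLMResult(
            beta=pd.DataFrame(betas, index=idx),
            var=pd.DataFrame(vars_, index=idx),
            t=pd.DataFrame(ts, index=idx),
            z=pd.DataFrame(zs, index=idx),
            dof=self.dof_,
            level="run",
        )


def fit_glm(
    timeseries: pd.DataFrame,
    design: DesignMatrix,
    contrasts: Mapping[str, Mapping[str, float]],
    ar1: bool = False,
) -> GLMResult:
    """Run-level OLS fit + contrasts (thin wrapper over :class:`ParcelGLM`)."""
    return ParcelGLM(design, ar1=ar1).fit(timeseries).contrast_results(contrasts)


def fixed_effects_average(run_results: Sequence[GLMResult]) -> GLMResult:
    """Combine run-level contrasts within a subject by inverse-variance.

    beta = sum(b_r / v_r) / sum(1 / v_r), var = 1 / sum(1 / v_r); the z is
    recomputed from the combined estimate (standard-normal reference, as in
    fixed-effects averaging of first-level runs).  A single run passes
    through unchanged.
    """
    if not run_results:
        raise ValueError("need at least one run")
    first = run_results[0]
    for r in run_results[1:]:
        if not r.beta.index.equals(first.beta.index) or list(r.beta.columns) != list(
            first.beta.columns
        ):
            raise ValueError("runs have inconsistent parcel sets or contrasts")
    if len(run_results) == 1:
        return dataclasses.replace(first, level="subject")
    w = [1.0 / r.var for r in run_results]
    wsum = sum(w)
    beta = sum(wi * r.beta for wi, r in zip(w, run_results)) / wsum
    var = 1.0 / wsum
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / np.sqrt(var)
    return GLMResult(beta=beta, var=var, t=None, z=z, dof=sum(r.dof for r in run_results), level="subject")
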