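"""First-level GLM: canonical HRF design matrices, AR(1) prewhitened
least squares, and the Near-vs-Far distance-effect contrast.

Each correct-trial condition (little_near, little_far, big_near, big_far)
is modeled as a 2500 ms boxcar convolved with a double-gamma canonical
hemodynamic response plus its temporal derivative; an error regressor
(incorrect trials) gets the same two bases; six head-motion series and an
intercept complete the 17-column layout.  Serial correlation is handled
by a single pooled lag-1 autoregressive coefficient estimated from
in-mask OLS residuals, followed by one-pass Cochrane-Orcutt style
prewhitening (Prais-Winsten scaling of the first sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

logger = logging.getLogger(__name__)

CONDITIONS = ("little_near", "little_far", "big_near", "big_far")
ERROR_CONDITION = "error"
TRIAL_DURATION_S = 2.5


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalized to 1.

    Standard parameterization: response gamma peaking ~5 s after onset,
    undershoot gamma peaking ~15 s, undershoot amplitude 1/6.
    """
    t = np.asarray(t, float)
    h = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp) - ratio * (
        gamma_dist.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    )
    peak = h.max()
    return h / peak if peak > 0 else h


@dataclass
class DesignMatrix:
    """Volumes x regressors design with TR and column labels."""

    frame: pd.DataFrame
    tr_ms: float

    @property
    def values(self) -> np.ndarray:
        return self.frame.values

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def _event_regressors(
    events: pd.DataFrame,
    n_vols: int,
    tr_ms: float,
    dt: float = 0.1,
    include_derivative: bool = True,
) -> pd.DataFrame:
    """Boxcar-convolved condition regressors sampled at volume onsets."""
    tr_s = tr_ms / 1000.0
    duration_s = n_vols * tr_s
    if ((events["onset_s"] < 0) | (events["onset_s"] + events["duration_s"] > duration_s)).any():
        raise ValueError("event outside scan duration")
    n_hi = int(np.ceil(duration_s / dt)) + 1
    t_hi = np.arange(n_hi) * dt
    hrf = double_gamma_hrf(np.arange(0, 32, dt))
    dhrf = np.gradient(hrf, dt)
    vol_idx = np.rint(np.arange(n_vols) * tr_s / dt).astype(int)
    cols = {}
    order = [c for c in CONDITIONS if c in set(events["condition"])]
    order += [ERROR_CONDITION] if ERROR_CONDITION in set(events["condition"]) else []
    for cond in order:
        neural = np.zeros(n_hi)
        for _, ev in events[events["condition"] == cond].iterrows():
            i0 = int(np.rint(ev["onset_s"] / dt))
            i1 = int(np.rint((ev["onset_s"] + ev["duration_s"]) / dt))
            neural[i0:i1] = 1.0
        cols[cond] = np.convolve(neural, hrf)[:n_hi][vol_idx] * dt
        if include_derivative:
            cols[f"{cond}_deriv"] = np.convolve(neural, dhrf)[:n_hi][vol_idx] * dt
    return pd.DataFrame(cols)


def build_design_matrix(
    events: pd.DataFrame,
    n_vols: int,
    tr_ms: float = 2000.0,
    motion: np.ndarray | None = None,
    include_derivative: bool = True,
    dt: float = 0.1,
) -> DesignMatrix:
    """Assemble the first-level design matrix.

    Parameters
    ----------
    events : DataFrame
        Columns onset_s, duration_s, condition; condition is one of the
        four size x distance cells or ``"error"``.
    n_vols : int
        Number of volumes (rows of the design).
    motion : (n_vols, 6) array, optional
        Translational and rotational realignment parameters.

    With all five event types, derivatives, 6 motion series and the
    intercept the design has 17 columns.  An error condition with no
    incorrect trials is simply absent (an all-zero column would be
    rank-deficient); its absence is logged.
    """
    df = _event_regressors(events, n_vols, tr_ms, dt, include_derivative)
    if ERROR_CONDITION not in set(events["condition"]):
        logger.warning("no error trials; error regressor dropped")
    if motion is not None:
        motion = np.asarray(motion, float)
        if motion.shape != (n_vols, 6):
            raise ValueError("motion must be (n_vols, 6)")
        if not np.isfinite(motion).all():
            raise ValueError("non-finite motion values")
        for j in range(6):
            df[f"motion{j + 1}"] = motion[:, j]
    df["intercept"] = 1.0
    return DesignMatrix(frame=df, tr_ms=tr_ms)


@dataclass
class GLMFit:
    """Per-voxel betas (one row per regressor), pooled AR(1) rho, residual variance."""

    betas: np.ndarray  # (n_regressors, n_voxels)
    columns: list[str]
    rho: float
    sigma2: np.ndarray  # (n_voxels,)

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.columns.index(name)]


def fit_glm_ar1(
    series: np.ndarray,
    design: DesignMatrix,
    ar1: bool = True,
    rho: float | None = None,
) -> GLMFit:
    """Least squares with pooled AR(1) prewhitening.

    ``series`` is (T,) or (T, V).  A first OLS pass estimates residuals;
    the pooled lag-1 autocorrelation rho is computed across all voxels
    (or taken from the ``rho`` argument when given); data and design are
    then prewhitened (first row scaled by sqrt(1 - rho^2)) and refit.
    With rho = 0 the prewhitened fit is identical to ordinary least
    squares.
    """
    y = np.asarray(series, float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    X = design.values
    if y.shape[0] != X.shape[0]:
        raise ValueError("series length must equal design rows")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if not ar1:
        rho = 0.0
    elif rho is None:
        num = float(np.sum(resid[1:] * resid[:-1]))
        den = float(np.sum(resid * resid))
        rho = num / den if den > 0 else 0.0
    if rho != 0.0:
        w0 = np.sqrt(1.0 - rho**2)
        yw = np.vstack([w0 * y[:1], y[1:] - rho * y[:-1]])
        Xw = np.vstack([w0 * X[:1], X[1:] - rho * X[:-1]])
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
    dof = y.shape[0] - X.shape[1]
    sigma2 = np.sum(resid**2, axis=0) / max(dof, 1)
    return GLMFit(betas=beta, columns=design.columns, rho=float(rho), sigma2=sigma2)


def contrast_near_vs_far(fit: GLMFit) -> np.ndarray:
    """Near-vs-Far contrast on canonical condition betas.

    Weights (+1/2 little_near, +1/2 big_near, -1/2 little_far, -1/2
    big_far): the neural distance effect averaged over pair size.
    Derivative betas are excluded.
    """
    weights = {
        "little_near": 0.5,
        "big_near": 0.5,
        "little_far": -0.5,
        "big_far": -0.5,
    }
    missing = [c for c in weights if c not in fit.columns]
    if missing:
        raise ValueError(f"missing condition betas: {missing}")
    out = sum(w * fit.beta(c) for c, w in weights.items())
    return np.asarray(out)
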