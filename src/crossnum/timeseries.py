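"""Synthetic BOLD time series for GLM validation.

Signal is the sum over conditions of 2500 ms boxcars convolved with the
canonical hemodynamic response, scaled by per-condition true betas, plus
AR(1) noise and optional linear leakage of head-motion series.  This is a
validation harness for the first-level GLM, not a scanner-physics model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TrialDesign
from .glm import ERROR_CONDITION, TRIAL_DURATION_S, _event_regressors


def events_from_design(
    design: TrialDesign,
    soa_s: float = 4.0,
    start_s: float = 8.0,
    error_trials: np.ndarray | None = None,
) -> pd.DataFrame:
    """Event table (onset_s, duration_s, condition) for a run.

    Trials are spaced ``soa_s`` apart starting at ``start_s``; each lasts
    2.5 s.  Trials flagged in ``error_trials`` (boolean mask) are assigned
    to the error condition instead of their design cell.
    """
    n = len(design.trials)
    if error_trials is None:
        error_trials = np.zeros(n, bool)
    onsets = start_s + soa_s * np.arange(n)
    conds = [
        ERROR_CONDITION if bad else tr.condition
        for tr, bad in zip(design.trials, error_trials)
    ]
    return pd.DataFrame(
        {"onset_s": onsets, "duration_s": TRIAL_DURATION_S, "condition": conds}
    )


def _check_no_overlap(events: pd.DataFrame) -> None:
    ev = events.sort_values("onset_s")
    ends = (ev["onset_s"] + ev["duration_s"]).values[:-1]
    nxt = ev["onset_s"].values[1:]
    if (nxt < ends - 1e-9).any():
        i = int(np.argmax(nxt < ends - 1e-9))
        raise ValueError(
            f"overlapping events at onsets {ev['onset_s'].values[i]:.3f}s and "
            f"{nxt[i]:.3f}s; refusing to merge"
        )


@dataclass
class SimulatedSeries:
    """A simulated run: data (T,) or (T, V), motion (T, 6), events, truth."""

    data: np.ndarray
    motion: np.ndarray
    events: pd.DataFrame
    true_betas: dict[str, float | np.ndarray]
    tr_ms: float


def simulate_timeseries(
    events: pd.DataFrame,
    n_vols: int,
    true_betas: dict[str, float | np.ndarray],
    tr_ms: float = 2000.0,
    noise_sd: float = 1.0,
    ar_rho: float = 0.0,
    motion_sd: float = 0.02,
    motion_leak: float = 0.0,
    baseline: float = 100.0,
    seed: int = 0,
) -> SimulatedSeries:
    """Simulate a run of BOLD data from an event table.

    ``true_betas`` maps condition names to scalar amplitudes (or length-V
    arrays for multi-voxel simulation).  ``ar_rho`` is the lag-1
    autocorrelation of the noise; ``motion_leak`` scales a linear leakage
    of the six random-walk motion series into the data.  Overlapping
    events raise instead of being silently merged.  Deterministic given
    ``seed``.
    """
    if tr_ms <= 0:
        raise ValueError("TR must be positive")
    _check_no_overlap(events)
    rng = np.random.default_rng(seed)

    reg = _event_regressors(events, n_vols, tr_ms, include_derivative=False)
    shapes = [np.shape(v) for v in true_betas.values()]
    n_vox = int(np.prod(shapes[0])) if shapes and shapes[0] else 1
    signal = np.zeros((n_vols, n_vox))
    for cond, amp in true_betas.items():
        if cond not in reg.columns:
            raise ValueError(f"no events for condition {cond!r}")
        signal += np.outer(reg[cond].values, np.ravel(np.asarray(amp, float)))

    eps = rng.standard_normal((n_vols, n_vox))
    noise = np.empty_like(eps)
    scale = noise_sd * np.sqrt(1.0 - ar_rho**2) if abs(ar_rho) < 1 else noise_sd
    noise[0] = noise_sd * eps[0]
    for t in range(1, n_vols):
        noise[t] = ar_rho * noise[t - 1] + scale * eps[t]

    motion = np.cumsum(motion_sd * rng.standard_normal((n_vols, 6)), axis=0)
    leak = motion @ (motion_leak * rng.standard_normal((6, n_vox)))

    data = baseline + signal + noise + leak
    if n_vox == 1:
        data = data[:, 0]
    return SimulatedSeries(
        data=data, motion=motion, events=events, true_betas=true_betas, tr_ms=tr_ms
    )
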