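"""Synthetic behavioral data for the two-group, two-session tutoring design.

Emulates per-trial responses of children with mathematical disabilities
(MD) and typically developing (TD) controls performing nonsymbolic and
symbolic number-comparison tasks before and after tutoring, plus a timed
arithmetic-fluency standard score.  Reaction times are log-normal (positive,
right-skewed); accuracy is Bernoulli per trial around a subject-level rate.

Planted structure (defaults):

* between-format dissimilarity |E_ns - E_sym| is high for MD pre-tutoring
  and low for TD pre-tutoring; after tutoring MD decreases while TD
  increases (crossover interaction);
* arithmetic fluency is far lower in MD, improves after tutoring, and a
  latent per-subject "responder" factor couples the fluency gain to the
  symbolic-RT improvement so that gain-gain correlations are plantable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import TrialDesign, generate_task_design

GROUPS = ("MD", "TD")
SESSIONS = ("pre", "post")
TASKS = ("nonsymbolic", "symbolic")


@dataclass(frozen=True)
class CellPerformance:
    """Population accuracy and median RT for one group x session x task cell."""

    accuracy: float
    median_rt_s: float

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if self.median_rt_s <= 0.150:
            raise ValueError("median RT must exceed the 150 ms floor")


#: Default cell means.  Implied efficiency (acc / median RT, 1/s) plants a
#: between-format dissimilarity of ~0.34 for MD-pre vs ~0.06 for TD-pre,
#: with MD decreasing and TD increasing after tutoring.
DEFAULT_PERFORMANCE: dict[tuple[str, str, str], CellPerformance] = {
    ("MD", "pre", "nonsymbolic"): CellPerformance(0.85, 0.95),
    ("MD", "pre", "symbolic"): CellPerformance(0.78, 1.40),
    ("MD", "post", "nonsymbolic"): CellPerformance(0.87, 0.95),
    ("MD", "post", "symbolic"): CellPerformance(0.85, 1.05),
    ("TD", "pre", "nonsymbolic"): CellPerformance(0.90, 1.00),
    ("TD", "pre", "symbolic"): CellPerformance(0.92, 1.10),
    ("TD", "post", "nonsymbolic"): CellPerformance(0.90, 0.95),
    ("TD", "post", "symbolic"): CellPerformance(0.94, 1.25),
}

#: Arithmetic-fluency standard scores: (pre mean, pre sd, gain mean, gain sd).
DEFAULT_FLUENCY: dict[str, tuple[float, float, float, float]] = {
    "MD": (84.0, 7.0, 6.0, 6.5),
    "TD": (102.0, 8.0, 2.0, 6.0),
}


@dataclass
class PopulationParams:
    """Generative parameters for the behavioral cohort.

    Noise components: ``accuracy_subject_sd`` jitters each subject's hit
    rate; ``rt_subject_sigma`` (log scale) scales each subject's median RT;
    ``rt_trial_sigma`` is the trial-level log-normal dispersion; a small
    ``fast_guess_rate`` injects sub-150 ms guesses (removed by the
    downstream trial filter).  ``responder_coupling`` sets how strongly a
    latent N(0,1) subject factor drives the MD fluency gain, and
    ``responder_rt_sigma`` how strongly the same factor drives MD
    post-tutoring symbolic-RT improvement (log scale), coupling fluency
    gains to dissimilarity reduction.
    """

    n_md: int = 25
    n_td: int = 28
    performance: dict[tuple[str, str, str], CellPerformance] = field(
        default_factory=lambda: dict(DEFAULT_PERFORMANCE)
    )
    fluency: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FLUENCY)
    )
    accuracy_subject_sd: float = 0.04
    rt_subject_sigma: float = 0.08
    rt_trial_sigma: float = 0.30
    fast_guess_rate: float = 0.02
    responder_coupling: float = 0.55
    responder_rt_sigma: float = 0.10
    n_trials: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.n_md < 2 or self.n_td < 2:
            raise ValueError("need at least 2 subjects per group")
        for sd in (
            self.accuracy_subject_sd,
            self.rt_subject_sigma,
            self.rt_trial_sigma,
        ):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")
        for cp in self.performance.values():
            if not isinstance(cp, CellPerformance):
                raise TypeError("performance values must be CellPerformance")


@dataclass
class SimulatedBehavior:
    """Per-trial tables plus fluency scores for a simulated cohort."""

    trials: pd.DataFrame
    fluency: pd.DataFrame
    params: PopulationParams


def make_roster(n_md: int, n_td: int) -> pd.DataFrame:
    sids = [f"MD{i + 1:02d}" for i in range(n_md)] + [
        f"TD{i + 1:02d}" for i in range(n_td)
    ]
    groups = ["MD"] * n_md + ["TD"] * n_td
    return pd.DataFrame({"subject_id": sids, "group": groups})


def simulate_behavior(
    params: PopulationParams, sessions: tuple[str, ...] = SESSIONS
) -> SimulatedBehavior:
    """Simulate per-trial comparison data and fluency scores.

    The task design (one 64-trial run per format) is fixed across
    subjects, as in a real administration; responses and RTs vary per
    subject and trial.  Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    designs: dict[str, TrialDesign] = {
        task: generate_task_design(params.seed + i, 1, task)[0]
        for i, task in enumerate(TASKS)
    }
    design_frames = {task: d.to_frame() for task, d in designs.items()}

    roster = make_roster(params.n_md, params.n_td)
    latent = rng.standard_normal(len(roster))  # responder factor, used for MD

    frames = []
    fluency_rows = []
    for (idx, row), z in zip(roster.iterrows(), latent):
        sid, group = row.subject_id, row.group
        pre_mu, pre_sd, gain_mu, gain_sd = params.fluency[group]
        pre_score = pre_mu + pre_sd * rng.standard_normal()
        w = params.responder_coupling if group == "MD" else 0.0
        gain = gain_mu + gain_sd * (
            w * z + np.sqrt(max(0.0, 1 - w**2)) * rng.standard_normal()
        )
        fluency_rows.append((sid, group, "pre", pre_score))
        fluency_rows.append((sid, group, "post", pre_score + gain))

        for session in sessions:
            for task in TASKS:
                cell = params.performance[(group, session, task)]
                p_acc = float(
                    np.clip(
                        cell.accuracy
                        + params.accuracy_subject_sd * rng.standard_normal(),
                        0.0,
                        1.0,
                    )
                )
                log_m = np.log(cell.median_rt_s) + params.rt_subject_sigma * (
                    rng.standard_normal()
                )
                # responders improve more on post-tutoring symbolic RTs
                if group == "MD" and session == "post" and task == "symbolic":
                    log_m -= params.responder_rt_sigma * z
                base = design_frames[task]
                n = len(base)
                correct = rng.random(n) < p_acc
                rt_s = np.exp(log_m + params.rt_trial_sigma * rng.standard_normal(n))
                guess = rng.random(n) < params.fast_guess_rate
                rt_s[guess] = rng.uniform(0.050, 0.150, guess.sum())
                correct[guess] = rng.random(guess.sum()) < 0.5
                df = base.copy()
                df.insert(0, "subject_id", sid)
                df.insert(1, "group", group)
                df.insert(2, "session", session)
                df.insert(3, "task", task)
                df["correct"] = correct
                df["response"] = np.where(
                    correct,
                    df["larger_side"],
                    np.where(df["larger_side"] == "left", "right", "left"),
                )
                df["rt_ms"] = rt_s * 1000.0
                frames.append(df)

    trials = pd.concat(frames, ignore_index=True)
    trials = trials[
        [
            "subject_id",
            "group",
            "session",
            "task",
            "trial",
            "condition",
            "pair_left",
            "pair_right",
            "response",
            "rt_ms",
            "correct",
        ]
    ]
    fluency = pd.DataFrame(
        fluency_rows, columns=["subject_id", "group", "session", "score"]
    )
    return SimulatedBehavior(trials=trials, fluency=fluency, params=params)


def noise_free(params: PopulationParams) -> PopulationParams:
    """Copy of ``params`` with every stochastic component switched off."""
    return replace(
        params,
        accuracy_subject_sd=0.0,
        rt_subject_sigma=0.0,
        rt_trial_sigma=0.0,
        fast_guess_rate=0.0,
        responder_coupling=0.0,
        responder_rt_sigma=0.0,
    )
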