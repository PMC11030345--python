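"""Behavioral scoring and planned statistics.

Efficiency = accuracy / median RT (1/s), a speed-accuracy-trade-off-robust
performance score.  Between-format dissimilarity D = |E_nonsymbolic -
E_symbolic| indexes how differently a child processes the two number
formats; lower D means more similar cross-format processing.

Conventions (documented, the underlying reports are silent on them):
trials faster than 150 ms are discarded before scoring; accuracy uses the
post-filter trial count as denominator; median RT is taken over correct
post-filter trials; two-sample tests are Welch by default with pooled-SD
Cohen's d; paired d = mean(diff)/sd(diff); all tests two-tailed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RT_FLOOR_MS = 150.0


@dataclass
class TestResult:
    """A single statistical test: statistic, df, p, and tagged effect size."""

    statistic: float
    df: float
    p: float
    effect_size: float
    effect_name: str = "cohen_d"
    tails: str = "two-sided"
    variant: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")


def filter_trials(trials: pd.DataFrame, floor_ms: float = RT_FLOOR_MS) -> pd.DataFrame:
    """Drop trials with RT below the floor (default 150 ms).

    Logs the removed-trial count and warns about any subject x task cell
    left empty (such subjects should be excluded downstream).
    """
    if (trials["rt_ms"] < 0).any():
        raise ValueError("negative rt_ms")
    kept = trials[trials["rt_ms"] >= floor_ms].copy()
    n_removed = len(trials) - len(kept)
    logger.info("filter_trials removed %d of %d trials", n_removed, len(trials))
    before = set(map(tuple, trials[["subject_id", "task"]].drop_duplicates().values))
    after = set(map(tuple, kept[["subject_id", "task"]].drop_duplicates().values))
    for sid, task in sorted(before - after):
        logger.warning("subject %s task %s has no trials after filtering", sid, task)
    return kept


def efficiency(accuracy: float, median_rt_s: float) -> float:
    """Accuracy divided by median RT in seconds (units 1/s)."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if median_rt_s <= 0:
        raise ValueError("median RT must be positive")
    return accuracy / median_rt_s


def between_format_dissimilarity(e_ns: float, e_sym: float) -> float:
    """Absolute efficiency difference |E_ns - E_sym|; symmetric, >= 0."""
    if not (np.isfinite(e_ns) and np.isfinite(e_sym)):
        raise ValueError("efficiencies must be finite")
    return abs(e_ns - e_sym)


def score_behavior(trials: pd.DataFrame, floor_ms: float = RT_FLOOR_MS) -> pd.DataFrame:
    """Per subject x session x task efficiency records from a trial table.

    Accuracy = fraction correct of post-filter trials; median RT over
    correct post-filter trials.  Cells without any correct trial are
    dropped with a warning.
    """
    kept = filter_trials(trials, floor_ms)
    rows = []
    for (sid, group, session, task), sub in kept.groupby(
        ["subject_id", "group", "session", "task"], sort=True
    ):
        acc = float(sub["correct"].mean())
        correct_rt = sub.loc[sub["correct"].astype(bool), "rt_ms"]
        if len(correct_rt) == 0:
            logger.warning(
                "no correct trials for %s %s %s; cell dropped", sid, session, task
            )
            continue
        med_s = float(np.median(correct_rt)) / 1000.0
        rows.append((sid, group, session, task, acc, med_s, efficiency(acc, med_s)))
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "group",
            "session",
            "task",
            "accuracy",
            "median_rt_s",
            "efficiency",
        ],
    )


def dissimilarity_table(
    records: pd.DataFrame, metric: str = "efficiency"
) -> pd.DataFrame:
    """Between-format dissimilarity per subject x session.

    ``metric="efficiency"`` uses |E_ns - E_sym|; ``metric="rt"`` is the
    supplementary variant |median RT_ns - median RT_sym| in seconds.
    Subjects missing either task in a session are dropped.
    """
    col = {"efficiency": "efficiency", "rt": "median_rt_s"}[metric]
    wide = records.pivot_table(
        index=["subject_id", "group", "session"], columns="task", values=col
    )
    wide = wide.dropna(subset=["nonsymbolic", "symbolic"])
    out = wide.reset_index()[["subject_id", "group", "session"]]
    out["D"] = np.abs(wide["nonsymbolic"].values - wide["symbolic"].values)
    out.attrs["metric"] = metric
    return out


# ---------------------------------------------------------------------------
# planned tests


def _pooled_d(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    return float((np.mean(x) - np.mean(y)) / np.sqrt(sp2))


def welch_two_sample_t(x, y) -> TestResult:
    """Welch two-sample t (Satterthwaite df), with pooled-SD Cohen's d."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            # degenerate identical constants: no evidence against the null
            return TestResult(0.0, float(len(x) + len(y) - 2), 1.0, 0.0,
                              variant="welch")
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
        _pooled_d(x, y),
        variant="welch",
    )


def paired_t(pre, post) -> TestResult:
    """Paired t on (post - pre); Cohen's d = mean(diff) / sd(diff)."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be matched by subject")
    n = len(pre)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    diff = post - pre
    sd = np.std(diff, ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return TestResult(0.0, float(n - 1), 1.0, 0.0, variant="paired")
        raise ValueError("zero-variance differences")
    t = float(np.mean(diff) / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return TestResult(t, float(n - 1), p, float(np.mean(diff) / sd), variant="paired")


def mixed_anova_2x2(
    d_table: pd.DataFrame,
    dv: str = "D",
    subject: str = "subject_id",
    between: str = "group",
    within: str = "session",
) -> dict[str, TestResult]:
    """2x2 mixed-design ANOVA (between: group; within: session).

    Returns F tests for Group, Time and Group x Time with generalized
    eta squared (SS_effect / (SS_effect + all subject and error SS)).
    Subjects missing a timepoint are rejected, never imputed.
    """
    import pingouin as pg  # deferred: slow import

    counts = d_table.groupby(subject)[within].nunique()
    if (counts != 2).any():
        bad = counts.index[counts != 2].tolist()
        raise ValueError(f"subjects missing a timepoint: {bad}")
    for g, sub in d_table.groupby(between):
        if sub[subject].nunique() < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
    aov = pg.mixed_anova(
        data=d_table,
        dv=dv,
        within=within,
        subject=subject,
        between=between,
        effsize="ng2",
    ).set_index("Source")
    key = {between: "group", within: "time", "Interaction": "interaction"}
    out = {}
    for src, name in key.items():
        row = aov.loc[src]
        out[name] = TestResult(
            float(row["F"]),
            float(row["DF1"]),
            float(row["p_unc"]),
            float(row["ng2"]),
            effect_name="eta_sq_generalized",
            variant=f"mixed_2x2 (df2={int(row['DF2'])})",
        )
        out[name].df = (float(row["DF1"]), float(row["DF2"]))
    return out


def gain_correlation(gain_a, gain_b) -> TestResult:
    """Pearson correlation between two per-subject gain scores (df = n - 2)."""
    a = np.asarray(gain_a, float)
    b = np.asarray(gain_b, float)
    if a.shape != b.shape:
        raise ValueError("gains must be matched by subject")
    if len(a) < 3:
        raise ValueError("need n >= 3 for a correlation")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero variance in a gain score")
    res = stats.pearsonr(a, b)
    r = float(res.statistic)
    return TestResult(r, float(len(a) - 2), float(res.pvalue), r, effect_name="r",
                      variant="pearson")
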