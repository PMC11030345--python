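"""Behavioral scoring and planned statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossnum.behavior import (
    between_format_dissimilarity,
    dissimilarity_table,
    efficiency,
    filter_trials,
    gain_correlation,
    mixed_anova_2x2,
    paired_t,
    score_behavior,
    welch_two_sample_t,
)

# ---------------------------------------------------------------------------
# trial filtering and scoring


def _trial_frame(rts, correct=None, **ids):
    n = len(rts)
    base = dict(
        subject_id="s1", group="MD", session="pre", task="symbolic",
        trial=np.arange(1, n + 1), condition="little_near",
        pair_left=1, pair_right=2, response="left",
    )
    base.update(ids)
    df = pd.DataFrame(base | {"rt_ms": rts})
    df["correct"] = True if correct is None else correct
    return df


def test_filter_drops_fast_guesses_only():
    df = _trial_frame([100.0, 150.0, 900.0, 149.9])
    kept = filter_trials(df)
    assert kept["rt_ms"].tolist() == [150.0, 900.0]
    all_slow = _trial_frame([200.0, 300.0])
    pd.testing.assert_frame_equal(filter_trials(all_slow), all_slow)


def test_filter_counts():
    rts = [100, 120, 140, 200, 300, 400, 500, 600, 700, 800]
    assert len(filter_trials(_trial_frame(rts))) == 7


def test_filter_rejects_negative_rt():
    with pytest.raises(ValueError):
        filter_trials(_trial_frame([-5.0]))


@pytest.mark.parametrize(
    "acc,rt,expected", [(0.90, 1.5, 0.60), (0.0, 2.0, 0.0), (1.0, 0.5, 2.0)]
)
def test_efficiency_arithmetic(acc, rt, expected):
    assert efficiency(acc, rt) == pytest.approx(expected)


def test_efficiency_domain():
    with pytest.raises(ValueError):
        efficiency(0.5, 0.0)
    with pytest.raises(ValueError):
        efficiency(1.2, 1.0)


def test_dissimilarity_symmetry_and_identity():
    assert between_format_dissimilarity(0.6, 0.6) == 0.0
    assert between_format_dissimilarity(0.8, 0.6) == pytest.approx(0.2)
    assert between_format_dissimilarity(0.6, 0.8) == pytest.approx(0.2)


def test_scoring_uses_postfilter_denominator_and_correct_trial_median():
    # 4 trials: one fast guess (dropped), one error, two correct
    df = _trial_frame([100.0, 500.0, 1000.0, 2000.0],
                      correct=[True, False, True, True])
    rec = score_behavior(df)
    assert len(rec) == 1
    row = rec.iloc[0]
    assert row.accuracy == pytest.approx(2 / 3)
    assert row.median_rt_s == pytest.approx(1.5)  # median of 1000, 2000 ms
    assert row.efficiency == pytest.approx((2 / 3) / 1.5)


def test_rt_metric_variant(default_sim):
    rec = score_behavior(default_sim.trials)
    d_eff = dissimilarity_table(rec, metric="efficiency")
    d_rt = dissimilarity_table(rec, metric="rt")
    assert (d_eff["D"] >= 0).all() and (d_rt["D"] >= 0).all()
    assert not np.allclose(d_eff["D"], d_rt["D"])
    # task-label swap invariance of D
    swapped = rec.assign(
        task=rec.task.map({"nonsymbolic": "symbolic", "symbolic": "nonsymbolic"})
    )
    pd.testing.assert_series_equal(
        dissimilarity_table(swapped)["D"], d_eff["D"], check_names=False
    )


# ---------------------------------------------------------------------------
# t-tests and correlation vs hand oracles


def welch_oracle(x, y):
    """Direct formula implementation, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def test_welch_hand_example():
    res = welch_two_sample_t([1, 2, 3], [4, 5, 6])
    assert res.statistic == pytest.approx(-3.674, abs=5e-4)
    assert res.df == pytest.approx(4.0)


def test_welch_matches_oracle_to_1e10(rng):
    x = rng.normal(0, 1, 9)
    y = rng.normal(0.5, 2, 7)
    res = welch_two_sample_t(x, y)
    t, df, p = welch_oracle(x, y)
    assert res.statistic == pytest.approx(t, abs=1e-10)
    assert res.df == pytest.approx(df, abs=1e-10)
    assert res.p == pytest.approx(p, abs=1e-10)


def test_welch_identical_samples_null():
    res = welch_two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0
    assert res.p == pytest.approx(1.0)


def test_welch_equals_student_for_equal_n_equal_variance(rng):
    x = rng.normal(size=8)
    y = x + 2.0  # identical sample variance
    res = welch_two_sample_t(x, y)
    student = stats.ttest_ind(x, y, equal_var=True)
    assert res.statistic == pytest.approx(student.statistic, abs=1e-12)
    assert res.df == pytest.approx(14.0)


def test_welch_sign_flips_p_invariant(rng):
    x, y = rng.normal(size=6), rng.normal(1, 1, 9)
    a, b = welch_two_sample_t(x, y), welch_two_sample_t(y, x)
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p == pytest.approx(b.p)


def test_welch_degenerate():
    with pytest.raises(ValueError):
        welch_two_sample_t([1.0, 1.0], [2.0, 2.0])
    with pytest.raises(ValueError):
        welch_two_sample_t([1.0], [2.0, 3.0])


def test_paired_t_hand_examples():
    res = paired_t([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-9)
    assert res.statistic == pytest.approx(3.464, abs=5e-4)
    assert res.df == 2
    assert res.effect_size == pytest.approx(2.0)  # mean/sd of diffs
    null = paired_t([1.0, 2.0], [1.0, 2.0])
    assert null.statistic == 0.0 and null.p == 1.0
    with pytest.raises(ValueError):
        paired_t([0.0, 0.0], [1.0, 1.0])  # constant nonzero diff, sd = 0


def test_gain_correlation_examples(rng):
    g = rng.normal(size=10)
    assert gain_correlation(g, 2 * g).statistic == pytest.approx(1.0)
    assert gain_correlation(g, -g).statistic == pytest.approx(-1.0)
    res = gain_correlation([1, 2, 3], [2, 1, 3])
    assert res.statistic == pytest.approx(0.5, abs=1e-12)
    assert res.df == 1
    with pytest.raises(ValueError):
        gain_correlation([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# mixed ANOVA vs an independent sums-of-squares oracle


def mixed_anova_oracle(wide_pre, wide_post, groups):
    """Brute-force SS decomposition for a balanced 2x2 mixed design."""
    y = {}
    subjects = list(range(len(groups)))
    for s in subjects:
        y[(s, "pre")] = wide_pre[s]
        y[(s, "post")] = wide_post[s]
    times = ["pre", "post"]
    gm = np.mean(list(y.values()))
    glev = sorted(set(groups))
    gmean = {g: np.mean([y[(s, t)] for s in subjects if groups[s] == g for t in times]) for g in glev}
    tmean = {t: np.mean([y[(s, t)] for s in subjects]) for t in times}
    smean = {s: np.mean([y[(s, t)] for t in times]) for s in subjects}
    cmean = {(g, t): np.mean([y[(s, t)] for s in subjects if groups[s] == g]) for g in glev for t in times}
    n_g = {g: sum(1 for s in subjects if groups[s] == g) for g in glev}
    ss_group = 2 * sum(n_g[g] * (gmean[g] - gm) ** 2 for g in glev)
    ss_subj = 2 * sum((smean[s] - gmean[groups[s]]) ** 2 for s in subjects)
    ss_time = sum(len(subjects) * (tmean[t] - gm) ** 2 for t in times)
    ss_int = sum(
        n_g[g] * (cmean[(g, t)] - gmean[g] - tmean[t] + gm) ** 2
        for g in glev for t in times
    )
    ss_err = sum(
        (y[(s, t)] - cmean[(groups[s], t)] - smean[s] + gmean[groups[s]]) ** 2
        for s in subjects for t in times
    )
    n = len(subjects)
    f_group = ss_group / (ss_subj / (n - 2))
    f_time = ss_time / (ss_err / (n - 2))
    f_int = ss_int / (ss_err / (n - 2))
    ges = {
        "group": ss_group / (ss_group + ss_subj + ss_err),
        "time": ss_time / (ss_time + ss_subj + ss_err),
        "interaction": ss_int / (ss_int + ss_subj + ss_err),
    }
    return {"group": f_group, "time": f_time, "interaction": f_int}, ges


def _anova_frame(pre, post, groups):
    rows = []
    for i, (a, b, g) in enumerate(zip(pre, post, groups)):
        rows.append((f"s{i}", g, "pre", a))
        rows.append((f"s{i}", g, "post", b))
    return pd.DataFrame(rows, columns=["subject_id", "group", "session", "D"])


def test_mixed_anova_matches_ss_oracle_on_8_subject_fixture():
    pre = [0.35, 0.28, 0.41, 0.30, 0.10, 0.08, 0.13, 0.05]
    post = [0.12, 0.15, 0.09, 0.20, 0.18, 0.22, 0.16, 0.25]
    groups = ["MD"] * 4 + ["TD"] * 4
    res = mixed_anova_2x2(_anova_frame(pre, post, groups))
    f_oracle, ges_oracle = mixed_anova_oracle(pre, post, groups)
    for eff in ("group", "time", "interaction"):
        assert res[eff].statistic == pytest.approx(f_oracle[eff], abs=1e-10)
        assert res[eff].effect_size == pytest.approx(ges_oracle[eff], abs=1e-10)
    assert res["interaction"].df == (1.0, 6.0)


def test_mixed_anova_interaction_equals_pooled_t_sq_on_diffs(rng):
    """Identity used by the voxelwise map: F_int = t^2 on (post - pre)."""
    pre = rng.normal(size=13)
    post = rng.normal(size=13)
    groups = ["MD"] * 6 + ["TD"] * 7  # unbalanced on purpose
    res = mixed_anova_2x2(_anova_frame(pre, post, groups))
    d = post - pre
    t = stats.ttest_ind(d[:6], d[6:], equal_var=True).statistic
    assert res["interaction"].statistic == pytest.approx(t**2, rel=1e-10)


def test_mixed_anova_group_label_permutation_invariance(rng):
    pre, post = rng.normal(size=10), rng.normal(size=10)
    groups = ["MD"] * 5 + ["TD"] * 5
    flipped = ["TD"] * 5 + ["MD"] * 5
    a = mixed_anova_2x2(_anova_frame(pre, post, groups))
    b = mixed_anova_2x2(_anova_frame(pre, post, flipped))
    for eff in ("group", "time", "interaction"):
        assert a[eff].statistic == pytest.approx(b[eff].statistic)


def test_mixed_anova_rejects_incomplete_subjects():
    df = _anova_frame([1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], ["MD", "MD", "TD", "TD"])
    df = df.drop(index=1)  # s0 loses its post session
    with pytest.raises(ValueError):
        mixed_anova_2x2(df)
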