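"""Group inference on NRS maps.

Voxelwise two-sample t and 2x2 mixed-design interaction F maps,
Monte-Carlo cluster-extent family-wise error correction, deterministic
cluster extraction, ROI follow-up with Benjamini-Hochberg FDR, and the
normalization / inverted-U summaries.

A voxel enters a group map only if every contributing subject has a valid
(finite) value there; missing values are never imputed.  Cluster-forming
thresholds are applied two-tailed to |stat| with face (6-neighbor)
connectivity, positive and negative suprathreshold sets labeled
separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

#: 6-connectivity (faces only) in 3-D.
FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def _stack(maps) -> np.ndarray:
    arr = np.stack([np.asarray(m, float) for m in maps])
    if arr.ndim != 4:
        raise ValueError("expected a stack of 3-D maps")
    return arr


@dataclass
class StatMap:
    """Voxelwise statistic map with its df and a contrast description."""

    data: np.ndarray
    df: tuple[float, ...]
    stat: str  # "t" or "F"
    description: str = ""

    def threshold_value(self, voxel_p: float, two_tailed: bool = True) -> float:
        """Statistic cutoff corresponding to a voxelwise p threshold."""
        if self.stat == "t":
            q = voxel_p / 2 if two_tailed else voxel_p
            return float(stats.t.isf(q, self.df[-1]))
        return float(stats.f.isf(voxel_p, *self.df))


def voxelwise_two_sample(
    maps_a, maps_b, equal_var: bool = True, description: str = ""
) -> StatMap:
    """Per-voxel two-sample t map (A minus B), pooled variance by default.

    Voxels where any subject is non-finite, or with zero variance in both
    groups, are NaN.
    """
    A, B = _stack(maps_a), _stack(maps_b)
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 subjects per group")
    valid = np.isfinite(A).all(axis=0) & np.isfinite(B).all(axis=0)
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if equal_var:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = float(na + nb - 2)
        else:
            se2 = va / na + vb / nb
            t = (ma - mb) / np.sqrt(se2)
            df = float(na + nb - 2)  # per-voxel Welch df not propagated to maps
    t = np.where(valid & np.isfinite(t), t, np.nan)
    return StatMap(t, (df,), "t", description or "two-sample t (A - B)")


def voxelwise_interaction(
    pre_a, post_a, pre_b, post_b, description: str = ""
) -> StatMap:
    """Group x Time interaction F map for the 2x2 mixed design.

    With two timepoints the mixed-ANOVA interaction test is exactly the
    pooled two-sample t (squared) on the per-subject post-minus-pre
    difference maps, df = (1, n_a + n_b - 2); this identity (which also
    holds for unbalanced groups) is what is computed here.
    """
    dA = _stack(post_a) - _stack(pre_a)
    dB = _stack(post_b) - _stack(pre_b)
    tmap = voxelwise_two_sample(dA, dB, equal_var=True)
    F = tmap.data**2
    # no change in any subject: zero numerator over zero variance is F = 0
    valid = np.isfinite(dA).all(axis=0) & np.isfinite(dB).all(axis=0)
    degenerate = (
        valid
        & (dA.var(axis=0) == 0)
        & (dB.var(axis=0) == 0)
        & (dA.mean(axis=0) == dB.mean(axis=0))
    )
    F = np.where(degenerate, 0.0, F)
    return StatMap(
        F, (1.0, tmap.df[0]), "F", description or "Group x Time interaction F"
    )


@dataclass
class MonteCarloThreshold:
    """Cluster-extent threshold k with the simulated null maxima behind it."""

    k: int
    voxel_p: float
    fwe_p: float
    stat_threshold: float
    max_extents: np.ndarray

    def fwe_rate(self, k: int | None = None) -> float:
        k = self.k if k is None else k
        return float(np.mean(self.max_extents >= k))


def _ball_kernel(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    from .searchlight import sphere_offsets

    offs = sphere_offsets(radius_mm, voxel_size_mm)
    m = int(np.abs(offs).max())
    kern = np.zeros((2 * m + 1,) * 3)
    kern[tuple((offs + m).T)] = 1.0
    return kern / kern.sum()


def _null_field(rng, shape, sigma_vox, ball=None):
    f = rng.standard_normal(shape)
    if sigma_vox > 0:
        f = ndimage.gaussian_filter(f, sigma_vox)
    if ball is not None:
        f = ndimage.convolve(f, ball, mode="constant")
    return f


def max_cluster_extent(binary: np.ndarray) -> int:
    lab, n = ndimage.label(binary, structure=FACE_STRUCTURE)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def monte_carlo_extent_threshold(
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float = 2.0,
    voxel_p: float = 0.005,
    fwe_p: float = 0.01,
    n_sims: int = 1000,
    seed: int = 0,
    two_tailed: bool = True,
    searchlight_radius_mm: float = 0.0,
) -> MonteCarloThreshold:
    """Smallest cluster extent k controlling family-wise error at fwe_p.

    Null model: white Gaussian fields smoothed to ``fwhm_mm``, masked and
    variance-normalized, thresholded two-tailed at the z corresponding to
    ``voxel_p``.  k is the smallest extent such that the fraction of null
    fields containing any suprathreshold cluster of >= k voxels is
    <= fwe_p.

    For statistic maps derived from searchlight correlations, pass
    ``searchlight_radius_mm > 0``: the null fields are additionally
    convolved with the searchlight's uniform ball kernel, which
    reproduces the compact sphere-overlap spatial covariance of such
    maps (a Gaussian of matched local smoothness would under-produce
    large null clusters).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    if 0 < fwhm_mm < voxel_size_mm:
        raise ValueError("fwhm below voxel size is meaningless (use 0 or >= voxel)")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    z_thr = float(stats.norm.isf(voxel_p / 2 if two_tailed else voxel_p))
    sigma_vox = fwhm_mm / (2.354820045 * voxel_size_mm) if fwhm_mm > 0 else 0.0
    ball = (
        _ball_kernel(searchlight_radius_mm, voxel_size_mm)
        if searchlight_radius_mm > 0
        else None
    )
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_sims, int)
    for i in range(n_sims):
        f = _null_field(rng, mask.shape, sigma_vox, ball)
        vals = f[mask]
        if vals.size > 1 and vals.std() > 0:
            f = (f - vals.mean()) / vals.std()
        supra = np.abs(f) >= z_thr if two_tailed else f >= z_thr
        supra &= mask
        maxima[i] = max_cluster_extent(supra)
    # smallest k with P(max extent >= k) <= fwe_p
    k = 1
    while np.mean(maxima >= k) > fwe_p:
        k += 1
    return MonteCarloThreshold(k, voxel_p, fwe_p, z_thr, maxima)


@dataclass
class ClusterTable:
    """Suprathreshold clusters: tidy table plus a label volume (0 = none)."""

    table: pd.DataFrame
    labels: np.ndarray
    stat_threshold: float
    extent_k: int

    def __len__(self) -> int:
        return len(self.table)


def extract_clusters(
    stat_map: StatMap,
    voxel_p: float = 0.005,
    extent_k: int = 1,
    two_tailed: bool = True,
) -> ClusterTable:
    """Face-connected clusters above the voxel threshold with extent >= k.

    Positive and negative suprathreshold voxels are labeled separately so
    adjacent opposite-sign clusters never merge.  Clusters are numbered
    1.. in order of descending peak |statistic|, ties broken by
    lexicographic peak coordinate.
    """
    thr = stat_map.threshold_value(voxel_p, two_tailed)
    data = stat_map.data
    finite = np.isfinite(data)
    pieces = [(1, finite & (data >= thr))]
    if two_tailed and stat_map.stat == "t":
        pieces.append((-1, finite & (data <= -thr)))
    found = []
    for sign, supra in pieces:
        lab, n = ndimage.label(supra, structure=FACE_STRUCTURE)
        for i in range(1, n + 1):
            members = np.argwhere(lab == i)
            if len(members) < extent_k:
                continue
            vals = data[tuple(members.T)]
            # deterministic tie-break: smallest lexicographic coordinate among peaks
            peak_val = np.abs(vals).max()
            cands = members[np.abs(vals) == peak_val]
            peak = tuple(int(v) for v in sorted(map(tuple, cands))[0])
            found.append(
                {
                    "sign": sign,
                    "extent": int(len(members)),
                    "peak_stat": float(data[peak]),
                    "peak_i": peak[0],
                    "peak_j": peak[1],
                    "peak_k": peak[2],
                    "_members": members,
                }
            )
    found.sort(
        key=lambda c: (-abs(c["peak_stat"]), (c["peak_i"], c["peak_j"], c["peak_k"]))
    )
    labels = np.zeros(data.shape, int)
    rows = []
    for idx, c in enumerate(found, start=1):
        labels[tuple(c.pop("_members").T)] = idx
        rows.append({"label": idx, **c})
    table = pd.DataFrame(
        rows, columns=["label", "sign", "extent", "peak_stat", "peak_i", "peak_j", "peak_k"]
    )
    return ClusterTable(table, labels, thr, extent_k)


# ---------------------------------------------------------------------------
# ROI-level follow-up


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvals, float)
    return multipletests(p, method="fdr_bh")[1]


def roi_means(nrs_map: np.ndarray, roi_labels: np.ndarray, roi_ids=None) -> dict[int, float]:
    """Mean NRS per ROI over valid (finite) voxels; empty ROI raises."""
    roi_ids = (
        sorted(int(v) for v in np.unique(roi_labels) if v != 0)
        if roi_ids is None
        else list(roi_ids)
    )
    out = {}
    for rid in roi_ids:
        vals = nrs_map[roi_labels == rid]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"ROI {rid} has no valid voxels")
        out[rid] = float(vals.mean())
    return out


def roi_normalization_report(
    maps_a,
    maps_b,
    roi_labels: np.ndarray,
    label_a: str = "MD-post",
    label_b: str = "TD-pre",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-ROI two-sample comparison with BH-FDR across ROIs.

    Used for the normalization read-out: compare MD post-tutoring against
    TD pre-tutoring NRS in ROIs from the pre-tutoring group contrast; no
    ROI surviving FDR means the groups are statistically comparable.
    """
    from .behavior import welch_two_sample_t

    roi_ids = sorted(int(v) for v in np.unique(roi_labels) if v != 0)
    if not roi_ids:
        raise ValueError("no ROIs in label volume")
    feats_a = np.array([[roi_means(m, roi_labels, roi_ids)[r] for r in roi_ids] for m in maps_a])
    feats_b = np.array([[roi_means(m, roi_labels, roi_ids)[r] for r in roi_ids] for m in maps_b])
    rows = []
    for j, rid in enumerate(roi_ids):
        x, y = feats_a[:, j], feats_b[:, j]
        if equal_var:
            res = stats.ttest_ind(x, y, equal_var=True)
            t, df, p = float(res.statistic), float(len(x) + len(y) - 2), float(res.pvalue)
            d = welch_two_sample_t(x, y).effect_size
        else:
            tr = welch_two_sample_t(x, y)
            t, df, p, d = tr.statistic, tr.df, tr.p, tr.effect_size
        rows.append(
            {
                "roi": rid,
                f"mean_{label_a}": float(x.mean()),
                f"mean_{label_b}": float(y.mean()),
                "t": t,
                "df": df,
                "p": p,
                "cohen_d": d,
            }
        )
    report = pd.DataFrame(rows)
    report["p_fdr"] = fdr_bh(report["p"].values)
    return report


def inverted_u_summary(
    pre_a, post_a, pre_b, post_b, roi_labels: np.ndarray,
    group_a: str = "MD", group_b: str = "TD",
) -> dict:
    """Mean NRS over the interaction ROI set, paired tests per group.

    Each subject's summary is the unweighted mean of per-ROI mean NRS
    (equal-size weighting across regions).  Returns paired t for each
    group's post-minus-pre change plus the 2x2 interaction on the
    summary scores.
    """
    from .behavior import mixed_anova_2x2, paired_t

    roi_ids = sorted(int(v) for v in np.unique(roi_labels) if v != 0)

    def summarize(maps):
        return np.array(
            [np.mean([roi_means(m, roi_labels, roi_ids)[r] for r in roi_ids]) for m in maps]
        )

    a_pre, a_post = summarize(pre_a), summarize(post_a)
    b_pre, b_post = summarize(pre_b), summarize(post_b)
    rows = []
    for g, pre, post in ((group_a, a_pre, a_post), (group_b, b_pre, b_post)):
        for i, (x0, x1) in enumerate(zip(pre, post)):
            rows.append((f"{g}{i}", g, "pre", x0))
            rows.append((f"{g}{i}", g, "post", x1))
    table = pd.DataFrame(rows, columns=["subject_id", "group", "session", "nrs"])
    anova = mixed_anova_2x2(table, dv="nrs")
    return {
        "summary_table": table,
        f"paired_{group_a}": paired_t(a_pre, a_post),
        f"paired_{group_b}": paired_t(b_pre, b_post),
        "interaction": anova["interaction"],
        "means": {
            (group_a, "pre"): float(a_pre.mean()),
            (group_a, "post"): float(a_post.mean()),
            (group_b, "pre"): float(b_pre.mean()),
            (group_b, "post"): float(b_post.mean()),
        },
    }
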