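"""End-to-end NRS pipeline on simulated cohorts.

Runs, from a :class:`~crossnum.brain_sim.BrainEffectSpec` and a roster:

1. simulate per-subject (nonsymbolic, symbolic) contrast-map pairs,
2. searchlight cross-format NRS maps per subject and session,
3. whole-brain two-sample t (TD - MD at pre-tutoring), Monte-Carlo
   cluster-extent threshold, cluster extraction -> "deficit" ROI set,
4. ROI normalization report (MD post vs TD pre, BH-FDR),
5. whole-brain Group x Time interaction F, cluster extraction ->
   "plasticity" ROI set, inverted-U summary (paired tests per group),
6. SVM classification: group at pre-tutoring and MD-post-vs-TD-pre on
   the deficit ROI features; MD vs TD on post-minus-pre change features
   from the plasticity ROIs, each with a permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior_sim import make_roster
from .brain_sim import BrainEffectSpec, simulate_contrast_maps
from .classify import ClassificationResult, build_features, permutation_p
from .group import (
    ClusterTable,
    StatMap,
    extract_clusters,
    inverted_u_summary,
    monte_carlo_extent_threshold,
    roi_normalization_report,
    voxelwise_interaction,
    voxelwise_two_sample,
)
from .searchlight import searchlight_map, sphere_offsets


@dataclass
class PipelineResult:
    roster: pd.DataFrame
    nrs: dict
    extent_k: int
    pre_t: StatMap
    pre_clusters: ClusterTable
    interaction_f: StatMap
    interaction_clusters: ClusterTable
    roi_report: pd.DataFrame | None
    inverted_u: dict | None
    clf_pre: ClassificationResult | None
    clf_norm: ClassificationResult | None
    clf_delta: ClassificationResult | None
    searchlight_voxels: int = 0
    extras: dict = field(default_factory=dict)


def nrs_maps_for(
    spec: BrainEffectSpec,
    roster: pd.DataFrame,
    seed: int,
    radius_mm: float = 6.0,
    min_voxels: int = 10,
) -> dict:
    """Simulate contrast maps and compute per-subject searchlight NRS maps."""
    offs = sphere_offsets(radius_mm, spec.voxel_size_mm)
    maps = simulate_contrast_maps(spec, roster, seed=seed)
    return {
        key: searchlight_map(ns, sym, spec.mask, offs, min_voxels=min_voxels)
        for key, (ns, sym) in maps.items()
    }


def run_pipeline(
    spec: BrainEffectSpec,
    n_md: int = 19,
    n_td: int = 21,
    seed: int = 0,
    radius_mm: float = 6.0,
    voxel_p: float = 0.005,
    fwe_p: float = 0.01,
    mc_sims: int = 1000,
    mc_fwhm_mm: float | None = None,
    n_perm: int = 5000,
    k_folds: int = 10,
    min_voxels: int = 10,
    run_classification: bool = True,
) -> PipelineResult:
    """Full group analysis on one simulated cohort (see module docstring)."""
    roster = make_roster(n_md, n_td)
    nrs = nrs_maps_for(spec, roster, seed, radius_mm, min_voxels)
    offs = sphere_offsets(radius_mm, spec.voxel_size_mm)

    md = roster.loc[roster.group == "MD", "subject_id"].tolist()
    td = roster.loc[roster.group == "TD", "subject_id"].tolist()
    md_pre = [nrs[(s, "pre")] for s in md]
    md_post = [nrs[(s, "post")] for s in md]
    td_pre = [nrs[(s, "pre")] for s in td]
    td_post = [nrs[(s, "post")] for s in td]

    # pre-tutoring group contrast (TD - MD): where is the MD deficit?
    pre_t = voxelwise_two_sample(td_pre, md_pre, description="TD - MD at pre")
    # null fields matched to searchlight maps: ball kernel of the sphere
    # plus the residual Gaussian smoothness of the correlated patterns
    # (products of FWHM-smoothed fields decorrelate ~sqrt(2) faster)
    if mc_fwhm_mm is None:
        mc_fwhm_mm = spec.smooth_fwhm_mm / np.sqrt(2.0)
        if mc_fwhm_mm < spec.voxel_size_mm:
            mc_fwhm_mm = 0.0
    mc = monte_carlo_extent_threshold(
        spec.mask,
        fwhm_mm=mc_fwhm_mm,
        voxel_size_mm=spec.voxel_size_mm,
        voxel_p=voxel_p,
        fwe_p=fwe_p,
        n_sims=mc_sims,
        seed=seed + 1,
        searchlight_radius_mm=radius_mm,
    )
    pre_clusters = extract_clusters(pre_t, voxel_p, mc.k)
    # deficit ROI set: TD > MD clusters only
    deficit = pre_clusters.labels.copy()
    neg = pre_clusters.table.loc[pre_clusters.table.sign < 0, "label"]
    for lab in neg:
        deficit[deficit == lab] = 0

    interaction_f = voxelwise_interaction(md_pre, md_post, td_pre, td_post)
    interaction_clusters = extract_clusters(
        interaction_f, voxel_p, mc.k, two_tailed=False
    )

    roi_report = None
    inv_u = None
    clf_pre = clf_norm = clf_delta = None
    if deficit.any():
        roi_report = roi_normalization_report(md_post, td_pre, deficit)
        if run_classification:
            feats_md_pre = build_features(nrs, deficit, md, "session", "pre")
            feats_md_post = build_features(nrs, deficit, md, "session", "post")
            feats_td_pre = build_features(nrs, deficit, td, "session", "pre")
            X_pre = np.vstack([feats_md_pre.values, feats_td_pre.values])
            X_norm = np.vstack([feats_md_post.values, feats_td_pre.values])
            y = np.array(["MD"] * len(md) + ["TD"] * len(td))
            clf_pre = permutation_p(X_pre, y, n_perm=n_perm, k_folds=k_folds, seed=seed)
            clf_norm = permutation_p(X_norm, y, n_perm=n_perm, k_folds=k_folds, seed=seed)
    plasticity = interaction_clusters.labels
    if plasticity.any():
        inv_u = inverted_u_summary(md_pre, md_post, td_pre, td_post, plasticity)
        if run_classification:
            Xd = build_features(nrs, plasticity, md + td, "delta").values
            y = np.array(["MD"] * len(md) + ["TD"] * len(td))
            clf_delta = permutation_p(Xd, y, n_perm=n_perm, k_folds=k_folds, seed=seed)

    return PipelineResult(
        roster=roster,
        nrs=nrs,
        extent_k=mc.k,
        pre_t=pre_t,
        pre_clusters=pre_clusters,
        interaction_f=interaction_f,
        interaction_clusters=interaction_clusters,
        roi_report=roi_report,
        inverted_u=inv_u,
        clf_pre=clf_pre,
        clf_norm=clf_norm,
        clf_delta=clf_delta,
        searchlight_voxels=len(offs),
        extras={"deficit_labels": deficit, "mc": mc},
    )


def cluster_roi_overlap(
    cluster_labels: np.ndarray, roi_labels: np.ndarray, halo_vox: int = 0
) -> dict:
    """Which planted ROIs are hit by clusters, and which clusters are strays.

    A planted ROI counts as detected if any cluster voxel falls inside
    it; a cluster is a stray if it lies entirely outside the planted
    ROIs dilated by ``halo_vox`` voxels (the smoothing halo).
    """
    from scipy import ndimage

    planted = roi_labels > 0
    if halo_vox > 0:
        planted = ndimage.binary_dilation(planted, iterations=halo_vox)
    detected = set()
    for rid in np.unique(roi_labels):
        if rid == 0:
            continue
        if (cluster_labels[roi_labels == rid] > 0).any():
            detected.add(int(rid))
    strays = []
    for lab in np.unique(cluster_labels):
        if lab == 0:
            continue
        if not planted[cluster_labels == lab].any():
            strays.append(int(lab))
    return {"detected_rois": detected, "stray_clusters": strays}
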