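"""Synthetic contrast-map pairs with planted cross-format correlation.

For each subject and session, nonsymbolic and symbolic Near-vs-Far
contrast maps are generated from the shared-field mixture

    x_ns  =        sqrt(|rho|) * s + sqrt(1 - |rho|) * e1
    x_sym = sign * sqrt(|rho|) * s + sqrt(1 - |rho|) * e2

with s, e1, e2 independent unit-variance Gaussian fields, so the expected
voxelwise correlation between the two maps equals rho.  rho varies by
ROI, group and session (the quantity whose group contrast the searchlight
NRS pipeline must recover); fields may be smoothed to a given FWHM, each
field being re-standardized after smoothing so the target rho is
preserved.

Between-subject variability of rho is drawn in Fisher-z space as a shared
subject component plus an independent per-ROI component.  The volumetric
defaults (0.03 and 0.06) are validation-scale: they keep planted
whole-brain group contrasts unambiguous at conventional cluster-corrected
thresholds with samples of ~20 per group; :func:`simulate_roi_features` generates region-level NRS
features directly (no volumes) with larger dispersion (a weak shared
subject component, sd 0.05, plus dominant per-region variation, sd 0.28),
calibrated so a planted group difference of 0.30 corresponds to a
single-region effect size of roughly d = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .behavior_sim import GROUPS, SESSIONS

#: Default planted cross-format correlations: children with MD start low
#: and normalize to the TD baseline after tutoring; TD children start
#: high and decrease (the inverted-U / symbolic-estrangement pattern).
DEFAULT_RHO: dict[tuple[str, str], dict[object, float]] = {
    ("MD", "pre"): {"background": 0.10, "roi": 0.15},
    ("MD", "post"): {"background": 0.10, "roi": 0.45},
    ("TD", "pre"): {"background": 0.10, "roi": 0.45},
    ("TD", "post"): {"background": 0.10, "roi": 0.15},
}


def ellipsoid_mask(shape: tuple[int, int, int], fraction: float = 0.92) -> np.ndarray:
    """Ellipsoidal analysis mask filling ``fraction`` of each half-axis."""
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    c = [(n - 1) / 2 for n in shape]
    r = [fraction * n / 2 for n in shape]
    d2 = sum(((g - ci) / ri) ** 2 for g, ci, ri in zip(grids, c, r))
    return d2 <= 1.0


#: Fractional centers (of the grid shape) for the default planted ROIs:
#: vertices of an equilateral triangle in the mid-axial plane, mutually
#: ~13.5 voxels apart on the default 30-voxel grid so that, with the
#: default radius, ROI edges stay ~5.5 voxels apart -- beyond the
#: searchlight smear, which keeps suprathreshold clusters from bridging
#: between regions -- while leaving a 2-voxel margin to the mask edge.
_ROI_CENTERS = (
    (0.743, 0.483, 0.483),
    (0.353, 0.708, 0.483),
    (0.353, 0.258, 0.483),
)


def default_roi_labels(
    mask: np.ndarray, n_rois: int = 3, radius_vox: float = 4.0
) -> np.ndarray:
    """Spherical ROIs placed deterministically inside the mask.

    Up to three balls of ``radius_vox`` voxels (~270 voxels at the
    default 4) at fixed fractional positions, labeled 1..n.
    """
    if n_rois > len(_ROI_CENTERS):
        raise ValueError(f"at most {len(_ROI_CENTERS)} default ROIs")
    shape = mask.shape
    labels = np.zeros(shape, dtype=int)
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    for i, frac in enumerate(_ROI_CENTERS[:n_rois], start=1):
        center = [f * n for f, n in zip(frac, shape)]
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, center))
        ball = (d2 <= radius_vox**2) & mask & (labels == 0)
        labels[ball] = i
    return labels


@dataclass
class BrainEffectSpec:
    """Grid geometry, mask/ROIs and planted rho structure for map simulation."""

    shape: tuple[int, int, int] = (30, 30, 30)
    voxel_size_mm: float = 2.0
    mask: np.ndarray | None = None
    roi_labels: np.ndarray | None = None
    rho: dict[tuple[str, str], dict[object, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RHO.items()}
    )
    smooth_fwhm_mm: float = 3.0
    subject_z_sd: float = 0.03
    roi_z_sd: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if self.mask is None:
            self.mask = ellipsoid_mask(self.shape)
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != tuple(self.shape):
            raise ValueError("mask shape mismatch")
        if self.roi_labels is None:
            self.roi_labels = default_roi_labels(self.mask)
        self.roi_labels = np.asarray(self.roi_labels, int)
        if self.roi_labels.shape != tuple(self.shape):
            raise ValueError("roi_labels shape mismatch")
        if (self.roi_labels[~self.mask] != 0).any():
            raise ValueError("ROI labels must lie inside the mask")
        for cell in self.rho.values():
            for v in cell.values():
                if not -1.0 <= v <= 1.0:
                    raise ValueError("|rho| must be <= 1")

    @property
    def roi_ids(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.roi_labels) if v != 0)

    def rho_volume(self, group: str, session: str) -> np.ndarray:
        """Per-voxel target rho for one group x session cell."""
        cell = self.rho[(group, session)]
        vol = np.full(self.shape, float(cell.get("background", 0.0)))
        for rid in self.roi_ids:
            vol[self.roi_labels == rid] = float(cell.get(rid, cell.get("roi", 0.0)))
        vol[~self.mask] = 0.0
        return vol


def simulate_roi_features(
    rho_by_group: dict[str, float | np.ndarray],
    n_per_group: dict[str, int],
    n_rois: int = 20,
    subject_z_sd: float = 0.05,
    roi_z_sd: float = 0.28,
    sphere_voxels: int = 123,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Region-level NRS feature matrices without simulating volumes.

    Each subject's per-region NRS is tanh(atanh(rho) + shared subject
    jitter + per-region jitter) plus the sampling noise of a Pearson r
    estimated from ``sphere_voxels`` voxel pairs (normal with sd
    (1 - rho^2) / sqrt(n - 3) on the z scale).  With the default jitter
    SDs a planted between-group difference of 0.30 gives a per-region
    effect size near d = 1.

    Returns (X, y): feature matrix (subjects x regions) and group labels.
    """
    rng = np.random.default_rng(seed)
    X_rows, y = [], []
    se_z = 1.0 / np.sqrt(max(sphere_voxels - 3, 1))
    for group, n in n_per_group.items():
        rho = np.broadcast_to(np.atleast_1d(rho_by_group[group]), (n_rois,))
        z0 = np.arctanh(np.clip(rho, -0.999999, 0.999999))
        for _ in range(n):
            z = (
                z0
                + subject_z_sd * rng.standard_normal()
                + roi_z_sd * rng.standard_normal(n_rois)
                + se_z * rng.standard_normal(n_rois)
            )
            X_rows.append(np.tanh(z))
            y.append(group)
    return np.array(X_rows), np.array(y)


def _unit_field(rng: np.random.Generator, shape, sigma_vox: float) -> np.ndarray:
    f = rng.standard_normal(shape)
    if sigma_vox > 0:
        f = gaussian_filter(f, sigma_vox)
        f = (f - f.mean()) / f.std()
    return f


def simulate_contrast_maps(
    spec: BrainEffectSpec,
    roster,
    seed: int | None = None,
    sessions: tuple[str, ...] = SESSIONS,
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Simulate (nonsymbolic, symbolic) contrast-map pairs.

    Parameters
    ----------
    spec : BrainEffectSpec
    roster : DataFrame with subject_id and group columns.
    seed : overrides ``spec.seed`` when given.

    Returns a dict keyed by (subject_id, session); voxels outside the
    mask are NaN.  Bit-reproducible from (seed, spec).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sigma_vox = 0.0
    if spec.smooth_fwhm_mm > 0:
        sigma_vox = spec.smooth_fwhm_mm / (2.354820045 * spec.voxel_size_mm)
    out: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    roi_ids = spec.roi_ids
    for _, row in roster.iterrows():
        sid, group = row["subject_id"], row["group"]
        for session in sessions:
            rho_vol = spec.rho_volume(group, session)
            z = np.arctanh(np.clip(rho_vol, -0.999999, 0.999999))
            z += spec.subject_z_sd * rng.standard_normal()
            for rid in roi_ids:
                z[spec.roi_labels == rid] += spec.roi_z_sd * rng.standard_normal()
            rho_s = np.tanh(z)
            # |rho| = 1 is the degenerate mixture: keep it exact
            rho_s = np.where(np.abs(rho_vol) == 1.0, rho_vol, rho_s)
            rho_s[~spec.mask] = 0.0

            s = _unit_field(rng, spec.shape, sigma_vox)
            e1 = _unit_field(rng, spec.shape, sigma_vox)
            e2 = _unit_field(rng, spec.shape, sigma_vox)
            a = np.sqrt(np.abs(rho_s))
            b = np.sqrt(1.0 - np.abs(rho_s))
            x_ns = a * s + b * e1
            x_sym = np.sign(rho_s) * a * s + b * e2
            x_ns[~spec.mask] = np.nan
            x_sym[~spec.mask] = np.nan
            out[(sid, session)] = (x_ns, x_sym)
    return out
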