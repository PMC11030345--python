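"""Searchlight cross-format neural representational similarity (NRS).

For every in-mask voxel, the Pearson correlation between the nonsymbolic
and symbolic Near-vs-Far contrast patterns is computed over the voxels of
a spherical neighborhood (default radius 6 mm) intersected with the
analysis mask.  The result is a per-subject, per-session NRS map bounded
in [-1, 1], with NaN wherever the sphere holds fewer than ``min_voxels``
valid voxels or a pattern is constant.

The implementation accumulates the five correlation sufficient statistics
(n, sums, sums of squares, cross products) over shifted copies of the
masked maps, one shift per sphere offset, which is algebraically identical
to looping over centers but vectorized over the whole grid.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)


def sphere_offsets(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Integer grid offsets within ``radius_mm`` (inclusive boundary).

    Returns an (K, 3) array of (i, j, k) displacements with
    ``voxel_size_mm * sqrt(i^2 + j^2 + k^2) <= radius_mm``.  Always
    contains the zero offset and is symmetric under negation.  At 6 mm
    radius on a 2 mm grid this yields 123 offsets (a strict boundary
    would give 93; the inclusive convention is used here).
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    if voxel_size_mm <= 0:
        raise ValueError("voxel size must be > 0")
    r_vox = radius_mm / voxel_size_mm
    m = int(np.floor(r_vox + 1e-9))
    axis = np.arange(-m, m + 1)
    ii, jj, kk = np.meshgrid(axis, axis, axis, indexing="ij")
    keep = ii**2 + jj**2 + kk**2 <= r_vox**2 + 1e-9
    return np.column_stack([ii[keep], jj[keep], kk[keep]])


def _shift_slices(offset, shape):
    """Source/destination slice pairs adding a shifted copy onto centers."""
    src, dst = [], []
    for d, n in zip(offset, shape):
        d = int(d)
        if d >= 0:
            src.append(slice(d, n))
            dst.append(slice(0, n - d))
        else:
            src.append(slice(0, n + d))
            dst.append(slice(-d, n))
    return tuple(src), tuple(dst)


def searchlight_map(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mask: np.ndarray,
    offsets: np.ndarray,
    min_voxels: int = 10,
) -> np.ndarray:
    """Per-center Pearson correlation of two maps over sphere & mask.

    ``map_a``/``map_b`` are 3-D volumes on the same grid (NaN allowed
    outside the mask); ``mask`` is boolean.  Centers outside the mask,
    with fewer than ``min_voxels`` valid sphere voxels, or with a
    zero-variance pattern are NaN.  Symmetric in the two maps and
    invariant to positive affine rescaling of either.
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    mask = np.asarray(mask, bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("maps and mask must share one grid")
    valid = mask & np.isfinite(a) & np.isfinite(b)
    am = np.where(valid, a, 0.0)
    bm = np.where(valid, b, 0.0)
    vm = valid.astype(float)

    shape = a.shape
    n = np.zeros(shape)
    sa = np.zeros(shape)
    sb = np.zeros(shape)
    saa = np.zeros(shape)
    sbb = np.zeros(shape)
    sab = np.zeros(shape)
    for off in offsets:
        src, dst = _shift_slices(off, shape)
        n[dst] += vm[src]
        sa[dst] += am[src]
        sb[dst] += bm[src]
        saa[dst] += am[src] ** 2
        sbb[dst] += bm[src] ** 2
        sab[dst] += am[src] * bm[src]

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sab - sa * sb
        var_a = n * saa - sa**2
        var_b = n * sbb - sb**2
        r = cov / np.sqrt(var_a * var_b)

    tol = 1e-12
    degenerate = mask & (n >= min_voxels) & ((var_a <= tol * np.maximum(saa * n, 1))
                                             | (var_b <= tol * np.maximum(sbb * n, 1)))
    if degenerate.any():
        logger.warning("%d centers with constant pattern set to NaN",
                       int(degenerate.sum()))
    bad = ~mask | (n < min_voxels) | ~np.isfinite(r)
    r = np.where(bad | degenerate, np.nan, np.clip(r, -1.0, 1.0))
    return r


def fisher_z(r: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Fisher r-to-z (atanh), clipping |r| to 1 - eps first.

    Monotone, so it never changes the rank order of an NRS map; NaNs
    propagate.
    """
    r = np.asarray(r, float)
    return np.arctanh(np.clip(r, -1.0 + eps, 1.0 - eps))
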