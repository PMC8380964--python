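"""Network homogeneity: the per-voxel mean correlation with the rest
of a network.

For a mask of N voxels with time series ``x_1 .. x_N``,

    NH(i) = (1 / (N - 1)) * sum_{j != i} corr(x_i, x_j),

i.e. how consistently a voxel fluctuates with every other voxel of
the network. The fast path uses the standardised-sum identity: with
z-scored series ``z_i`` (population sd) and ``S = sum_j z_j``,
``sum_j corr(x_i, x_j) = z_i . S / T``, giving O(N*T) cost instead of
the O(N^2*T) full correlation matrix. The brute-force pairwise
implementation is kept as an independent oracle.
"""

from __future__ import annotations

import numpy as np

from .types import BoldRun, NHMap, NetworkMask, NethomError

__all__ = [
    "compute_nh_map",
    "nh_bruteforce_oracle",
    "standardize_nh_map",
    "smooth_nh_map",
]


def _masked_series(run: BoldRun, mask: NetworkMask) -> np.ndarray:
    if tuple(run.grid_shape) != mask.grid_shape or not np.allclose(
        run.affine, mask.affine
    ):
        raise NethomError("run and mask are not on the same grid")
    if mask.n_voxels < 2:
        raise NethomError("mask must contain at least 2 voxels")
    d = run.data[mask.indicator].astype(float)  # N x T
    sd = d.std(axis=1)
    bad = np.flatnonzero(sd < 1e-12)
    if bad.size:
        ijk = mask.voxel_indices()[bad[0]]
        raise NethomError(
            f"zero-variance series at in-mask voxel {tuple(int(v) for v in ijk)} "
            f"({bad.size} such voxels); run preprocessing produced a degenerate "
            "series"
        )
    return d


def compute_nh_map(run: BoldRun, mask: NetworkMask, fisher_z: bool = False) -> NHMap:
    """Per-voxel NH over ``mask`` via the standardised-sum identity.

    With ``fisher_z=True`` the pairwise correlations are averaged on
    the arctanh scale and the mean transformed back (requires the full
    pairwise matrix, so it falls back to the O(N^2) path).
    """
    d = _masked_series(run, mask)
    n, t = d.shape
    if fisher_z:
        c = np.corrcoef(d)
        np.clip(c, -1 + 1e-12, 1 - 1e-12, out=c)
        zsum = np.arctanh(c).sum(axis=1)  # diagonal arctanh(~1) excluded below
        zsum -= np.arctanh(np.diag(c))
        nh = np.tanh(zsum / (n - 1))
    else:
        z = d - d.mean(axis=1, keepdims=True)
        z /= z.std(axis=1, keepdims=True)
        s = z.sum(axis=0)
        rowsum = z @ s / t  # includes the self-term corr=1
        nh = (rowsum - 1.0) / (n - 1)
    nh = np.clip(nh, -1.0, 1.0)
    values = np.full(mask.grid_shape, np.nan)
    values[mask.indicator] = nh
    return NHMap(values, mask, standardized=False, subject_id=run.subject_id)


def nh_bruteforce_oracle(run: BoldRun, mask: NetworkMask) -> NHMap:
    """Reference NH via the explicit N x N correlation matrix.

    Guarded to small masks; used as the independent check of
    :func:`compute_nh_map`.
    """
    if mask.n_voxels > 2000:
        raise NethomError("brute-force oracle limited to masks of <= 2000 voxels")
    d = _masked_series(run, mask)
    c = np.corrcoef(d)
    n = d.shape[0]
    nh = (c.sum(axis=1) - np.diag(c)) / (n - 1)
    nh = np.clip(nh, -1.0, 1.0)
    values = np.full(mask.grid_shape, np.nan)
    values[mask.indicator] = nh
    return NHMap(values, mask, standardized=False, subject_id=run.subject_id)


def smooth_nh_map(nh: NHMap, fwhm_mm: float) -> NHMap:
    """Mask-constrained Gaussian smoothing of an NH map.

    Values are smoothed using in-mask neighbours only (the kernel is
    renormalised by the smoothed mask), so the network boundary does
    not bleed zeros into the map. ``fwhm_mm=0`` returns the input
    unchanged. Voxel size is taken from the mask affine.
    """
    from scipy import ndimage

    if fwhm_mm < 0:
        raise NethomError("smoothing FWHM must be non-negative")
    if fwhm_mm == 0:
        return nh
    voxel_mm = np.abs(np.diag(nh.mask.affine)[:3])
    sigma_vox = (fwhm_mm / 2.354820045) / voxel_mm
    ind = nh.mask.indicator
    filled = np.where(ind, nh.values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma_vox)
    den = ndimage.gaussian_filter(ind.astype(float), sigma=sigma_vox)
    out = np.full(nh.mask.grid_shape, np.nan)
    out[ind] = num[ind] / den[ind]
    return NHMap(out, nh.mask, standardized=nh.standardized, subject_id=nh.subject_id)


def standardize_nh_map(nh: NHMap) -> NHMap:
    """Z-score an NH map across its mask (per-subject scaling removal)."""
    if nh.standardized:
        raise NethomError("NH map is already standardized")
    v = nh.in_mask()
    sd = v.std()
    if sd < 1e-12:
        raise NethomError("NH map is constant over the mask; cannot standardize")
    out = np.full(nh.mask.grid_shape, np.nan)
    out[nh.mask.indicator] = (v - v.mean()) / sd
    return NHMap(out, nh.mask, standardized=True, subject_id=nh.subject_id)
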