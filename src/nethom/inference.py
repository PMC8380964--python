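"""Voxel-wise group inference with permutation cluster-extent FWE.

Per voxel, NH is regressed on ``[intercept, group, age, mean FD]``
(ordinary least squares); the reported t is the group coefficient
with a patients-minus-controls sign convention. Candidate clusters
are formed at a two-tailed voxel threshold (default p < 0.001) with
26-connectivity, separately for each sign. Family-wise error is
controlled by a label-permutation null of the maximum cluster extent
(covariates stay attached to their subjects; only group labels are
shuffled), with an optional Bonferroni factor of 2 across the two
signed contrasts. Peak voxels are converted to millimetre coordinates
through the mask affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import NHMap, NetworkMask, NethomError

__all__ = [
    "GroupDesign",
    "TStatMap",
    "Cluster",
    "ClusterTable",
    "fit_voxelwise_glm",
    "cluster_extent_inference",
    "extract_region_means",
]

_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class GroupDesign:
    """Subjects, group labels and nuisance covariates."""

    subject_ids: list[str]
    group: np.ndarray  # 'patient' / 'control' per subject
    age: np.ndarray
    mean_fd: np.ndarray

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group)
        self.age = np.asarray(self.age, dtype=float)
        self.mean_fd = np.asarray(self.mean_fd, dtype=float)
        n = len(self.subject_ids)
        if not (self.group.size == self.age.size == self.mean_fd.size == n):
            raise NethomError("design columns must all have one entry per subject")
        if not set(np.unique(self.group)) <= {"patient", "control"}:
            raise NethomError("group labels must be 'patient' or 'control'")
        if (self.group == "patient").sum() == 0 or (self.group == "control").sum() == 0:
            raise NethomError("empty group: both groups must be non-empty")
        if not (np.all(np.isfinite(self.age)) and np.all(np.isfinite(self.mean_fd))):
            raise NethomError("covariates must be complete and finite")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def matrix(self, use_covariates: bool = True, group=None) -> np.ndarray:
        g = self.group if group is None else group
        ind = (np.asarray(g) == "patient").astype(float)
        cols = [np.ones(self.n_subjects), ind]
        if use_covariates:
            cols += [self.age, self.mean_fd]
        return np.column_stack(cols)


@dataclass
class TStatMap:
    t: np.ndarray  # 3D, NaN outside mask
    df: int
    mask: NetworkMask

    def in_mask(self) -> np.ndarray:
        return self.t[self.mask.indicator]


@dataclass
class Cluster:
    label: str
    direction: str  # 'patients>controls' or 'patients<controls'
    voxels: np.ndarray  # (extent, 3) voxel indices
    extent: int
    peak_ijk: tuple[int, int, int]
    peak_mni_mm: tuple[float, float, float]
    peak_t: float
    p_fwe: float


@dataclass
class ClusterTable:
    clusters: list[Cluster]
    mask: NetworkMask
    df: int
    t_critical: float
    n_perm: int

    def __len__(self) -> int:
        return len(self.clusters)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": c.label,
                "direction": c.direction,
                "peak_x_mm": c.peak_mni_mm[0],
                "peak_y_mm": c.peak_mni_mm[1],
                "peak_z_mm": c.peak_mni_mm[2],
                "extent_voxels": c.extent,
                "peak_t": c.peak_t,
                "p_fwe": c.p_fwe,
            }
            for c in self.clusters
        ]
        cols = [
            "cluster", "direction", "peak_x_mm", "peak_y_mm", "peak_z_mm",
            "extent_voxels", "peak_t", "p_fwe",
        ]
        return pd.DataFrame(rows, columns=cols)

    def label_volume(self) -> np.ndarray:
        out = np.zeros(self.mask.grid_shape, dtype=np.int16)
        for i, c in enumerate(self.clusters, start=1):
            out[tuple(c.voxels.T)] = i
        return out


def _stack_maps(nh_maps: list[NHMap]) -> tuple[np.ndarray, NetworkMask]:
    if not nh_maps:
        raise NethomError("no NH maps given")
    mask = nh_maps[0].mask
    for m in nh_maps[1:]:
        if not mask.same_grid_as(m.mask) or not np.array_equal(
            mask.indicator, m.mask.indicator
        ):
            raise NethomError("NH maps do not share a common mask")
    return np.vstack([m.in_mask() for m in nh_maps]), mask


def _group_t(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """t statistic of the group column (index 1) per voxel."""
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.clip(sigma2 * xtx_inv[1, 1], 1e-300, None))
    return beta[1] / se, df


def fit_voxelwise_glm(
    nh_maps: list[NHMap], design: GroupDesign, use_covariates: bool = True
) -> TStatMap:
    """Per-voxel OLS of NH on [intercept, group(, age, mean FD)]."""
    Y, mask = _stack_maps(nh_maps)
    if Y.shape[0] != design.n_subjects:
        raise NethomError("one NH map per design row required")
    X = design.matrix(use_covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NethomError("rank-deficient group design")
    if design.n_subjects <= X.shape[1]:
        raise NethomError("more design columns than subjects")
    tvals, df = _group_t(X, Y)
    t3 = np.full(mask.grid_shape, np.nan)
    t3[mask.indicator] = tvals
    return TStatMap(t3, df, mask)


def _signed_clusters(t3: np.ndarray, mask_ind: np.ndarray, t_crit: float):
    """Cluster voxel-index arrays for each sign, largest first."""
    out = {}
    for sign, name in ((1, "patients>controls"), (-1, "patients<controls")):
        supra = np.zeros(mask_ind.shape, dtype=bool)
        supra[mask_ind] = (sign * t3[mask_ind]) >= t_crit
        labels, n = ndimage.label(supra, structure=_CONN26)
        comps = []
        for lab in range(1, n + 1):
            vox = np.argwhere(labels == lab)
            comps.append(vox)
        comps.sort(key=lambda v: -len(v))
        out[name] = comps
    return out


def _max_extents(t3, mask_ind, t_crit) -> tuple[int, int]:
    pos = neg = 0
    for sign in (1, -1):
        supra = np.zeros(mask_ind.shape, dtype=bool)
        supra[mask_ind] = (sign * t3[mask_ind]) >= t_crit
        labels, n = ndimage.label(supra, structure=_CONN26)
        m = int(np.bincount(labels.ravel())[1:].max()) if n else 0
        if sign == 1:
            pos = m
        else:
            neg = m
    return pos, neg


def cluster_extent_inference(
    nh_maps: list[NHMap],
    design: GroupDesign,
    voxel_p: float = 0.001,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    use_covariates: bool = True,
    bonferroni_signs: bool = True,
) -> ClusterTable:
    """Permutation max-cluster-extent FWE inference.

    The null distribution of the maximum supra-threshold cluster
    extent is built, per sign, from ``n_perm`` random permutations of
    the group labels (covariates kept with their subjects), refitting
    the GLM each time. A cluster's FWE p-value is
    ``(1 + #{perm max >= observed}) / (1 + n_perm)``, optionally
    doubled across the two signed contrasts; clusters with adjusted
    p < alpha are reported.
    """
    if not 0 < voxel_p < 1:
        raise NethomError("voxel_p must be in (0, 1)")
    if n_perm < 100:
        raise NethomError("need at least 100 permutations")
    import logging

    log = logging.getLogger(__name__)
    min_p = (1 + (2 if bonferroni_signs else 1)) / (1 + n_perm)
    if min_p > alpha:
        log.warning(
            "n_perm=%d cannot resolve alpha=%g (minimum attainable p=%g)",
            n_perm, alpha, min_p,
        )

    Y, mask = _stack_maps(nh_maps)
    if Y.shape[0] != design.n_subjects:
        raise NethomError("one NH map per design row required")
    X = design.matrix(use_covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NethomError("rank-deficient group design")
    tvals, df = _group_t(X, Y)
    t_crit = float(stats.t.ppf(1 - voxel_p / 2, df))
    t3 = np.full(mask.grid_shape, np.nan)
    t3[mask.indicator] = tvals

    observed = _signed_clusters(t3, mask.indicator, t_crit)

    rng = np.random.default_rng(seed)
    null_pos = np.zeros(n_perm, dtype=int)
    null_neg = np.zeros(n_perm, dtype=int)
    t3p = np.full(mask.grid_shape, np.nan)
    for b in range(n_perm):
        perm = rng.permutation(design.n_subjects)
        Xp = design.matrix(use_covariates, group=design.group[perm])
        tp, _ = _group_t(Xp, Y)
        t3p[mask.indicator] = tp
        null_pos[b], null_neg[b] = _max_extents(t3p, mask.indicator, t_crit)

    factor = 2.0 if bonferroni_signs else 1.0
    clusters: list[Cluster] = []
    idx = 0
    for direction, comps in observed.items():
        null = null_pos if direction == "patients>controls" else null_neg
        for vox in comps:
            ext = len(vox)
            p = (1 + int((null >= ext).sum())) / (1 + n_perm)
            p_adj = min(1.0, factor * p)
            if p_adj < alpha:
                tv = t3[tuple(vox.T)]
                # peak = max |t|; ties -> smallest linear voxel index
                atv = np.abs(tv)
                lin = np.ravel_multi_index(vox.T, mask.grid_shape)
                order = np.lexsort((lin, -atv))
                peak = vox[order[0]]
                mm = mask.affine @ np.array([*peak, 1.0])
                idx += 1
                clusters.append(
                    Cluster(
                        label=f"cluster_{idx:02d}",
                        direction=direction,
                        voxels=vox,
                        extent=ext,
                        peak_ijk=tuple(int(v) for v in peak),
                        peak_mni_mm=tuple(round(float(v), 1) for v in mm[:3]),
                        peak_t=float(t3[tuple(peak)]),
                        p_fwe=p_adj,
                    )
                )
    return ClusterTable(clusters, mask, df, t_crit, n_perm)


def extract_region_means(
    nh_maps: list[NHMap], clusters: ClusterTable
) -> pd.DataFrame:
    """Per-subject mean NH over each significant cluster.

    Rows are subjects (NH map order), columns cluster labels.
    """
    if len(clusters) == 0:
        raise NethomError("cluster table is empty")
    _, mask = _stack_maps(nh_maps)
    if not mask.same_grid_as(clusters.mask):
        raise NethomError("clusters and NH maps on different grids")
    data = {}
    for c in clusters.clusters:
        if c.extent == 0:
            raise NethomError(f"empty cluster {c.label}")
        ix = tuple(c.voxels.T)
        data[c.label] = [float(m.values[ix].mean()) for m in nh_maps]
    ids = [m.subject_id for m in nh_maps]
    return pd.DataFrame(data, index=pd.Index(ids, name="subject_id"))
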