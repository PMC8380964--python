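"""Group spatial ICA and network-mask derivation from control runs.

The mask path mirrors a standard temporal-concatenation group ICA:
per-subject voxel-wise variance normalisation, concatenation along
time, PCA reduction of the temporal dimension, fixed-point
negentropy-maximising spatial ICA (tanh contrast), template-matched
component selection and z-threshold binarisation with a minimum
cluster size at 26-connectivity.

The mask is derived from control runs only; patient runs never enter
this module's fit path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.decomposition import FastICA

from .types import BoldRun, NetworkMask, NethomError, check_consistent_grids

__all__ = [
    "ComponentSet",
    "ReducedData",
    "IcaConvergenceError",
    "concatenate_and_reduce",
    "spatial_ica",
    "select_network_component",
    "select_network_components",
    "threshold_to_mask",
    "derive_mask_from_controls",
]

_CONN26 = np.ones((3, 3, 3), dtype=int)


class IcaConvergenceError(NethomError):
    def __init__(self, n_iter: int, max_iter: int):
        self.n_iter = n_iter
        super().__init__(
            f"spatial ICA did not converge within {max_iter} iterations "
            f"(ran {n_iter})"
        )


@dataclass
class ReducedData:
    """PCA-reduced concatenated group data.

    ``components`` is (k, n_voxels): the top-k temporal principal
    directions projected onto voxel space. ``explained_variance_ratio``
    reports the variance fraction each retained component carries.
    """

    components: np.ndarray
    explained_variance_ratio: np.ndarray
    brain_indicator: np.ndarray
    affine: np.ndarray

    @property
    def k(self) -> int:
        return int(self.components.shape[0])


@dataclass
class ComponentSet:
    """Z-scored spatial ICA maps on the cohort grid."""

    maps: np.ndarray  # (n_components, nx, ny, nz), 0 outside brain
    brain_indicator: np.ndarray
    affine: np.ndarray
    selection_scores: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return int(self.maps.shape[0])


def concatenate_and_reduce(
    runs: list[BoldRun], brain_indicator: np.ndarray | None, k: int
) -> ReducedData:
    """Temporally concatenate variance-normalised runs and PCA-reduce.

    Every voxel series is demeaned and scaled to unit variance within
    each subject before concatenation, so no subject dominates. The
    concatenated (time x voxel) matrix is reduced to its top ``k``
    temporal principal components.
    """
    if len(runs) < 2:
        raise NethomError("group reduction needs at least 2 runs")
    check_consistent_grids(runs)
    if brain_indicator is None:
        brain_indicator = np.ones(runs[0].grid_shape, dtype=bool)
    brain_indicator = np.asarray(brain_indicator).astype(bool)
    if brain_indicator.shape != runs[0].grid_shape:
        raise NethomError("brain indicator grid mismatch")
    total_t = sum(r.n_volumes for r in runs)
    if not 1 <= k < total_t:
        raise NethomError(f"k={k} must be in [1, total volumes)")
    blocks = []
    for r in runs:
        y = r.data[brain_indicator].astype(float)  # voxels x t
        y = y - y.mean(axis=1, keepdims=True)
        sd = y.std(axis=1, keepdims=True)
        sd[sd < 1e-12] = 1.0
        blocks.append((y / sd).T)  # t x voxels
    X = np.concatenate(blocks, axis=0)
    # economy PCA through the smaller-side Gram matrix
    if X.shape[0] <= X.shape[1]:
        G = X @ X.T
        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        comps = evecs[:, :k].T @ X  # k x voxels
    else:
        C = X.T @ X
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # X = U S V^T  =>  U_k^T X = S_k V_k^T
        comps = np.sqrt(np.clip(evals[:k], 0, None))[:, None] * evecs[:, :k].T
    evals = np.clip(evals, 0, None)
    ratio = evals[:k] / evals.sum() if evals.sum() > 0 else np.zeros(k)
    return ReducedData(
        components=comps,
        explained_variance_ratio=ratio,
        brain_indicator=brain_indicator,
        affine=runs[0].affine.copy(),
    )


def spatial_ica(
    reduced: ReducedData,
    n_components: int,
    seed: int,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ComponentSet:
    """Fixed-point spatial ICA on the reduced data.

    Components are spatial maps independent over voxels. Each
    recovered map is z-scored over in-brain voxels and its sign fixed
    so the map skewness is positive. Raises
    :class:`IcaConvergenceError` if the fixed-point iteration does not
    reach ``tol`` within ``max_iter`` sweeps.
    """
    if n_components < 1 or n_components > reduced.k:
        raise NethomError(
            f"n_components={n_components} exceeds reduced rank {reduced.k}"
        )
    rank = np.linalg.matrix_rank(reduced.components)
    if n_components > rank:
        raise NethomError(f"n_components={n_components} exceeds data rank {rank}")
    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun="logcosh",
        max_iter=max_iter,
        tol=tol,
        whiten="unit-variance",
        random_state=int(seed),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sources = ica.fit_transform(reduced.components.T)  # voxels x comps
    if ica.n_iter_ >= max_iter:
        raise IcaConvergenceError(ica.n_iter_, max_iter)
    maps = np.zeros((n_components, *reduced.brain_indicator.shape))
    for c in range(n_components):
        m = sources[:, c]
        sd = m.std()
        if sd < 1e-12:
            raise NethomError(f"degenerate (constant) ICA component {c}")
        z = (m - m.mean()) / sd
        if stats.skew(z) < 0:
            z = -z
        maps[c][reduced.brain_indicator] = z
    return ComponentSet(
        maps=maps,
        brain_indicator=reduced.brain_indicator,
        affine=reduced.affine.copy(),
    )


def select_network_component(
    components: ComponentSet, template: NetworkMask
) -> tuple[int, float]:
    """Pick the component whose |z| map best matches the template.

    Returns ``(index, score)`` where score is the Pearson spatial
    correlation between the absolute z-map and the binary template
    over in-brain voxels; ties resolve to the lowest index.
    """
    if template.indicator.shape != components.brain_indicator.shape:
        raise NethomError("template grid does not match components")
    if template.indicator.sum() == 0:
        raise NethomError("empty template")
    tvec = template.indicator[components.brain_indicator].astype(float)
    if tvec.std() < 1e-12:
        raise NethomError("template is constant over the brain")
    scores = np.empty(components.n_components)
    for c in range(components.n_components):
        z = np.abs(components.maps[c][components.brain_indicator])
        if z.std() < 1e-12:
            raise NethomError(f"all-zero component map {c}")
        scores[c] = np.corrcoef(z, tvec)[0, 1]
    components.selection_scores = scores
    best = int(np.argmax(scores))  # argmax takes the first maximum
    return best, float(scores[best])


def select_network_components(
    components: ComponentSet, template: NetworkMask, min_score: float = 0.2
) -> list[int]:
    """All components whose template match reaches ``min_score``.

    Large-scale networks routinely split into subnetwork components
    (e.g. anterior and posterior subsystems), so the network mask is
    built from the union of every component matching the template, not
    just the single best one. The best-matching component is always
    included even if below ``min_score``.
    """
    best, _ = select_network_component(components, template)
    scores = components.selection_scores
    chosen = sorted(set([best]) | {i for i, s in enumerate(scores) if s >= min_score})
    return chosen


def threshold_to_mask(
    map3d: np.ndarray,
    affine: np.ndarray,
    z_thresh: float = 2.3,
    min_cluster_voxels: int = 10,
) -> NetworkMask:
    """Binarise a z-map: keep z >= threshold, drop small 26-connected
    clusters."""
    map3d = np.asarray(map3d, dtype=float)
    if not np.all(np.isfinite(map3d)):
        raise NethomError("non-finite values in z-map")
    if z_thresh <= 0:
        raise NethomError("z threshold must be positive")
    keep = map3d >= z_thresh
    labels, n = ndimage.label(keep, structure=_CONN26)
    if n:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_cluster_voxels)
        keep &= ~np.isin(labels, small[small > 0])
    if keep.sum() < 2:
        raise NethomError(
            "mask empty after thresholding; lower z_thresh or min_cluster_voxels"
        )
    return NetworkMask(keep, affine)


def derive_mask_from_controls(
    control_runs: list[BoldRun],
    template: NetworkMask,
    k: int = 20,
    n_components: int = 20,
    z_thresh: float = 2.3,
    min_cluster_voxels: int = 10,
    seed: int = 0,
    brain_indicator: np.ndarray | None = None,
    min_score: float = 0.2,
    max_restarts: int = 5,
) -> tuple[NetworkMask, ComponentSet, list[int]]:
    """End-to-end mask derivation from control-group runs only.

    The fixed-point ICA is restarted with shifted (still deterministic)
    seeds if it fails to converge. The mask is the union of the
    supra-threshold voxels of every template-matched component, then
    filtered for minimum cluster size. Returns the mask, the component
    set (with selection scores) and the selected component indices.
    """
    reduced = concatenate_and_reduce(control_runs, brain_indicator, k)
    last: IcaConvergenceError | None = None
    comps = None
    for attempt in range(max_restarts):
        try:
            comps = spatial_ica(reduced, n_components, seed + 7919 * attempt)
            break
        except IcaConvergenceError as exc:
            last = exc
    if comps is None:
        raise last
    idxs = select_network_components(comps, template, min_score)
    union = np.zeros(comps.brain_indicator.shape, dtype=bool)
    for i in idxs:
        union |= comps.maps[i] >= z_thresh
    mask = threshold_to_mask(
        union.astype(float), comps.affine, z_thresh=0.5,
        min_cluster_voxels=min_cluster_voxels,
    )
    return mask, comps, idxs
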