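"""Core in-memory containers shared across pipeline stages.

Conventions used throughout the package:

* volumes are indexed ``(x, y, z, t)`` with 0-based voxel indices;
* the affine maps homogeneous voxel indices to RAS+ millimetre
  coordinates (MNI-style space for real data);
* translations are millimetres, rotations radians, time seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class NethomError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass
class BoldRun:
    """One subject's 4D BOLD acquisition.

    Parameters
    ----------
    subject_id:
        Stable identifier, used to join runs with motion traces and
        phenotype rows.
    data:
        Array of shape ``(nx, ny, nz, n_volumes)``; any float dtype.
    tr_s:
        Repetition time in seconds.
    affine:
        4x4 voxel-index -> mm transform (RAS+).
    """

    subject_id: str
    data: np.ndarray
    tr_s: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise NethomError(
                f"BoldRun data must be 4D (x,y,z,t), got shape {self.data.shape}"
            )
        if self.n_volumes < 2:
            raise NethomError("BoldRun needs at least 2 volumes")
        if not self.tr_s > 0:
            raise NethomError(f"tr_s must be positive, got {self.tr_s}")
        if self.affine.shape != (4, 4):
            raise NethomError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise NethomError("affine must be invertible")
        if not np.all(np.isfinite(self.data)):
            raise NethomError(f"non-finite values in run {self.subject_id!r}")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.data.shape[:3])

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=data)


@dataclass
class MotionTrace:
    """Per-volume rigid-body realignment parameters.

    ``params`` has shape ``(n_volumes, 6)``: three translations in mm
    followed by three rotations in radians.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise NethomError(
                f"motion params must have shape (n_volumes, 6), got {self.params.shape}"
            )
        if not np.all(np.isfinite(self.params)):
            raise NethomError("non-finite motion parameters")

    @property
    def n_volumes(self) -> int:
        return int(self.params.shape[0])

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class NetworkMask:
    """Binary in-network indicator on the cohort grid."""

    indicator: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.indicator.ndim != 3:
            raise NethomError("mask indicator must be 3D")
        if self.affine.shape != (4, 4):
            raise NethomError("mask affine must be 4x4")
        if self.n_voxels < 2:
            raise NethomError("mask must contain at least 2 voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.indicator.shape)

    def voxel_indices(self) -> np.ndarray:
        """(n_voxels, 3) array of in-mask voxel indices, C order."""
        return np.argwhere(self.indicator)

    def same_grid_as(self, other) -> bool:
        return self.grid_shape == tuple(other.grid_shape) and np.allclose(
            self.affine, other.affine
        )


@dataclass
class NHMap:
    """Per-voxel network homogeneity on a mask.

    ``values`` is a 3D array, NaN outside the mask. ``standardized``
    marks maps that were z-scored across the mask (see
    :func:`nethom.homogeneity.standardize_nh_map`).
    """

    values: np.ndarray
    mask: NetworkMask
    standardized: bool = False
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.grid_shape:
            raise NethomError("NH values grid does not match mask grid")
        inmask = self.values[self.mask.indicator]
        if not np.all(np.isfinite(inmask)):
            raise NethomError("non-finite NH values inside the mask")

    def in_mask(self) -> np.ndarray:
        """Flat vector of in-mask NH values (mask C order)."""
        return self.values[self.mask.indicator]


def check_consistent_grids(objs) -> None:
    """Raise if the given runs/masks do not share grid shape and affine."""
    objs = list(objs)
    if not objs:
        return
    ref = objs[0]
    for o in objs[1:]:
        if tuple(o.grid_shape) != tuple(ref.grid_shape) or not np.allclose(
            _affine_of(o), _affine_of(ref)
        ):
            raise NethomError("inputs do not share a common grid/affine")


def _affine_of(o) -> np.ndarray:
    return o.affine
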