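"""Temporal preprocessing and motion quality control.

Implements the temporal half of a conventional resting-state pipeline:
discard initial volumes, ordinary-least-squares nuisance regression
(six rigid-body motion parameters by default), and a discrete-Fourier
band-pass at 0.01-0.08 Hz. Spatial steps (realignment, normalisation,
smoothing) are out of scope: cohorts are generated, or assumed
registered, on a common grid.

Motion QC follows the classic "2 mm / 2 degree" rule plus a mean
framewise-displacement ceiling; FD is Power's scalar formulation with
a 50 mm head radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import BoldRun, MotionTrace, NethomError

__all__ = [
    "FDSeries",
    "QCThresholds",
    "QCDecision",
    "drop_initial_volumes",
    "compute_framewise_displacement",
    "apply_exclusion_rule",
    "regress_nuisance",
    "bandpass_filter",
    "preprocess_run",
]


@dataclass
class FDSeries:
    """Per-volume Power framewise displacement in millimetres."""

    fd: np.ndarray

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.ndim != 1 or self.fd.size < 1:
            raise NethomError("FD must be a 1D series")
        if self.fd[0] != 0:
            raise NethomError("FD of the first volume must be 0")
        if np.any(self.fd < 0) or not np.all(np.isfinite(self.fd)):
            raise NethomError("FD values must be finite and non-negative")

    @property
    def mean_fd(self) -> float:
        return float(self.fd.mean())


@dataclass(frozen=True)
class QCThresholds:
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    max_mean_fd_mm: float = 0.5


@dataclass
class QCDecision:
    subject_id: str
    included: bool
    reasons: list[str]
    mean_fd: float
    max_abs_translation_mm: float
    max_abs_rotation_deg: float

    def __post_init__(self) -> None:
        if not self.included and not self.reasons:
            raise NethomError("an excluded subject must carry at least one reason")


def drop_initial_volumes(run: BoldRun, k: int) -> BoldRun:
    """Remove the first ``k`` volumes (signal-equilibration discard)."""
    if k < 0 or k > run.n_volumes - 20:
        raise NethomError(
            f"cannot drop {k} of {run.n_volumes} volumes (need >= 20 left)"
        )
    if k == 0:
        return run
    return run.with_data(run.data[..., k:])


def compute_framewise_displacement(
    motion: MotionTrace, head_radius_mm: float = 50.0
) -> FDSeries:
    """Power FD: sum of absolute backward differences of the six
    parameters, rotations converted to arc length at ``head_radius_mm``."""
    if head_radius_mm <= 0:
        raise NethomError("head radius must be positive")
    if motion.n_volumes < 2:
        raise NethomError("FD needs at least 2 volumes")
    d = np.abs(np.diff(motion.params, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return FDSeries(np.concatenate([[0.0], fd]))


def apply_exclusion_rule(
    subject_id: str,
    motion: MotionTrace,
    fd: FDSeries,
    thresholds: QCThresholds = QCThresholds(),
) -> QCDecision:
    """Exclude a subject whose cumulative translation, cumulative
    rotation, or mean FD exceeds the configured thresholds."""
    if fd.fd.size != motion.n_volumes:
        raise NethomError("FD series length does not match motion trace")
    max_t = float(np.abs(motion.translations_mm).max())
    max_r = float(np.degrees(np.abs(motion.rotations_rad).max()))
    reasons = []
    if max_t > thresholds.max_translation_mm:
        reasons.append(
            f"translation {max_t:.2f} mm exceeds {thresholds.max_translation_mm} mm"
        )
    if max_r > thresholds.max_rotation_deg:
        reasons.append(
            f"rotation {max_r:.2f} deg exceeds {thresholds.max_rotation_deg} deg"
        )
    if fd.mean_fd > thresholds.max_mean_fd_mm:
        reasons.append(
            f"mean FD {fd.mean_fd:.3f} mm exceeds {thresholds.max_mean_fd_mm} mm"
        )
    return QCDecision(
        subject_id=subject_id,
        included=not reasons,
        reasons=reasons,
        mean_fd=fd.mean_fd,
        max_abs_translation_mm=max_t,
        max_abs_rotation_deg=max_r,
    )


def regress_nuisance(run: BoldRun, regressors: np.ndarray | None) -> BoldRun:
    """Replace every voxel series by its OLS residual on
    ``[intercept | regressors]``. With no regressors this demeans."""
    t = run.n_volumes
    if regressors is None or (hasattr(regressors, "size") and np.size(regressors) == 0):
        X = np.ones((t, 1))
    else:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != t:
            raise NethomError(
                f"regressors have {regressors.shape[0]} rows for {t} volumes"
            )
        if not np.all(np.isfinite(regressors)):
            raise NethomError("non-finite regressor values")
        X = np.column_stack([np.ones(t), regressors])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NethomError("nuisance design is rank-deficient")
    Y = run.data.reshape(-1, t).T.astype(float)  # t x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T.reshape(run.data.shape)
    return run.with_data(out)


def bandpass_filter(run: BoldRun, low_hz: float, high_hz: float) -> BoldRun:
    """Ideal (frequency-mask) band-pass along time.

    Discrete-Fourier coefficients with frequency outside
    ``[low_hz, high_hz]`` are zeroed (the DC term is removed whenever
    ``low_hz > 0``) and the series inverse-transformed.
    """
    nyquist = 1.0 / (2.0 * run.tr_s)
    if not (0 <= low_hz < high_hz < nyquist):
        raise NethomError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy 0 <= low < high < "
            f"Nyquist ({nyquist:g} Hz)"
        )
    t = run.n_volumes
    freqs = np.fft.rfftfreq(t, d=run.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if low_hz > 0:
        keep[0] = False
    Y = run.data.reshape(-1, t).astype(float)
    spec = np.fft.rfft(Y, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=1).reshape(run.data.shape)
    return run.with_data(out)


def preprocess_run(
    run: BoldRun,
    motion: MotionTrace,
    drop: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    use_motion_regressors: bool = True,
    friston24: bool = False,
) -> BoldRun:
    """drop volumes -> nuisance regression -> band-pass (fixed order)."""
    if motion.n_volumes != run.n_volumes:
        raise NethomError("motion trace length does not match run")
    out = drop_initial_volumes(run, drop)
    if use_motion_regressors:
        p = motion.params[drop:]
        if friston24:
            prev = np.vstack([np.zeros(6), p[:-1]])
            p = np.column_stack([p, prev, p**2, prev**2])
        out = regress_nuisance(out, p)
    else:
        out = regress_nuisance(out, None)
    return bandpass_filter(out, low_hz, high_hz)
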