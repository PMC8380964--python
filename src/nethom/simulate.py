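"""Seeded synthetic rs-fMRI cohorts with known network structure.

The generator emulates a two-group resting-state study. A spatially
contiguous network of labelled regions carries two levels of coherent
signal: a global network latent shared by every in-network voxel
(weight ``a``) and one latent per region (weight ``b_r``). A voxel in
region ``r`` follows

    x_v(t) = sigma * ( sqrt(a) G_s(t) + sqrt(b_r) R_{s,r}(t)
                       + sqrt(q_s) A_s(t)
                       + sqrt(1 - a - b_r - q_s) eps_v(t) ) + baseline,

with all latents unit-variance and band-limited to the retained
0.01-0.08 Hz band, ``A_s`` an optional motion-locked artifact
component whose weight ``q_s`` is proportional to the subject's true
mean framewise displacement, and ``eps_v`` unit-variance white noise.
Population correlations are then exact and simple:

    corr(x_i, x_j) = a + b_r + q_s   (same region r)
    corr(x_i, x_j) = a + q_s         (different regions),

so every "true" regional NH value has a closed form that downstream
modules are tested against (:func:`true_region_nh`). A region's
*within-region weight* is ``w_r = a + b_r``, the correlation between
two of its voxels. Patients' ``w_r`` is shifted by a signed delta in
planted effect regions, producing known group differences in NH
confined to those regions; phenotype variables are drawn to correlate
with a subject's true regional NH at a planted r.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawns, so a cohort is a pure function
of its :class:`SimSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import BoldRun, MotionTrace, NetworkMask, NethomError

__all__ = [
    "Box",
    "NetworkRegion",
    "PlantedEffect",
    "PlantedCorrelation",
    "SimSpec",
    "GroundTruth",
    "SyntheticCohort",
    "default_spec",
    "null_spec",
    "generate_cohort",
    "generate_motion_trace",
    "generate_phenotypes",
    "true_region_nh",
]

# E|N(0,1)| = sqrt(2/pi); a random walk with per-step sd `s` on each of
# the 6 parameters (rotations scaled by the 50 mm head radius) has
# expected Power-FD per frame of 6 * s * sqrt(2/pi).
_FD_PER_STEP_SD = 6.0 * np.sqrt(2.0 / np.pi)
_HEAD_RADIUS_MM = 50.0

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class NetworkRegion:
    """A labelled axis-aligned voxel box with a coupling weight.

    ``box`` is ``((x0, x1), (y0, y1), (z0, z1))`` with half-open
    bounds. ``weight`` is the within-region correlation ``w_r`` in
    (0, 1): two voxels of the same region correlate at ``w_r``; the
    region-specific latent carries ``b_r = w_r - a`` of the variance.
    """

    label: str
    box: Box
    weight: float = 0.4

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.box)

    def n_voxels(self) -> int:
        return int(np.prod([hi - lo for lo, hi in self.box]))


@dataclass(frozen=True)
class PlantedEffect:
    """Signed within-region coupling shift applied to patients."""

    region: str
    sign: int
    delta: float


@dataclass(frozen=True)
class PlantedCorrelation:
    """Target Pearson correlation between a phenotype variable and a
    region's true mean NH across patients."""

    variable: str
    region: str
    r: float
    mean: float = 0.0
    sd: float = 1.0


@dataclass
class SimSpec:
    grid_shape: tuple[int, int, int] = (18, 22, 18)
    voxel_size_mm: float = 3.0
    n_volumes: int = 100
    tr_s: float = 2.0
    n_patients: int = 20
    n_controls: int = 20
    network_regions: list[NetworkRegion] = field(default_factory=list)
    effect_regions: list[PlantedEffect] = field(default_factory=list)
    phenotype_plan: list[PlantedCorrelation] = field(default_factory=list)
    global_weight: float = 0.05
    motion_scale: float = 0.12
    patient_motion_scale: float | None = None  # group-confounded motion if set
    motion_scale_sd: float = 0.25  # lognormal sd of per-subject scales
    n_high_motion_patients: int = 0
    high_motion_scale: float = 1.2
    fd_artifact_coupling: float = 0.0
    subject_w_sd: float = 0.03
    noise_sd: float = 1.0
    baseline: float = 100.0
    n_latent_harmonics: int = 24
    band_hz: tuple[float, float] = (0.01, 0.08)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def region(self, label: str) -> NetworkRegion:
        for r in self.network_regions:
            if r.label == label:
                return r
        raise NethomError(f"unknown region label {label!r}")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def subject_ids(self) -> list[str]:
        return [f"pat{i:03d}" for i in range(self.n_patients)] + [
            f"con{i:03d}" for i in range(self.n_controls)
        ]

    def groups(self) -> np.ndarray:
        return np.array(
            ["patient"] * self.n_patients + ["control"] * self.n_controls
        )

    def validate(self) -> None:
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise NethomError("grid_shape must be 3 positive integers")
        if self.n_volumes < 20:
            raise NethomError("n_volumes must be >= 20")
        if self.tr_s <= 0 or self.voxel_size_mm <= 0:
            raise NethomError("tr_s and voxel_size_mm must be positive")
        if self.n_patients < 4 or self.n_controls < 4:
            raise NethomError("need at least 4 subjects per group")
        if self.noise_sd <= 0:
            raise NethomError(
                "noise_sd must be positive (a zero-noise cohort is degenerate: "
                "all subjects would share identical signals)"
            )
        if not 0.0 <= self.global_weight < 1.0:
            raise NethomError("global_weight must be in [0, 1)")
        labels = [r.label for r in self.network_regions]
        if len(set(labels)) != len(labels):
            raise NethomError("duplicate region labels")
        for r in self.network_regions:
            for (lo, hi), n in zip(r.box, self.grid_shape):
                if not (0 <= lo < hi <= n):
                    raise NethomError(f"region {r.label!r} box outside grid")
            if not self.global_weight <= r.weight < 1.0:
                raise NethomError(
                    f"region {r.label!r} weight must be in [global_weight, 1)"
                )
        effect_signs: dict[str, int] = {}
        for e in self.effect_regions:
            if e.region not in labels:
                raise NethomError(f"effect region {e.region!r} not in network")
            if e.sign not in (-1, 1):
                raise NethomError("effect sign must be +1 or -1")
            if e.delta < 0:
                raise NethomError("effect delta must be non-negative")
            if e.region in effect_signs and effect_signs[e.region] != e.sign:
                raise NethomError(
                    f"conflicting effect signs planted in region {e.region!r}"
                )
            effect_signs[e.region] = e.sign
        for p in self.phenotype_plan:
            if not abs(p.r) < 1.0:
                raise NethomError("planted correlations must lie in (-1, 1)")
            if p.region not in labels:
                raise NethomError(f"phenotype region {p.region!r} not in network")
        lo, hi = self.band_hz
        if not 0 < lo < hi < 1.0 / (2 * self.tr_s):
            raise NethomError("latent band must lie inside (0, Nyquist)")
        if self.motion_scale < 0 or self.high_motion_scale < 0:
            raise NethomError("motion scales must be non-negative")

    def affine(self) -> np.ndarray:
        """Centered RAS+ affine with isotropic voxels."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * self.voxel_size_mm
        return aff

    def network_indicator(self) -> np.ndarray:
        ind = np.zeros(self.grid_shape, dtype=bool)
        for r in self.network_regions:
            ind[r.slices()] = True
        return ind

    def region_sizes(self) -> dict[str, int]:
        return {r.label: r.n_voxels() for r in self.network_regions}


def default_spec(**overrides) -> SimSpec:
    """Desk-scale two-group cohort with the dissociation-pattern layout.

    Four network boxes stand in for default-mode constituents (medial
    prefrontal cortex, posterior cingulate, precuneus, lateral
    temporal cortex). Patients get raised within-region coupling in
    the MPFC box and lowered coupling in the PCC box, emulating the
    anterior-increase / posterior-decrease dissociation. Base weights
    are heterogeneous — the increase is planted in the
    lowest-coherence region, the decrease in the highest — so both
    planted shifts have headroom after band-pass filtering. Lipid and
    cognitive phenotype variables are planted against the affected
    regions' true NH with the signs the study reports.
    """
    regions = [
        NetworkRegion("mpfc", ((6, 12), (14, 20), (10, 14)), weight=0.15),
        NetworkRegion("pcc", ((7, 13), (4, 9), (8, 12)), weight=0.55),
        NetworkRegion("precuneus", ((6, 10), (2, 6), (12, 16)), weight=0.35),
        NetworkRegion("ltc", ((1, 5), (8, 12), (7, 11)), weight=0.30),
    ]
    effects = [PlantedEffect("mpfc", +1, 0.60), PlantedEffect("pcc", -1, 0.45)]
    plan = [
        PlantedCorrelation("TG", "mpfc", -0.40, mean=1.6, sd=0.8),
        PlantedCorrelation("HDL_C", "pcc", -0.35, mean=1.2, sd=0.3),
        PlantedCorrelation("CHOL", "precuneus", 0.45, mean=4.5, sd=0.9),
        PlantedCorrelation("LDL_C", "precuneus", 0.38, mean=2.6, sd=0.8),
        PlantedCorrelation("RBANS_verbal_fluency", "pcc", 0.35, mean=95.0, sd=12.0),
        PlantedCorrelation("RBANS_verbal_total", "pcc", 0.34, mean=92.0, sd=11.0),
    ]
    kwargs = dict(
        network_regions=regions, effect_regions=effects, phenotype_plan=plan
    )
    kwargs.update(overrides)
    return SimSpec(**kwargs)


def null_spec(**overrides) -> SimSpec:
    """Small no-effect cohort used for false-positive calibration."""
    regions = [NetworkRegion("net", ((2, 7), (2, 7), (2, 7)), weight=0.40)]
    kwargs = dict(
        grid_shape=(10, 10, 10),
        n_volumes=60,
        n_patients=12,
        n_controls=12,
        network_regions=regions,
        effect_regions=[],
        phenotype_plan=[],
    )
    kwargs.update(overrides)
    return SimSpec(**kwargs)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream oracles."""

    effect_masks: dict[str, np.ndarray]  # label -> int8 3D array of +-1
    planted_correlations: list[PlantedCorrelation]
    true_mean_fd: pd.Series  # by subject_id
    region_true_nh: pd.DataFrame  # subjects x region labels
    subject_weights: pd.DataFrame  # subjects x regions: within-region corr w_r

    def __post_init__(self) -> None:
        for label, m in self.effect_masks.items():
            vals = np.unique(m[m != 0])
            if not set(vals.tolist()) <= {-1, 1}:
                raise NethomError(f"effect mask {label!r} signs must be +-1")


@dataclass
class SyntheticCohort:
    spec: SimSpec
    runs: list[BoldRun]
    motions: list[MotionTrace]
    phenotypes: pd.DataFrame
    mask_truth: NetworkMask
    truth: GroundTruth

    def patients(self) -> list[BoldRun]:
        return self.runs[: self.spec.n_patients]

    def controls(self) -> list[BoldRun]:
        return self.runs[self.spec.n_patients :]


def _bandlimited_series(rng: np.random.Generator, n: int, tr_s: float,
                        band: tuple[float, float], n_harmonics: int) -> np.ndarray:
    """Unit-variance mixture of sinusoids with frequencies in `band`."""
    f = rng.uniform(band[0], band[1], size=n_harmonics)
    phase = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    amp = rng.uniform(0.5, 1.0, size=n_harmonics)
    t = np.arange(n) * tr_s
    x = (amp[:, None] * np.sin(2 * np.pi * f[:, None] * t[None, :] + phase[:, None])).sum(0)
    x -= x.mean()
    sd = x.std()
    if sd < 1e-12:  # pathologically cancelling phases; redraw deterministically
        return _bandlimited_series(rng, n, tr_s, band, n_harmonics)
    return x / sd


def generate_motion_trace(
    n_volumes: int, scale: float, seed, head_radius_mm: float = _HEAD_RADIUS_MM
) -> MotionTrace:
    """Random-walk rigid-body motion calibrated so that the expected
    Power framewise displacement per frame is ``scale`` millimetres.

    ``seed`` may be an int or a ``SeedSequence``. ``scale=0`` gives an
    all-zero trace. Doubling ``scale`` (same seed) exactly doubles
    every parameter, hence the mean FD.
    """
    if n_volumes < 2:
        raise NethomError("motion trace needs >= 2 volumes")
    if scale < 0:
        raise NethomError("motion scale must be non-negative")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes - 1, 6))
    step_sd = scale / _FD_PER_STEP_SD
    steps[:, :3] *= step_sd
    steps[:, 3:] *= step_sd / head_radius_mm
    params = np.zeros((n_volumes, 6))
    params[1:] = np.cumsum(steps, axis=0)
    return MotionTrace(params)


def _power_fd(params: np.ndarray, head_radius_mm: float = _HEAD_RADIUS_MM) -> np.ndarray:
    d = np.abs(np.diff(params, axis=0))
    fd = d[:, :3].sum(1) + head_radius_mm * d[:, 3:].sum(1)
    return np.concatenate([[0.0], fd])


def true_region_nh(
    spec: SimSpec, subject_w: dict[str, float], q: float = 0.0
) -> dict[str, float]:
    """Closed-form regional mean NH for one subject.

    ``subject_w`` maps region label -> the subject's within-region
    correlation ``w_r``; ``q`` is the artifact weight. With
    corr = w_r + q within a region and global_weight + q across
    regions, the NH of a voxel in region r is

        [(n_r - 1) (w_r + q) + (N - n_r) (a + q)] / (N - 1).
    """
    sizes = spec.region_sizes()
    n_total = sum(sizes.values())
    a = spec.global_weight
    out = {}
    for label, n_r in sizes.items():
        w = subject_w[label]
        out[label] = (
            (n_r - 1) * (w + q) + (n_total - n_r) * (a + q)
        ) / (n_total - 1)
    return out


def generate_phenotypes(
    spec: SimSpec, true_nh: pd.DataFrame, seed
) -> pd.DataFrame:
    """Phenotype table with planted NH correlations among patients.

    ``true_nh`` has one row per subject (patients first) and one
    column per region label; planned variables are generated for
    patients as ``v = mean + sd*(r*z(NH_region) + sqrt(1-r^2)*eps)``
    so corr(v, NH_region) -> r as n grows. Clinical variables are
    missing for controls, mirroring a study in which only patients
    had lipids and cognition assessed. Demographics (age, sex,
    education) are generated for everyone, independent of NH.
    """
    for p in spec.phenotype_plan:
        if not abs(p.r) < 1.0:
            raise NethomError("planted |r| must be < 1")
    ids = spec.subject_ids()
    if true_nh.shape[0] != spec.n_subjects:
        raise NethomError("true_nh must have one row per subject")
    rng = np.random.default_rng(seed)
    n_pat = spec.n_patients
    df = pd.DataFrame(index=pd.Index(ids, name="subject_id"))
    df["group"] = spec.groups()
    df["age_years"] = np.clip(rng.normal(26, 7, spec.n_subjects).round(1), 16, 45)
    df["sex"] = rng.choice(["F", "M"], size=spec.n_subjects)
    df["education_years"] = np.clip(
        rng.normal(12, 3, spec.n_subjects).round(), 6, 22
    )
    patient_cols = {
        "illness_duration_years": (2.0, 1.2),
        "HAMD17": (22.0, 5.0),
        "YMRS": (6.0, 4.0),
        "HAMA14": (14.0, 6.0),
    }
    for col, (m, s) in patient_cols.items():
        v = np.full(spec.n_subjects, np.nan)
        v[:n_pat] = np.clip(rng.normal(m, s, n_pat), 0, None).round(1)
        df[col] = v
    for p in spec.phenotype_plan:
        nh = true_nh[p.region].to_numpy()[:n_pat]
        sd = nh.std()
        if sd < 1e-12:
            raise NethomError(
                f"true NH of region {p.region!r} is constant across patients; "
                "cannot plant a correlation (increase subject_w_sd)"
            )
        z = (nh - nh.mean()) / sd
        eps = rng.standard_normal(n_pat)
        eps = eps - eps.mean()
        eps /= eps.std() if eps.std() > 0 else 1.0
        # exact planted correlation in-sample up to eps-z overlap
        v = np.full(spec.n_subjects, np.nan)
        v[:n_pat] = p.mean + p.sd * (p.r * z + np.sqrt(1 - p.r**2) * eps)
        df[p.variable] = v
    return df


def generate_cohort(spec: SimSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``spec`` (pure in the seed)."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ss_subjects, ss_pheno, ss_motion_scales = root.spawn(3)
    subject_seeds = ss_subjects.spawn(spec.n_subjects)

    affine = spec.affine()
    ind = spec.network_indicator()
    if ind.sum() < 2:
        raise NethomError("network must contain at least 2 voxels")
    mask_truth = NetworkMask(ind, affine)
    a = spec.global_weight

    ids = spec.subject_ids()
    groups = spec.groups()

    # per-subject motion scales (lognormal around spec.motion_scale);
    # the last `n_high_motion_patients` patients are planted violators
    rng_scales = np.random.default_rng(ss_motion_scales)
    base_scales = np.full(spec.n_subjects, float(spec.motion_scale))
    if spec.patient_motion_scale is not None:
        base_scales[: spec.n_patients] = float(spec.patient_motion_scale)
    lognorm = np.exp(
        rng_scales.normal(0.0, spec.motion_scale_sd, spec.n_subjects)
        - spec.motion_scale_sd**2 / 2.0
    )
    scales = base_scales * lognorm
    k = spec.n_high_motion_patients
    if k > spec.n_patients:
        raise NethomError("more high-motion patients than patients")
    if k:
        scales[spec.n_patients - k : spec.n_patients] = spec.high_motion_scale

    effect_lookup = {e.region: e for e in spec.effect_regions}
    runs: list[BoldRun] = []
    motions: list[MotionTrace] = []
    true_fd = np.zeros(spec.n_subjects)
    region_nh_rows = []
    weight_rows = []

    for s_i, (sid, grp) in enumerate(zip(ids, groups)):
        ss_run, ss_motion = subject_seeds[s_i].spawn(2)
        rng = np.random.default_rng(ss_run)

        motion = generate_motion_trace(spec.n_volumes, float(scales[s_i]), ss_motion)
        true_fd[s_i] = _power_fd(motion.params).mean()

        # subject within-region correlations: base, signed delta, jitter
        w_s: dict[str, float] = {}
        for r in spec.network_regions:
            w = r.weight
            e = effect_lookup.get(r.label)
            if grp == "patient" and e is not None:
                w += e.sign * e.delta
            if spec.subject_w_sd > 0:
                w += rng.normal(0.0, spec.subject_w_sd)
            w_s[r.label] = float(np.clip(w, a + 0.01, 0.95))

        q = 0.0
        if spec.fd_artifact_coupling > 0:
            head = 0.95 - max(w_s.values())
            q = float(np.clip(spec.fd_artifact_coupling * true_fd[s_i], 0.0, head))

        glob = _bandlimited_series(
            rng, spec.n_volumes, spec.tr_s, spec.band_hz, spec.n_latent_harmonics
        )
        artifact = None
        if q > 0:
            artifact = _bandlimited_series(
                rng, spec.n_volumes, spec.tr_s, spec.band_hz, spec.n_latent_harmonics
            )
        data = rng.standard_normal((*spec.grid_shape, spec.n_volumes)).astype(
            np.float32
        )
        for r in spec.network_regions:
            b = w_s[r.label] - a
            regional = _bandlimited_series(
                rng, spec.n_volumes, spec.tr_s, spec.band_hz, spec.n_latent_harmonics
            )
            block = data[r.slices()]
            mix = (
                np.sqrt(a) * glob
                + np.sqrt(b) * regional
                + np.sqrt(np.clip(1.0 - a - b - q, 0.0, None))
                * block.reshape(-1, spec.n_volumes)
            )
            if artifact is not None:
                mix = mix + np.sqrt(q) * artifact
            data[r.slices()] = mix.reshape(block.shape)
        data *= np.float32(spec.noise_sd)
        data += np.float32(spec.baseline)

        runs.append(BoldRun(sid, data, spec.tr_s, affine))
        motions.append(motion)
        region_nh_rows.append(true_region_nh(spec, w_s, q))
        weight_rows.append(w_s)

    region_nh = pd.DataFrame(region_nh_rows, index=pd.Index(ids, name="subject_id"))
    weights_df = pd.DataFrame(weight_rows, index=pd.Index(ids, name="subject_id"))

    effect_masks: dict[str, np.ndarray] = {}
    for e in spec.effect_regions:
        m = np.zeros(spec.grid_shape, dtype=np.int8)
        m[spec.region(e.region).slices()] = e.sign
        effect_masks[e.region] = m

    truth = GroundTruth(
        effect_masks=effect_masks,
        planted_correlations=list(spec.phenotype_plan),
        true_mean_fd=pd.Series(true_fd, index=pd.Index(ids, name="subject_id")),
        region_true_nh=region_nh,
        subject_weights=weights_df,
    )
    phenotypes = generate_phenotypes(spec, region_nh, ss_pheno)
    phenotypes["mean_fd_true"] = true_fd

    return SyntheticCohort(
        spec=spec,
        runs=runs,
        motions=motions,
        phenotypes=phenotypes,
        mask_truth=mask_truth,
        truth=truth,
    )
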