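"""End-to-end orchestration: simulate -> preprocess -> mask -> nh ->
compare -> correlate -> classify.

Each stage is a function reading its inputs from, and writing its
outputs under, the configured output root, so stages can be run
individually (the CLI does exactly that) or chained by
:func:`run_pipeline`. The manifest records the config hash and a
checksum of every file written; identical config + seed reproduce a
byte-identical manifest.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as nio
from .classify import loo_svm_single_region
from .config import PipelineConfig, config_hash
from .correlations import correlate_regions_with_clinical
from .homogeneity import compute_nh_map, smooth_nh_map, standardize_nh_map
from .ica_mask import derive_mask_from_controls
from .inference import (
    ClusterTable,
    GroupDesign,
    cluster_extent_inference,
    extract_region_means,
)
from .preprocess import (
    QCThresholds,
    apply_exclusion_rule,
    compute_framewise_displacement,
    preprocess_run,
)
from .simulate import PlantedEffect, default_spec, generate_cohort
from .types import NHMap, NethomError

__all__ = ["PipelineError", "RunManifest", "run_pipeline", "STAGES"]

log = logging.getLogger("nethom.pipeline")


class PipelineError(NethomError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunManifest:
    config_hash: str
    software_version: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], root: Path, **counts) -> None:
        self.stages[stage] = {
            "outputs": {
                str(p.relative_to(root)): nio.sha256_file(p) for p in sorted(outputs)
            },
            "counts": counts,
        }

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "software_version": self.software_version,
            "stages": self.stages,
        }


def _root(cfg: PipelineConfig) -> Path:
    return Path(cfg.out_dir)


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    root = _root(cfg)
    s = cfg.simulate
    spec = default_spec(
        grid_shape=tuple(s.grid_shape),
        voxel_size_mm=s.voxel_size_mm,
        n_volumes=s.n_volumes,
        tr_s=s.tr_s,
        n_patients=s.n_patients,
        n_controls=s.n_controls,
        n_high_motion_patients=s.n_high_motion_patients,
        motion_scale=s.motion_scale,
        fd_artifact_coupling=s.fd_artifact_coupling,
        subject_w_sd=s.subject_w_sd,
        effect_regions=[
            PlantedEffect("mpfc", +1, s.delta_increase),
            PlantedEffect("pcc", -1, s.delta_decrease),
        ],
        seed=cfg.stage_seed("simulate"),
    )
    cohort = generate_cohort(spec)
    out: list[Path] = []
    for run, motion in zip(cohort.runs, cohort.motions):
        out.append(nio.write_bold(run, root / "sim" / "runs" / f"{run.subject_id}.nii"))
        out.append(
            nio.write_motion(motion, root / "sim" / "motion" / f"{run.subject_id}.txt")
        )
    out.append(nio.write_table(cohort.phenotypes, root / "sim" / "phenotypes.tsv"))
    out.append(nio.write_mask(cohort.mask_truth, root / "sim" / "truth_mask.nii"))
    out.append(
        nio.write_table(
            cohort.truth.region_true_nh, root / "sim" / "true_region_nh.tsv"
        )
    )
    log.info("simulate: %d subjects, %d network voxels",
             spec.n_subjects, cohort.mask_truth.n_voxels)
    return out


def _subject_ids(root: Path, stage_dir: str) -> list[str]:
    return sorted(p.stem for p in (root / stage_dir / "runs").glob("*.nii"))


def stage_preprocess(cfg: PipelineConfig) -> list[Path]:
    root = _root(cfg)
    p = cfg.preprocess
    thresholds = QCThresholds(p.max_translation_mm, p.max_rotation_deg, p.max_mean_fd_mm)
    out: list[Path] = []
    qc_rows = []
    for sid in _subject_ids(root, "sim"):
        run = nio.read_bold(root / "sim" / "runs" / f"{sid}.nii")
        motion = nio.read_motion(root / "sim" / "motion" / f"{sid}.txt")
        fd = compute_framewise_displacement(motion, p.head_radius_mm)
        dec = apply_exclusion_rule(sid, motion, fd, thresholds)
        qc_rows.append(
            {
                "subject_id": sid,
                "included": dec.included,
                "reasons": "; ".join(dec.reasons),
                "mean_fd": dec.mean_fd,
                "max_abs_translation_mm": dec.max_abs_translation_mm,
                "max_abs_rotation_deg": dec.max_abs_rotation_deg,
            }
        )
        if not dec.included:
            continue
        clean = preprocess_run(
            run, motion, p.drop_initial_volumes, p.low_hz, p.high_hz,
            p.use_motion_regressors, p.friston24,
        )
        out.append(nio.write_bold(clean, root / "preproc" / "runs" / f"{sid}.nii"))
    qc = pd.DataFrame(qc_rows).set_index("subject_id")
    out.append(nio.write_table(qc, root / "preproc" / "qc.tsv"))
    log.info("preprocess: %d/%d subjects retained",
             int(qc["included"].sum()), len(qc))
    return out


def _included_ids(root: Path) -> list[str]:
    qc = nio.read_table(root / "preproc" / "qc.tsv")
    return sorted(qc.index[qc["included"]])


def stage_mask(cfg: PipelineConfig) -> list[Path]:
    root = _root(cfg)
    template = nio.read_mask(root / "sim" / "truth_mask.nii")
    out: list[Path] = []
    if cfg.mask.source == "truth":
        out.append(nio.write_mask(template, root / "mask" / "mask.nii"))
        return out
    controls = [
        nio.read_bold(root / "preproc" / "runs" / f"{sid}.nii")
        for sid in _included_ids(root)
        if sid.startswith("con")
    ]
    mask, comps, idxs = derive_mask_from_controls(
        controls,
        template,
        k=cfg.mask.pca_k,
        n_components=cfg.mask.n_components,
        z_thresh=cfg.mask.z_thresh,
        min_cluster_voxels=cfg.mask.min_cluster_voxels,
        seed=cfg.stage_seed("mask"),
    )
    out.append(nio.write_mask(mask, root / "mask" / "mask.nii"))
    report = pd.DataFrame(
        {
            "component": np.arange(comps.n_components),
            "template_correlation": comps.selection_scores,
            "selected": np.isin(np.arange(comps.n_components), idxs),
        }
    ).set_index("component")
    out.append(nio.write_table(report, root / "mask" / "components.tsv"))
    log.info("mask: components %s selected, %d voxels", idxs, mask.n_voxels)
    return out


def stage_nh(cfg: PipelineConfig) -> list[Path]:
    root = _root(cfg)
    mask = nio.read_mask(root / "mask" / "mask.nii")
    out: list[Path] = []
    for sid in _included_ids(root):
        run = nio.read_bold(root / "preproc" / "runs" / f"{sid}.nii")
        nh = compute_nh_map(run, mask, fisher_z=cfg.nh.fisher_z)
        if cfg.nh.smooth_fwhm_mm > 0:
            nh = smooth_nh_map(nh, cfg.nh.smooth_fwhm_mm)
        if cfg.nh.standardize:
            nh = standardize_nh_map(nh)
        out.append(nio.write_volume(nh.values, mask.affine, root / "nh" / f"{sid}.nii"))
    log.info("nh: %d maps over %d voxels", len(out), mask.n_voxels)
    return out


def _load_nh_maps(root: Path, cfg: PipelineConfig):
    mask = nio.read_mask(root / "mask" / "mask.nii")
    maps = []
    for sid in _included_ids(root):
        vol, _ = nio.read_volume(root / "nh" / f"{sid}.nii")
        maps.append(NHMap(vol, mask, standardized=cfg.nh.standardize, subject_id=sid))
    return maps, mask


def _design(root: Path, ids: list[str]) -> GroupDesign:
    pheno = nio.read_table(root / "sim" / "phenotypes.tsv")
    qc = nio.read_table(root / "preproc" / "qc.tsv")
    return GroupDesign(
        subject_ids=ids,
        group=pheno.loc[ids, "group"].to_numpy(),
        age=pheno.loc[ids, "age_years"].to_numpy(),
        mean_fd=qc.loc[ids, "mean_fd"].to_numpy(),
    )


def stage_compare(cfg: PipelineConfig) -> list[Path]:
    root = _root(cfg)
    maps, mask = _load_nh_maps(root, cfg)
    ids = [m.subject_id for m in maps]
    design = _design(root, ids)
    c = cfg.compare
    table = cluster_extent_inference(
        maps,
        design,
        voxel_p=c.voxel_p,
        n_perm=c.n_perm,
        alpha=c.alpha,
        seed=cfg.stage_seed("compare"),
        use_covariates=c.use_covariates,
        bonferroni_signs=c.bonferroni_signs,
    )
    out: list[Path] = []
    out.append(nio.write_table(table.to_dataframe(), root / "compare" / "clusters.tsv",
                               index=False))
    from .inference import fit_voxelwise_glm

    tmap = fit_voxelwise_glm(maps, design, use_covariates=c.use_covariates)
    out.append(nio.write_volume(tmap.t, mask.affine, root / "compare" / "tmap.nii"))
    out.append(
        nio.write_volume(
            table.label_volume(), mask.affine, root / "compare" / "cluster_labels.nii"
        )
    )
    if len(table):
        features = extract_region_means(maps, table)
    else:
        features = pd.DataFrame(index=pd.Index(ids, name="subject_id"))
    out.append(nio.write_table(features, root / "compare" / "features.tsv"))
    log.info("compare: %d significant clusters (t_crit=%.3f, df=%d)",
             len(table), table.t_critical, table.df)
    return out


def stage_correlate(cfg: PipelineConfig) -> list[Path]:
    root = _root(cfg)
    features = nio.read_table(root / "compare" / "features.tsv")
    pheno = nio.read_table(root / "sim" / "phenotypes.tsv")
    if features.shape[1] == 0:
        empty = pd.DataFrame(columns=["region", "variable", "n", "r", "p"])
        return [nio.write_table(empty, root / "correlate" / "correlations.tsv",
                                index=False)]
    table = correlate_regions_with_clinical(
        features, pheno, cfg.correlate.variables, cfg.correlate.group,
        cfg.correlate.adjust,
    )
    log.info("correlate: %d region-variable pairs", len(table))
    return [nio.write_table(table, root / "correlate" / "correlations.tsv", index=False)]


def stage_classify(cfg: PipelineConfig) -> list[Path]:
    root = _root(cfg)
    features = nio.read_table(root / "compare" / "features.tsv")
    pheno = nio.read_table(root / "sim" / "phenotypes.tsv")
    cols = ["region", "sensitivity", "specificity", "accuracy",
            "sens_counts", "spec_counts", "acc_counts", "C", "gamma"]
    rows = []
    if features.shape[1] > 0:
        labels = pheno.loc[features.index, "group"].to_numpy()
        regions = (
            list(features.columns)
            if cfg.classify.regions == "all"
            else [cfg.classify.regions]
        )
        for region in regions:
            res = loo_svm_single_region(
                features, labels, region, nested=cfg.classify.nested
            )
            counts = res.counts()
            rows.append(
                {
                    "region": region,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "accuracy": res.accuracy,
                    "sens_counts": counts["sensitivity"],
                    "spec_counts": counts["specificity"],
                    "acc_counts": counts["accuracy"],
                    "C": res.C,
                    "gamma": res.gamma,
                }
            )
    table = pd.DataFrame(rows, columns=cols)
    log.info("classify: %d regions", len(table))
    return [nio.write_table(table, root / "classify" / "classification.tsv",
                            index=False)]


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "mask": stage_mask,
    "nh": stage_nh,
    "compare": stage_compare,
    "correlate": stage_correlate,
    "classify": stage_classify,
}


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute all stages in order and write ``manifest.json``."""
    root = _root(cfg)
    root.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(cfg), software_version=__version__)
    for name, fn in STAGES.items():
        if name == "simulate" and not cfg.simulate.enabled:
            continue
        t0 = time.perf_counter()
        try:
            outputs = fn(cfg)
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        log.info("stage %s: %.2f s, %d files", name, time.perf_counter() - t0,
                 len(outputs))
        manifest.record(name, outputs, root)
    nio.write_json(manifest.to_dict(), root / "manifest.json")
    return manifest
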