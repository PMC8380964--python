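"""Pipeline configuration: a validated, hashable parameter schema.

Unknown keys are rejected so typos fail loudly; every random stage
carries an explicit seed derived from the top-level one unless set.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .types import NethomError

__all__ = ["PipelineConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    enabled: bool = True
    grid_shape: tuple[int, int, int] = (18, 22, 18)
    voxel_size_mm: float = 3.0
    n_volumes: int = 100
    tr_s: float = 2.0
    n_patients: int = 20
    n_controls: int = 20
    n_high_motion_patients: int = 0
    motion_scale: float = 0.12
    fd_artifact_coupling: float = 0.0
    subject_w_sd: float = 0.03
    delta_increase: float = 0.60  # patients' MPFC within-region coupling shift
    delta_decrease: float = 0.45  # patients' PCC within-region coupling shift
    seed: int | None = None


class PreprocessConfig(_Strict):
    drop_initial_volumes: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.08
    use_motion_regressors: bool = True
    friston24: bool = False
    head_radius_mm: float = 50.0
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    max_mean_fd_mm: float = 0.5


class MaskConfig(_Strict):
    source: str = "ica"  # 'ica' or 'truth'
    pca_k: int = 20
    n_components: int = 20
    z_thresh: float = 2.3
    min_cluster_voxels: int = 10
    seed: int | None = None


class NHConfig(_Strict):
    fisher_z: bool = False
    standardize: bool = False
    smooth_fwhm_mm: float = 6.0


class CompareConfig(_Strict):
    voxel_p: float = 0.001
    n_perm: int = 500
    alpha: float = 0.05
    use_covariates: bool = True
    bonferroni_signs: bool = True
    seed: int | None = None


class CorrelateConfig(_Strict):
    group: str = "patient"
    variables: list[str] = Field(
        default_factory=lambda: [
            "TG", "CHOL", "HDL_C", "LDL_C",
            "RBANS_verbal_fluency", "RBANS_verbal_total",
        ]
    )
    adjust: str | None = None


class ClassifyConfig(_Strict):
    regions: str = "all"
    nested: bool = False


class PipelineConfig(_Strict):
    schema_version: int = 1
    seed: int = 0
    out_dir: str = "results/pipeline"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    mask: MaskConfig = Field(default_factory=MaskConfig)
    nh: NHConfig = Field(default_factory=NHConfig)
    compare: CompareConfig = Field(default_factory=CompareConfig)
    correlate: CorrelateConfig = Field(default_factory=CorrelateConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed (explicit override wins)."""
        explicit = getattr(getattr(self, stage), "seed", None)
        if explicit is not None:
            return int(explicit)
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def load_config(path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise NethomError(f"no such config file: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return PipelineConfig(**raw)
    except Exception as exc:
        raise NethomError(f"invalid config {path}: {exc}") from exc


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()
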