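"""File formats: NIfTI-1 volumes, motion text, TSV tables, JSON manifests.

Conventions: 4D runs and 3D masks are NIfTI-1 (uncompressed ``.nii``
by default so byte-identical reruns are possible); motion traces are
6-column whitespace-delimited text (translations mm then rotations
radians, one row per volume); tables are TSV with a header row and
floats printed to 6 significant digits; manifests are sorted-key JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import BoldRun, MotionTrace, NetworkMask, NethomError

__all__ = [
    "read_bold",
    "write_bold",
    "read_mask",
    "write_mask",
    "read_volume",
    "write_volume",
    "read_motion",
    "write_motion",
    "read_table",
    "write_table",
    "write_json",
    "sha256_file",
]


def read_bold(path, tr_override: float | None = None) -> BoldRun:
    """Load a 4D NIfTI run; TR comes from the header unless overridden."""
    path = Path(path)
    if not path.exists():
        raise NethomError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        shape = img.shape
        data = np.asarray(img.dataobj)
    except NethomError:
        raise
    except Exception as exc:  # corrupted header/payload
        raise NethomError(f"cannot read NIfTI file {path}: {exc}") from exc
    if len(shape) != 4:
        raise NethomError(f"{path} is {len(shape)}D; a 4D BOLD run is required")
    tr = tr_override
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr > 0:
            raise NethomError(
                f"{path} has no repetition time in its header; pass tr_override"
            )
    return BoldRun(path.name.split(".")[0], data, tr, np.asarray(img.affine))


def write_bold(run: BoldRun, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float32), run.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], run.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def write_volume(vol: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(path))
    return path


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), np.asarray(img.affine)


def write_mask(mask: NetworkMask, path) -> Path:
    return write_volume(mask.indicator.astype(np.uint8), mask.affine, path)


def read_mask(path) -> NetworkMask:
    vol, affine = read_volume(path)
    return NetworkMask(vol > 0.5, affine)


def write_motion(motion: MotionTrace, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, motion.params, fmt="%.10g")
    return path


def read_motion(path) -> MotionTrace:
    arr = np.loadtxt(path)
    if arr.ndim == 1:
        arr = arr[None, :]
    return MotionTrace(arr)


def write_table(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.6g", index=index)
    return path


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
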