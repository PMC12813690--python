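"""File IO: NIfTI volumes, TSV tables, JSON metadata, checksums."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

DEFAULT_AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])  # 3 mm isotropic


def write_nifti(path: str | Path, data: np.ndarray,
                tr_seconds: float | None = None) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, np.float32), DEFAULT_AFFINE)
    if tr_seconds is not None and data.ndim == 4:
        img.header["pixdim"][4] = tr_seconds
    img.to_filename(str(path))
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    tr = float(img.header["pixdim"][4])
    return np.asarray(img.dataobj, float), tr


def write_tsv(path: str | Path, frame: pd.DataFrame, index: bool = False) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
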