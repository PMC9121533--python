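"""NIfTI / CSV / JSON I/O with grid checks and a checksummed output manifest."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GridMismatchError

__all__ = [
    "save_nifti", "load_nifti", "check_same_grid",
    "write_table", "read_table", "write_json", "write_manifest",
]


def save_nifti(data: np.ndarray, affine: np.ndarray, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(np.float32)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, dtype=float)), str(path))
    return path


def load_nifti(path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def check_same_grid(shape_a, affine_a, shape_b, affine_b,
                    name_a: str = "a", name_b: str = "b") -> None:
    """Raise GridMismatchError unless both volumes share shape and orientation."""
    if tuple(shape_a[:3]) != tuple(shape_b[:3]):
        raise GridMismatchError(
            f"{name_a} shape {tuple(shape_a[:3])} != {name_b} shape {tuple(shape_b[:3])}")
    if not np.allclose(affine_a, affine_b, atol=1e-4):
        raise GridMismatchError(
            f"{name_a} and {name_b} have different orientations (affines differ)")


def write_table(df: pd.DataFrame, path: Path | str) -> Path:
    """CSV, UTF-8, comma-separated, header row, missing values as empty cells."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", na_rep="")
    return path


def read_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_json(obj, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    return str(o)


def write_manifest(outputs: list[Path], path: Path | str) -> Path:
    """Manifest of produced files with sha256 checksums, for provenance."""
    entries = []
    for f in outputs:
        f = Path(f)
        entries.append({
            "path": str(f),
            "bytes": f.stat().st_size,
            "sha256": hashlib.sha256(f.read_bytes()).hexdigest(),
        })
    return write_json({"outputs": entries}, path)
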