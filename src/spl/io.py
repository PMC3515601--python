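"""Readers and writers: delimited-text matrices, labels, maps, reports.

Matrices are TSV/CSV (delimiter chosen by extension) with one header
row of feature ids; labels are one value per row, +-1 (0/1 is remapped
with a warning).  Feature identity is carried by the header names
end-to-end so grid/NIfTI adapters can reshape outputs.  An optional
NIfTI adapter flattens masked voxels to matrix columns and writes maps
back as volumes in the mask geometry.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .localization import ProbabilityMap
from .synth_data import LabeledDataset

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_map",
    "read_map",
    "write_report",
    "read_nifti_dataset",
    "write_map_nifti",
]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(matrix_path, labels_path) -> LabeledDataset:
    """Load a delimited matrix (header row of feature ids) plus a label file."""
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    try:
        df = pd.read_csv(matrix_path, sep=_sep(matrix_path))
    except ValueError as exc:
        raise ValueError(f"{matrix_path}: cannot parse matrix: {exc}") from exc
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        col = bad[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        row = int(coerced.isna().idxmax())
        raise ValueError(
            f"{matrix_path}: non-numeric cell in column {col!r} at line {row + 2}"
        )
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().values)[0]
        raise ValueError(f"{matrix_path}: missing/NaN value at line {r + 2}, column {df.columns[c]!r}")
    y = read_labels(labels_path)
    if len(y) != len(df):
        raise ValueError(
            f"{matrix_path}: {len(df)} data rows but {len(y)} labels in {labels_path}"
        )
    return LabeledDataset(A=df.values, y=y, feature_names=list(df.columns.astype(str)))


def read_labels(path) -> np.ndarray:
    path = Path(path)
    vals = pd.read_csv(path, header=None).iloc[:, 0].values.astype(float)
    uniq = set(np.unique(vals))
    if uniq == {0.0, 1.0}:
        warnings.warn(f"{path}: labels coded 0/1; remapping to -1/+1")
        vals = np.where(vals > 0, 1.0, -1.0)
    return vals


def write_matrix(dataset: LabeledDataset, path) -> None:
    path = Path(path)
    names = dataset.feature_names or [f"f{j}" for j in range(dataset.n_features)]
    pd.DataFrame(dataset.A, columns=names).to_csv(path, sep=_sep(path), index=False)


def write_labels(y: np.ndarray, path) -> None:
    pd.Series(np.asarray(y, dtype=int)).to_csv(path, index=False, header=False)


def write_map(mp: ProbabilityMap, path, feature_names=None) -> None:
    """TSV of (feature_id, probability)."""
    names = feature_names or [f"f{j}" for j in range(mp.p.shape[0])]
    pd.DataFrame({"feature_id": names, "probability": mp.p}).to_csv(
        Path(path), sep="\t", index=False
    )


def read_map(path, class_label: int = +1) -> ProbabilityMap:
    df = pd.read_csv(Path(path), sep="\t")
    return ProbabilityMap(p=df["probability"].values, class_label=class_label, n_folds=0)


def write_report(result: dict, path) -> None:
    """JSON report with stable key order; numpy types coerced to plain Python."""

    def coerce(obj):
        if isinstance(obj, dict):
            return {str(kk): coerce(vv) for kk, vv in obj.items()}
        if isinstance(obj, (list, tuple, np.ndarray)):
            return [coerce(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    Path(path).write_text(json.dumps(coerce(result), indent=2, sort_keys=True) + "\n")


# --- optional NIfTI adapter ------------------------------------------------

def read_nifti_dataset(bold_path, mask_path, labels_path) -> tuple[LabeledDataset, object]:
    """Flatten masked voxels of a 4-D volume into matrix columns.

    Returns the dataset and the mask image (needed to write maps back).
    """
    import nibabel as nib

    bold = nib.load(str(bold_path))
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    data = np.asarray(bold.dataobj)
    if data.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, time)")
    if mask.shape != data.shape[:3]:
        raise ValueError("mask and volume geometries differ")
    A = data[mask].T  # time x voxels
    y = read_labels(labels_path)
    ds = LabeledDataset(A=A, y=y)
    ds.feature_shape = mask.shape
    return ds, mask_img


def write_map_nifti(mp: ProbabilityMap, mask_img, path) -> None:
    """Write a probability map back into the mask geometry."""
    import nibabel as nib

    mask = np.asarray(mask_img.dataobj) > 0
    vol = np.zeros(mask.shape, dtype=np.float64)
    vol[mask] = mp.p
    # fresh header: the mask's (often integer) dtype must not quantize the map
    nib.save(nib.Nifti1Image(vol, mask_img.affine), str(path))
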