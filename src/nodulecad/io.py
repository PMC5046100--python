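"""Reading and writing volumes, masks, feature tables and manifests.

Supported volume formats: NIfTI-1 (``.nii`` / ``.nii.gz``, via nibabel) and
directories of equally sized TIFF/PNG slices stacked in lexicographic
z-order.  Feature tables are plain CSV (UTF-8, ``.`` decimal, comma
separator) with columns ``roi_id,label,fs1..ft16``; floats are written with
12 significant digits so that a write/read round trip is lossless at that
precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .roi import FEATURE_NAMES, FeatureVector, RoiVolume, representative_slice  # noqa: F401

_SLICE_EXTS = {".tif", ".tiff", ".png"}


def _load_array(path: Path) -> Tuple[np.ndarray, Optional[Tuple[float, float, float]]]:
    """Load a 3D array from NIfTI or a slice-stack directory.

    Returns the array in (z, y, x) order plus the header spacing when the
    format carries one (NIfTI), else None.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTS
        )
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG slices found in {path}")
        slices = [np.asarray(iio.imread(f)) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"slices in {path} have differing shapes: {shapes}")
        return np.stack(slices, axis=0), None
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D NIfTI volume, got ndim={data.ndim}")
        # NIfTI stores (x, y, z); the package convention is (z, y, x).
        data = np.transpose(data, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        return data, spacing
    raise ValueError(f"unsupported volume format: {path}")


def read_volume(
    path,
    mask_path,
    spacing: Optional[Sequence[float]] = None,
    label: str = "unknown",
    roi_id: Optional[str] = None,
) -> RoiVolume:
    """Read an image volume and its binary ROI mask into a :class:`RoiVolume`.

    Spacing priority: NIfTI header (image file) > ``spacing`` argument >
    (1, 1, 1).  Any nonzero mask voxel is foreground.  A shape mismatch or an
    empty mask is a hard error.
    """
    img, header_spacing = _load_array(Path(path))
    mask, _ = _load_array(Path(mask_path))
    if img.shape != mask.shape:
        raise ValueError(
            f"image shape {img.shape} does not match mask shape {mask.shape} "
            f"({path} vs {mask_path})"
        )
    if header_spacing is not None:
        sp = header_spacing
    elif spacing is not None:
        sp = tuple(float(s) for s in spacing)
    else:
        sp = (1.0, 1.0, 1.0)
    rid = roi_id if roi_id is not None else Path(path).name.split(".")[0]
    return RoiVolume(intensities=img, mask=mask, spacing=sp, label=label, id=rid)


def write_volume(roi: RoiVolume, path, mask_path) -> None:
    """Write an ROI as a pair of NIfTI files (image + uint8 mask)."""
    affine = np.diag([roi.spacing[2], roi.spacing[1], roi.spacing[0], 1.0])
    img = np.transpose(roi.intensities, (2, 1, 0)).astype(np.float32)
    msk = np.transpose(roi.mask.astype(np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(img, affine), str(path))
    nib.save(nib.Nifti1Image(msk, affine), str(mask_path))


def write_feature_table(rows: List[FeatureVector], path) -> None:
    """Write feature vectors as CSV with header ``roi_id,label,fs1..ft16``."""
    records = []
    for row in rows:
        if not isinstance(row, FeatureVector):
            raise TypeError("write_feature_table expects FeatureVector rows")
        rec = {"roi_id": row.roi_id, "label": "" if row.label is None else int(row.label)}
        rec.update(row.as_dict())
        records.append(rec)
    df = pd.DataFrame(records, columns=["roi_id", "label", *FEATURE_NAMES])
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV into a DataFrame with the canonical column order."""
    df = pd.read_csv(path, dtype={"roi_id": str})
    missing = [c for c in ("roi_id", "label", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} is missing columns {missing}")
    return df[["roi_id", "label", *FEATURE_NAMES]]


def split_feature_table(df: pd.DataFrame) -> Tuple[pd.DataFrame, np.ndarray]:
    """Split a feature table into (42-column feature frame, int label array)."""
    labels = df["label"]
    if labels.isna().any():
        raise ValueError("feature table has unlabeled rows")
    return df[list(FEATURE_NAMES)].astype(float), labels.astype(int).to_numpy()


def write_manifest(entries: List[dict], path) -> None:
    """Write an ROI manifest CSV with columns image,mask,label,id."""
    pd.DataFrame(entries, columns=["image", "mask", "label", "id"]).to_csv(
        path, index=False
    )


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("image", "mask", "label", "id") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns {missing}")
    return df
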