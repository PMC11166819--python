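"""NIfTI/JSON plumbing shared by the phantom writer and the pipeline.

On disk a dynamic series is a 4D NIfTI ordered (x, y, slice, time) with a
JSON sidecar carrying the frame rate, voxel size and (for phantoms) the
true modulation frequencies; masks are 3D NIfTI with labels
0=background, 1=right lung, 2=left lung, 3=heart.  In memory the package
uses (slice, time, row, col) ordering; these helpers do the transposes.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigurationError
from .phantom import PhantomTruth
from .preprocess import DynamicSeries, LungMask


def _sidecar_path(nifti_path: Path) -> Path:
    name = nifti_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return nifti_path.with_name(name[: -len(suffix)] + ".json")
    return nifti_path.with_suffix(".json")


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def write_series(series: DynamicSeries, path: str | Path,
                 extra_sidecar: dict | None = None) -> Path:
    """Write a 4D series + JSON sidecar; returns the NIfTI path."""
    path = Path(path)
    arr = np.transpose(series.data, (2, 3, 0, 1))  # (row, col, slice, time)
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32),
                             _affine(series.voxel_size)), path)
    sidecar = {"frame_rate_hz": series.frame_rate,
               "voxel_size_mm": list(series.voxel_size)}
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_series(path: str | Path) -> DynamicSeries:
    """Read a 4D series written by :func:`write_series` (or compatible)."""
    path = Path(path)
    img = nib.load(path)
    arr = np.asarray(img.dataobj)
    if arr.ndim != 4:
        raise ConfigurationError(f"{path}: expected a 4D series, got "
                                 f"{arr.ndim}D")
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise ConfigurationError(f"missing JSON sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    data = np.transpose(arr, (2, 3, 0, 1))
    return DynamicSeries(data=data, frame_rate=float(sidecar["frame_rate_hz"]),
                         voxel_size=tuple(sidecar["voxel_size_mm"]))


def write_mask(mask: LungMask, path: str | Path,
               voxel_size=(3.3, 3.3, 12.0)) -> Path:
    path = Path(path)
    arr = np.transpose(mask.labels, (1, 2, 0)).astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size)), path)
    return path


def read_mask(path: str | Path) -> LungMask:
    arr = np.asarray(nib.load(path).dataobj)
    if arr.ndim != 3:
        raise ConfigurationError(f"{path}: expected a 3D mask, got "
                                 f"{arr.ndim}D")
    return LungMask(np.transpose(arr, (2, 0, 1)).astype(np.uint8))


def write_truth(truth: PhantomTruth, out_dir: str | Path,
                voxel_size=(3.3, 3.3, 12.0)) -> Path:
    """Write ground truth: JSON scalars plus NIfTI defect/amplitude fields."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(voxel_size)

    def _save(arr, name, dtype):
        nib.save(nib.Nifti1Image(
            np.transpose(arr, (1, 2, 0)).astype(dtype), aff),
            out_dir / name)

    _save(truth.defect_mask_v.astype(np.uint8)
          + 2 * truth.defect_mask_q.astype(np.uint8), "truth_defects.nii.gz",
          np.uint8)
    _save(truth.amp_resp, "truth_amp_resp.nii.gz", np.float32)
    _save(truth.amp_card, "truth_amp_card.nii.gz", np.float32)
    payload = {
        "f_resp_hz": truth.f_resp,
        "f_card_hz": truth.f_card,
        "s0": truth.s0,
        "phases": list(truth.phases),
        "true_defect_fraction_by_side": truth.true_defect_fraction_by_side,
        "bulk_shifts": truth.bulk_shifts.tolist(),
    }
    path = out_dir / "truth.json"
    path.write_text(json.dumps(payload, indent=2))
    return path
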