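"""NIfTI / JSON input-output helpers."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .pseudolabel import IGNORE, PseudoLabel
from .segmentation import UNLABELED, ScribbleSet
from .volume import CAMVolume, VolumeImage

__all__ = [
    "save_nifti", "load_nifti", "save_pseudolabel", "load_pseudolabel",
    "save_scribbles", "load_manifest",
]

_NIFTI_IGNORE = 255


def save_nifti(array: np.ndarray, path, spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_pseudolabel(pseudo: PseudoLabel, path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Export with IGNORE mapped to 255; legend written as a sidecar JSON."""
    arr = pseudo.values.astype(np.int16).copy()
    arr[arr == IGNORE] = _NIFTI_IGNORE
    save_nifti(arr.astype(np.uint8), path, spacing)
    legend = {str(k): v for k, v in pseudo.legend.items()}
    Path(str(path) + ".legend.json").write_text(json.dumps(legend, indent=2))


def load_pseudolabel(path) -> PseudoLabel:
    arr, _ = load_nifti(path)
    arr = arr.astype(np.int16)
    arr[arr == _NIFTI_IGNORE] = IGNORE
    return PseudoLabel(arr)


def save_scribbles(scribbles: ScribbleSet, path, spacing=(1.0, 1.0, 1.0)) -> None:
    arr = scribbles.labels.astype(np.int16).copy()
    arr[arr == UNLABELED] = _NIFTI_IGNORE
    save_nifti(arr.astype(np.uint8), path, spacing)


def load_manifest(path) -> dict:
    path = Path(path)
    manifest = json.loads(path.read_text())
    manifest["_dir"] = str(path.parent)
    return manifest


def load_case(manifest: dict, case: dict):
    """Load a manifest case's (volume, mask, cam) triplet."""
    base = Path(manifest["_dir"])
    vol, spacing = load_nifti(base / case["paths"]["volume"])
    mask, _ = load_nifti(base / case["paths"]["mask"])
    cam, _ = load_nifti(base / case["paths"]["cam"])
    volume = VolumeImage(np.asarray(vol, dtype=np.float64), spacing)
    cam_v = CAMVolume(np.asarray(cam, dtype=np.float64),
                      class_names=["background", "cavity"], spacing=spacing)
    return volume, np.asarray(mask).astype(np.int16), cam_v
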