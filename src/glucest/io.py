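"""NIfTI + JSON-sidecar serialisation for stacks, maps and masks.

A Z-spectrum stack is written as one 3D NIfTI volume with offsets along
the third axis and a JSON sidecar (same stem, ``.json``) listing the
offsets in ppm and the acquisition metadata.  2D maps and masks are
plain single-slice NIfTI.  Identity affines are used throughout: the
simulated slice has no meaningful scanner frame.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import ZStack


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))


def save_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    nib.save(_nifti(image), path)
    return path


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(path).get_fdata(), dtype=float)


def save_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    nib.save(
        nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine=np.eye(4)), path
    )
    return path


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(path).get_fdata()) > 0.5


def save_zstack(stack: ZStack, path: str | Path, sidecar: dict | None = None) -> Path:
    """Write stack + sidecar; ``<stem>_s0.nii.gz`` holds S0 if present."""
    path = Path(path)
    nib.save(_nifti(stack.data), path)
    meta = {"offsets_ppm": stack.offsets.tolist()}
    if sidecar:
        meta.update(sidecar)
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    if stack.s0 is not None:
        s0_path = path.with_name(stem + "_s0.nii.gz")
        nib.save(_nifti(stack.s0), s0_path)
        meta["s0_file"] = s0_path.name
    sidecar_path = path.with_name(stem + ".json")
    sidecar_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_zstack(path: str | Path) -> tuple[ZStack, dict]:
    """Read a stack written by :func:`save_zstack`; returns (stack, sidecar)."""
    path = Path(path)
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    meta = json.loads(path.with_name(stem + ".json").read_text())
    data = load_image(path)
    s0 = None
    if "s0_file" in meta:
        s0 = load_image(path.with_name(meta["s0_file"]))
    stack = ZStack(data=data, offsets=np.asarray(meta["offsets_ppm"]), s0=s0)
    return stack, meta
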