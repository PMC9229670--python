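"""Reading and writing volumes (NIfTI or PNG/TIFF slice directories) and
network checkpoints.

A volume on disk is either a single ``.nii``/``.nii.gz`` file or a directory
of 2-D slice images ordered by natural filename sort.  Masks are stored as
0/255 PNG (or 0/1 NIfTI) and come back as {0,1}.  Checkpoints are ``.npz``
archives holding every named parameter plus the generator config as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .networks import GeneratorConfig, NetworkHandle, build_generator
from .preprocess import VolumeStack

_SLICE_EXTS = (".png", ".tif", ".tiff")


def natural_sort_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def load_volume(path: str | Path, is_mask: bool = False) -> VolumeStack:
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTS),
            key=lambda p: natural_sort_key(p.name),
        )
        if not files:
            raise FileNotFoundError(f"no slice images in {path}")
        data = np.stack([np.asarray(iio.imread(f)).astype(np.float32) for f in files])
        spacing = 0.5
        declared_hi = 255.0 if data.max() > 1 else 1.0
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        # stored (h, w, n_slices); stack axis first
        data = np.ascontiguousarray(np.asanyarray(img.dataobj).astype(np.float32).transpose(2, 0, 1))
        zooms = img.header.get_zooms()
        spacing = float(zooms[2]) if len(zooms) >= 3 else 0.5
        declared_hi = float(max(1.0, data.max()))
    else:
        raise ValueError(f"unsupported volume path: {path}")
    if is_mask:
        data = (data > (declared_hi / 2)).astype(np.float32)
        return VolumeStack.from_array(data, value_range=(0.0, 1.0), spacing_mm=spacing)
    return VolumeStack.from_array(data, value_range=(0.0, declared_hi), spacing_mm=spacing)


def save_volume(vol: VolumeStack, path: str | Path, is_mask: bool = False) -> Path:
    """Write as NIfTI when the path ends in .nii/.nii.gz, else as a directory
    of per-slice PNGs (masks scaled to 0/255)."""
    path = Path(path)
    data = vol.as_array()
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        affine = np.diag([1.0, 1.0, vol.spacing_mm, 1.0])
        arr = data.transpose(1, 2, 0).astype(np.float32)
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(arr, affine), str(path))
        return path
    path.mkdir(parents=True, exist_ok=True)
    for j, sl in enumerate(data):
        if is_mask:
            out = (sl > 0.5).astype(np.uint8) * 255
        else:
            lo, hi = vol.value_range
            out = np.clip((sl - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
        iio.imwrite(path / f"slice{j:04d}.png", out)
    return path


def load_dataset(data_dir: str | Path) -> list[tuple[VolumeStack, VolumeStack]]:
    """Paired volumes from ``<data_dir>/images`` and ``<data_dir>/masks``
    (matching names; NIfTI files or per-volume slice directories)."""
    data_dir = Path(data_dir)
    img_dir, mask_dir = data_dir / "images", data_dir / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"expected {img_dir} and {mask_dir}")
    entries = sorted(img_dir.iterdir(), key=lambda p: natural_sort_key(p.name))
    pairs = []
    for entry in entries:
        counterpart = mask_dir / entry.name
        if not counterpart.exists():
            raise FileNotFoundError(f"no mask for {entry.name}")
        pairs.append((load_volume(entry), load_volume(counterpart, is_mask=True)))
    if not pairs:
        raise FileNotFoundError(f"no volumes under {img_dir}")
    return pairs


def save_checkpoint(handle: NetworkHandle, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = handle.model.state_dict()
    meta = json.dumps(
        {"role": handle.role, "config": dataclasses.asdict(handle.config)}
    )
    np.savez_compressed(path, __meta__=np.array(meta), **state)
    return path


def load_checkpoint(path: str | Path) -> NetworkHandle:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["role"] != "generator":
        raise ValueError("checkpoint does not hold a generator")
    cfg = meta["config"]
    handle = build_generator(GeneratorConfig(**cfg))
    handle.model.load_state_dict(state)
    return handle
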