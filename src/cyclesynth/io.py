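"""File I/O: NIfTI volumes, 16-bit PNG slices, normalization, configuration."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import yaml

from .phantom import DatasetManifest


@dataclass
class Volume3D:
    """Voxel array with NIfTI affine metadata (spacing in mm)."""

    data: np.ndarray  # (H, W, D)
    affine: np.ndarray  # 4x4

    @property
    def spacing(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


def read_volume(path) -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - surface filename with the cause
        raise ValueError(f"could not parse {path}: {exc}") from exc
    return Volume3D(data=np.asarray(img.get_fdata()), affine=np.asarray(img.affine))


def write_volume(vol: Volume3D, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def normalize_intensity(array) -> np.ndarray:
    """Min-max rescale to [-1, 1]; a constant input maps to all zeros."""
    arr = np.asarray(array, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr, dtype=np.float32)
    return (2.0 * (arr - lo) / (hi - lo) - 1.0).astype(np.float32)


def extract_axial_slices(vol: Volume3D, n: int) -> list[np.ndarray]:
    """n equally spaced axial slices centered on the volume's middle third.

    If n exceeds the middle third's extent the whole depth range is used;
    n == D returns every slice in order, n == 1 the single middle slice.
    """
    d = vol.data.shape[2]
    if n > d:
        raise ValueError(f"requested {n} slices from a depth-{d} volume")
    lo = d // 3
    hi = d - d // 3 - 1
    if n > hi - lo + 1:
        lo, hi = 0, d - 1
    span = hi - lo + 1
    indices = [lo + int((k + 0.5) * span / n) for k in range(n)]
    return [np.asarray(vol.data[:, :, i]) for i in indices]


# -- 16-bit grayscale PNG slices -----------------------------------------------


def write_image(image: np.ndarray, path) -> None:
    """Store a [-1, 1] slice as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), -1.0, 1.0)
    iio.imwrite(Path(path), ((arr + 1.0) / 2.0 * 65535.0).round().astype(np.uint16))


def read_image(path) -> np.ndarray:
    """Load a 16-bit grayscale PNG back onto the [-1, 1] scale."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = np.asarray(iio.imread(path), dtype=np.float64)
    return (arr / 65535.0 * 2.0 - 1.0).astype(np.float32)


def save_dataset(manifest: DatasetManifest, out_dir) -> Path:
    """Materialize a manifest: per-subject contrast_a/contrast_b PNG trees
    plus manifest.json. Returns the manifest path."""
    out = Path(out_dir)
    for i, entry in enumerate(manifest.entries):
        rec = manifest.render(i)
        for sub, img in (("contrast_a", rec.contrast1), ("contrast_b", rec.contrast2)):
            d = out / entry.subject_id / sub
            d.mkdir(parents=True, exist_ok=True)
            write_image(img, d / f"slice{entry.slice_index:03d}.png")
    path = out / "manifest.json"
    manifest.save(path)
    return path


def load_dataset(manifest_path) -> DatasetManifest:
    path = Path(manifest_path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    return DatasetManifest.load(path)


# -- run configuration -----------------------------------------------------------


def save_config(config: dict, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yml", ".yaml"):
            yaml.safe_dump(config, fh, sort_keys=True)
        else:
            import json

            json.dump(config, fh, indent=1, sort_keys=True)


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    with open(path) as fh:
        if path.suffix in (".yml", ".yaml"):
            return yaml.safe_load(fh)
        import json

        return json.load(fh)
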