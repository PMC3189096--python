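"""Reading and writing slices and masks (8-bit grayscale PNG, single-slice NIfTI)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .histogram_fcm import ImagePair

__all__ = ["read_slice", "read_pair", "read_mask", "write_mask", "write_slice"]


def read_slice(path: str | Path) -> np.ndarray:
    """Load one 2D 8-bit grayscale slice from PNG or single-slice NIfTI."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single 2D slice, got shape {data.shape}")
    else:
        data = np.asarray(Image.open(path).convert("L"))
    if data.min() < 0 or data.max() > 255:
        raise ValueError(f"{path}: intensities outside the 8-bit range [0, 255]")
    return data.astype(np.uint8)


def read_pair(t1_path: str | Path, t2_path: str | Path) -> ImagePair:
    return ImagePair(t1=read_slice(t1_path), t2=read_slice(t2_path))


def read_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask (any nonzero pixel is foreground)."""
    return read_slice(path) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a 0/255 grayscale PNG."""
    img = Image.fromarray((np.asarray(mask, dtype=bool) * np.uint8(255)), mode="L")
    img.save(str(path))


def write_slice(arr: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(arr, dtype=np.uint8), mode="L").save(str(path))
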