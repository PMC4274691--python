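"""Image and label-mask readers/writers.

RGB sections are read from TIFF or PNG and auto-scaled to [0, 1] from
8/16-bit integer data.  Label masks are written as 16-bit PNG (or TIFF),
intermediate float images as 32-bit float TIFF.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .types import DEFAULT_PX_SCALE_UM, GrayImage, LabelMask, MuscleSegError, RGBImage


def _to_unit(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    info = np.iinfo(arr.dtype)
    return arr.astype(np.float64) / info.max


def read_image(path: str | Path,
               px_scale_um: float = DEFAULT_PX_SCALE_UM) -> RGBImage:
    """Read a TIFF/PNG section as an RGBImage in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise MuscleSegError(f"input image not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return RGBImage(_to_unit(arr), px_scale_um=px_scale_um)


def write_image(path: str | Path, img: RGBImage) -> None:
    """Write an RGB image as 8-bit TIFF or PNG by extension."""
    arr = np.round(img.pixels * 255).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_gray_tiff(path: str | Path, gray: GrayImage) -> None:
    """Write a grayscale image as 32-bit float TIFF (inspection output)."""
    tifffile.imwrite(Path(path), gray.pixels.astype(np.float32))


def write_label_mask(path: str | Path, labels: LabelMask) -> None:
    """Write a label mask as 16-bit PNG or TIFF by extension."""
    lab = labels.labels
    if lab.max() > np.iinfo(np.uint16).max:
        raise MuscleSegError("too many labels for 16-bit output")
    arr = lab.astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_label_mask(path: str | Path,
                    px_scale_um: float = DEFAULT_PX_SCALE_UM) -> LabelMask:
    """Read a 8/16-bit integer label mask."""
    path = Path(path)
    if not path.exists():
        raise MuscleSegError(f"label mask not found: {path}")
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise MuscleSegError(f"label mask must be single-channel: {path}")
    return LabelMask(arr.astype(np.int32), px_scale_um=px_scale_um)


def write_overlay(path: str | Path, img: RGBImage, labels: LabelMask,
                  alpha: float = 0.35) -> None:
    """Write a colour overlay of the segmentation on the source image."""
    from skimage.color import label2rgb

    over = label2rgb(labels.labels, image=img.pixels, alpha=alpha,
                     bg_label=0, kind="overlay")
    iio.imwrite(Path(path), np.round(np.clip(over, 0, 1) * 255).astype(np.uint8))
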