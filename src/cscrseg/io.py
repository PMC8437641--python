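"""Image pair loading, ROI boxes, and mask I/O.

The pipeline operates on a *registered* multimodal pair: a fluorescein
angiography image and a color fundus photograph of the same eye sharing a
pixel grid. Registration itself is out of scope — inputs are assumed
pre-registered, and a dimension mismatch is treated as a registration error.
All intensities are normalized to [0, 1] at load time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ImagePair",
    "ROIBox",
    "RegistrationError",
    "load_image_pair",
    "load_mask",
    "save_mask",
]


class RegistrationError(ValueError):
    """The two modalities do not share a pixel grid."""


@dataclass(frozen=True)
class ImagePair:
    """A registered angiography / color-fundus pair.

    Attributes
    ----------
    angiography : ndarray, shape (H, W)
        Single-channel angiography intensities in [0, 1].
    color_fundus : ndarray, shape (H, W, 3)
        RGB fundus photograph in [0, 1], same height/width.
    pixel_size_note : str, optional
        Free-text acquisition metadata.
    """

    angiography: np.ndarray
    color_fundus: np.ndarray
    pixel_size_note: str | None = None

    def __post_init__(self) -> None:
        if self.angiography.ndim != 2:
            raise ValueError("angiography must be a 2-D intensity raster")
        if self.color_fundus.ndim != 3 or self.color_fundus.shape[2] != 3:
            raise ValueError("color_fundus must be an (H, W, 3) RGB raster")
        if self.angiography.shape != self.color_fundus.shape[:2]:
            raise RegistrationError(
                f"modalities differ in size: angiography "
                f"{self.angiography.shape} vs fundus {self.color_fundus.shape[:2]}"
            )
        for name, arr in (("angiography", self.angiography),
                          ("color_fundus", self.color_fundus)):
            if arr.size and (np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0):
                raise ValueError(f"{name} intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.angiography.shape


@dataclass(frozen=True)
class ROIBox:
    """Half-open rectangle [r0, r1) x [c0, c1) in 0-based pixel coordinates.

    The box is the operator's manual localization of the suspected leakage
    area; every downstream computation is restricted to it.
    """

    r0: int
    c0: int
    r1: int
    c1: int

    def __post_init__(self) -> None:
        if not (0 <= self.r0 < self.r1 and 0 <= self.c0 < self.c1):
            raise ValueError(f"degenerate ROI box {self.astuple()}")

    def astuple(self) -> tuple[int, int, int, int]:
        return (self.r0, self.c0, self.r1, self.c1)

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    def validate_for(self, shape: tuple[int, int],
                     min_side: int | None = None) -> None:
        """Raise if the box exceeds ``shape`` or is smaller than ``min_side``."""
        h, w = shape
        if self.r1 > h or self.c1 > w:
            raise ValueError(
                f"ROI box {self.astuple()} exceeds image shape {(h, w)}")
        if min_side is not None and (self.height < min_side
                                     or self.width < min_side):
            raise ValueError(
                f"ROI box {self.height}x{self.width} is smaller than the "
                f"patch size {min_side}; enlarge the selection")


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer raster to [0, 1] floats; floats pass through."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    out = arr.astype(np.float64)
    if out.size and out.max() > 1.0:  # float file on a 0..255 scale
        out = out / 255.0
    return out


def _read_raster(path: str | Path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:  # backends raise mixed types for bad files
        raise OSError(f"cannot read image {path!r}: {exc}") from exc
    return _to_unit_float(np.asarray(arr))


def load_image_pair(angio_path: str | Path,
                    fundus_path: str | Path) -> ImagePair:
    """Load and normalize a registered angiography/fundus pair.

    RGB angiography files are reduced to the green channel (the standard
    high-contrast channel in fundus imaging); grayscale passes through.
    An alpha channel, if present, is dropped.
    """
    angio = _read_raster(angio_path)
    fundus = _read_raster(fundus_path)
    if angio.ndim == 3:
        angio = angio[..., 1] if angio.shape[2] >= 3 else angio[..., 0]
    if fundus.ndim == 3 and fundus.shape[2] == 4:
        fundus = fundus[..., :3]
    if fundus.ndim != 3:
        raise ValueError(f"fundus image {fundus_path!r} is not RGB")
    if angio.shape != fundus.shape[:2]:
        raise RegistrationError(
            f"angiography {angio.shape} and fundus {fundus.shape[:2]} "
            "differ in size; register the pair upstream")
    return ImagePair(angiography=np.clip(angio, 0.0, 1.0),
                     color_fundus=np.clip(fundus, 0.0, 1.0))


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a lossless 0/255 PNG."""
    arr = np.asarray(mask)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1, True, False))):
        raise ValueError("mask must be binary (0/1) to be saved")
    iio.imwrite(Path(path), (arr.astype(np.uint8) * 255), extension=".png")


def load_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG mask back as a boolean raster."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127
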