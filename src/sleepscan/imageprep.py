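"""Page-image preprocessing ahead of OCR.

Six methods are supported, all combinations of three primitive stages:
gray-scaling (luma weighting), one iteration of dilation followed by one
iteration of erosion with a 3x3 square kernel (which removes small dark
noise specks from a light background), and a multiplicative contrast gain
of 20% or 60%. The composed default is gray -> dilate/erode -> contrast 20%.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "PageImage",
    "PrepMethod",
    "to_grayscale",
    "dilate_erode",
    "adjust_contrast",
    "apply_method",
    "load_page_image",
]

#: Luma weights for RGB -> gray conversion (ITU-R BT.601).
_LUMA = np.array([0.299, 0.587, 0.114])

#: Square structuring element; the minimal neighborhood that removes
#: isolated noise dots while leaving multi-pixel strokes intact.
_KERNEL_SIZE = (3, 3)


@dataclass
class PageImage:
    """One report page as a pixel matrix.

    ``pixels`` is H x W (gray) or H x W x 3 (color), dtype uint8.
    ``page_num`` is 1-based.
    """

    pixels: np.ndarray
    report_id: str = ""
    page_num: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"pixels must be HxW or HxWx3, got shape {self.pixels.shape}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError(f"color image must have 3 channels, got {self.pixels.shape[2]}")
        if self.page_num < 1:
            raise ValueError("page_num is 1-based and must be >= 1")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 255):
            raise ValueError("pixel values must lie in [0, 255]")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def is_gray(self) -> bool:
        return self.pixels.ndim == 2

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def copy_with(self, pixels: np.ndarray) -> "PageImage":
        return PageImage(pixels=pixels, report_id=self.report_id, page_num=self.page_num)


class PrepMethod(enum.Enum):
    """The six preprocessing method combinations."""

    GRAY = "gray"
    GRAY_DE = "gray_de"
    GRAY_C20 = "gray_c20"
    GRAY_C60 = "gray_c60"
    GRAY_DE_C20 = "gray_de_c20"
    GRAY_DE_C60 = "gray_de_c60"

    @property
    def uses_morphology(self) -> bool:
        return "de" in self.value.split("_")

    @property
    def contrast_pct(self) -> int | None:
        if self.value.endswith("c20"):
            return 20
        if self.value.endswith("c60"):
            return 60
        return None


#: The pipeline's default method: gray-scale + dilate/erode + 20% contrast.
DEFAULT_METHOD = PrepMethod.GRAY_DE_C20


def to_grayscale(img: PageImage) -> PageImage:
    """Convert a 3-channel color page to 1-channel gray (luma weighting).

    A page that is already gray is returned unchanged (identity).
    """
    if img.is_gray:
        return img
    gray = np.rint(img.pixels.astype(np.float64) @ _LUMA)
    return img.copy_with(np.clip(gray, 0, 255).astype(np.uint8))


def dilate_erode(img: PageImage) -> PageImage:
    """One iteration of dilation then one of erosion (3x3 square kernel).

    With the standard bright-region-growing convention this is a
    morphological closing of the bright background, i.e. an opening with
    respect to dark strokes: isolated dark noise dots vanish while strokes
    thick enough to contain the kernel survive. The operation is
    idempotent and never darkens any pixel.
    """
    if not img.is_gray:
        raise ValueError("dilate_erode expects a gray image; call to_grayscale first")
    dilated = ndimage.grey_dilation(img.pixels, size=_KERNEL_SIZE)
    eroded = ndimage.grey_erosion(dilated, size=_KERNEL_SIZE)
    return img.copy_with(eroded)


def adjust_contrast(img: PageImage, pct: int) -> PageImage:
    """Multiplicative contrast gain: pixel -> clip(round((1 + pct/100) * pixel)).

    The canonical gains are 20 and 60; other values work but are flagged.
    The mapping is monotone non-decreasing, so pixel ordering is preserved.
    """
    if not img.is_gray:
        raise ValueError("adjust_contrast expects a gray image")
    if pct not in (20, 60):
        warnings.warn(f"contrast gain {pct}% is non-canonical (expected 20 or 60)", stacklevel=2)
    gain = 1.0 + pct / 100.0
    out = np.clip(np.rint(img.pixels.astype(np.float64) * gain), 0, 255)
    return img.copy_with(out.astype(np.uint8))


def apply_method(img: PageImage, method: PrepMethod = DEFAULT_METHOD) -> PageImage:
    """Apply one of the six preprocessing methods.

    Stage order: gray -> (dilate/erode?) -> (contrast?).
    """
    method = PrepMethod(method)
    out = to_grayscale(img)
    if method.uses_morphology:
        out = dilate_erode(out)
    if method.contrast_pct is not None:
        out = adjust_contrast(out, method.contrast_pct)
    return out


def load_page_image(path: str | Path, report_id: str = "", page_num: int = 1) -> PageImage:
    """Load a PNG/TIFF page image from disk.

    PDF inputs are not supported (no rasterizer backend); export pages to
    PNG or TIFF first.
    """
    path = Path(path)
    if path.suffix.lower() == ".pdf":
        raise ValueError(
            "PDF ingestion is not supported in this build; rasterize pages to PNG/TIFF first"
        )
    from PIL import Image

    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        pixels = np.asarray(im)
    return PageImage(pixels=pixels, report_id=report_id or path.stem, page_num=page_num)
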