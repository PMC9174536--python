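"""Angiogram loading, enhancement and paired augmentation.

Images are handled as 2-D float rasters in [0, 1] ("gray images"); vessel
masks are binary {0, 1} rasters of identical shape.  Two mutually exclusive
enhancement strategies are offered, mirroring how they are ablated in
practice: a morphological top-hat procedure (add the white top-hat, subtract
the black top-hat — brightens bright detail, darkens dark vessels) and CLAHE
(contrast-limited adaptive histogram equalization).  Exactly one of
``{none, tophat, clahe}`` is applied per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage import morphology as morph
from skimage import transform as sktransform

__all__ = [
    "StructuringElement",
    "SamplePair",
    "AugmentParams",
    "load_image",
    "load_mask",
    "save_image",
    "save_mask",
    "white_tophat",
    "black_tophat",
    "tophat_enhance",
    "clahe",
    "center_crop",
    "resize",
    "augment_pair",
    "enhance",
]

#: Rec.601 luma weights used to collapse RGB inputs to gray.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def _validate_gray(img: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"{name} must be a 2-D raster, got shape {img.shape}")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError(f"{name} must be at least 8x8, got {img.shape}")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError(f"{name} intensities must lie in [0, 1]")
    return img


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be strictly binary {0, 1}")
    return mask.astype(np.uint8)


@dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element for gray-scale morphology."""

    shape: str = "disk"
    radius: int = 9

    def __post_init__(self):
        if self.shape not in ("disk", "square"):
            raise ValueError("shape must be 'disk' or 'square'")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    def footprint(self) -> np.ndarray:
        if self.shape == "disk":
            return morph.disk(self.radius)
        side = 2 * self.radius + 1
        return np.ones((side, side), dtype=np.uint8)

    @classmethod
    def scaled(cls, image_shape, shape: str = "disk",
               base_radius: int = 9, base_side: int = 300) -> "StructuringElement":
        """Radius proportional to image side (radius 9 at a 300-pixel side)."""
        side = min(image_shape)
        return cls(shape, max(1, round(base_radius * side / base_side)))


@dataclass
class SamplePair:
    """An angiogram with its aligned binary vessel mask."""

    image: np.ndarray
    mask: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.image = _validate_gray(self.image)
        self.mask = _validate_mask(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} differ")


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Load a PNG/PGM/BMP/TIFF frame as a gray raster in [0, 1].

    Three-channel inputs are collapsed with Rec.601 luma weights
    (0.299, 0.587, 0.114); 8- and 16-bit depths are rescaled by their
    full-scale value.
    """
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(
                f"unsupported channel count {arr.shape[2]} in {path!r}")
        arr = arr.astype(np.float64) @ np.asarray(LUMA_WEIGHTS)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image layout {arr.shape} in {path!r}")
    arr = arr.astype(np.float64)
    if arr.max() > 255.0:
        arr /= 65535.0
    else:
        arr /= 255.0
    return np.clip(arr, 0.0, 1.0)


def load_mask(path) -> np.ndarray:
    """Load a single-channel mask PNG, mapping {0, 255} (or any >0) to {0, 1}."""
    arr = load_image(path)
    return (arr > 0.5).astype(np.uint8)


def save_image(path, img: np.ndarray) -> None:
    img = _validate_gray(img)
    Image.fromarray(np.round(img * 255.0).astype(np.uint8)).save(path)


def save_mask(path, mask: np.ndarray) -> None:
    mask = _validate_mask(mask)
    Image.fromarray((mask * 255).astype(np.uint8)).save(path)


# ---------------------------------------------------------------------------
# morphological enhancement
# ---------------------------------------------------------------------------

def _check_se(img: np.ndarray, se: StructuringElement) -> np.ndarray:
    fp = se.footprint()
    if fp.shape[0] > img.shape[0] or fp.shape[1] > img.shape[1]:
        raise ValueError(
            f"structuring element {fp.shape} larger than image {img.shape}")
    return fp


def white_tophat(img: np.ndarray, se: StructuringElement) -> np.ndarray:
    """img minus its gray-scale opening: bright detail smaller than ``se``."""
    img = _validate_gray(img)
    return morph.white_tophat(img, footprint=_check_se(img, se))


def black_tophat(img: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Gray-scale closing minus img: dark detail smaller than ``se``."""
    img = _validate_gray(img)
    return morph.black_tophat(img, footprint=_check_se(img, se))


def tophat_enhance(img: np.ndarray, se: StructuringElement | None = None) -> np.ndarray:
    """Contrast enhancement: img + white top-hat - black top-hat, clipped.

    Small bright structures get brighter and small dark structures (vessels
    filled with contrast agent) get darker; regions flat at the scale of the
    structuring element are left untouched.
    """
    img = _validate_gray(img)
    if se is None:
        se = StructuringElement.scaled(img.shape)
    return np.clip(img + white_tophat(img, se) - black_tophat(img, se), 0.0, 1.0)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def _clahe_tile_luts(img8: np.ndarray, clip_limit: float, tiles,
                     return_hists: bool = False):
    """Per-tile clipped-histogram lookup tables on an 8-bit raster.

    The clip ceiling follows the common convention ``clip_limit`` times the
    mean bin height; clipped excess is redistributed uniformly.
    """
    th, tw = tiles
    H, W = img8.shape
    tile_h = -(-H // th)
    tile_w = -(-W // tw)
    pad_h, pad_w = tile_h * th - H, tile_w * tw - W
    padded = np.pad(img8, ((0, pad_h), (0, pad_w)), mode="reflect")
    npix = tile_h * tile_w
    limit = max(1, int(clip_limit * npix / 256.0))
    luts = np.empty((th, tw, 256), dtype=np.float64)
    raw_hists = np.empty((th, tw, 256), dtype=np.int64)
    clipped_hists = np.empty_like(raw_hists)
    for i in range(th):
        for j in range(tw):
            tile = padded[i * tile_h:(i + 1) * tile_h,
                          j * tile_w:(j + 1) * tile_w]
            hist = np.bincount(tile.ravel(), minlength=256)
            raw_hists[i, j] = hist
            clipped = np.minimum(hist, limit)
            clipped_hists[i, j] = clipped
            excess = int(hist.sum() - clipped.sum())
            redist = clipped + excess / 256.0
            cdf = np.cumsum(redist)
            luts[i, j] = np.clip(cdf / npix * 255.0, 0.0, 255.0)
    if return_hists:
        return luts, (tile_h, tile_w), limit, raw_hists, clipped_hists
    return luts, (tile_h, tile_w), limit


def clahe(img: np.ndarray, clip_limit: float = 2.0, tiles=(8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Operates on an internal 8-bit quantization of [0, 1]; tile mappings are
    blended with bilinear interpolation between tile centers, so no tile
    boundaries are visible in the output.
    """
    img = _validate_gray(img)
    if clip_limit <= 0:
        raise ValueError("clip limit must be positive")
    th, tw = tiles
    if th < 1 or tw < 1:
        raise ValueError("tile grid dims must be positive")
    img8 = np.round(img * 255.0).astype(np.uint8)
    luts, (tile_h, tile_w), _ = _clahe_tile_luts(img8, clip_limit, tiles)

    H, W = img8.shape
    yy, xx = np.mgrid[0:H, 0:W]
    gy = np.clip((yy + 0.5) / tile_h - 0.5, 0.0, th - 1.0)
    gx = np.clip((xx + 0.5) / tile_w - 0.5, 0.0, tw - 1.0)
    y0 = np.floor(gy).astype(int)
    x0 = np.floor(gx).astype(int)
    y1 = np.minimum(y0 + 1, th - 1)
    x1 = np.minimum(x0 + 1, tw - 1)
    fy, fx = gy - y0, gx - x0
    v = img8
    out = ((1 - fy) * (1 - fx) * luts[y0, x0, v]
           + (1 - fy) * fx * luts[y0, x1, v]
           + fy * (1 - fx) * luts[y1, x0, v]
           + fy * fx * luts[y1, x1, v])
    return np.clip(out / 255.0, 0.0, 1.0)


def enhance(img: np.ndarray, strategy: str = "none",
            se: StructuringElement | None = None,
            clip_limit: float = 2.0, tiles=(8, 8)) -> np.ndarray:
    """Apply exactly one enhancement strategy: none, tophat or clahe."""
    if strategy == "none":
        return _validate_gray(img)
    if strategy == "tophat":
        return tophat_enhance(img, se)
    if strategy == "clahe":
        return clahe(img, clip_limit, tiles)
    raise ValueError(f"unknown enhancement strategy {strategy!r}")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def center_crop(img: np.ndarray, target) -> np.ndarray:
    """Central window of the requested (h, w) size."""
    img = np.asarray(img)
    h, w = target
    if h > img.shape[0] or w > img.shape[1]:
        raise ValueError(f"crop {target} exceeds image dims {img.shape}")
    top = (img.shape[0] - h) // 2
    left = (img.shape[1] - w) // 2
    return img[top:top + h, left:left + w]


def resize(img: np.ndarray, target, mode: str = "bilinear") -> np.ndarray:
    """Resize a raster: bilinear for images, nearest for masks."""
    h, w = target
    if h < 8 or w < 8:
        raise ValueError("target dims must be >= 8")
    if mode not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resize mode {mode!r}")
    img = np.asarray(img)
    if img.shape == (h, w):
        return img.copy()
    order = 1 if mode == "bilinear" else 0
    out = sktransform.resize(img.astype(np.float64), (h, w), order=order,
                             mode="edge", anti_aliasing=False,
                             preserve_range=True)
    if mode == "nearest":
        return out.astype(img.dtype)
    return np.clip(out, img.min(), img.max())


# ---------------------------------------------------------------------------
# paired augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    """Magnitudes of the random augmentation draws."""

    rotation_deg: float = 15.0
    crop_range: tuple = (0.9, 1.0)
    hflip: bool = True
    vflip: bool = True


def _apply_geometry(raster: np.ndarray, angle: float, crop_box, flips,
                    out_shape, order: int) -> np.ndarray:
    """One geometric transform shared by image and mask (order differs)."""
    out = raster
    if angle != 0.0:
        out = ndi.rotate(out.astype(np.float64), angle, reshape=False,
                         order=order, mode="reflect")
    top, left, ch, cw = crop_box
    if (ch, cw) != out.shape:
        out = out[top:top + ch, left:left + cw]
        out = sktransform.resize(out.astype(np.float64), out_shape,
                                 order=order, mode="edge",
                                 anti_aliasing=False, preserve_range=True)
    if flips[0]:
        out = out[:, ::-1]
    if flips[1]:
        out = out[::-1, :]
    return out


def augment_pair(sample: SamplePair, seed: int,
                 params: AugmentParams = AugmentParams()) -> SamplePair:
    """Apply one randomly drawn transform identically to image and mask.

    The image is interpolated bilinearly, the mask with nearest neighbour so
    it stays strictly binary; the same seed always yields the same output.
    """
    rng = np.random.default_rng(seed)
    h, w = sample.image.shape
    angle = float(rng.uniform(-params.rotation_deg, params.rotation_deg))
    frac = float(rng.uniform(*params.crop_range))
    ch, cw = max(8, round(h * frac)), max(8, round(w * frac))
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    flips = (params.hflip and bool(rng.integers(0, 2)),
             params.vflip and bool(rng.integers(0, 2)))
    box = (top, left, ch, cw)
    img = _apply_geometry(sample.image, angle, box, flips, (h, w), order=1)
    msk = _apply_geometry(sample.mask, angle, box, flips, (h, w), order=0)
    return SamplePair(np.clip(img, 0.0, 1.0), (msk > 0.5).astype(np.uint8),
                      name=sample.name)
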