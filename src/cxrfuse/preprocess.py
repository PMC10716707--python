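"""Chest X-ray preprocessing: lung segmentation, lung-region cropping,
resizing/normalization, and stochastic affine augmentation.

Cropping to the lung bounding box makes the network attend to the lungs
instead of the surrounding anatomy.  Production use expects lung masks
from a dedicated segmentation model supplied as files or via a model
hook; the built-in heuristic backend (Otsu threshold + two largest
bright components) is a documented fallback for mask-less inputs and
synthetic data, not a segmentation model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.transform import AffineTransform, resize, warp


class SegmentationError(RuntimeError):
    pass


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG (or DICOM, when pydicom is installed) as a
    grayscale float image scaled to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        arr = pydicom.dcmread(path).pixel_array.astype(float)
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=float)
        if arr.ndim == 3:
            arr = arr.mean(axis=-1)
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def _validate_mask(mask: np.ndarray, image: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} does not match "
                         f"image shape {image.shape}")
    if not mask.any():
        raise SegmentationError("empty lung mask")
    return mask


def segment_lungs(image: np.ndarray, backend: str = "heuristic",
                  mask: np.ndarray | str | Path | None = None,
                  model_hook: Callable[[np.ndarray], np.ndarray] | None = None,
                  ) -> np.ndarray:
    """Binary lung mask for an image.

    backend="external": return the supplied mask file/array or call the
    user's segmentation-model hook verbatim.  backend="heuristic": Otsu
    threshold, keep the two largest bright connected components.
    """
    image = np.asarray(image, dtype=float)
    if backend == "external":
        if mask is not None:
            if isinstance(mask, (str, Path)):
                mask = load_image(mask) > 0.5
            return _validate_mask(mask, image)
        if model_hook is not None:
            return _validate_mask(model_hook(image), image)
        raise SegmentationError(
            "external backend needs a mask file/array or a model hook")
    if backend != "heuristic":
        raise ValueError(f"unknown backend {backend!r}")

    if np.ptp(image) == 0:
        raise SegmentationError("constant image: no lung structure to segment")
    bright = image > threshold_otsu(image)
    if not bright.any():
        raise SegmentationError("thresholding produced an empty mask")
    labels = measure.label(bright)
    regions = sorted(measure.regionprops(labels), key=lambda r: r.area,
                     reverse=True)[:2]
    out = np.isin(labels, [r.label for r in regions])
    return _validate_mask(out, image)


def _minmax(image: np.ndarray) -> np.ndarray:
    lo, hi = image.min(), image.max()
    if hi - lo <= 0:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def crop_to_mask(image: np.ndarray, mask: np.ndarray,
                 margin: float = 0.05) -> np.ndarray:
    """Crop to the tight bounding box of the mask, expanded on each side
    by ``margin`` of the box size (clipped to the frame), then rescale
    intensities to [0, 1]."""
    image = np.asarray(image, dtype=float)
    mask = _validate_mask(mask, image)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    dr = int(round(margin * (r1 - r0)))
    dc = int(round(margin * (c1 - c0)))
    r0, r1 = max(0, r0 - dr), min(image.shape[0], r1 + dr)
    c0, c1 = max(0, c0 - dc), min(image.shape[1], c1 + dc)
    return _minmax(image[r0:r1, c0:c1])


def resize_normalize(image: np.ndarray, target: int,
                     channels: int = 1) -> np.ndarray:
    """Bilinear resize to target x target (anti-aliased when
    downsampling) and min-max scale to [0, 1]; a constant image maps to
    zeros.  ``channels > 1`` replicates the grayscale plane to a
    (channels, target, target) stack."""
    if target < 32:
        raise ValueError("target size must be >= 32")
    image = np.asarray(image, dtype=float)
    out = resize(image, (target, target), order=1, mode="reflect",
                 anti_aliasing=min(image.shape) > target,
                 preserve_range=True)
    out = _minmax(out)
    if channels > 1:
        out = np.repeat(out[None, :, :], channels, axis=0)
    return out


@dataclass(frozen=True)
class AugmentParams:
    max_translation: float = 0.05   # fraction of width/height
    max_rotation: float = 10.0      # degrees
    zoom_range: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_translation < 1.0:
            raise ValueError("max_translation must lie in [0, 1)")
        lo, hi = self.zoom_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("zoom bounds must be positive with low <= high")


def apply_affine(image: np.ndarray, translation: tuple[float, float] = (0, 0),
                 angle_deg: float = 0.0, zoom: float = 1.0) -> np.ndarray:
    """Affine warp (rotation and zoom about the image center, then
    translation); out-of-frame regions are filled with 0."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    tx, ty = translation
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    to_origin = AffineTransform(translation=-center)
    motion = AffineTransform(rotation=np.deg2rad(angle_deg),
                             scale=(zoom, zoom))
    back = AffineTransform(translation=center + [tx, ty])
    tform = to_origin + motion + back
    return warp(image, tform.inverse, order=1, cval=0.0, preserve_range=True)


def augment(image: np.ndarray, params: AugmentParams,
            rng: np.random.Generator) -> np.ndarray:
    """One random affine draw (translation, rotation, zoom about the
    image center).  Deterministic under a replayed generator state."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    ty = rng.uniform(-params.max_translation, params.max_translation) * h
    tx = rng.uniform(-params.max_translation, params.max_translation) * w
    angle = rng.uniform(-params.max_rotation, params.max_rotation)
    zoom = rng.uniform(*params.zoom_range)
    return apply_affine(image, (tx, ty), angle, zoom)


def preprocess_image(image: np.ndarray, target: int,
                     mask: np.ndarray | None = None,
                     margin: float = 0.05, channels: int = 1) -> np.ndarray:
    """Segment (or accept) a lung mask, crop to it, resize and
    normalize: the standard evaluation-time pipeline."""
    if mask is None:
        mask = segment_lungs(image)
    else:
        mask = _validate_mask(mask, np.asarray(image, dtype=float))
    return resize_normalize(crop_to_mask(image, mask, margin), target,
                            channels=channels)
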