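"""Image preparation: standard-size resize, min-max normalization, rigid augmentation.

Images are downsized to a square standard resolution (704 x 704 for
study-scale work) with bilinear interpolation; masks use nearest-neighbor
so they stay binary.  Intensities are rescaled per image to [0, 1] by

    x_hat = (x - x_min) / (x_max - x_min)

with constant images mapping to all zeros.  Augmentation is the 6-element
rigid set {identity, rot90, rot180, rot270, horizontal flip, vertical
flip}, applied identically to image and mask — 405 study images become
2430 training pairs.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from .datatypes import ImageRecord, MaskImage

__all__ = [
    "AUGMENTATIONS",
    "resize_to_standard",
    "resize_mask",
    "normalize_minmax",
    "augment",
    "augment_arrays",
]

#: name -> array transform; the six rigid symmetries used for augmentation.
AUGMENTATIONS = {
    "identity": lambda a: a,
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
    "rot270": lambda a: np.rot90(a, 3),
    "fliplr": lambda a: np.fliplr(a),
    "flipud": lambda a: np.flipud(a),
}


def resize_to_standard(image: ImageRecord, target: int = 704) -> ImageRecord:
    """Bilinearly resize an intensity image to ``target`` x ``target``."""
    if target < 32:
        raise ValueError("target size must be at least 32")
    if image.pixels.shape == (target, target):
        return image
    out = _sk_resize(
        image.pixels.astype(np.float64),
        (target, target),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )
    return ImageRecord(
        np.clip(np.rint(out), 0, 255).astype(np.uint8),
        subject_id=image.subject_id,
        bc_group=image.bc_group,
        scan_mm=image.scan_mm,
    )


def resize_mask(mask: MaskImage, target: int = 704) -> MaskImage:
    """Nearest-neighbor resize of a binary mask; output stays binary."""
    if target < 32:
        raise ValueError("target size must be at least 32")
    if mask.pixels.shape == (target, target):
        return mask
    out = _sk_resize(
        mask.pixels, (target, target), order=0, preserve_range=True, anti_aliasing=False
    )
    return MaskImage(out.astype(np.uint8))


def normalize_minmax(image) -> np.ndarray:
    """Per-image min-max rescale to [0, 1]; constant images map to zeros."""
    x = np.asarray(image.pixels if isinstance(image, ImageRecord) else image, dtype=np.float64)
    lo = x.min()
    hi = x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def augment(image: ImageRecord, mask: MaskImage) -> list:
    """All six rigid transforms of an (image, mask) pair.

    Returns a list of 6 ``(ImageRecord, MaskImage)`` pairs in the fixed
    order identity, rot90, rot180, rot270, fliplr, flipud.  Inputs must be
    square (rotations would otherwise change the shape).
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask must have equal dimensions")
    h, w = image.shape
    if h != w:
        raise ValueError("augmentation requires square inputs")
    pairs = []
    for fn in AUGMENTATIONS.values():
        pairs.append(
            (
                ImageRecord(
                    np.ascontiguousarray(fn(image.pixels)),
                    subject_id=image.subject_id,
                    bc_group=image.bc_group,
                    scan_mm=image.scan_mm,
                ),
                MaskImage(np.ascontiguousarray(fn(mask.pixels))),
            )
        )
    return pairs


def augment_arrays(image: np.ndarray, mask: np.ndarray, name: str):
    """Apply one named rigid transform identically to two arrays."""
    fn = AUGMENTATIONS[name]
    return np.ascontiguousarray(fn(image)), np.ascontiguousarray(fn(mask))
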