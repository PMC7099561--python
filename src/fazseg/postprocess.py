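"""Probability-map refinement: binarize, keep the largest component, fill holes.

Network outputs occasionally contain small spurious spots and tiny interior
holes; the refinement stage guarantees the final sFAZ mask is a single
8-connected, hole-free region (or empty, if nothing crossed the threshold).
Foreground uses 8-connectivity and holes (background components) use
4-connectivity — the standard dual pairing.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import MaskImage

__all__ = ["binarize", "largest_connected_region", "fill_holes", "refine"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


def _as_mask(m) -> np.ndarray:
    return (m.pixels if isinstance(m, MaskImage) else np.asarray(m)).astype(bool)


def binarize(prob: np.ndarray, threshold: float) -> MaskImage:
    """Foreground where probability >= threshold (so threshold 0 keeps all)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    p = np.asarray(prob, dtype=np.float64)
    return MaskImage((p >= threshold).astype(np.uint8))


def largest_connected_region(mask) -> MaskImage:
    """Keep only the largest 8-connected foreground component.

    Size ties are broken deterministically in favor of the component whose
    first pixel in row-major order comes first.  An empty mask passes
    through unchanged.
    """
    m = _as_mask(mask)
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n == 0:
        return MaskImage(np.zeros(m.shape, dtype=np.uint8))
    counts = np.bincount(labels.ravel())[1:]
    best = counts.max()
    tied = np.flatnonzero(counts == best) + 1
    if len(tied) == 1:
        keep = tied[0]
    else:
        flat = labels.ravel()
        keep = min(tied, key=lambda lab: np.argmax(flat == lab))
    return MaskImage((labels == keep).astype(np.uint8))


def fill_holes(mask) -> MaskImage:
    """Fill background regions (4-connected) not reachable from the border."""
    m = _as_mask(mask)
    return MaskImage(ndimage.binary_fill_holes(m).astype(np.uint8))


def refine(prob: np.ndarray, threshold: float) -> MaskImage:
    """Binarize then clean: at most one foreground component, no holes."""
    return fill_holes(largest_connected_region(binarize(prob, threshold)))
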