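"""Core value types shared across the pipeline.

Conventions: arrays are row-major with origin at the top-left corner and
0-based indices.  Grayscale images are 8-bit (0-255).  Binary masks are
0/1 ``uint8`` in memory and 0/255 grayscale PNG on disk; mask foreground is
the superficial foveal avascular zone (sFAZ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImageRecord",
    "MaskImage",
    "BCSetting",
    "SubjectSpec",
    "SyntheticSample",
    "AreaResult",
    "ConfusionCounts",
]


@dataclass
class ImageRecord:
    """One grayscale en-face OCTA image plus acquisition metadata.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W)
    subject_id : str
    bc_group : int
        Brightness/contrast rendering group, 1-9 (1 = device default 130/20).
    scan_mm : float
        Physical width of the scanned field, 3 mm for the standard macular scan.
    """

    pixels: np.ndarray
    subject_id: str = ""
    bc_group: int = 1
    scan_mm: float = 3.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image pixels must be a non-empty 2-D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.scan_mm <= 0:
            raise ValueError("scan_mm must be positive")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class MaskImage:
    """Binary sFAZ mask; foreground (1) marks the avascular zone."""

    pixels: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.size == 0:
            raise ValueError("mask pixels must be a non-empty 2-D array")
        vals = np.unique(p)
        if np.isin(vals, (0, 1)).all():
            self.pixels = p.astype(np.uint8)
        elif np.isin(vals, (0, 255)).all():
            self.pixels = (p > 0).astype(np.uint8)
        else:
            raise ValueError("mask must be binary (0/1 in memory or 0/255 on disk)")

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())

    def to_disk_values(self) -> np.ndarray:
        return (self.pixels * 255).astype(np.uint8)


@dataclass(frozen=True)
class BCSetting:
    """One brightness/contrast rendering of the viewer, groups 1-9."""

    group_id: int
    brightness: int
    contrast: int


@dataclass
class SubjectSpec:
    """Generative description of one synthetic subject's macular scan."""

    subject_id: str
    myopia_class: str  # "high" (spherical equivalent <= -6 D) or "low"
    faz_center: tuple  # (row, col) fractional coordinates in [0, 1]
    faz_radius_mm: float
    boundary_harmonics: list  # [(order, amplitude, phase), ...]
    vessel_density: float
    rng_seed: int

    def __post_init__(self):
        if self.myopia_class not in ("high", "low"):
            raise ValueError("myopia_class must be 'high' or 'low'")
        if not 0.15 <= self.faz_radius_mm <= 0.5:
            raise ValueError("faz_radius_mm must lie in [0.15, 0.5] mm")
        if not 0.0 <= self.vessel_density <= 1.0:
            raise ValueError("vessel_density must lie in [0, 1]")
        amp = sum(abs(a) for _, a, _ in self.boundary_harmonics)
        if amp >= 0.5:
            raise ValueError("boundary harmonic amplitudes too large; region must stay star-convex")


@dataclass
class SyntheticSample:
    """One rendered image with its shared per-subject ground-truth mask."""

    image: ImageRecord
    gt: MaskImage
    subject_id: str
    bc: BCSetting
    myopia_class: str = "low"

    def __post_init__(self):
        if self.image.shape != self.gt.shape:
            raise ValueError("image and ground truth must have equal dimensions")


@dataclass(frozen=True)
class AreaResult:
    """Physical sFAZ area obtained from a pixel count and scan calibration."""

    n_pixels: int
    area_mm2: float
    scan_mm: float
    height: int
    width: int


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion table of a predicted mask against ground truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn
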