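"""Synthetic en-face OCTA cohort simulator.

Emulates the study conditions no public dataset exists for: 3 mm x 3 mm
macular scans of the superficial capillary plexus, each with a single dark
foveal avascular zone (FAZ) surrounded by a bright curvilinear vessel
plexus, exported under nine viewer brightness/contrast (B/C) settings.
Ground truth is drawn once per subject and shared by all nine renderings,
exactly as a manual grader would delineate the default export once.

The generative model:

* FAZ region — star-convex about its center, radius ``r(theta) = r0 * (1 +
  sum_k a_k cos(k theta + phi_k))`` with low-order harmonics perturbing a
  circle; hole-free and single-component by construction.
* Vessels — seeded biased random walks stamped as bright Gaussian-profile
  strokes, suppressed inside the (slightly eroded) FAZ, over a dim noisy
  background.
* B/C renderings — a monotone pointwise affine-then-clip intensity remap
  whose direction of effect matches the Cirrus viewer: higher brightness or
  contrast values darken the image, and lowering contrast below the default
  makes faint capillaries more visible.  The default setting 130/20 is the
  identity (the exported baseline).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import BCSetting, ImageRecord, MaskImage, SubjectSpec, SyntheticSample

__all__ = [
    "BC_SETTINGS",
    "DEFAULT_BC",
    "generate_faz_mask",
    "generate_vessel_image",
    "apply_bc_transform",
    "random_subject_spec",
    "generate_cohort",
]

#: The nine viewer settings, keyed by group id.  Group 1 is the device default.
BC_SETTINGS = {
    1: BCSetting(1, 130, 20),
    2: BCSetting(2, 90, 20),
    3: BCSetting(3, 110, 20),
    4: BCSetting(4, 150, 20),
    5: BCSetting(5, 170, 20),
    6: BCSetting(6, 130, 0),
    7: BCSetting(7, 130, 10),
    8: BCSetting(8, 130, 30),
    9: BCSetting(9, 130, 40),
}

DEFAULT_BC = BC_SETTINGS[1]

# Remap calibration: pivot shift per brightness step and gain decay per
# contrast step.  Chosen once so that the full 90-170 brightness range spans
# a clearly visible darkening without saturating group 5 to black, and the
# 0-40 contrast range brightens faint strokes at low contrast.
_PIVOT_PER_BRIGHTNESS = 0.9
_GAIN_DECAY_PER_CONTRAST = 0.02


def generate_faz_mask(spec: SubjectSpec, size: tuple, scan_mm: float = 3.0) -> MaskImage:
    """Rasterize the subject's FAZ region as a binary mask.

    The boundary is a radial-harmonic perturbation of a circle of radius
    ``faz_radius_mm`` (converted to pixels via ``scan_mm``), so the region is
    star-convex, single-component and hole-free by construction.

    Raises
    ------
    ValueError
        If the perturbed radius becomes non-positive (self-intersection) or
        the boundary exits the image.
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("mask size must be at least 64x64")
    r0 = spec.faz_radius_mm * w / scan_mm
    cy = spec.faz_center[0] * h
    cx = spec.faz_center[1] * w

    theta_grid = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    r_bound = _radius(spec, r0, theta_grid)
    if r_bound.min() <= 0:
        raise ValueError("harmonic perturbation self-intersects (non-positive radius)")
    by = cy + r_bound * np.sin(theta_grid)
    bx = cx + r_bound * np.cos(theta_grid)
    if by.min() < 0 or bx.min() < 0 or by.max() > h - 1 or bx.max() > w - 1:
        raise ValueError("FAZ boundary exits the image")

    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    rr = np.hypot(dy, dx)
    th = np.arctan2(dy, dx)
    mask = rr <= _radius(spec, r0, th)
    return MaskImage(mask.astype(np.uint8))


def _radius(spec: SubjectSpec, r0: float, theta: np.ndarray) -> np.ndarray:
    r = np.full_like(theta, r0, dtype=float)
    for order, amp, phase in spec.boundary_harmonics:
        r += r0 * amp * np.cos(order * theta + phase)
    return r


def generate_vessel_image(
    spec: SubjectSpec, faz: MaskImage, size: tuple, scan_mm: float = 3.0
) -> ImageRecord:
    """Render the baseline (group 1) grayscale angiogram for a subject.

    Bright branching strokes from seeded biased random walks cover the field
    outside the FAZ; the eroded FAZ interior contains only the dim noisy
    background, giving the dark central zone the segmentation target relies
    on.  Bit-identical for identical (spec, size).
    """
    h, w = size
    if faz.shape != (h, w):
        raise ValueError("FAZ mask does not match the requested image size")
    rng = np.random.default_rng(spec.rng_seed)

    strokes = np.zeros((h, w), dtype=np.float64)
    n_walks = int(round(spec.vessel_density * 180 * (h * w) / (128 * 128)))
    step = 1.0
    for _ in range(n_walks):
        y = rng.uniform(0, h - 1)
        x = rng.uniform(0, w - 1)
        direction = rng.uniform(0, 2 * np.pi)
        length = int(rng.uniform(0.25, 0.7) * w)
        brightness = rng.uniform(110.0, 200.0)
        for _ in range(length):
            direction += rng.normal(0.0, 0.18)
            y += step * np.sin(direction)
            x += step * np.cos(direction)
            if not (0 <= y < h and 0 <= x < w):
                break
            strokes[int(y), int(x)] = max(strokes[int(y), int(x)], brightness)

    # capillary-like profile: slight blur widens strokes to ~1-3 px
    strokes = ndimage.gaussian_filter(strokes, sigma=0.7) * 1.6
    interior = ndimage.binary_erosion(faz.pixels.astype(bool), iterations=1)
    strokes[interior] = 0.0

    background = 28.0 + rng.normal(0.0, 6.0, size=(h, w))
    img = np.clip(background + strokes, 0, 255).astype(np.uint8)
    return ImageRecord(img, subject_id=spec.subject_id, bc_group=1, scan_mm=scan_mm)


def apply_bc_transform(image: ImageRecord, bc: BCSetting) -> ImageRecord:
    """Re-render a baseline image under a different viewer B/C setting.

    A pointwise affine-then-clip map ``out = clip(gain(contrast) * (x -
    pivot(brightness)))`` with gain decreasing in contrast and pivot
    increasing in brightness.  The default setting (130, 20) is the identity;
    mean intensity is non-increasing in either parameter, and contrast below
    20 lifts faint strokes above visibility thresholds.
    """
    if bc.group_id not in BC_SETTINGS:
        raise ValueError(f"unknown B/C group id: {bc.group_id}")
    gain = np.exp(-_GAIN_DECAY_PER_CONTRAST * (bc.contrast - DEFAULT_BC.contrast))
    pivot = _PIVOT_PER_BRIGHTNESS * (bc.brightness - DEFAULT_BC.brightness)
    x = image.pixels.astype(np.float64)
    out = np.clip(gain * (x - pivot), 0, 255)
    return ImageRecord(
        np.rint(out).astype(np.uint8),
        subject_id=image.subject_id,
        bc_group=bc.group_id,
        scan_mm=image.scan_mm,
    )


def random_subject_spec(
    subject_id: str, myopia_class: str, rng: np.random.Generator
) -> SubjectSpec:
    """Draw one subject's generative parameters.

    FAZ radii span the range reported for healthy adults (area roughly
    0.1-0.6 mm^2); high myopes draw from the lower part of the range,
    reflecting the smaller FAZ observed with longer axial lengths.
    """
    if myopia_class == "high":
        radius = rng.uniform(0.16, 0.34)
    else:
        radius = rng.uniform(0.20, 0.44)
    center = (0.5 + rng.uniform(-0.03, 0.03), 0.5 + rng.uniform(-0.03, 0.03))
    harmonics = [
        (int(order), rng.uniform(0.0, 0.07), rng.uniform(0, 2 * np.pi))
        for order in rng.choice(np.arange(2, 6), size=3, replace=False)
    ]
    return SubjectSpec(
        subject_id=subject_id,
        myopia_class=myopia_class,
        faz_center=center,
        faz_radius_mm=float(radius),
        boundary_harmonics=harmonics,
        vessel_density=float(rng.uniform(0.5, 0.85)),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n_subjects: int,
    n_high_myopia: int,
    seed: int,
    size: tuple = (128, 128),
    scan_mm: float = 3.0,
) -> list:
    """Simulate a full cohort: ``n_subjects`` x 9 B/C renderings.

    Each subject gets one ground-truth mask shared pixel-for-pixel by the
    nine renderings.  The study-scale call is ``generate_cohort(45, 12,
    seed)`` yielding 405 images; smaller cohorts keep the same structure.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if not 0 <= n_high_myopia <= n_subjects:
        raise ValueError("n_high_myopia must lie in [0, n_subjects]")
    rng = np.random.default_rng(seed)
    classes = ["high"] * n_high_myopia + ["low"] * (n_subjects - n_high_myopia)
    rng.shuffle(classes)

    samples = []
    for i, cls in enumerate(classes):
        spec = random_subject_spec(f"S{i + 1:03d}", cls, rng)
        gt = generate_faz_mask(spec, size, scan_mm)
        baseline = generate_vessel_image(spec, gt, size, scan_mm)
        for gid in sorted(BC_SETTINGS):
            rendered = apply_bc_transform(baseline, BC_SETTINGS[gid])
            samples.append(
                SyntheticSample(
                    image=rendered,
                    gt=gt,
                    subject_id=spec.subject_id,
                    bc=BC_SETTINGS[gid],
                    myopia_class=cls,
                )
            )
    return samples
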