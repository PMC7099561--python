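"""Dataset manifests and image I/O.

Images and masks travel as 8-bit grayscale PNG (mask foreground 255);
probability maps as 16-bit PNG with probability = value / 65535, which
keeps quantization far below the resolution of the threshold sweep.  A
cohort manifest is a CSV with one row per rendered image:

    subject_id, myopia_class, group_id, brightness, contrast,
    image_path, mask_path

Paths are stored relative to the manifest's directory.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .datatypes import BCSetting, ImageRecord, MaskImage, SyntheticSample
from .synthetic import BC_SETTINGS

__all__ = [
    "MANIFEST_COLUMNS",
    "save_image",
    "load_image",
    "save_mask",
    "load_mask",
    "save_probability_map",
    "load_probability_map",
    "write_cohort",
    "load_manifest",
]

MANIFEST_COLUMNS = [
    "subject_id",
    "myopia_class",
    "group_id",
    "brightness",
    "contrast",
    "image_path",
    "mask_path",
]


def save_image(path, image: ImageRecord):
    iio.imwrite(path, image.pixels)


def load_image(path, subject_id="", bc_group=1, scan_mm=3.0) -> ImageRecord:
    px = np.asarray(iio.imread(path))
    if px.ndim == 3:  # collapse an accidental RGB export
        px = px[..., 0]
    return ImageRecord(px.astype(np.uint8), subject_id=subject_id,
                       bc_group=bc_group, scan_mm=scan_mm)


def save_mask(path, mask: MaskImage):
    iio.imwrite(path, mask.to_disk_values())


def load_mask(path) -> MaskImage:
    px = np.asarray(iio.imread(path))
    if px.ndim == 3:
        px = px[..., 0]
    vals = np.unique(px)
    if not np.isin(vals, (0, 255)).all():
        raise ValueError(f"mask file {path} is not binary 0/255 (found {vals[:6]})")
    return MaskImage(px)


def save_probability_map(path, prob: np.ndarray):
    p = np.asarray(prob, dtype=np.float64)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    iio.imwrite(path, np.rint(p * 65535).astype(np.uint16))


def load_probability_map(path) -> np.ndarray:
    raw = np.asarray(iio.imread(path))
    return raw.astype(np.float64) / 65535.0


def write_cohort(samples, out_dir, scan_mm: float = 3.0) -> str:
    """Write images, masks and the manifest CSV; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    img_dir = os.path.join(out_dir, "images")
    mask_dir = os.path.join(out_dir, "masks")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(mask_dir, exist_ok=True)
    rows = []
    written_masks = set()
    for s in samples:
        img_rel = os.path.join("images", f"{s.subject_id}_g{s.bc.group_id}.png")
        mask_rel = os.path.join("masks", f"{s.subject_id}.png")
        save_image(os.path.join(out_dir, img_rel), s.image)
        if s.subject_id not in written_masks:
            save_mask(os.path.join(out_dir, mask_rel), s.gt)
            written_masks.add(s.subject_id)
        rows.append(
            {
                "subject_id": s.subject_id,
                "myopia_class": s.myopia_class,
                "group_id": s.bc.group_id,
                "brightness": s.bc.brightness,
                "contrast": s.bc.contrast,
                "image_path": img_rel,
                "mask_path": mask_rel,
            }
        )
    manifest_path = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    return manifest_path


def load_manifest(path, scan_mm: float = 3.0) -> list:
    """Load a manifest back into validated SyntheticSample objects.

    Raises on a missing file, an unknown group id (naming the row), or a
    non-binary mask.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(path))
    samples = []
    mask_cache = {}
    for i, row in df.iterrows():
        gid = int(row["group_id"])
        if gid not in BC_SETTINGS:
            raise ValueError(f"manifest row {i}: unknown group_id {gid}")
        bc = BC_SETTINGS[gid]
        if (int(row["brightness"]), int(row["contrast"])) != (bc.brightness, bc.contrast):
            raise ValueError(f"manifest row {i}: B/C values disagree with group {gid}")
        mask_path = os.path.join(base, row["mask_path"])
        if mask_path not in mask_cache:
            mask_cache[mask_path] = load_mask(mask_path)
        image = load_image(
            os.path.join(base, row["image_path"]),
            subject_id=row["subject_id"],
            bc_group=gid,
            scan_mm=scan_mm,
        )
        samples.append(
            SyntheticSample(
                image=image,
                gt=mask_cache[mask_path],
                subject_id=row["subject_id"],
                bc=bc,
                myopia_class=row["myopia_class"],
            )
        )
    return samples
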