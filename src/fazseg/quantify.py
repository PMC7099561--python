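"""Physical sFAZ area from a refined binary mask.

Area = N * scan_mm^2 / (H * W), where N is the foreground pixel count and
scan_mm the physical side length of the (square-field) scan — 3 mm for the
standard macular protocol, so a full-field mask measures 9 mm^2.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AreaResult, MaskImage

__all__ = ["compute_area"]


def compute_area(mask, scan_mm: float) -> AreaResult:
    """Count foreground pixels and convert to mm^2 via the scan calibration."""
    if scan_mm <= 0:
        raise ValueError("scan_mm must be positive")
    m = mask.pixels if isinstance(mask, MaskImage) else np.asarray(mask)
    if m.size == 0:
        raise ValueError("empty image")
    h, w = m.shape
    n = int(np.count_nonzero(m))
    return AreaResult(
        n_pixels=n,
        area_mm2=n * scan_mm ** 2 / (h * w),
        scan_mm=scan_mm,
        height=h,
        width=w,
    )
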