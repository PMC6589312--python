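"""Per-pixel-threshold vessel-area occupancy of conjunctival photographs.

Redness of the eye comes from dilated blood vessels crossing the pale
sclera.  A per-pixel redness score classifies each pixel as vessel or
background; the measurement is the percentage of evaluated pixels above
the threshold.  The redness score used here is the normalised red-green
contrast

    r = (R - G) / (R + G + 1)   in [-1, 1)

which is robust to overall illumination (scaling R and G together leaves
it nearly unchanged) and monotone in how red a pixel is.  The default
threshold is 0.15.

The evaluated region defaults to the full frame; an ROI mask restricts it
(e.g. to a segmented conjunctiva).  The measurement refuses pathological
inputs — a tiny ROI (< 100 pixels) or a degenerate redness distribution
(every pixel identical) — by flagging them unmeasurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VesselAreaResult",
    "redness_score",
    "measure_vessel_area",
    "grade_vs_area_table",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.15
_MIN_ROI_PIXELS = 100


@dataclass
class VesselAreaResult:
    """Vessel-area percentage with its mask and measurability flag."""

    percent: float
    mask: np.ndarray = field(repr=False)
    measurable: bool
    n_roi_pixels: int


def redness_score(image: np.ndarray) -> np.ndarray:
    """Per-pixel normalised red-green contrast (R - G) / (R + G + 1)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB raster of shape (H, W, 3)")
    r = image[..., 0].astype(float)
    g = image[..., 1].astype(float)
    return (r - g) / (r + g + 1.0)


def measure_vessel_area(
    image: np.ndarray,
    roi: np.ndarray | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> VesselAreaResult:
    """Percentage of evaluated pixels whose redness exceeds the threshold.

    `roi`, when given, must match the image frame; the mask is zero
    outside it.  Raising the threshold can only shrink the reported
    percentage.
    """
    score = redness_score(image)
    if roi is None:
        roi_mask = np.ones(score.shape, dtype=bool)
    else:
        roi_mask = np.asarray(roi).astype(bool)
        if roi_mask.shape != score.shape:
            raise ValueError(
                f"roi shape {roi_mask.shape} does not match image frame {score.shape}"
            )
    n_roi = int(roi_mask.sum())
    mask = roi_mask & (score > threshold)
    in_roi = score[roi_mask]
    degenerate = n_roi == 0 or bool(np.all(in_roi == in_roi.flat[0])) if n_roi else True
    measurable = n_roi >= _MIN_ROI_PIXELS and not degenerate
    percent = 100.0 * mask.sum() / n_roi if n_roi else float("nan")
    return VesselAreaResult(
        percent=float(percent), mask=mask, measurable=measurable, n_roi_pixels=n_roi
    )


def grade_vs_area_table(
    grades: Mapping[str, int],
    areas: Mapping[str, VesselAreaResult],
) -> tuple[dict[int, list[float]], pd.DataFrame, int]:
    """Group vessel-area percentages by response grade.

    Only measurable areas are kept; the number dropped is returned.
    Returns (grade -> list of percents, per-grade summary with n and
    median, n_dropped).
    """
    common = set(grades) & set(areas)
    if not common:
        raise ValueError("no image ids shared between grades and area results")
    groups: dict[int, list[float]] = {}
    n_dropped = 0
    for img in sorted(common):
        res = areas[img]
        if not res.measurable:
            n_dropped += 1
            continue
        groups.setdefault(int(grades[img]), []).append(res.percent)
    summary = pd.DataFrame(
        [
            {"grade": g, "n": len(v), "median_percent": float(np.median(v))}
            for g, v in sorted(groups.items())
        ]
    )
    return groups, summary, n_dropped
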