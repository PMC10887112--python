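"""Brightfield spheroid morphometry and live/dead viability quantification.

Spheroid size is measured from brightfield images: contrast-limited adaptive
histogram equalization, Otsu thresholding of the inverted image, hole
filling, and the largest interior connected component give the spheroid
area, reported as the equivalent circular diameter
``d = 2 * sqrt(area / pi)``.

Viability is quantified from a calcein-AM (green, live) / ethidium
homodimer-1 (red, dead) channel pair: each channel is thresholded, connected
components above a minimum area are counted as cells, and viability is
``live / (live + dead)``.  Component counting is the default; a pixel-area
mode is available for densely stained spheroids where cells merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.exposure import equalize_adapthist
from skimage.filters import threshold_otsu
from skimage.measure import label as label_components
from skimage.morphology import remove_small_objects
from skimage.segmentation import clear_border
from scipy.ndimage import binary_fill_holes

__all__ = [
    "MorphometryResult",
    "ViabilityResult",
    "measure_spheroid",
    "quantify_viability",
    "growth_series",
]


@dataclass
class MorphometryResult:
    chamber_id: int
    equivalent_diameter: float  # um
    area: float  # um^2
    day: int = 0
    group: str = "untreated"
    empty: bool = False


@dataclass
class ViabilityResult:
    chamber_id: int
    live_count: int
    dead_count: int
    viability: float  # proportion in [0, 1]; NaN when undefined
    undefined: bool = False


def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)


def measure_spheroid(
    roi: np.ndarray,
    pixel_size: float,
    *,
    chamber_id: int = 0,
    day: int = 0,
    group: str = "untreated",
    min_area_px: int = 50,
    clip_limit: float = 0.01,
    min_contrast: float = 0.1,
) -> MorphometryResult:
    """Measure the spheroid in one chamber's brightfield ROI.

    The ROI should be a tight crop around one chamber; dark structures
    touching the ROI border (the chamber wall ring) are discarded so only the
    interior spheroid remains.  When no sufficiently dark or large component
    exists the result is flagged empty with zero size.
    """
    img = _normalize(roi)
    enhanced = equalize_adapthist(img, clip_limit=clip_limit)
    inverted = 1.0 - enhanced
    values = inverted.ravel()
    if values.max() == values.min():
        return MorphometryResult(chamber_id, 0.0, 0.0, day, group, empty=True)
    thr = threshold_otsu(inverted)
    fg = inverted > thr
    # guard against splitting a featureless chamber on noise
    if fg.any() and (~fg).any():
        contrast = float(inverted[fg].mean() - inverted[~fg].mean())
        if contrast < min_contrast:
            return MorphometryResult(chamber_id, 0.0, 0.0, day, group, empty=True)
    fg = clear_border(fg)
    fg = remove_small_objects(fg, max_size=min_area_px - 1)
    labels = label_components(fg)
    if labels.max() == 0:
        return MorphometryResult(chamber_id, 0.0, 0.0, day, group, empty=True)
    areas = np.bincount(labels.ravel())[1:]
    largest = np.argmax(areas) + 1
    component = binary_fill_holes(labels == largest)
    area_px = int(component.sum())
    area_um2 = area_px * pixel_size**2
    diameter = 2.0 * np.sqrt(area_um2 / np.pi)
    return MorphometryResult(
        chamber_id=chamber_id,
        equivalent_diameter=diameter,
        area=area_um2,
        day=day,
        group=group,
        empty=False,
    )


def _count_cells(channel: np.ndarray, min_area_px: int) -> int:
    img = _normalize(channel)
    if img.max() == img.min():
        return 0
    thr = threshold_otsu(img)
    fg = img > thr
    # threshold must actually separate signal from background
    if fg.mean() > 0.5:
        return 0
    fg = remove_small_objects(fg, max_size=min_area_px - 1)
    return int(label_components(fg).max())


def quantify_viability(
    green: np.ndarray,
    red: np.ndarray,
    *,
    chamber_id: int = 0,
    min_area_px: int = 4,
    mode: str = "components",
) -> ViabilityResult:
    """Viability from an aligned live (green) / dead (red) channel pair.

    ``mode="components"`` counts connected components per channel (cells);
    ``mode="area"`` uses above-threshold pixel areas instead, for stains too
    dense to resolve single cells.  Viability is live / (live + dead),
    flagged undefined when both are zero.
    """
    if green.shape != red.shape:
        raise ValueError("channels must have the same shape")
    if mode == "components":
        live = _count_cells(green, min_area_px)
        dead = _count_cells(red, min_area_px)
    elif mode == "area":
        def area(ch):
            img = _normalize(ch)
            if img.max() == img.min():
                return 0
            fg = img > threshold_otsu(img)
            return 0 if fg.mean() > 0.5 else int(fg.sum())

        live, dead = area(green), area(red)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total = live + dead
    if total == 0:
        return ViabilityResult(chamber_id, 0, 0, float("nan"), undefined=True)
    return ViabilityResult(chamber_id, live, dead, live / total)


def growth_series(results: list[MorphometryResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-day growth summary and between-group comparisons.

    Returns
    -------
    (summary, comparisons)
        ``summary``: mean, SD and n of the equivalent diameter per group per
        day.  ``comparisons``: one row per (day, group pair) with the
        difference of means and a two-sample Student's t-test where both
        groups have >= 2 measurements.
    """
    df = pd.DataFrame(
        [
            {
                "chamber_id": r.chamber_id,
                "group": r.group,
                "day": r.day,
                "diameter_um": r.equivalent_diameter,
            }
            for r in results
            if not r.empty
        ]
    )
    if df.empty:
        raise ValueError("no non-empty morphometry results")
    summary = (
        df.groupby(["group", "day"])["diameter_um"]
        .agg(mean_um="mean", sd_um="std", n="count")
        .reset_index()
    )
    rows = []
    for day, day_df in df.groupby("day"):
        groups = sorted(day_df["group"].unique())
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = day_df[day_df["group"] == groups[i]]["diameter_um"].to_numpy()
                b = day_df[day_df["group"] == groups[j]]["diameter_um"].to_numpy()
                diff = float(a.mean() - b.mean())
                if a.size >= 2 and b.size >= 2:
                    res = stats.ttest_ind(a, b)
                    t_stat, p = float(res.statistic), float(res.pvalue)
                else:
                    t_stat, p = float("nan"), float("nan")
                rows.append(
                    {
                        "day": day,
                        "group_a": groups[i],
                        "group_b": groups[j],
                        "mean_diff_um": diff,
                        "t_statistic": t_stat,
                        "p_value": p,
                    }
                )
    return summary, pd.DataFrame(rows)
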