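"""Spheroid- and gel-level readouts: area/count summaries, actin spread
beyond the spheroid edge, and radioligand uptake from gamma-counter tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.filters import threshold_otsu

from .segmentation import SpheroidRecord


@dataclass
class GelSummary:
    """Spheroid statistics for one gel at one timepoint."""

    gel_id: str
    condition: str
    timepoint: str
    n_spheroids: int
    median_area_um2: float          # NaN when the gel has no spheroids
    records: list = field(default_factory=list)


def gel_summary(spheroids: list, gel_id: str, condition: str,
                timepoint: str) -> GelSummary:
    """Median spheroid area and count for one gel.

    Paired differences across timepoints (area shrinkage, spheroid loss) are
    computed downstream with Welch's t test over gels.
    """
    ids = [s.spheroid_id for s in spheroids]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate spheroid ids in gel")
    if not spheroids:
        return GelSummary(gel_id, condition, timepoint, 0, float("nan"), [])
    median = float(np.median([s.area_um2 for s in spheroids]))
    return GelSummary(gel_id, condition, timepoint, len(spheroids),
                      median, list(spheroids))


def actin_spread(actin_image: np.ndarray, spheroid: SpheroidRecord,
                 window_radius_factor: float = 3.0,
                 threshold: float | None = None) -> float:
    """Actin area beyond the spheroid mask, normalized by spheroid area.

    Actin-positive pixels are found by Otsu thresholding within a circular
    window of ``window_radius_factor`` times the spheroid's equivalent
    radius; only positives outside the spheroid mask count.  The positivity
    threshold is relative, so the metric is invariant to positive rescaling
    of the actin channel.  Absolute values depend on this definition; fold
    comparisons between conditions are the meaningful readout.
    """
    actin_image = np.asarray(actin_image, dtype=float)
    if spheroid.touches_border:
        warnings.warn(
            f"spheroid {spheroid.spheroid_id} touches the field border; "
            "actin spread may be truncated", stacklevel=2)
    r_win = window_radius_factor * spheroid.equivalent_radius_px
    rr, cc = draw_disk(spheroid.centroid, r_win, shape=actin_image.shape)
    window = np.zeros(actin_image.shape, dtype=bool)
    window[rr, cc] = True

    sph_mask = np.zeros(actin_image.shape, dtype=bool)
    r0, c0, r1, c1 = spheroid.bbox
    sph_mask[r0:r1, c0:c1] = spheroid.mask

    vals = actin_image[window]
    if threshold is None:
        if np.ptp(vals) == 0:
            return 0.0
        threshold = threshold_otsu(vals)
    positive = (actin_image > threshold) & window & ~sph_mask
    return float(positive.sum() / spheroid.area_px)


def uptake_fraction(table: pd.DataFrame, condition: str) -> float:
    """Cellular uptake as percent of total recovered activity.

    Uptake = (dissolved cells + glycine wash) / all collected fractions,
    times 100.  ``table`` columns: condition, fraction_name, activity.
    """
    sub = table[table["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no rows for condition {condition!r}")
    if (sub["activity"] < 0).any():
        raise ValueError("activities must be nonnegative")
    total = float(sub["activity"].sum())
    if total <= 0:
        raise ValueError("total activity must be positive")
    cellular = float(sub[sub["fraction_name"].isin(
        ["dissolved_cells", "glycine_wash"])]["activity"].sum())
    return 100.0 * cellular / total


def specific_internalization(target_pct: float, blocked_pct: float) -> float:
    """Receptor-specific uptake: target minus blocked-control percent.

    Negative differences (blocking above target, within noise) floor at 0
    with a warning.
    """
    for name, v in (("target_pct", target_pct), ("blocked_pct", blocked_pct)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100], got {v}")
    diff = target_pct - blocked_pct
    if diff < 0:
        warnings.warn("blocked uptake exceeds target uptake; "
                      "specific internalization floored at 0", stacklevel=2)
        return 0.0
    return float(diff)


def gel_frame(summaries: list) -> pd.DataFrame:
    """Tidy table of gel summaries."""
    return pd.DataFrame([{
        "gel_id": g.gel_id, "condition": g.condition,
        "timepoint": g.timepoint, "n_spheroids": g.n_spheroids,
        "median_area_um2": g.median_area_um2,
    } for g in summaries])
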