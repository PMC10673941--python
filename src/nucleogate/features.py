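"""Morphometric and chromatin-organization features per nucleus.

The feature bank covers the three axes known to separate damage/death
subpopulations: nuclear size/shape (area, perimeter, eccentricity, solidity,
aspect ratio, boundary curvature), DNA intensity statistics (sum, mean, CV,
the P80/P20 condensation ratio, heterochromatin fraction and blob count) and
gray-level co-occurrence texture (contrast, homogeneity, entropy,
correlation at 1 and 2 px offsets, averaged over four directions).

Nuclei for which a feature is undefined (e.g. a degenerate per-nucleus Otsu
on uniform texture, or a zero 20th percentile) are flagged, never imputed.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import graycomatrix
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, regionprops

GLCM_LEVELS = 32
GLCM_DISTANCES = (1, 2)

SCALE_EQUIVARIANT = ("dna_sum", "dna_mean")  # all others intensity-scale free

FEATURE_COLUMNS = [
    "area_um2", "perimeter_um", "eccentricity", "solidity", "aspect_ratio",
    "curv_mean", "curv_sd", "curv_max",
    "dna_sum", "dna_mean", "dna_cv",
    "condensation_ratio", "heterochromatin_fraction", "n_high_intensity_blobs",
] + [f"glcm_{prop}_d{d}" for d in GLCM_DISTANCES
     for prop in ("contrast", "homogeneity", "entropy", "correlation")]


def condensation_ratio(dna_pixels_in_mask) -> float:
    """P80/P20 of background-subtracted DNA intensity within one nucleus.

    Higher values mean more condensed chromatin (bright heterochromatin
    against a dim euchromatin background).  Returns NaN (undefined) when the
    20th percentile is zero; requires at least 10 pixels.
    """
    vals = np.asarray(dna_pixels_in_mask, dtype=float).ravel()
    if vals.size < 10:
        raise ValueError("need at least 10 pixels for the condensation ratio")
    p20, p80 = np.percentile(vals, [20.0, 80.0])
    if p20 <= 0:
        return float("nan")
    return float(p80 / p20)


def _resample_closed(contour: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Resample a closed contour to uniform arc-length spacing."""
    closed = np.vstack([contour, contour[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(round(total / step)), 8)
    t = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack([np.interp(t, arc, closed[:, 0]),
                            np.interp(t, arc, closed[:, 1])])


def boundary_curvature(mask: np.ndarray, arc_step_px: float = 2.0,
                       touches_border: bool = False):
    """Signed curvature summaries (mean, sd, max) of the nucleus boundary.

    The boundary contour is resampled to 1 px arc steps, smoothed with a
    periodic Gaussian (sd = ``arc_step_px``), and differentiated by central
    differences.  The sign convention makes the mean of a convex shape
    positive.  Set ``touches_border`` when the mask was clipped by the field
    of view: the curvature is then computed on the truncated contour and a
    warning is raised.
    """
    mask = np.asarray(mask, dtype=bool)
    if ndi.label(mask)[1] != 1:
        raise ValueError("mask must be a single connected component")
    if touches_border:
        warnings.warn("mask touches the image border; curvature is partial",
                      stacklevel=2)
    padded = np.pad(mask, 2)
    contours = find_contours(padded.astype(float), 0.5)
    contour = max(contours, key=len)
    if len(contour) < 20:
        raise ValueError("need at least 20 boundary pixels")
    pts = _resample_closed(contour, step=1.0)
    sm = np.column_stack([
        ndi.gaussian_filter1d(pts[:, 0], arc_step_px, mode="wrap"),
        ndi.gaussian_filter1d(pts[:, 1], arc_step_px, mode="wrap"),
    ])
    d1 = (np.roll(sm, -1, axis=0) - np.roll(sm, 1, axis=0)) / 2.0
    d2 = np.roll(sm, -1, axis=0) - 2.0 * sm + np.roll(sm, 1, axis=0)
    speed2 = d1[:, 0]**2 + d1[:, 1]**2
    kappa = (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]) / \
        np.maximum(speed2, 1e-12)**1.5
    if kappa.mean() < 0:       # orientation-independent sign convention
        kappa = -kappa
    return float(kappa.mean()), float(kappa.std()), float(kappa.max())


def _glcm_props(quantized: np.ndarray) -> dict:
    """Texture descriptors from a masked, quantized patch.

    ``quantized`` holds levels 1..GLCM_LEVELS inside the mask and 0 outside;
    co-occurrences involving the outside level are discarded.
    """
    angles = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4)
    glcm = graycomatrix(quantized, distances=GLCM_DISTANCES, angles=angles,
                        levels=GLCM_LEVELS + 1, symmetric=True, normed=False)
    out = {}
    i_idx, j_idx = np.meshgrid(np.arange(GLCM_LEVELS),
                               np.arange(GLCM_LEVELS), indexing="ij")
    for di, d in enumerate(GLCM_DISTANCES):
        # drop background row/column, average the four directions
        mat = glcm[1:, 1:, di, :].sum(axis=-1).astype(float)
        total = mat.sum()
        if total == 0:
            for prop in ("contrast", "homogeneity", "entropy", "correlation"):
                out[f"glcm_{prop}_d{d}"] = float("nan")
            continue
        p = mat / total
        diff = i_idx - j_idx
        out[f"glcm_contrast_d{d}"] = float((p * diff**2).sum())
        out[f"glcm_homogeneity_d{d}"] = float((p / (1.0 + diff**2)).sum())
        nz = p[p > 0]
        out[f"glcm_entropy_d{d}"] = float(-(nz * np.log2(nz)).sum())
        mu_i = (p * i_idx).sum()
        mu_j = (p * j_idx).sum()
        sd_i = math.sqrt((p * (i_idx - mu_i)**2).sum())
        sd_j = math.sqrt((p * (j_idx - mu_j)**2).sum())
        if sd_i > 0 and sd_j > 0:
            corr = ((p * (i_idx - mu_i) * (j_idx - mu_j)).sum()
                    / (sd_i * sd_j))
            out[f"glcm_correlation_d{d}"] = float(corr)
        else:
            out[f"glcm_correlation_d{d}"] = float("nan")
    return out


def nucleus_features(mask: np.ndarray, dna_patch: np.ndarray,
                     pixel_size_um: float = 1.0,
                     arc_step_px: float = 2.0,
                     touches_border: bool = False) -> dict:
    """Feature dictionary for one nucleus (bbox-local mask and DNA patch)."""
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(dna_patch, dtype=float)[mask]
    out: dict = {}

    props = regionprops(mask.astype(np.uint8))[0]
    out["area_um2"] = float(props.area * pixel_size_um**2)
    out["perimeter_um"] = float(props.perimeter * pixel_size_um)
    out["eccentricity"] = float(props.eccentricity)
    out["solidity"] = float(props.solidity)
    minor = props.axis_minor_length
    out["aspect_ratio"] = float(props.axis_major_length / minor) \
        if minor > 0 else float("nan")

    try:
        cm, cs, cx = boundary_curvature(mask, arc_step_px=arc_step_px,
                                        touches_border=touches_border)
    except ValueError:
        cm = cs = cx = float("nan")
    out["curv_mean"], out["curv_sd"], out["curv_max"] = cm, cs, cx

    out["dna_sum"] = float(vals.sum())
    mean = float(vals.mean())
    out["dna_mean"] = mean
    out["dna_cv"] = float(vals.std() / mean) if mean > 0 else float("nan")
    try:
        out["condensation_ratio"] = condensation_ratio(vals)
    except ValueError:
        out["condensation_ratio"] = float("nan")

    vmin, vmax = vals.min(), vals.max()
    if vmax > vmin:
        thr = threshold_otsu(vals)
        hetero = vals > thr
        out["heterochromatin_fraction"] = float(hetero.mean())
        hi = np.zeros_like(mask)
        hi[mask] = hetero
        lab, n = ndi.label(hi)
        sizes = np.bincount(lab.ravel())[1:]
        out["n_high_intensity_blobs"] = int((sizes >= 3).sum())
        q = np.zeros(mask.shape, dtype=np.uint8)
        scaled = (vals - vmin) / (vmax - vmin) * (GLCM_LEVELS - 1e-9)
        q[mask] = 1 + np.floor(scaled).astype(np.uint8)
        out.update(_glcm_props(q))
    else:
        out["heterochromatin_fraction"] = float("nan")
        out["n_high_intensity_blobs"] = 0
        for d in GLCM_DISTANCES:
            for prop in ("contrast", "homogeneity", "entropy", "correlation"):
                out[f"glcm_{prop}_d{d}"] = float("nan")
    return out


def extract_features(nuclei: list, dna_image: np.ndarray,
                     pixel_size_um: float = 1.0,
                     arc_step_px: float = 2.0) -> pd.DataFrame:
    """Feature table for a list of :class:`~.segmentation.NucleusRecord`.

    ``dna_image`` should already be background-subtracted.  Rows with any
    undefined feature carry ``undefined=True``; they are flagged here and
    excluded later by the classifier, never silently dropped.
    """
    dna_image = np.asarray(dna_image, dtype=float)
    rows = []
    for rec in nuclei:
        r0, c0, r1, c1 = rec.bbox
        patch = dna_image[r0:r1, c0:c1]
        touches = (r0 == 0 or c0 == 0 or r1 == dna_image.shape[0]
                   or c1 == dna_image.shape[1])
        feats = nucleus_features(rec.mask, patch,
                                 pixel_size_um=pixel_size_um,
                                 arc_step_px=arc_step_px,
                                 touches_border=touches)
        feats["nucleus_id"] = rec.nucleus_id
        rows.append(feats)
    table = pd.DataFrame(rows, columns=["nucleus_id"] + FEATURE_COLUMNS)
    table["undefined"] = table[FEATURE_COLUMNS].isna().any(axis=1)
    return table
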