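"""Synthetic multi-channel spheroid scenes with planted, per-nucleus ground truth.

The generator emulates maximum-intensity projections of 3D spheroid
co-cultures: compact clusters of cancer nuclei (spheroids) plus scattered
stromal fibroblasts, imaged in six channels (DNA, γH2AX, DRAQ7, Ki67,
CellTracker, actin).  Per-nucleus marker levels follow a log-normal model
with per-subpopulation location; chromatin texture is rendered as
high-intensity heterochromatin blobs on a softer euchromatin background;
imaging noise is Poisson shot noise plus Gaussian read noise over a flat
background.  Every nucleus is recorded in a ground-truth table, which makes
each downstream stage of the pipeline testable without real data.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.stats import norm
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

CHANNELS = ("dna", "gamma_h2ax", "draq7", "ki67", "celltracker", "actin")

#: marker channels whose per-nucleus level is drawn from the log-normal model
MARKER_CHANNELS = ("gamma_h2ax", "draq7", "ki67")

#: the per-nucleus summary each marker uses downstream (mirrors the readout:
#: integrated intensity for the damage marker, mean intensity for the rest)
MARKER_SUMMARY = {"gamma_h2ax": "sum", "draq7": "mean", "ki67": "mean"}


class Subpopulation(str, enum.Enum):
    """Four damage/death classes from two-marker quadrant gating."""

    LOW_LOW = "LowDamage_LowDeath"
    HIGH_LOW = "HighDamage_LowDeath"
    LOW_HIGH = "LowDamage_HighDeath"
    HIGH_HIGH = "HighDamage_HighDeath"


SUBPOP_ORDER = (
    Subpopulation.LOW_LOW,
    Subpopulation.HIGH_LOW,
    Subpopulation.LOW_HIGH,
    Subpopulation.HIGH_HIGH,
)


class CellType(str, enum.Enum):
    A431 = "A431"
    A431_CCKBR = "A431/CCKBR"
    FIBROBLAST = "fibroblast"


class PlacementError(RuntimeError):
    """Raised when dart-throwing cannot place all nuclei without overlap."""


@dataclass(frozen=True)
class MarkerModel:
    """Log-normal model of one marker's per-nucleus level.

    ``mean`` is the distribution mean of the per-nucleus level (integrated
    intensity for γH2AX, mean intensity for DRAQ7/Ki67), one value per
    subpopulation in :data:`SUBPOP_ORDER`.  ``sigma`` is the log-scale sd.
    """

    mean: tuple[float, float, float, float]
    sigma: float = 0.5

    def mu(self, subpop_index: int) -> float:
        # location so that E[X] equals the configured mean exactly
        return math.log(self.mean[subpop_index]) - 0.5 * self.sigma**2

    def scaled(self, factor: float) -> "MarkerModel":
        return MarkerModel(tuple(m * factor for m in self.mean), self.sigma)


@dataclass(frozen=True)
class NoiseModel:
    """Poisson gain + Gaussian read noise over a flat background (counts)."""

    gain: float = 1.0            # photons per count; 0 disables shot noise
    read_sd: float = 2.0         # Gaussian read noise sd; 0 disables
    background: dict | None = None  # per-channel background level

    def background_for(self, channel: str) -> float:
        default = {"dna": 12.0, "gamma_h2ax": 8.0, "draq7": 8.0,
                   "ki67": 8.0, "celltracker": 10.0, "actin": 10.0}
        if self.background is None:
            return default[channel]
        return self.background.get(channel, default[channel])


def _default_markers() -> dict:
    return {
        "gamma_h2ax": MarkerModel(mean=(6000.0, 15000.0, 7000.0, 16000.0)),
        "draq7": MarkerModel(mean=(25.0, 28.0, 60.0, 65.0)),
        "ki67": MarkerModel(mean=(30.0, 30.0, 30.0, 30.0), sigma=0.4),
    }


def _default_condensation() -> dict:
    # (heterochromatin blob area fraction, blob/euchromatin contrast)
    # damage and death both decondense chromatin, death more strongly
    return {
        Subpopulation.LOW_LOW: (0.30, 2.6),
        Subpopulation.HIGH_LOW: (0.30, 2.1),
        Subpopulation.LOW_HIGH: (0.26, 1.7),
        Subpopulation.HIGH_HIGH: (0.26, 1.4),
    }


@dataclass(frozen=True)
class SceneConfig:
    """Full parameterization of one synthetic scene."""

    n_spheroids: int = 10
    nuclei_per_spheroid: int = 40
    n_fibroblasts: int = 20
    field_shape: tuple[int, int] | None = None  # rows, cols; None = auto
    pixel_size_um: float = 0.65
    nucleus_radius_um: tuple[float, float] = (4.5, 0.5)  # mean, sd
    condition: str = "untreated"
    cell_line: str = "A431/CCKBR"
    a431_fraction: float = 0.0   # fraction of cancer nuclei that are A431
    subpop_mix: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    #: draw classes as an exactly balanced permutation of subpop_mix counts
    balance_subpops: bool = False
    marker_params: dict = field(default_factory=_default_markers)
    fold_params: dict = field(default_factory=dict)
    condensation_params: dict = field(default_factory=_default_condensation)
    #: per-subpopulation nuclear area multipliers (damage/death inflate area)
    area_scale: tuple[float, float, float, float] = (1.0, 1.25, 1.5, 1.8)
    dna_level: float = 100.0     # target mean DNA intensity inside a nucleus
    blob_radius_px: float = 1.6
    actin_spread_factor: float = 0.08
    actin_level: float = 60.0
    celltracker_level: float = 80.0
    fibroblast_marker_factor: float = 0.6
    psf_sigma_px: float = 0.8
    noise: NoiseModel = field(default_factory=NoiseModel)
    packing_fraction: float = 0.40
    max_failed_darts: int = 10_000
    seed: int = 0

    # ---- derived quantities -------------------------------------------------

    @property
    def mean_radius_px(self) -> float:
        return self.nucleus_radius_um[0] / self.pixel_size_um

    @property
    def max_radius_scale(self) -> float:
        """Largest radius multiplier among classes present in the mix."""
        scales = [s for s, w in zip(self.area_scale, self.subpop_mix) if w > 0]
        return math.sqrt(max(scales)) if scales else 1.0

    @property
    def min_center_distance_px(self) -> float:
        # 2.2x the mean radius of the largest planted class, so that
        # area-inflated damage/death nuclei still separate
        return 2.2 * self.mean_radius_px * self.max_radius_scale

    @property
    def spheroid_radius_px(self) -> float:
        """Placement-disk radius so dart-throwing converges reliably."""
        d = self.min_center_distance_px
        return 0.5 * d * math.sqrt(max(self.nuclei_per_spheroid, 1)
                                   / self.packing_fraction)

    def validate(self) -> None:
        mix = np.asarray(self.subpop_mix, dtype=float)
        if mix.shape != (4,) or np.any(mix < 0):
            raise ValueError("subpop_mix must be four nonnegative weights")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("subpop_mix must sum to 1 within 1e-9")
        if self.nucleus_radius_um[0] <= 0 or self.pixel_size_um <= 0:
            raise ValueError("radius and pixel size must be positive")
        if not (0.0 <= self.a431_fraction <= 1.0):
            raise ValueError("a431_fraction must lie in [0, 1]")
        for name, mm in self.marker_params.items():
            if not all(np.isfinite(mm.mean)) or min(mm.mean) <= 0:
                raise ValueError(f"marker {name}: means must be finite > 0")
            if not (mm.sigma > 0 and np.isfinite(mm.sigma)):
                raise ValueError(f"marker {name}: sigma must be finite > 0")
        if self.noise.gain < 0 or self.noise.read_sd < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.actin_spread_factor < 0:
            raise ValueError("actin_spread_factor must be >= 0")

    def with_folds(self, folds: dict, condition: str | None = None) -> "SceneConfig":
        """Return a copy with marker means scaled by planted fold changes.

        ``folds`` maps channel name to the treated/untreated fold change.
        Run the copy with the same seed as the baseline and the truth-table
        marker values scale by exactly the planted factor per nucleus.
        """
        markers = dict(self.marker_params)
        for channel, f in folds.items():
            markers[channel] = markers[channel].scaled(f)
        return replace(
            self,
            marker_params=markers,
            fold_params={**self.fold_params, **folds},
            condition=condition or self.condition,
        )


@dataclass
class Scene:
    """A multi-channel image field plus acquisition metadata."""

    channels: dict  # name -> float32 image, all same shape
    pixel_size_um: float
    condition: str
    config: SceneConfig | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class GroundTruth:
    """Planted truth: one row per nucleus, plus spheroid geometry."""

    nuclei: pd.DataFrame
    spheroids: pd.DataFrame

    def validate(self) -> None:
        ids = self.nuclei["nucleus_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate nucleus ids in ground truth")
        referenced = set(self.nuclei["spheroid_id"].dropna().astype(int))
        declared = set(self.spheroids["spheroid_id"].astype(int))
        if not referenced <= declared:
            raise ValueError("nucleus references an undeclared spheroid")


# ---------------------------------------------------------------------------
# placement


def _dart_throw_disk(rng, n, disk_radius, min_dist, max_failures):
    """Random sequential placement of n points in a disk, min pair distance."""
    pts = np.empty((0, 2))
    failures = 0
    while len(pts) < n:
        r = disk_radius * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        p = np.array([r * math.cos(theta), r * math.sin(theta)])
        if len(pts) and np.min(np.hypot(*(pts - p).T)) < min_dist:
            failures += 1
            if failures > max_failures:
                raise PlacementError(
                    f"dart-throwing failed after {max_failures} rejected darts "
                    f"(placed {len(pts)}/{n})")
            continue
        pts = np.vstack([pts, p])
    return pts


def _spheroid_grid(config: SceneConfig):
    """Spheroid center layout and the (possibly auto-sized) field shape."""
    n = config.n_spheroids
    r_out = config.spheroid_radius_px + config.mean_radius_px
    spacing = 2.0 * r_out * (1.0 + max(config.actin_spread_factor, 0.15)) \
        + 6.0 * config.mean_radius_px
    if n == 0:
        shape = config.field_shape or (256, 256)
        return np.empty((0, 2)), shape
    ncols = math.ceil(math.sqrt(n))
    nrows = math.ceil(n / ncols)
    if config.field_shape is None:
        shape = (int(round(nrows * spacing)), int(round(ncols * spacing)))
        row_sp, col_sp = spacing, spacing
    else:
        shape = config.field_shape
        row_sp = shape[0] / nrows
        col_sp = shape[1] / ncols
    centers = []
    for k in range(n):
        i, j = divmod(k, ncols)
        centers.append(((i + 0.5) * row_sp, (j + 0.5) * col_sp))
    return np.asarray(centers, dtype=float), shape


# ---------------------------------------------------------------------------
# per-nucleus rendering


def render_nucleus_texture(radius_px, blob_fraction, contrast, dna_level, rng,
                           axis_ratio=1.0, angle=0.0, blob_radius_px=1.6):
    """Render one noiseless nucleus: chromatin blobs on a soft background.

    The euchromatin base level is chosen so the mask mean equals
    ``dna_level`` regardless of blob coverage.  Returns (mask, patch).
    """
    r_major = radius_px * math.sqrt(axis_ratio)
    r_minor = radius_px / math.sqrt(axis_ratio)
    half = int(math.ceil(r_major)) + 2
    size = 2 * half + 1
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw_ellipse(half, half, r_minor, r_major,
                          shape=mask.shape, rotation=angle)
    mask[rr, cc] = True
    base = dna_level / (1.0 + blob_fraction * (contrast - 1.0))
    patch = np.where(mask, base, 0.0)
    area = int(mask.sum())
    n_blobs = int(round(blob_fraction * area / (math.pi * blob_radius_px**2)))
    if n_blobs > 0 and area > 0:
        idx = np.flatnonzero(mask.ravel())
        chosen = rng.choice(idx, size=n_blobs, replace=True)
        for flat in chosen:
            br, bc = np.unravel_index(flat, mask.shape)
            dr, dc = draw_disk((br, bc), blob_radius_px, shape=mask.shape)
            keep = mask[dr, dc]
            patch[dr[keep], dc[keep]] = base * contrast
    # renormalize so the mask mean is dna_level exactly (blob overlap would
    # otherwise lower effective coverage)
    m = patch[mask].mean()
    if m > 0:
        patch[mask] *= dna_level / m
    return mask, patch


def _add_patch(canvas, center, patch_mask, values):
    """Add a local patch (masked) into the canvas at integer center."""
    half = patch_mask.shape[0] // 2
    r0 = int(round(center[0])) - half
    c0 = int(round(center[1])) - half
    pr0 = max(0, -r0)
    pc0 = max(0, -c0)
    pr1 = patch_mask.shape[0] - max(0, r0 + patch_mask.shape[0] - canvas.shape[0])
    pc1 = patch_mask.shape[1] - max(0, c0 + patch_mask.shape[1] - canvas.shape[1])
    if pr1 <= pr0 or pc1 <= pc0:
        return 0
    sub_mask = patch_mask[pr0:pr1, pc0:pc1]
    target = canvas[r0 + pr0:r0 + pr1, c0 + pc0:c0 + pc1]
    target[sub_mask] += values[pr0:pr1, pc0:pc1][sub_mask]
    return int(sub_mask.sum())


# ---------------------------------------------------------------------------
# the generator


def generate_scene(config: SceneConfig):
    """Generate a seeded scene and its exact ground truth.

    Returns ``(scene, truth)``.  The same config (including seed) always
    produces byte-identical pixel arrays and truth tables.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    # fixed spawn order: placement, classes, geometry, markers, texture, noise
    keys = root.spawn(6)
    rng_place = np.random.default_rng(keys[0])
    rng_class = np.random.default_rng(keys[1])
    rng_geom = np.random.default_rng(keys[2])
    rng_marker = np.random.default_rng(keys[3])
    rng_texture = np.random.default_rng(keys[4])
    rng_noise = np.random.default_rng(keys[5])

    centers_sph, shape = _spheroid_grid(config)
    r_px = config.mean_radius_px
    d_min = config.min_center_distance_px
    R_place = config.spheroid_radius_px

    # --- nucleus placement
    rows_nuc = []
    for sid, c in enumerate(centers_sph):
        jitter = rng_place.uniform(-0.5, 0.5, size=2) * r_px
        local = _dart_throw_disk(rng_place, config.nuclei_per_spheroid,
                                 R_place, d_min, config.max_failed_darts)
        for p in local:
            rows_nuc.append((c[0] + jitter[0] + p[0],
                             c[1] + jitter[1] + p[1], sid))
    # fibroblasts scattered outside the spheroid (and actin) footprints
    keepout = R_place + r_px * 2.0
    keepout *= (1.0 + config.actin_spread_factor)
    placed = np.array([(r, c) for r, c, _ in rows_nuc]) if rows_nuc else \
        np.empty((0, 2))
    fib_pts = []
    failures = 0
    margin = 2.0 * r_px
    while len(fib_pts) < config.n_fibroblasts:
        p = rng_place.uniform([margin, margin],
                              [shape[0] - margin, shape[1] - margin])
        ok = True
        if len(centers_sph) and np.min(
                np.hypot(*(centers_sph - p).T)) < keepout:
            ok = False
        if ok and len(placed) and np.min(np.hypot(*(placed - p).T)) < d_min:
            ok = False
        if ok and fib_pts and np.min(
                np.hypot(*(np.asarray(fib_pts) - p).T)) < d_min:
            ok = False
        if not ok:
            failures += 1
            if failures > config.max_failed_darts:
                raise PlacementError("could not place fibroblasts")
            continue
        fib_pts.append(p)

    n_cancer = len(rows_nuc)
    n_total = n_cancer + len(fib_pts)

    # --- per-nucleus attributes
    mix = np.asarray(config.subpop_mix, dtype=float)
    mix = mix / mix.sum()
    if config.balance_subpops:
        counts = np.floor(mix * n_cancer).astype(int)
        while counts.sum() < n_cancer:
            counts[int(np.argmax(mix * n_cancer - counts))] += 1
        subpop_idx = rng_class.permutation(np.repeat(np.arange(4), counts))
    else:
        subpop_idx = rng_class.choice(4, size=n_cancer, p=mix)
    is_a431 = rng_class.uniform(size=n_cancer) < config.a431_fraction

    mean_um, sd_um = config.nucleus_radius_um
    radii_um = np.clip(rng_geom.normal(mean_um, sd_um, size=n_total),
                       0.3 * mean_um, None)
    axis_ratio = rng_geom.uniform(1.0, 1.3, size=n_total)
    angles = rng_geom.uniform(0.0, math.pi, size=n_total)
    area_mult = np.ones(n_total)
    area_mult[:n_cancer] = np.asarray(config.area_scale)[subpop_idx]
    radii_px = radii_um / config.pixel_size_um * np.sqrt(area_mult)

    # marker draws: one standard-normal per nucleus per marker, scaled by the
    # subpopulation's log-normal model; fibroblasts use the low-damage model
    # attenuated by fibroblast_marker_factor
    marker_true = {}
    for channel in MARKER_CHANNELS:
        mm = config.marker_params[channel]
        z = rng_marker.standard_normal(n_total)
        mu = np.array([mm.mu(0) + math.log(config.fibroblast_marker_factor)
                       if i >= n_cancer else mm.mu(int(subpop_idx[i]))
                       for i in range(n_total)])
        marker_true[channel] = np.exp(mu + mm.sigma * z)

    # --- rasterize
    images = {name: np.zeros(shape, dtype=np.float64) for name in CHANNELS}
    records = []
    all_pts = list(rows_nuc) + [(p[0], p[1], None) for p in fib_pts]
    for i, (row, col, sid) in enumerate(all_pts):
        cancer = sid is not None
        sp = SUBPOP_ORDER[int(subpop_idx[i])] if cancer else Subpopulation.LOW_LOW
        f_blob, contrast = config.condensation_params[sp]
        mask, dna_patch = render_nucleus_texture(
            radii_px[i], f_blob, contrast, config.dna_level, rng_texture,
            axis_ratio=axis_ratio[i], angle=angles[i],
            blob_radius_px=config.blob_radius_px)
        area = _add_patch(images["dna"], (row, col), mask, dna_patch)
        if area == 0:
            continue
        flat = np.where(mask, 1.0, 0.0)
        gamma_sum = marker_true["gamma_h2ax"][i]
        _add_patch(images["gamma_h2ax"], (row, col), mask,
                   flat * (gamma_sum / max(int(mask.sum()), 1)))
        _add_patch(images["draq7"], (row, col), mask,
                   flat * marker_true["draq7"][i])
        _add_patch(images["ki67"], (row, col), mask,
                   flat * marker_true["ki67"][i])
        ctype = CellType.FIBROBLAST if not cancer else (
            CellType.A431 if is_a431[i] else CellType.A431_CCKBR)
        if ctype is CellType.A431:
            half = int(math.ceil(radii_px[i] * 1.7)) + 2
            size = 2 * half + 1
            cyto = np.zeros((size, size), dtype=bool)
            rr, cc = draw_disk((half, half), radii_px[i] * 1.6,
                               shape=cyto.shape)
            cyto[rr, cc] = True
            _add_patch(images["celltracker"], (row, col), cyto,
                       np.full(cyto.shape, config.celltracker_level))
        records.append({
            "nucleus_id": i,
            "row": row, "col": col,
            "spheroid_id": sid,
            "cell_type": ctype.value,
            "subpop": sp.value if cancer else "",
            "radius_px": radii_px[i],
            "axis_ratio": axis_ratio[i],
            "angle": angles[i],
            "area_px": area,
            "dna_level": config.dna_level,
            "blob_fraction": f_blob,
            "blob_contrast": contrast,
            "gamma_sum": marker_true["gamma_h2ax"][i],
            "draq7_mean": marker_true["draq7"][i],
            "ki67_mean": marker_true["ki67"][i],
        })

    # actin: a ring beyond the DNA-defined spheroid edge
    s = config.actin_spread_factor
    sph_rows = []
    for sid, c in enumerate(centers_sph):
        R_edge = R_place + r_px
        if s > 0:
            rr_o, cc_o = draw_disk(tuple(c), R_edge * (1.0 + s), shape=shape)
            ring = np.zeros(shape, dtype=bool)
            ring[rr_o, cc_o] = True
            rr_i, cc_i = draw_disk(tuple(c), R_edge, shape=shape)
            ring[rr_i, cc_i] = False
            images["actin"][ring] += config.actin_level
        sph_rows.append({"spheroid_id": sid, "row": c[0], "col": c[1],
                         "radius_px": R_edge,
                         "actin_spread_factor": s})

    # --- optics and noise
    noise = config.noise
    for k, name in enumerate(CHANNELS):
        img = images[name]
        if config.psf_sigma_px > 0:
            img = ndi.gaussian_filter(img, config.psf_sigma_px)
        img = img + noise.background_for(name)
        if noise.gain > 0:
            img = rng_noise.poisson(np.clip(img, 0, None) * noise.gain)
            img = img / noise.gain
        if noise.read_sd > 0:
            img = img + rng_noise.normal(0.0, noise.read_sd, size=shape)
        images[name] = np.clip(img, 0.0, None).astype(np.float32)

    nuclei_df = pd.DataFrame(
        records, columns=["nucleus_id", "row", "col", "spheroid_id",
                          "cell_type", "subpop", "radius_px", "axis_ratio",
                          "angle", "area_px", "dna_level", "blob_fraction",
                          "blob_contrast", "gamma_sum", "draq7_mean",
                          "ki67_mean"])
    nuclei_df["spheroid_id"] = nuclei_df["spheroid_id"].astype("Int64")
    spheroids_df = pd.DataFrame(
        sph_rows, columns=["spheroid_id", "row", "col", "radius_px",
                           "actin_spread_factor"])
    truth = GroundTruth(nuclei=nuclei_df, spheroids=spheroids_df)
    truth.validate()
    scene = Scene(channels=images, pixel_size_um=config.pixel_size_um,
                  condition=config.condition, config=config)
    return scene, truth


# ---------------------------------------------------------------------------
# calibration helpers


def calibrate_treated_mix(target_lowlow: float):
    """Per-marker exceedance probabilities reproducing a low/low fraction.

    With the two markers independent and equal exceedance p against the
    untreated thresholds, the low/low fraction is (1-p)^2; inverting gives
    p = 1 - sqrt(target).  Returns ``(p_gamma, p_draq7)``.
    """
    if not 0.0 < target_lowlow < 1.0:
        raise ValueError("target low/low fraction must lie strictly in (0, 1)")
    p = 1.0 - math.sqrt(target_lowlow)
    return p, p


def exceedance_shift(p: float, sigma: float) -> float:
    """Log-location shift so a log-normal exceeds the untreated true 90th
    percentile with probability ``p`` (instead of the untreated 0.10)."""
    if not 0.0 < p < 1.0:
        raise ValueError("exceedance probability must lie in (0, 1)")
    return sigma * (norm.ppf(0.9) - norm.ppf(1.0 - p))


def make_uptake_fixture(seed: int) -> pd.DataFrame:
    """Seeded gamma-counter activity table for the uptake computation.

    Three compartments per condition: culture medium + PBS wash, acid
    (glycine) wash of surface-bound ligand, and dissolved cells
    (internalized).  Conditions cover receptor-positive, receptor-negative
    and receptor-positive + blocking peptide wells; activities are arbitrary
    counter units with total uptake near 8%, 2% and 2% respectively.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    conditions = {
        "receptor_positive": (92.0, 2.7, 5.3),
        "receptor_negative": (98.0, 1.0, 1.0),
        "blocked": (98.0, 0.9, 1.1),
    }
    rows = []
    for cond, (medium, glycine, dissolved) in conditions.items():
        for name, level in (("medium_pbs", medium),
                            ("glycine_wash", glycine),
                            ("dissolved_cells", dissolved)):
            activity = rng.gamma(shape=400.0, scale=level / 400.0)
            rows.append({"condition": cond, "fraction_name": name,
                         "activity": float(activity)})
    table = pd.DataFrame(rows)
    assert (table.groupby("condition")["activity"].sum() > 0).all()
    return table
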