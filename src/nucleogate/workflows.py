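"""Mid-level workflows tying generator, segmentation, features and gating.

These are the building blocks used by the command-line pipeline and by the
validation studies: analyze one scene into tables, recover planted fold
changes between paired arms, and assemble balanced feature cohorts for the
classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gating as gt
from .features import extract_features
from .matching import match_to_truth
from .morphometrics import actin_spread
from .segmentation import (assign_cell_types, measure_nuclei,
                           records_to_frame, segment_nuclei,
                           segment_spheroids, subtract_background)
from .synthetic import (MARKER_SUMMARY, Scene, SceneConfig, generate_scene)

MEASURE_CHANNELS = ("dna", "gamma_h2ax", "draq7", "ki67")


@dataclass
class SceneAnalysis:
    """All per-scene outputs of the measurement stages."""

    scene: Scene
    labels: np.ndarray
    records: list
    spheroids: list
    nuclei: pd.DataFrame                 # tidy per-nucleus table
    features: pd.DataFrame | None = None
    truth: object = None                 # GroundTruth when synthetic
    dna_corrected: np.ndarray | None = None

    def cancer_nuclei(self) -> pd.DataFrame:
        """Nuclei inside spheroids, excluding fibroblast-like singletons."""
        df = self.nuclei
        keep = df["spheroid_id"].notna()
        if "cell_type" in df and df["cell_type"].notna().any():
            keep &= df["cell_type"] != "fibroblast"
        return df[keep].reset_index(drop=True)

    def matched(self, max_dist_px: float = 6.0) -> pd.DataFrame:
        if self.truth is None:
            raise ValueError("no ground truth attached to this analysis")
        if self.features is None:
            df = self.nuclei
        else:
            df = self.nuclei.merge(self.features, on="nucleus_id",
                                   how="left", suffixes=("_meas", ""))
        return match_to_truth(df, self.truth.nuclei, max_dist_px=max_dist_px)


def analyze_scene(scene: Scene, truth=None, with_features: bool = False,
                  with_celltypes: bool = False, min_nuclei: int = 5,
                  closing_radius_px: int | None = None,
                  bg_downscale: int = 4) -> SceneAnalysis:
    """Segment, group into spheroids and measure one scene."""
    cfg = scene.config
    r_px = cfg.mean_radius_px if cfg is not None else 7.0
    required = set(MEASURE_CHANNELS)
    missing = required - set(scene.channels)
    if missing:
        raise ValueError(f"scene is missing channels: {sorted(missing)}")
    labels = segment_nuclei(scene.channels["dna"], mean_radius_px=r_px,
                            bg_downscale=bg_downscale)
    bg_radius = 4.0 * r_px
    corrected = {name: subtract_background(scene.channels[name], bg_radius,
                                           downscale=bg_downscale)
                 for name in MEASURE_CHANNELS}
    records = measure_nuclei(labels, corrected,
                             pixel_size_um=scene.pixel_size_um)
    if closing_radius_px is None:
        closing_radius_px = int(round(1.5 * r_px))
    spheroids = segment_spheroids(scene.channels["dna"], labels,
                                  closing_radius_px=closing_radius_px,
                                  min_nuclei=min_nuclei, records=records,
                                  pixel_size_um=scene.pixel_size_um)
    if with_celltypes:
        assign_cell_types(records, scene.channels.get("celltracker"))
        for sph in spheroids:
            types = [rec.cell_type for rec in records
                     if rec.spheroid_id == sph.spheroid_id]
            sph.cell_type_counts = dict(pd.Series(types).value_counts())
    nuclei = records_to_frame(records)
    features = None
    if with_features:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            features = extract_features(records, corrected["dna"],
                                        pixel_size_um=scene.pixel_size_um)
    return SceneAnalysis(scene=scene, labels=labels, records=records,
                         spheroids=spheroids, nuclei=nuclei,
                         features=features, truth=truth,
                         dna_corrected=corrected["dna"])


def analyze_config(config: SceneConfig, **kwargs) -> SceneAnalysis:
    scene, truth = generate_scene(config)
    return analyze_scene(scene, truth=truth, **kwargs)


def marker_column(channel: str) -> str:
    """Measured column carrying a marker's per-nucleus summary."""
    return f"{channel}_{MARKER_SUMMARY[channel]}"


def recover_fold(arms: dict, channel: str, treated_arm: str | None = None,
                 reference_arm: str = "untreated", **analyze_kwargs) -> float:
    """End-to-end recovery of a planted fold change between two arms.

    Generates and measures both arms, normalizes the marker by the
    reference-arm mean, and returns the mean fold change of the treated arm
    relative to the reference.
    """
    names = list(arms)
    if treated_arm is None:
        treated_arm = next(n for n in names if n != reference_arm)
    col = marker_column(channel)
    values = {}
    for name in (reference_arm, treated_arm):
        analysis = analyze_config(arms[name], **analyze_kwargs)
        values[name] = analysis.cancer_nuclei()[col].to_numpy()
    return gt.fold_change(values[treated_arm], values[reference_arm])


def recover_actin_fold(arms: dict, high_arm: str, low_arm: str) -> float:
    """Ratio of mean actin-spread metrics between two spheroid cohorts."""
    means = {}
    for name in (low_arm, high_arm):
        analysis = analyze_config(arms[name])
        spreads = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for sph in analysis.spheroids:
                if sph.touches_border:
                    continue
                spreads.append(actin_spread(
                    analysis.scene.channels["actin"], sph))
        if not spreads:
            raise RuntimeError(f"no measurable spheroids in arm {name!r}")
        means[name] = float(np.mean(spreads))
    return means[high_arm] / means[low_arm]


def gate_cohorts(reference: SceneAnalysis, *others: SceneAnalysis,
                 min_reference: int = 50):
    """Fit gating on the reference cohort and gate every cohort with it.

    Returns ``(model, [gated reference, gated others...])``.
    """
    ref_nuclei = reference.cancer_nuclei()
    model = gt.GatingModel.fit(ref_nuclei, min_reference=min_reference,
                               reference_condition=reference.scene.condition)
    gated = [gt.gate_nuclei(ref_nuclei, model)]
    for other in others:
        gated.append(gt.gate_nuclei(other.cancer_nuclei(), model))
    return model, gated


def balanced_feature_cohort(seed: int, n_per_class: int = 100,
                            separable: bool = False,
                            ki67_ordering: bool = False,
                            margin: float = 1.35):
    """Measured features with true class labels, exactly balanced.

    Generates a four-class scene oversized by ``margin`` (segmentation loses
    a few percent of nuclei), matches detections to the planted truth, and
    keeps the first ``n_per_class`` matched nuclei of each class.

    Returns ``(features, labels, matched_table)``.
    """
    from .presets import four_class
    n_gen = int(np.ceil(n_per_class * margin))
    arms = four_class(seed, n_per_class=n_gen, separable=separable,
                      ki67_ordering=ki67_ordering)
    analysis = analyze_config(arms["cohort"], with_features=True)
    matched = analysis.matched()
    matched = matched[~matched["undefined"].astype(bool)]
    parts = []
    for name, grp in matched.groupby("true_subpop", sort=True):
        if len(grp) < n_per_class:
            raise RuntimeError(
                f"class {name!r} yielded only {len(grp)} usable nuclei; "
                "increase the margin")
        parts.append(grp.sort_values("nucleus_id").head(n_per_class))
    cohort = pd.concat(parts).reset_index(drop=True)
    from .features import FEATURE_COLUMNS
    features = cohort[FEATURE_COLUMNS]
    labels = cohort["true_subpop"].reset_index(drop=True)
    return features, labels, cohort
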