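"""Configurable end-to-end runs: generate/load -> segment -> features ->
gate -> classify -> report, with seeded determinism and provenance.

A run directory holds, per arm, ``nuclei.csv`` and ``features.csv``, plus
shared ``gating.json``, ``gated.csv``, ``classifier_report.json``,
``gel_summaries.csv``, ``stats_report.json`` and ``provenance.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import gating as gt
from .classify import SubpopulationClassifier
from .morphometrics import actin_spread, gel_frame, gel_summary
from .presets import get_preset
from .sceneio import read_scene, read_yaml, write_scene
from .synthetic import generate_scene
from .workflows import analyze_scene, gate_cohorts

log = logging.getLogger("nucleogate")

REQUIRED_CHANNELS = ("dna", "gamma_h2ax", "draq7", "ki67")

#: metrics compared between conditions; (column, source table)
COMPARISON_METRICS = ("norm_gamma", "norm_draq7", "ki67_mean", "area_um2",
                      "condensation_ratio")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to YAML."""

    out_dir: str
    preset: str | None = None
    preset_kwargs: dict = field(default_factory=dict)
    scene_paths: dict = field(default_factory=dict)   # arm -> TIFF path
    channel_map: dict = field(default_factory=dict)   # file name -> canonical
    reference_arm: str = "untreated"
    seed: int = 0
    min_nuclei_per_spheroid: int = 5
    min_reference_nuclei: int = 50
    bonferroni_m: int | None = None
    run_classifier: bool = False
    classifier_floor: int = 100
    n_trees: int = 500
    save_scenes: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = read_yaml(path)
        return cls(**data)

    def validate(self) -> None:
        if self.preset is None and not self.scene_paths:
            raise ValueError("config needs a preset or scene_paths")
        if self.seed is None:
            raise ValueError("seed must be set")


def _load_arm(path, channel_map) -> "object":
    scene = read_scene(path)
    if channel_map:
        scene.channels = {channel_map.get(k, k): v
                          for k, v in scene.channels.items()}
    missing = set(REQUIRED_CHANNELS) - set(scene.channels)
    if missing:
        raise ValueError(
            f"scene {path} is missing required channels {sorted(missing)}; "
            f"found {sorted(scene.channels)}")
    return scene


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # --- scenes per arm
    arms = {}
    truths = {}
    if config.preset:
        arm_configs = get_preset(config.preset, config.seed,
                                 **config.preset_kwargs)
        for name, cfg in arm_configs.items():
            scene, truth = generate_scene(cfg)
            arms[name] = scene
            truths[name] = truth
            if config.save_scenes:
                write_scene(scene, out / f"scene_{_safe(name)}.ome.tif")
    else:
        for name, path in config.scene_paths.items():
            arms[name] = _load_arm(path, config.channel_map)

    # --- per-arm measurement
    analyses = {}
    for name, scene in arms.items():
        log.info("analyzing arm %r", name)
        analyses[name] = analyze_scene(
            scene, truth=truths.get(name), with_features=True,
            with_celltypes=True,
            min_nuclei=config.min_nuclei_per_spheroid)
        a = analyses[name]
        a.nuclei.to_csv(out / f"nuclei_{_safe(name)}.csv", index=False)
        a.features.to_csv(out / f"features_{_safe(name)}.csv", index=False)
        log.info("arm %r: %d nuclei, %d spheroids",
                 name, len(a.nuclei), len(a.spheroids))

    # --- gating against the reference arm
    ref_name = config.reference_arm if config.reference_arm in analyses \
        else next(iter(analyses))
    other_names = [n for n in analyses if n != ref_name]
    model, gated = gate_cohorts(
        analyses[ref_name], *[analyses[n] for n in other_names],
        min_reference=config.min_reference_nuclei)
    model.to_json(out / "gating.json")
    gated_frames = []
    for name, frame in zip([ref_name] + other_names, gated):
        frame = frame.copy()
        frame["arm"] = name
        gated_frames.append(frame)
    gated_all = pd.concat(gated_frames, ignore_index=True)
    gated_all.to_csv(out / "gated.csv", index=False)

    # --- spheroid morphometrics
    summaries = []
    spread_rows = []
    for name, a in analyses.items():
        summaries.append(gel_summary(a.spheroids, gel_id=_safe(name),
                                     condition=a.scene.condition,
                                     timepoint="t0"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for sph in a.spheroids:
                if sph.touches_border:
                    continue
                spread_rows.append({
                    "arm": name, "spheroid_id": sph.spheroid_id,
                    "actin_spread": actin_spread(
                        a.scene.channels["actin"], sph)})
    gel_frame(summaries).to_csv(out / "gel_summaries.csv", index=False)
    pd.DataFrame(spread_rows).to_csv(out / "actin_spread.csv", index=False)

    # --- classifier on gated labels (optional; needs enough per class)
    classifier_report = None
    if config.run_classifier:
        pooled = gated_all.merge(
            pd.concat([a.features.assign(arm=name)
                       for name, a in analyses.items()]),
            on=["nucleus_id", "arm"])
        counts = pooled["subpop"].value_counts()
        if (counts >= config.classifier_floor).sum() == 4:
            clf = SubpopulationClassifier(
                n_trees=config.n_trees, seed=config.seed,
                class_floor=config.classifier_floor)
            feats = pooled.drop(columns=[
                c for c in pooled.columns
                if c in ("arm", "subpop") or "gamma" in c or "draq7" in c])
            classifier_report = clf.fit(feats, pooled["subpop"])
            classifier_report.to_json(out / "classifier_report.json")
            pd.DataFrame(classifier_report.confusion,
                         index=classifier_report.class_names,
                         columns=classifier_report.class_names
                         ).to_csv(out / "confusion.csv")
        else:
            log.warning("classifier skipped: classes below floor %s",
                        counts.to_dict())

    # --- condition statistics
    stats = {"reference_arm": ref_name, "arms": {}, "comparisons": {}}
    for name, frame in zip([ref_name] + other_names, gated):
        stats["arms"][name] = {
            "n_cancer_nuclei": int(len(frame)),
            "n_spheroids": len(analyses[name].spheroids),
            "subpop_fractions": gt.subpop_fractions(frame["subpop"]),
            "median_spheroid_area_um2": float(np.median(
                [s.area_um2 for s in analyses[name].spheroids]))
            if analyses[name].spheroids else float("nan"),
        }
    plan = [(n, ref_name) for n in other_names]
    m = config.bonferroni_m or max(len(plan) * len(COMPARISON_METRICS), 1)
    for arm_a, arm_b in plan:
        stats["comparisons"][f"{arm_a}_vs_{arm_b}"] = compare_conditions(
            _arm_table(analyses, gated_all, arm_a),
            _arm_table(analyses, gated_all, arm_b), m_comparisons=m)
    stats["bonferroni_m"] = m
    with open(out / "stats_report.json", "w") as fh:
        json.dump(stats, fh, indent=2)

    # --- provenance
    cfg_dict = asdict(config)
    digest = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()
    prov = {"config": cfg_dict, "config_sha256": digest,
            "seed": config.seed, "nucleogate_version": __version__,
            "numpy_version": np.__version__,
            "elapsed_s": round(time.time() - t0, 2)}
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, default=str)
    return out


def _safe(name: str) -> str:
    return name.replace("/", "-").replace("+", "_")


def _arm_table(analyses, gated_all, arm):
    sub = gated_all[gated_all["arm"] == arm]
    feats = analyses[arm].features
    return sub.merge(feats[["nucleus_id", "condensation_ratio", "area_um2"]
                           ].rename(columns={"area_um2": "feat_area_um2"}),
                     on="nucleus_id", how="left")


def compare_conditions(table_a: pd.DataFrame, table_b: pd.DataFrame,
                       m_comparisons: int = 1) -> dict:
    """Fold change + Welch's t (raw and Bonferroni-adjusted) per metric.

    ``table_a`` is the condition of interest, ``table_b`` the reference.
    """
    out = {}
    for metric in COMPARISON_METRICS:
        col = metric if metric in table_a.columns else None
        if col is None or metric not in table_b.columns:
            continue
        a = pd.to_numeric(table_a[col], errors="coerce").dropna().to_numpy()
        b = pd.to_numeric(table_b[col], errors="coerce").dropna().to_numpy()
        if len(a) < 2 or len(b) < 2 or b.mean() <= 0:
            continue
        t, p_raw, p_adj = gt.welch_test(a, b, m_comparisons=m_comparisons)
        out[metric] = {"fold_change": gt.fold_change(a, b),
                       "t": t, "p_raw": p_raw, "p_bonferroni": p_adj,
                       "n_a": int(len(a)), "n_b": int(len(b))}
    return out
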