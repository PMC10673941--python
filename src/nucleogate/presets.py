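"""Named generator presets for the study conditions exercised end-to-end.

Each preset returns a mapping ``arm name -> SceneConfig``.  Paired arms
share the root seed so that the underlying per-nucleus draws coincide and a
planted fold change is exact at the truth-table level.  Defaults mirror the
cohort sizes used throughout: 2000 cancer nuclei for gating cohorts, 1000
per arm for fold-change recovery, 50 spheroids per arm for actin spread.
"""

from __future__ import annotations

import math

from .synthetic import (MarkerModel, SceneConfig, calibrate_treated_mix,
                        exceedance_shift)

#: low/low fractions printed for the untreated and treated cohorts
UNTREATED_LOWLOW = 0.81
TREATED_LOWLOW = 0.69

#: planted treatment fold changes (treated vs untreated arm)
RLT_FOLDS = {"gamma_h2ax": 2.1, "draq7": 1.9, "ki67": 1.3}
TSA_RLT_GAMMA_FOLD = 12.0
CHROMATIN_MODIFIER_DEATH_FOLD = 28.0   # planted above the >= 25-fold bound
ACTIN_SPREAD_FOLD = 1.7


def untreated_baseline(seed: int, n_spheroids: int = 50,
                       nuclei_per_spheroid: int = 40,
                       n_fibroblasts: int = 40) -> dict:
    """Untreated reference cohort: markers independent per nucleus.

    A single-population mix with log-normal γH2AX and DRAQ7 drawn from
    independent streams, so gating at the cohort's own 90th percentiles
    yields an expected low/low fraction of 0.9^2 = 0.81.
    """
    cfg = SceneConfig(
        n_spheroids=n_spheroids, nuclei_per_spheroid=nuclei_per_spheroid,
        n_fibroblasts=n_fibroblasts, condition="untreated",
        subpop_mix=(1.0, 0.0, 0.0, 0.0),
        marker_params={
            "gamma_h2ax": MarkerModel(mean=(6000.0,) * 4, sigma=0.5),
            "draq7": MarkerModel(mean=(25.0,) * 4, sigma=0.5),
            "ki67": MarkerModel(mean=(30.0,) * 4, sigma=0.4),
        },
        seed=seed)
    return {"untreated": cfg}


def treated_69(seed: int, **kw) -> dict:
    """Untreated arm plus a treated arm calibrated by (1-p)^2 = 0.69.

    Both marker locations shift so each exceeds the untreated true 90th
    percentile with probability p = 1 - sqrt(0.69).
    """
    arms = untreated_baseline(seed, **kw)
    cfg = arms["untreated"]
    p_g, p_d = calibrate_treated_mix(TREATED_LOWLOW)
    folds = {}
    for channel, p in (("gamma_h2ax", p_g), ("draq7", p_d)):
        sigma = cfg.marker_params[channel].sigma
        folds[channel] = math.exp(exceedance_shift(p, sigma))
    treated = cfg.with_folds(folds, condition="treated")
    # the treated arm is an independent cohort, not a resampled baseline
    treated = _reseed(treated, seed + 1)
    arms["treated"] = treated
    return arms


def _reseed(cfg: SceneConfig, seed: int) -> SceneConfig:
    from dataclasses import replace
    return replace(cfg, seed=seed)


def _fold_pair(seed: int, folds: dict, condition: str,
               n_spheroids: int = 25, nuclei_per_spheroid: int = 40) -> dict:
    arms = untreated_baseline(seed, n_spheroids=n_spheroids,
                              nuclei_per_spheroid=nuclei_per_spheroid)
    arms[condition] = arms["untreated"].with_folds(folds, condition=condition)
    return arms


def gamma_2p1(seed: int, **kw) -> dict:
    """Radiotherapy effect on the DNA-damage marker: 2.1x γH2AX sum."""
    return _fold_pair(seed, {"gamma_h2ax": RLT_FOLDS["gamma_h2ax"]},
                      "treated", **kw)


def draq7_1p9(seed: int, **kw) -> dict:
    """Radiotherapy effect on the death marker: 1.9x DRAQ7 mean."""
    return _fold_pair(seed, {"draq7": RLT_FOLDS["draq7"]}, "treated", **kw)


def ki67_1p3(seed: int, **kw) -> dict:
    """Radiotherapy effect on proliferation: 1.3x Ki67 mean."""
    return _fold_pair(seed, {"ki67": RLT_FOLDS["ki67"]}, "treated", **kw)


def tsa_12x(seed: int, **kw) -> dict:
    """HDAC inhibitor + radioligand: 12x γH2AX relative to untreated."""
    return _fold_pair(seed, {"gamma_h2ax": TSA_RLT_GAMMA_FOLD},
                      "treated+TSA", **kw)


def chemomod_25x(seed: int, n_spheroids: int = 25,
                 nuclei_per_spheroid: int = 40) -> dict:
    """Chromatin modifier + radiotherapy vs radiotherapy alone.

    The radiotherapy-alone arm carries the 1.9x DRAQ7 effect; the
    combinatorial arm plants a 28x DRAQ7 increase over it, exceeding the
    >= 25-fold bound.
    """
    arms = untreated_baseline(seed, n_spheroids=n_spheroids,
                              nuclei_per_spheroid=nuclei_per_spheroid)
    rlt = arms.pop("untreated").with_folds(
        {"draq7": RLT_FOLDS["draq7"]}, condition="treated")
    combo = rlt.with_folds({"draq7": CHROMATIN_MODIFIER_DEATH_FOLD},
                           condition="treated+TSA")
    return {"treated": rlt, "treated+TSA": combo}


def actin_1p7(seed: int, n_spheroids: int = 50,
              base_spread: float = 0.08) -> dict:
    """Two spheroid cohorts whose actin spread factors differ 1.7-fold."""
    from dataclasses import replace
    arms = untreated_baseline(seed, n_spheroids=n_spheroids,
                              nuclei_per_spheroid=40, n_fibroblasts=0)
    low = replace(arms["untreated"], actin_spread_factor=base_spread,
                  condition="A431")
    high = replace(arms["untreated"],
                   actin_spread_factor=base_spread * ACTIN_SPREAD_FOLD,
                   condition="A431/CCKBR", seed=seed + 1)
    return {"A431": low, "A431/CCKBR": high}


def mixed_50_74(seed: int, n_spheroids: int = 50,
                nuclei_per_spheroid: int = 40) -> dict:
    """Mixed spheroids: 50% receptor-negative cells before treatment, 74%
    among survivors after (selective death of receptor-positive cells)."""
    arms = untreated_baseline(seed, n_spheroids=n_spheroids,
                              nuclei_per_spheroid=nuclei_per_spheroid)
    from dataclasses import replace
    untreated = replace(arms["untreated"], a431_fraction=0.50)
    treated = replace(arms["untreated"], a431_fraction=0.74,
                      condition="treated", seed=seed + 1)
    return {"untreated": untreated, "treated": treated}


def four_class(seed: int, n_per_class: int = 100, separable: bool = False,
               ki67_ordering: bool = False) -> dict:
    """Balanced four-subpopulation cohort with morphology coupling.

    With ``separable`` the class-to-feature coupling is strong (distinct
    area and condensation levels, tight within-class spread); otherwise the
    default moderate coupling applies.  ``ki67_ordering`` plants a Ki67
    ordering across classes (low/low lowest, high-damage/low-death highest).
    """
    from .synthetic import Subpopulation
    n_total = 4 * n_per_class
    n_spheroids = max(n_total // 40, 1)
    ki67 = (30.0, 54.0, 42.0, 39.0) if ki67_ordering else (30.0,) * 4
    kwargs = dict(
        n_spheroids=n_spheroids, nuclei_per_spheroid=40, n_fibroblasts=0,
        subpop_mix=(0.25, 0.25, 0.25, 0.25),
        marker_params={
            "gamma_h2ax": MarkerModel(mean=(6000.0, 15000.0, 7000.0, 16000.0)),
            "draq7": MarkerModel(mean=(25.0, 28.0, 60.0, 65.0)),
            "ki67": MarkerModel(mean=ki67, sigma=0.4),
        },
        condition="treated", balance_subpops=True, seed=seed)
    if separable:
        kwargs.update(
            area_scale=(1.0, 1.6, 2.4, 3.4),
            nucleus_radius_um=(4.5, 0.15),
            condensation_params={
                Subpopulation.LOW_LOW: (0.30, 3.2),
                Subpopulation.HIGH_LOW: (0.30, 2.35),
                Subpopulation.LOW_HIGH: (0.26, 1.7),
                Subpopulation.HIGH_HIGH: (0.26, 1.25),
            })
    return {"cohort": SceneConfig(**kwargs)}


PRESETS = {
    "untreated_baseline": untreated_baseline,
    "treated_69": treated_69,
    "gamma_2p1": gamma_2p1,
    "draq7_1p9": draq7_1p9,
    "ki67_1p3": ki67_1p3,
    "tsa_12x": tsa_12x,
    "chemomod_25x": chemomod_25x,
    "actin_1p7": actin_1p7,
    "mixed_50_74": mixed_50_74,
    "four_class": four_class,
}


def get_preset(name: str, seed: int, **kwargs) -> dict:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; "
                       f"known: {sorted(PRESETS)}")
    return PRESETS[name](seed, **kwargs)
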