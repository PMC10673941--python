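"""Segmentation and per-nucleus measurement against constructed fixtures."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from nucleogate.presets import untreated_baseline
from nucleogate.segmentation import (measure_nuclei, records_to_frame,
                                     segment_nuclei, segment_spheroids,
                                     subtract_background)
from nucleogate.workflows import analyze_config


def disks_image(centers, radius=12, level=100.0, background=10.0,
                shape=(128, 128)):
    img = np.full(shape, background)
    for c in centers:
        rr, cc = draw_disk(c, radius, shape=shape)
        img[rr, cc] = level
    return img


def test_blank_image_yields_no_labels():
    img = np.full((96, 96), 10.0)
    labels = segment_nuclei(img, mean_radius_px=8)
    assert labels.max() == 0


def test_input_validation():
    with pytest.raises(ValueError):
        segment_nuclei(np.zeros((4, 4, 4)), mean_radius_px=8)
    with pytest.raises(ValueError):
        segment_nuclei(np.full((32, 32), -1.0), mean_radius_px=8)


def test_two_disjoint_disks_centroids():
    centers = [(40, 40), (90, 90)]
    labels = segment_nuclei(disks_image(centers), mean_radius_px=12)
    assert labels.max() == 2
    recs = measure_nuclei(labels, {})
    found = sorted(r.centroid for r in recs)
    for (fr, fc), (tr, tc) in zip(found, sorted(centers)):
        assert abs(fr - tr) <= 1.0 and abs(fc - tc) <= 1.0


def test_overlapping_disks_split_by_watershed():
    # centers 1.8 radii apart: ~20% radial overlap
    centers = [(60, 50), (60, 50 + int(1.8 * 12))]
    labels = segment_nuclei(disks_image(centers), mean_radius_px=12)
    assert labels.max() == 2


def test_labels_contiguous_and_disjoint(untreated_small):
    labels = untreated_small.labels
    present = np.unique(labels)
    assert present[0] == 0
    assert np.array_equal(present[1:], np.arange(1, labels.max() + 1))
    # every foreground pixel belongs to exactly one nucleus
    total_mask_area = sum(r.area_px for r in untreated_small.records)
    assert total_mask_area == int((labels > 0).sum())


def test_count_recovery_within_5_percent():
    arms = untreated_baseline(23, n_spheroids=13, nuclei_per_spheroid=40,
                              n_fibroblasts=0)
    analysis = analyze_config(arms["untreated"])
    planted = len(analysis.truth.nuclei)
    detected = len(analysis.nuclei)
    assert planted == 520
    assert abs(detected - planted) / planted <= 0.05


def test_spheroid_grouping_cluster_plus_singletons():
    arms = untreated_baseline(31, n_spheroids=1, nuclei_per_spheroid=30,
                              n_fibroblasts=5)
    analysis = analyze_config(arms["untreated"], min_nuclei=5)
    assert len(analysis.spheroids) == 1
    members = analysis.spheroids[0].member_ids
    assert len(members) >= 28          # small segmentation losses tolerated
    singles = analysis.nuclei["spheroid_id"].isna().sum()
    assert singles >= 4


def test_two_separated_clusters_make_two_spheroids():
    arms = untreated_baseline(32, n_spheroids=2, nuclei_per_spheroid=20,
                              n_fibroblasts=0)
    analysis = analyze_config(arms["untreated"], min_nuclei=5)
    assert len(analysis.spheroids) == 2


def test_empty_label_image_gives_no_spheroids():
    img = np.full((64, 64), 5.0)
    out = segment_spheroids(img, np.zeros((64, 64), np.int32),
                            closing_radius_px=3, min_nuclei=2)
    assert out == []


def test_spheroid_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        segment_spheroids(np.zeros((10, 10)), np.zeros((12, 12), np.int32),
                          closing_radius_px=3, min_nuclei=2)


# ---------------------------------------------------------------------------
# measurement


def one_disk_label(radius=10, shape=(48, 48)):
    labels = np.zeros(shape, np.int32)
    rr, cc = draw_disk((24, 24), radius, shape=shape)
    labels[rr, cc] = 1
    return labels


def test_uniform_channel_summaries():
    labels = one_disk_label()
    n = int((labels == 1).sum())
    chan = np.where(labels == 1, 7.5, 0.0)
    rec = measure_nuclei(labels, {"x": chan})[0]
    st = rec.channel_stats["x"]
    assert st["sum"] == pytest.approx(n * 7.5)
    assert st["mean"] == pytest.approx(7.5)
    assert st["p20"] == st["p80"] == pytest.approx(7.5)


def test_percentiles_match_hand_constructed_mixture():
    labels = np.zeros((10, 10), np.int32)
    labels.ravel()[:100] = 1
    chan = np.concatenate([np.full(70, 10.0), np.full(30, 100.0)])
    rng = np.random.default_rng(1)
    chan = rng.permutation(chan).reshape(10, 10)
    st = measure_nuclei(labels, {"x": chan})[0].channel_stats["x"]
    assert st["p20"] == pytest.approx(10.0)
    assert st["p80"] == pytest.approx(100.0)


def test_zero_channel_all_zero_summaries():
    labels = one_disk_label()
    st = measure_nuclei(labels, {"x": np.zeros(labels.shape)})[0]
    assert all(v == 0.0 for v in st.channel_stats["x"].values())


def test_percentiles_agree_with_sort_oracle(rng):
    """Linear-interpolation percentiles vs an independent full-sort oracle
    on random masks."""
    def oracle(vals, q):
        s = np.sort(vals)
        pos = (len(s) - 1) * q / 100.0
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return s[lo] + (pos - lo) * (s[hi] - s[lo])

    for _ in range(100):
        n = rng.integers(10, 300)
        vals = rng.gamma(2.0, 50.0, size=n)
        labels = np.zeros(512, np.int32)
        labels[:n] = 1
        chan = np.zeros(512)
        chan[:n] = vals
        st = measure_nuclei(labels.reshape(16, 32),
                            {"x": chan.reshape(16, 32)})[0].channel_stats["x"]
        assert st["p20"] == pytest.approx(oracle(vals, 20), abs=1e-9)
        assert st["p80"] == pytest.approx(oracle(vals, 80), abs=1e-9)


def test_constant_offset_invariance():
    """Adding a constant before background subtraction leaves per-nucleus
    summaries unchanged (the background model absorbs it)."""
    img = disks_image([(40, 40), (90, 80)], level=120.0, background=15.0)
    labels = segment_nuclei(img, mean_radius_px=12)
    a = measure_nuclei(labels, {"x": img}, bg_radius_px=48)
    b = measure_nuclei(labels, {"x": img + 50.0}, bg_radius_px=48)
    for ra, rb in zip(a, b):
        for key in ("sum", "mean", "p20", "p80"):
            assert ra.channel_stats["x"][key] == pytest.approx(
                rb.channel_stats["x"][key], abs=1e-6)


def test_background_subtraction_clips_negatives():
    img = np.full((64, 64), 10.0)
    out = subtract_background(img, 16)
    assert (out >= 0).all()


def test_channel_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        measure_nuclei(one_disk_label(), {"x": np.zeros((3, 3))})


def test_records_frame_columns(untreated_small):
    frame = records_to_frame(untreated_small.records)
    for col in ("nucleus_id", "area_um2", "spheroid_id", "cell_type",
                "gamma_h2ax_sum", "draq7_mean", "dna_p20", "dna_p80"):
        assert col in frame.columns
    assert (frame["dna_p20"] <= frame["dna_p80"]).all()


def test_mixed_celltype_fractions_recovered():
    from dataclasses import replace
    from nucleogate.gating import celltype_fraction_per_spheroid
    arms = untreated_baseline(41, n_spheroids=10, nuclei_per_spheroid=40,
                              n_fibroblasts=0)
    cfg = replace(arms["untreated"], a431_fraction=0.5)
    analysis = analyze_config(cfg, with_celltypes=True)
    fracs = celltype_fraction_per_spheroid(analysis.nuclei)
    assert fracs["frac_a431"].mean() == pytest.approx(0.50, abs=0.05)
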