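"""Gating model, subpopulation assignment and cohort statistics."""

import numpy as np
import pandas as pd
import pytest

from nucleogate.gating import (GatingModel, assign_subpopulation,
                               celltype_fraction_per_spheroid, fold_change,
                               gate_nuclei, positive_fraction_per_spheroid,
                               subpop_abundance_change, subpop_fractions,
                               welch_test)
from nucleogate.synthetic import Subpopulation


def reference_frame(gamma, draq7):
    return pd.DataFrame({"gamma_h2ax_sum": gamma, "draq7_mean": draq7})


@pytest.fixture()
def linear_model():
    vals = np.arange(1.0, 101.0)
    return GatingModel.fit(reference_frame(vals, vals))


class TestGatingModel:
    def test_linear_reference_threshold(self, linear_model):
        # raw-scale 90th percentile of 1..100 is 90.1 (linear interpolation)
        m = linear_model
        assert m.thr_gamma * m.norm_gamma == pytest.approx(90.1)
        assert m.thr_draq7 * m.norm_draq7 == pytest.approx(90.1)

    def test_normalized_reference_mean_is_one(self, linear_model):
        vals = np.arange(1.0, 101.0)
        normed = linear_model.normalize(reference_frame(vals, vals))
        assert normed["norm_gamma"].mean() == pytest.approx(1.0)
        assert normed["norm_draq7"].mean() == pytest.approx(1.0)

    def test_constant_reference_gates_everything_low(self):
        vals = np.full(60, 5.0)
        m = GatingModel.fit(reference_frame(vals, vals))
        gated = gate_nuclei(reference_frame(vals, vals), m)
        assert (gated["subpop"] == Subpopulation.LOW_LOW.value).all()

    def test_reference_high_fraction_bounded(self, linear_model):
        vals = np.arange(1.0, 101.0)
        normed = linear_model.normalize(reference_frame(vals, vals))
        frac_high = (normed["norm_gamma"] > linear_model.thr_gamma).mean()
        assert frac_high <= 0.10 + 1.0 / len(vals)

    def test_too_few_reference_nuclei_rejected(self):
        vals = np.arange(1.0, 11.0)
        with pytest.raises(ValueError):
            GatingModel.fit(reference_frame(vals, vals))

    def test_zero_reference_mean_rejected(self):
        vals = np.zeros(60)
        with pytest.raises(ValueError):
            GatingModel.fit(reference_frame(vals, vals))

    def test_json_round_trip(self, linear_model, tmp_path):
        path = tmp_path / "gating.json"
        linear_model.to_json(path)
        back = GatingModel.from_json(path)
        assert back == linear_model

    def test_summary_mentions_thresholds(self, linear_model):
        text = linear_model.summary()
        assert "90th-percentile" in text
        assert f"{linear_model.thr_gamma:.4f}" in text


class TestAssignSubpopulation:
    def test_quadrants(self, linear_model):
        m = linear_model
        lo = 0.5 * m.thr_gamma
        hi = 1.5 * m.thr_gamma
        assert assign_subpopulation(lo, lo, m) is Subpopulation.LOW_LOW
        assert assign_subpopulation(hi, lo, m) is Subpopulation.HIGH_LOW
        assert assign_subpopulation(lo, hi, m) is Subpopulation.LOW_HIGH
        assert assign_subpopulation(hi, hi, m) is Subpopulation.HIGH_HIGH

    def test_tie_on_threshold_gates_low(self, linear_model):
        m = linear_model
        assert assign_subpopulation(m.thr_gamma, m.thr_draq7, m) \
            is Subpopulation.LOW_LOW

    def test_nonfinite_rejected(self, linear_model):
        with pytest.raises(ValueError):
            assign_subpopulation(np.nan, 1.0, linear_model)

    def test_labels_partition(self, linear_model, rng):
        g = rng.lognormal(0.0, 1.0, 500)
        d = rng.lognormal(0.0, 1.0, 500)
        fracs = subpop_fractions(assign_subpopulation(g, d, linear_model))
        assert sum(fracs.values()) == pytest.approx(1.0)


class TestAbundanceChange:
    def test_identical_distributions_zero(self):
        labels = [Subpopulation.LOW_LOW] * 8 + [Subpopulation.HIGH_LOW] * 2
        delta = subpop_abundance_change(labels, labels)
        assert all(v == 0.0 for v in delta.values())

    def test_deltas_sum_to_zero(self, rng):
        names = [sp.value for sp in Subpopulation]
        a = rng.choice(names, 300)
        b = rng.choice(names, 200)
        delta = subpop_abundance_change(a, b)
        assert sum(delta.values()) == pytest.approx(0.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            subpop_fractions([])


def test_positive_fractions_hand_count(linear_model):
    m = linear_model
    lo_g, hi_g = 0.5 * m.thr_gamma, 2.0 * m.thr_gamma
    lo_d, hi_d = 0.5 * m.thr_draq7, 2.0 * m.thr_draq7
    # 10 nuclei: 2 gamma-only, 3 draq7-only, 1 both, 4 unaffected
    norm_g = [hi_g, hi_g, lo_g, lo_g, lo_g, hi_g, lo_g, lo_g, lo_g, lo_g]
    norm_d = [lo_d, lo_d, hi_d, hi_d, hi_d, hi_d, lo_d, lo_d, lo_d, lo_d]
    gated = pd.DataFrame({"norm_gamma": norm_g, "norm_draq7": norm_d,
                          "spheroid_id": [0] * 10})
    out = positive_fraction_per_spheroid(gated, m).iloc[0]
    assert out["frac_gamma_only"] == pytest.approx(0.2)
    assert out["frac_draq7_only"] == pytest.approx(0.3)
    assert out["frac_both"] == pytest.approx(0.1)
    assert out["frac_affected"] == pytest.approx(0.6)


class TestFoldChange:
    def test_identity(self):
        assert fold_change([3.0, 4.0], [3.0, 4.0]) == 1.0

    def test_mixed_spheroid_worked_example(self):
        # receptor-negative fraction rises from 50% to 74% after treatment
        assert round(fold_change([0.74], [0.50]), 1) == 1.5

    def test_reciprocal_property(self, rng):
        a = rng.lognormal(1.0, 0.5, 40)
        b = rng.lognormal(0.5, 0.5, 30)
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            fold_change([], [1.0])
        with pytest.raises(ValueError):
            fold_change([1.0], [0.0, 0.0])


class TestWelch:
    def test_identical_groups(self):
        t, p, padj = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        t, p, _ = welch_test(a, b)
        # independent implementation of Welch's statistic and df
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_ref = (va + vb) ** 2 / (va**2 / (len(a) - 1)
                                   + vb**2 / (len(b) - 1))
        from scipy.stats import t as tdist
        p_ref = 2.0 * tdist.sf(abs(t_ref), df_ref)
        assert t == pytest.approx(t_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_bonferroni_scaling_and_cap(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [1.5, 2.5, 3.1, 4.4]
        _, p1, padj1 = welch_test(a, b, m_comparisons=1)
        _, _, padj10 = welch_test(a, b, m_comparisons=10)
        assert padj1 == p1
        assert padj10 == pytest.approx(min(1.0, 10 * p1))

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            welch_test([1.0], [2.0, 3.0])

    def test_type_one_error_calibrated(self, rng):
        """Null rejection rate at alpha = 0.05 over 10^4 repetitions."""
        n_rep = 10_000
        a = rng.normal(0.0, 1.0, size=(n_rep, 8))
        b = rng.normal(0.0, 2.0, size=(n_rep, 12))
        rejections = sum(welch_test(a[i], b[i])[1] < 0.05
                         for i in range(n_rep))
        assert rejections / n_rep == pytest.approx(0.05, abs=0.01)


def test_celltype_fraction_per_spheroid_hand_built():
    nuclei = pd.DataFrame({
        "spheroid_id": [0, 0, 0, 0, 1, 1, None],
        "cell_type": ["A431", "A431", "A431/CCKBR", "A431/CCKBR",
                      "A431", "A431", "fibroblast"],
    })
    out = celltype_fraction_per_spheroid(nuclei)
    assert out.set_index("spheroid_id")["frac_a431"].to_dict() == \
        pytest.approx({0: 0.5, 1: 1.0})
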