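"""Marker normalization, 90th-percentile gating and cohort statistics.

Per-nucleus γH2AX is quantified as the integrated (summed) nuclear intensity
and DRAQ7 as the mean nuclear intensity.  Both are normalized by their mean
over an untreated reference population (receptor-positive cancer nuclei), so
the reference normalized mean is 1 by construction.  Gating thresholds are
the 90th percentiles (linear interpolation) of the normalized reference
values; a nucleus is "high" on a marker only when strictly above the
threshold (ties gate low), which partitions nuclei into four damage/death
subpopulations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SUBPOP_ORDER, Subpopulation

GAMMA_COLUMN = "gamma_h2ax_sum"    # integrated intensity
DRAQ7_COLUMN = "draq7_mean"        # mean intensity


@dataclass(frozen=True)
class GatingModel:
    """Reference normalization constants plus the two gating thresholds."""

    norm_gamma: float
    norm_draq7: float
    thr_gamma: float
    thr_draq7: float
    n_reference: int
    reference_condition: str = "untreated"
    cell_line: str = "A431/CCKBR"

    @classmethod
    def fit(cls, reference: pd.DataFrame, min_reference: int = 50,
            gamma_column: str = GAMMA_COLUMN,
            draq7_column: str = DRAQ7_COLUMN,
            reference_condition: str = "untreated",
            cell_line: str = "A431/CCKBR") -> "GatingModel":
        """Fit normalization constants and thresholds on reference nuclei.

        ``reference`` must hold one row per untreated reference nucleus with
        the raw per-nucleus γH2AX sum and DRAQ7 mean columns.
        """
        if len(reference) < min_reference:
            raise ValueError(
                f"need at least {min_reference} reference nuclei, "
                f"got {len(reference)}")
        gamma = np.asarray(reference[gamma_column], dtype=float)
        draq7 = np.asarray(reference[draq7_column], dtype=float)
        norm_gamma = float(gamma.mean())
        norm_draq7 = float(draq7.mean())
        if norm_gamma <= 0 or norm_draq7 <= 0:
            raise ValueError("reference mean intensities must be positive")
        thr_gamma = float(np.percentile(gamma / norm_gamma, 90.0))
        thr_draq7 = float(np.percentile(draq7 / norm_draq7, 90.0))
        return cls(norm_gamma=norm_gamma, norm_draq7=norm_draq7,
                   thr_gamma=thr_gamma, thr_draq7=thr_draq7,
                   n_reference=len(reference),
                   reference_condition=reference_condition,
                   cell_line=cell_line)

    def normalize(self, nuclei: pd.DataFrame,
                  gamma_column: str = GAMMA_COLUMN,
                  draq7_column: str = DRAQ7_COLUMN) -> pd.DataFrame:
        """Return a copy with ``norm_gamma``/``norm_draq7`` columns added."""
        out = nuclei.copy()
        out["norm_gamma"] = np.asarray(out[gamma_column], float) / self.norm_gamma
        out["norm_draq7"] = np.asarray(out[draq7_column], float) / self.norm_draq7
        return out

    def summary(self) -> str:
        lines = [
            "Marker gating model",
            f"  reference: {self.reference_condition} {self.cell_line} "
            f"(n = {self.n_reference})",
            f"  gamma-H2AX normalization (mean of sums): {self.norm_gamma:.4g}",
            f"  DRAQ7 normalization (mean of means):     {self.norm_draq7:.4g}",
            f"  90th-percentile thresholds: gamma = {self.thr_gamma:.4f}, "
            f"DRAQ7 = {self.thr_draq7:.4f}",
        ]
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "GatingModel":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    data = json.load(fh)
        return cls(**data)


def assign_subpopulation(norm_gamma, norm_draq7, model: GatingModel):
    """Quadrant label(s) for normalized marker values.

    Strict inequality on both axes; values equal to a threshold gate low
    (conservative calling).  Accepts scalars or arrays; returns a single
    :class:`Subpopulation` or an object array of them.
    """
    g = np.asarray(norm_gamma, dtype=float)
    d = np.asarray(norm_draq7, dtype=float)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(d))):
        raise ValueError("normalized marker values must be finite")
    high_g = g > model.thr_gamma
    high_d = d > model.thr_draq7
    idx = high_g.astype(int) + 2 * high_d.astype(int)
    # index order: 0 low/low, 1 high/low, 2 low/high, 3 high/high
    lut = np.array([Subpopulation.LOW_LOW, Subpopulation.HIGH_LOW,
                    Subpopulation.LOW_HIGH, Subpopulation.HIGH_HIGH],
                   dtype=object)
    if np.ndim(idx) == 0:
        return lut[int(idx)]
    return lut[idx]


def gate_nuclei(nuclei: pd.DataFrame, model: GatingModel) -> pd.DataFrame:
    """Normalize and label a nucleus table; adds a ``subpop`` column."""
    out = model.normalize(nuclei)
    labels = assign_subpopulation(out["norm_gamma"].to_numpy(),
                                  out["norm_draq7"].to_numpy(), model)
    out["subpop"] = [lab.value for lab in np.atleast_1d(labels)]
    return out


def subpop_fractions(labels) -> dict:
    """Fraction of nuclei per subpopulation; fractions sum to 1."""
    labels = [lab.value if isinstance(lab, Subpopulation) else str(lab)
              for lab in labels]
    if len(labels) == 0:
        raise ValueError("empty label list")
    counts = pd.Series(labels).value_counts()
    return {sp.value: float(counts.get(sp.value, 0)) / len(labels)
            for sp in SUBPOP_ORDER}


def subpop_abundance_change(untreated_labels, treated_labels) -> dict:
    """Treated minus untreated fraction per class (the four deltas sum to 0)."""
    f_un = subpop_fractions(untreated_labels)
    f_tr = subpop_fractions(treated_labels)
    return {sp.value: f_tr[sp.value] - f_un[sp.value] for sp in SUBPOP_ORDER}


def positive_fraction_per_spheroid(gated: pd.DataFrame,
                                   model: GatingModel) -> pd.DataFrame:
    """Per-spheroid fractions of γH2AX+ only, DRAQ7+ only, and double
    positive nuclei (three disjoint fractions, plus their sum)."""
    if "spheroid_id" not in gated:
        raise ValueError("spheroid membership not assigned")
    rows = []
    for sid, grp in gated.dropna(subset=["spheroid_id"]).groupby("spheroid_id"):
        n = len(grp)
        if n == 0:
            raise ValueError(f"spheroid {sid} has no nuclei")
        high_g = grp["norm_gamma"].to_numpy() > model.thr_gamma
        high_d = grp["norm_draq7"].to_numpy() > model.thr_draq7
        gamma_only = float(np.mean(high_g & ~high_d))
        draq7_only = float(np.mean(~high_g & high_d))
        both = float(np.mean(high_g & high_d))
        rows.append({"spheroid_id": sid, "n_nuclei": n,
                     "frac_gamma_only": gamma_only,
                     "frac_draq7_only": draq7_only,
                     "frac_both": both,
                     "frac_affected": gamma_only + draq7_only + both})
    return pd.DataFrame(rows)


def fold_change(group_a, group_b) -> float:
    """mean(a) / mean(b); the b group is the reference (denominator)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mb = b.mean()
    if mb <= 0:
        raise ValueError("reference group mean must be positive")
    return float(a.mean() / mb)


def welch_test(group_a, group_b, m_comparisons: int = 1):
    """Welch's unequal-variance t test with Bonferroni adjustment.

    Returns ``(t, p_raw, p_bonferroni)`` with a two-sided p-value and
    Welch–Satterthwaite degrees of freedom; ``p_bonferroni = min(1, m*p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0, 1.0
        raise ValueError("degenerate (zero-variance) groups differ in mean")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    res = stats.ttest_ind(a, b, equal_var=False)
    t = float(res.statistic)
    p = float(res.pvalue)
    return t, p, min(1.0, m_comparisons * p)


def celltype_fraction_per_spheroid(nuclei: pd.DataFrame) -> pd.DataFrame:
    """Fraction of receptor-negative (A431) cells per mixed spheroid.

    Counts only cancer nuclei (fibroblasts have no spheroid membership).
    """
    if "cell_type" not in nuclei:
        raise ValueError("cell types not assigned")
    rows = []
    cancer = nuclei.dropna(subset=["spheroid_id"])
    for sid, grp in cancer.groupby("spheroid_id"):
        if len(grp) == 0:
            raise ValueError(f"spheroid {sid} is empty")
        frac = float((grp["cell_type"] == "A431").mean())
        rows.append({"spheroid_id": sid, "n_nuclei": len(grp),
                     "frac_a431": frac})
    return pd.DataFrame(rows)
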