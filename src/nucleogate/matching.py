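"""Match segmented nuclei to planted ground truth by nearest centroid."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


def match_to_truth(measured: pd.DataFrame, truth: pd.DataFrame,
                   max_dist_px: float = 6.0) -> pd.DataFrame:
    """Left-join measured nuclei onto the nearest ground-truth nucleus.

    ``measured`` needs ``row``/``col`` centroid columns; ``truth`` is the
    generator's per-nucleus table.  One-to-one greedy matching by distance;
    unmatched measured nuclei (merges, debris) are dropped.  Truth columns
    come back with a ``true_`` prefix.
    """
    if measured.empty or truth.empty:
        return pd.DataFrame()
    tree = cKDTree(truth[["row", "col"]].to_numpy())
    dist, idx = tree.query(measured[["row", "col"]].to_numpy())
    order = np.argsort(dist)
    taken: set = set()
    pairs = []
    for k in order:
        if dist[k] > max_dist_px or idx[k] in taken:
            continue
        taken.add(idx[k])
        pairs.append((k, idx[k], dist[k]))
    if not pairs:
        return pd.DataFrame()
    m_idx, t_idx, dists = map(np.asarray, zip(*pairs))
    left = measured.iloc[m_idx].reset_index(drop=True)
    right = truth.iloc[t_idx].reset_index(drop=True)
    right = right.rename(columns={c: f"true_{c}" for c in right.columns})
    out = pd.concat([left, right], axis=1)
    out["match_dist_px"] = dists
    return out
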