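"""Motion subpopulations by 1D k-means on per-track anomalous exponents.

Trajectories are classified into ``k = 2`` populations by k-means on their
fitted per-track α values, with k-means++ initialisation (centroid seeds
D²-sampled from the data points) and multiple restarts. Labels are ordered
so that population 0 has the smaller centroid (constrained motion, α < 1
on average) and population 1 the larger (directed motion). Classification
is run once per resolution regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["SubpopulationResult", "cluster_alpha", "subpop_shell_distribution"]


@dataclass
class SubpopulationResult:
    labels: np.ndarray  # population per input value, 0 = lower-α
    centroids: np.ndarray  # ascending mean α per population
    inertia: float


def cluster_alpha(
    alphas, k: int = 2, seed: int = 0, n_init: int = 10
) -> SubpopulationResult:
    """1D k-means (k-means++ init, ``n_init`` restarts, best objective kept).

    Raises ``ValueError`` with fewer than ``k`` distinct finite values.
    NaN entries are excluded from the fit and labelled -1.
    """
    x = np.asarray(alphas, dtype=float).ravel()
    finite = np.isfinite(x)
    vals = x[finite]
    if len(np.unique(vals)) < k:
        raise ValueError(f"need at least {k} distinct alpha values")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(vals.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = np.full(len(x), -1, dtype=int)
    labels[finite] = relabel[raw]
    return SubpopulationResult(
        labels=labels,
        centroids=np.sort(km.cluster_centers_.ravel()),
        inertia=float(km.inertia_),
    )


def subpop_shell_distribution(
    labels_by_track: dict[int, int], shell_of_track: dict[int, int], n_shells: int
) -> pd.DataFrame:
    """Per-shell counts and fractions of each motion population.

    Fractions are NaN in empty shells; within a populated shell they sum
    to 1.
    """
    pops = sorted({p for p in labels_by_track.values() if p >= 0})
    rows = []
    for s in range(1, n_shells + 1):
        ids = [tid for tid, sh in shell_of_track.items() if sh == s]
        counts = {p: sum(1 for t in ids if labels_by_track.get(t) == p) for p in pops}
        total = sum(counts.values())
        row = {"shell": s, "n_tracks": total}
        for p in pops:
            row[f"count_pop{p}"] = counts[p]
            row[f"frac_pop{p}"] = counts[p] / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("shell")
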