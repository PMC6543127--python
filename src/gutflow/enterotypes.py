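"""Community-type (enterotype) detection.

Samples are compared by the Jensen-Shannon distance between their genus
profiles (square root of the base-2 JS divergence, a metric bounded by
[0, 1]), partitioned around medoids (deterministic BUILD + SWAP), and the
cluster count chosen by the distance-based Calinski-Harabasz index.
The cluster-by-group association is tested with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .containers import AbundanceMatrix

__all__ = [
    "jsd_matrix",
    "pam",
    "ch_index",
    "select_k",
    "enterotype_association",
    "fisher_exact",
    "EnterotypeResult",
]


@dataclass
class EnterotypeResult:
    k_selected: int
    labels: pd.Series
    medoids: list[str]
    ch_curve: dict[int, float]
    dominant_taxon: dict[int, str] = field(default_factory=dict)
    contingency: pd.DataFrame | None = None
    fisher_p: float | None = None


def jsd_matrix(profiles: AbundanceMatrix) -> pd.DataFrame:
    """Pairwise Jensen-Shannon distance between sample columns.

    D(a,b) = sqrt(1/2 KL(a||m) + 1/2 KL(b||m)), m = (a+b)/2, logs base 2;
    zero-abundance terms contribute nothing.
    """
    values = profiles.values()
    if (values < 0).any():
        raise ValueError("negative abundances")
    n = values.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jensenshannon(values[:, i], values[:, j], base=2)
    np.fill_diagonal(d, 0.0)
    ids = profiles.sample_ids
    return pd.DataFrame(d, index=ids, columns=ids)


def _total_cost(d: np.ndarray, medoids: list[int]) -> float:
    return d[:, medoids].min(axis=1).sum()


def pam(distance: pd.DataFrame, k: int, seed: int = 0) -> tuple[pd.Series, list[str]]:
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic BUILD initialisation followed by greedy SWAP steps that
    apply the best cost-reducing (medoid, non-medoid) exchange until no
    improvement remains. Ties break toward the lowest sample index, so the
    result does not depend on ``seed`` (kept for API symmetry).
    Returns labels in 1..k plus the medoid sample ids.
    """
    d = distance.to_numpy(dtype=float)
    n = d.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    # BUILD: start from the 1-medoid minimiser, then greedy additions
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        best_gain, best_c = -np.inf, None
        for c in range(n):
            if c in medoids:
                continue
            gain = np.maximum(current - d[:, c], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_c = gain, c
        medoids.append(best_c)
    # SWAP
    cost = _total_cost(d, medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = cost - _total_cost(d, trial)
                if delta > best[0] + 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            cost -= best[0]
            improved = True
    medoids = sorted(medoids)
    assign = np.argmin(d[:, medoids], axis=1)
    labels = pd.Series(assign + 1, index=distance.index, name="enterotype")
    return labels, [distance.index[m] for m in medoids]


def ch_index(distance: pd.DataFrame, labels) -> float:
    """Distance-based Calinski-Harabasz index.

    Uses the standard sum-of-squared-distance decomposition:
    W = sum over clusters of (sum of squared within-cluster distances over
    unordered pairs) / cluster size; T is the analogue over all samples;
    CH = [(T - W)/(k - 1)] / [W/(n - k)].
    """
    d2 = distance.to_numpy(dtype=float) ** 2
    lab = np.asarray(labels)
    n = d2.shape[0]
    levels = np.unique(lab)
    k = len(levels)
    if k < 2:
        raise ValueError("CH requires at least 2 clusters")
    if k >= n:
        raise ValueError("CH undefined when every sample is its own cluster")
    total = d2.sum() / (2.0 * n)
    within = 0.0
    for g in levels:
        idx = np.where(lab == g)[0]
        if idx.size == 0:
            raise ValueError("empty cluster")
        within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    between = max(total - within, 0.0)
    if within == 0:
        return np.inf if between > 0 else 0.0
    return (between / (k - 1)) / (within / (n - k))


def select_k(
    distance: pd.DataFrame, k_range=range(2, 11), seed: int = 0
) -> EnterotypeResult:
    """Run PAM for each candidate k and keep the CH-maximising clustering."""
    n = distance.shape[0]
    ch_curve: dict[int, float] = {}
    results = {}
    for k in k_range:
        if k >= n:
            continue
        labels, medoids = pam(distance, k, seed=seed)
        ch_curve[k] = ch_index(distance, labels)
        results[k] = (labels, medoids)
    if not ch_curve:
        raise ValueError("no feasible k in range")
    k_best = max(ch_curve, key=lambda k: (ch_curve[k], -k))
    labels, medoids = results[k_best]
    return EnterotypeResult(
        k_selected=k_best, labels=labels, medoids=medoids, ch_curve=ch_curve
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test on a 2x2 table.

    Two-sided by the standard rule: sum hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's (1e-12 relative tolerance for ties).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        tf = np.asarray(table, dtype=float)
        if (tf < 0).any() or not np.allclose(tf, np.round(tf)):
            raise ValueError("table must hold nonnegative integers")
        t = np.round(tf).astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def enterotype_association(
    labels: pd.Series,
    meta: pd.DataFrame,
    genus_rel: AbundanceMatrix | None = None,
    case: str = "case",
    control: str = "control",
) -> EnterotypeResult:
    """Cluster-by-group contingency with Fisher (k=2) or chi-square (k>2) p,
    plus the dominant genus (highest mean relative abundance) per cluster."""
    groups = meta.loc[labels.index, "group"]
    contingency = pd.crosstab(labels, groups)
    k = contingency.shape[0]
    cols = [c for c in (control, case) if c in contingency.columns]
    contingency = contingency[cols + [c for c in contingency.columns if c not in cols]]
    if k == 2 and contingency.shape[1] == 2:
        p = fisher_exact(contingency.to_numpy())
    else:
        p = float(stats.chi2_contingency(contingency.to_numpy())[1])
    dominant: dict[int, str] = {}
    if genus_rel is not None:
        for cluster in contingency.index:
            members = labels.index[labels == cluster]
            means = genus_rel.data.loc[:, members].mean(axis=1)
            dominant[int(cluster)] = str(means.idxmax())
    return EnterotypeResult(
        k_selected=k,
        labels=labels,
        medoids=[],
        ch_curve={},
        dominant_taxon=dominant,
        contingency=contingency,
        fisher_p=p,
    )
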