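"""Alpha-diversity, richness, evenness, phylum-ratio statistics and
sample-accumulation rarefaction.

Shannon entropy is reported in nats by default (a ``base`` switch is
provided); Chao richness uses the bias-corrected Chao1 estimator, which
stays defined when no doubletons are observed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix
from .differential import wilcoxon_rank_sum

__all__ = [
    "shannon_index",
    "chao_richness",
    "pielou_evenness",
    "fb_ratio",
    "rarefaction",
    "compare_groups",
    "diversity_report",
]


def shannon_index(profile, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive entries.

    ``base=None`` gives natural log (nats); pass ``base=2`` for bits.
    """
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero profile")
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"profile must sum to 1, got {total:.6g}")
    h = float(stats.entropy(p))
    if base is not None:
        h /= np.log(base)
    return h


def chao_richness(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1)).

    F1/F2 are the numbers of features observed exactly once/twice; defined
    on integer counts only.
    """
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        cf = np.asarray(counts, dtype=float)
        if not np.allclose(cf, np.round(cf)):
            raise ValueError("Chao1 is defined on integer counts")
        c = np.round(cf).astype(int)
    if (c < 0).any():
        raise ValueError("negative counts")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def pielou_evenness(profile) -> float:
    """Pielou's J = H / ln S_obs; requires at least two detected taxa."""
    p = np.asarray(profile, dtype=float)
    s_obs = int((p > 0).sum())
    if s_obs < 2:
        raise ValueError("evenness undefined for fewer than 2 detected taxa")
    return shannon_index(p) / np.log(s_obs)


def fb_ratio(phylum_profile: pd.Series,
             firmicutes: str = "Firmicutes",
             bacteroidetes: str = "Bacteroidetes") -> float:
    """Firmicutes / Bacteroidetes abundance ratio (scale invariant)."""
    if firmicutes not in phylum_profile.index or bacteroidetes not in phylum_profile.index:
        raise ValueError("profile must contain both Firmicutes and Bacteroidetes")
    b = float(phylum_profile[bacteroidetes])
    if b == 0:
        raise ValueError("Bacteroidetes abundance is zero; ratio undefined")
    return float(phylum_profile[firmicutes]) / b


def rarefaction(
    m: AbundanceMatrix, iterations: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Sample-accumulation curve: expected distinct genes vs samples drawn.

    For each m in 1..N and each iteration, m samples are drawn with
    replacement and the union of genes with positive depth is counted; the
    curve is the mean over iterations. Returns a DataFrame with columns
    ``m``, ``mean_genes`` and ``sd_genes``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    presence = m.values() > 0
    n = presence.shape[1]
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    counts = np.empty((iterations, n))
    for it in range(iterations):
        drawn = rng.integers(0, n, size=n)
        cum = np.logical_or.accumulate(presence[:, drawn], axis=1)
        counts[it] = cum.sum(axis=0)
    return pd.DataFrame(
        {
            "m": np.arange(1, n + 1),
            "mean_genes": counts.mean(axis=0),
            "sd_genes": counts.std(axis=0, ddof=0),
        }
    )


def compare_groups(values, groups, test: str = "wilcoxon") -> tuple[float, float]:
    """Compare a per-sample statistic across groups.

    ``wilcoxon`` (two groups, delegates to the rank-sum test) or
    ``kruskal_wallis`` (two or more groups).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in levels]
    if test == "wilcoxon":
        if len(levels) != 2:
            raise ValueError("wilcoxon requires exactly two groups")
        return wilcoxon_rank_sum(samples[0], samples[1])
    if test == "kruskal_wallis":
        stat, p = stats.kruskal(*samples)
        return float(stat), float(p)
    raise ValueError(f"unknown test {test!r}")


def diversity_report(
    genus_rel: AbundanceMatrix,
    phylum_rel: AbundanceMatrix | None = None,
    gene_depth: AbundanceMatrix | None = None,
) -> pd.DataFrame:
    """Per-sample diversity summary.

    Shannon, Pielou and (when a phylum table is given) the F/B ratio are
    computed on the genus/phylum relative profiles; gene count and Chao
    richness on the gene table when given, with depths rounded to the
    nearest integer pseudo-count for the Chao estimator.
    """
    rows = {}
    gvals = genus_rel.values()
    rows["shannon"] = [shannon_index(gvals[:, j]) for j in range(gvals.shape[1])]
    rows["pielou"] = [pielou_evenness(gvals[:, j]) for j in range(gvals.shape[1])]
    if phylum_rel is not None:
        rows["fb_ratio"] = [
            fb_ratio(phylum_rel.data.iloc[:, j]) for j in range(phylum_rel.shape[1])
        ]
    if gene_depth is not None:
        depth = gene_depth.values()
        rows["gene_count"] = (depth > 0).sum(axis=0)
        pseudo = np.round(depth).astype(int)
        rows["chao"] = [chao_richness(pseudo[:, j]) for j in range(pseudo.shape[1])]
    return pd.DataFrame(rows, index=genus_rel.sample_ids)
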