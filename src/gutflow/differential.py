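"""Two-group differential abundance and the clinical summary tests.

The core recipe is the one ubiquitous in case-control metagenomics:
abundance/prevalence filter, per-feature two-sided Wilcoxon rank-sum test,
Benjamini-Hochberg adjustment across the tested features, and a call at
q < alpha with the direction given by the higher group mean. Clinical
summary tables are compared with a pooled two-sample t-test (from printed
summary statistics) and a Pearson chi-square without continuity correction.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix, group_masks
from .profiles_io import filter_features

__all__ = [
    "wilcoxon_rank_sum",
    "bh_adjust",
    "differential_features",
    "zscore_rows",
    "summary_ttest",
    "chi_square_2x2",
]

#: largest pooled sample size for which the exact permutation path is used
EXACT_LIMIT = 20


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    For pooled sample sizes up to 20 the p-value is computed by full
    enumeration of the permutation distribution of the rank sum, which is
    exact with or without ties. Larger samples use the normal approximation
    with tie and continuity corrections. Returns ``(U, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    u_stat, p = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    if n + m <= EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:n].sum()
        mu = n * (n + m + 1) / 2.0
        d_obs = abs(w_obs - mu)
        total = comb(n + m, n)
        hits = 0
        for idx in combinations(range(n + m), n):
            if abs(ranks[list(idx)].sum() - mu) >= d_obs - 1e-9:
                hits += 1
        return float(u_stat), hits / total
    return float(u_stat), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_features(
    m: AbundanceMatrix,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    min_mean: float = 1e-4,
    min_prevalence: int = 6,
    case: str = "case",
    control: str = "control",
    apply_filter: bool = True,
) -> pd.DataFrame:
    """Filtered Wilcoxon + BH differential-abundance table.

    Returns a DataFrame indexed by feature id with columns ``mean_case``,
    ``mean_control``, ``direction``, ``statistic``, ``p``, ``q`` and
    ``significant`` (q < alpha).
    """
    case_mask, control_mask = group_masks(meta, m.sample_ids, case, control)
    if case_mask.sum() < 2 or control_mask.sum() < 2:
        raise ValueError("need at least 2 samples per group")
    if apply_filter:
        m = filter_features(m, min_mean=min_mean, min_prevalence=min_prevalence)
    values = m.values()
    stats_u = np.empty(values.shape[0])
    pvals = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        stats_u[i], pvals[i] = wilcoxon_rank_sum(
            values[i, case_mask], values[i, control_mask]
        )
    qvals = bh_adjust(pvals) if pvals.size else pvals
    mean_case = values[:, case_mask].mean(axis=1) if values.size else np.array([])
    mean_control = values[:, control_mask].mean(axis=1) if values.size else np.array([])
    direction = np.where(mean_case >= mean_control, "case_enriched", "control_enriched")
    return pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_control,
            "direction": direction,
            "statistic": stats_u,
            "p": pvals,
            "q": qvals,
            "significant": qvals < alpha,
        },
        index=m.data.index,
    )


def zscore_rows(m: AbundanceMatrix, ddof: int = 0) -> pd.DataFrame:
    """Per-feature z-scores (subtract row mean, divide by row SD).

    Population SD (ddof=0) by default; constant rows map to all zeros.
    """
    values = m.values()
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=m.data.index, columns=m.data.columns)


def summary_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided two-sample t-test from summary statistics.

    Pooled-variance by default (df = n1+n2-2); ``equal_var=False`` gives
    Welch's test.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    return float(t), float(p)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    chi2, p = stats.chi2_contingency(t, correction=False)[:2]
    return float(chi2), float(p)
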