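"""Microbe-metabolite association.

Selected taxa are correlated with selected metabolites by Spearman's rank
correlation over the samples common to both assays; cells are annotated
with the conventional significance stars (* for p < 0.05, ** for p < 0.01,
on raw p-values, with a BH-adjusted matrix emitted alongside).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix, PeakTable
from .differential import bh_adjust

__all__ = ["spearman", "correlation_grid", "CorrelationGrid"]

#: maximum n for which the exact permutation p-value is used
EXACT_N = 9


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value is computed by exhaustive permutation for n <= 9 and by the
    t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector passed to spearman")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_N:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
        obs = abs(rxc @ ryc)
        hits = total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(rxc @ ryc[list(perm)]) >= obs - 1e-9 * denom:
                hits += 1
        return rho, hits / total
    return rho, float(stats.spearmanr(x, y)[1])


@dataclass
class CorrelationGrid:
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    stars: pd.DataFrame

    def edge_list(self, rho_min: float = 0.0) -> pd.DataFrame:
        rows = []
        for taxon in self.rho.index:
            for met in self.rho.columns:
                r = self.rho.loc[taxon, met]
                if abs(r) >= rho_min:
                    rows.append(
                        (taxon, met, r, self.p.loc[taxon, met],
                         self.q.loc[taxon, met], self.stars.loc[taxon, met])
                    )
        return pd.DataFrame(
            rows, columns=["taxon", "metabolite", "rho", "p", "q", "stars"]
        )


def correlation_grid(
    taxa: AbundanceMatrix,
    metabolites: PeakTable,
    taxa_selection=None,
    metabolite_selection=None,
) -> CorrelationGrid:
    """Spearman grid of selected taxa (rows) vs metabolites (columns).

    Computed on the intersection of the two sample sets; stars use raw
    p-value thresholds 0.05 (*) and 0.01 (**); a BH-adjusted q matrix over
    all grid cells is returned as well.
    """
    shared = [s for s in taxa.sample_ids if s in set(metabolites.sample_ids)]
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared samples between assays")
    t_rows = list(taxa_selection) if taxa_selection is not None else taxa.feature_ids
    m_rows = (
        list(metabolite_selection)
        if metabolite_selection is not None
        else metabolites.feature_ids
    )
    t_data = taxa.data.loc[t_rows, shared].to_numpy()
    m_data = metabolites.areas.loc[m_rows, shared].to_numpy()
    rho = np.empty((len(t_rows), len(m_rows)))
    p = np.empty_like(rho)
    for i in range(len(t_rows)):
        for j in range(len(m_rows)):
            rho[i, j], p[i, j] = spearman(t_data[i], m_data[j])
    q = bh_adjust(p.ravel()).reshape(p.shape)
    stars = np.where(p < 0.01, "**", np.where(p < 0.05, "*", ""))
    mk = lambda a: pd.DataFrame(a, index=t_rows, columns=m_rows)
    return CorrelationGrid(rho=mk(rho), p=mk(p), q=mk(q), stars=mk(stars))
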