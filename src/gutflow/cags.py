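"""Co-abundance gene groups (CAGs).

Marker genes (group-differential genes) are clustered by a deterministic
canopy procedure on the Pearson correlation of their depth profiles; a
cluster with more than 50 member genes is a CAG. CAG abundance is the
length-weighted mean gene depth; taxonomy is assigned from tracer-gene
alignment hits by identity/coverage thresholds (species: >=90% of genes at
>=95% nucleotide identity and >=70% query overlap; genus: >=80% of genes at
>=85% identity in both DNA and protein); group enrichment is scored by a
presence/absence odds ratio (case-enriched >2, case-depleted <0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .containers import AbundanceMatrix, group_masks
from .differential import bh_adjust, wilcoxon_rank_sum

__all__ = [
    "CAG",
    "marker_genes",
    "canopy_cluster",
    "cag_abundance",
    "assign_taxonomy",
    "odds_ratio_score",
    "cooccurrence_network",
]

#: a cluster must exceed this many genes to count as a CAG
MIN_CAG_SIZE = 50


@dataclass
class CAG:
    cag_id: str
    gene_ids: list[str]
    abundance: pd.Series | None = None
    taxon: str = "unassigned"
    level: str = "unassigned"
    odds_ratio: float | None = None
    enrichment: str = "neutral"
    extra: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def marker_genes(
    genes: AbundanceMatrix, meta: pd.DataFrame, alpha: float = 0.05,
    case: str = "case", control: str = "control",
) -> list[str]:
    """Genes whose depth differs between groups at BH q < alpha."""
    case_mask, control_mask = group_masks(meta, genes.sample_ids, case, control)
    values = genes.values()
    pvals = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        pvals[i] = wilcoxon_rank_sum(values[i, case_mask], values[i, control_mask])[1]
    qvals = bh_adjust(pvals)
    return [g for g, q in zip(genes.feature_ids, qvals) if q < alpha]


def _corr_to_profile(values: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``values`` with ``profile``."""
    vc = values - values.mean(axis=1, keepdims=True)
    pc = profile - profile.mean()
    denom = np.sqrt((vc ** 2).sum(axis=1) * (pc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = vc @ pc / denom
    return np.where(denom > 0, r, -np.inf)


def canopy_cluster(
    marker_profiles: AbundanceMatrix,
    r_threshold: float = 0.9,
    min_size: int = MIN_CAG_SIZE + 1,
    max_rounds: int = 20,
) -> tuple[list[list[str]], list[list[str]]]:
    """Deterministic canopy clustering of gene depth profiles.

    Seeds are taken in descending mean-abundance order (gene id breaks
    ties) over the unclustered pool. A canopy collects every pool gene with
    Pearson correlation >= ``r_threshold`` to the seed profile; the canopy
    profile is then re-centred to the member-wise median profile and
    membership re-evaluated until a fixed point (at most ``max_rounds``
    rounds). Members leave the pool. Returns ``(cags, small_clusters)``
    where CAGs have at least ``min_size`` genes.
    """
    if marker_profiles.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate profiles")
    values = marker_profiles.values()
    ids = np.array(marker_profiles.feature_ids)
    order = sorted(
        range(len(ids)), key=lambda i: (-values[i].mean(), ids[i])
    )
    in_pool = np.ones(len(ids), dtype=bool)
    cags: list[list[str]] = []
    small: list[list[str]] = []
    for seed in order:
        if not in_pool[seed]:
            continue
        profile = values[seed].copy()
        members = np.array([seed])
        for _ in range(max_rounds):
            r = _corr_to_profile(values, profile)
            new_members = np.where(in_pool & (r >= r_threshold))[0]
            if new_members.size == 0:
                break
            if new_members.size == members.size and (new_members == members).all():
                members = new_members
                break
            members = new_members
            profile = np.median(values[members], axis=0)
        cluster = sorted(ids[members])
        in_pool[members] = False
        if len(cluster) >= min_size:
            cags.append(cluster)
        else:
            small.append(cluster)
    return cags, small


def cag_abundance(
    gene_ids, gene_depths: AbundanceMatrix, gene_lengths: pd.Series
) -> pd.Series:
    """Length-weighted mean depth: sum(depth_g * L_g) / sum(L_g) per sample."""
    gene_ids = sorted(gene_ids)
    missing = [g for g in gene_ids if g not in gene_lengths.index]
    if missing:
        raise ValueError(f"missing gene lengths for {missing[:5]}")
    depths = gene_depths.data.loc[gene_ids]
    lengths = gene_lengths.loc[gene_ids].to_numpy(dtype=float)
    weighted = (depths.to_numpy() * lengths[:, None]).sum(axis=0) / lengths.sum()
    return pd.Series(weighted, index=gene_depths.sample_ids)


def assign_taxonomy(
    gene_ids,
    hits: pd.DataFrame,
    species_gene_frac: float = 0.90,
    species_nt_identity: float = 95.0,
    species_overlap: float = 0.70,
    genus_gene_frac: float = 0.80,
    genus_identity: float = 85.0,
) -> tuple[str, str]:
    """Tracer-gene taxonomy for a CAG from a filtered alignment-hit table.

    ``hits`` columns: gene_id, taxon, level ('species'/'genus'),
    nt_identity, aa_identity (percent), overlap (fraction of query).
    Candidates are ranked by (fraction of member genes mapped, mean
    nucleotide identity); species calls take precedence over genus calls.
    """
    members = set(gene_ids)
    n = len(members)
    if n == 0:
        raise ValueError("empty CAG")
    if hits.empty:
        return "unassigned", "unassigned"
    h = hits[hits["gene_id"].isin(members)]

    def best(level_hits: pd.DataFrame, frac_needed: float):
        candidates = []
        for taxon, sub in level_hits.groupby("taxon"):
            frac = sub["gene_id"].nunique() / n
            if frac >= frac_needed:
                candidates.append((frac, sub["nt_identity"].mean(), str(taxon)))
        if not candidates:
            return None
        return max(candidates)[2]

    sp_hits = h[
        (h["level"] == "species")
        & (h["nt_identity"] >= species_nt_identity)
        & (h["overlap"] >= species_overlap)
    ]
    sp = best(sp_hits, species_gene_frac)
    if sp is not None:
        return sp, "species"
    ge_hits = h[
        (h["level"] == "genus")
        & (h["nt_identity"] >= genus_identity)
        & (h["aa_identity"] >= genus_identity)
    ]
    ge = best(ge_hits, genus_gene_frac)
    if ge is not None:
        return ge, "genus"
    return "unassigned", "unassigned"


def odds_ratio_score(
    abundance: pd.Series,
    meta: pd.DataFrame,
    presence_threshold: float | str = 0.0,
    enriched_cutoff: float = 2.0,
    depleted_cutoff: float = 0.5,
    case: str = "case",
    control: str = "control",
) -> tuple[float, str]:
    """Presence/absence odds ratio of a CAG between groups.

    2x2 of presence (abundance > threshold) vs group; Haldane-Anscombe
    +0.5 on every cell when any cell is zero. ``presence_threshold`` may be
    the string ``"median"`` for a cohort-median split, useful when a CAG is
    detected in every sample. Odds ratio above ``enriched_cutoff`` is
    case-enriched, below ``depleted_cutoff`` case-depleted, else neutral.
    """
    case_mask, control_mask = group_masks(meta, abundance.index, case, control)
    if presence_threshold == "median":
        presence_threshold = float(np.median(abundance.to_numpy()))
    present = abundance.to_numpy() > presence_threshold
    a = float((present & case_mask).sum())
    b = float((~present & case_mask).sum())
    c = float((present & control_mask).sum())
    d = float((~present & control_mask).sum())
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    if oratio > enriched_cutoff:
        enrichment = "case_enriched"
    elif oratio < depleted_cutoff:
        enrichment = "case_depleted"
    else:
        enrichment = "neutral"
    return oratio, enrichment


def cooccurrence_network(
    features: AbundanceMatrix,
    rho_min: float = 0.5,
    alpha: float = 0.05,
    node_attrs: dict[str, dict] | None = None,
) -> nx.Graph:
    """Spearman co-occurrence network over feature rows.

    All pairwise Spearman correlations are computed, BH-adjusted across
    pairs, and edges kept when |rho| >= ``rho_min`` and q < ``alpha``.
    Constant features are excluded with a warning.
    """
    if features.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    values = features.values()
    ids = list(features.feature_ids)
    keep = values.std(axis=1) > 0
    if not keep.all():
        dropped = [i for i, k in zip(ids, keep) if not k]
        warnings.warn(f"excluding constant features: {dropped[:5]}")
        values = values[keep]
        ids = [i for i, k in zip(ids, keep) if k]
    g = nx.Graph()
    for i, fid in enumerate(ids):
        g.add_node(fid, **(node_attrs or {}).get(fid, {}))
    pairs, rhos, pvals = [], [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rho, p = stats.spearmanr(values[i], values[j])
            pairs.append((ids[i], ids[j]))
            rhos.append(rho)
            pvals.append(p)
    if pairs:
        qvals = bh_adjust(np.asarray(pvals))
        for (u, v), rho, q in zip(pairs, rhos, qvals):
            if abs(rho) >= rho_min and q < alpha:
                g.add_edge(u, v, rho=float(rho), q=float(q))
    return g


def build_cags(
    genes: AbundanceMatrix,
    gene_lengths: pd.Series,
    hits: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    r_threshold: float = 0.9,
    presence_threshold: float | str = "median",
) -> tuple[list[CAG], list[list[str]]]:
    """Full CAG stage: markers -> canopy -> abundance/taxonomy/odds ratio."""
    markers = marker_genes(genes, meta, alpha=alpha)
    if len(markers) <= MIN_CAG_SIZE:
        return [], []
    clusters, small = canopy_cluster(
        genes.subset_features(markers), r_threshold=r_threshold
    )
    cags = []
    for i, cluster in enumerate(clusters, start=1):
        ab = cag_abundance(cluster, genes, gene_lengths)
        taxon, level = assign_taxonomy(cluster, hits)
        oratio, enr = odds_ratio_score(ab, meta, presence_threshold=presence_threshold)
        cags.append(
            CAG(
                cag_id=f"CAG{i:03d}",
                gene_ids=list(cluster),
                abundance=ab,
                taxon=taxon,
                level=level,
                odds_ratio=oratio,
                enrichment=enr,
            )
        )
    return cags, small
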