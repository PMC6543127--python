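"""Synthetic case-control study generator with planted ground truth.

Emulates the shape of a 50 + 50 case-control gut-metagenome +
LC-MS-metabolome cohort so every pipeline stage can be exercised and
checked against known structure:

* a gene-depth matrix with planted co-abundant gene blocks (shared
  lognormal latent factor per block, gene-specific gain and noise tuned to
  a target pairwise Pearson correlation), a subset of blocks carrying a
  group fold-change;
* genus/species/phylum relative-abundance tables drawn from two Dirichlet
  mixtures, one dominated by *Bacteroides* and one by *Prevotella*, with
  configurable enterotype proportions per group and planted differential
  genera;
* serum/feces peak-area tables in both ionisation modes with planted
  differential compounds (concordant and discordant across compartments)
  and metabolites linearly coupled to named genera;
* a clinical covariate table with group-specific normal/lognormal draws.

All generators are bit-reproducible under the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, GroundTruth, PeakTable
from . import profiles_io

__all__ = [
    "SimulationConfig",
    "generate_gene_study",
    "generate_taxon_study",
    "generate_metabolome_study",
    "generate_clinical_table",
    "GENUS_PHYLUM",
    "write_study",
]

#: fixed genus -> phylum map used by the taxon generator
GENUS_PHYLUM = {
    "Bacteroides": "Bacteroidetes",
    "Prevotella": "Bacteroidetes",
    "Alistipes": "Bacteroidetes",
    "Parabacteroides": "Bacteroidetes",
    "Faecalibacterium": "Firmicutes",
    "Blautia": "Firmicutes",
    "Streptococcus": "Firmicutes",
    "Ruminococcus": "Firmicutes",
    "Dorea": "Firmicutes",
    "Veillonella": "Firmicutes",
    "Enterococcus": "Firmicutes",
    "Coprobacillus": "Firmicutes",
    "Roseburia": "Firmicutes",
    "Oscillibacter": "Firmicutes",
    "Bifidobacterium": "Actinobacteria",
    "Escherichia": "Proteobacteria",
}

#: genera pushed up (+1) or down (-1) in cases by the taxon generator
DIFFERENTIAL_GENERA = {
    "Streptococcus": 1,
    "Blautia": 1,
    "Veillonella": 1,
    "Faecalibacterium": -1,
    "Alistipes": -1,
}


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters (defaults mirror the cohort design:
    50 cases + 50 controls, 3 planted 60-gene blocks at correlation 0.95,
    82%/18% vs 50%/50% enterotype mixing, 4-fold planted effects)."""

    n_case: int = 50
    n_control: int = 50
    n_genes: int = 400
    n_planted_cags: int = 3
    cag_size_range: tuple[int, int] = (60, 60)
    small_block_size: int = 40
    within_cag_correlation: float = 0.95
    n_genera: int = 16
    n_species_per_genus: int = 2
    enterotype_mix: dict = field(
        default_factory=lambda: {"case": 0.82, "control": 0.5}
    )
    effect_size: float = 4.0
    noise_sd: float = 1.0
    n_metabolites: int = 150
    n_shared_compounds: int = 27
    n_concordant: int = 16
    n_extra_shared_null: int = 13
    metabolite_effect: float = 3.0
    metabolite_noise_sd: float = 0.3
    linkage_strength: float = 0.8
    n_linked_metabolites: int = 5
    hit_fraction: float = 0.95
    hit_nt_identity: float = 97.0
    hit_overlap: float = 0.85
    n_differential_genera: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_genes", "n_genera",
                     "n_metabolites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.within_cag_correlation <= 1.0:
            raise ValueError("within_cag_correlation must be in [0, 1]")
        for g, frac in self.enterotype_mix.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"enterotype_mix[{g!r}] must be in [0, 1]")
        lo, hi = self.cag_size_range
        if lo > hi or lo < 1:
            raise ValueError("invalid cag_size_range")
        if hi >= self.n_genes:
            raise ValueError("cag_size_range upper bound must be < n_genes")
        planted = self.n_planted_cags * hi + max(self.small_block_size, 0)
        if planted > self.n_genes:
            raise ValueError(
                f"planted blocks need {planted} genes but n_genes={self.n_genes}"
            )
        if self.noise_sd < 0 or self.metabolite_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.n_concordant > self.n_shared_compounds:
            raise ValueError("n_concordant cannot exceed n_shared_compounds")

    def sample_ids(self) -> list[str]:
        return [f"case_{i + 1:03d}" for i in range(self.n_case)] + [
            f"control_{i + 1:03d}" for i in range(self.n_control)
        ]

    def metadata(self) -> pd.DataFrame:
        ids = self.sample_ids()
        groups = ["case"] * self.n_case + ["control"] * self.n_control
        return pd.DataFrame({"group": groups}, index=pd.Index(ids, name="sample_id"))


def _block_depths(rng, factor: np.ndarray, size: int, correlation: float) -> np.ndarray:
    """Depth profiles for one co-abundant block.

    Each gene is ``gain * (factor + noise)`` with the noise variance set to
    var(factor) * (1 - r) / r so the expected pairwise Pearson correlation
    equals ``r``. r = 1 yields exact scalar multiples of the factor.
    """
    gains = rng.lognormal(0.0, 0.3, size=size)
    if correlation >= 1.0:
        block = np.outer(gains, factor)
    else:
        var_f = factor.var()
        sd_e = np.sqrt(var_f * (1.0 - correlation) / max(correlation, 1e-6))
        noise = rng.normal(0.0, sd_e, size=(size, factor.size))
        block = gains[:, None] * np.clip(factor[None, :] + noise, 0.0, None)
    return block


def generate_gene_study(config: SimulationConfig):
    """Gene-depth matrix with planted CAG blocks, lengths, alignment hits.

    Returns ``(depths, gene_lengths, hit_table, metadata, ground_truth)``.
    Planted blocks alternate case-enriched / case-depleted fold changes of
    ``effect_size``; one sub-threshold block of ``small_block_size`` genes
    (if positive) is planted to exercise the >50-gene CAG rule.
    """
    rng = np.random.default_rng(config.seed)
    meta = config.metadata()
    ids = config.sample_ids()
    n = len(ids)
    case_mask = (meta["group"] == "case").to_numpy()

    truth = GroundTruth()
    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    hit_rows: list[dict] = []
    gene_counter = 0

    def new_ids(k):
        nonlocal gene_counter
        out = [f"gene_{gene_counter + i + 1:05d}" for i in range(k)]
        gene_counter += k
        return out

    block_sizes = [
        int(rng.integers(config.cag_size_range[0], config.cag_size_range[1] + 1))
        for _ in range(config.n_planted_cags)
    ]
    if config.small_block_size > 0:
        block_sizes.append(config.small_block_size)
    gene_sign: dict[str, int] = {}
    for b, size in enumerate(block_sizes):
        is_small = config.small_block_size > 0 and b == len(block_sizes) - 1
        block_name = "block_small" if is_small else f"block_{b + 1}"
        factor = rng.lognormal(1.0, 1.0, size=n)
        sign = 1 if b % 2 == 0 else -1
        if config.effect_size > 0 and config.effect_size != 1.0:
            fold = config.effect_size if sign > 0 else 1.0 / config.effect_size
            factor = factor * np.where(case_mask, fold, 1.0)
        else:
            sign = 0
        block = _block_depths(rng, factor, size, config.within_cag_correlation)
        ids_b = new_ids(size)
        gene_rows.append(block)
        gene_ids.extend(ids_b)
        for g in ids_b:
            truth.cag_membership[g] = block_name
            if sign != 0:
                gene_sign[g] = sign
        # tracer-gene hits against one synthetic genome per block
        n_hit = int(round(config.hit_fraction * size))
        hit_genes = list(rng.choice(ids_b, size=n_hit, replace=False))
        species = f"Species_{block_name}"
        genus = f"Genus_{block_name}"
        for g in hit_genes:
            nt = float(rng.uniform(config.hit_nt_identity - 1,
                                   config.hit_nt_identity + 1))
            aa = float(rng.uniform(config.hit_nt_identity - 2,
                                   config.hit_nt_identity + 1))
            ov = float(rng.uniform(config.hit_overlap - 0.05,
                                   min(config.hit_overlap + 0.1, 1.0)))
            hit_rows.append(dict(gene_id=g, taxon=species, level="species",
                                 nt_identity=nt, aa_identity=aa, overlap=ov))
            hit_rows.append(dict(gene_id=g, taxon=genus, level="genus",
                                 nt_identity=nt, aa_identity=aa, overlap=ov))

    n_background = config.n_genes - gene_counter
    if n_background > 0:
        ids_bg = new_ids(n_background)
        mu = rng.normal(0.5, 1.0, size=n_background)
        bg = rng.lognormal(mu[:, None], max(config.noise_sd, 1e-12),
                           size=(n_background, n))
        gene_rows.append(bg)
        gene_ids.extend(ids_bg)
        # sparse, low-identity decoy hits on a third of the background
        decoys = rng.choice(ids_bg, size=max(n_background // 3, 1), replace=False)
        for g in decoys:
            hit_rows.append(dict(
                gene_id=g,
                taxon=f"Species_decoy_{int(rng.integers(1, 6))}",
                level="species",
                nt_identity=float(rng.uniform(70, 90)),
                aa_identity=float(rng.uniform(60, 85)),
                overlap=float(rng.uniform(0.3, 0.65)),
            ))

    depths = AbundanceMatrix(
        pd.DataFrame(np.vstack(gene_rows),
                     index=pd.Index(gene_ids, name="feature_id"), columns=ids),
        kind="depth",
    )
    lengths = pd.Series(
        rng.integers(300, 3001, size=len(gene_ids)),
        index=pd.Index(gene_ids, name="gene_id"), name="length",
    )
    hits = pd.DataFrame(
        hit_rows,
        columns=["gene_id", "taxon", "level", "nt_identity", "aa_identity", "overlap"],
    )
    truth.differential_features["gene"] = gene_sign
    return depths, lengths, hits, meta, truth


def _genus_names(config: SimulationConfig) -> list[str]:
    names = list(GENUS_PHYLUM)
    phyla = ["Firmicutes", "Bacteroidetes"]
    i = 0
    while len(names) < config.n_genera:
        names.append(f"Genus_{i + 1:03d}")
        GENUS_PHYLUM.setdefault(f"Genus_{i + 1:03d}", phyla[i % 2])
        i += 1
    return names[: config.n_genera]


def generate_taxon_study(config: SimulationConfig):
    """Genus/species/phylum relative-abundance tables with two planted
    enterotypes and differential genera.

    Genus profiles are Dirichlet draws; enterotype 1 inflates the
    *Bacteroides* mass, enterotype 2 the *Prevotella* mass. Per-group
    enterotype counts are the rounded ``enterotype_mix`` fractions, so the
    default yields 41/9 cases and 25/25 controls in enterotypes 1/2.
    Returns ``({"genus":…, "species":…, "phylum":…}, metadata, truth)``.
    """
    if config.n_genera < 2:
        raise ValueError("need at least 2 genera")
    rng = np.random.default_rng(config.seed + 1)
    meta = config.metadata()
    ids = config.sample_ids()
    genera = _genus_names(config)
    base = np.array([5.0 / (i + 1) for i in range(len(genera))])
    alphas = pd.Series(base, index=genera)

    truth = GroundTruth()
    # deterministic per-group enterotype counts, shuffled over sample order
    labels = {}
    for group, n_g in (("case", config.n_case), ("control", config.n_control)):
        frac = config.enterotype_mix.get(group, 0.5)
        n_et1 = int(round(frac * n_g))
        group_ids = [s for s in ids if meta.loc[s, "group"] == group]
        order = rng.permutation(n_g)
        for rank, s in zip(order, group_ids):
            labels[s] = 1 if rank < n_et1 else 2
    truth.enterotype_label = labels

    genus_sign = {g: s for g, s in DIFFERENTIAL_GENERA.items() if g in genera}
    # beyond the named genera, further planted effects alternate sign over
    # the generic genera (keeps the net compositional shift small)
    extras = [g for g in genera if g.startswith("Genus_")]
    for i, g in enumerate(extras):
        if len(genus_sign) >= config.n_differential_genera:
            break
        genus_sign[g] = 1 if i % 2 == 0 else -1
    truth.differential_features["genus"] = genus_sign

    profiles = np.empty((len(genera), len(ids)))
    for j, s in enumerate(ids):
        a = alphas.copy()
        if labels[s] == 1:
            a["Bacteroides"] += 40.0
        else:
            a["Prevotella"] += 40.0
        if meta.loc[s, "group"] == "case" and config.effect_size not in (0, 1.0):
            for g, sign in genus_sign.items():
                a[g] = a[g] * config.effect_size if sign > 0 else a[g] / config.effect_size
        profiles[:, j] = rng.dirichlet(a.to_numpy())
    genus = AbundanceMatrix(
        pd.DataFrame(profiles, index=pd.Index(genera, name="feature_id"), columns=ids),
        kind="relative",
    )

    # fixed within-genus species split
    split = rng.beta(5, 5, size=len(genera))
    sp_rows, sp_ids = [], []
    for i, g in enumerate(genera):
        for k in range(config.n_species_per_genus):
            if config.n_species_per_genus == 1:
                w = 1.0
            elif k == 0:
                w = split[i]
            else:
                w = (1 - split[i]) / (config.n_species_per_genus - 1)
            sp_rows.append(profiles[i] * w)
            sp_ids.append(f"{g} species_{k + 1}")
    species = AbundanceMatrix(
        pd.DataFrame(np.array(sp_rows), index=pd.Index(sp_ids, name="feature_id"),
                     columns=ids),
        kind="relative",
    )

    phylum_map = pd.Series({g: GENUS_PHYLUM[g] for g in genera})
    phyl = genus.data.groupby(phylum_map).sum().sort_index()
    phylum = AbundanceMatrix(phyl, kind="relative")
    return {"genus": genus, "species": species, "phylum": phylum}, meta, truth


def generate_metabolome_study(config: SimulationConfig, taxon_study=None):
    """Serum/feces x ES+/ES- peak tables with planted effects and
    taxon-coupled metabolites.

    ``n_shared_compounds`` named compounds are differential in both
    compartments, ``n_concordant`` of them with the same fold-change sign;
    ``n_extra_shared_null`` shared names carry no effect. A further
    ``n_linked_metabolites`` serum ES+ features are multiplicatively coupled
    to planted differential genera. Returns ``(tables, truth)`` where
    ``tables[("serum", "ES+")]`` etc. are :class:`PeakTable`.
    """
    rng = np.random.default_rng(config.seed + 2)
    meta = config.metadata()
    ids = config.sample_ids()
    case_mask = (meta["group"] == "case").to_numpy()
    genus = taxon_study[0]["genus"] if taxon_study is not None else None
    if genus is not None and list(genus.sample_ids) != ids:
        raise ValueError("taxon study and metabolome study sample sets differ")

    n_shared = config.n_shared_compounds
    n_conc = config.n_concordant
    n_null_shared = config.n_extra_shared_null
    shared_names = [f"Compound_{i + 1:04d}" for i in range(n_shared)]
    null_shared = [f"Compound_{i + 1:04d}" for i in range(n_shared, n_shared + n_null_shared)]
    # fold-change sign plan per compartment
    signs = {}
    for i, name in enumerate(shared_names):
        s_serum = 1 if i % 2 == 0 else -1
        s_feces = s_serum if i < n_conc else -s_serum
        signs[name] = {"serum": s_serum, "feces": s_feces}

    genus_sign = dict(DIFFERENTIAL_GENERA)
    linked = []
    if genus is not None and config.n_linked_metabolites > 0:
        link_taxa = [g for g in genus_sign if g in genus.feature_ids]
        for i in range(config.n_linked_metabolites):
            linked.append((link_taxa[i % len(link_taxa)], f"Linked_{i + 1:03d}"))

    tables = {}
    truth = GroundTruth()
    truth.taxon_metabolite_links = [
        (t, c, config.linkage_strength) for t, c in linked
    ]
    diff_record: dict[str, int] = {}
    for compartment in ("serum", "feces"):
        for mode in ("ES+", "ES-"):
            n_feat = config.n_metabolites
            fid_prefix = f"{compartment[:2]}_{'pos' if mode == 'ES+' else 'neg'}"
            feature_ids = [f"{fid_prefix}_{i + 1:04d}" for i in range(n_feat)]
            compounds = [""] * n_feat
            # shared (planted) compounds live in ES+ of both compartments;
            # a copy of each also appears in ES- with a weaker effect so the
            # lower-p mode-merge rule has real work to do
            planted = shared_names + null_shared
            for i, name in enumerate(planted):
                compounds[i] = name
            for i, (_, name) in enumerate(linked):
                if compartment == "serum":
                    compounds[len(planted) + i] = name
            mu = rng.normal(10.0, 1.0, size=n_feat)
            areas = rng.lognormal(
                mu[:, None], max(config.metabolite_noise_sd, 1e-12),
                size=(n_feat, len(ids)),
            )
            for i, name in enumerate(planted):
                if name in signs:
                    sign = signs[name][compartment]
                    fold = config.metabolite_effect if sign > 0 else 1.0 / config.metabolite_effect
                    if mode == "ES-":
                        fold = fold ** 0.5  # weaker in the minor mode
                    areas[i, case_mask] *= fold
                    diff_record[f"{compartment}:{name}"] = sign
            if compartment == "serum" and genus is not None:
                z = genus.data.loc[:, ids]
                for i, (taxon, name) in enumerate(linked):
                    row = len(planted) + i
                    x = z.loc[taxon].to_numpy()
                    xs = (x - x.mean()) / (x.std() + 1e-12)
                    areas[row] *= np.exp(config.linkage_strength * xs)
            pmeta = pd.DataFrame(
                {
                    "compound": compounds,
                    "mode": mode,
                    "compartment": compartment,
                    "rt_min": rng.uniform(0.5, 15.0, size=n_feat),
                    "mass_da": rng.uniform(80.0, 800.0, size=n_feat),
                },
                index=pd.Index(feature_ids, name="feature_id"),
            )
            tables[(compartment, mode)] = PeakTable(
                meta=pmeta,
                areas=pd.DataFrame(areas, index=pmeta.index, columns=ids),
            )
    truth.differential_features["metabolite"] = diff_record
    return tables, truth


def generate_cag_feature_study(
    config: SimulationConfig,
    n_informative: int = 10,
    n_features: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Samples x features table of CAG-abundance-shaped profiles for
    discrimination tests: ``n_informative`` features carry the configured
    group fold change (alternating direction) on a lognormal between-subject
    baseline, the rest are noise. Returns ``(X, metadata)``.
    """
    rng = np.random.default_rng(config.seed + 4)
    meta = config.metadata()
    case_mask = (meta["group"] == "case").to_numpy()
    cols = {}
    for i in range(n_features):
        base = rng.lognormal(1.0, 1.0, size=len(meta))
        if i < n_informative and config.effect_size not in (0, 1.0):
            fold = config.effect_size if i % 2 == 0 else 1.0 / config.effect_size
            base = base * np.where(case_mask, fold, 1.0)
        cols[f"cag_{i + 1:04d}"] = base
    return pd.DataFrame(cols, index=meta.index), meta


#: Table-1-style generator parameters: column -> (distribution, case params,
#: control params); normal params are (mean, sd), lognormal (log-mean, log-sd),
#: binary the success probability.
CLINICAL_LAYOUT = {
    "age": ("normal", (64.0, 9.0), (54.0, 6.0)),
    "sex_male": ("binary", 0.64, 0.82),
    "bmi": ("normal", (26.4, 3.2), (25.1, 3.0)),
    "total_cholesterol": ("normal", (4.13, 1.05), (4.82, 0.96)),
    "triglyceride": ("lognormal", (0.30, 0.45), (0.10, 0.50)),
    "ldl_cholesterol": ("normal", (2.35, 0.80), (2.40, 0.70)),
    "fasting_glucose": ("lognormal", (1.62, 0.15), (1.62, 0.12)),
    "creatinine": ("normal", (69.0, 14.0), (72.0, 18.0)),
}


def generate_clinical_table(config: SimulationConfig,
                            layout: dict = CLINICAL_LAYOUT) -> pd.DataFrame:
    """Sample metadata with group plus clinical covariates drawn from
    group-specific distributions; deterministic under the config seed."""
    rng = np.random.default_rng(config.seed + 3)
    meta = config.metadata()
    case_mask = (meta["group"] == "case").to_numpy()
    n = len(meta)
    for col, (dist, case_par, control_par) in layout.items():
        vals = np.empty(n)
        for mask, par in ((case_mask, case_par), (~case_mask, control_par)):
            k = int(mask.sum())
            if dist == "normal":
                vals[mask] = rng.normal(par[0], par[1], size=k)
            elif dist == "lognormal":
                vals[mask] = rng.lognormal(par[0], par[1], size=k)
            elif dist == "binary":
                vals[mask] = rng.binomial(1, par, size=k)
            else:
                raise ValueError(f"unknown distribution {dist!r}")
        meta[col] = vals
    return meta


def write_study(config: SimulationConfig, out_dir) -> dict:
    """Generate every layer and write the TSV/JSON bundle to ``out_dir``.

    Returns a manifest of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    depths, lengths, hits, meta, gene_truth = generate_gene_study(config)
    taxon_tables, _, taxon_truth = generate_taxon_study(config)
    met_tables, met_truth = generate_metabolome_study(
        config, (taxon_tables, meta, taxon_truth)
    )
    clinical = generate_clinical_table(config)

    manifest = {}
    profiles_io.write_matrix(depths, out / "genes.tsv")
    manifest["genes"] = "genes.tsv"
    lengths.to_frame().to_csv(out / "gene_lengths.tsv", sep="\t")
    manifest["gene_lengths"] = "gene_lengths.tsv"
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    manifest["hits"] = "hits.tsv"
    for rank, m in taxon_tables.items():
        profiles_io.write_matrix(m, out / f"{rank}.tsv")
        manifest[rank] = f"{rank}.tsv"
    for (compartment, mode), table in met_tables.items():
        tag = f"{compartment}_{'pos' if mode == 'ES+' else 'neg'}"
        joined = pd.concat([table.meta, table.areas], axis=1)
        joined.to_csv(out / f"metabolome_{tag}.tsv", sep="\t",
                      index_label="feature_id")
        manifest[f"metabolome_{tag}"] = f"metabolome_{tag}.tsv"
    profiles_io.write_metadata(clinical, out / "metadata.tsv")
    manifest["metadata"] = "metadata.tsv"

    truth = {
        "gene": gene_truth.to_dict(),
        "taxon": taxon_truth.to_dict(),
        "metabolome": met_truth.to_dict(),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    manifest["ground_truth"] = "ground_truth.json"
    (out / "config.json").write_text(json.dumps(asdict(config), indent=1))
    manifest["config"] = "config.json"
    return manifest


def read_peak_table(path) -> PeakTable:
    """Read a metabolome TSV written by :func:`write_study`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = list(PeakTable.META_COLUMNS)
    meta = df[meta_cols].copy()
    meta["compound"] = meta["compound"].fillna("").astype(str)
    areas = df.drop(columns=meta_cols).astype(float)
    return PeakTable(meta=meta, areas=areas)
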