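"""End-to-end orchestration over a study directory.

``run_all`` chains the analysis stages — ecology, enterotypes,
differential abundance, CAGs, discrimination, metabolomics, integration —
over the TSV bundle produced by :func:`gutflow.simulate.write_study` (or
user data in the same layout), writing per-stage artifacts and a
machine-readable ``summary.json`` per stage plus a run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    cags,
    classifier,
    differential,
    ecology,
    enterotypes,
    integration,
    metabolomics,
    profiles_io,
)
from .containers import AbundanceMatrix
from .simulate import read_peak_table

log = logging.getLogger("gutflow")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Paths, stage toggles, and tunables for a pipeline run."""

    study_dir: str = "."
    out_dir: str = "gutflow_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: [
        "ecology", "enterotypes", "differential", "cags",
        "classifier", "metabolomics", "integration",
    ])
    # stage tunables (defaults are the pipeline's standard settings)
    alpha: float = 0.05
    min_mean: float = 1e-4
    min_prevalence: int = 6
    rarefaction_iterations: int = 100
    k_max: int = 10
    canopy_r: float = 0.9
    or_enriched: float = 2.0
    or_depleted: float = 0.5
    train_fraction: float = 0.8
    cv_trials: int = 5
    cv_folds: int = 10
    n_trees: int = 500
    vip_cutoff: float = 1.0
    p_cutoff: float = 0.05
    pls_components: int = 2
    rho_min: float = 0.5
    n_top_taxa: int = 10
    n_top_metabolites: int = 16

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_inputs(self) -> None:
        study = Path(self.study_dir)
        needed = ["metadata.tsv"]
        if set(self.stages) & {"ecology", "enterotypes", "differential",
                               "integration"}:
            needed.append("genus.tsv")
        if "ecology" in self.stages:
            needed += ["phylum.tsv", "genes.tsv"]
        if set(self.stages) & {"cags", "classifier"}:
            needed += ["genes.tsv", "gene_lengths.tsv", "hits.tsv"]
        if set(self.stages) & {"metabolomics", "integration"}:
            needed += [f"metabolome_{c}_{m}.tsv"
                       for c in ("serum", "feces") for m in ("pos", "neg")]
        missing = [n for n in dict.fromkeys(needed) if not (study / n).exists()]
        if missing:
            raise FileNotFoundError(
                f"study dir {study} is missing inputs: {missing}"
            )


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray,)):
        return x.tolist()
    if isinstance(x, (pd.Series,)):
        return x.to_dict()
    raise TypeError(f"not JSON serialisable: {type(x)}")


def run_all(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the run summary."""
    config.validate_inputs()
    study = Path(config.study_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = profiles_io.read_metadata(study / "metadata.tsv")
    summary: dict = {"seed": config.seed, "stages": {}}

    state: dict = {}
    for stage in config.stages:
        log.info("running stage %s", stage)
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            runner = _STAGES[stage]
        except KeyError:
            raise ValueError(f"unknown stage {stage!r}") from None
        stage_summary = runner(config, study, stage_dir, meta, state)
        _dump(stage_summary, stage_dir / "summary.json")
        summary["stages"][stage] = stage_summary
    _dump({"config": asdict(config)}, out / "run_log.json")
    _dump(summary, out / "summary.json")
    return summary


def _genus(config, study, state) -> AbundanceMatrix:
    if "genus" not in state:
        state["genus"] = profiles_io.read_matrix(study / "genus.tsv", kind="relative")
    return state["genus"]


def _genes(config, study, state):
    if "genes" not in state:
        state["genes"] = profiles_io.read_matrix(study / "genes.tsv", kind="depth")
    return state["genes"]


def _stage_ecology(config, study, stage_dir, meta, state):
    genus = _genus(config, study, state)
    phylum = profiles_io.read_matrix(study / "phylum.tsv", kind="relative")
    genes = _genes(config, study, state)
    report = ecology.diversity_report(genus, phylum, genes)
    report.to_csv(stage_dir / "diversity.tsv", sep="\t", index_label="sample_id")
    curve = ecology.rarefaction(
        genes, iterations=config.rarefaction_iterations, seed=config.seed
    )
    curve.to_csv(stage_dir / "rarefaction.tsv", sep="\t", index=False)
    groups = meta.loc[report.index, "group"].to_numpy()
    tests = {}
    for col in report.columns:
        stat, p = ecology.compare_groups(report[col].to_numpy(), groups,
                                         test="wilcoxon")
        tests[col] = {"statistic": stat, "p": p}
    return {"group_tests": tests,
            "saturation_genes": float(curve["mean_genes"].iloc[-1])}


def _stage_enterotypes(config, study, stage_dir, meta, state):
    genus = _genus(config, study, state)
    filtered = profiles_io.filter_features(
        genus, min_mean=config.min_mean, min_prevalence=config.min_prevalence
    )
    renorm = profiles_io.relative_abundance(
        AbundanceMatrix.unchecked(filtered.data, "depth")
    )
    dist = enterotypes.jsd_matrix(renorm)
    result = enterotypes.select_k(
        dist, k_range=range(2, config.k_max + 1), seed=config.seed
    )
    assoc = enterotypes.enterotype_association(result.labels, meta, genus)
    result.labels.to_frame().to_csv(stage_dir / "labels.tsv", sep="\t",
                                    index_label="sample_id")
    pd.Series(result.ch_curve, name="CH").to_csv(
        stage_dir / "ch_curve.tsv", sep="\t", index_label="k"
    )
    state["enterotype_labels"] = result.labels
    return {
        "k_selected": result.k_selected,
        "ch_curve": {str(k): v for k, v in result.ch_curve.items()},
        "medoids": result.medoids,
        "contingency": {str(k): v for k, v in
                        assoc.contingency.to_dict().items()},
        "fisher_p": assoc.fisher_p,
        "dominant_taxon": {str(k): v for k, v in assoc.dominant_taxon.items()},
    }


def _stage_differential(config, study, stage_dir, meta, state):
    genus = _genus(config, study, state)
    table = differential.differential_features(
        genus, meta, alpha=config.alpha,
        min_mean=config.min_mean, min_prevalence=config.min_prevalence,
    )
    table.to_csv(stage_dir / "differential_genera.tsv", sep="\t",
                 index_label="feature_id")
    sig = table.index[table["significant"]]
    if len(sig):
        z = differential.zscore_rows(genus.subset_features(sig))
        z.to_csv(stage_dir / "zscores.tsv", sep="\t", index_label="feature_id")
    clinical = {}
    numeric = [c for c in meta.columns
               if c != "group" and pd.api.types.is_numeric_dtype(meta[c])]
    case = meta[meta["group"] == "case"]
    control = meta[meta["group"] == "control"]
    for col in numeric:
        if set(meta[col].dropna().unique()) <= {0, 1}:
            tab = [[int(case[col].sum()), int((1 - case[col]).sum())],
                   [int(control[col].sum()), int((1 - control[col]).sum())]]
            chi2, p = differential.chi_square_2x2(tab)
            clinical[col] = {"test": "chi_square", "statistic": chi2, "p": p}
        else:
            t, p = differential.summary_ttest(
                case[col].mean(), case[col].std(ddof=1), len(case),
                control[col].mean(), control[col].std(ddof=1), len(control),
            )
            clinical[col] = {"test": "pooled_t", "statistic": t, "p": p}
    state["differential_genera"] = table
    return {"n_tested": int(len(table)),
            "n_significant": int(table["significant"].sum()),
            "clinical": clinical}


def _stage_cags(config, study, stage_dir, meta, state):
    genes = _genes(config, study, state)
    lengths = pd.read_csv(study / "gene_lengths.tsv", sep="\t",
                          index_col=0)["length"]
    hits = pd.read_csv(study / "hits.tsv", sep="\t")
    cag_list, small = cags.build_cags(
        genes, lengths, hits, meta,
        alpha=config.alpha, r_threshold=config.canopy_r,
    )
    membership = pd.DataFrame(
        [(c.cag_id, g) for c in cag_list for g in c.gene_ids],
        columns=["cag_id", "gene_id"],
    )
    membership.to_csv(stage_dir / "membership.tsv", sep="\t", index=False)
    if cag_list:
        ab = pd.DataFrame({c.cag_id: c.abundance for c in cag_list}).T
        ab.to_csv(stage_dir / "abundance.tsv", sep="\t", index_label="cag_id")
        info = pd.DataFrame(
            [
                (c.cag_id, c.size, c.taxon, c.level, c.odds_ratio, c.enrichment)
                for c in cag_list
            ],
            columns=["cag_id", "size", "taxon", "level", "odds_ratio",
                     "enrichment"],
        )
        info.to_csv(stage_dir / "cags.tsv", sep="\t", index=False)
        enriched = [c for c in cag_list if c.enrichment != "neutral"]
        if len(enriched) >= 2:
            net = cags.cooccurrence_network(
                AbundanceMatrix.unchecked(
                    pd.DataFrame({c.cag_id: c.abundance for c in enriched}).T,
                    "depth",
                ),
                rho_min=config.rho_min, alpha=config.alpha,
            )
            edges = pd.DataFrame(
                [(u, v, d["rho"], d["q"]) for u, v, d in net.edges(data=True)],
                columns=["source", "target", "rho", "q"],
            )
            edges.to_csv(stage_dir / "network_edges.tsv", sep="\t", index=False)
    state["cags"] = cag_list
    return {
        "n_cags": len(cag_list),
        "n_small_clusters": len(small),
        "cags": {c.cag_id: {"size": c.size, "taxon": c.taxon,
                            "level": c.level, "odds_ratio": c.odds_ratio,
                            "enrichment": c.enrichment}
                 for c in cag_list},
    }


def _stage_classifier(config, study, stage_dir, meta, state):
    cag_list = state.get("cags")
    if not cag_list:
        return {"skipped": "no CAGs available"}
    X = pd.DataFrame({c.cag_id: c.abundance for c in cag_list})
    ks = [k for k in (1, 2, 3, 5, 10, 20, 50, 70, 100, 200, 500, 1000)
          if k <= X.shape[1]]
    report = classifier.classify_report(
        X, meta, ks=ks, trials=config.cv_trials, folds=config.cv_folds,
        n_trees=config.n_trees, train_fraction=config.train_fraction,
        seed=config.seed,
    )
    report.cv_curve.to_csv(stage_dir / "cv_curve.tsv", sep="\t",
                           index_label="k")
    report.importance.to_frame("mean_decrease_accuracy").to_csv(
        stage_dir / "importance.tsv", sep="\t", index_label="feature"
    )
    report.test_scores.to_frame("p_case").to_csv(
        stage_dir / "test_scores.tsv", sep="\t", index_label="sample_id"
    )
    return {
        "k_selected": report.k_selected,
        "train_auc": report.train_auc,
        "train_ci": list(report.train_ci),
        "test_auc": report.test_auc,
        "test_ci": list(report.test_ci),
        "cv_curve": {str(k): v for k, v in report.cv_curve.items()},
    }


def _stage_metabolomics(config, study, stage_dir, meta, state):
    merged = {}
    counts = {}
    for compartment in ("serum", "feces"):
        tables = {}
        for mode, tag in (("ES+", "pos"), ("ES-", "neg")):
            peaks = read_peak_table(study / f"metabolome_{compartment}_{tag}.tsv")
            norm = metabolomics.normalize_total(peaks)
            tables[mode] = metabolomics.differential_metabolites(
                norm, meta, n_components=config.pls_components,
                vip_cutoff=config.vip_cutoff, p_cutoff=config.p_cutoff,
            )
            state[f"peaks_{compartment}_{tag}"] = norm
        merged[compartment] = metabolomics.merge_modes(tables["ES+"], tables["ES-"])
        merged[compartment].to_csv(
            stage_dir / f"differential_{compartment}.tsv", sep="\t",
            index_label="feature_id",
        )
        counts[compartment] = int(merged[compartment]["selected"].sum())
    shared, concordant, heat = metabolomics.cross_compartment(
        merged["serum"], merged["feces"]
    )
    heat.to_csv(stage_dir / "fold_change_heat.tsv", sep="\t",
                index_label="compound")
    state["merged_metabolites"] = merged
    return {
        "n_selected": counts,
        "n_shared": len(shared),
        "n_concordant": len(concordant),
        "shared": shared,
        "concordant": concordant,
    }


def _stage_integration(config, study, stage_dir, meta, state):
    genus = _genus(config, study, state)
    diff = state.get("differential_genera")
    if diff is None:
        diff = differential.differential_features(genus, meta, alpha=config.alpha)
    top_taxa = (
        diff[diff["significant"]].sort_values("q").head(config.n_top_taxa).index
    )
    serum = state.get("peaks_serum_pos")
    if serum is None:
        serum = metabolomics.normalize_total(
            read_peak_table(study / "metabolome_serum_pos.tsv")
        )
    merged = state.get("merged_metabolites", {}).get("serum")
    if merged is not None:
        chosen = merged[merged["selected"]].sort_values("p")
        met_ids = [f for f in chosen.index if f in set(serum.feature_ids)]
        met_ids = met_ids[: config.n_top_metabolites]
    else:
        met_ids = serum.feature_ids[: config.n_top_metabolites]
    if len(top_taxa) == 0 or len(met_ids) == 0:
        return {"skipped": "no selected taxa or metabolites"}
    grid = integration.correlation_grid(
        genus, serum, taxa_selection=list(top_taxa),
        metabolite_selection=met_ids,
    )
    grid.rho.to_csv(stage_dir / "rho.tsv", sep="\t", index_label="taxon")
    grid.stars.to_csv(stage_dir / "stars.tsv", sep="\t", index_label="taxon")
    grid.edge_list().to_csv(stage_dir / "edges.tsv", sep="\t", index=False)
    n_starred = int((grid.stars.to_numpy() != "").sum())
    return {"n_taxa": len(top_taxa), "n_metabolites": len(met_ids),
            "n_starred_cells": n_starred}


_STAGES = {
    "ecology": _stage_ecology,
    "enterotypes": _stage_enterotypes,
    "differential": _stage_differential,
    "cags": _stage_cags,
    "classifier": _stage_classifier,
    "metabolomics": _stage_metabolomics,
    "integration": _stage_integration,
}
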