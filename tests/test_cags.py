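import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutflow import cags
from gutflow.containers import AbundanceMatrix
from gutflow.simulate import SimulationConfig, generate_gene_study


@pytest.fixture(scope="module")
def recovered(gene_study, meta):
    depths, lengths, hits, m, truth = gene_study
    markers = cags.marker_genes(depths, m)
    clusters, small = cags.canopy_cluster(depths.subset_features(markers))
    return depths, lengths, hits, m, truth, markers, clusters, small


class TestMarkerGenes:
    def test_planted_block_genes_selected(self, recovered):
        depths, _, _, _, truth, markers, _, _ = recovered
        planted = {g for g, s in truth.differential_features["gene"].items()}
        assert len(planted & set(markers)) / len(planted) >= 0.9
        assert set(markers) <= set(depths.feature_ids)

    def test_null_study_yields_no_markers(self):
        cfg = SimulationConfig(seed=3, effect_size=0.0)
        depths, _, _, m, _ = generate_gene_study(cfg)
        assert len(cags.marker_genes(depths, m)) <= 2


class TestCanopy:
    def test_planted_blocks_form_exactly_three_cags(self, recovered):
        *_, truth, markers, clusters, small = recovered
        assert len(clusters) == 3
        membership = truth.cag_membership
        for cluster in clusters:
            blocks = pd.Series([membership.get(g, "noise") for g in cluster])
            assert blocks.value_counts(normalize=True).iloc[0] >= 0.95

    def test_small_planted_block_is_not_a_cag(self, recovered):
        *_, truth, markers, clusters, small = recovered
        small_genes = {g for g, b in truth.cag_membership.items() if b == "block_small"}
        for cluster in clusters:
            assert len(small_genes & set(cluster)) / len(cluster) < 0.5
        # the 40-gene block shows up among the sub-threshold clusters instead
        assert any(len(small_genes & set(c)) >= 0.9 * len(small_genes) for c in small)

    def test_partition_invariant_to_gene_order(self, recovered):
        depths, *_ , markers, clusters, _ = recovered
        sub = depths.subset_features(markers)
        perm = np.random.default_rng(0).permutation(len(markers))
        shuffled = AbundanceMatrix.unchecked(sub.data.iloc[perm], "depth")
        clusters2, _ = cags.canopy_cluster(shuffled)
        assert sorted(map(tuple, clusters)) == sorted(map(tuple, clusters2))

    def test_too_few_samples_rejected(self):
        m = AbundanceMatrix(pd.DataFrame(np.ones((5, 2)),
                                         index=[f"g{i}" for i in range(5)],
                                         columns=["a", "b"]))
        with pytest.raises(ValueError):
            cags.canopy_cluster(m)


class TestCagAbundance:
    def test_equal_lengths_give_plain_mean(self):
        depths = AbundanceMatrix(
            pd.DataFrame({"s": [2.0, 4.0]}, index=["g1", "g2"])
        )
        lengths = pd.Series([100, 100], index=["g1", "g2"])
        assert cags.cag_abundance(["g1", "g2"], depths, lengths)["s"] == 3.0

    def test_length_weighting(self):
        depths = AbundanceMatrix(
            pd.DataFrame({"s": [2.0, 4.0]}, index=["g1", "g2"])
        )
        lengths = pd.Series([100, 300], index=["g1", "g2"])
        assert cags.cag_abundance(["g1", "g2"], depths, lengths)["s"] == pytest.approx(3.5)

    def test_linearity_and_order_invariance(self, rng):
        ids = [f"g{i}" for i in range(6)]
        depths = AbundanceMatrix(
            pd.DataFrame(rng.random((6, 4)), index=ids, columns=list("abcd"))
        )
        scaled = AbundanceMatrix(depths.data * 3.0)
        lengths = pd.Series(rng.integers(300, 3000, 6), index=ids)
        a1 = cags.cag_abundance(ids, depths, lengths)
        a2 = cags.cag_abundance(ids[::-1], depths, lengths)
        a3 = cags.cag_abundance(ids, scaled, lengths)
        pd.testing.assert_series_equal(a1, a2)
        np.testing.assert_allclose(a3, a1 * 3.0)

    def test_missing_length_rejected(self):
        depths = AbundanceMatrix(pd.DataFrame({"s": [1.0]}, index=["g1"]))
        with pytest.raises(ValueError):
            cags.cag_abundance(["g1"], depths, pd.Series(dtype=float))


def _hit_rows(genes, taxon, level, nt, aa, ov):
    return [dict(gene_id=g, taxon=taxon, level=level,
                 nt_identity=nt, aa_identity=aa, overlap=ov) for g in genes]


class TestTaxonomyRules:
    genes = [f"g{i}" for i in range(10)]

    def test_species_rule(self):
        hits = pd.DataFrame(_hit_rows(self.genes[:9], "S. bongori", "species",
                                      96.0, 90.0, 0.75))
        assert cags.assign_taxonomy(self.genes, hits) == ("S. bongori", "species")

    def test_genus_rule(self):
        hits = pd.DataFrame(_hit_rows(self.genes[:8], "Salmonella", "genus",
                                      86.0, 86.0, 0.75))
        assert cags.assign_taxonomy(self.genes, hits) == ("Salmonella", "genus")

    def test_below_both_thresholds_unassigned(self):
        hits = pd.DataFrame(
            _hit_rows(self.genes[:7], "S. bongori", "species", 96.0, 96.0, 0.75)
            + _hit_rows(self.genes[:7], "Salmonella", "genus", 86.0, 86.0, 0.75)
        )
        assert cags.assign_taxonomy(self.genes, hits) == ("unassigned", "unassigned")

    def test_species_needs_overlap(self):
        hits = pd.DataFrame(_hit_rows(self.genes, "S. bongori", "species",
                                      96.0, 96.0, 0.5))
        assert cags.assign_taxonomy(self.genes, hits)[1] != "species"

    def test_genus_needs_both_identities(self):
        hits = pd.DataFrame(_hit_rows(self.genes, "Salmonella", "genus",
                                      86.0, 80.0, 0.9))
        assert cags.assign_taxonomy(self.genes, hits) == ("unassigned", "unassigned")

    def test_empty_hits_unassigned_not_error(self):
        hits = pd.DataFrame(columns=["gene_id", "taxon", "level",
                                     "nt_identity", "aa_identity", "overlap"])
        assert cags.assign_taxonomy(self.genes, hits) == ("unassigned", "unassigned")

    def test_adding_hits_never_demotes(self):
        hits = pd.DataFrame(_hit_rows(self.genes[:9], "S. bongori", "species",
                                      96.0, 90.0, 0.75))
        more = pd.concat([hits, pd.DataFrame(
            _hit_rows(self.genes, "Other sp.", "species", 95.5, 90.0, 0.71)
        )])
        assert cags.assign_taxonomy(self.genes, more)[1] == "species"

    def test_planted_blocks_assigned_to_their_genome(self, recovered):
        _, _, hits, _, truth, _, clusters, _ = recovered
        for cluster in clusters:
            block = truth.cag_membership[cluster[0]]
            taxon, level = cags.assign_taxonomy(cluster, hits)
            assert level == "species"
            assert taxon == f"Species_{block}"


class TestOddsRatio:
    def _meta(self):
        ids = [f"case_{i}" for i in range(50)] + [f"ctrl_{i}" for i in range(50)]
        return pd.DataFrame({"group": ["case"] * 50 + ["control"] * 50}, index=ids)

    def test_hand_2x2(self):
        meta = self._meta()
        ab = pd.Series([1.0] * 40 + [0.0] * 10 + [1.0] * 10 + [0.0] * 40,
                       index=meta.index)
        oratio, enr = cags.odds_ratio_score(ab, meta, presence_threshold=0.5)
        assert oratio == pytest.approx(16.0)
        assert enr == "case_enriched"

    def test_identical_presence_neutral(self):
        meta = self._meta()
        ab = pd.Series(([1.0] * 25 + [0.0] * 25) * 2, index=meta.index)
        oratio, enr = cags.odds_ratio_score(ab, meta, presence_threshold=0.5)
        assert oratio == pytest.approx(1.0)
        assert enr == "neutral"

    def test_group_swap_inverts(self):
        meta = self._meta()
        rng = np.random.default_rng(2)
        ab = pd.Series(rng.random(100) > 0.4, index=meta.index, dtype=float)
        o1, _ = cags.odds_ratio_score(ab, meta, presence_threshold=0.5)
        swapped = meta.copy()
        swapped["group"] = np.where(meta["group"] == "case", "control", "case")
        o2, _ = cags.odds_ratio_score(ab, swapped, presence_threshold=0.5)
        assert o2 == pytest.approx(1.0 / o1)

    def test_planted_effect_signs_recovered_end_to_end(self, recovered):
        depths, lengths, hits, m, truth, _, clusters, _ = recovered
        for cluster in clusters:
            ab = cags.cag_abundance(cluster, depths, lengths)
            _, enr = cags.odds_ratio_score(ab, m, presence_threshold="median")
            sign = truth.differential_features["gene"][cluster[0]]
            assert enr == ("case_enriched" if sign > 0 else "case_depleted")


class TestNetwork:
    def test_comonotone_features_get_unit_edge(self, rng):
        base = rng.random(30)
        data = pd.DataFrame(
            [base, base * 2 + 1, rng.random(30)],
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(30)],
        )
        g = cags.cooccurrence_network(AbundanceMatrix(data))
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["rho"] == pytest.approx(1.0)

    def test_independent_features_yield_few_edges(self, rng):
        data = pd.DataFrame(
            rng.random((40, 50)),
            index=[f"f{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(50)],
        )
        g = cags.cooccurrence_network(AbundanceMatrix(data))
        assert g.number_of_edges() <= 3

    def test_rho_matches_rank_oracle_small_n(self, rng):
        x, y = rng.random(8), rng.random(8)
        data = pd.DataFrame([x, y], index=["a", "b"],
                            columns=[f"s{i}" for i in range(8)])
        g = cags.cooccurrence_network(AbundanceMatrix(data), rho_min=0.0, alpha=1.1)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert g.edges["a", "b"]["rho"] == pytest.approx(oracle)

    def test_constant_feature_excluded_with_warning(self, rng):
        data = pd.DataFrame(
            [np.full(10, 2.0), rng.random(10), rng.random(10)],
            index=["const", "a", "b"], columns=[f"s{i}" for i in range(10)],
        )
        with pytest.warns(UserWarning, match="const"):
            g = cags.cooccurrence_network(AbundanceMatrix(data))
        assert "const" not in g.nodes
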