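import numpy as np
import pandas as pd
import pytest

from gutflow import metabolomics as mb
from gutflow.containers import PeakTable


def _peak_table(areas: np.ndarray, compounds=None, mode="ES+",
                compartment="serum", sample_ids=None):
    n, s = areas.shape
    fids = [f"f{i}" for i in range(n)]
    sample_ids = sample_ids or [f"s{j}" for j in range(s)]
    meta = pd.DataFrame(
        {
            "compound": compounds or [""] * n,
            "mode": mode,
            "compartment": compartment,
            "rt_min": np.linspace(1, 10, n),
            "mass_da": np.linspace(100, 500, n),
        },
        index=pd.Index(fids, name="feature_id"),
    )
    return PeakTable(meta=meta,
                     areas=pd.DataFrame(areas, index=fids, columns=sample_ids))


class TestNormalizeTotal:
    def test_sample_scaled_to_one_million(self):
        t = _peak_table(np.array([[2.0], [3.0], [5.0]]))
        out = mb.normalize_total(t)
        np.testing.assert_allclose(out.areas["s0"], [2e5, 3e5, 5e5])

    def test_idempotent_and_column_sums(self, rng):
        t = _peak_table(rng.lognormal(size=(20, 6)))
        once = mb.normalize_total(t)
        twice = mb.normalize_total(once)
        pd.testing.assert_frame_equal(once.areas, twice.areas)
        np.testing.assert_allclose(once.areas.sum(axis=0), 1e6, atol=1e-6)

    def test_zero_total_sample_rejected(self):
        t = _peak_table(np.array([[1.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="s1"):
            mb.normalize_total(t)


def _class_data(rng, n=20, p=10, effect_cols=(0,), fold=4.0):
    y = np.array(["case"] * (n // 2) + ["control"] * (n // 2))
    X = rng.lognormal(0, 0.3, size=(n, p))
    for c in effect_cols:
        X[: n // 2, c] *= fold
    return pd.DataFrame(X, columns=[f"m{i}" for i in range(p)]), y


class TestPLSDA:
    def test_single_perfect_feature_captures_response(self):
        y = np.array(["case"] * 5 + ["control"] * 5)
        x = np.where(y == "case", 1.0, -1.0) + 0.0
        X = pd.DataFrame({"m0": x})
        model = mb.plsda_fit(X, y, n_components=1)
        t1 = model.scores[:, 0]
        yc = np.where(y == "case", 1.0, -1.0)
        r = np.corrcoef(t1, yc)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_score_orthogonality(self, rng):
        X, y = _class_data(rng)
        model = mb.plsda_fit(X, y, n_components=2)
        t1, t2 = model.scores[:, 0], model.scores[:, 1]
        assert abs(t1 @ t2) <= 1e-8 * np.linalg.norm(t1) * np.linalg.norm(t2)

    def test_first_component_matches_power_iteration_oracle(self, rng):
        for _ in range(5):
            X, y = _class_data(rng, n=10, p=8)
            model = mb.plsda_fit(X, y, n_components=1)
            # power iteration on M = X'y y'X (dominant eigenvector direction)
            Xc = (X - X.mean()) / X.std(ddof=1)
            yc = np.where(y == "case", 1.0, -1.0)
            yc = yc - yc.mean()
            M = np.outer(Xc.T @ yc, yc @ Xc)
            v = np.ones(M.shape[0]) / np.sqrt(M.shape[0])
            for _ in range(200):
                v = M @ v
                v /= np.linalg.norm(v)
            cos = abs(v @ model.weights[0])
            assert cos >= 1 - 1e-8

    def test_constant_feature_dropped_with_warning(self, rng):
        X, y = _class_data(rng)
        X["const"] = 1.0
        with pytest.warns(UserWarning):
            model = mb.plsda_fit(X, y, n_components=1)
        assert "const" not in model.feature_ids


class TestVIP:
    def test_closed_form_at_one_component(self):
        model = mb.PLSModel(
            weights=np.array([[0.6, 0.8]]),
            scores=np.array([[1.0], [2.0], [-1.0]]),
            x_loadings=np.zeros((1, 2)),
            y_loadings=np.array([0.5]),
            x_mean=np.zeros(2), x_scale=np.ones(2), y_mean=0.0,
            feature_ids=["a", "b"],
        )
        vip = mb.vip_scores(model)
        np.testing.assert_allclose(vip, [0.84852814, 1.13137085])

    def test_mean_square_identity_and_permutation(self, rng):
        X, y = _class_data(rng, n=16, p=12, effect_cols=(0, 3))
        model = mb.plsda_fit(X, y, n_components=3)
        vip = mb.vip_scores(model)
        assert (vip ** 2).mean() == pytest.approx(1.0, abs=1e-12)
        perm = rng.permutation(X.columns)
        vip_p = mb.vip_scores(mb.plsda_fit(X[perm], y, n_components=3))
        pd.testing.assert_series_equal(vip.sort_index(), vip_p.sort_index())


class TestOPLS:
    def test_orthogonal_scores_uncorrelated_with_response(self, rng):
        X, y = _class_data(rng, n=20, p=15, effect_cols=(0, 1))
        model = mb.oplsda_fit(X, y, n_orthogonal=2)
        yc = np.where(np.asarray(y) == "case", 1.0, -1.0)
        yc = yc - yc.mean()
        for a in range(model.ortho_scores.shape[1]):
            t_o = model.ortho_scores[:, a]
            assert abs(t_o @ yc) <= 1e-8 * np.linalg.norm(t_o) * np.linalg.norm(yc)

    def test_zero_orthogonal_components_reduce_to_plsda(self, rng):
        X, y = _class_data(rng)
        m0 = mb.oplsda_fit(X, y, n_orthogonal=0)
        m1 = mb.plsda_fit(X, y, n_components=1)
        np.testing.assert_allclose(m0.weights, m1.weights, atol=1e-12)
        np.testing.assert_allclose(m0.scores, m1.scores, atol=1e-12)

    def test_stripping_structured_noise_improves_fit(self, rng):
        n = 24
        y = np.array(["case"] * 12 + ["control"] * 12)
        yc = np.where(y == "case", 1.0, -1.0)
        ortho = np.tile(rng.normal(size=n)[:, None], (1, 6))
        ortho -= yc[:, None] * (ortho.T @ yc)[None, :] / (yc @ yc)
        X = pd.DataFrame(
            yc[:, None] * rng.normal(1.0, 0.1, size=(1, 6)) + 3 * ortho
            + rng.normal(0, 0.05, size=(n, 6)),
            columns=[f"m{i}" for i in range(6)],
        )
        def r2y(model):
            yhat = model.scores[:, 0] * model.y_loadings[0]
            return 1 - ((yc - yc.mean() - yhat) ** 2).sum() / ((yc - yc.mean()) ** 2).sum()
        assert r2y(mb.oplsda_fit(X, y, 1)) >= r2y(mb.plsda_fit(X, y, 1)) - 1e-9


class TestSelection:
    def test_conjunction_required(self, metabolome_study, meta):
        tables, _ = metabolome_study
        table = mb.differential_metabolites(
            mb.normalize_total(tables[("serum", "ES+")]), meta
        )
        not_selected = table[(table["p"] < 0.05) & (table["VIP"] <= 1.0)]
        assert (~not_selected["selected"]).all()
        assert (table["selected"] == ((table["VIP"] > 1) & (table["p"] < 0.05))).all()

    def test_planted_metabolites_recovered(self, metabolome_study, meta):
        tables, truth = metabolome_study
        table = mb.differential_metabolites(
            mb.normalize_total(tables[("serum", "ES+")]), meta
        )
        planted = {
            name.split(":")[1]
            for name in truth.differential_features["metabolite"]
            if name.startswith("serum:")
        }
        named = table[table["compound"].isin(planted)]
        recall = named["selected"].mean()
        assert recall >= 0.8
        hits = set(table[table["selected"]]["compound"]) - {""}
        precision = len(hits & planted) / max(len(hits), 1)
        assert precision >= 0.8


class TestMergeModes:
    def _table(self, compounds, ps, mode):
        df = pd.DataFrame(
            {
                "compound": compounds,
                "mode": mode,
                "compartment": "serum",
                "rt_min": 1.0,
                "mass_da": 100.0,
                "p": ps,
                "VIP": 1.5,
                "log2FC": 1.0,
                "selected": True,
            },
            index=[f"{mode}_{i}" for i in range(len(compounds))],
        )
        return df

    def test_lower_p_mode_retained(self):
        pos = self._table(["A", "B"], [0.01, 0.5], "ES+")
        neg = self._table(["A", "C"], [0.03, 0.2], "ES-")
        merged = mb.merge_modes(pos, neg)
        assert merged[merged["compound"] == "A"]["mode"].iloc[0] == "ES+"
        assert set(merged["compound"]) == {"A", "B", "C"}

    def test_duplicate_compound_within_mode_rejected(self):
        pos = self._table(["A", "A"], [0.01, 0.02], "ES+")
        neg = self._table(["B"], [0.03], "ES-")
        with pytest.raises(ValueError, match="A"):
            mb.merge_modes(pos, neg)


class TestCrossCompartment:
    def _diff(self, compounds, log2fcs, selected):
        return pd.DataFrame(
            {
                "compound": compounds,
                "log2FC": log2fcs,
                "selected": selected,
            },
            index=[f"f{i}" for i in range(len(compounds))],
        )

    def test_concordant_subset_of_shared(self):
        serum = self._diff(["A", "B", "C"], [1.0, -1.0, 2.0], [True, True, True])
        feces = self._diff(["A", "B", "D"], [0.5, 1.0, 1.0], [True, True, True])
        shared, concordant, heat = mb.cross_compartment(serum, feces)
        assert shared == ["A", "B"]
        assert concordant == ["A"]
        assert set(concordant) <= set(shared)
        assert list(heat.index) == shared

    def test_disjoint_names_give_empty(self):
        serum = self._diff(["A"], [1.0], [True])
        feces = self._diff(["B"], [1.0], [True])
        shared, concordant, _ = mb.cross_compartment(serum, feces)
        assert shared == [] and concordant == []
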