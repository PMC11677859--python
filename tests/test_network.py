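"""Correlation-network modules: TOM, clustering, eigenfeatures, kME, traits."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import salivamics as sm
from conftest import make_imputed


def tom_dissim_bruteforce(corr: np.ndarray, power: int) -> np.ndarray:
    """Triple-loop oracle for the topological overlap dissimilarity."""
    a = np.abs(corr) ** power
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = 1.0 - (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


def block_fixture(seed, loading=0.8, block_size=30, n_noise=40, n=80):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b in range(2):
        factor = rng.standard_normal(n)
        rows.append(loading * factor
                    + np.sqrt(1 - loading**2) * rng.standard_normal((block_size, n)))
        labels += [b] * block_size
    rows.append(rng.standard_normal((n_noise, n)))
    labels += [-1] * n_noise
    return make_imputed(np.vstack(rows)), np.array(labels)


class TestAdjacencyTom:
    @pytest.mark.parametrize("n_features,seed", [(6, 0), (12, 1), (20, 2)])
    def test_matches_bruteforce_oracle(self, n_features, seed):
        rng = np.random.default_rng(seed)
        mat = make_imputed(rng.normal(size=(n_features, 15)))
        power = int(rng.integers(1, 8))
        dissim = sm.adjacency_tom(mat, power).to_numpy()
        corr = np.corrcoef(mat.values.to_numpy())
        ref = tom_dissim_bruteforce(corr, power)
        assert np.abs(dissim - ref).max() < 1e-10

    def test_orthogonal_features_fully_dissimilar(self):
        # exactly uncorrelated design -> zero TOM, dissimilarity 1 off-diagonal
        x = np.array([[1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]], float)
        dissim = sm.adjacency_tom(make_imputed(x), 2).to_numpy()
        off = dissim[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)
        assert np.allclose(np.diag(dissim), 0.0)

    def test_perfectly_correlated_triplet(self):
        # all pairwise adjacency 1: TOM = (1+1)/(2+1-1) = 1, dissimilarity 0
        base = np.array([1.0, 2.0, 5.0, 3.0])
        x = np.vstack([base, 2 * base + 1, 3 * base - 2])
        dissim = sm.adjacency_tom(make_imputed(x), 1).to_numpy()
        assert np.allclose(dissim, 0.0, atol=1e-12)

    def test_entries_bounded_and_symmetric(self):
        rng = np.random.default_rng(3)
        dissim = sm.adjacency_tom(make_imputed(rng.normal(size=(15, 20))), 6).to_numpy()
        assert np.allclose(dissim, dissim.T)
        assert dissim.min() >= 0.0 and dissim.max() <= 1.0 + 1e-12

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError, match="3 features"):
            sm.adjacency_tom(make_imputed(np.random.default_rng(0).normal(size=(2, 10))), 2)


class TestSoftThreshold:
    def test_fit_table_covers_grid_and_choice_rule(self):
        mat, _ = block_fixture(0)
        params = sm.NetworkParams()
        power, table = sm.pick_soft_threshold(mat, params)
        assert list(table["power"]) == list(params.power_grid)
        reaching = table[table["signed_rsq"] >= params.rsq_cutoff]
        if len(reaching):
            assert power == reaching["power"].iloc[0]
        else:
            assert power == table.loc[table["signed_rsq"].idxmax(), "power"]

    def test_low_cutoff_returns_first_reaching_power(self):
        mat, _ = block_fixture(1)
        params = sm.NetworkParams(rsq_cutoff=0.05)
        power, table = sm.pick_soft_threshold(mat, params)
        assert power == table.loc[table["signed_rsq"] >= 0.05, "power"].iloc[0]

    def test_default_generator_layer_reaches_cutoff(self, imputed_protein):
        mat, _ = imputed_protein
        power, table = sm.pick_soft_threshold(mat)
        assert (table["signed_rsq"] >= 0.85).any()
        assert table.loc[table["power"] == power, "signed_rsq"].iloc[0] >= 0.85


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        mat, labels = block_fixture(0)
        power, _ = sm.pick_soft_threshold(mat)
        modules = sm.detect_modules(sm.adjacency_tom(mat, power))
        assert len(modules.module_names()) == 2
        pred = modules.labels.to_numpy()
        nongrey = pred != "grey"
        assert adjusted_rand_score(labels[nongrey], pred[nongrey]) >= 0.8

    def test_small_block_goes_grey(self):
        rng = np.random.default_rng(4)
        factor = rng.standard_normal(80)
        block = 0.9 * factor + np.sqrt(1 - 0.81) * rng.standard_normal((10, 80))
        mat = make_imputed(np.vstack([block, rng.standard_normal((40, 80))]))
        power, _ = sm.pick_soft_threshold(mat)
        modules = sm.detect_modules(sm.adjacency_tom(mat, power),
                                    sm.NetworkParams(min_module_size=20))
        assert (modules.labels.iloc[:10] == "grey").all()

    def test_color_order_follows_size_rank(self):
        mat, _ = block_fixture(5, block_size=25)
        power, _ = sm.pick_soft_threshold(mat)
        modules = sm.detect_modules(sm.adjacency_tom(mat, power))
        sizes = modules.sizes().drop("grey", errors="ignore")
        names = list(sizes.sort_values(ascending=False).index)
        assert names == list(sm.network.MODULE_COLORS[: len(names)])

    def test_labels_partition_features(self):
        mat, _ = block_fixture(6)
        power, _ = sm.pick_soft_threshold(mat)
        modules = sm.detect_modules(sm.adjacency_tom(mat, power))
        assert modules.sizes().sum() == mat.n_features


class TestEigenfeatures:
    def test_rank_one_module_explains_everything(self):
        base = np.sin(np.arange(20))
        x = np.vstack([base, 2 * base + 3, -0.5 * base])
        mat = make_imputed(x)
        modules = sm.ModuleSet(labels=pd.Series("turquoise", index=mat.feature_ids))
        eig = sm.module_eigenfeatures(mat, modules)["turquoise"]
        assert eig.variance_explained == pytest.approx(1.0)
        std_profile = (base - base.mean()) / base.std()
        aligned = eig.scores.to_numpy() * np.sign(eig.scores.to_numpy() @ std_profile)
        assert np.allclose(aligned / np.linalg.norm(aligned),
                           std_profile / np.linalg.norm(std_profile), atol=1e-9)

    def test_sign_convention_and_variance_floor(self):
        mat, _ = block_fixture(7)
        power, _ = sm.pick_soft_threshold(mat)
        modules = sm.detect_modules(sm.adjacency_tom(mat, power))
        eigs = sm.module_eigenfeatures(mat, modules)
        kme_table, _ = sm.kme(mat, eigs, modules)
        for module, eig in eigs.items():
            size = len(modules.members(module))
            assert eig.variance_explained >= 1.0 / size - 1e-12
            assert kme_table.loc[kme_table["module"] == module, "kme"].mean() >= 0


class TestKme:
    def test_feature_identical_to_eigenfeature_scores_one(self):
        base = np.cos(np.arange(30))
        mat = make_imputed(np.vstack([base, base]))
        modules = sm.ModuleSet(labels=pd.Series("turquoise", index=mat.feature_ids))
        eigs = sm.module_eigenfeatures(mat, modules)
        table, hubs = sm.kme(mat, eigs, modules)
        assert np.allclose(table["kme"], 1.0, atol=1e-9)
        assert hubs["turquoise"] == ["F000", "F001"]

    def test_highest_loading_member_is_a_hub(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            factor = rng.standard_normal(80)
            loadings = np.linspace(0.95, 0.5, 25)
            block = loadings[:, None] * factor + \
                np.sqrt(1 - loadings[:, None] ** 2) * rng.standard_normal((25, 80))
            mat = make_imputed(np.vstack([block, rng.standard_normal((30, 80))]))
            labels = pd.Series(["turquoise"] * 25 + ["grey"] * 30, index=mat.feature_ids)
            modules = sm.ModuleSet(labels=labels)
            eigs = sm.module_eigenfeatures(mat, modules)
            _, hubs = sm.kme(mat, eigs, modules)
            hits += "F000" in hubs["turquoise"]
        assert hits >= 9

    def test_noise_feature_has_low_kme(self):
        low = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            factor = rng.standard_normal(80)
            block = 0.8 * factor + 0.6 * rng.standard_normal((20, 80))
            noise = rng.standard_normal(80)
            mat = make_imputed(np.vstack([block, noise]))
            labels = pd.Series(["turquoise"] * 20 + ["grey"], index=mat.feature_ids)
            eigs = sm.module_eigenfeatures(mat, sm.ModuleSet(labels=labels))
            table, _ = sm.kme(mat, eigs, sm.ModuleSet(
                labels=pd.Series(["turquoise"] * 21, index=mat.feature_ids)))
            kme_noise = table.set_index("feature_id").loc["F020", "kme"]
            low += abs(kme_noise) < 0.3
        assert low >= 0.95 * 40 - 2


class TestModuleTrait:
    def test_eigenfeature_equal_to_trait_flags_significant(self):
        rng = np.random.default_rng(0)
        trait = rng.normal(size=40)
        eig = sm.network.Eigenfeature(
            "turquoise", pd.Series(trait, index=[f"S{j:03d}" for j in range(40)]), 0.9)
        meta = pd.DataFrame({"mmse": trait, "diagnosis": ["CN"] * 40},
                            index=eig.scores.index)
        out = sm.module_trait_correlations({"turquoise": eig}, meta, traits=["mmse"])
        row = out.iloc[0]
        assert row["correlation"] == pytest.approx(1.0)
        assert row["significant_mmse"]

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=40), rng.normal(size=40)
        eig = sm.network.Eigenfeature(
            "blue", pd.Series(x, index=[f"S{j:03d}" for j in range(40)]), 0.5)
        meta = pd.DataFrame({"trait": y, "diagnosis": ["CN"] * 40}, index=eig.scores.index)
        out = sm.module_trait_correlations({"blue": eig}, meta, traits=["trait"])
        ref = ((x - x.mean()) @ (y - y.mean())) / (
            np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert out["correlation"].iloc[0] == pytest.approx(ref, abs=1e-12)

    def test_planted_severity_module_correlates_with_mmse(self):
        hits = 0
        for seed in range(10):
            cfg = sm.SynthConfig(seed=seed)
            meta, layers, truth = sm.generate_study(cfg)
            imp = sm.impute_downshift(sm.log_median_normalize(layers["protein"]),
                                      sm.ImputationParams(seed=seed))
            net = sm.run_network_analysis(imp, meta, traits=["mmse"])
            planted = {f for f, m in truth.module_membership["protein"].items() if m == 0}
            best, overlap = None, 0
            for module in net["modules"].module_names():
                o = len(planted & set(net["modules"].members(module)))
                if o > overlap:
                    best, overlap = module, o
            if best is None:
                continue
            mt = net["module_trait"]
            corr = mt.loc[(mt["module"] == best) & (mt["trait"] == "mmse"),
                          "correlation"].iloc[0]
            hits += abs(corr) >= 0.4
        assert hits >= 9
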