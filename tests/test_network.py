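"""SC/GS networks, coupling, dendrogram similarity, modules and hubs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from pleiomap import network, synthdata
from pleiomap.datatypes import GeneZMatrix, SymmetricNetwork
from pleiomap.synthdata import SyntheticConfig


def _net(W, ids=None, kind="SC"):
    W = np.asarray(W, float)
    ids = ids or [f"n{i}" for i in range(W.shape[0])]
    return SymmetricNetwork(node_ids=ids, W=W, kind=kind)


class TestStructuralCovariance:
    def test_identical_columns_fully_correlated(self, rng):
        col = rng.normal(size=100)
        df = pd.DataFrame({"a": col, "b": col, "c": rng.normal(size=100)})
        sc = network.structural_covariance(df)
        assert sc.W[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        df = pd.DataFrame(rng.normal(size=(10_000, 6)),
                          columns=[f"r{i}" for i in range(6)])
        sc = network.structural_covariance(df)
        off = sc.W[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_constant_column_rejected_with_name(self, rng):
        df = pd.DataFrame({"ok": rng.normal(size=50), "flat": np.ones(50)})
        with pytest.raises(ValueError, match="flat"):
            network.structural_covariance(df)


class TestGeneticSimilarity:
    def _zmat(self, z):
        z = np.asarray(z, float)
        return GeneZMatrix("m", [f"r{i}" for i in range(z.shape[0])],
                           [f"g{j}" for j in range(z.shape[1])], z)

    def test_diagonal_one_reversed_ranks_minus_one(self):
        z = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        gs = network.genetic_similarity(self._zmat(z))
        assert gs.W[0, 0] == 1.0
        assert gs.W[0, 1] == pytest.approx(-1.0)

    def test_common_factor_entry_matches_closed_form(self):
        # two regions load a on a shared factor with unit noise:
        # Pearson = a^2/(a^2+1); Spearman via (6/pi) asin(r/2)
        rng = np.random.default_rng(42)
        G, a = 20_000, 1.0
        f = rng.normal(size=G)
        z = np.vstack([a * f + rng.normal(size=G),
                       a * f + rng.normal(size=G),
                       rng.normal(size=G)])
        gs = network.genetic_similarity(self._zmat(z))
        pearson_expected = a * a / (a * a + 1.0)
        spearman_expected = (6 / np.pi) * np.arcsin(pearson_expected / 2.0)
        assert gs.W[0, 1] == pytest.approx(spearman_expected, abs=0.03)


class TestEdgewiseCoupling:
    def test_self_coupling_is_one(self, rng):
        W = np.corrcoef(rng.normal(size=(20, 8)))
        A = _net(W)
        assert network.edgewise_coupling(A, A) == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        W = np.corrcoef(rng.normal(size=(30, 10)))
        A = _net(W)
        B = _net(np.tanh(2.0 * W))
        np.fill_diagonal(B.W, 1.0)
        assert network.edgewise_coupling(A, B) == pytest.approx(1.0)

    def test_independent_networks_near_zero(self, rng):
        R = 60
        A = _net(np.corrcoef(rng.normal(size=(R, 80))))
        B = _net(np.corrcoef(rng.normal(size=(R, 80))))
        n_edges = R * (R - 1) // 2
        assert abs(network.edgewise_coupling(A, B)) < 3 / np.sqrt(n_edges)

    def test_node_mismatch_rejected(self, rng):
        A = _net(np.eye(4))
        B = _net(np.eye(4), ids=["x0", "x1", "x2", "x3"])
        with pytest.raises(ValueError):
            network.edgewise_coupling(A, B)


class TestScGsCoupling:
    def test_strong_shared_genetic_structure_gives_high_coupling(self):
        # when the same latent regional structure drives genes and phenotypes
        # with little noise, SC and GS networks become near-duplicates
        cfg = SyntheticConfig(n_regions=60, n_genes=2000, n_subjects=2000,
                              noise_sd=0.5, metric_loading_scale=1.5,
                              shared_loading_scale=0.3, spatial_field_scale=0.8,
                              seed=2)
        geo = synthdata.gen_parcellation(cfg)
        ann = synthdata.gen_gene_annotations(cfg)
        zmats, _, _ = synthdata.gen_gene_assoc(cfg, geo, ann)
        tables, _ = synthdata.gen_phenotypes(cfg, geo)
        sc = network.structural_covariance(tables["metric1"])
        gs = network.genetic_similarity(zmats[0])
        assert network.edgewise_coupling(sc, gs) > 0.8


class TestDistanceAdjustedCoupling:
    def test_shared_distance_confound_removed(self, rng):
        R = 40
        pts = rng.normal(size=(R, 3))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        noise_a = rng.normal(scale=0.05, size=(R, R))
        noise_b = rng.normal(scale=0.05, size=(R, R))
        A = _net(np.exp(-D) + (noise_a + noise_a.T) / 2)
        B = _net(np.exp(-D) + (noise_b + noise_b.T) / 2)
        raw = network.edgewise_coupling(A, B)
        adj = network.distance_adjusted_coupling(A, B, D, form="exp")
        assert raw > 0.8
        assert abs(adj) < 0.15

    def test_constant_distance_equals_unadjusted(self, rng):
        W1 = np.corrcoef(rng.normal(size=(15, 10)))
        W2 = np.corrcoef(rng.normal(size=(15, 10)))
        A, B = _net(W1), _net(W2)
        D = np.ones((15, 15)) - np.eye(15)
        np.fill_diagonal(D, 0)
        D[:] = 2.0
        np.fill_diagonal(D, 0.0)
        # all off-diagonal distances equal -> regression removes nothing
        adj = network.distance_adjusted_coupling(A, B, D)
        raw = network.edgewise_coupling(A, B)
        assert adj == pytest.approx(raw, abs=1e-10)

    def test_self_adjusted_coupling_is_one(self, rng):
        W = np.corrcoef(rng.normal(size=(12, 9)))
        A = _net(W)
        D = np.abs(rng.normal(size=(12, 12)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        assert network.distance_adjusted_coupling(A, A, D) == pytest.approx(1.0)


class TestCopheneticTest:
    def test_self_similarity(self, rng):
        W = np.corrcoef(rng.normal(size=(10, 12)))
        A = _net(W)
        r_c, p = network.cophenetic_test(A, A, n_perm=100, seed=0)
        assert r_c == pytest.approx(1.0)
        assert p == pytest.approx(1 / 101)

    def test_matches_brute_force_cophenetic(self, rng):
        # independent oracle: scipy linkage+cophenet applied from scratch
        W1 = np.corrcoef(rng.normal(size=(6, 20)))
        W2 = np.corrcoef(rng.normal(size=(6, 20)))
        A, B = _net(W1), _net(W2)
        r_c, _ = network.cophenetic_test(A, B, n_perm=100, seed=0)

        def coph(W):
            return squareform(cophenet(linkage(pdist(W), method="ward")))

        ca, cb = coph(W1), coph(W2)
        iu = np.triu_indices(6, 1)
        oracle = stats.pearsonr(ca[iu], cb[iu]).statistic
        assert r_c == pytest.approx(oracle, abs=1e-10)

    def test_two_block_toy_structure(self):
        # two tight 2-node clusters; both matrices agree -> R_c = 1
        W = np.array([
            [1.0, 0.9, 0.1, 0.1],
            [0.9, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.9],
            [0.1, 0.1, 0.9, 1.0],
        ])
        A, B = _net(W), _net(W.copy())
        r_c, _ = network.cophenetic_test(A, B, n_perm=100, seed=0)
        assert r_c == pytest.approx(1.0)


class TestLouvainModules:
    def test_two_disconnected_cliques(self):
        W = np.zeros((10, 10))
        W[:5, :5] = 1.0
        W[5:, 5:] = 1.0
        np.fill_diagonal(W, 1.0)
        part = network.louvain_modules(_net(W), seed=0)
        labels = part.labels
        assert len(set(labels)) == 2
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_recovers_planted_partition(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        cfg = SyntheticConfig(n_regions=24, n_genes=50, n_subjects=4000,
                              module_count=3, spatial_field_scale=0.0,
                              noise_sd=0.5, seed=6)
        geo = synthdata.gen_parcellation(cfg)
        tables, truth = synthdata.gen_phenotypes(cfg, geo)
        sc = network.structural_covariance(tables["metric1"])
        part = network.louvain_modules(sc, seed=0)
        planted = [truth.module_assignment[p] for p in geo.parcel_ids]
        ari = sklearn_metrics.adjusted_rand_score(planted, list(part.labels))
        assert ari >= 0.9

    def test_uniform_graph_low_modularity(self):
        W = np.full((12, 12), 0.5)
        np.fill_diagonal(W, 1.0)
        part = network.louvain_modules(_net(W), seed=0)
        assert part.modularity <= 0.05

    def test_deterministic_under_seed(self, rng):
        W = np.corrcoef(rng.normal(size=(20, 15)))
        A = _net(W)
        p1 = network.louvain_modules(A, seed=3)
        p2 = network.louvain_modules(A, seed=3)
        np.testing.assert_array_equal(p1.labels, p2.labels)


class TestDegreeProfile:
    def test_complete_unit_graph(self):
        W = np.ones((5, 5))
        part = network.ModulePartition([f"n{i}" for i in range(5)],
                                       np.array(["M1"] * 5, dtype=object), 0.0)
        prof = network.degree_profile(_net(W), part)
        np.testing.assert_allclose(prof.degree, 4.0)

    def test_toy_hand_computation(self):
        # weights w12=0.5, w13=0.2, w34=0.9; modules {1,2} and {3,4}
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 0.2
        W[2, 3] = W[3, 2] = 0.9
        np.fill_diagonal(W, 1.0)
        part = network.ModulePartition(
            [f"n{i}" for i in range(4)],
            np.array(["A", "A", "B", "B"], dtype=object), 0.0,
        )
        prof = network.degree_profile(_net(W), part)
        assert prof.degree[0] == pytest.approx(0.7)
        assert prof.intra_modular[0] == pytest.approx(0.5)
        assert prof.inter_modular[0] == pytest.approx(0.1)  # mean(0.2, 0)

    def test_empty_graph_all_zero(self):
        W = np.eye(6)
        part = network.ModulePartition([f"n{i}" for i in range(6)],
                                       np.array(["A"] * 3 + ["B"] * 3, dtype=object), 0.0)
        prof = network.degree_profile(_net(W), part)
        assert prof.degree.sum() == 0
        assert prof.intra_modular.sum() == 0

    def test_negative_weights_clamped_by_default(self):
        W = np.array([[1.0, -0.5], [-0.5, 1.0]])
        part = network.ModulePartition(["n0", "n1"],
                                       np.array(["A", "A"], dtype=object), 0.0)
        prof = network.degree_profile(_net(W), part)
        assert np.all(prof.degree >= 0)


class TestHubPleiotropyCoupling:
    def test_perfect_coupling_with_itself(self, geometry, phenotypes):
        tables, _ = phenotypes
        sc = network.structural_covariance(tables["metric1"])
        part = network.louvain_modules(sc, seed=0)
        prof = network.degree_profile(sc, part)
        rho, p = network.hub_pleiotropy_coupling(
            prof, prof.degree, geometry, n_spins=100, seed=0
        )
        assert rho == pytest.approx(1.0)
        assert 1 / 101 <= p < 0.05

    def test_planted_hub_loading_coupling_positive(self):
        cfg = SyntheticConfig(n_regions=40, n_genes=3000, n_subjects=2000,
                              shared_loading_scale=0.8, seed=19)
        geo = synthdata.gen_parcellation(cfg)
        ann = synthdata.gen_gene_annotations(cfg)
        zmats, dis, truth = synthdata.gen_gene_assoc(cfg, geo, ann)
        tables, _ = synthdata.gen_phenotypes(cfg, geo)
        from pleiomap import pls

        sc = network.structural_covariance(tables["metric1"])
        part = network.louvain_modules(sc, seed=0)
        prof = network.degree_profile(sc, part)
        model = pls.fit_pls1(zmats[0], dis)
        rho, p = network.hub_pleiotropy_coupling(prof, model.w_x, geo,
                                                 n_spins=200, seed=0)
        assert rho > 0.3
        assert p < 0.05
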