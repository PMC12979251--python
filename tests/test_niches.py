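"""Neighbor composition, niche clustering and tissue network summaries."""

import numpy as np
import pandas as pd
import pytest

from cpibind import (
    SimSpatialConfig,
    cluster_niches,
    cooccurrence_network,
    crypt_adjacency_network,
    neighbor_composition,
    simulate_spatial,
)
from cpibind.simulate import lattice_coords


def brute_force_neighbors(coords, radius):
    n = len(coords)
    out = []
    for i in range(n):
        s = {j for j in range(n)
             if j != i and np.hypot(*(coords[i] - coords[j])) <= radius}
        out.append(s)
    return out


class TestNeighborComposition:
    def test_single_cell_zero_row(self):
        comp = neighbor_composition(np.array([[0.0, 0.0]]), np.array(["A"]))
        assert comp.to_numpy().sum() == 0

    def test_three_collinear_cells(self):
        """Middle cell sees both A neighbors; ends see only the middle B
        (the far A is outside the 1.5-unit radius)."""
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        comp = neighbor_composition(coords, np.array(["A", "B", "A"]),
                                    rule="knn", k=10, radius=1.5)
        assert comp.loc[1, "A"] == 2 and comp.loc[1, "B"] == 0
        for i in (0, 2):
            assert comp.loc[i, "B"] == 1 and comp.loc[i, "A"] == 0

    @pytest.mark.parametrize("rule", ["knn", "delaunay"])
    def test_row_sums_match_brute_force(self, rule, rng):
        """Row sums equal brute-force neighbor counts exactly (k-NN with a
        large k reduces to the radius rule)."""
        coords = rng.random((200, 2)) * 10
        types = rng.choice(["A", "B", "C"], 200)
        radius = 1.0
        comp = neighbor_composition(coords, types, rule=rule, k=250,
                                    radius=radius, mutual=False)
        ref = brute_force_neighbors(coords, radius)
        if rule == "knn":
            np.testing.assert_array_equal(
                comp.sum(axis=1).to_numpy(), [len(s) for s in ref])
        else:
            # Delaunay edges are a subset of the radius graph
            assert (comp.sum(axis=1).to_numpy()
                    <= np.array([len(s) for s in ref])).all()

    def test_neighbors_respect_fov(self):
        coords = np.zeros((4, 2))
        fov = np.array([0, 0, 1, 1])
        comp = neighbor_composition(coords, np.array(["A"] * 4), fov=fov,
                                    rule="knn", k=5, radius=1.0)
        assert (comp["A"] == 1).all()


class TestClusterNiches:
    def test_two_pure_blocks_give_two_niches(self, rng):
        comp = pd.DataFrame(
            np.vstack([np.tile([6, 0, 0], (60, 1)) + rng.poisson(0.2, (60, 3)),
                       np.tile([0, 6, 0], (60, 1)) + rng.poisson(0.2, (60, 3))]),
            columns=["A", "B", "C"])
        nm = cluster_niches(comp, seed=0)
        assert nm.n_niches == 2
        assert len(set(nm.labels[:60])) == 1 and len(set(nm.labels[60:])) == 1

    def test_identical_rows_single_niche(self):
        comp = pd.DataFrame(np.tile([2, 2], (30, 1)), columns=["A", "B"])
        nm = cluster_niches(comp, seed=0)
        assert nm.n_niches == 1

    def test_determinism(self, rng):
        comp = pd.DataFrame(rng.poisson(3, (200, 4)),
                            columns=list("ABCD"))
        a = cluster_niches(comp, seed=5)
        b = cluster_niches(comp, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_profiles_sum_to_one(self, rng):
        comp = pd.DataFrame(rng.poisson(3, (150, 4)) + 1, columns=list("ABCD"))
        nm = cluster_niches(comp, seed=1)
        np.testing.assert_allclose(nm.profiles.sum(axis=1), 1.0, atol=1e-9)

    def test_planted_niche_recovery(self):
        """Planted niche bands recovered with high agreement (ARI)."""
        from sklearn.metrics import adjusted_rand_score
        cfg = SimSpatialConfig(lattice="square", n_rows=40, n_cols=50,
                               n_genes=5, n_niches=4, jitter=0.15, seed=2)
        smap, truth = simulate_spatial(cfg)
        comp = neighbor_composition(smap.coords,
                                    smap.obs["cell_type"].to_numpy(),
                                    rule="knn", k=10, radius=3.0)
        nm = cluster_niches(comp, seed=2)
        ari = adjusted_rand_score(truth.cells["niche_label"].to_numpy(),
                                  nm.labels)
        assert ari >= 0.8


class TestCryptAdjacency:
    def test_single_cluster_self_loop_one(self):
        coords = lattice_coords("square", 4, 4, 1.0)
        g, edges = crypt_adjacency_network(coords, np.zeros(16, dtype=int),
                                           np.full(16, 2.0),
                                           dist_window=(0, 1.5))
        assert len(edges) == 1
        assert edges.iloc[0]["weight"] == pytest.approx(1.0)
        assert g.has_edge(0, 0)

    def test_checkerboard_matches_brute_force(self):
        coords = lattice_coords("square", 8, 8, 1.0)
        clusters = np.array([(int(x) + int(y)) % 2 for x, y in coords])
        _, edges = crypt_adjacency_network(coords, clusters,
                                           np.full(64, 2.0),
                                           dist_window=(0, 1.5))
        # brute-force reference
        frac_sum = np.zeros((2, 2))
        cnt = np.zeros(2)
        for i in range(64):
            adj = [j for j in range(64)
                   if 0 < np.hypot(*(coords[i] - coords[j])) < 1.5]
            c = np.zeros(2)
            for j in adj:
                c[clusters[j]] += 1
            frac_sum[clusters[i]] += c / len(adj)
            cnt[clusters[i]] += 1
        ref = frac_sum / cnt[:, None]
        got = {(r.source, r.target): r.weight for r in edges.itertuples()}
        for a in (0, 1):
            for b in (0, 1):
                assert got.get((a, b), 0.0) == pytest.approx(ref[a, b],
                                                             abs=1e-12)

    def test_outgoing_weights_sum_to_one(self):
        coords = lattice_coords("square", 8, 8, 1.0)
        clusters = np.array([(int(x) + int(y)) % 2 for x, y in coords])
        _, edges = crypt_adjacency_network(coords, clusters,
                                           np.full(64, 2.0),
                                           dist_window=(0, 1.5))
        sums = edges.groupby("source")["weight"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_crypt_threshold_subsets(self):
        coords = lattice_coords("square", 4, 4, 1.0)
        scores = np.zeros(16)
        scores[:8] = 2.0
        clusters = np.zeros(16, dtype=int)
        clusters[8:] = 1  # only present below threshold
        g, edges = crypt_adjacency_network(coords, clusters, scores,
                                           dist_window=(0, 1.5))
        assert set(edges["source"]) == {0} and set(edges["target"]) == {0}

    def test_spot_without_neighbors_excluded(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [50.0, 50.0]])
        _, edges = crypt_adjacency_network(coords, np.array([0, 0, 1]),
                                           np.full(3, 2.0),
                                           dist_window=(0, 1.5))
        # the isolated cluster-1 spot contributes no outgoing edges
        assert 1 not in set(edges["source"])

    def test_no_spots_past_threshold_rejected(self):
        with pytest.raises(ValueError):
            crypt_adjacency_network(np.zeros((3, 2)), np.zeros(3),
                                    np.zeros(3))


class TestCooccurrence:
    def test_anticorrelated_pair_has_no_edge(self, rng):
        z = rng.standard_normal(300)
        df = pd.DataFrame({"A": z, "B": -z + 0.1 * rng.standard_normal(300)})
        g = cooccurrence_network(df)[0]
        assert g.number_of_edges() == 0

    def test_shared_latent_factor_recovered(self, rng):
        z = rng.standard_normal(500)
        df = pd.DataFrame({"A": z + rng.standard_normal(500),
                           "B": z + rng.standard_normal(500),
                           "C": rng.standard_normal(500)})
        g = cooccurrence_network(df)[0]
        assert g.has_edge("A", "B")
        assert not g.has_edge("A", "C") and not g.has_edge("B", "C")
        assert g["A"]["B"]["weight"] >= 0.15

    def test_null_false_positive_rate(self, rng):
        """Independent scores produce edges at about the nominal rate of the
        p < 0.01 filter (capped further by the r >= 0.15 filter)."""
        edges = 0
        trials = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(r.standard_normal((400, 8)),
                              columns=[f"T{i}" for i in range(8)])
            g = cooccurrence_network(df)[0]
            edges += g.number_of_edges()
            trials += 28
        assert edges / trials <= 0.02

    def test_edges_symmetric(self, rng):
        z = rng.standard_normal(300)
        df = pd.DataFrame({"A": z + rng.standard_normal(300),
                           "B": z + rng.standard_normal(300)})
        g = cooccurrence_network(df)[0]
        assert g["A"]["B"]["weight"] == g["B"]["A"]["weight"]

    def test_constant_column_excluded_with_warning(self, rng):
        df = pd.DataFrame({"A": rng.standard_normal(100),
                           "B": np.ones(100)})
        with pytest.warns(UserWarning):
            g = cooccurrence_network(df)[0]
        assert "B" not in g.nodes

    def test_per_condition_split(self, rng):
        z = rng.standard_normal(200)
        df = pd.DataFrame({"A": z + 0.5 * rng.standard_normal(200),
                           "B": z + 0.5 * rng.standard_normal(200)})
        cond = np.array(["UC"] * 100 + ["HC"] * 100)
        nets = cooccurrence_network(df, conditions=cond)
        assert set(nets) == {"UC", "HC"}

    def test_too_few_locations_rejected(self):
        df = pd.DataFrame({"A": [1.0, 2.0], "B": [2.0, 1.0]})
        with pytest.raises(ValueError):
            cooccurrence_network(df)
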