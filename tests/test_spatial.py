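"""Spatial weights, RL scores, permutation null, FDR and enrichment."""

import numpy as np
import pandas as pd
import pytest

from cpibind import (
    RlColocalization,
    SimSpatialConfig,
    WeightScheme,
    compute_weights,
    rl_score,
    simulate_spatial,
)
from cpibind.simulate import lattice_coords
from cpibind.spatial import (
    compare_scores_by_neighbor_class,
    crosstalk_enrichment,
    empirical_pvalues,
)


def naive_scores(coords, L, R, scheme):
    """O(n^2) reference implementation of the smoothed product score."""
    n_loc = len(coords)
    den = scheme.cutoff * (1 + scheme.rel_tol)
    S = np.zeros(n_loc)
    for i in range(n_loc):
        sl = sr = 0.0
        cnt = 0
        for j in range(n_loc):
            d = np.hypot(*(coords[i] - coords[j]))
            if i == j:
                w = scheme.self_weight
            elif d <= scheme.cutoff:
                w = max(1.0 - d / den, 0.0)
            else:
                w = 0.0
            if w > 0:
                cnt += 1
                sl += w * L[j]
                sr += w * R[j]
        S[i] = (sl / cnt) * (sr / cnt)
    return S


class TestWeights:
    def test_isolated_location_self_only(self):
        coords = np.array([[0.0, 0.0], [100.0, 100.0]])
        W, n = compute_weights(coords, WeightScheme(cutoff=2.0))
        assert n.tolist() == [1, 1]
        assert W[0, 0] == 1.0 and W[0, 1] == 0.0

    def test_two_ring_cutoff_on_hex_lattice(self):
        """Locations farther than two rings (2 * pitch) get weight zero."""
        coords = lattice_coords("hex", 9, 9, 1.0)
        W, _ = compute_weights(coords, WeightScheme.from_pitch(1.0))
        center = 40
        d = np.linalg.norm(coords - coords[center], axis=1)
        w_row = W[center].toarray().ravel()
        assert np.all(w_row[d > 2.0 + 1e-6] == 0.0)
        assert np.all(w_row[(d > 0) & (d <= 2.0)] > 0.0)

    def test_collinear_hand_weights(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        sch = WeightScheme(cutoff=2.0)
        W, n = compute_weights(coords, sch)
        den = 2.0 * (1 + 1e-6)
        assert W[1, 0] == pytest.approx(1 - 1 / den)
        assert W[0, 2] == pytest.approx(1 - 2 / den)
        assert n.tolist() == [3, 3, 3]

    def test_translation_invariance(self, rng):
        coords = rng.random((40, 2)) * 5
        sch = WeightScheme(cutoff=1.5)
        W1, _ = compute_weights(coords, sch)
        W2, _ = compute_weights(coords + 100.0, sch)
        assert abs(W1 - W2).max() < 1e-9

    def test_no_cross_slide_neighbors(self):
        coords = np.zeros((4, 2))
        slides = np.array([0, 0, 1, 1])
        W, n = compute_weights(coords, WeightScheme(cutoff=1.0), slides=slides)
        assert W[0, 2] == 0.0 and W[0, 1] > 0
        assert n.tolist() == [2, 2, 2, 2]

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(np.array([[0.0, np.inf]]), WeightScheme(cutoff=1))


class TestRlScore:
    def test_zero_ligand_gives_zero(self, rng):
        coords = rng.random((30, 2)) * 4
        W, n = compute_weights(coords, WeightScheme(cutoff=1.0))
        S = rl_score(np.zeros(30), rng.poisson(5, 30), W, n)
        np.testing.assert_array_equal(S, 0.0)

    def test_symmetry_under_swap(self, rng):
        coords = rng.random((50, 2)) * 5
        W, n = compute_weights(coords, WeightScheme(cutoff=1.5))
        L, R = rng.poisson(3, 50).astype(float), rng.poisson(2, 50).astype(float)
        np.testing.assert_allclose(rl_score(L, R, W, n), rl_score(R, L, W, n),
                                   rtol=0, atol=1e-12)

    def test_three_spot_line_brute_force(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        sch = WeightScheme(cutoff=10.0)
        L = np.array([1.0, 2.0, 3.0])
        R = np.array([3.0, 2.0, 1.0])
        W, n = compute_weights(coords, sch)
        np.testing.assert_allclose(rl_score(L, R, W, n),
                                   naive_scores(coords, L, R, sch),
                                   atol=1e-12)

    def test_oracle_equivalence_random_map(self, rng):
        """Vectorized score equals the naive O(n^2) reference to 1e-10."""
        coords = rng.random((200, 2)) * 10
        sch = WeightScheme(cutoff=2.0)
        L = rng.poisson(3, 200).astype(float)
        R = rng.poisson(2, 200).astype(float)
        W, n = compute_weights(coords, sch)
        np.testing.assert_allclose(rl_score(L, R, W, n),
                                   naive_scores(coords, L, R, sch),
                                   rtol=0, atol=1e-10)

    def test_invariant_to_location_relabeling(self, rng):
        coords = rng.random((60, 2)) * 6
        L, R = rng.poisson(3, 60).astype(float), rng.poisson(2, 60).astype(float)
        sch = WeightScheme(cutoff=1.5)
        W, n = compute_weights(coords, sch)
        S = rl_score(L, R, W, n)
        perm = rng.permutation(60)
        Wp, np_ = compute_weights(coords[perm], sch)
        Sp = rl_score(L[perm], R[perm], Wp, np_)
        np.testing.assert_allclose(Sp, S[perm], atol=1e-10)


class TestPermutationNull:
    def test_constant_expression_degenerate_null(self):
        """With constant expression every permutation reproduces the observed
        score, so each location's null is degenerate at its own value."""
        smap, _ = simulate_spatial(SimSpatialConfig(n_rows=5, n_cols=5, seed=0))
        smap.expr["G0"] = 2.0
        smap.expr["G1"] = 3.0
        model = RlColocalization(smap, [("G0", "G1")],
                                 WeightScheme.from_pitch(1.0))
        res = model.fit(n_perm=20, seed=0, per_location_null=True)
        np.testing.assert_allclose(res.table["p_value"], 1.0)
        assert not res.table["positive"].any()
        # pooled null likewise yields no FDR positives
        pooled = model.fit(n_perm=20, seed=0)
        assert not pooled.table["positive"].any()

    def test_default_permutations_is_100(self):
        import inspect
        sig = inspect.signature(RlColocalization.fit)
        assert sig.parameters["n_perm"].default == 100

    def test_seed_stability_of_rejection_rate(self):
        """Different seeds give different nulls but similar p < 0.05 rates."""
        rates = []
        for seed in (0, 1):
            smap, _ = simulate_spatial(SimSpatialConfig(
                lattice="hex", n_rows=15, n_cols=15, n_genes=10, seed=3))
            pairs = [(f"G{2*i}", f"G{2*i+1}") for i in range(5)]
            res = RlColocalization(smap, pairs,
                                   WeightScheme.from_pitch(1.0)).fit(
                n_perm=100, seed=seed)
            rates.append((res.table["p_value"] < 0.05).mean())
        assert abs(rates[0] - rates[1]) < 0.04

    def test_missing_gene_named(self):
        smap, _ = simulate_spatial(SimSpatialConfig(n_rows=4, n_cols=4, seed=0))
        with pytest.raises(KeyError, match="NOPE"):
            RlColocalization(smap, [("G0", "NOPE")])

    def test_nperm_validation(self):
        smap, _ = simulate_spatial(SimSpatialConfig(n_rows=4, n_cols=4, seed=0))
        with pytest.raises(ValueError):
            RlColocalization(smap, [("G0", "G1")]).fit(n_perm=0)


class TestEmpiricalPvalues:
    def test_observed_zero_all_null_positive(self):
        p, fdr, pos = empirical_pvalues(np.zeros(5), np.ones(100))
        np.testing.assert_allclose(p, 1.0)
        assert not pos.any()

    def test_never_returns_zero(self, rng):
        p, _, _ = empirical_pvalues(rng.random(50) + 10, rng.random(200))
        assert (p >= 1 / 201).all()

    def test_bh_matches_textbook_implementation(self, rng):
        """The reported FDR agrees exactly with a step-up BH implementation
        written from the definition, applied to the reported p-values."""
        observed = rng.random(97) * 3
        null = rng.random(500)
        p, fdr, _ = empirical_pvalues(observed, null)
        p, fdr = p.ravel(), fdr.ravel()
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        stepup = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepup, 1.0)
        np.testing.assert_allclose(fdr, expected, atol=1e-12)


class TestEnrichment:
    @staticmethod
    def _map_with_regions(seed=0, boost=None):
        """Two x-bands as regions; optional boosted disc inside region 1."""
        smap, _ = simulate_spatial(SimSpatialConfig(
            lattice="square", n_rows=20, n_cols=20, n_genes=6, seed=seed))
        smap.obs["region"] = (smap.coords[:, 0] >= 10).astype(int)
        if boost:
            d = np.hypot(smap.coords[:, 0] - 15, smap.coords[:, 1] - 10)
            sel = d <= 3.0
            for g in boost:
                smap.expr.loc[sel, g] = smap.expr.loc[sel, g] * 3 + 6
        return smap

    def test_planted_region_enrichment_recovered(self):
        smap = self._map_with_regions(seed=1, boost=["G0", "G1"])
        res = RlColocalization(smap, [("G0", "G1"), ("G2", "G3")],
                               WeightScheme.from_pitch(1.0)).fit(n_perm=100,
                                                                 seed=1)
        enr = res.enrichment("region")
        row = enr[(enr["pair"] == "G0->G1") & (enr["group"] == 1)]
        assert len(row) == 1
        assert row["coef"].iloc[0] > 0
        assert row["fdr"].iloc[0] < 0.05

    def test_single_group_rejected(self):
        smap = self._map_with_regions(seed=0)
        smap.obs["region"] = 0
        res = RlColocalization(smap, [("G0", "G1")],
                               WeightScheme.from_pitch(1.0)).fit(n_perm=20,
                                                                 seed=0)
        with pytest.raises(ValueError):
            res.enrichment("region")

    def test_degenerate_constant_scores_no_crash(self):
        smap = self._map_with_regions(seed=0)
        table = pd.DataFrame({
            "slide": 0, "location": smap.expr.index, "ligand": "G0",
            "receptor": "G1", "pair": "G0->G1", "score": 1.0,
            "p_value": 0.001, "fdr": 0.01, "positive": True,
        })
        out = crosstalk_enrichment(table, smap, "region")
        assert (out["coef"] == 0.0).all()
        assert (out["p_value"] == 1.0).all()


class TestNeighborClasses:
    @staticmethod
    def _setup(shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        coords = lattice_coords("square", 25, 20, 1.0)
        n_loc = len(coords)
        W, _ = compute_weights(coords, WeightScheme(cutoff=1.5))
        bound = np.zeros(n_loc, dtype=bool)
        bound[rng.choice(n_loc, 30, replace=False)] = True
        tcell = bound.copy()
        tcell[rng.choice(n_loc, 80, replace=False)] = True
        A = W.copy().tolil()
        A.setdiag(0)
        near_bound = (A.tocsr() @ bound.astype(float)) > 0
        scores = rng.standard_normal(n_loc) + shift * near_bound
        return scores, W, bound, tcell

    def test_planted_shift_detected(self):
        scores, W, bound, tcell = self._setup(shift=1.0, seed=1)
        summary, tests = compare_scores_by_neighbor_class(scores, W, bound,
                                                          tcell)
        row = tests[(tests["class_a"] == "near_cpi_bound_t")
                    & (tests["class_b"] == "near_other")]
        assert row["p_value"].iloc[0] < 0.01
        assert summary.loc["near_cpi_bound_t", "median"] \
            > summary.loc["near_other", "median"]

    def test_null_shift_not_detected(self):
        ps = []
        for seed in range(4):
            scores, W, bound, tcell = self._setup(shift=0.0, seed=seed)
            _, tests = compare_scores_by_neighbor_class(scores, W, bound,
                                                        tcell)
            ps.extend(tests["p_value"])
        assert min(ps) > 1e-4  # no spurious strong signal under the null

    def test_empty_class_skipped(self):
        scores = np.random.default_rng(0).standard_normal(9)
        coords = lattice_coords("square", 3, 3, 1.0)
        W, _ = compute_weights(coords, WeightScheme(cutoff=1.5))
        bound = np.zeros(9, dtype=bool)
        tcell = np.zeros(9, dtype=bool)
        summary, tests = compare_scores_by_neighbor_class(scores, W, bound,
                                                          tcell)
        assert summary.loc["near_other", "n"] == 9
        assert np.isnan(summary.loc["near_cpi_bound_t", "median"])
        assert len(tests) == 0
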