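"""Benchmark experiments on synthetic data with ground truth.

Each function runs one self-contained study at desk scale — generate data,
run the pipeline, score against truth — and returns the headline numbers.
They back both the validation test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .binding import PdOccupancyModel
from .niches import cluster_niches, crypt_adjacency_network, neighbor_composition
from .simulate import (
    PlantedPair,
    SimCiteSeqConfig,
    SimSpatialConfig,
    lattice_coords,
    simulate_citeseq,
    simulate_hashtags,
    simulate_spatial,
)
from .spatial import RlColocalization, WeightScheme, compute_weights, rl_score
from .tags import demux_hashtags

__all__ = [
    "naive_rl_scores",
    "rl_oracle_deviation",
    "permutation_calibration",
    "planted_microdomain_recovery",
    "qrf_calibration",
    "binding_recovery",
    "demux_benchmark",
    "niche_recovery",
    "adjacency_oracle_deviation",
]


def naive_rl_scores(coords, L, R, scheme: WeightScheme) -> np.ndarray:
    """O(n^2) reference implementation of the smoothed RL product score."""
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


def rl_oracle_deviation(seed: int = 0, n_loc: int = 200) -> float:
    """Max |vectorized - naive| RL score on a random map."""
    rng = np.random.default_rng(seed)
    coords = rng.random((n_loc, 2)) * 10
    L = rng.poisson(3, n_loc).astype(float)
    R = rng.poisson(2, n_loc).astype(float)
    scheme = WeightScheme(cutoff=2.0)
    W, n = compute_weights(coords, scheme)
    return float(np.abs(rl_score(L, R, W, n)
                        - naive_rl_scores(coords, L, R, scheme)).max())


def permutation_calibration(seeds=(0, 1, 2, 3, 4), n_perm: int = 100) -> dict:
    """Null rejection rate of the RL permutation test on i.i.d. expression.

    500 hex locations x 20 pairs per seed; reports the mean fraction of
    locations with p < 0.05 and the total FDR < 0.05 positive count (both
    should reflect a well-calibrated null: ~0.05 and ~0 respectively).
    """
    fracs, positives = [], 0
    for seed in seeds:
        smap, _ = simulate_spatial(SimSpatialConfig(
            lattice="hex", n_rows=20, n_cols=25, n_genes=40, seed=seed))
        pairs = [(f"G{2*i}", f"G{2*i+1}") for i in range(20)]
        res = RlColocalization(smap, pairs, WeightScheme.from_pitch(1.0)).fit(
            n_perm=n_perm, seed=seed)
        fracs.append(float((res.table["p_value"] < 0.05).mean()))
        positives += int(res.table["positive"].sum())
    return {"mean_frac_p05": float(np.mean(fracs)), "per_seed": fracs,
            "total_positives": positives,
            "n_tests_per_seed": 500 * 20}


def planted_microdomain_recovery(seed: int = 1, n_perm: int = 100) -> dict:
    """Recovery of 5-fold co-elevated RL microdomains.

    A 100x100 hex slide carries one 7-location disc per tested pair (10
    pairs, one signaling microdomain each, as in a tissue with several
    active pathways).  Reports the fraction of planted (location, pair)
    combinations called positive at FDR < 0.05 and the false-positive count
    outside the discs.
    """
    centers = [(15 + (i % 5) * 17, 12 + (i // 5) * 40) for i in range(10)]
    planted = [PlantedPair(f"G{2*i}", f"G{2*i+1}", centers[i], 1.05, 5.0)
               for i in range(10)]
    smap, truth = simulate_spatial(SimSpatialConfig(
        lattice="hex", n_rows=100, n_cols=100, n_genes=40, seed=seed,
        planted_pairs=planted))
    pairs = [(f"G{2*i}", f"G{2*i+1}") for i in range(10)]
    res = RlColocalization(smap, pairs, WeightScheme.from_pitch(1.0)).fit(
        n_perm=n_perm, seed=seed)
    tp = fp = tot = 0
    for i in range(10):
        name = f"G{2*i}->G{2*i+1}"
        pl = truth.planted_positive[name].to_numpy()
        pos = res.table.loc[res.table["pair"] == name, "positive"].to_numpy()
        tp += int(pos[pl].sum())
        fp += int(pos[~pl].sum())
        tot += int(pl.sum())
    return {"recovery": tp / tot, "true_positives": tp, "planted": tot,
            "false_positives": fp, "discoveries": tp + fp}


def qrf_calibration(seed: int = 1, alphas=(0.05, 0.10, 0.15)) -> dict:
    """Conditional-CDF calibration on held-out untreated cells.

    7000 untreated cells; the occupancy pipeline (feature selection + QRF)
    trains on 5000 and evaluates u on the 2000-cell random hold-out.  A
    calibrated model gives P(u < alpha) = alpha.
    """
    ds, _ = simulate_citeseq(SimCiteSeqConfig(n_cells=7000, frac_treated=0.0,
                                              seed=seed))
    model = PdOccupancyModel.from_dataset(ds)
    res = model.fit(holdout_donor=None, holdout_frac=2000 / 7000, seed=seed)
    u = res.conditional_cdf(res.holdout_idx)
    out = {f"frac_u_lt_{a:g}": float((u < a).mean()) for a in alphas}
    out["n_train"] = int(len(res.train_idx))
    out["n_holdout"] = int(len(res.holdout_idx))
    return out


def binding_recovery(seed: int = 2, alpha: float = 0.05) -> dict:
    """Sensitivity/specificity of bound-cell calling on treated cells.

    ~2000 treated cells with 30% drug-bound and an ADT blocking factor of
    0.125; the model trains on the untreated remainder.  Also checks exact
    nestedness of the bound sets across the confidence ladder.
    """
    ds, truth = simulate_citeseq(SimCiteSeqConfig(
        n_cells=7000, frac_treated=0.3, n_donors=10, seed=seed))
    model = PdOccupancyModel.from_dataset(ds)
    res = model.fit(seed=seed)
    treated = np.where(model.treated)[0]
    calls = res.call_bound(treated)
    bound_true = truth.cells["bound"].to_numpy()[treated]
    b = calls.bound(alpha)
    nested = True
    a_sorted = sorted(calls.alphas)
    for lo, hi in zip(a_sorted, a_sorted[1:]):
        nested &= not bool(np.any(calls.bound(lo) & ~calls.bound(hi)))
    return {
        "sensitivity": float(b[bound_true].mean()),
        "specificity": float((~b[~bound_true]).mean()),
        "nested": nested,
        "n_treated": int(len(treated)),
        "frac_bound_true": float(bound_true.mean()),
    }


def demux_benchmark(seed: int = 3, n_cells: int = 2000) -> dict:
    """Demultiplexing accuracy on a 4-sample pool with 5% doublets."""
    tags, truth = simulate_hashtags(n_cells, 4, 0.05, mu_pos=500, mu_neg=10,
                                    seed=seed)
    res = demux_hashtags(tags, n_samples=4, seed=seed)
    t = truth.cells
    singlet = ~t["doublet"].to_numpy()
    called = res.calls["classification"].to_numpy()
    sample = res.calls["sample"].fillna("").to_numpy()
    expected = np.array([f"HTO{a+1}" for a in t["sample_a"]])
    ok = (called == "singlet") & (sample == expected)
    return {
        "singlet_accuracy": float(ok[singlet].mean()),
        "doublet_detection": float((called[~singlet] == "doublet").mean()),
        "n_cells": n_cells,
    }


def niche_recovery(seeds=(1, 2, 3)) -> dict:
    """ARI of recovered vs planted niches on 10,000-cell maps (5 niches)."""
    aris = []
    for seed in seeds:
        smap, truth = simulate_spatial(SimSpatialConfig(
            lattice="square", n_rows=100, n_cols=100, n_genes=5,
            n_niches=5, jitter=0.15, seed=seed))
        comp = neighbor_composition(smap.coords,
                                    smap.obs["cell_type"].to_numpy(),
                                    rule="knn", k=10, radius=3.0)
        nm = cluster_niches(comp, seed=seed)
        aris.append(float(adjusted_rand_score(
            truth.cells["niche_label"].to_numpy(), nm.labels)))
    return {"ari_per_seed": aris, "min_ari": min(aris),
            "mean_ari": float(np.mean(aris)), "n_cells": 10000}


def adjacency_oracle_deviation(n: int = 8) -> dict:
    """Checkerboard cluster adjacency network vs a brute-force reference."""
    coords = lattice_coords("square", n, n, 1.0)
    clusters = np.array([(int(x) + int(y)) % 2 for x, y in coords])
    _, edges = crypt_adjacency_network(coords, clusters,
                                       np.full(n * n, 2.0),
                                       dist_window=(0, 1.5))
    frac_sum = np.zeros((2, 2))
    cnt = np.zeros(2)
    for i in range(n * n):
        adj = [j for j in range(n * n)
               if 0 < np.hypot(*(coords[i] - coords[j])) < 1.5]
        c = np.zeros(2)
        for j in adj:
            c[clusters[j]] += 1
        frac_sum[clusters[i]] += c / len(adj)
        cnt[clusters[i]] += 1
    ref = frac_sum / cnt[:, None]
    got = {(r.source, r.target): r.weight for r in edges.itertuples()}
    dev = max(abs(got.get((a, b), 0.0) - ref[a, b])
              for a in (0, 1) for b in (0, 1))
    sums = edges.groupby("source")["weight"].sum()
    return {"max_abs_deviation": float(dev),
            "max_outgoing_sum_error": float((sums - 1.0).abs().max())}
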