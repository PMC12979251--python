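"""ADT/hashtag normalization, NB-threshold demultiplexing and QC filtering.

Demultiplexing follows the threshold scheme used for hashed CITE-seq pools:
CLR-normalize the tag counts, partition cells with k-medoids into
``n_samples + 1`` groups, fit a negative binomial to each tag's counts in its
lowest-signal group, and call a cell positive for a tag when its raw count
exceeds the NB quantile at ``positive_quantile``.  Cells positive for exactly
one tag are singlets; for several, doublets; for none, negatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = ["clr_normalize", "demux_hashtags", "qc_filter", "DemuxResult"]


def clr_normalize(counts) -> np.ndarray:
    """Centered log-ratio transform of tag counts, per cell.

    ``y_ij = ln(x_ij + 1) - mean_k ln(x_ik + 1)`` with the mean taken over the
    tag panel of that cell, so each row sums to zero.  Accepts an array or a
    DataFrame (returned as the same type).
    """
    x = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    if x.size == 0:
        raise ValueError("empty tag matrix")
    if np.any(x < 0):
        raise ValueError("tag counts must be non-negative")
    logx = np.log1p(x.astype(float))
    y = logx - logx.mean(axis=1, keepdims=True)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(y, index=counts.index, columns=counts.columns)
    return y


# ---------------------------------------------------------------------------
# k-medoids (CLARA-style: PAM refinement on a subsample, assign the rest)
# ---------------------------------------------------------------------------


def _kmedoids(X: np.ndarray, k: int, rng: np.random.Generator,
              max_sub: int = 1000, max_iter: int = 50,
              n_restarts: int = 8) -> np.ndarray:
    """Euclidean k-medoids labels (CLARA-style).

    Alternating PAM on a subsample of <= max_sub points with multiple
    seeded restarts; the solution with the lowest total within-cluster
    distance wins, then all points are assigned to the nearest medoid.
    """
    n = X.shape[0]
    if n < k:
        raise ValueError(f"fewer cells ({n}) than clusters ({k})")
    sub = rng.choice(n, size=min(n, max_sub), replace=False)
    S = X[sub]
    D = np.linalg.norm(S[:, None, :] - S[None, :, :], axis=2)

    best_cost, best_medoids = np.inf, None
    for _ in range(n_restarts):
        # k-means++-style seeding on the subsample
        medoids = [int(rng.integers(len(sub)))]
        for _ in range(k - 1):
            d2 = np.min(D[:, medoids] ** 2, axis=1)
            tot = d2.sum()
            if tot <= 0:
                remaining = [i for i in range(len(sub)) if i not in medoids]
                medoids.append(remaining[0])
                continue
            medoids.append(int(rng.choice(len(sub), p=d2 / tot)))
        medoids = np.array(medoids)

        for _ in range(max_iter):
            lab = np.argmin(D[:, medoids], axis=1)
            new = medoids.copy()
            for j in range(k):
                members = np.where(lab == j)[0]
                if len(members) == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new[j] = members[np.argmin(within)]
            if np.array_equal(np.sort(new), np.sort(medoids)):
                break
            medoids = new
        cost = np.min(D[:, medoids], axis=1).sum()
        if cost < best_cost:
            best_cost, best_medoids = cost, medoids

    centers = S[best_medoids]
    full_d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
    return np.argmin(full_d, axis=1)


# ---------------------------------------------------------------------------
# NB fit
# ---------------------------------------------------------------------------


def fit_negative_binomial(x: np.ndarray) -> tuple:
    """Fit NB(mean mu, shape theta) to counts: moments init, ML refinement.

    Returns ``(mu, theta)``.  Degenerate inputs (constant or underdispersed)
    fall back to a near-Poisson shape.
    """
    x = np.asarray(x, dtype=float)
    mu = float(x.mean())
    if mu <= 0:
        return 0.0, np.inf
    var = float(x.var(ddof=1)) if len(x) > 1 else mu
    theta0 = mu**2 / (var - mu) if var > mu else 1e6

    def nll(log_theta):
        th = np.exp(log_theta)
        p = th / (th + mu)
        return -stats.nbinom.logpmf(x, th, p).sum()

    with np.errstate(all="ignore"):
        res = minimize_scalar(
            nll, bounds=(np.log(1e-3), np.log(1e6)),
            method="bounded",
            options={"xatol": 1e-4},
        )
    theta = float(np.exp(res.x)) if res.success else float(np.clip(theta0, 1e-3, 1e6))
    return mu, theta


def _nb_quantile(q: float, mu: float, theta: float) -> float:
    if mu <= 0:
        return np.inf
    if not np.isfinite(theta):
        return float(stats.poisson.ppf(q, mu))
    p = theta / (theta + mu)
    return float(stats.nbinom.ppf(q, theta, p))


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


@dataclass
class DemuxResult:
    """Per-cell classification plus per-tag NB fits and thresholds.

    ``calls`` has columns ``classification`` (singlet/doublet/negative),
    ``sample`` (tag name for singlets, NA otherwise) and one boolean
    ``pos_<tag>`` column per tag.  ``thresholds`` maps tag -> count threshold;
    ``nb_params`` maps tag -> (mu, theta).  ``metadata`` records the fitting
    conventions so downstream users can audit them.
    """

    calls: pd.DataFrame
    thresholds: dict
    nb_params: dict
    metadata: dict = field(default_factory=dict)

    @property
    def singlet_mask(self) -> np.ndarray:
        return (self.calls["classification"] == "singlet").to_numpy()


def demux_hashtags(
    counts,
    n_samples: int | None = None,
    positive_quantile: float = 0.99,
    seed: int = 0,
    min_cluster_size: int = 20,
) -> DemuxResult:
    """Demultiplex a hashed pool by per-tag NB count thresholds.

    Parameters
    ----------
    counts : DataFrame (cells x tags) or array
        Raw hashing-tag UMI counts, restricted to tags present in the pool.
    n_samples : int, optional
        Number of hashed samples; defaults to the number of tag columns.
        The initial k-medoids partition uses ``n_samples + 1`` groups (one
        per sample plus one for negatives).
    positive_quantile : float
        NB quantile defining the positive-count threshold per tag.
    min_cluster_size : int
        If a tag's lowest-signal cluster is smaller than this, the NB is fit
        on the tag's global lowest quintile instead (robustness on small
        pools).
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame(
            np.asarray(counts),
            columns=[f"HTO{j+1}" for j in range(np.asarray(counts).shape[1])],
        )
    if not (0 < positive_quantile < 1):
        raise ValueError("positive_quantile must lie in (0, 1)")
    tag_names = list(counts.columns)
    if n_samples is None:
        n_samples = len(tag_names)
    k = n_samples + 1
    raw = counts.to_numpy()
    clr = clr_normalize(raw)

    rng = np.random.default_rng(seed)
    labels = _kmedoids(clr, k, rng)

    thresholds, nb_params = {}, {}
    positive = np.zeros(raw.shape, dtype=bool)
    for j, tag in enumerate(tag_names):
        if raw[:, j].max() == 0:
            warnings.warn(f"tag {tag} has all-zero counts; threshold set to +inf")
            thresholds[tag] = np.inf
            nb_params[tag] = (0.0, np.inf)
            continue
        # negative sample: cells from every cluster whose mean tag count sits
        # below the log-midpoint between the lowest and highest cluster means
        # (robust when one tag's positives are split across clusters)
        m = np.array([raw[labels == c, j].mean() if np.any(labels == c)
                      else np.nan for c in range(k)])
        lm = np.log1p(m)
        lo_m, hi_m = np.nanmin(lm), np.nanmax(lm)
        if hi_m - lo_m < np.log(2.0):
            neg_clusters = np.arange(k)  # no separated positive cluster
        else:
            neg_clusters = np.where(lm <= (lo_m + hi_m) / 2.0)[0]
        neg = raw[np.isin(labels, neg_clusters), j]
        if len(neg) < min_cluster_size:
            q20 = np.quantile(raw[:, j], 0.2)
            neg = raw[raw[:, j] <= q20, j]
        mu, theta = fit_negative_binomial(neg)
        thr = _nb_quantile(positive_quantile, mu, theta)
        thresholds[tag] = thr
        nb_params[tag] = (mu, theta)
        positive[:, j] = raw[:, j] > thr

    n_pos = positive.sum(axis=1)
    classification = np.where(
        n_pos == 0, "negative", np.where(n_pos == 1, "singlet", "doublet")
    )
    sample = pd.array(
        [tag_names[int(np.argmax(row))] if npos == 1 else pd.NA
         for row, npos in zip(positive, n_pos)],
        dtype="string",
    )
    calls = pd.DataFrame(
        {"classification": classification, "sample": sample}, index=counts.index
    )
    for j, tag in enumerate(tag_names):
        calls[f"pos_{tag}"] = positive[:, j]

    meta = {
        "nb_fit": "raw counts of the per-tag lowest-mean k-medoids cluster "
                  "(fallback: global lowest quintile)",
        "positive_quantile": positive_quantile,
        "k": k,
        "seed": seed,
    }
    return DemuxResult(calls=calls, thresholds=thresholds, nb_params=nb_params,
                       metadata=meta)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def qc_filter(dataset, thresholds: dict, compartment_col: str | None = None):
    """Remove cells failing per-compartment QC thresholds.

    ``thresholds`` is either a flat dict ``{"min_total_counts": ..,
    "max_mito_pct": ..}`` applied to all cells, or, with ``compartment_col``
    given, a mapping compartment -> such a dict.  Returns
    ``(filtered dataset, report DataFrame)`` with removal counts per rule.
    """
    obs = dataset.obs
    flat = compartment_col is None
    groups = {None: thresholds} if flat else thresholds
    keep = np.ones(dataset.n_cells, dtype=bool)
    rows = []
    if not flat and compartment_col not in obs.columns:
        raise KeyError(f"metadata column {compartment_col!r} is missing")
    for comp, th in groups.items():
        in_comp = (
            np.ones(dataset.n_cells, dtype=bool)
            if flat
            else (obs[compartment_col] == comp).to_numpy()
        )
        for rule, col, op in [
            ("min_total_counts", "total_counts", "lt"),
            ("max_mito_pct", "mito_pct", "gt"),
        ]:
            if rule not in th:
                continue
            if col not in obs.columns:
                raise KeyError(f"metadata column {col!r} is missing")
            vals = obs[col].to_numpy(dtype=float)
            fails = in_comp & ((vals < th[rule]) if op == "lt" else (vals > th[rule]))
            rows.append({"compartment": comp, "rule": rule,
                         "removed": int((fails & keep).sum())})
            keep &= ~fails
    report = pd.DataFrame(rows, columns=["compartment", "rule", "removed"])
    return dataset.subset(keep), report
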