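"""Drug-occupancy calling from measured-vs-predicted PD-1 tag discordance.

The caller trains a quantile regression forest to predict the CLR-normalized
anti-PD-1 antibody-tag signal of untreated cells from features that carry no
drug information (embedding components, QC covariates, PDCD1 mRNA).  For a
treated cell the conditional CDF value ``u = F(measured | x)`` locates the
measured signal within the model's predicted distribution; epitope blocking
by the drug can only suppress the measured tag, so cells in the lower tail
(``u < alpha``) are called bound at confidence ``alpha``.  The default
confidence ladder {0.01, 0.05, 0.10, 0.15} corresponds to predicted-quantile
thresholds 0.99/0.95/0.90/0.85.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .datasets import CiteSeqDataset
from .qrf import QuantileRegressionForest
from .tags import clr_normalize

__all__ = [
    "assemble_features",
    "select_features",
    "PdOccupancyModel",
    "PdOccupancyResults",
    "BindingCalls",
    "cluster_bound_fractions",
]

DEFAULT_ALPHAS = (0.01, 0.05, 0.10, 0.15)


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------


def assemble_features(dataset: CiteSeqDataset, pdcd1_gene: str = "PDCD1",
                      max_embed_dims: int = 30) -> pd.DataFrame:
    """Build the predictor table for the occupancy model.

    Columns: up to 30 embedding components, cell-cycle scores and one-hot
    phase, one-hot reaction, total RNA counts, gene detection rate,
    mitochondrial and ribosomal percentages, and normalized PDCD1 mRNA
    (log1p of library-size-scaled counts).
    """
    if dataset.embedding is None:
        raise ValueError("dataset has no embedding; required for feature assembly")
    obs = dataset.obs
    n_dims = min(max_embed_dims, dataset.embedding.shape[1])
    feats = pd.DataFrame(
        dataset.embedding[:, :n_dims],
        columns=[f"embed_{i}" for i in range(n_dims)],
        index=obs.index,
    )
    for col in ("s_score", "g2m_score", "total_counts", "detection_rate",
                "mito_pct", "ribo_pct"):
        if col not in obs.columns:
            raise ValueError(f"metadata column {col!r} is missing")
        feats[col] = obs[col].to_numpy(dtype=float)
    if "phase" in obs.columns:
        for ph in sorted(obs["phase"].unique())[1:]:
            feats[f"phase_{ph}"] = (obs["phase"] == ph).to_numpy(dtype=float)
    if "reaction" in obs.columns:
        for rx in sorted(pd.unique(obs["reaction"]))[1:]:
            feats[f"reaction_{rx}"] = (obs["reaction"] == rx).to_numpy(dtype=float)

    if pdcd1_gene not in dataset.gene_names:
        raise ValueError(f"gene {pdcd1_gene!r} not found in dataset")
    gi = dataset.gene_names.index(pdcd1_gene)
    counts = dataset.counts[:, gi].astype(float)
    total = dataset.counts.sum(axis=1).astype(float)
    med = np.median(total[total > 0]) if np.any(total > 0) else 1.0
    feats["pdcd1_norm"] = np.log1p(counts / np.maximum(total, 1.0) * med)

    if feats.isna().any().any():
        raise ValueError("assembled features contain missing values")
    return feats


def clr_pd1(dataset: CiteSeqDataset, tag: str = "PD1") -> np.ndarray:
    """CLR-normalized anti-PD-1 tag signal over the ADT panel."""
    if dataset.adt is None:
        raise ValueError("dataset has no ADT counts")
    j = dataset.adt_names.index(tag)
    return clr_normalize(dataset.adt)[:, j]


# ---------------------------------------------------------------------------
# Recursive feature selection
# ---------------------------------------------------------------------------


def select_features(
    features: pd.DataFrame,
    target: np.ndarray,
    importance_threshold: float = 5.0,
    seed: int = 0,
    n_estimators: int = 100,
    n_repeats: int = 3,
    max_perm_samples: int = 1000,
) -> tuple:
    """Recursive elimination keeping features with relative importance above
    the threshold.

    Each round fits a forest, computes permutation importances on a
    subsample, clips negatives to zero and rescales so the total is 100
    (threshold 5 then reads "at least 5% of total importance"), and drops the
    single weakest feature until every remaining one clears the threshold.

    Returns ``(selected names, final importance Series)``.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features")
    cols = list(features.columns)
    X = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    rng = np.random.default_rng(seed)
    sub = (
        rng.choice(len(y), size=max_perm_samples, replace=False)
        if len(y) > max_perm_samples
        else np.arange(len(y))
    )

    active = np.arange(len(cols))
    while True:
        rf = RandomForestRegressor(
            n_estimators=n_estimators, min_samples_leaf=10,
            max_features=1.0 / 3, random_state=seed, n_jobs=1,
        ).fit(X[:, active], y)
        imp = permutation_importance(
            rf, X[np.ix_(sub, active)], y[sub],
            n_repeats=n_repeats, random_state=seed, n_jobs=1,
        ).importances_mean
        imp = np.clip(imp, 0, None)
        tot = imp.sum()
        if tot <= 0:
            raise ValueError(
                "all remaining features are uninformative; lower the threshold"
            )
        rel = 100.0 * imp / tot
        if rel.min() >= importance_threshold or len(active) == 1:
            break
        active = np.delete(active, int(np.argmin(rel)))
        if len(active) == 0:
            raise ValueError("all features eliminated; lower the threshold")
    if rel.min() < importance_threshold:
        raise ValueError(
            "all features eliminated before clearing the threshold; lower it"
        )
    names = [cols[i] for i in active]
    return names, pd.Series(rel, index=names).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Calls container
# ---------------------------------------------------------------------------


@dataclass
class BindingCalls:
    """Per-cell conditional-CDF values and bound flags per confidence level.

    ``table`` has a ``u`` column and one boolean ``bound_<alpha>`` column per
    level; flag sets are nested across alphas because they all threshold the
    same ``u``.
    """

    table: pd.DataFrame
    alphas: tuple = DEFAULT_ALPHAS

    def bound(self, alpha: float) -> np.ndarray:
        col = f"bound_{alpha:g}"
        if col not in self.table.columns:
            raise KeyError(f"no calls at alpha={alpha}")
        return self.table[col].to_numpy()


def call_bound(u: np.ndarray, alphas=DEFAULT_ALPHAS,
               index=None) -> BindingCalls:
    """Flag cells as drug-bound at each confidence level: bound iff u < alpha.

    One-sided lower tail: competitive epitope blocking can only reduce the
    measured tag signal, so only unexpectedly low measurements are evidence
    of occupancy.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("conditional CDF values must lie in [0, 1]")
    alphas = tuple(float(a) for a in alphas)
    for a in alphas:
        if not (0 < a < 0.5):
            raise ValueError(f"alpha={a} outside (0, 0.5)")
    table = pd.DataFrame({"u": u}, index=index)
    for a in alphas:
        table[f"bound_{a:g}"] = u < a
    return BindingCalls(table=table, alphas=alphas)


def cluster_bound_fractions(
    calls: BindingCalls,
    clusters,
    alpha: float = 0.05,
    conditional_u_draws: np.ndarray | None = None,
    n_draws: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster bound fraction with a conditional-distribution CI.

    The point estimate is the fraction of cluster cells bound at ``alpha``.
    The interval resamples each cell's hypothetical measurement from its
    model conditional distribution (``conditional_u_draws``: cells x draws
    matrix of the resampled measurements' own CDF values, produced by
    :meth:`PdOccupancyResults.conditional_u_draws`), re-calls bound status
    and takes the 2.5/97.5 percentiles of the per-draw fractions.  Without
    draws a plain binomial (Wilson) interval is reported instead and flagged
    in the ``ci_method`` column.
    """
    clusters = np.asarray(clusters)
    bound = calls.bound(alpha)
    if len(clusters) != len(bound):
        raise ValueError("clusters and calls disagree on the number of cells")
    rows = []
    for cl in pd.unique(clusters):
        m = clusters == cl
        n = int(m.sum())
        if n == 0:
            continue
        frac = float(bound[m].mean())
        if conditional_u_draws is not None:
            draws = conditional_u_draws[m]  # (n_cells_in_cluster, n_draws)
            fr = (draws < alpha).mean(axis=0)
            lo, hi = np.percentile(fr, [2.5, 97.5])
            method = "conditional"
        else:
            ci = stats.binomtest(int(bound[m].sum()), n).proportion_ci(method="wilson")
            lo, hi = ci.low, ci.high
            method = "binomial"
        rows.append({"cluster": cl, "n": n, "fraction": frac,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "ci_method": method})
    return pd.DataFrame(rows).set_index("cluster")


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class PdOccupancyModel:
    """Occupancy model: predict PD-1 tag signal of untreated cells, flag
    treated cells whose measured signal falls in the lower tail.

    Parameters
    ----------
    features : DataFrame (cells x predictors)
        Typically from :func:`assemble_features`.
    target : array
        CLR-normalized anti-PD-1 tag signal per cell.
    treated : boolean array
        Drug-treated flag per cell; only untreated cells are used for
        training/validation.
    donor : array, optional
        Donor id per cell; one untreated donor is held out entirely as an
        independent validation set.
    """

    def __init__(self, features: pd.DataFrame, target, treated, donor=None):
        self.features = features
        self.target = np.asarray(target, dtype=float)
        self.treated = np.asarray(treated, dtype=bool)
        self.donor = None if donor is None else np.asarray(donor)
        if len(self.target) != len(features) or len(self.treated) != len(features):
            raise ValueError("features, target and treated must align")

    @classmethod
    def from_dataset(cls, dataset: CiteSeqDataset, pd1_tag: str = "PD1"):
        feats = assemble_features(dataset)
        target = clr_pd1(dataset, pd1_tag)
        donor = dataset.obs["donor"].to_numpy() if "donor" in dataset.obs else None
        return cls(feats, target, dataset.obs["treated"].to_numpy(), donor)

    def fit(
        self,
        importance_threshold: float = 5.0,
        feature_selection: bool = True,
        holdout_frac: float = 0.33,
        holdout_donor="auto",
        n_trees: int = 300,
        min_leaf: int = 20,
        seed: int = 0,
        selection_kwargs: dict | None = None,
    ) -> "PdOccupancyResults":
        """Train on untreated cells and return a results object.

        Splits the untreated cells into one fully held-out donor, a random
        ``holdout_frac`` testing subset of the remaining donors, and a
        training set; runs recursive feature selection on the training set;
        fits the quantile regression forest on the selected features.
        """
        rng = np.random.default_rng(seed)
        untreated = np.where(~self.treated)[0]
        if len(untreated) < 50:
            raise ValueError("need at least 50 untreated training cells")

        if holdout_donor == "auto":
            if self.donor is not None:
                udonors = np.unique(self.donor[untreated])
                holdout_donor = udonors[-1] if len(udonors) > 1 else None
            else:
                holdout_donor = None
        donor_mask = (
            (self.donor == holdout_donor) if holdout_donor is not None
            else np.zeros(len(self.target), dtype=bool)
        )
        pool = untreated[~donor_mask[untreated]]
        perm = rng.permutation(len(pool))
        n_hold = int(round(holdout_frac * len(pool)))
        holdout_idx = pool[perm[:n_hold]]
        train_idx = pool[perm[n_hold:]]
        donor_idx = untreated[donor_mask[untreated]]
        if len(train_idx) < 50:
            raise ValueError("need at least 50 untreated training cells")

        X = self.features
        y = self.target
        if feature_selection:
            selected, importances = select_features(
                X.iloc[train_idx], y[train_idx],
                importance_threshold=importance_threshold, seed=seed,
                **(selection_kwargs or {}),
            )
        else:
            selected = list(X.columns)
            importances = pd.Series(np.nan, index=selected)

        qrf = QuantileRegressionForest(
            n_estimators=n_trees, min_samples_leaf=min_leaf, random_state=seed
        ).fit(X.iloc[train_idx][selected], y[train_idx])

        return PdOccupancyResults(
            model=self, qrf=qrf, selected_features=selected,
            importances=importances, train_idx=train_idx,
            holdout_idx=holdout_idx, donor_holdout_idx=donor_idx,
            holdout_donor=holdout_donor, seed=seed,
        )


@dataclass
class PdOccupancyResults:
    """Fitted occupancy model: validation, conditional CDFs, bound calls."""

    model: PdOccupancyModel
    qrf: QuantileRegressionForest
    selected_features: list
    importances: pd.Series
    train_idx: np.ndarray
    holdout_idx: np.ndarray
    donor_holdout_idx: np.ndarray
    holdout_donor: object
    seed: int
    metadata: dict = field(default_factory=lambda: {
        "tail": "one-sided lower (u < alpha); epitope blocking can only "
                "suppress the measured tag signal",
        "tie_convention": "weak inequality (<=) in the conditional CDF",
    })

    def _X(self, idx):
        return self.model.features.iloc[idx][self.selected_features]

    # -- validation --------------------------------------------------------

    def validate(self, min_r: float = 0.2) -> pd.DataFrame:
        """Pearson r between predicted median and measured signal on the
        random hold-out and the held-out donor; flagged below ``min_r``."""
        rows = []
        for name, idx in [("random_holdout", self.holdout_idx),
                          ("heldout_donor", self.donor_holdout_idx)]:
            if len(idx) == 0:
                continue
            pred = self.qrf.predict_median(self._X(idx))
            r, p = stats.pearsonr(pred, self.model.target[idx])
            rows.append({"set": name, "n": len(idx), "pearson_r": r,
                         "p_value": p, "flagged": bool(r < min_r)})
        if not rows:
            raise ValueError("no hold-out cells available for validation")
        return pd.DataFrame(rows).set_index("set")

    # -- conditional CDF and calls -----------------------------------------

    def conditional_cdf(self, idx=None) -> np.ndarray:
        """``u = F(measured | x)`` for the given cell indices (default: all
        treated cells)."""
        if idx is None:
            idx = np.where(self.model.treated)[0]
        idx = np.asarray(idx)
        return self.qrf.predict_cdf(self._X(idx), self.model.target[idx])

    def call_bound(self, idx=None, alphas=DEFAULT_ALPHAS) -> BindingCalls:
        if idx is None:
            idx = np.where(self.model.treated)[0]
        idx = np.asarray(idx)
        u = self.conditional_cdf(idx)
        return call_bound(u, alphas, index=self.model.features.index[idx])

    def conditional_u_draws(self, idx, n_draws: int = 200,
                            seed: int | None = None) -> np.ndarray:
        """Monte-Carlo draws from each cell's conditional distribution,
        returned as the draws' own conditional-CDF values (cells x draws)."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        _, us = self.qrf.sample_conditional_cdf(self._X(np.asarray(idx)),
                                                n_draws, rng)
        return us

    def cluster_fractions(self, clusters, idx=None, alpha: float = 0.05,
                          n_draws: int = 200, seed: int | None = None,
                          alphas=DEFAULT_ALPHAS) -> pd.DataFrame:
        """Per-cluster bound fractions at ``alpha`` with conditional-
        distribution CIs (see :func:`cluster_bound_fractions`)."""
        if idx is None:
            idx = np.where(self.model.treated)[0]
        idx = np.asarray(idx)
        calls = self.call_bound(idx, alphas)
        draws = self.conditional_u_draws(idx, n_draws=n_draws, seed=seed)
        return cluster_bound_fractions(calls, np.asarray(clusters),
                                       alpha=alpha,
                                       conditional_u_draws=draws)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        val = self.validate()
        lines = [
            "PD-1 occupancy model (quantile regression forest)",
            "=" * 52,
            f"training cells (untreated):   {len(self.train_idx)}",
            f"random hold-out cells:        {len(self.holdout_idx)}",
            f"held-out donor:               {self.holdout_donor} "
            f"({len(self.donor_holdout_idx)} cells)",
            f"selected features ({len(self.selected_features)}): "
            + ", ".join(self.selected_features),
            "",
            "validation (predicted median vs measured):",
        ]
        for name, row in val.iterrows():
            flag = "  [FLAGGED]" if row["flagged"] else ""
            lines.append(
                f"  {name:16s} n={int(row['n']):6d}  r={row['pearson_r']:.3f}{flag}"
            )
        lines.append("")
        lines.append(f"decision rule: {self.metadata['tail']}")
        return "\n".join(lines)
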