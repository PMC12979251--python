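"""Quantile regression forest: conditional distributions from forest leaves.

A random forest regressor is grown as usual, but instead of retaining only
per-leaf means, every leaf keeps the training targets that fall into it.
For a query point x the conditional CDF is estimated as

    F(y | x) = mean over trees of (fraction of targets in x's leaf <= y)

which equals the leaf-co-membership-weighted empirical CDF of the training
targets.  Conditional quantiles are read off this CDF (type-1 inverse), so
``Q_tau(x)`` is non-decreasing in ``tau`` by construction, and conditional
sampling draws a leaf target from a uniformly chosen tree.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestRegressor

__all__ = ["QuantileRegressionForest"]


class QuantileRegressionForest:
    """Forest regressor exposing conditional quantiles, CDF and sampling.

    Parameters
    ----------
    n_estimators : int
        Number of trees.
    min_samples_leaf : int
        Minimum leaf size; leaves are the resolution of the conditional
        distribution estimate, so very small leaves give noisy CDFs.
    random_state : int
        Seed for the forest.
    """

    def __init__(self, n_estimators: int = 200, min_samples_leaf: int = 20,
                 max_features: float | str = 1.0, random_state: int = 0,
                 n_jobs: int = 1):
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.random_state = random_state
        self.n_jobs = n_jobs

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "QuantileRegressionForest":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training samples")
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
        ).fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.y_train_ = y

        # per tree: leaf ids sorted, CSR-style offsets into per-leaf target
        # values sorted ascending within each leaf
        leaves = self.forest_.apply(X)  # (n_train, n_trees)
        self._leaf_ids, self._offsets, self._leaf_y, self._leaf_idx = [], [], [], []
        for t in range(leaves.shape[1]):
            order = np.lexsort((y, leaves[:, t]))
            lt = leaves[order, t]
            uniq, starts = np.unique(lt, return_index=True)
            self._leaf_ids.append(uniq)
            self._offsets.append(np.append(starts, len(lt)))
            self._leaf_y.append(y[order])
            self._leaf_idx.append(order)
        return self

    def _check(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature mismatch: expected {self.n_features_in_} columns, "
                f"got {X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        return X

    def _leaf_segments(self, leaves_row, t):
        """(start, end) of the leaf segment for one tree/query leaf."""
        pos = np.searchsorted(self._leaf_ids[t], leaves_row)
        return self._offsets[t][pos], self._offsets[t][pos + 1]

    # -- conditional CDF ---------------------------------------------------

    def predict_cdf(self, X, y) -> np.ndarray:
        """``u_i = F(y_i | x_i)`` with the weak (<=) tie convention.

        ``y`` may be a scalar (same threshold for all rows) or an array
        aligned with the rows of ``X``.
        """
        X = self._check(X)
        leaves = self.forest_.apply(X)
        y = np.broadcast_to(np.asarray(y, dtype=float), (X.shape[0],))
        u = np.zeros(X.shape[0])
        for t in range(leaves.shape[1]):
            starts, ends = self._leaf_segments(leaves[:, t], t)
            ly = self._leaf_y[t]
            for i in range(X.shape[0]):
                s, e = starts[i], ends[i]
                u[i] += np.searchsorted(ly[s:e], y[i], side="right") / (e - s)
        return u / leaves.shape[1]

    # -- merged per-query conditional ECDF ---------------------------------

    def _conditional_ecdf(self, X):
        """Per query row: (sorted support values, cumulative weights)."""
        X = self._check(X)
        leaves = self.forest_.apply(X)
        T = leaves.shape[1]
        seg = [self._leaf_segments(leaves[:, t], t) for t in range(T)]
        out = []
        for i in range(X.shape[0]):
            vals, wts = [], []
            for t in range(T):
                s, e = seg[t][0][i], seg[t][1][i]
                vals.append(self._leaf_y[t][s:e])
                wts.append(np.full(e - s, 1.0 / (T * (e - s))))
            v = np.concatenate(vals)
            w = np.concatenate(wts)
            order = np.argsort(v, kind="stable")
            out.append((v[order], np.cumsum(w[order])))
        return out

    def predict_quantiles(self, X, taus) -> np.ndarray:
        """Conditional quantiles ``Q_tau(x)``, shape (n_rows, len(taus)).

        Monotone non-decreasing in ``tau`` for every row (type-1 inverse of
        a single per-row CDF).
        """
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        if np.any((taus < 0) | (taus > 1)):
            raise ValueError("quantile levels must lie in [0, 1]")
        ecdfs = self._conditional_ecdf(X)
        q = np.empty((len(ecdfs), len(taus)))
        for i, (v, cw) in enumerate(ecdfs):
            idx = np.searchsorted(cw, np.clip(taus, 0, cw[-1] - 1e-12), side="left")
            q[i] = v[np.minimum(idx, len(v) - 1)]
        return q

    def predict_median(self, X) -> np.ndarray:
        return self.predict_quantiles(X, [0.5])[:, 0]

    def sample_conditional(self, X, n_draws: int, rng) -> np.ndarray:
        """Draw hypothetical targets from each row's conditional distribution.

        Returns values of shape (n_rows, n_draws); used for Monte-Carlo
        confidence intervals.  Each draw inverts the merged conditional ECDF
        at a uniform variate (equivalent to picking a uniformly random tree
        and then a uniformly random target in its leaf).
        """
        ecdfs = self._conditional_ecdf(X)
        out = np.empty((len(ecdfs), n_draws))
        for i, (v, cw) in enumerate(ecdfs):
            u0 = rng.random(n_draws) * cw[-1]
            out[i] = v[np.searchsorted(cw, u0, side="left")]
        return out

    def sample_conditional_cdf(self, X, n_draws: int, rng):
        """As :meth:`sample_conditional` but also return each draw's own
        conditional-CDF value ``u* = F(y* | x)`` under the <= convention."""
        ecdfs = self._conditional_ecdf(X)
        ys = np.empty((len(ecdfs), n_draws))
        us = np.empty((len(ecdfs), n_draws))
        for i, (v, cw) in enumerate(ecdfs):
            u0 = rng.random(n_draws) * cw[-1]
            idx = np.searchsorted(cw, u0, side="left")
            ys[i] = v[idx]
            # mass at or below the drawn atom, including tied values
            hi = np.searchsorted(v, ys[i], side="right") - 1
            us[i] = cw[hi]
        return ys, us
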