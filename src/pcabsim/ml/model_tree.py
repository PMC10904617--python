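"""M5-style model trees with linear leaves, bagged into a random forest.

A model tree is grown greedily: each internal node splits on the
(feature, threshold) pair maximising the standard-deviation reduction

    SDR = sd(y) - sum_i (n_i / n) sd(y_i)

and every leaf holds an ordinary-least-squares linear model on the
tree's feature subset.  Following the classic M5' scheme, growth stops
when a node holds fewer than twice the minimum leaf size or its target
spread falls below 5% of the root spread; no smoothing is applied.  The
ensemble draws a bootstrap sample of instances and a random subset of
features for each tree and averages the tree predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModelTree", "ModelTreeEnsemble", "m5p_fit", "m5p_predict"]

_SD_STOP_FRACTION = 0.05


@dataclass
class _Node:
    # leaf fields
    coef: np.ndarray | None = None  # intercept-first coefficients
    # internal fields
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.coef is not None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"coef": self.coef.tolist()}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


def _fit_leaf(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    design = np.hstack([np.ones((X.shape[0], 1)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """(feature, threshold, sdr) of the best variance-reducing split."""
    n = len(y)
    sd_parent = y.std()
    best = (None, None, 0.0)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="mergesort")
        xs = X[order, j]
        ys = y[order]
        csum = np.cumsum(ys)
        csum2 = np.cumsum(ys**2)
        total, total2 = csum[-1], csum2[-1]
        for i in range(min_leaf, n - min_leaf + 1):
            if i < n and xs[i - 1] == xs[i]:
                continue  # cannot separate equal values
            nl, nr = i, n - i
            var_l = max(csum2[i - 1] / nl - (csum[i - 1] / nl) ** 2, 0.0)
            var_r = max(
                (total2 - csum2[i - 1]) / nr - ((total - csum[i - 1]) / nr) ** 2, 0.0
            )
            sdr = sd_parent - (
                nl / n * np.sqrt(var_l) + nr / n * np.sqrt(var_r)
            )
            if sdr > best[2]:
                best = (j, 0.5 * (xs[i - 1] + xs[i]), float(sdr))
    return best


def _grow(X: np.ndarray, y: np.ndarray, min_leaf: int, root_sd: float) -> _Node:
    if len(y) < 2 * min_leaf or y.std() <= _SD_STOP_FRACTION * root_sd:
        return _Node(coef=_fit_leaf(X, y))
    feature, threshold, sdr = _best_split(X, y, min_leaf)
    if feature is None or sdr <= 0:
        return _Node(coef=_fit_leaf(X, y))
    mask = X[:, feature] <= threshold
    return _Node(
        feature=feature,
        threshold=threshold,
        left=_grow(X[mask], y[mask], min_leaf, root_sd),
        right=_grow(X[~mask], y[~mask], min_leaf, root_sd),
    )


@dataclass
class ModelTree:
    """One fitted model tree restricted to a feature subset."""

    root: _Node
    features: np.ndarray  # column indices (into the full feature matrix)

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, features, min_leaf: int = 4) -> "ModelTree":
        features = np.asarray(features, dtype=int)
        Xs = X[:, features]
        root_sd = float(y.std())
        return cls(root=_grow(Xs, y, min_leaf, root_sd), features=features)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = np.asarray(X, dtype=float)[:, self.features]
        out = np.empty(Xs.shape[0])
        for i, row in enumerate(Xs):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.coef[0] + row @ node.coef[1:]
        return out

    def to_dict(self) -> dict:
        return {"features": self.features.tolist(), "root": self.root.to_dict()}


@dataclass
class ModelTreeEnsemble:
    """A seeded bag of model trees; prediction is the unweighted mean."""

    trees: list[ModelTree]
    sample_indices: list[np.ndarray]
    seed: int
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        return np.mean([tree.predict(X) for tree in self.trees], axis=0)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_features": self.n_features,
            "trees": [t.to_dict() for t in self.trees],
        }


def m5p_fit(
    X,
    y,
    n_trees: int = 30,
    min_leaf: int = 4,
    feature_fraction: float = 1.0,
    sample_fraction: float = 1.0,
    seed: int = 0,
) -> ModelTreeEnsemble:
    """Fit a bagged model-tree ensemble, bit-reproducible from the seed.

    Each tree sees a bootstrap draw (with replacement) of
    ``sample_fraction * n`` instances and a random subset of
    ``ceil(feature_fraction * p)`` features.  Constant-target data yields
    single-leaf trees rather than an error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != len(y):
        raise ValueError("X and y lengths differ")
    if n < 2 * min_leaf:
        raise ValueError(f"need at least {2 * min_leaf} instances, got {n}")
    rng = np.random.default_rng(seed)
    n_feat = max(1, int(np.ceil(feature_fraction * p)))
    n_samp = max(2 * min_leaf, int(round(sample_fraction * n)))
    trees, samples = [], []
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n_samp)
        feats = np.sort(rng.choice(p, size=n_feat, replace=False))
        trees.append(ModelTree.fit(X[idx], y[idx], feats, min_leaf))
        samples.append(idx)
    return ModelTreeEnsemble(
        trees=trees, sample_indices=samples, seed=seed, n_features=p
    )


def m5p_predict(ensemble: ModelTreeEnsemble, X) -> np.ndarray:
    """Average the tree predictions of a fitted ensemble."""
    return ensemble.predict(X)
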