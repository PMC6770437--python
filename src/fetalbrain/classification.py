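"""Classifiers for the texture feature subsets.

Five individual models — diagonal quadratic discriminant analysis (DQDA),
Gaussian naive Bayes, cosine K-NN with inverse-distance weighting, an RBF
network (seeded k-means centres + ridge least-squares output layer), and a
random forest — plus bagging and AdaBoost.M1 (resampling variant)
ensembles over any of them.

All estimators follow the fit/predict/predict_proba protocol, are
deterministic under a fixed seed, and break prediction ties toward the
smallest class index.  ``classes_`` is always the sorted label set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

log = logging.getLogger(__name__)

_VAR_FLOOR_REL = 1e-9  # relative variance floor for Gaussian models


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n_samples, n_features) matching y")
    return X, y


def _check_two_classes(y, classes):
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    counts = [int(np.sum(y == c)) for c in classes]
    if min(counts) < 2:
        raise ValueError("each class needs at least 2 training samples")


class _GaussianPerFeature:
    """Shared parameter estimation for DQDA and Gaussian naive Bayes.

    Both models assume per-class, per-feature independent Gaussians; they
    differ only in narrative (discriminant vs posterior), so with identical
    estimates their decisions coincide.
    """

    def __init__(self):
        self.classes_ = None

    def fit(self, X, y):
        X, y = _as_xy(X, y)
        self.classes_ = np.unique(y)
        _check_two_classes(y, self.classes_)
        overall_var = float(np.mean(X.var(axis=0))) or 1.0
        self._floor = max(_VAR_FLOOR_REL * overall_var, 1e-300)
        self.means_, self.vars_, self.priors_ = [], [], []
        n = len(y)
        for c in self.classes_:
            Xc = X[y == c]
            self.means_.append(Xc.mean(axis=0))
            v = Xc.var(axis=0)
            if np.any(v < self._floor):
                log.info("class %r: %d degenerate feature variance(s) floored",
                         c, int(np.sum(v < self._floor)))
            self.vars_.append(np.maximum(v, self._floor))
            self.priors_.append(len(Xc) / n)
        self.means_ = np.array(self.means_)
        self.vars_ = np.array(self.vars_)
        self.priors_ = np.array(self.priors_)
        return self

    def _log_joint(self, X):
        """log pi_k + sum_j log N(x_j | mu_kj, sigma_kj^2), one column per class."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            z = (X - self.means_[k]) ** 2 / self.vars_[k]
            out[:, k] = (np.log(self.priors_[k])
                         - 0.5 * np.sum(np.log(2 * np.pi * self.vars_[k]))
                         - 0.5 * z.sum(axis=1))
        return out

    def predict_proba(self, X):
        lj = self._log_joint(X)
        lj -= lj.max(axis=1, keepdims=True)
        p = np.exp(lj)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._log_joint(X), axis=1)]


class DQDA(_GaussianPerFeature):
    """Quadratic discriminant analysis with diagonal class covariances.

    delta_k(x) = -1/2 log|Sigma_k| - 1/2 (x-mu_k)^T Sigma_k^-1 (x-mu_k)
    + log pi_k, with Sigma_k diagonal; prediction is argmax_k delta_k.
    """

    def __init__(self, seed: int | None = None):
        super().__init__()
        self.seed = seed  # unused; kept for a uniform constructor

    def discriminants(self, X):
        """delta_k(x) per class (the log-joint up to the shared constant)."""
        d = self._log_joint(X)
        return d + 0.5 * X.shape[-1] * np.log(2 * np.pi)


class GaussianNaiveBayes(_GaussianPerFeature):
    """Naive Bayes with Gaussian class-conditionals, computed in log space."""

    def __init__(self, seed: int | None = None):
        super().__init__()
        self.seed = seed


@dataclass(frozen=True)
class KNNSpec:
    k: int = 10
    metric: str = "cosine"
    weighting: str = "inverse_distance"


class CosineKNN:
    """K nearest neighbours under cosine distance with 1/d vote weights.

    An exact training match (zero distance) decides the label outright;
    vote ties break toward the smallest class index.
    """

    def __init__(self, k: int = 10, seed: int | None = None):
        self.k = k
        self.seed = seed

    def fit(self, X, y):
        X, y = _as_xy(X, y)
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValueError("cosine distance undefined for zero-norm vectors")
        if self.k < 1 or self.k > len(y):
            raise ValueError("k must be in [1, n_train]")
        self._X = X / norms[:, None]
        self._y = y
        self.classes_ = np.unique(y)
        return self

    def _distances(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValueError("cosine distance undefined for zero-norm vectors")
        return 1.0 - (X / norms[:, None]) @ self._X.T

    def _vote(self, d_row):
        order = np.argsort(d_row, kind="stable")[:self.k]
        d = d_row[order]
        labels = self._y[order]
        weights = np.zeros(len(self.classes_))
        exact = d < 1e-12
        if exact.any():
            for lab in labels[exact]:
                weights[np.searchsorted(self.classes_, lab)] += 1.0
        else:
            for dist, lab in zip(d, labels):
                weights[np.searchsorted(self.classes_, lab)] += 1.0 / dist
        return weights

    def predict_proba(self, X):
        D = self._distances(X)
        W = np.vstack([self._vote(row) for row in D])
        return W / W.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class RBFNetwork:
    """Radial basis function network.

    Hidden layer: Gaussian units exp(-||x - c||^2 / (2 sigma^2)) at k-means
    centres (``centers_per_class`` per class, seeded); output layer: ridge
    least squares onto one-hot class indicators; prediction by argmax of
    the linear outputs.  sigma is the median inter-centre distance.
    Inputs are z-scored internally so no single large-magnitude feature
    dominates the radial distances.
    """

    def __init__(self, centers_per_class: int = 2, ridge: float = 1e-6,
                 seed: int | None = 0):
        self.centers_per_class = centers_per_class
        self.ridge = ridge
        self.seed = seed

    def fit(self, X, y):
        X, y = _as_xy(X, y)
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        Xs = (X - self._mu) / self._sd
        self.classes_ = np.unique(y)
        n_centers = min(self.centers_per_class * len(self.classes_), len(y))
        if n_centers < 1:
            raise ValueError("need at least one centre")
        km = KMeans(n_clusters=n_centers, n_init=10,
                    random_state=(self.seed or 0) % (2**32))
        km.fit(Xs)
        self.centers_ = km.cluster_centers_
        if n_centers > 1:
            diff = self.centers_[:, None, :] - self.centers_[None, :, :]
            dists = np.linalg.norm(diff, axis=-1)
            sigma = float(np.median(dists[np.triu_indices(n_centers, k=1)]))
        else:
            sigma = 0.0
        self.sigma_ = sigma if sigma > 0 else 1.0
        Phi = self._activations(X)
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        A = Phi.T @ Phi + self.ridge * np.eye(Phi.shape[1])
        self.weights_ = np.linalg.solve(A, Phi.T @ Y)
        return self

    @property
    def n_centers(self) -> int:
        return self.centers_.shape[0]

    def _activations(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        X = (X - self._mu) / self._sd
        sq = ((X[:, None, :] - self.centers_[None, :, :]) ** 2).sum(axis=-1)
        Phi = np.exp(-sq / (2.0 * self.sigma_ ** 2))
        return np.hstack([Phi, np.ones((X.shape[0], 1))])  # bias unit

    def decision_function(self, X):
        return self._activations(X) @ self.weights_

    def predict_proba(self, X):
        # linear outputs approximate class indicators; softmax normalizes
        s = self.decision_function(X)
        s = s - s.max(axis=1, keepdims=True)
        p = np.exp(s)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class RandomForest:
    """Random forest (bootstrap per tree, random feature subsets at splits,
    information-gain impurity, majority vote); backed by scikit-learn."""

    def __init__(self, n_trees: int = 100, seed: int | None = 0):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X, y):
        X, y = _as_xy(X, y)
        self._rf = RandomForestClassifier(
            n_estimators=self.n_trees, criterion="entropy",
            random_state=(self.seed or 0) % (2**32))
        self._rf.fit(X, y)
        self.classes_ = self._rf.classes_
        return self

    @property
    def trees_(self):
        return self._rf.estimators_

    def predict(self, X):
        return self._rf.predict(np.atleast_2d(np.asarray(X, dtype=float)))

    def predict_proba(self, X):
        return self._rf.predict_proba(np.atleast_2d(np.asarray(X, dtype=float)))


# --------------------------------------------------------------------------
# Ensembles

@dataclass(frozen=True)
class EnsembleSpec:
    base_learner: str = "naive_bayes"  # naive_bayes | random_forest | rbf_network
    method: str = "bagging"  # bagging | adaboost
    n_learners: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")


def _clone_base(est, seed: int):
    """Fresh unfitted copy of a base estimator with a derived seed."""
    cls = type(est)
    kwargs = {}
    for name in ("k", "centers_per_class", "ridge", "n_trees"):
        if hasattr(est, name):
            kwargs[name] = getattr(est, name)
    kwargs["seed"] = seed
    return cls(**kwargs)


def _stratified_ok(y):
    vals, counts = np.unique(y, return_counts=True)
    return len(vals) >= 2 and counts.min() >= 2


def _bootstrap_indices(rng, y, weights=None, max_tries: int = 100):
    """Size-n (weighted) resample whose class composition supports fitting."""
    n = len(y)
    for _ in range(max_tries):
        idx = rng.choice(n, size=n, replace=True, p=weights)
        if _stratified_ok(y[idx]):
            return idx
    raise RuntimeError("could not draw a resample containing both classes")


class BaggingEnsemble:
    """Bootstrap-aggregated ensemble with majority voting."""

    def __init__(self, base, n_learners: int = 60, seed: int = 0):
        self.base = base
        self.n_learners = n_learners
        self.seed = seed

    def fit(self, X, y):
        X, y = _as_xy(X, y)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.seed)
        self.learners_ = []
        self.sample_sizes_ = []
        for t in range(self.n_learners):
            idx = _bootstrap_indices(rng, y)
            self.sample_sizes_.append(len(idx))
            learner = _clone_base(self.base, seed=int(rng.integers(2**31 - 1)))
            learner.fit(X[idx], y[idx])
            self.learners_.append(learner)
        return self

    def member_predictions(self, X):
        return np.vstack([m.predict(X) for m in self.learners_])

    def predict_proba(self, X):
        preds = self.member_predictions(X)
        votes = (preds[:, :, None] == self.classes_[None, None, :]).sum(axis=0)
        return votes / votes.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class AdaBoostEnsemble:
    """AdaBoost.M1 with weighted resampling.

    Round t trains a fresh base learner on a weight-proportional resample,
    measures the weighted training error eps_t, assigns the learner weight
    alpha_t = ln((1 - eps_t)/eps_t), upweights misclassified instances and
    renormalizes.  Rounds stop early at eps_t = 0 (perfect) or >= 0.5; a
    first-round eps >= 0.5 falls back to that single learner.
    """

    def __init__(self, base, n_learners: int = 60, seed: int = 0):
        self.base = base
        self.n_learners = n_learners
        self.seed = seed

    def fit(self, X, y):
        X, y = _as_xy(X, y)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.seed)
        n = len(y)
        w = np.full(n, 1.0 / n)
        self.learners_, self.alphas_, self.errors_ = [], [], []
        for t in range(self.n_learners):
            idx = _bootstrap_indices(rng, y, weights=w)
            learner = _clone_base(self.base, seed=int(rng.integers(2**31 - 1)))
            learner.fit(X[idx], y[idx])
            miss = learner.predict(X) != y
            eps = float(np.sum(w[miss]))
            if eps >= 0.5:
                if t == 0:
                    log.info("adaboost: first learner error %.3f >= 0.5; "
                             "falling back to that single learner", eps)
                    self.learners_.append(learner)
                    self.alphas_.append(1.0)
                    self.errors_.append(eps)
                break
            self.learners_.append(learner)
            self.errors_.append(eps)
            if eps == 0.0:
                self.alphas_.append(np.log(1e12))  # effectively decisive
                break
            alpha = float(np.log((1.0 - eps) / eps))
            self.alphas_.append(alpha)
            w = w * np.exp(alpha * miss)
            w = w / w.sum()
        self.final_weights_ = w
        return self

    def predict_proba(self, X):
        alphas = np.asarray(self.alphas_)
        preds = np.vstack([m.predict(X) for m in self.learners_])
        score = (alphas[:, None, None]
                 * (preds[:, :, None] == self.classes_[None, None, :])).sum(axis=0)
        return score / score.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# --------------------------------------------------------------------------
# Factory

_BASE_NAMES = {
    "dqda": DQDA,
    "nb": GaussianNaiveBayes,
    "naive_bayes": GaussianNaiveBayes,
    "knn": CosineKNN,
    "rbf": RBFNetwork,
    "rbf_network": RBFNetwork,
    "rf": RandomForest,
    "random_forest": RandomForest,
}


def make_classifier(name: str, ensemble: str | None = None,
                    n_learners: int = 60, seed: int = 0):
    """Build a (possibly ensembled) classifier by name."""
    if name not in _BASE_NAMES:
        raise ValueError(f"unknown classifier {name!r}; "
                         f"choose from {sorted(set(_BASE_NAMES))}")
    base = _BASE_NAMES[name](seed=seed)
    if ensemble is None:
        return base
    if ensemble in ("bag", "bagging"):
        return BaggingEnsemble(base, n_learners=n_learners, seed=seed)
    if ensemble in ("boost", "adaboost"):
        return AdaBoostEnsemble(base, n_learners=n_learners, seed=seed)
    raise ValueError(f"unknown ensemble method {ensemble!r}")
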