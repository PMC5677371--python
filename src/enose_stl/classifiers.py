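"""RBF-network and PLS-DA classifiers with swarm-tuned hyperparameters.

The RBF network places K Gaussian kernels at k-means centers with a shared
width sigma and fits a ridge-regularized linear output layer against
one-hot class targets; prediction is the argmax over class scores (ties
break toward the lowest class index).  PLS-DA is NIPALS PLS2 regression of
centered features on one-hot class indicators with an argmax decision
rule.  Hyperparameters (sigma, ridge, K; number of latent components) are
tuned by quantum-behaved PSO on the stratified cross-validated
misclassification rate of the training set — the test split never enters
tuning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import cdist

from .qpso import SwarmConfig, SwarmResult, optimize


@dataclass(frozen=True)
class SplitSpec:
    """Stratified per-class split; defaults mirror a 20-per-class design."""

    train_per_class: int = 15
    test_per_class: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train_per_class < 1 or self.test_per_class < 1:
            raise ValueError("per-class counts must be >= 1")


def stack_xy(samples: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """[n x d] matrix and label vector from objects with .values/.label."""
    X = np.array([np.asarray(s.values, dtype=float) for s in samples])
    y = np.array([int(s.label) for s in samples])
    return X, y


def split_dataset(samples: Sequence, spec: SplitSpec) -> tuple[list, list]:
    """Stratified random split, deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    by_class: dict[int, list[int]] = {}
    for i, s in enumerate(samples):
        by_class.setdefault(int(s.label), []).append(i)
    need = spec.train_per_class + spec.test_per_class
    train_idx, test_idx = [], []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        if idx.size < need:
            raise ValueError(
                f"class {label} has {idx.size} samples, needs >= {need}"
            )
        perm = rng.permutation(idx.size)
        train_idx.extend(idx[perm[: spec.train_per_class]])
        test_idx.extend(idx[perm[spec.train_per_class : need]])
    return [samples[i] for i in train_idx], [samples[i] for i in test_idx]


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    Y = np.zeros((y.size, classes.size))
    for j, c in enumerate(classes):
        Y[y == c, j] = 1.0
    return Y


# ---------------------------------------------------------------------------
# RBF network


@dataclass
class RBFModel:
    centers: np.ndarray  # [K x d]
    sigma: float
    weights: np.ndarray  # [K+1 x C], bias row last
    classes: np.ndarray  # sorted class labels

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        phi = np.exp(
            -cdist(X, self.centers, "sqeuclidean") / (2.0 * self.sigma**2)
        )
        phi = np.hstack([phi, np.ones((X.shape[0], 1))])
        return phi @ self.weights

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax takes the first maximum -> ties break to the lowest class
        return self.classes[np.argmax(self.scores(X), axis=1)]


def _kmeans_centers(X: np.ndarray, K: int, seed: int) -> np.ndarray:
    # K beyond the number of distinct points cannot be realized; use the
    # distinct points themselves (the k-means fixed point)
    unique = np.unique(X, axis=0)
    if K >= unique.shape[0]:
        return unique
    for attempt in range(3):
        centers, assignment = kmeans2(
            X, K, minit="++", seed=seed + attempt, missing="warn"
        )
        if np.unique(assignment).size == K:
            return centers
    raise RuntimeError(f"k-means produced an empty cluster for K={K}")


def train_rbf(
    train: Sequence | tuple[np.ndarray, np.ndarray],
    K: int,
    sigma: float,
    ridge: float = 1e-6,
    seed: int = 0,
) -> RBFModel:
    """Fit an RBF network: seeded k-means centers, shared Gaussian width,
    ridge least-squares output layer (exact interpolation at K=n, ridge=0)."""
    X, y = train if isinstance(train, tuple) else stack_xy(train)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 1 <= K <= X.shape[0]:
        raise ValueError(f"K must be in 1..{X.shape[0]}")
    classes = np.unique(y)
    centers = _kmeans_centers(X, K, seed)
    phi = np.exp(-cdist(X, centers, "sqeuclidean") / (2.0 * sigma**2))
    phi = np.hstack([phi, np.ones((X.shape[0], 1))])
    Y = _one_hot(y, classes)
    if ridge > 0:
        A = phi.T @ phi + ridge * np.eye(phi.shape[1])
        weights = np.linalg.solve(A, phi.T @ Y)
    else:
        weights = np.linalg.lstsq(phi, Y, rcond=None)[0]
    return RBFModel(centers=centers, sigma=float(sigma), weights=weights, classes=classes)


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS PLS2 on one-hot targets)


@dataclass
class PLSDAModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray  # W [d x A]
    x_loadings: np.ndarray  # P [d x A]
    y_loadings: np.ndarray  # Q [C x A]
    coef: np.ndarray  # B [d x C]
    classes: np.ndarray

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.scores(X), axis=1)]


def train_plsda(
    train: Sequence | tuple[np.ndarray, np.ndarray],
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PLSDAModel:
    """NIPALS PLS2 against one-hot class indicators.

    Latent components are extracted iteratively with deflation of both
    blocks, which copes with collinear (e.g. duplicated) feature columns;
    extraction stops early if a residual block is exhausted.  With
    n_components equal to the feature rank the coefficients reproduce the
    multivariate least-squares solution.
    """
    X, y = train if isinstance(train, tuple) else stack_xy(train)
    n, d = X.shape
    if not 1 <= n_components <= min(d, n - 1):
        raise ValueError(f"n_components must be in 1..{min(d, n - 1)}")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("features have zero variance")
    classes = np.unique(y)
    Y = _one_hot(y, classes)
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    Xr, Yr = X - x_mean, Y - y_mean

    W = np.zeros((d, n_components))
    P = np.zeros((d, n_components))
    Q = np.zeros((classes.size, n_components))
    extracted = 0
    for a in range(n_components):
        if np.sum(Xr**2) < tol or np.sum(Yr**2) < tol:
            break  # residual exhausted; fewer components suffice
        u = Yr[:, int(np.argmax(Yr.var(axis=0)))].copy()
        t_old = None
        for _ in range(max_iter):
            w = Xr.T @ u
            norm = np.linalg.norm(w)
            if norm < tol:
                break
            w /= norm
            t = Xr @ w
            tt = t @ t
            if tt < tol:
                break
            q = Yr.T @ t / tt
            qq = q @ q
            if qq < tol:
                break
            u = Yr @ q / qq
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.sqrt(tt):
                break
            t_old = t
        t = Xr @ w
        tt = t @ t
        if tt < tol:
            break
        p = Xr.T @ t / tt
        q = Yr.T @ t / tt
        Xr = Xr - np.outer(t, p)
        Yr = Yr - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a] = w, p, q
        extracted = a + 1
    if extracted == 0:
        raise ValueError("no latent component could be extracted")
    W, P, Q = W[:, :extracted], P[:, :extracted], Q[:, :extracted]
    coef = W @ np.linalg.pinv(P.T @ W) @ Q.T
    return PLSDAModel(
        n_components=extracted,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        coef=coef,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# evaluation and tuning


def accuracy(model, samples_or_xy) -> float:
    """Percentage of correct argmax predictions."""
    X, y = (
        samples_or_xy
        if isinstance(samples_or_xy, tuple)
        else stack_xy(samples_or_xy)
    )
    if X.shape[0] == 0:
        raise ValueError("cannot score an empty sample list")
    return 100.0 * float(np.mean(model.predict(X) == y))


def stratified_folds(
    y: np.ndarray, n_folds: int, seed: int = 0
) -> list[np.ndarray]:
    """Per-class shuffled round-robin assignment into ``n_folds`` folds."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(idx.size)]
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.array(sorted(f)) for f in folds]


def _cv_error(fit, X: np.ndarray, y: np.ndarray, folds: list[np.ndarray]) -> float:
    errors = []
    for test_idx in folds:
        mask = np.ones(y.size, dtype=bool)
        mask[test_idx] = False
        try:
            model = fit(X[mask], y[mask])
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            return 1.0  # infeasible hyperparameters score as total error
        errors.append(np.mean(model.predict(X[test_idx]) != y[test_idx]))
    return float(np.mean(errors))


def tune_with_eqpso(
    kind: str,
    train: Sequence | tuple[np.ndarray, np.ndarray],
    cv_folds: int = 5,
    swarm: SwarmConfig | None = None,
    n_particles: int = 30,
    iterations: int = 300,
    seed: int = 0,
):
    """Swarm-tune a classifier on cross-validated training error.

    kind='rbf' searches (log10 sigma, log10 ridge, K); kind='plsda'
    searches the (continuous-relaxed, rounded) component count.  Returns
    ``(model refit on the full training set, best hyperparameters dict,
    best-so-far trace)``.  A search box collapsed to a single point is
    evaluated directly without running the swarm.
    """
    X, y = train if isinstance(train, tuple) else stack_xy(train)
    folds = stratified_folds(y, cv_folds, seed)
    min_train = min(y.size - f.size for f in folds)
    d = X.shape[1]

    if kind == "rbf":
        k_hi = max(2.0, float(min(25, min_train)))
        bounds = ((-2.0, 1.5), (-8.0, 0.0), (2.0, k_hi))

        def decode(v):
            return {
                "sigma": 10.0 ** v[0],
                "ridge": 10.0 ** v[1],
                "K": int(np.clip(round(v[2]), 1, min_train)),
            }

        def fit_with(h):
            return lambda Xt, yt: train_rbf(
                (Xt, yt), K=min(h["K"], Xt.shape[0]), sigma=h["sigma"],
                ridge=h["ridge"], seed=seed,
            )

        def refit(h):
            return train_rbf(
                (X, y), K=min(h["K"], X.shape[0]), sigma=h["sigma"],
                ridge=h["ridge"], seed=seed,
            )

    elif kind == "plsda":
        a_hi = float(min(d, min_train - 1))
        bounds = ((1.0, max(a_hi, 1.0 + 1e-9)),)

        def decode(v):
            return {"n_components": int(np.clip(round(v[0]), 1, min(d, min_train - 1)))}

        def fit_with(h):
            return lambda Xt, yt: train_plsda(
                (Xt, yt), n_components=min(h["n_components"], min(d, Xt.shape[0] - 1))
            )

        def refit(h):
            return train_plsda(
                (X, y), n_components=min(h["n_components"], min(d, X.shape[0] - 1))
            )

    else:
        raise ValueError("kind must be 'rbf' or 'plsda'")

    def objective(v: np.ndarray) -> float:
        return _cv_error(fit_with(decode(v)), X, y, folds)

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if np.allclose(lo, hi):  # degenerate search space: evaluate the point
        best = decode(lo)
        return refit(best), best, np.array([objective(lo)])

    if swarm is None:
        swarm = SwarmConfig(
            bounds=bounds, n_particles=n_particles, iterations=iterations, seed=seed
        )
    else:
        swarm = SwarmConfig(
            bounds=bounds,
            n_particles=swarm.n_particles,
            iterations=swarm.iterations,
            ce_start=swarm.ce_start,
            ce_end=swarm.ce_end,
            seed=swarm.seed,
        )
    result = optimize(objective, swarm)
    best = decode(result.best_position)
    return refit(best), best, result.trace


# ---------------------------------------------------------------------------
# model serialization


def save_classifier(model, path: str | Path) -> None:
    if isinstance(model, RBFModel):
        payload = {
            "kind": "rbf",
            "centers": model.centers.tolist(),
            "sigma": model.sigma,
            "weights": model.weights.tolist(),
            "classes": model.classes.tolist(),
        }
    elif isinstance(model, PLSDAModel):
        payload = {
            "kind": "plsda",
            "n_components": model.n_components,
            "x_mean": model.x_mean.tolist(),
            "y_mean": model.y_mean.tolist(),
            "x_weights": model.x_weights.tolist(),
            "x_loadings": model.x_loadings.tolist(),
            "y_loadings": model.y_loadings.tolist(),
            "coef": model.coef.tolist(),
            "classes": model.classes.tolist(),
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(payload))


def load_classifier(path: str | Path):
    payload = json.loads(Path(path).read_text())
    if payload["kind"] == "rbf":
        return RBFModel(
            centers=np.array(payload["centers"]),
            sigma=payload["sigma"],
            weights=np.array(payload["weights"]),
            classes=np.array(payload["classes"]),
        )
    return PLSDAModel(
        n_components=payload["n_components"],
        x_mean=np.array(payload["x_mean"]),
        y_mean=np.array(payload["y_mean"]),
        x_weights=np.array(payload["x_weights"]),
        x_loadings=np.array(payload["x_loadings"]),
        y_loadings=np.array(payload["y_loadings"]),
        coef=np.array(payload["coef"]),
        classes=np.array(payload["classes"]),
    )
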