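"""Sparse autoencoder: sigmoid network, KL sparsity penalty, batch GD.

A single-hidden-layer autoencoder with sigmoid activations is trained to
reproduce its input (targets y = x) by full-batch gradient descent on

    J_sparse(W, b) = (1/k) sum_i 1/2 ||h(x_i) - x_i||^2
                     + (mu/2) (sum W1^2 + sum W2^2)
                     + beta * sum_j KL(rho || rho_hat_j)

where rho_hat_j is the mean activation of hidden unit j over the batch and
KL(rho||q) = rho log(rho/q) + (1-rho) log((1-rho)/(1-q)).  Weight decay
covers weights only, never biases.  Backpropagation carries the sparsity
term into the hidden-layer delta; a central-difference gradient checker
(epsilon ~ 1e-4 on the unrolled parameter vector theta) verifies it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

_RHO_EPS = 1e-12  # keep rho_hat away from {0,1} before logs/divisions


class DivergenceError(RuntimeError):
    """Raised when the training cost becomes non-finite."""


@dataclass
class AutoencoderParams:
    """theta = (W1, b1, W2, b2) of an n^2 -> s2 -> n^2 network."""

    W1: np.ndarray  # [s2 x d]
    b1: np.ndarray  # [s2]
    W2: np.ndarray  # [d x s2]
    b2: np.ndarray  # [d]

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        s2, d = self.W1.shape
        if self.b1.shape != (s2,) or self.W2.shape != (d, s2) or self.b2.shape != (d,):
            raise ValueError("inconsistent parameter shapes")
        for arr in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    def unroll(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2]
        )

    @classmethod
    def from_unrolled(cls, theta: np.ndarray, d: int, s2: int) -> "AutoencoderParams":
        i = 0
        W1 = theta[i : i + s2 * d].reshape(s2, d); i += s2 * d
        b1 = theta[i : i + s2]; i += s2
        W2 = theta[i : i + d * s2].reshape(d, s2); i += d * s2
        b2 = theta[i : i + d]; i += d
        if i != theta.size:
            raise ValueError("unrolled vector has wrong length")
        return cls(W1=W1.copy(), b1=b1.copy(), W2=W2.copy(), b2=b2.copy())


@dataclass(frozen=True)
class TrainConfig:
    mu: float = 3e-3  # weight-decay coefficient
    beta: float = 3.0  # sparsity-penalty weight
    rho: float = 0.01  # target mean hidden activation
    alpha: float = 0.5  # learning rate
    iterations: int = 400
    hidden: int = 10
    init_radius: float | None = None  # None -> sqrt(6/(fan_in+fan_out+1))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 0 or self.beta < 0:
            raise ValueError("mu and beta must be nonnegative")
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie strictly in (0,1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")


@dataclass
class ForwardPass:
    z2: np.ndarray
    a2: np.ndarray
    z3: np.ndarray
    a3: np.ndarray
    rho_hat: np.ndarray  # [s2] mean hidden activation over the batch


@dataclass
class Gradients:
    dW1: np.ndarray
    db1: np.ndarray
    dW2: np.ndarray
    db2: np.ndarray

    def unroll(self) -> np.ndarray:
        return np.concatenate([self.dW1.ravel(), self.db1, self.dW2.ravel(), self.db2])


def sigmoid(z):
    """Logistic function 1/(1+exp(-z)), numerically stable for large |z|."""
    return expit(z)


def feedforward(params: AutoencoderParams, X: np.ndarray) -> ForwardPass:
    """Forward pass on a [d x k] batch (samples are columns)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != params.n_visible:
        raise ValueError(
            f"input dimension {X.shape[0]} != model dimension {params.n_visible}"
        )
    z2 = params.W1 @ X + params.b1[:, None]
    a2 = sigmoid(z2)
    z3 = params.W2 @ a2 + params.b2[:, None]
    a3 = sigmoid(z3)
    return ForwardPass(z2=z2, a2=a2, z3=z3, a3=a3, rho_hat=a2.mean(axis=1))


def kl_divergence(rho: float, rho_hat: np.ndarray) -> float:
    """Sum over hidden units of KL(rho || rho_hat_j); >= 0, zero iff equal."""
    if not 0 < rho < 1:
        raise ValueError("rho must lie strictly in (0,1)")
    q = np.clip(np.asarray(rho_hat, dtype=float), _RHO_EPS, 1.0 - _RHO_EPS)
    return float(
        np.sum(rho * np.log(rho / q) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - q)))
    )


def cost_sparse(
    params: AutoencoderParams, X: np.ndarray, config: TrainConfig
) -> float:
    """J_sparse: mean reconstruction error + weight decay + sparsity penalty."""
    fp = feedforward(params, X)
    k = fp.a3.shape[1]
    recon = 0.5 * np.sum((fp.a3 - X) ** 2) / k
    decay = 0.5 * config.mu * (np.sum(params.W1**2) + np.sum(params.W2**2))
    sparsity = config.beta * kl_divergence(config.rho, fp.rho_hat)
    return float(recon + decay + sparsity)


def backprop(
    params: AutoencoderParams, X: np.ndarray, config: TrainConfig
) -> tuple[Gradients, float]:
    """Exact gradient of J_sparse by backpropagation.

    The hidden-layer delta carries the derivative of the batch sparsity
    penalty, ``beta * (-rho/rho_hat + (1-rho)/(1-rho_hat))``, broadcast per
    hidden unit.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    fp = feedforward(params, X)
    k = X.shape[1]

    delta3 = -(X - fp.a3) * fp.a3 * (1.0 - fp.a3)
    q = np.clip(fp.rho_hat, _RHO_EPS, 1.0 - _RHO_EPS)
    sparsity_grad = config.beta * (
        -config.rho / q + (1.0 - config.rho) / (1.0 - q)
    )
    delta2 = (params.W2.T @ delta3 + sparsity_grad[:, None]) * fp.a2 * (1.0 - fp.a2)

    grads = Gradients(
        dW1=delta2 @ X.T / k + config.mu * params.W1,
        db1=delta2.mean(axis=1),
        dW2=delta3 @ fp.a2.T / k + config.mu * params.W2,
        db2=delta3.mean(axis=1),
    )
    recon = 0.5 * np.sum((fp.a3 - X) ** 2) / k
    decay = 0.5 * config.mu * (np.sum(params.W1**2) + np.sum(params.W2**2))
    cost = recon + decay + config.beta * kl_divergence(config.rho, fp.rho_hat)
    return grads, float(cost)


def gradient_check(
    params: AutoencoderParams,
    X: np.ndarray,
    config: TrainConfig,
    epsilon: float = 1e-4,
) -> float:
    """Max relative discrepancy between backprop and central differences.

    For each coordinate of the unrolled theta, the numeric derivative is
    (J(theta+eps) - J(theta-eps)) / (2 eps); the discrepancy is
    |analytic - numeric| / max(1, |analytic| + |numeric|).
    """
    d, s2 = params.n_visible, params.n_hidden
    analytic = backprop(params, X, config)[0].unroll()
    theta = params.unroll()
    numeric = np.empty_like(theta)
    for i in range(theta.size):
        bump = np.zeros_like(theta)
        bump[i] = epsilon
        jp = cost_sparse(AutoencoderParams.from_unrolled(theta + bump, d, s2), X, config)
        jm = cost_sparse(AutoencoderParams.from_unrolled(theta - bump, d, s2), X, config)
        numeric[i] = (jp - jm) / (2.0 * epsilon)
    rel = np.abs(analytic - numeric) / np.maximum(
        1.0, np.abs(analytic) + np.abs(numeric)
    )
    return float(rel.max())


def init_params(
    n_visible: int, hidden: int, seed: int, init_radius: float | None = None
) -> AutoencoderParams:
    """Near-zero init: W uniform in [-r, r], r = sqrt(6/(fan_in+fan_out+1)),
    biases zero.  Symmetric-uniform init breaks hidden-unit symmetry."""
    r = init_radius
    if r is None:
        r = np.sqrt(6.0 / (n_visible + hidden + 1.0))
    rng = np.random.default_rng(seed)
    return AutoencoderParams(
        W1=rng.uniform(-r, r, size=(hidden, n_visible)),
        b1=np.zeros(hidden),
        W2=rng.uniform(-r, r, size=(n_visible, hidden)),
        b2=np.zeros(n_visible),
    )


def train(
    X: np.ndarray,
    config: TrainConfig,
    params: AutoencoderParams | None = None,
) -> tuple[AutoencoderParams, np.ndarray]:
    """Full-batch gradient descent on J_sparse.

    Parameters
    ----------
    X : [d x k] matrix of normalized samples in [0,1] (columns are samples).
    config : hyperparameters; all randomness flows through ``config.seed``.
    params : optional starting point (defaults to the seeded near-zero init),
        useful for paired runs from an identical initialization.

    Returns the trained parameters and the per-iteration J_sparse trace
    (cost evaluated at the start of each iteration, before its update).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if params is None:
        params = init_params(X.shape[0], config.hidden, config.seed, config.init_radius)
    trace = np.empty(config.iterations)
    for it in range(config.iterations):
        # overflow here is the divergence signal, not an error in itself
        with np.errstate(over="ignore"):
            grads, cost = backprop(params, X, config)
        if not np.isfinite(cost):
            raise DivergenceError(
                f"cost diverged at iteration {it} with learning rate "
                f"alpha={config.alpha}; reduce alpha"
            )
        trace[it] = cost
        updated = [
            params.W1 - config.alpha * grads.dW1,
            params.b1 - config.alpha * grads.db1,
            params.W2 - config.alpha * grads.dW2,
            params.b2 - config.alpha * grads.db2,
        ]
        if not all(np.all(np.isfinite(u)) for u in updated):
            raise DivergenceError(
                f"parameters diverged at iteration {it} with learning rate "
                f"alpha={config.alpha}; reduce alpha"
            )
        params = AutoencoderParams(*updated)
    return params, trace


# ---------------------------------------------------------------------------
# model serialization (structured text, exact round-trip)


def save_model(
    params: AutoencoderParams,
    path: str | Path,
    config: TrainConfig | None = None,
) -> None:
    payload = {
        "shape": {"visible": params.n_visible, "hidden": params.n_hidden},
        "config": None,
        "W1": params.W1.tolist(),
        "b1": params.b1.tolist(),
        "W2": params.W2.tolist(),
        "b2": params.b2.tolist(),
    }
    if config is not None:
        payload["config"] = {
            "mu": config.mu, "beta": config.beta, "rho": config.rho,
            "alpha": config.alpha, "iterations": config.iterations,
            "hidden": config.hidden, "init_radius": config.init_radius,
            "seed": config.seed,
        }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[AutoencoderParams, TrainConfig | None]:
    payload = json.loads(Path(path).read_text())
    params = AutoencoderParams(
        W1=np.array(payload["W1"]), b1=np.array(payload["b1"]),
        W2=np.array(payload["W2"]), b2=np.array(payload["b2"]),
    )
    config = None
    if payload.get("config"):
        config = TrainConfig(**payload["config"])
    return params, config
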