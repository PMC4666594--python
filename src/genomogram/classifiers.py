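"""Pattern classifiers over HOG genomic features.

Two classifiers operate on the 36-element feature vectors with one-hot
class targets:

* A Gaussian radial-basis-function network trained by greedy incremental
  centre selection: starting from an empty hidden layer, the training input
  with the largest current squared output error is promoted to a centre,
  the linear output layer (weights + bias) is refit by least squares on the
  Gaussian activations, and the loop stops when the training MSE reaches
  the goal or the hidden layer reaches its cap. The Gaussian width is set
  from the ``spread`` parameter so that the activation falls to 0.5 at a
  distance of exactly ``spread`` from the centre: b = sqrt(-ln 0.5) / spread.
  The procedure is deterministic — ties break to the lowest index and
  duplicate inputs of an existing centre are never selected.

* A two-hidden-layer perceptron baseline (identity input layer, hyperbolic
  tangent hidden and output activations) trained by full-batch gradient
  descent on the MSE with momentum and a multiplicative adaptive learning
  rate, stopping on the epoch budget, performance goal, minimum gradient
  norm, wall-clock limit or validation patience.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RbfConfig",
    "RbfNetwork",
    "train_rbf",
    "rbf_predict",
    "MlpConfig",
    "MlpNetwork",
    "train_mlp",
    "mlp_predict",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


def _check_one_hot(y: np.ndarray) -> None:
    if y.ndim != 2:
        raise ValueError("targets must be a 2-D one-hot matrix")
    if not (np.isin(y, (0, 1)).all() and (y.sum(axis=1) == 1).all()):
        raise ValueError("target rows must be one-hot")


# ---------------------------------------------------------------------------
# Gaussian RBF network


@dataclass(frozen=True)
class RbfConfig:
    """spread > 0 sets the Gaussian half-activation radius; training adds
    centres until MSE <= mse_goal or the hidden layer holds max_neurons
    (default: one per training instance).

    ``ridge`` is a Tikhonov level for the final output-weight solve,
    relative to the largest squared singular value of the design matrix.
    ``None`` (default) means: plain least squares, unless a validation set
    is supplied to the trainer, in which case the level is selected from a
    log grid (including zero) by validation MSE. Near-coincident centres —
    duplicated references, single-mutation neighbours — make the Gaussian
    design matrix numerically singular, and an unregularised solve then
    returns unbounded weights."""

    spread: float = 0.1
    mse_goal: float = 0.0
    max_neurons: int | None = None
    ridge: float | None = None

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if self.mse_goal < 0:
            raise ValueError("mse_goal must be nonnegative")
        if self.max_neurons is not None and self.max_neurons < 1:
            raise ValueError("max_neurons must be positive")
        if self.ridge is not None and self.ridge < 0:
            raise ValueError("ridge must be nonnegative")

    @property
    def width(self) -> float:
        """Gaussian width b = sqrt(-ln 0.5) / spread (~ 0.8326 / spread)."""
        return float(np.sqrt(-np.log(0.5)) / self.spread)


@dataclass
class RbfNetwork:
    centers: np.ndarray  # n_centers x d
    width: float
    weights: np.ndarray  # (n_centers + 1) x K, last row is the bias
    class_names: list[str] | None = None
    history: list[float] = field(default_factory=list)  # training MSE per added centre

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]

    def activations(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d2 = (
            np.sum(x**2, axis=1)[:, None]
            - 2.0 * x @ self.centers.T
            + np.sum(self.centers**2, axis=1)[None, :]
        )
        return np.exp(-(self.width**2) * np.maximum(d2, 0.0))

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "kind": "rbf",
            "width": self.width,
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
            "class_names": self.class_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RbfNetwork":
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            width=float(d["width"]),
            weights=np.asarray(d["weights"], dtype=float),
            class_names=d.get("class_names"),
        )


def _design(phi: np.ndarray) -> np.ndarray:
    return np.hstack([phi, np.ones((phi.shape[0], 1))])


def _ridge_weights(u, s, vt, y, lam_abs: float) -> np.ndarray:
    # minimiser of ||A w - y||^2 + lam_abs ||w||^2 from the SVD of A
    f = s / (s**2 + lam_abs) if lam_abs > 0 else np.divide(
        1.0, s, out=np.zeros_like(s), where=s > s.max() * np.finfo(float).eps * max(u.shape)
    )
    return (vt.T * f) @ (u.T @ y)


def train_rbf(
    x: np.ndarray,
    y: np.ndarray,
    cfg: RbfConfig = RbfConfig(),
    seed: int = 0,
    class_names: list[str] | None = None,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> RbfNetwork:
    """Greedy incremental training of a Gaussian RBF network.

    At each step the non-centre training input with the largest current
    squared output error becomes the next centre (ties to the lowest index;
    exact duplicates of existing centres are skipped), and output weights
    plus bias are refit by linear least squares on the Gaussian activations.
    The ``seed`` argument is accepted for interface uniformity; the greedy
    path is fully deterministic.

    After the greedy loop the output layer is solved once more: with
    ``cfg.ridge`` set, at that Tikhonov level; with a validation set
    supplied and ``cfg.ridge=None``, at the level (possibly zero) that
    minimises validation MSE; otherwise by plain least squares.
    """
    del seed
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("training set must be a nonempty 2-D array")
    _check_one_hot(y)
    n = x.shape[0]
    cap = min(cfg.max_neurons or n, n)
    b = cfg.width

    # full candidate kernel, columns indexed by training input
    d2 = (
        np.sum(x**2, axis=1)[:, None]
        - 2.0 * x @ x.T
        + np.sum(x**2, axis=1)[None, :]
    )
    phi_all = np.exp(-(b**2) * np.maximum(d2, 0.0))

    selectable = np.ones(n, dtype=bool)
    centers: list[int] = []
    weights = np.zeros((1, y.shape[1]))
    pred = np.zeros_like(y)
    history: list[float] = []
    while len(centers) < cap and selectable.any():
        err = np.sum((y - pred) ** 2, axis=1)
        err[~selectable] = -np.inf
        c = int(np.argmax(err))  # argmax takes the lowest index on ties
        centers.append(c)
        # exact duplicates of the new centre can never add information
        selectable &= ~np.all(x == x[c], axis=1)
        a = _design(phi_all[:, centers])
        weights, *_ = np.linalg.lstsq(a, y, rcond=None)
        pred = a @ weights
        mse = float(np.mean((y - pred) ** 2))
        history.append(mse)
        if mse <= cfg.mse_goal:
            break

    net = RbfNetwork(
        centers=x[centers].copy(),
        width=b,
        weights=weights,
        class_names=class_names,
        history=history,
    )
    if cfg.ridge is not None or (x_val is not None and y_val is not None):
        a = _design(phi_all[:, centers])
        u, s, vt = np.linalg.svd(a, full_matrices=False)
        smax2 = float(s.max() ** 2)
        if cfg.ridge is not None:
            net.weights = _ridge_weights(u, s, vt, y, cfg.ridge * smax2)
        else:
            phi_val = _design(net.activations(x_val))
            best = (np.inf, 0.0)
            for rel in [0.0] + [10.0**e for e in range(-16, 1)]:
                w = _ridge_weights(u, s, vt, y, rel * smax2)
                val_mse = float(np.mean((phi_val @ w - y_val) ** 2))
                if val_mse < best[0]:
                    best = (val_mse, rel)
            net.weights = _ridge_weights(u, s, vt, y, best[1] * smax2)
    return net


def rbf_predict(net: RbfNetwork, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score inputs and pick classes: scores = activations @ weights + bias;
    label = argmax score (ties to the lowest class index)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != net.centers.shape[1]:
        raise ValueError(
            f"feature width {x.shape[1]} != training width {net.centers.shape[1]}"
        )
    scores = _design(net.activations(x)) @ net.weights
    idx = np.argmax(scores, axis=1)
    if net.class_names is not None:
        labels = np.asarray([net.class_names[i] for i in idx])
    else:
        labels = idx
    return scores, labels


# ---------------------------------------------------------------------------
# MLP baseline


@dataclass(frozen=True)
class MlpConfig:
    """36 -> h1 -> h2 -> K with tanh hidden and output units; h1 must equal
    h2 (the published sweep tried 100..500 per layer)."""

    hidden1: int = 400
    hidden2: int = 400
    epochs: int = 500
    learning_rate: float = 0.1
    max_time: float = 120.0
    min_gradient: float = 1e-6
    validation_checks: int = 500
    goal: float = 0.0
    momentum: float = 0.9
    lr_up: float = 1.05
    lr_down: float = 0.7
    max_regression: float = 1.04

    def __post_init__(self) -> None:
        if self.hidden1 != self.hidden2:
            raise ValueError("the two hidden layers must have equal size")
        for name in ("hidden1", "epochs", "learning_rate", "max_time",
                     "min_gradient", "validation_checks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MlpNetwork:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    class_names: list[str] | None = None
    history: list[float] = field(default_factory=list)
    stop_reason: str = ""

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(x, dtype=float))
        for w, b in zip(self.weights, self.biases):
            a = np.tanh(a @ w + b)
        return a

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "kind": "mlp",
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "class_names": self.class_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MlpNetwork":
        return cls(
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            biases=[np.asarray(b, dtype=float) for b in d["biases"]],
            class_names=d.get("class_names"),
        )


def _mlp_loss_grads(net_w, net_b, x, y):
    acts = [x]
    a = x
    for w, b in zip(net_w, net_b):
        a = np.tanh(a @ w + b)
        acts.append(a)
    err = acts[-1] - y
    loss = float(np.mean(err**2))
    m = y.size
    delta = (2.0 / m) * err * (1.0 - acts[-1] ** 2)
    gw, gb = [], []
    for layer in range(len(net_w) - 1, -1, -1):
        gw.append(acts[layer].T @ delta)
        gb.append(delta.sum(axis=0))
        if layer > 0:
            delta = (delta @ net_w[layer].T) * (1.0 - acts[layer] ** 2)
    return loss, gw[::-1], gb[::-1]


def train_mlp(
    x: np.ndarray,
    y: np.ndarray,
    cfg: MlpConfig = MlpConfig(),
    seed: int = 0,
    class_names: list[str] | None = None,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> MlpNetwork:
    """Full-batch gradient descent with momentum and adaptive learning rate.

    The learning rate starts at ``cfg.learning_rate``, grows by ``lr_up``
    after an improving epoch and shrinks by ``lr_down`` (rejecting the step
    and clearing momentum) when the loss regresses by more than
    ``max_regression``. Training stops at the epoch budget, performance
    goal, minimum gradient norm, wall-clock limit, or after
    ``validation_checks`` consecutive epochs without validation improvement.
    Deterministic for a given seed. A non-finite loss raises rather than
    being silently ignored.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("inconsistent input/target row counts")
    rng = np.random.default_rng(seed)
    sizes = [x.shape[1], cfg.hidden1, cfg.hidden2, y.shape[1]]
    ws = [
        rng.standard_normal((a, b)) / np.sqrt(a)
        for a, b in zip(sizes[:-1], sizes[1:])
    ]
    bs = [np.zeros(b) for b in sizes[1:]]
    vel_w = [np.zeros_like(w) for w in ws]
    vel_b = [np.zeros_like(b) for b in bs]

    lr = cfg.learning_rate
    loss, gw, gb = _mlp_loss_grads(ws, bs, x, y)
    history = [loss]
    best_val = np.inf
    val_fail = 0
    stop = "epochs"
    t0 = time.monotonic()
    for _ in range(cfg.epochs):
        if not np.isfinite(loss):
            raise FloatingPointError("MLP training diverged (non-finite loss)")
        if loss <= cfg.goal:
            stop = "goal"
            break
        gnorm = np.sqrt(sum(float(np.sum(g**2)) for g in gw + gb))
        if gnorm < cfg.min_gradient:
            stop = "min_gradient"
            break
        if time.monotonic() - t0 > cfg.max_time:
            stop = "max_time"
            break
        vel_w = [cfg.momentum * v - lr * g for v, g in zip(vel_w, gw)]
        vel_b = [cfg.momentum * v - lr * g for v, g in zip(vel_b, gb)]
        new_w = [w + v for w, v in zip(ws, vel_w)]
        new_b = [b + v for b, v in zip(bs, vel_b)]
        new_loss, new_gw, new_gb = _mlp_loss_grads(new_w, new_b, x, y)
        if np.isfinite(new_loss) and new_loss <= loss * cfg.max_regression:
            ws, bs, gw, gb = new_w, new_b, new_gw, new_gb
            if new_loss < loss:
                lr *= cfg.lr_up
            loss = new_loss
        else:  # reject the step
            lr *= cfg.lr_down
            vel_w = [np.zeros_like(w) for w in ws]
            vel_b = [np.zeros_like(b) for b in bs]
        history.append(loss)
        if x_val is not None and y_val is not None:
            probe = MlpNetwork(ws, bs)
            val_loss = float(np.mean((probe.forward(x_val) - y_val) ** 2))
            if val_loss < best_val:
                best_val = val_loss
                val_fail = 0
            else:
                val_fail += 1
                if val_fail >= cfg.validation_checks:
                    stop = "validation"
                    break
    return MlpNetwork(ws, bs, class_names=class_names, history=history,
                      stop_reason=stop)


def mlp_predict(net: MlpNetwork, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = net.forward(x)
    idx = np.argmax(scores, axis=1)
    if net.class_names is not None:
        labels = np.asarray([net.class_names[i] for i in idx])
    else:
        labels = idx
    return scores, labels


# ---------------------------------------------------------------------------
# Serialization


def save_model(net: RbfNetwork | MlpNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(net.to_dict()))


def load_model(path: str | Path) -> RbfNetwork | MlpNetwork:
    d = json.loads(Path(path).read_text())
    if d.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {d.get('format_version')!r}")
    if d["kind"] == "rbf":
        return RbfNetwork.from_dict(d)
    if d["kind"] == "mlp":
        return MlpNetwork.from_dict(d)
    raise ValueError(f"unknown model kind {d['kind']!r}")
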