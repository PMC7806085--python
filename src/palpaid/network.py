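"""Window-level tumor-probability segmentation network.

A fully connected network with three hidden layers maps one sensor window
(W samples) to a vector of W per-sample tumor probabilities:

    h_0 = x,   h_i = relu(W_i h_{i-1} + b_i)  for i = 1..3,
    y   = logistic(W_4 h_3 + b_4)

At the study scale W = 1000 and each hidden layer has 2000 units; the 1:2
input:hidden ratio is preserved when the input dimension is reduced for
desk-scale runs. Weights are He-initialized (zero-mean normal, SD
sqrt(2/fan_in)), biases zero; training minimises binary cross-entropy with
Adam over shuffled mini-batches of 100 windows for a fixed number of epochs.

Two documented fidelity switches exist. ``paper_sign=True`` uses
``logistic(-z)`` at the output (the sign variant under which larger
pre-activations mean *lower* probability — kept for comparison only), and
``loss_mode="positive_only"`` drops the negative-class term of the
cross-entropy (degenerate: its optimum is y ≡ 1). Defaults are the standard
logistic and the full binary cross-entropy.

Everything is plain numpy in float64; gradients are exact backpropagation
through the forward pass above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "ArchitectureConfig",
    "ModelParams",
    "TrainConfig",
    "init_params",
    "forward",
    "loss",
    "train",
    "WindowSegmenterMLP",
]

_EPS = 1e-12  # probability clipping before logs


@dataclass(frozen=True)
class ArchitectureConfig:
    """Layer sizes: input/output dimension and the three hidden widths."""

    input_dim: int = 1000
    hidden_dims: Tuple[int, int, int] = (2000, 2000, 2000)

    def __post_init__(self) -> None:
        if len(self.hidden_dims) != 3:
            raise ValueError("exactly three hidden layers are required")
        if self.input_dim < 1 or min(self.hidden_dims) < 1:
            raise ValueError("all layer dimensions must be >= 1")

    @classmethod
    def scaled(cls, input_dim: int) -> "ArchitectureConfig":
        """Reduced architecture keeping the 1:2 input:hidden ratio."""
        return cls(input_dim=input_dim, hidden_dims=(2 * input_dim,) * 3)

    @property
    def layer_dims(self) -> List[int]:
        return [self.input_dim, *self.hidden_dims, self.input_dim]


@dataclass
class ModelParams:
    """Weight matrices W_1..W_4 (shape out x in) and bias vectors b_1..b_4."""

    weights: List[np.ndarray]
    biases: List[np.ndarray]

    def copy(self) -> "ModelParams":
        return ModelParams([w.copy() for w in self.weights],
                           [b.copy() for b in self.biases])

    @property
    def arch(self) -> ArchitectureConfig:
        dims = [self.weights[0].shape[1]] + [w.shape[0] for w in self.weights]
        return ArchitectureConfig(input_dim=dims[0], hidden_dims=tuple(dims[1:4]))


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; Adam hyperparameters are the standard defaults."""

    epochs: int = 200
    batch_size: int = 100
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    loss_mode: str = "binary_cross_entropy"
    paper_sign: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss_mode not in ("binary_cross_entropy", "positive_only"):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")


def init_params(arch: ArchitectureConfig,
                rng: Optional[np.random.Generator] = None) -> ModelParams:
    """He initialization: W ~ N(0, 2/fan_in), biases exactly zero."""
    if rng is None:
        rng = np.random.default_rng()
    dims = arch.layer_dims
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i + 1], dims[i]))
        for i in range(4)
    ]
    biases = [np.zeros(dims[i + 1]) for i in range(4)]
    return ModelParams(weights, biases)


def _logistic(z: np.ndarray) -> np.ndarray:
    # numerically stable in both tails
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(params: ModelParams, x: np.ndarray,
            paper_sign: bool = False) -> np.ndarray:
    """Per-sample tumor probabilities for one window or a batch of windows.

    Accepts ``x`` of shape (W,) or (n, W); output matches. Every component
    lies strictly in (0, 1).
    """
    y, _ = _forward_cached(params, np.atleast_2d(np.asarray(x, dtype=float)),
                           paper_sign)
    return y[0] if np.asarray(x).ndim == 1 else y


def _forward_cached(params: ModelParams, X: np.ndarray, paper_sign: bool):
    if X.shape[1] != params.weights[0].shape[1]:
        raise ValueError(
            f"input dimension {X.shape[1]} does not match model input "
            f"{params.weights[0].shape[1]}"
        )
    h = X
    hidden: List[np.ndarray] = [h]
    for W, b in zip(params.weights[:3], params.biases[:3]):
        h = np.maximum(h @ W.T + b, 0.0)
        hidden.append(h)
    z = h @ params.weights[3].T + params.biases[3]
    y = _logistic(-z) if paper_sign else _logistic(z)
    # keep the output strictly inside (0, 1) even where the logistic
    # saturates in float64
    np.clip(y, 5e-324, np.nextafter(1.0, 0.0), out=y)
    return y, hidden


def loss(y: np.ndarray, t: np.ndarray,
         mode: str = "binary_cross_entropy") -> float:
    """Cross-entropy between label window(s) t and probability window(s) y.

    Per window the loss is summed over samples; for a batch the per-window
    sums are averaged. ``positive_only`` keeps only the -t ln y term.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    t = np.atleast_2d(np.asarray(t, dtype=float))
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs t {t.shape}")
    yc = np.clip(y, _EPS, 1.0 - _EPS)
    if mode == "positive_only":
        per_window = -(t * np.log(yc)).sum(axis=1)
    elif mode == "binary_cross_entropy":
        per_window = -(t * np.log(yc) + (1.0 - t) * np.log1p(-yc)).sum(axis=1)
    else:
        raise ValueError(f"unknown loss mode {mode!r}")
    return float(per_window.mean())


def _gradients(params: ModelParams, X: np.ndarray, T: np.ndarray,
               mode: str, paper_sign: bool):
    """Analytic gradients of ``loss`` w.r.t. every weight and bias."""
    y, hidden = _forward_cached(params, X, paper_sign)
    n = X.shape[0]
    yc = np.clip(y, _EPS, 1.0 - _EPS)
    if mode == "binary_cross_entropy":
        dz = (yc - T) / n
    else:  # positive_only: dE/dy = -t/y, dy/dz = y(1-y)
        dz = -(T * (1.0 - yc)) / n
    if paper_sign:
        dz = -dz
    gW: List[np.ndarray] = [np.empty(0)] * 4
    gb: List[np.ndarray] = [np.empty(0)] * 4
    delta = dz
    for i in range(3, -1, -1):
        gW[i] = delta.T @ hidden[i]
        gb[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ params.weights[i]) * (hidden[i] > 0)
    return gW, gb, y


def train(
    params: ModelParams,
    X: np.ndarray,
    T: np.ndarray,
    cfg: TrainConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ModelParams, List[float]]:
    """Adam mini-batch training; returns new params and per-epoch mean loss.

    Windows are reshuffled every epoch; a final short batch is kept. The
    input ``params`` object is not modified. Raises ``RuntimeError`` on a
    non-finite loss (this typically indicates the degenerate positive-only
    loss or a too-large learning rate).
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if X.ndim != 2 or X.shape != T.shape:
        raise ValueError("X and T must be equal-shape (n_windows, W) arrays")
    if X.shape[0] < 1:
        raise ValueError("at least one window pair is required")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    params = params.copy()
    m = [np.zeros_like(w) for w in params.weights] + [np.zeros_like(b) for b in params.biases]
    v = [np.zeros_like(w) for w in params.weights] + [np.zeros_like(b) for b in params.biases]
    step = 0
    history: List[float] = []
    n = X.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, cfg.batch_size):
            batch = order[lo:lo + cfg.batch_size]
            gW, gb, y = _gradients(params, X[batch], T[batch],
                                   cfg.loss_mode, cfg.paper_sign)
            batch_loss = loss(y, T[batch], cfg.loss_mode)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    "non-finite training loss; if loss_mode='positive_only' "
                    "switch to the default binary cross-entropy, or lower "
                    "the learning rate"
                )
            epoch_losses.append(batch_loss)
            step += 1
            grads = gW + gb
            tensors = params.weights + params.biases
            bc1 = 1.0 - cfg.beta1 ** step
            bc2 = 1.0 - cfg.beta2 ** step
            for i, (p, g) in enumerate(zip(tensors, grads)):
                m[i] = cfg.beta1 * m[i] + (1.0 - cfg.beta1) * g
                v[i] = cfg.beta2 * v[i] + (1.0 - cfg.beta2) * g * g
                p -= cfg.learning_rate * (m[i] / bc1) / (np.sqrt(v[i] / bc2) + cfg.adam_eps)
        history.append(float(np.mean(epoch_losses)))
    return params, history


class WindowSegmenterMLP(BaseEstimator):
    """Scikit-learn style estimator around the window segmentation network.

    Parameters
    ----------
    hidden_dims : tuple of 3 ints or None
        Hidden-layer widths; ``None`` uses twice the input dimension for
        each of the three layers (the study's 1:2 ratio).
    epochs, batch_size, learning_rate, beta1, beta2, adam_eps
        Training settings (Adam).
    loss_mode : {"binary_cross_entropy", "positive_only"}
    paper_sign : bool
        Use the inverted-sign output logistic (fidelity experiments only).
    normalize : bool
        Z-score the input windows with the training set's global mean/SD.
    random_state : int or None
        Seeds both initialization and batch shuffling.

    Attributes
    ----------
    params_ : ModelParams
    loss_curve_ : list of per-epoch mean training losses
    input_mean_, input_scale_ : floats used to normalize inputs
    n_features_in_ : window width W
    """

    def __init__(self, hidden_dims=None, epochs=200, batch_size=100,
                 learning_rate=1e-3, beta1=0.9, beta2=0.999, adam_eps=1e-8,
                 loss_mode="binary_cross_entropy", paper_sign=False,
                 normalize=True, random_state=None):
        self.hidden_dims = hidden_dims
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.adam_eps = adam_eps
        self.loss_mode = loss_mode
        self.paper_sign = paper_sign
        self.normalize = normalize
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, beta1=self.beta1,
            beta2=self.beta2, adam_eps=self.adam_eps,
            loss_mode=self.loss_mode, paper_sign=self.paper_sign,
        )

    def fit(self, X, T):
        """Train on windows X (n, W) with binary label windows T (n, W)."""
        X = np.asarray(X, dtype=float)
        T = np.asarray(T, dtype=float)
        if X.ndim != 2 or X.shape != T.shape:
            raise ValueError("X and T must be equal-shape 2-D arrays")
        if not np.isin(T, (0.0, 1.0)).all():
            raise ValueError("label windows must be binary")
        self.n_features_in_ = X.shape[1]
        if self.normalize:
            self.input_mean_ = float(X.mean())
            self.input_scale_ = float(X.std()) or 1.0
        else:
            self.input_mean_, self.input_scale_ = 0.0, 1.0
        Xn = (X - self.input_mean_) / self.input_scale_

        hidden = (tuple(self.hidden_dims) if self.hidden_dims is not None
                  else (2 * self.n_features_in_,) * 3)
        arch = ArchitectureConfig(input_dim=self.n_features_in_,
                                  hidden_dims=hidden)
        rng = np.random.default_rng(self.random_state)
        params = init_params(arch, rng)
        self.params_, self.loss_curve_ = train(params, Xn, T,
                                               self._train_config(), rng)
        return self

    def predict_proba(self, X):
        """Per-sample tumor probabilities, shape (n, W), values in (0, 1)."""
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        Xn = (X - self.input_mean_) / self.input_scale_
        return forward(self.params_, Xn, paper_sign=self.paper_sign)
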