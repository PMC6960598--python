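"""Single-hidden-layer feedforward regression network.

The blood-pressure estimators are classic three-layer perceptrons: a tanh
("tansig") hidden layer and a linear ("purelin") scalar output, trained by
Levenberg-Marquardt on min-max normalized inputs and targets.  All weights
and thresholds live in one flat parameter vector in a fixed order

    [W1 (hidden x in, row-major), b1 (hidden), W2 (hidden), b2 (1)]

so that a genetic optimizer can encode, perturb and decode complete
networks.  Input features and the target are scaled to [-1, 1] with the
training-set minimum and maximum; the scaling records are stored with the
parameters and predictions are always returned in mmHg.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NetworkTopology",
    "NetworkParams",
    "TrainConfig",
    "sizing_range",
    "forward",
    "train_lm",
    "rmse_fitness",
]


@dataclass(frozen=True)
class NetworkTopology:
    n_in: int
    n_hidden: int
    n_out: int = 1

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.n_out != 1:
            raise ValueError("only scalar outputs are supported")

    @property
    def n_params(self) -> int:
        return self.n_hidden * (self.n_in + 1) + self.n_out * (self.n_hidden + 1)


def sizing_range(n: int, l: int) -> tuple[int, int]:  # noqa: E741
    """Empirical hidden-layer size range m = sqrt(n + l) + d, d in [1, 10].

    ``n`` and ``l`` are the input and output layer widths; both bounds are
    rounded half-up to integers.
    """
    if n < 1 or l < 1:
        raise ValueError("layer sizes must be >= 1")
    root = math.sqrt(n + l)
    half_up = lambda v: int(math.floor(v + 0.5))  # noqa: E731
    return half_up(root + 1), half_up(root + 10)


@dataclass(frozen=True)
class _MinMaxScale:
    """Per-column min-max map onto [-1, 1]; constant columns map to 0."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "_MinMaxScale":
        v = np.atleast_2d(np.asarray(values, float))
        return cls(lo=v.min(axis=0), hi=v.max(axis=0))

    @property
    def span(self) -> np.ndarray:
        span = self.hi - self.lo
        return np.where(span > 0, span, 1.0)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(values, float) - self.lo) / self.span - 1.0

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return (np.asarray(scaled, float) + 1.0) / 2.0 * self.span + self.lo


@dataclass(frozen=True)
class NetworkParams:
    topology: NetworkTopology
    vector: np.ndarray
    x_scale: _MinMaxScale
    y_scale: _MinMaxScale

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, float)
        if vec.shape != (self.topology.n_params,):
            raise ValueError(
                f"parameter vector length {vec.shape} does not match "
                f"topology ({self.topology.n_params} parameters)"
            )
        if np.any(~np.isfinite(vec)):
            raise ValueError("parameters must be finite")
        object.__setattr__(self, "vector", vec)

    def unpack(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        t = self.topology
        v = self.vector
        i = t.n_hidden * t.n_in
        w1 = v[:i].reshape(t.n_hidden, t.n_in)
        b1 = v[i : i + t.n_hidden]
        w2 = v[i + t.n_hidden : i + 2 * t.n_hidden]
        b2 = float(v[-1])
        return w1, b1, w2, b2

    def with_vector(self, vector: np.ndarray) -> "NetworkParams":
        return replace(self, vector=np.asarray(vector, float))

    def to_json(self) -> str:
        return json.dumps(
            {
                "topology": [self.topology.n_in, self.topology.n_hidden,
                             self.topology.n_out],
                "vector": self.vector.tolist(),
                "x_lo": self.x_scale.lo.tolist(),
                "x_hi": self.x_scale.hi.tolist(),
                "y_lo": self.y_scale.lo.tolist(),
                "y_hi": self.y_scale.hi.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkParams":
        d = json.loads(text)
        return cls(
            topology=NetworkTopology(*d["topology"]),
            vector=np.asarray(d["vector"], float),
            x_scale=_MinMaxScale(np.asarray(d["x_lo"]), np.asarray(d["x_hi"])),
            y_scale=_MinMaxScale(np.asarray(d["y_lo"]), np.asarray(d["y_hi"])),
        )


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01        # used by the plain-gradient fallback
    max_epochs: int = 1000
    goal_mse: float = 1e-4             # on the [-1, 1] target scale
    algorithm: str = "levenberg_marquardt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs <= 0 or self.goal_mse <= 0:
            raise ValueError("training hyper-parameters must be positive")
        if self.algorithm not in ("levenberg_marquardt", "gradient"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


def _forward_scaled(
    params: NetworkParams, xs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    w1, b1, w2, b2 = params.unpack()
    hidden = np.tanh(xs @ w1.T + b1)
    return hidden @ w2 + b2, hidden


def forward(params: NetworkParams, x: np.ndarray) -> np.ndarray:
    """Predict mmHg for raw (unscaled) feature rows ``x``."""
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[1] != params.topology.n_in:
        raise ValueError(
            f"expected {params.topology.n_in} features, got {x.shape[1]}"
        )
    ys, _ = _forward_scaled(params, params.x_scale.transform(x))
    return params.y_scale.inverse(ys[:, None]).ravel()


def _jacobian(params: NetworkParams, xs: np.ndarray) -> np.ndarray:
    """d(prediction)/d(parameters) on the scaled output, rows per sample."""
    w1, b1, w2, b2 = params.unpack()
    z = xs @ w1.T + b1
    h = np.tanh(z)
    sech2 = 1.0 - h**2
    n, t = xs.shape[0], params.topology
    jac = np.empty((n, t.n_params))
    dw1 = (w2 * sech2)[:, :, None] * xs[:, None, :]  # n x hidden x in
    i = t.n_hidden * t.n_in
    jac[:, :i] = dw1.reshape(n, -1)
    jac[:, i : i + t.n_hidden] = w2 * sech2
    jac[:, i + t.n_hidden : i + 2 * t.n_hidden] = h
    jac[:, -1] = 1.0
    return jac


def init_params(
    X: np.ndarray,
    y: np.ndarray,
    topo: NetworkTopology,
    seed: int = 0,
    init_range: tuple[float, float] = (-0.5, 0.5),
) -> NetworkParams:
    """Random network with scaling records fitted to ``X``/``y``."""
    rng = np.random.default_rng(seed)
    vec = rng.uniform(*init_range, topo.n_params)
    return NetworkParams(
        topology=topo,
        vector=vec,
        x_scale=_MinMaxScale.fit(X),
        y_scale=_MinMaxScale.fit(np.asarray(y, float)[:, None]),
    )


def train_lm(
    X: np.ndarray,
    y: np.ndarray,
    topo: NetworkTopology,
    cfg: TrainConfig | None = None,
    *,
    start: NetworkParams | None = None,
) -> NetworkParams:
    """Train the network; Levenberg-Marquardt by default.

    ``start`` may carry pre-optimized initial weights (e.g. from a genetic
    search); otherwise parameters are drawn uniformly from [-0.5, 0.5] with
    the config seed.  The LM loop accepts a step only when the sum of
    squared residuals decreases, scaling the damping factor by 2 on
    rejection and 1/3 on acceptance (the gentle "delayed gratification"
    schedule, which tracks the narrow curved valleys these networks
    produce); it stops at ``max_epochs`` accepted steps, at ``goal_mse``
    (scaled units), or when damping overflows.
    """
    cfg = cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, float))
    yv = np.asarray(y, float).ravel()
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(yv)):
        raise ValueError("training data contain NaN or infinite values")
    if X.shape[0] != yv.size:
        raise ValueError("X and y lengths differ")
    params = start if start is not None else init_params(X, yv, topo, cfg.seed)
    if params.topology != topo:
        raise ValueError("start parameters do not match the topology")
    if X.shape[0] < topo.n_params / 2:
        warnings.warn(
            f"only {X.shape[0]} samples for {topo.n_params} parameters",
            stacklevel=2,
        )
    xs = params.x_scale.transform(X)
    ys = params.y_scale.transform(yv[:, None]).ravel()

    if cfg.algorithm == "gradient":
        return _train_gradient(params, xs, ys, cfg)

    vec = params.vector.copy()
    lam = 1e-3
    pred, _ = _forward_scaled(params.with_vector(vec), xs)
    resid = ys - pred
    sse = float(resid @ resid)
    n = ys.size
    for _ in range(cfg.max_epochs):
        if sse / n <= cfg.goal_mse:
            break
        jac = _jacobian(params.with_vector(vec), xs)
        jtj = jac.T @ jac
        jtr = jac.T @ resid
        accepted = False
        while lam <= 1e10:
            try:
                step = np.linalg.solve(jtj + lam * np.eye(jtj.shape[0]), jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = vec + step
            cand_pred, _ = _forward_scaled(params.with_vector(cand), xs)
            cand_resid = ys - cand_pred
            cand_sse = float(cand_resid @ cand_resid)
            if cand_sse < sse:
                vec, resid, sse = cand, cand_resid, cand_sse
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                break
            lam *= 2.0
        if not accepted:
            break
    return params.with_vector(vec)


def _train_gradient(
    params: NetworkParams, xs: np.ndarray, ys: np.ndarray, cfg: TrainConfig
) -> NetworkParams:
    vec = params.vector.copy()
    n = ys.size
    for _ in range(cfg.max_epochs):
        p = params.with_vector(vec)
        pred, _ = _forward_scaled(p, xs)
        resid = ys - pred
        if float(resid @ resid) / n <= cfg.goal_mse:
            break
        grad = -2.0 / n * (_jacobian(p, xs).T @ resid)
        vec = vec - cfg.learning_rate * grad
    return params.with_vector(vec)


def rmse_fitness(params: NetworkParams, X: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square prediction error in mmHg."""
    yv = np.asarray(y, float).ravel()
    if yv.size == 0:
        raise ValueError("empty evaluation set")
    err = yv - forward(params, X)
    return float(np.sqrt(np.mean(err**2)))
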