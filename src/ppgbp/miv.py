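"""Mean-impact-value (MIV) feature screening.

MIV measures how strongly each input feature moves a trained network's
output: the feature column is scaled by +10% and by -10% (all other
columns untouched), and the MIV is the mean, over the training samples, of
the difference between the two resulting predictions.  Features are ranked
by |MIV|, each one's relative contribution is |MIV_i| / sum_j |MIV_j|, and
screening keeps the smallest ranked prefix whose cumulative contribution
reaches the requested threshold.  The screening is applied twice — a rough
round on all features followed by a refining round on the survivors — which
empirically removes redundant inputs while retaining the causal ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neuralnet import (
    NetworkParams,
    NetworkTopology,
    TrainConfig,
    forward,
    train_lm,
)

__all__ = ["miv_scores", "contributions", "screen", "two_round_screen"]


def miv_scores(net: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Signed mean impact value of every feature column of ``X``."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != net.topology.n_in:
        raise ValueError(
            f"network expects {net.topology.n_in} features, got {X.shape[1]}"
        )
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        up = X.copy()
        down = X.copy()
        up[:, j] *= 1.1
        down[:, j] *= 0.9
        out[j] = float(np.mean(forward(net, up) - forward(net, down)))
    return out


def contributions(
    miv: np.ndarray, names: list[str] | tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Rank features by |MIV| and attach normalized/cumulative contributions.

    Returns a frame sorted by rank with columns ``feature``, ``miv``,
    ``contribution`` and ``cumulative``; ties in |MIV| keep the original
    column order.
    """
    miv = np.asarray(miv, float).ravel()
    if miv.size == 0:
        raise ValueError("at least one feature is required")
    total = float(np.sum(np.abs(miv)))
    if total == 0:
        raise ValueError("all MIV values are zero; contributions undefined")
    if names is None:
        names = [f"x{j}" for j in range(miv.size)]
    if len(names) != miv.size:
        raise ValueError("names length must match the MIV vector")
    order = np.argsort(-np.abs(miv), kind="stable")
    contrib = np.abs(miv[order]) / total
    return pd.DataFrame(
        {
            "rank": np.arange(1, miv.size + 1),
            "feature": np.asarray(names, object)[order],
            "miv": miv[order],
            "contribution": contrib,
            "cumulative": np.cumsum(contrib),
        }
    )


def screen(table: pd.DataFrame, threshold: float) -> list[str]:
    """Smallest ranked prefix whose cumulative contribution >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    cum = table["cumulative"].to_numpy()
    n_keep = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    n_keep = min(n_keep, len(table))
    return table["feature"].head(n_keep).tolist()


@dataclass(frozen=True)
class ScreenResult:
    selected: list[str]
    round1: pd.DataFrame
    round2: pd.DataFrame


def two_round_screen(
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    n_hidden: int = 11,
    train_cfg: TrainConfig | None = None,
    thresholds: tuple[float, float] = (0.91, 0.89),
    seed: int = 0,
) -> ScreenResult:
    """Two-pass MIV screening on a named feature matrix.

    A network with ``n_hidden`` hidden nodes is trained on all features and
    screened at ``thresholds[0]``; a second network is retrained on the
    survivors and screened at ``thresholds[1]``.  Both ranking tables are
    returned alongside the final feature list.
    """
    cfg = train_cfg or TrainConfig(seed=seed)
    names = list(X.columns)
    yv = np.asarray(y, float)

    net1 = train_lm(
        X.to_numpy(float), yv, NetworkTopology(len(names), n_hidden), cfg
    )
    table1 = contributions(miv_scores(net1, X.to_numpy(float)), names)
    keep1 = screen(table1, thresholds[0])

    X2 = X[keep1]
    cfg2 = TrainConfig(
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs,
        goal_mse=cfg.goal_mse,
        algorithm=cfg.algorithm,
        seed=cfg.seed + 1,
    )
    net2 = train_lm(
        X2.to_numpy(float), yv, NetworkTopology(len(keep1), n_hidden), cfg2
    )
    table2 = contributions(miv_scores(net2, X2.to_numpy(float)), keep1)
    keep2 = screen(table2, thresholds[1])
    return ScreenResult(selected=keep2, round1=table1, round2=table2)
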