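"""Personalized blood-pressure estimation by weighted model integration.

Five independent networks per pressure target are trained on the pooled
training cohort via fivefold cross-validation: the records are shuffled
once (seeded), split into five folds, and network *k* is optimized on the
four folds excluding fold *k*, so each base model sees a different 80% of
the data.  A new individual is then personalized by fitting proportional
coefficients — one per base network, bounded to the genetic coding range —
that minimize the RMSE of the weighted prediction

    NET(x) = a1*net1(x) + ... + a5*net5(x)

on a handful of calibration records (six by default).  SBP and DBP get
separate base models and separate coefficients; the coefficients are not
normalized and need not sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mpga import GAConfig, EvolutionResult, evolve, optimize_network
from .neuralnet import NetworkParams, NetworkTopology, TrainConfig, forward

__all__ = [
    "EnsembleModel",
    "train_base_models",
    "calibrate_individual",
    "predict",
    "N_BASE_MODELS",
]

N_BASE_MODELS = 5

#: default MPGA settings for coefficient calibration: finer 25-bit coding
#: and more (15) populations than the network search, same coding range.
CALIBRATION_GA = GAConfig(
    n_populations=15,
    pop_size=20,
    bits_per_variable=25,
    var_range=(-0.5, 0.8),
)


@dataclass
class EnsembleModel:
    nets_sbp: tuple[NetworkParams, ...]
    nets_dbp: tuple[NetworkParams, ...]
    feature_names: tuple[str, ...]
    fold_rmse_sbp: tuple[float, ...] = ()
    fold_rmse_dbp: tuple[float, ...] = ()
    #: per-individual proportional coefficients, id -> (a[5], b[5])
    coefficients: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if len(self.nets_sbp) != N_BASE_MODELS or len(self.nets_dbp) != N_BASE_MODELS:
            raise ValueError(f"exactly {N_BASE_MODELS} base models per target")

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "nets_sbp": [n.to_json() for n in self.nets_sbp],
                "nets_dbp": [n.to_json() for n in self.nets_dbp],
                "feature_names": list(self.feature_names),
                "fold_rmse_sbp": list(self.fold_rmse_sbp),
                "fold_rmse_dbp": list(self.fold_rmse_dbp),
                "coefficients": {
                    k: [a.tolist(), b.tolist()]
                    for k, (a, b) in self.coefficients.items()
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        import json

        d = json.loads(text)
        return cls(
            nets_sbp=tuple(NetworkParams.from_json(t) for t in d["nets_sbp"]),
            nets_dbp=tuple(NetworkParams.from_json(t) for t in d["nets_dbp"]),
            feature_names=tuple(d["feature_names"]),
            fold_rmse_sbp=tuple(d["fold_rmse_sbp"]),
            fold_rmse_dbp=tuple(d["fold_rmse_dbp"]),
            coefficients={
                k: (np.asarray(a), np.asarray(b))
                for k, (a, b) in d["coefficients"].items()
            },
        )


def _base_predictions(
    nets: tuple[NetworkParams, ...], X: np.ndarray
) -> np.ndarray:
    """n_samples x n_models matrix of base-model predictions (mmHg)."""
    return np.column_stack([forward(net, X) for net in nets])


def train_base_models(
    X: np.ndarray,
    y: np.ndarray,
    topo: NetworkTopology,
    ga_cfg: GAConfig | None = None,
    train_cfg: TrainConfig | None = None,
    *,
    seed: int = 0,
    n_folds: int = N_BASE_MODELS,
) -> tuple[tuple[NetworkParams, ...], tuple[float, ...]]:
    """Fivefold-CV training of the base networks for one pressure target.

    Returns the networks and each one's RMSE on its held-out fold.  Every
    fold gets a fresh genetic search (distinct derived seed).
    """
    X = np.atleast_2d(np.asarray(X, float))
    yv = np.asarray(y, float).ravel()
    if X.shape[0] < 50:
        raise ValueError("at least 50 samples are required for 5-CV training")
    ga_cfg = ga_cfg or GAConfig(seed=seed)
    train_cfg = train_cfg or TrainConfig(seed=seed)

    rng = np.random.default_rng(seed)
    order = rng.permutation(X.shape[0])
    folds = np.array_split(order, n_folds)

    nets, fold_rmse = [], []
    for k, fold in enumerate(folds):
        train_idx = np.setdiff1d(order, fold, assume_unique=True)
        fold_seed = (ga_cfg.seed + 7919 * (k + 1)) % 2**31
        ga_k = GAConfig(
            n_populations=ga_cfg.n_populations,
            pop_size=ga_cfg.pop_size,
            bits_per_variable=ga_cfg.bits_per_variable,
            var_range=ga_cfg.var_range,
            pc_range=ga_cfg.pc_range,
            pm_range=ga_cfg.pm_range,
            min_preserve_generations=ga_cfg.min_preserve_generations,
            max_generations=ga_cfg.max_generations,
            seed=fold_seed,
        )
        net, _ = optimize_network(
            X[train_idx], yv[train_idx], topo, ga_k, train_cfg
        )
        nets.append(net)
        err = yv[fold] - forward(net, X[fold])
        fold_rmse.append(float(np.sqrt(np.mean(err**2))))
    return tuple(nets), tuple(fold_rmse)


def calibrate_individual(
    model: EnsembleModel,
    individual_id: str,
    calib_X: np.ndarray,
    calib_y_sbp: np.ndarray,
    calib_y_dbp: np.ndarray,
    ga_cfg: GAConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the individual's proportional coefficients by MPGA.

    SBP and DBP coefficients are optimized independently against the
    calibration records; both vectors are stored on the model and returned.
    """
    calib_X = np.atleast_2d(np.asarray(calib_X, float))
    if calib_X.shape[0] < 2:
        raise ValueError("at least 2 calibration records are required")
    ga_cfg = ga_cfg or CALIBRATION_GA

    coeffs = []
    for nets, y, salt in (
        (model.nets_sbp, calib_y_sbp, 0),
        (model.nets_dbp, calib_y_dbp, 1),
    ):
        preds = _base_predictions(nets, calib_X)
        yv = np.asarray(y, float).ravel()

        def objective(a: np.ndarray) -> float:
            return float(np.sqrt(np.mean((preds @ a - yv) ** 2)))

        cfg = GAConfig(
            n_populations=ga_cfg.n_populations,
            pop_size=ga_cfg.pop_size,
            bits_per_variable=ga_cfg.bits_per_variable,
            var_range=ga_cfg.var_range,
            pc_range=ga_cfg.pc_range,
            pm_range=ga_cfg.pm_range,
            min_preserve_generations=ga_cfg.min_preserve_generations,
            max_generations=ga_cfg.max_generations,
            seed=(ga_cfg.seed + 2 * _stable_hash(individual_id) + salt) % 2**31,
        )
        # warm start at the uniform blend: elitism then guarantees the
        # calibrated ensemble never trails the equal-weight one
        result: EvolutionResult = evolve(
            objective, N_BASE_MODELS, cfg,
            initial=[np.full(N_BASE_MODELS, 1.0 / N_BASE_MODELS)],
        )
        coeffs.append(result.best_x)

    model.coefficients[individual_id] = (coeffs[0], coeffs[1])
    return coeffs[0], coeffs[1]


def _stable_hash(text: str) -> int:
    """Deterministic small hash of an identifier (process-independent)."""
    h = 0
    for ch in text:
        h = (h * 31 + ord(ch)) % 1_000_003
    return h


def predict(
    model: EnsembleModel, individual_id: str, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Personalized (SBP, DBP) predictions in mmHg for one individual."""
    if individual_id not in model.coefficients:
        raise KeyError(f"individual {individual_id!r} is not calibrated")
    a, b = model.coefficients[individual_id]
    X = np.atleast_2d(np.asarray(X, float))
    sbp = _base_predictions(model.nets_sbp, X) @ a
    dbp = _base_predictions(model.nets_dbp, X) @ b
    if np.any(sbp < 40.0) or np.any(dbp < 40.0):
        warnings.warn(
            "implausible prediction below 40 mmHg; check calibration",
            stacklevel=2,
        )
    return sbp, dbp
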