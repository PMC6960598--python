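"""End-to-end orchestration: synth -> preprocess -> features -> screen ->
train -> calibrate -> evaluate.

One :class:`RunConfig` (a single global seed plus per-stage settings)
drives the whole chain deterministically; rerunning the same config
reproduces bit-identical CSV artifacts.  The defaults are sized for a
quick demonstration cohort; the full-scale layout is available through
``synthgen.DEFAULT_TRAIN_RECORD_COUNTS``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble as ens
from .evaluate import EvalReport, evaluate_predictions
from .features import FEATURE_NAMES, beat_features, record_features
from .fiducials import detect_ppg_fiducials, detect_r_peaks
from .miv import ScreenResult, two_round_screen
from .mpga import GAConfig
from .neuralnet import NetworkTopology, TrainConfig
from .preprocess import DenoiseConfig, baseline_correct, wp_denoise
from .synthgen import Cohort, NoiseConfig, SubjectProfile, make_cohort

__all__ = ["RunConfig", "PipelineResult", "extract_features", "run_pipeline"]

log = logging.getLogger("ppgbp")


@dataclass(frozen=True)
class RunConfig:
    seed: int
    # cohort: a demonstration-sized campaign (8 x 45 = 360 training records)
    n_train_subjects: int = 8
    n_test_subjects: int = 4
    records_per_subject: int = 45
    test_records_per_subject: int = 12
    noise: NoiseConfig = field(default_factory=lambda: NoiseConfig(white_sd=0.01))
    # preprocessing / features
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    k_variant: str = "standard"
    # screening
    thresholds: tuple[float, float] = (0.91, 0.89)
    n_hidden_screen: int = 11
    # model topologies: the lower end of the empirical sizing range, which
    # keeps the parameter count well below the demo cohort's record count
    n_hidden_sbp: int = 5
    n_hidden_dbp: int = 5
    # optimizers
    ga_network: GAConfig = field(
        default_factory=lambda: GAConfig(max_generations=15)
    )
    ga_calibration: GAConfig = field(
        default_factory=lambda: GAConfig(
            n_populations=15, bits_per_variable=25, max_generations=15
        )
    )
    train: TrainConfig = field(default_factory=lambda: TrainConfig(max_epochs=30))
    # personalization protocol: first n_calib records calibrate, rest test
    n_calibration_records: int = 6

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a global seed is required")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                k: (v if isinstance(v, (int, float, str, tuple, list)) else repr(v))
                for k, v in self.__dict__.items()
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    features_train: pd.DataFrame
    features_test: pd.DataFrame
    screen_sbp: ScreenResult
    screen_dbp: ScreenResult
    model: ens.EnsembleModel
    predictions: pd.DataFrame
    report_sbp: EvalReport
    report_dbp: EvalReport


def process_record(
    ppg: np.ndarray,
    ecg: np.ndarray,
    fs: float,
    denoise_cfg: DenoiseConfig,
    subject: SubjectProfile,
    *,
    k_variant: str = "standard",
) -> pd.Series:
    """Denoise one record, locate fiducials and return its feature vector."""
    ecg_dn = wp_denoise(ecg, denoise_cfg)
    ppg_dn = wp_denoise(ppg, denoise_cfg)
    r_peaks = detect_r_peaks(ecg_dn, fs)
    fids = detect_ppg_fiducials(ppg_dn, r_peaks, fs)
    onsets = fids.arrays()["b"]
    if onsets.size >= 4:
        ppg_dn = baseline_correct(ppg_dn, onsets)
        fids = detect_ppg_fiducials(ppg_dn, r_peaks, fs)
    beats = beat_features(fids, ppg_dn, fs, k_variant=k_variant)
    return record_features(beats, subject)


def extract_features(
    records,
    subjects,
    denoise_cfg: DenoiseConfig | None = None,
    *,
    k_variant: str = "standard",
) -> pd.DataFrame:
    """Feature matrix for a list of records; one row per accepted record.

    Rejected records (too few valid beats) are skipped with a log entry.
    """
    denoise_cfg = denoise_cfg or DenoiseConfig()
    by_id = {s.subject_id: s for s in subjects}
    rows = []
    for rec in records:
        try:
            vec = process_record(
                rec.ppg, rec.ecg, rec.fs, denoise_cfg, by_id[rec.subject_id],
                k_variant=k_variant,
            )
        except ValueError as err:
            log.warning("record %s rejected: %s", rec.record_id, err)
            continue
        row = {"subject_id": rec.subject_id, "record_id": rec.record_id,
               "sbp_ref": rec.sbp_ref, "dbp_ref": rec.dbp_ref}
        row.update(vec.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _ga_with_seed(cfg: GAConfig, seed: int) -> GAConfig:
    return replace(cfg, seed=seed % 2**31)


def run_pipeline(
    cfg: RunConfig, out_dir: str | Path | None = None, cohort: Cohort | None = None
) -> PipelineResult:
    """Execute the full chain and (optionally) write stage artifacts.

    Artifacts: ``features_{train,test}.csv``, MIV ranking tables per target
    and round, per-individual coefficient table, per-target agreement
    reports and a ``run.json`` provenance stamp (seed + config hash).
    """
    t0 = time.perf_counter()
    if cohort is None:
        cohort = make_cohort(
            cfg.n_train_subjects,
            cfg.n_test_subjects,
            cfg.records_per_subject,
            test_records_per_subject=cfg.test_records_per_subject,
            seed=cfg.seed,
            noise=cfg.noise,
        )
    log.info("cohort: %d train / %d test records",
             cohort.n_train_records, cohort.n_test_records)

    feat_train = extract_features(
        cohort.train_records, cohort.train_subjects, cfg.denoise,
        k_variant=cfg.k_variant,
    )
    feat_test = extract_features(
        cohort.test_records, cohort.test_subjects, cfg.denoise,
        k_variant=cfg.k_variant,
    )
    if feat_train.empty or feat_test.empty:
        raise RuntimeError("feature extraction produced no usable records")
    log.info("features: %d train / %d test rows (%.1f s)",
             len(feat_train), len(feat_test), time.perf_counter() - t0)

    X = feat_train[list(FEATURE_NAMES)]
    screens = {}
    for target, y_col in (("sbp", "sbp_ref"), ("dbp", "dbp_ref")):
        screens[target] = two_round_screen(
            X,
            feat_train[y_col].to_numpy(),
            n_hidden=cfg.n_hidden_screen,
            train_cfg=cfg.train,
            thresholds=cfg.thresholds,
            seed=cfg.seed,
        )
        log.info("%s screening kept %d features", target,
                 len(screens[target].selected))

    nets = {}
    for target, y_col, n_hidden in (
        ("sbp", "sbp_ref", cfg.n_hidden_sbp),
        ("dbp", "dbp_ref", cfg.n_hidden_dbp),
    ):
        sel = screens[target].selected
        topo = NetworkTopology(len(sel), n_hidden)
        nets[target] = ens.train_base_models(
            feat_train[sel].to_numpy(float),
            feat_train[y_col].to_numpy(),
            topo,
            _ga_with_seed(cfg.ga_network, cfg.seed + (0 if target == "sbp" else 1)),
            cfg.train,
            seed=cfg.seed,
        )
        log.info("%s base models trained; fold RMSE %s", target,
                 np.round(nets[target][1], 3))

    model = ens.EnsembleModel(
        nets_sbp=nets["sbp"][0],
        nets_dbp=nets["dbp"][0],
        feature_names=tuple(FEATURE_NAMES),
        fold_rmse_sbp=nets["sbp"][1],
        fold_rmse_dbp=nets["dbp"][1],
    )

    pred_rows = []
    for subject_id, grp in feat_test.groupby("subject_id", sort=True):
        grp = grp.sort_values("record_id")
        n_cal = cfg.n_calibration_records
        if len(grp) <= n_cal:
            log.warning("subject %s: too few records to hold out a test set",
                        subject_id)
            continue
        cal, tst = grp.iloc[:n_cal], grp.iloc[n_cal:]
        Xs_cal = cal[list(screens["sbp"].selected)].to_numpy(float)
        Xd_cal = cal[list(screens["dbp"].selected)].to_numpy(float)
        _calibrate_two_target(
            model, subject_id, Xs_cal, Xd_cal,
            cal["sbp_ref"].to_numpy(), cal["dbp_ref"].to_numpy(),
            _ga_with_seed(cfg.ga_calibration, cfg.seed),
        )
        sbp_hat = _predict_target(model.nets_sbp,
                                  tst[list(screens["sbp"].selected)].to_numpy(float),
                                  model.coefficients[subject_id][0])
        dbp_hat = _predict_target(model.nets_dbp,
                                  tst[list(screens["dbp"].selected)].to_numpy(float),
                                  model.coefficients[subject_id][1])
        for i, (_, row) in enumerate(tst.iterrows()):
            pred_rows.append(
                {"individual": subject_id, "record_id": row["record_id"],
                 "sbp_ref": row["sbp_ref"], "sbp_hat": float(sbp_hat[i]),
                 "dbp_ref": row["dbp_ref"], "dbp_hat": float(dbp_hat[i])}
            )
    predictions = pd.DataFrame(pred_rows)
    if predictions.empty:
        raise RuntimeError("no test subject had enough records to evaluate")

    report_sbp = evaluate_predictions(
        predictions.rename(columns={"sbp_ref": "y", "sbp_hat": "y_hat"})
    )
    report_dbp = evaluate_predictions(
        predictions.rename(columns={"dbp_ref": "y", "dbp_hat": "y_hat"})
    )
    log.info("pooled SBP RMSE %.3f / DBP RMSE %.3f mmHg (%.1f s total)",
             report_sbp.pooled["rmse"], report_dbp.pooled["rmse"],
             time.perf_counter() - t0)

    result = PipelineResult(
        features_train=feat_train,
        features_test=feat_test,
        screen_sbp=screens["sbp"],
        screen_dbp=screens["dbp"],
        model=model,
        predictions=predictions,
        report_sbp=report_sbp,
        report_dbp=report_dbp,
    )
    if out_dir is not None:
        _write_artifacts(result, cfg, Path(out_dir))
    return result


def _calibrate_two_target(model, subject_id, Xs, Xd, y_sbp, y_dbp, ga_cfg):
    """Per-target calibration when SBP/DBP use different feature subsets."""
    from .mpga import evolve

    coeffs = []
    for nets, Xc, y, salt in (
        (model.nets_sbp, Xs, y_sbp, 0),
        (model.nets_dbp, Xd, y_dbp, 1),
    ):
        preds = np.column_stack(
            [ens.forward(net, Xc) for net in nets]
        )
        yv = np.asarray(y, float)

        def objective(a):
            return float(np.sqrt(np.mean((preds @ a - yv) ** 2)))

        cfg = replace(
            ga_cfg,
            seed=(ga_cfg.seed + 2 * ens._stable_hash(subject_id) + salt) % 2**31,
        )
        result = evolve(
            objective, ens.N_BASE_MODELS, cfg,
            initial=[np.full(ens.N_BASE_MODELS, 1.0 / ens.N_BASE_MODELS)],
        )
        coeffs.append(result.best_x)
    model.coefficients[subject_id] = (coeffs[0], coeffs[1])


def _predict_target(nets, X, coeff):
    return np.column_stack([ens.forward(net, X) for net in nets]) @ coeff


def _write_artifacts(result: PipelineResult, cfg: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.features_train.to_csv(out / "features_train.csv", index=False)
    result.features_test.to_csv(out / "features_test.csv", index=False)
    for target, screen in (("sbp", result.screen_sbp), ("dbp", result.screen_dbp)):
        screen.round1.to_csv(out / f"miv_{target}_round1.csv", index=False)
        screen.round2.to_csv(out / f"miv_{target}_round2.csv", index=False)
    coeff_rows = []
    for ind, (a, b) in sorted(result.model.coefficients.items()):
        row = {"individual": ind}
        row.update({f"a{i + 1}": a[i] for i in range(len(a))})
        row.update({f"b{i + 1}": b[i] for i in range(len(b))})
        coeff_rows.append(row)
    pd.DataFrame(coeff_rows).to_csv(out / "coefficients.csv", index=False)
    result.predictions.to_csv(out / "predictions.csv", index=False)
    result.report_sbp.to_frame().to_csv(out / "report_sbp.csv", index=False)
    result.report_dbp.to_frame().to_csv(out / "report_dbp.csv", index=False)
    (out / "run.json").write_text(
        json.dumps(
            {"seed": cfg.seed, "config_hash": cfg.config_hash(),
             "selected_sbp": result.screen_sbp.selected,
             "selected_dbp": result.screen_dbp.selected},
            indent=1,
        )
    )
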