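"""Agreement metrics and clinical grading for blood-pressure estimators.

Implements the error statistics used to validate cuffless devices against
a cuff reference: RMSE, mean absolute difference (MAD) and the sample
standard deviation of the error (STD), per individual and pooled; the AAMI
pass criterion (MAD <= 5 mmHg and STD <= 8 mmHg, bounds inclusive); BHS
letter grading from the fractions of absolute errors within 5/10/15 mmHg;
Pearson correlation; and Bland-Altman limits of agreement.  Differences
follow the predicted-minus-measured sign convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mad",
    "std_err",
    "rmse",
    "pooled_rmse",
    "aami_check",
    "bhs_grade",
    "error_fractions",
    "bland_altman",
    "pearson_r",
    "evaluate_predictions",
]

#: BHS thresholds: grade -> minimum % of absolute errors within 5/10/15 mmHg
_BHS_ROWS = (("A", 60.0, 85.0, 95.0), ("B", 50.0, 75.0, 90.0), ("C", 40.0, 65.0, 85.0))


def _errors(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.size == 0 or y.size != y_hat.size:
        raise ValueError("y and y_hat must be equal-length and non-empty")
    return y_hat - y


def mad(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute difference between prediction and reference, mmHg."""
    return float(np.mean(np.abs(_errors(y, y_hat))))


def std_err(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Sample standard deviation (n-1) of the prediction error, mmHg."""
    e = _errors(y, y_hat)
    if e.size < 2:
        raise ValueError("STD needs at least 2 samples")
    return float(np.std(e, ddof=1))


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    return float(np.sqrt(np.mean(_errors(y, y_hat) ** 2)))


def pooled_rmse(per_group_rmse, per_group_n) -> float:
    """Combine per-group RMSEs: sqrt(sum n_i * RMSE_i^2 / sum n_i)."""
    r = np.asarray(per_group_rmse, float).ravel()
    n = np.asarray(per_group_n, float).ravel()
    if r.size == 0 or r.size != n.size:
        raise ValueError("group RMSE and n lists must be equal-length, non-empty")
    if np.any(n <= 0):
        raise ValueError("group sizes must be positive")
    return float(np.sqrt(np.sum(n * r**2) / np.sum(n)))


def aami_check(mad_value: float, std_value: float) -> bool:
    """AAMI agreement: mean absolute error <= 5 and error SD <= 8 mmHg."""
    if mad_value < 0 or std_value < 0:
        raise ValueError("inputs must be non-negative")
    return mad_value <= 5.0 and std_value <= 8.0


def bhs_grade(p5: float, p10: float, p15: float) -> str:
    """BHS letter grade from cumulative error percentages (inclusive).

    ``p5``, ``p10``, ``p15`` are the percentages of absolute errors within
    5, 10 and 15 mmHg; the highest grade whose three thresholds are all met
    is returned, or ``"D"``.
    """
    if not 0.0 <= p5 <= p10 <= p15 <= 100.0:
        raise ValueError("percentages must be non-decreasing within [0, 100]")
    for grade, q5, q10, q15 in _BHS_ROWS:
        if p5 >= q5 and p10 >= q10 and p15 >= q15:
            return grade
    return "D"


def error_fractions(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, float, float]:
    """Percent of absolute errors <= 5, <= 10 and <= 15 mmHg."""
    a = np.abs(_errors(y, y_hat))
    return tuple(float(100.0 * np.mean(a <= t)) for t in (5.0, 10.0, 15.0))


def bland_altman(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, float, float]:
    """Mean difference (predicted - measured) and 95% limits of agreement."""
    e = _errors(y, y_hat)
    if e.size < 2:
        raise ValueError("Bland-Altman needs at least 2 samples")
    mean_diff = float(np.mean(e))
    sd = float(np.std(e, ddof=1))
    return mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd


def pearson_r(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Product-moment correlation between reference and prediction."""
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.size < 3:
        raise ValueError("correlation needs at least 3 samples")
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        raise ValueError("correlation is undefined for constant input")
    return float(stats.pearsonr(y, y_hat).statistic)


@dataclass(frozen=True)
class EvalReport:
    per_individual: pd.DataFrame
    pooled: dict

    def to_frame(self) -> pd.DataFrame:
        pooled_row = pd.DataFrame([{"individual": "pooled", **self.pooled}])
        return pd.concat([self.per_individual, pooled_row], ignore_index=True)


def evaluate_predictions(frame: pd.DataFrame) -> EvalReport:
    """Per-individual and pooled agreement report.

    ``frame`` needs columns ``individual``, ``y`` (reference, mmHg) and
    ``y_hat`` (prediction, mmHg).  Pooled RMSE combines the per-individual
    values weighted by record count; pooled MAD/STD and the clinical
    criteria are computed on the concatenated errors.
    """
    required = {"individual", "y", "y_hat"}
    if not required.issubset(frame.columns):
        raise ValueError(f"frame must have columns {sorted(required)}")
    rows = []
    for ind, grp in frame.groupby("individual", sort=True):
        y, y_hat = grp["y"].to_numpy(), grp["y_hat"].to_numpy()
        rows.append(
            {
                "individual": ind,
                "n": len(grp),
                "rmse": rmse(y, y_hat),
                "mad": mad(y, y_hat),
                "std": std_err(y, y_hat) if len(grp) > 1 else np.nan,
            }
        )
    per_ind = pd.DataFrame(rows)
    y, y_hat = frame["y"].to_numpy(), frame["y_hat"].to_numpy()
    p5, p10, p15 = error_fractions(y, y_hat)
    mean_diff, loa_low, loa_high = bland_altman(y, y_hat)
    pooled = {
        "n": int(len(frame)),
        "rmse": pooled_rmse(per_ind["rmse"], per_ind["n"]),
        "mad": mad(y, y_hat),
        "std": std_err(y, y_hat),
        "aami_pass": aami_check(mad(y, y_hat), std_err(y, y_hat)),
        "bhs_grade": bhs_grade(p5, p10, p15),
        "p5": p5,
        "p10": p10,
        "p15": p15,
        "pearson_r": pearson_r(y, y_hat) if len(frame) >= 3 else np.nan,
        "bland_altman_mean": mean_diff,
        "bland_altman_low": loa_low,
        "bland_altman_high": loa_high,
    }
    return EvalReport(per_individual=per_ind, pooled=pooled)
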