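"""Beat-wise and record-wise waveform features for blood-pressure models.

Each retained beat yields 22 waveform characteristics: five time intervals
(t_up, t_bf, t_down, t_fb, t_ae), their ratios to the cardiac cycle
(t_upr, t_bfr, t_downr, t_fbr, t_aer), three pulse transit times measured
from the ECG R-peak to the PPG onset/maximum-slope/peak points (PTT_b,
PTT_a, PTT_c), four amplitude ratios of the a/e/f/g landmarks to the
systolic peak (H_ar, H_er, H_fr, H_gr), the systolic and diastolic areas
(S_bf, S_fb), the waveform factor K, the heart rate from the adjacent R-R
interval, and the systolic upstroke slope C_slope.  All amplitudes are
referenced to the beat foot (the PPG value at the onset b), and areas are
trapezoidal integrals of the foot-referenced pulse.

A record's feature vector is the per-feature median across its valid beats
with the subject's BMI and gender appended, 24 components in total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fiducials import FiducialSet
from .synthgen import SubjectProfile

__all__ = [
    "WAVEFORM_FEATURES",
    "FEATURE_NAMES",
    "beat_features",
    "record_features",
]

WAVEFORM_FEATURES: tuple[str, ...] = (
    "t_up", "t_bf", "t_down", "t_fb", "t_ae",
    "t_upr", "t_bfr", "t_downr", "t_fbr", "t_aer",
    "PTT_b", "PTT_a", "PTT_c",
    "H_ar", "H_er", "H_fr", "H_gr",
    "S_bf", "S_fb", "K", "HR", "C_slope",
)

#: full per-record feature order: 22 waveform features + BMI + gender
FEATURE_NAMES: tuple[str, ...] = WAVEFORM_FEATURES + ("BMI", "gender")


def beat_features(
    fids: FiducialSet,
    ppg: np.ndarray,
    fs: float,
    *,
    k_variant: str = "standard",
) -> pd.DataFrame:
    """Per-beat feature table; one row per beat with a complete next onset.

    ``k_variant`` selects the waveform-factor definition: ``"standard"``
    computes (S_m - H_b)/(H_c - H_b) — the mean pulse height over the peak
    height, the conventional shape factor — while ``"peak_referenced"``
    computes (S_m - H_c)/(H_c - H_b).  The chosen variant is recorded in
    ``DataFrame.attrs['k_variant']``.
    """
    if k_variant not in ("standard", "peak_referenced"):
        raise ValueError(f"unknown K variant {k_variant!r}")
    x = np.asarray(ppg, float)
    rows = []
    beats = fids.beats
    for k in range(len(beats) - 1):
        cur, nxt = beats[k], beats[k + 1]
        t = lambda i: i / fs  # noqa: E731
        T = t(nxt.b - cur.b)
        rr = t(nxt.r - cur.r)
        if T <= 0 or rr <= 0:
            continue
        foot = x[cur.b]
        h = lambda i: x[i] - foot  # noqa: E731  foot-referenced amplitude
        H_c = h(cur.c)
        if H_c <= 0:
            continue
        seg_bf = x[cur.b : cur.f + 1] - foot
        seg_fb = x[cur.f : nxt.b + 1] - foot
        s_bf = float(np.trapezoid(seg_bf, dx=1.0 / fs))
        s_fb = float(np.trapezoid(seg_fb, dx=1.0 / fs))
        s_m = (s_bf + s_fb) / T  # mean foot-referenced height over the cycle
        if k_variant == "standard":
            kval = s_m / H_c  # (S_m - H_b)/(H_c - H_b) with H_b = 0
        else:
            kval = (s_m - H_c) / H_c
        t_up = t(cur.c - cur.b)
        rows.append(
            {
                "t_up": t_up,
                "t_bf": t(cur.f - cur.b),
                "t_down": t(nxt.b - cur.c),
                "t_fb": t(nxt.b - cur.f),
                "t_ae": t(cur.e - cur.a),
                "t_upr": t(cur.c - cur.b) / T,
                "t_bfr": t(cur.f - cur.b) / T,
                "t_downr": t(nxt.b - cur.c) / T,
                "t_fbr": t(nxt.b - cur.f) / T,
                "t_aer": t(cur.e - cur.a) / T,
                "PTT_b": t(cur.b - cur.r),
                "PTT_a": t(cur.a - cur.r),
                "PTT_c": t(cur.c - cur.r),
                "H_ar": h(cur.a) / H_c,
                "H_er": h(cur.e) / H_c,
                "H_fr": h(cur.f) / H_c,
                "H_gr": h(cur.g) / H_c,
                "S_bf": s_bf,
                "S_fb": s_fb,
                "K": kval,
                "HR": 60.0 / rr,
                "C_slope": H_c / t_up,
            }
        )
    frame = pd.DataFrame(rows, columns=list(WAVEFORM_FEATURES))
    frame.attrs["k_variant"] = k_variant
    return frame


def record_features(
    beat_table: pd.DataFrame,
    subject: SubjectProfile,
    *,
    min_beats: int = 3,
) -> pd.Series:
    """Aggregate per-beat features to one record vector (median over beats).

    Raises ``ValueError`` when fewer than ``min_beats`` valid beats remain;
    such records carry too little waveform evidence to represent 20 s of
    monitoring.
    """
    if len(beat_table) < min_beats:
        raise ValueError(
            f"record rejected: only {len(beat_table)} valid beats "
            f"(minimum {min_beats})"
        )
    vec = beat_table[list(WAVEFORM_FEATURES)].median()
    vec["BMI"] = subject.bmi
    vec["gender"] = float(subject.gender)
    return vec.reindex(list(FEATURE_NAMES))
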