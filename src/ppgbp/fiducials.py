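"""R-peak and PPG fiducial-point detection.

Six landmarks are located on every pulse: the onset ``b`` (foot), the point
of maximum ascending slope ``a``, the systolic peak ``c``, the point of
minimum descending slope ``e``, the dicrotic notch ``f`` and the dicrotic
peak ``g``.  The ECG contributes only R-peak timing, which anchors the
pulse-transit-time features and the beat segmentation.

Detection is deliberately simple and deterministic: R-peaks come from an
adaptive-threshold peak search on the (denoised) ECG; PPG landmarks are
derivative extrema and local extrema inside the beat window between
consecutive R-peaks.  Beats missing any landmark are dropped and counted
rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = ["FiducialSet", "detect_r_peaks", "detect_ppg_fiducials"]

#: physiological R-to-onset pairing window, seconds
_PAIR_MIN_S = 0.05
_PAIR_MAX_S = 0.60


@dataclass(frozen=True)
class BeatFiducials:
    """Sample indices of one beat's landmarks (R from ECG, b..g from PPG)."""

    r: int
    b: int
    a: int
    c: int
    e: int
    f: int
    g: int

    def __post_init__(self) -> None:
        seq = (self.r, self.b, self.a, self.c, self.e, self.f, self.g)
        strict = seq[:5]
        if not all(x < y for x, y in zip(strict, strict[1:])):
            raise ValueError("fiducials must satisfy R < b < a < c < e")
        if not self.e <= self.f <= self.g:
            raise ValueError("fiducials must satisfy e <= f <= g")


@dataclass(frozen=True)
class FiducialSet:
    beats: tuple[BeatFiducials, ...]
    fs: float
    n_dropped: int = 0
    drop_reasons: tuple[str, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.beats)

    def arrays(self) -> dict[str, np.ndarray]:
        """Landmark indices as named arrays, one entry per retained beat."""
        return {
            name: np.array([getattr(b, name) for b in self.beats])
            for name in ("r", "b", "a", "c", "e", "f", "g")
        }


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-peak sample indices on a (denoised) single-lead ECG.

    Uses an amplitude threshold halfway between the median and the maximum
    of the signal with a refractory distance of 60/200 bpm.  Returns an
    empty array (with a warning) when no plausible peak exists.
    """
    x = np.asarray(ecg, float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if x.size < 2 * fs:
        raise ValueError("record must be at least 2 s long")
    spread = float(np.max(x) - np.median(x))
    if spread <= 0:
        warnings.warn("flat ECG: no R-peaks found", stacklevel=2)
        return np.array([], dtype=int)
    height = np.median(x) + 0.5 * spread
    distance = int(round(fs * 60.0 / 200.0))
    peaks, _ = find_peaks(x, height=height, distance=distance)
    if peaks.size == 0:
        warnings.warn("no R-peaks found", stacklevel=2)
    return peaks.astype(int)


def _first_local_min(x: np.ndarray, start: int, stop: int) -> int | None:
    for i in range(max(start, 1), min(stop, x.size - 1)):
        if x[i] <= x[i - 1] and x[i] < x[i + 1]:
            return i
    return None


def _first_local_max(x: np.ndarray, start: int, stop: int) -> int | None:
    for i in range(max(start, 1), min(stop, x.size - 1)):
        if x[i] >= x[i - 1] and x[i] > x[i + 1]:
            return i
    return None


def detect_ppg_fiducials(
    ppg: np.ndarray, r_peaks: np.ndarray, fs: float
) -> FiducialSet:
    """Locate b/a/c/e/f/g on every beat delimited by consecutive R-peaks.

    The last R-peak opens an incomplete beat and is skipped.  Beats where a
    landmark cannot be found, or where the landmark ordering is violated,
    are dropped with a recorded reason.
    """
    x = np.asarray(ppg, float)
    r = np.asarray(r_peaks, int)
    if r.size < 1:
        raise ValueError("at least one R-peak is required")
    deriv = np.gradient(x)

    beats: list[BeatFiducials] = []
    reasons: list[str] = []
    pair_lo = int(round(_PAIR_MIN_S * fs))
    pair_hi = int(round(_PAIR_MAX_S * fs))

    for k in range(len(r) - 1):
        r0, r1 = int(r[k]), int(r[k + 1])
        if r1 >= x.size:
            reasons.append(f"beat {k}: window exceeds record")
            continue
        # systolic peak: maximum of the beat window after the pairing delay
        w0 = min(r0 + pair_lo, r1 - 1)
        c = w0 + int(np.argmax(x[w0:r1]))
        # onset: minimum between the R-peak and the systolic peak; the last
        # minimal sample wins so a flat diastolic run ends at the true foot
        if c > w0:
            seg = x[w0:c]
            b = w0 + int(seg.size - 1 - np.argmin(seg[::-1]))
        else:
            b = w0
        if not pair_lo <= b - r0 <= pair_hi:
            reasons.append(f"beat {k}: onset outside pairing window")
            continue
        if c <= b + 1:
            reasons.append(f"beat {k}: no systolic upstroke")
            continue
        a = b + int(np.argmax(deriv[b : c + 1]))
        # descending limb: search up to the next onset estimate (next R + lag)
        limit = min(r1 + (b - r0), x.size - 1)
        if limit <= c + 1:
            reasons.append(f"beat {k}: descending limb truncated")
            continue
        e = c + 1 + int(np.argmin(deriv[c + 1 : limit]))
        f = _first_local_min(x, e, limit)
        if f is None:
            reasons.append(f"beat {k}: no dicrotic notch")
            continue
        g = _first_local_max(x, f + 1, limit)
        if g is None:
            reasons.append(f"beat {k}: no dicrotic peak")
            continue
        try:
            beats.append(BeatFiducials(r=r0, b=b, a=a, c=c, e=e, f=f, g=g))
        except ValueError as err:
            reasons.append(f"beat {k}: {err}")

    if not beats and len(r) > 1:
        raise ValueError(
            "no complete beat found; reasons: " + "; ".join(reasons[:5])
        )
    return FiducialSet(
        beats=tuple(beats),
        fs=fs,
        n_dropped=len(reasons),
        drop_reasons=tuple(reasons),
    )
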