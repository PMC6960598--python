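"""Signal conditioning for ECG and PPG channels.

Both channels are denoised with a wavelet-packet scheme: the signal is
expanded into a depth-3 packet tree, the best basis is selected by
minimizing a SURE-entropy cost, and the coefficients of the selected nodes
are soft-thresholded with the universal threshold sigma*sqrt(2 ln N), where
sigma is the robust (median-absolute-deviation) noise estimate taken from
the finest-scale detail coefficients.  The PPG channel is additionally
detrended by subtracting a natural cubic spline anchored at the pulse
onsets, which removes respiratory/vasomotor baseline wander without
touching beat-relative amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

__all__ = ["DenoiseConfig", "wp_denoise", "baseline_correct"]


@dataclass(frozen=True)
class DenoiseConfig:
    wavelet: str = "coif5"
    levels: int = 3
    cost_function: str = "sure"
    threshold_rule: str = "universal_soft"
    spline_anchor: str = "pulse_onsets"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.cost_function != "sure":
            raise ValueError("only the SURE-entropy cost is supported")
        if self.threshold_rule not in ("universal_soft",):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")


def _sure_cost(coeffs: np.ndarray) -> float:
    """SURE-entropy cost of one coefficient block (lower = more compact)."""
    n = coeffs.size
    if n == 0:
        return 0.0
    t2 = 2.0 * np.log(max(n, 2))
    x2 = coeffs.astype(float) ** 2
    return float(n - np.count_nonzero(x2 <= t2) + np.sum(np.minimum(x2, t2)))


def _best_basis(wp: pywt.WaveletPacket, levels: int) -> list[str]:
    """Coifman-Wickerhauser best-basis paths, ties resolved to the parent."""
    cost: dict[str, float] = {}
    keep: dict[str, bool] = {}
    for level in range(levels, 0, -1):
        for node in wp.get_level(level, order="natural"):
            c = _sure_cost(np.asarray(node.data))
            if level == levels:
                cost[node.path] = c
                keep[node.path] = True
            else:
                child_cost = cost[node.path + "a"] + cost[node.path + "d"]
                if c <= child_cost:
                    cost[node.path] = c
                    keep[node.path] = True
                    keep[node.path + "a"] = False
                    keep[node.path + "d"] = False
                else:
                    cost[node.path] = child_cost
                    keep[node.path] = False

    selected: list[str] = []

    def collect(path: str) -> None:
        if keep.get(path, False):
            selected.append(path)
        else:
            collect(path + "a")
            collect(path + "d")

    collect("a")
    collect("d")
    return selected


def wp_denoise(signal: np.ndarray, cfg: DenoiseConfig | None = None) -> np.ndarray:
    """Wavelet-packet denoise ``signal``; output has the input's length."""
    cfg = cfg or DenoiseConfig()
    x = np.asarray(signal, float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if np.any(~np.isfinite(x)):
        raise ValueError("signal contains NaN or infinite samples")
    if x.size < 2**cfg.levels:
        raise ValueError("signal too short for the requested decomposition depth")

    # robust noise scale from the finest detail coefficients
    _, detail = pywt.dwt(x, cfg.wavelet)
    sigma = float(np.median(np.abs(detail - np.median(detail)))) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(x.size))

    wp = pywt.WaveletPacket(x, cfg.wavelet, mode="symmetric", maxlevel=cfg.levels)
    basis = _best_basis(wp, cfg.levels)

    out = pywt.WaveletPacket(
        None, cfg.wavelet, mode="symmetric", maxlevel=cfg.levels
    )
    for path in basis:
        data = np.asarray(wp[path].data, float)
        if thr > 0 and path != "a" * len(path):
            # approximation chain carries the trend and is left untouched
            data = pywt.threshold(data, thr, mode="soft")
        out[path] = data
    rec = out.reconstruct(update=False)
    return np.asarray(rec[: x.size], float)


def baseline_correct(ppg: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Subtract a natural cubic spline through ``(anchor, ppg[anchor])``.

    Anchors are typically the detected pulse onsets; the corrected signal is
    zero at every anchor.
    """
    x = np.asarray(ppg, float)
    idx = np.asarray(anchors, int)
    if idx.size < 4:
        raise ValueError("baseline correction needs at least 4 anchor points")
    if np.any(np.diff(idx) <= 0):
        raise ValueError("anchors must be strictly increasing")
    if idx[0] < 0 or idx[-1] >= x.size:
        raise ValueError("anchors out of bounds")
    spline = CubicSpline(idx, x[idx], bc_type="natural")
    return x - spline(np.arange(x.size))
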