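"""Signal conditioning for accelerometer/gyroscope channels.

Movement-onset gating, DC (gravity) removal, drift removal, resultant
("total") channels, and angular acceleration derived from gyroscope rates.
Waist-worn accelerometers pick up gravity, so the spectrum of a raw channel
is dominated by a DC component; all smoothness computations therefore run
on mean-subtracted, drift-corrected signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import OnsetError

__all__ = [
    "PreprocessConfig",
    "detect_onset",
    "remove_dc",
    "remove_drift",
    "resultant_total",
    "angular_acceleration",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Movement-onset and drift-removal parameters.

    A channel is considered to contain movement from the first 10-frame
    moving window whose mean deviation from the initial-noise baseline
    exceeds three times the SD of the first 100 frames; ``sd_floor`` guards
    the degenerate zero-noise case.
    """

    noise_window: int = 100
    moving_window: int = 10
    threshold_k: float = 3.0
    sd_floor: float = 1e-6
    drift_method: str = "linear-detrend"  # or "moving-mean"
    drift_window_s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.noise_window >= self.moving_window >= 1):
            raise ValueError("need noise_window >= moving_window >= 1")
        if self.threshold_k <= 0 or self.sd_floor <= 0:
            raise ValueError("threshold_k and sd_floor must be positive")
        if self.drift_method not in ("linear-detrend", "moving-mean"):
            raise ValueError(f"unknown drift_method {self.drift_method!r}")


def detect_onset(series: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> int:
    """First index at which movement emerges from the initial noise.

    Returns the start index ``i`` of the first ``moving_window``-frame
    window whose mean absolute deviation from the noise-window mean exceeds
    ``threshold_k`` times the noise SD (floored at ``sd_floor``).  The
    deviation is taken from the baseline mean, not zero, so a gravity
    offset cannot mask onset.  Data before ``i`` are excluded downstream.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(x) <= cfg.noise_window + cfg.moving_window:
        raise ValueError(
            f"series of {len(x)} samples is too short for onset detection "
            f"(need > {cfg.noise_window + cfg.moving_window})"
        )
    baseline = x[: cfg.noise_window].mean()
    sd = max(x[: cfg.noise_window].std(), cfg.sd_floor)
    dev = np.abs(x - baseline)
    win_mean = np.convolve(dev, np.ones(cfg.moving_window) / cfg.moving_window, "valid")
    hits = np.nonzero(win_mean[cfg.noise_window :] > cfg.threshold_k * sd)[0]
    if len(hits) == 0:
        raise OnsetError(
            "no moving window exceeded the onset threshold "
            f"({cfg.threshold_k} x noise SD)"
        )
    return int(hits[0]) + cfg.noise_window


def remove_dc(series: np.ndarray) -> np.ndarray:
    """Subtract the mean (removes the gravity/DC spectral component)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot remove DC from an empty series")
    return x - x.mean()


def remove_drift(
    series: np.ndarray, cfg: PreprocessConfig = PreprocessConfig(), sample_rate: float = 100.0
) -> np.ndarray:
    """Remove slow drift (trend below ~0.25 Hz) and the mean.

    ``linear-detrend`` removes the least-squares line; ``moving-mean``
    subtracts a running mean over ``drift_window_s`` seconds.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot remove drift from an empty series")
    if cfg.drift_method == "linear-detrend":
        out = sps.detrend(x, type="linear") if x.size > 1 else x - x
    else:
        win = max(1, int(round(cfg.drift_window_s * sample_rate)))
        out = x - uniform_filter1d(x, size=win, mode="nearest")
    return remove_dc(out)


def resultant_total(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of three axes, mean-subtracted.

    The mean subtraction removes the static gravity magnitude from the
    resultant, leaving the dynamic "total" channel analysed for smoothness.
    """
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("resultant_total requires three equal-length channels")
    norm = np.sqrt(x * x + y * y + z * z)
    return remove_dc(norm)


def angular_acceleration(gyro_rate: np.ndarray, sample_rate: float) -> np.ndarray:
    """Differentiate a gyroscope rate channel (°/s) to angular acceleration (°/s²).

    Central finite differences in the interior, one-sided at the endpoints;
    length is preserved.
    """
    r = np.asarray(gyro_rate, dtype=float)
    if r.size < 3:
        raise ValueError("angular_acceleration needs at least 3 samples")
    return np.gradient(r, 1.0 / sample_rate)
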