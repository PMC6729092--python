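"""Spectral arc length (SPARC) smoothness and the freeze-of-gait frequency ratio.

SPARC is the negative arc length of the normalized power spectral density
of a movement signal over a fixed band (0–10 Hz here), with the frequency
axis rescaled to unit length::

    SPARC = - sum_i sqrt( (dw_i / (f_high - f_low))**2
                          + (normPSD_{i+1} - normPSD_i)**2 )

A perfectly flat unit spectrum has arc length exactly 1, so SPARC is
bounded above by -1; every additional spectral peak lengthens the curve
and pushes SPARC further negative — smoother movement concentrates power
in fewer frequencies and yields SPARC closer to -1.

The freeze index FR is the squared band power in the 3–8 Hz "freeze" band
divided by the squared band power in the 0.5–3 Hz "locomotor" band;
values near 0 indicate healthy gait, ~0.3 parkinsonian gait without
freezing, and ~2 freezing episodes.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .errors import SpectrumError
from .io import IMURecording
from .preprocessing import (
    angular_acceleration,
    remove_dc,
    resultant_total,
)
from .segmentation import PHASES, SegmentedTUG

__all__ = [
    "CHANNELS",
    "ALL_PHASES",
    "SmoothnessConfig",
    "SpectralProfile",
    "FreezeBands",
    "SmoothnessResult",
    "tile_segment",
    "normalized_psd",
    "sparc",
    "sparc_of_segment",
    "band_power",
    "frequency_ratio",
    "analyze_recording",
    "average_trials",
]

CHANNELS = (
    "AccL_V",
    "AccL_ML",
    "AccL_AP",
    "AccL_total",
    "AccA_V",
    "AccA_ML",
    "AccA_AP",
    "AccA_total",
)
ALL_PHASES = (*PHASES, "full")


@dataclass(frozen=True)
class SmoothnessConfig:
    """Band limits, tiling factors and zero-padding for SPARC.

    Short TUG phases carry few gait cycles, so each phase segment is tiled
    end-to-end 4x (2x for the full test) before the periodogram to sharpen
    its dominant frequencies; the FFT is then zero padded to 4x the next
    power of two for a dense spectral grid.
    """

    f_low: float = 0.0
    f_high: float = 10.0
    tile_factor_phase: int = 4
    tile_factor_full: int = 2
    zero_pad: int | str = "pow2x4"
    psd_estimator: str = "periodogram"

    def __post_init__(self) -> None:
        if not 0 <= self.f_low < self.f_high:
            raise ValueError("need 0 <= f_low < f_high")
        if self.tile_factor_phase < 1 or self.tile_factor_full < 1:
            raise ValueError("tile factors must be >= 1")
        if self.psd_estimator != "periodogram":
            raise ValueError(f"unknown psd_estimator {self.psd_estimator!r}")

    def nfft(self, n: int) -> int:
        if isinstance(self.zero_pad, int):
            return max(self.zero_pad, n)
        return 4 * int(2 ** np.ceil(np.log2(n)))


@dataclass(frozen=True)
class FreezeBands:
    """Freeze (3–8 Hz) and locomotor (0.5–3 Hz) bands.

    The shared 3 Hz edge belongs to the locomotor band: the bands are
    [0.5, 3] and (3, 8].
    """

    freeze: tuple[float, float] = (3.0, 8.0)
    locomotor: tuple[float, float] = (0.5, 3.0)


@dataclass
class SpectralProfile:
    """Max-normalized PSD restricted to the SPARC integration band."""

    freq: np.ndarray
    norm_psd: np.ndarray
    f_low: float = 0.0
    f_high: float = 10.0

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.norm_psd = np.asarray(self.norm_psd, dtype=float)
        if self.freq.shape != self.norm_psd.shape or self.freq.ndim != 1:
            raise ValueError("freq and norm_psd must be equal-length 1-D arrays")
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("freq must be strictly increasing")
        if self.freq[0] < self.f_low - 1e-12 or self.freq[-1] > self.f_high + 1e-12:
            raise ValueError("freq must lie within [f_low, f_high]")
        if np.any(self.norm_psd < -1e-12) or np.any(self.norm_psd > 1 + 1e-9):
            raise ValueError("norm_psd values must lie in [0, 1]")
        if abs(self.norm_psd.max() - 1.0) > 1e-9:
            raise ValueError("norm_psd must be normalized to max 1")

    @property
    def resolution(self) -> float:
        return float(np.median(np.diff(self.freq)))


def tile_segment(series: np.ndarray, factor: int) -> np.ndarray:
    """Repeat a segment end-to-end ``factor`` times after DC removal.

    DC removal avoids step discontinuities at the tile junctions.
    """
    if factor < 1:
        raise ValueError("tile factor must be >= 1")
    return np.tile(remove_dc(series), int(factor))


def normalized_psd(
    series: np.ndarray,
    sample_rate: float,
    cfg: SmoothnessConfig = SmoothnessConfig(),
) -> SpectralProfile:
    """Periodogram of a (mean-subtracted, zero-padded) segment on [f_low, f_high].

    The DC bin is zeroed (the mean is already removed) and the band is
    normalized to unit maximum, as the SPARC arc-length geometry requires.
    """
    x = remove_dc(np.asarray(series, dtype=float))
    if x.size < 8:
        raise ValueError("need at least 8 samples for a spectral estimate")
    freq, psd = periodogram(
        x, fs=sample_rate, window="boxcar", nfft=cfg.nfft(x.size), detrend=False
    )
    mask = (freq >= cfg.f_low) & (freq <= cfg.f_high)
    freq, psd = freq[mask], psd[mask]
    psd[freq == 0.0] = 0.0
    peak = psd.max()
    if peak <= 0:
        raise SpectrumError("spectrum is identically zero in the analysis band")
    return SpectralProfile(freq, psd / peak, cfg.f_low, cfg.f_high)


def sparc(profile: SpectralProfile) -> float:
    """Discrete arc length of the normalized spectrum (negated).

    The frequency axis is scaled by 1/(f_high - f_low) so a flat unit
    spectrum spanning the band gives exactly -1.
    """
    if profile.freq.size < 2:
        raise ValueError("SPARC needs at least 2 spectral bins")
    scale = profile.f_high - profile.f_low
    dw = np.diff(profile.freq) / scale
    dp = np.diff(profile.norm_psd)
    return float(-np.sum(np.sqrt(dw * dw + dp * dp)))


def sparc_of_segment(
    series: np.ndarray,
    sample_rate: float,
    phase_kind: str = "phase",
    cfg: SmoothnessConfig = SmoothnessConfig(),
) -> float:
    """Tile a TUG segment (4x for phases, 2x for the full test) and score it."""
    if phase_kind not in ("phase", "full"):
        raise ValueError("phase_kind must be 'phase' or 'full'")
    factor = cfg.tile_factor_phase if phase_kind == "phase" else cfg.tile_factor_full
    tiled = tile_segment(series, factor)
    return sparc(normalized_psd(tiled, sample_rate, cfg))


def band_power(
    freq: np.ndarray, psd: np.ndarray, band: tuple[float, float], closed_low: bool = True
) -> float:
    """Integrated PSD (trapezoid) over the bins inside ``band``.

    ``closed_low`` controls whether the lower edge is included — the 3 Hz
    edge shared by the freeze and locomotor bands belongs to the locomotor
    band only.
    """
    lo, hi = band
    mask = (freq > lo) & (freq <= hi) if not closed_low else (freq >= lo) & (freq <= hi)
    if mask.sum() < 2:
        raise SpectrumError(
            f"fewer than 2 spectral bins in band [{lo}, {hi}] Hz; "
            "segment too short for band-power estimation"
        )
    return float(np.trapezoid(psd[mask], freq[mask]))


def frequency_ratio(
    series: np.ndarray,
    sample_rate: float,
    bands: FreezeBands = FreezeBands(),
    cfg: SmoothnessConfig = SmoothnessConfig(),
) -> float:
    """Freeze index: squared freeze-band power over squared locomotor power."""
    x = np.asarray(series, dtype=float)
    if x.size < 2 * sample_rate:
        raise ValueError(
            "frequency_ratio needs at least 2 s of signal for sub-Hz band resolution"
        )
    x = remove_dc(x)
    freq, psd = periodogram(
        x, fs=sample_rate, window="boxcar", nfft=cfg.nfft(x.size), detrend=False
    )
    p_freeze = band_power(freq, psd, bands.freeze, closed_low=False)
    p_loco = band_power(freq, psd, bands.locomotor, closed_low=True)
    return frequency_ratio_from_band_powers(p_freeze, p_loco)


def frequency_ratio_from_band_powers(p_freeze: float, p_locomotor: float) -> float:
    """FR = P_freeze² / P_locomotor²; errors on zero locomotor power."""
    if p_locomotor <= 0:
        raise SpectrumError(
            "locomotor-band (0.5–3 Hz) power is zero; frequency ratio undefined"
        )
    return float((p_freeze / p_locomotor) ** 2)


@dataclass
class SmoothnessResult:
    """SPARC per channel x phase (one trial, or the mean of three).

    ``sparc`` is a DataFrame indexed by channel with one column per phase
    (five phases plus "full"); ``fr`` is the freeze index computed on the
    anteroposterior linear acceleration over the full test.
    """

    sparc: pd.DataFrame
    fr: float
    subject_id: str = "unknown"
    group: str = "control"
    trial_index: int | str = 1

    def to_tidy(self) -> pd.DataFrame:
        tidy = (
            self.sparc.rename_axis("channel")
            .reset_index()
            .melt(id_vars="channel", var_name="phase", value_name="sparc")
        )
        tidy.insert(0, "subject_id", self.subject_id)
        tidy.insert(1, "group", self.group)
        tidy.insert(2, "trial", self.trial_index)
        tidy["fr"] = self.fr
        return tidy


def _channel_series(rec: IMURecording) -> dict[str, np.ndarray]:
    """The eight analysis channels of a recording.

    Angular acceleration axes follow the rotation axes: yaw rotates about
    the vertical axis (V), pitch about the mediolateral axis (ML), roll
    about the anteroposterior axis (AP).
    """
    fs = rec.sample_rate
    acc_v, acc_ml, acc_ap = rec.acc.T
    ang = {ax: angular_acceleration(rec.gyro_axis(ax), fs) for ax in ("yaw", "pitch", "roll")}
    return {
        "AccL_V": acc_v,
        "AccL_ML": acc_ml,
        "AccL_AP": acc_ap,
        "AccL_total": resultant_total(acc_v, acc_ml, acc_ap),
        "AccA_V": ang["yaw"],
        "AccA_ML": ang["pitch"],
        "AccA_AP": ang["roll"],
        "AccA_total": resultant_total(ang["yaw"], ang["pitch"], ang["roll"]),
    }


def analyze_recording(
    rec: IMURecording,
    seg: SegmentedTUG,
    cfg: SmoothnessConfig = SmoothnessConfig(),
) -> SmoothnessResult:
    """SPARC for all 8 channels x 6 phases, plus FR on Acc L AP (full test)."""
    series = _channel_series(rec)
    table = pd.DataFrame(index=list(CHANNELS), columns=list(ALL_PHASES), dtype=float)
    for ch, x in series.items():
        for phase in ALL_PHASES:
            s, e = seg.full if phase == "full" else seg.intervals[phase]
            kind = "full" if phase == "full" else "phase"
            try:
                table.loc[ch, phase] = sparc_of_segment(x[s:e], rec.sample_rate, kind, cfg)
            except (ValueError, SpectrumError) as exc:
                raise type(exc)(f"channel {ch}, phase {phase}: {exc}") from exc
    fs_full = slice(*seg.full)
    fr = frequency_ratio(series["AccL_AP"][fs_full], rec.sample_rate, cfg=cfg)
    return SmoothnessResult(
        sparc=table,
        fr=fr,
        subject_id=rec.subject_id,
        group=rec.group,
        trial_index=rec.trial_index,
    )


def average_trials(results: list[SmoothnessResult]) -> SmoothnessResult:
    """Arithmetic mean across a subject's trials, per channel x phase."""
    if not results:
        raise ValueError("no results to average")
    subjects = {r.subject_id for r in results}
    if len(subjects) > 1:
        raise ValueError(f"cannot average across subjects: {sorted(subjects)}")
    mean_sparc = sum(r.sparc for r in results) / len(results)
    return SmoothnessResult(
        sparc=mean_sparc,
        fr=float(np.mean([r.fr for r in results])),
        subject_id=results[0].subject_id,
        group=results[0].group,
        trial_index=f"mean of {len(results)}",
    )
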