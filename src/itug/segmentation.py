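"""TUG phase identification from integrated yaw and pitch angles.

The Timed-Up-and-Go test decomposes into five contiguous phases:
sit-to-stand, walk 1 (3 m out), turn (around the cone), walk 2 (3 m back),
and a combined turn-and-stand-to-sit.  Turns are located on the yaw axis
(net rotation close to 180°), postural transitions on the pitch axis
(trunk-lean excursions).  Indices are 0-based and intervals half-open
``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import SegmentationError
from .io import IMURecording
from .preprocessing import PreprocessConfig, detect_onset, remove_drift

__all__ = [
    "PHASES",
    "SegmentationConfig",
    "SegmentedTUG",
    "integrate_rate",
    "detect_turns",
    "detect_postural_transitions",
    "segment_tug",
]

PHASES = ("sit_to_stand", "walk1", "turn", "walk2", "turn_stand_to_sit")


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds for turn and postural-transition detection.

    Defaults were chosen to recover ground-truth boundaries of the
    synthetic generator and are exposed for tuning on real data.
    """

    turn_rate_threshold: float = 30.0   # °/s on the smoothed yaw rate
    turn_net_angle_min: float = 120.0   # degrees of net rotation per turn
    pitch_peak_prominence: float = 15.0  # degrees
    smoothing_s: float = 0.15            # moving-average window, seconds
    boundary_frac: float = 0.05          # excursion edge, fraction of peak

    def __post_init__(self) -> None:
        for name in ("turn_rate_threshold", "turn_net_angle_min",
                     "pitch_peak_prominence", "smoothing_s", "boundary_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SegmentedTUG:
    """Ordered, contiguous phase intervals covering one TUG trial.

    ``intervals`` maps each phase name to a half-open sample range; the
    full interval spans movement onset to the end of stand-to-sit.
    ``turn2_split`` optionally records where the internal second turn ends
    and pure stand-to-sit begins, for diagnostics.
    """

    intervals: dict[str, tuple[int, int]]
    sample_rate: float
    turn2_split: int | None = None

    def __post_init__(self) -> None:
        missing = [p for p in PHASES if p not in self.intervals]
        if missing:
            raise SegmentationError(f"missing phase interval(s): {missing}")
        prev_end = None
        for p in PHASES:
            s, e = self.intervals[p]
            if e < s:
                raise SegmentationError(f"{p}: end {e} before start {s}")
            if prev_end is not None and s != prev_end:
                raise SegmentationError(
                    f"{p} starts at {s}, expected previous phase end {prev_end}"
                )
            prev_end = e

    @property
    def full(self) -> tuple[int, int]:
        return (self.intervals[PHASES[0]][0], self.intervals[PHASES[-1]][1])

    def duration(self, phase: str) -> float:
        if phase == "full":
            s, e = self.full
        else:
            s, e = self.intervals[phase]
        return (e - s) / self.sample_rate

    @property
    def durations(self) -> dict[str, float]:
        d = {p: self.duration(p) for p in PHASES}
        d["full"] = self.duration("full")
        return d

    @property
    def total_duration(self) -> float:
        return self.duration("full")

    def shifted(self, n: int) -> "SegmentedTUG":
        return SegmentedTUG(
            intervals={p: (s + n, e + n) for p, (s, e) in self.intervals.items()},
            sample_rate=self.sample_rate,
            turn2_split=None if self.turn2_split is None else self.turn2_split + n,
        )

    def to_frame(self, recording_id: str = "") -> pd.DataFrame:
        rows = []
        for p in (*PHASES, "full"):
            s, e = self.full if p == "full" else self.intervals[p]
            rows.append(
                {
                    "recording_id": recording_id,
                    "phase": p,
                    "start_sample": s,
                    "end_sample": e,
                    "duration_s": (e - s) / self.sample_rate,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path, recording_id: str = "") -> None:
        self.to_frame(recording_id).to_csv(path, sep="\t", index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_rate": self.sample_rate,
                "intervals": {p: list(v) for p, v in self.intervals.items()},
                "full": list(self.full),
                "durations": self.durations,
            },
            indent=2,
        )


def integrate_rate(
    rate: np.ndarray,
    sample_rate: float,
    drift_method: str | None = None,
    pcfg: PreprocessConfig | None = None,
) -> np.ndarray:
    """Cumulative trapezoidal integral of a rate channel, starting at 0°.

    By default no drift correction is applied (the integral of a constant
    rate is a genuine ramp, not drift); pass ``drift_method`` to apply
    :func:`itug.preprocessing.remove_drift` to the integrated angle.
    """
    r = np.asarray(rate, dtype=float)
    if r.size == 0:
        raise ValueError("cannot integrate an empty rate series")
    angle = cumulative_trapezoid(r, dx=1.0 / sample_rate, initial=0.0)
    if drift_method is not None:
        cfg = pcfg or PreprocessConfig()
        cfg = PreprocessConfig(
            noise_window=cfg.noise_window,
            moving_window=cfg.moving_window,
            threshold_k=cfg.threshold_k,
            sd_floor=cfg.sd_floor,
            drift_method=drift_method,
            drift_window_s=cfg.drift_window_s,
        )
        angle = remove_drift(angle, cfg, sample_rate)
    return angle


def _smooth(x: np.ndarray, sample_rate: float, smoothing_s: float) -> np.ndarray:
    win = max(1, int(round(smoothing_s * sample_rate)))
    return uniform_filter1d(x, size=win, mode="nearest")


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where a boolean mask is true."""
    idx = np.nonzero(np.diff(mask.astype(int)))[0] + 1
    edges = np.concatenate(([0], idx, [len(mask)]))
    return [
        (int(edges[i]), int(edges[i + 1]))
        for i in range(len(edges) - 1)
        if mask[edges[i]]
    ]


def detect_turns(
    yaw_angle: np.ndarray,
    sample_rate: float,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[tuple[int, int]]:
    """Locate the two ~180° turns from the integrated yaw angle.

    Candidate intervals are runs where the smoothed |yaw rate| exceeds
    ``turn_rate_threshold``; an interval qualifies when its net angle
    change is at least ``turn_net_angle_min``.  Returns the two qualifying
    intervals in time order (the mid-test cone turn and the pre-sit turn);
    with more than two candidates the two largest net rotations are kept.
    """
    a = np.asarray(yaw_angle, dtype=float)
    if a.size < 3:
        raise SegmentationError("yaw angle too short for turn detection")
    rate = np.gradient(a, 1.0 / sample_rate)
    rate = _smooth(rate, sample_rate, cfg.smoothing_s)
    runs = _runs_above(np.abs(rate) >= cfg.turn_rate_threshold)
    # merge runs separated by less than one smoothing window
    gap = max(1, int(round(cfg.smoothing_s * sample_rate)))
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    qualifying = [
        (s, e)
        for s, e in merged
        if abs(a[min(e, a.size - 1)] - a[s]) >= cfg.turn_net_angle_min
    ]
    if len(qualifying) < 2:
        found = [
            f"[{s}, {e}) net {a[min(e, a.size - 1)] - a[s]:+.0f}°" for s, e in merged
        ]
        raise SegmentationError(
            f"expected 2 turns (|net angle| >= {cfg.turn_net_angle_min}°), "
            f"found {len(qualifying)}; candidate intervals: {found or 'none'}"
        )
    if len(qualifying) > 2:
        qualifying = sorted(
            qualifying,
            key=lambda iv: abs(a[min(iv[1], a.size - 1)] - a[iv[0]]),
            reverse=True,
        )[:2]
        qualifying.sort()
    return qualifying


def detect_postural_transitions(
    pitch_angle: np.ndarray,
    sample_rate: float,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[tuple[int, int]]:
    """Locate sit-to-stand and stand-to-sit pitch excursions.

    The first and last excursions of |pitch| exceeding
    ``pitch_peak_prominence`` mark the two postural transitions; each
    interval extends outward from the peak until the angle falls below
    ``boundary_frac`` of the peak value.
    """
    a = np.asarray(pitch_angle, dtype=float)
    if a.size < 3:
        raise SegmentationError("pitch angle too short for transition detection")
    mag = np.abs(_smooth(a, sample_rate, cfg.smoothing_s))
    peaks, _ = find_peaks(mag, prominence=cfg.pitch_peak_prominence)
    if len(peaks) < 2:
        raise SegmentationError(
            f"expected 2 pitch excursions with prominence >= "
            f"{cfg.pitch_peak_prominence}°, found {len(peaks)}"
        )
    out: list[tuple[int, int]] = []
    for pk in (peaks[0], peaks[-1]):
        thr = cfg.boundary_frac * mag[pk]
        s = pk
        while s > 0 and mag[s - 1] > thr:
            s -= 1
        e = pk
        while e < a.size - 1 and mag[e + 1] > thr:
            e += 1
        out.append((int(s), int(e) + 1))
    if out[0][1] > out[1][0]:
        raise SegmentationError("pitch excursions overlap; cannot separate transitions")
    return out


def segment_tug(
    rec: IMURecording,
    pcfg: PreprocessConfig = PreprocessConfig(),
    scfg: SegmentationConfig = SegmentationConfig(),
) -> SegmentedTUG:
    """Compose onset, turns and postural transitions into the five phases.

    walk1 spans end of sit-to-stand to the first turn; walk2 spans the
    first turn to the second; the combined fifth phase spans the second
    turn to the end of stand-to-sit (test ends seated, back resting).
    """
    fs = rec.sample_rate
    norm = np.sqrt((rec.acc ** 2).sum(axis=1))
    try:
        onset = detect_onset(norm, pcfg)
    except Exception as exc:
        raise SegmentationError(f"movement onset not found: {exc}") from exc

    yaw = integrate_rate(rec.gyro_axis("yaw"), fs)
    pitch = integrate_rate(rec.gyro_axis("pitch"), fs)
    try:
        turns = detect_turns(yaw, fs, scfg)
    except SegmentationError as exc:
        raise SegmentationError(f"turn phase: {exc}") from exc
    try:
        transitions = detect_postural_transitions(pitch, fs, scfg)
    except SegmentationError as exc:
        raise SegmentationError(f"postural transitions: {exc}") from exc

    (t1s, t1e), (t2s, t2e) = turns
    (sts_s, sts_e), (s2s_s, s2s_e) = transitions
    sts_end = max(sts_e, onset + 1)
    bounds = [onset, sts_end, t1s, t1e, t2s, s2s_e]
    if any(b2 < b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise SegmentationError(
            "phase boundaries out of order: onset "
            f"{onset}, sit_to_stand end {sts_end}, turn1 [{t1s},{t1e}), "
            f"turn2 [{t2s},{t2e}), stand_to_sit end {s2s_e}"
        )
    intervals = {
        "sit_to_stand": (onset, sts_end),
        "walk1": (sts_end, t1s),
        "turn": (t1s, t1e),
        "walk2": (t1e, t2s),
        "turn_stand_to_sit": (t2s, s2s_e),
    }
    return SegmentedTUG(intervals=intervals, sample_rate=fs, turn2_split=t2e)
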