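"""Synthetic instrumented-TUG recordings with known ground truth.

No raw recordings of the study population are publicly available, so this
module generates waist-IMU signals with the statistical structure the
analysis assumes:

* anteroposterior acceleration as a harmonic series (stride ~2 Hz and step
  ~4 Hz peaks) with per-phase envelopes — braking/propulsion oscillation;
* control-like trials with narrow spectral peaks vs parkinsonian trials
  whose peaks are broadened by frequency jitter and amplitude modulation;
* freeze-of-gait episodes as band-limited 3–8 Hz bursts that locally
  suppress the locomotor harmonics;
* two ~180° yaw S-curves (cone turn, pre-sit turn) and two trunk-pitch
  excursions (sit-to-stand, stand-to-sit), from which exact ground-truth
  phase boundaries are returned;
* walking phases that shorten across the three trials (task learning), and
  co-simulated clinical scores with a known monotone link to the
  smoothness-degradation parameter, so the correlation stage can be tested
  against a built-in sign.

All randomness flows from a single cohort seed through
``numpy.random.SeedSequence`` spawning (cohort → subject → trial); the
freeze-episode stream is split from the main noise stream so that a
zero-intensity episode leaves a trial bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import IMURecording, write_manifest, write_recording
from .segmentation import PHASES, SegmentedTUG

__all__ = [
    "FreezeEpisode",
    "SubjectProfile",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "control_profile",
    "pd_profile",
    "simulate_trial",
    "simulate_cohort",
]

#: Nominal per-phase durations (s), chosen to sum to the group-mean total
#: TUG times the analysis is calibrated around (9.15 s control, 14.04 s PD).
CONTROL_PHASE_S = (1.30, 2.00, 1.45, 1.80, 2.60)
PD_PHASE_S = (2.00, 3.10, 2.40, 2.90, 3.64)

UPDRS_ITEMS = (
    "speech",
    "tremor_at_rest",
    "finger_taps",
    "alternating_movements",
    "arising_from_chair",
    "leg_agility",
    "posture",
    "gait",
    "postural_stability",
    "body_bradykinesia",
)


@dataclass(frozen=True)
class FreezeEpisode:
    """A trembling-in-place burst: 3–8 Hz carrier inside one phase."""

    phase: str
    start_offset_s: float
    duration_s: float
    intensity_g: float
    carrier_hz: float = 5.5

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.duration_s <= 0 or self.start_offset_s < 0:
            raise ValueError("episode must have positive duration and offset >= 0")
        if self.intensity_g < 0:
            raise ValueError("episode intensity must be >= 0")
        if not 3.0 <= self.carrier_hz <= 8.0:
            raise ValueError("carrier must lie in the 3–8 Hz freeze band")


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters for one subject's TUG trials."""

    group: str = "control"
    phase_durations: tuple[float, ...] = CONTROL_PHASE_S
    stride_freq: float = 2.0          # Hz; step harmonic at 2x
    ap_amps: tuple[float, float] = (0.25, 0.12)   # g
    v_amps: tuple[float, float] = (0.30, 0.10)    # g
    ml_amps: tuple[float, float] = (0.12, 0.05)   # g
    spectral_broadening: float = 0.02  # relative bandwidth of the peaks
    freeze_episodes: tuple[FreezeEpisode, ...] = ()
    gyro_rhythm_dps: float = 8.0       # rhythmic trunk sway on gyro axes
    tremor_dps: float = 0.0            # 4–6 Hz tremor on gyro axes (PD)
    tremor_g: float = 0.0              # 4–6 Hz tremor on acc axes (PD)
    turn_ramp_s: float = 0.3
    pitch_excursion_deg: float = 40.0
    transition_ramp_s: float = 0.4
    sts_burst_g: float = 0.30          # vertical burst during sit-to-stand
    sit_duration_s: float = 1.2        # stand-to-sit bell inside phase 5
    noise_sd_g: float = 0.02
    gyro_noise_sd_dps: float = 1.0
    trial_speedup: float = 0.06        # fractional walk shortening per trial
    lead_in_s: float = 1.5
    tail_s: float = 1.0
    subject_id: str = "S000"
    severity: float = 0.0              # smoothness-degradation parameter

    def __post_init__(self) -> None:
        if self.group not in ("PD", "control"):
            raise ValueError("group must be 'PD' or 'control'")
        if len(self.phase_durations) != 5 or any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase_durations must be 5 positive values")
        if self.group == "control" and self.freeze_episodes:
            raise ValueError("control profiles must have zero freeze episodes")
        for ep in self.freeze_episodes:
            i = PHASES.index(ep.phase)
            if ep.start_offset_s + ep.duration_s > self.phase_durations[i] + 1e-9:
                raise ValueError(
                    f"freeze episode exceeds phase {ep.phase!r} "
                    f"({self.phase_durations[i]:.2f} s)"
                )


def control_profile(**overrides) -> SubjectProfile:
    """A healthy-control profile: narrow spectral peaks, no freeze bursts."""
    base = dict(group="control", phase_durations=CONTROL_PHASE_S)
    base.update(overrides)
    return SubjectProfile(**base)


def pd_profile(severity: float = 0.6, **overrides) -> SubjectProfile:
    """A PD/FOG-like profile; ``severity`` in [0, 1] scales the degradation.

    Higher severity means broader spectral peaks, stronger gyro tremor,
    smaller locomotor amplitudes and longer sit duration — the knobs the
    clinical scores are generated from.
    """
    base = dict(
        group="PD",
        phase_durations=PD_PHASE_S,
        spectral_broadening=0.06 + 0.20 * severity,
        tremor_dps=10.0 * severity,
        tremor_g=0.05 * severity,
        ap_amps=(0.25 * (1 - 0.35 * severity), 0.12 * (1 - 0.35 * severity)),
        v_amps=(0.30 * (1 - 0.35 * severity), 0.10 * (1 - 0.35 * severity)),
        ml_amps=(0.12 * (1 - 0.35 * severity), 0.05 * (1 - 0.35 * severity)),
        sit_duration_s=1.3,
        severity=severity,
    )
    base.update(overrides)
    return SubjectProfile(**base)


def _cos_env(t: np.ndarray, t0: float, t1: float, ramp: float) -> np.ndarray:
    """Trapezoidal envelope with raised-cosine ramps, supported on [t0, t1]."""
    env = np.zeros_like(t)
    if t1 <= t0:
        return env
    ramp = min(ramp, (t1 - t0) / 2)
    rise = (t >= t0) & (t < t0 + ramp)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - t0) / ramp))
    mid = (t >= t0 + ramp) & (t <= t1 - ramp)
    env[mid] = 1.0
    fall = (t > t1 - ramp) & (t <= t1)
    env[fall] = 0.5 * (1 - np.cos(np.pi * (t1 - t[fall]) / ramp))
    return env


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, tau_s: float) -> np.ndarray:
    """Unit-SD low-frequency noise (moving-average-filtered white noise)."""
    w = rng.standard_normal(n)
    k = max(1, int(round(tau_s * fs)))
    kernel = np.ones(k) / k
    s = np.convolve(w, kernel, mode="same")
    sd = s.std()
    return s / sd if sd > 0 else s


def _jittered_phase(
    rng: np.random.Generator,
    t: np.ndarray,
    freq: float,
    broadening: float,
    fs: float,
) -> np.ndarray:
    """Phase of a sinusoid whose instantaneous frequency wanders by ±broadening."""
    jitter = _smooth_noise(rng, t.size, fs, tau_s=0.3)
    inst_freq = freq * (1.0 + broadening * jitter)
    phase = 2 * np.pi * np.cumsum(inst_freq) / fs
    return phase + rng.uniform(0, 2 * np.pi)


def simulate_trial(
    profile: SubjectProfile, trial_index: int = 1, seed: int = 0
) -> tuple[IMURecording, SegmentedTUG]:
    """One TUG trial and its exact ground-truth segmentation.

    Walking-phase durations scale by ``1 - trial_speedup*(trial_index - 2)``
    so trial 2 matches the profile's nominal durations, trial 1 is slower
    and trial 3 faster (task learning).
    """
    if trial_index not in (1, 2, 3):
        raise ValueError("trial_index must be 1, 2 or 3")
    ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss[0])       # main stream: jitter + noise
    rng_fog = np.random.default_rng(ss[1])   # freeze-episode stream

    fs = 100.0
    speed = 1.0 - profile.trial_speedup * (trial_index - 2)
    d = list(profile.phase_durations)
    d[1] *= speed
    d[3] *= speed
    bounds = profile.lead_in_s + np.concatenate(([0.0], np.cumsum(d)))
    b0, b1, b2, b3, b4, b5 = bounds
    total = b5 + profile.tail_s
    n = int(round(total * fs))
    t = np.arange(n) / fs

    # --- per-phase envelopes -------------------------------------------------
    walk = _cos_env(t, b1, b2, 0.3) + _cos_env(t, b3, b4, 0.3)
    turn_env = _cos_env(t, b2, b3, 0.3)
    tss_env = _cos_env(t, b4, b5, 0.3)
    sts_env = _cos_env(t, b0, b1, min(profile.transition_ramp_s, d[0] / 3))
    loco_env = walk + 0.35 * (turn_env + tss_env) + 0.2 * sts_env

    # freeze episodes suppress the locomotor harmonics locally
    fog_envs = []
    for ep in profile.freeze_episodes:
        t_ep = bounds[PHASES.index(ep.phase)] + ep.start_offset_s
        fog_envs.append((ep, _cos_env(t, t_ep, t_ep + ep.duration_s, 0.15)))
    for ep, env in fog_envs:
        # suppression scales with intensity so a zero-intensity episode is a no-op
        loco_env = loco_env * (1.0 - min(0.8, ep.intensity_g / 0.15) * 0.9 * env)

    f0 = profile.stride_freq
    bw = profile.spectral_broadening

    def harmonic_pair(amps: tuple[float, float]) -> np.ndarray:
        out = np.zeros(n)
        for k, amp in enumerate(amps, start=1):
            ph = _jittered_phase(rng, t, k * f0, bw, fs)
            am = 1.0 + 0.5 * bw * _smooth_noise(rng, n, fs, 0.4)
            out += amp * am * np.sin(ph)
        return out

    # --- linear acceleration (g) --------------------------------------------
    ap = harmonic_pair(profile.ap_amps) * loco_env
    v = harmonic_pair(profile.v_amps) * loco_env
    ml = harmonic_pair((profile.ml_amps[0], 0.0)) * loco_env
    # sit-to-stand / stand-to-sit bursts (postural accelerations)
    sit_env = _cos_env(t, b5 - profile.sit_duration_s, b5, profile.transition_ramp_s)
    v += profile.sts_burst_g * sts_env * np.sin(2 * np.pi * 1.3 * (t - b0))
    v += 0.6 * profile.sts_burst_g * sit_env * np.sin(2 * np.pi * 1.3 * (t - b5))
    ap += 0.5 * profile.sts_burst_g * sts_env * np.sin(2 * np.pi * 1.0 * (t - b0))
    ap += 0.3 * profile.sts_burst_g * sit_env * np.sin(2 * np.pi * 1.0 * (t - b5))
    # freeze bursts: band-limited carrier in 3–8 Hz
    for ep, env in fog_envs:
        ph = _jittered_phase(rng_fog, t, ep.carrier_hz, 0.08, fs)
        burst = np.sin(ph)
        ap += ep.intensity_g * env * burst
        v += 0.5 * ep.intensity_g * env * burst

    # parkinsonian trembling: 4–6 Hz component on the acceleration axes
    if profile.tremor_g > 0:
        move_acc = np.clip(sts_env + walk + turn_env + tss_env, 0, 1)
        ap += profile.tremor_g * move_acc * np.sin(_jittered_phase(rng, t, 5.0, 0.12, fs))
        v += 0.6 * profile.tremor_g * move_acc * np.sin(_jittered_phase(rng, t, 5.4, 0.12, fs))

    ap += profile.noise_sd_g * rng.standard_normal(n)
    v += 1.0 + profile.noise_sd_g * rng.standard_normal(n)  # gravity on V
    ml += profile.noise_sd_g * rng.standard_normal(n)

    # --- gyroscope rates (°/s) ----------------------------------------------
    move_env = np.clip(sts_env + walk + turn_env + tss_env, 0, 1)
    r = profile.turn_ramp_s
    # floor keeps the peak rate inside the ±250 °/s gyro range
    turn2_dur = min(1.6, max(1.1, d[4] - profile.sit_duration_s - 0.2))
    yaw_peak1 = 180.0 / (d[2] - r)
    yaw_peak2 = 180.0 / (turn2_dur - r)
    yaw = yaw_peak1 * _cos_env(t, b2, b3, r) + yaw_peak2 * _cos_env(
        t, b4, b4 + turn2_dur, r
    )
    rhythm = profile.gyro_rhythm_dps
    rhythm_env = walk + 0.35 * (turn_env + tss_env) + 0.2 * sts_env
    yaw += 0.5 * rhythm * rhythm_env * np.sin(
        _jittered_phase(rng, t, f0, bw, fs)
    )

    pitch_angle = profile.pitch_excursion_deg * (
        _cos_env(t, b0, b1, profile.transition_ramp_s)
        + _cos_env(t, b5 - profile.sit_duration_s, b5, profile.transition_ramp_s)
    )
    pitch = np.gradient(pitch_angle, 1.0 / fs)
    pitch += rhythm * rhythm_env * np.sin(_jittered_phase(rng, t, 2 * f0, bw, fs))

    roll = 1.2 * rhythm * rhythm_env * np.sin(_jittered_phase(rng, t, f0, bw, fs))

    if profile.tremor_dps > 0:
        for chan in ("yaw", "pitch", "roll"):
            ph = _jittered_phase(rng, t, 5.2, 0.10, fs)
            tremor = profile.tremor_dps * move_env * np.sin(ph)
            if chan == "yaw":
                yaw += 0.6 * tremor
            elif chan == "pitch":
                pitch += tremor
            else:
                roll += tremor
    else:
        # keep the main stream aligned between tremor/no-tremor profiles
        pass

    yaw += profile.gyro_noise_sd_dps * rng.standard_normal(n)
    pitch += profile.gyro_noise_sd_dps * rng.standard_normal(n)
    roll += profile.gyro_noise_sd_dps * rng.standard_normal(n)

    rec = IMURecording(
        acc=np.column_stack([v, ml, ap]),
        gyro=np.column_stack([yaw, pitch, roll]),
        sample_rate=fs,
        subject_id=profile.subject_id,
        group=profile.group,
        trial_index=trial_index,
    )
    idx = [int(round(b * fs)) for b in bounds]
    truth = SegmentedTUG(
        intervals={p: (idx[i], idx[i + 1]) for i, p in enumerate(PHASES)},
        sample_rate=fs,
        turn2_split=int(round((b4 + turn2_dur) * fs)),
    )
    return rec, truth


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort-level generative parameters (defaults mirror the study design)."""

    n_pd: int = 31
    n_control: int = 6
    n_trials: int = 3
    seed: int = 0
    noise_sd_g: float = 0.02
    gyro_noise_sd_dps: float = 1.0
    duration_cv: float = 0.10
    trial_speedup: float = 0.06

    def __post_init__(self) -> None:
        if self.n_pd < 1 or self.n_control < 1 or self.n_trials < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SyntheticCohort:
    """All simulated trials, their ground truth, and the clinical-score table."""

    spec: SyntheticCohortSpec
    trials: list[tuple[IMURecording, SegmentedTUG]]
    scores: pd.DataFrame

    @property
    def n_recordings(self) -> int:
        return len(self.trials)

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    def write(self, out_dir: str | Path) -> Path:
        """Write recordings in the canonical dialect plus a YAML manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for rec, _ in self.trials:
            name = f"{rec.subject_id}_{rec.group}_trial{rec.trial_index}.tsv"
            write_recording(rec, out_dir / name)
            entries.append(
                {
                    "path": name,
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "trial_index": rec.trial_index,
                }
            )
        manifest = out_dir / "manifest.yaml"
        write_manifest(entries, manifest, scores=self.scores)
        return manifest


def _clip_round(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    return float(np.clip(np.round(mean + sd * rng.standard_normal()), lo, hi))


def _scores_for(rng: np.random.Generator, severity: float) -> dict:
    """Clinical scores with a monotone link to the degradation parameter."""
    scores: dict = {}
    for item in UPDRS_ITEMS:
        slope = 2.0 if item == "tremor_at_rest" else 3.2
        scores[item] = _clip_round(rng, 0.4 + slope * severity, 0.45, 0, 4)
    scores["updrs_iii"] = _clip_round(rng, 8 + 28 * severity, 3.0, 0, 108)
    scores["hy"] = _clip_round(rng, 1 + 3 * severity, 0.4, 1, 5)
    scores["fogq"] = _clip_round(rng, 6 + 15 * severity, 1.5, 1, 24)
    scores["mmse"] = _clip_round(rng, 29 - 4 * severity, 1.0, 20, 30)
    return scores


def _sample_profile(
    rng: np.random.Generator, group: str, subject_id: str, spec: SyntheticCohortSpec
) -> SubjectProfile:
    cv = spec.duration_cv
    common = dict(
        noise_sd_g=spec.noise_sd_g,
        gyro_noise_sd_dps=spec.gyro_noise_sd_dps,
        trial_speedup=spec.trial_speedup,
        subject_id=subject_id,
    )
    if group == "control":
        durations = tuple(
            d * float(np.exp(rng.normal(0, cv))) for d in CONTROL_PHASE_S
        )
        return control_profile(
            phase_durations=durations,
            spectral_broadening=float(0.02 + abs(rng.normal(0, 0.005))),
            **common,
        )
    severity = float(rng.uniform(0.25, 1.0))
    dur_scale = 0.8 + 0.32 * severity
    durations = tuple(
        d * dur_scale * float(np.exp(rng.normal(0, cv))) for d in PD_PHASE_S
    )
    episodes = []
    n_ep = int(rng.binomial(3, min(1.0, 0.4 * severity)))
    for _ in range(n_ep):
        phase = str(rng.choice(["turn", "walk2", "turn_stand_to_sit"]))
        phase_len = durations[PHASES.index(phase)]
        dur = float(rng.uniform(0.6, min(1.2, max(0.65, phase_len - 0.2))))
        offset = float(rng.uniform(0, max(1e-3, phase_len - dur)))
        episodes.append(
            FreezeEpisode(
                phase=phase,
                start_offset_s=offset,
                duration_s=dur,
                intensity_g=float((0.08 + 0.15 * severity) * rng.uniform(0.8, 1.2)),
                carrier_hz=float(rng.uniform(4.0, 7.0)),
            )
        )
    return pd_profile(
        severity=severity,
        phase_durations=durations,
        freeze_episodes=tuple(episodes),
        **common,
    )


def simulate_cohort(spec: SyntheticCohortSpec = SyntheticCohortSpec()) -> SyntheticCohort:
    """Simulate the full cohort: ``n_pd + n_control`` subjects x ``n_trials``.

    Deterministic under ``spec.seed``: subject parameter draws, clinical
    scores and every trial's noise all descend from one SeedSequence.
    """
    root = np.random.SeedSequence(spec.seed)
    n_subj = spec.n_pd + spec.n_control
    subj_seeds = root.spawn(n_subj)
    trials: list[tuple[IMURecording, SegmentedTUG]] = []
    rows = []
    groups = ["PD"] * spec.n_pd + ["control"] * spec.n_control
    for i, (group, sseq) in enumerate(zip(groups, subj_seeds)):
        subject_id = f"{'P' if group == 'PD' else 'C'}{i:03d}"
        param_seq, score_seq, *trial_seqs = sseq.spawn(2 + spec.n_trials)
        profile = _sample_profile(
            np.random.default_rng(param_seq), group, subject_id, spec
        )
        row = {"subject_id": subject_id, "group": group, "severity": profile.severity}
        if group == "PD":
            row.update(_scores_for(np.random.default_rng(score_seq), profile.severity))
        rows.append(row)
        for k in range(spec.n_trials):
            seed_k = int(trial_seqs[k].generate_state(1)[0] % (2**31))
            trials.append(simulate_trial(profile, trial_index=k + 1, seed=seed_k))
    scores = pd.DataFrame(rows)
    return SyntheticCohort(spec=spec, trials=trials, scores=scores)
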