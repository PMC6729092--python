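"""Reading and writing waist-worn IMU recordings as delimited text.

The canonical dialect is one header line of column names, tab separated,
columns ``time_s, accV_g, accML_g, accAP_g, gyroYaw_dps, gyroPitch_dps,
gyroRoll_dps``, preceded by ``# key: value`` metadata lines (subject id,
group, trial index, sample rate).  Acceleration is stored in g and angular
rate in degrees per second — the acquisition units of a ±8 g / ±250 °/s
sensor sampled at 100 Hz.  Unit conversion to SI is an explicit helper,
never implicit.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError

__all__ = [
    "DialectConfig",
    "IMURecording",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
    "metadata_from_filename",
    "acc_to_mps2",
    "GRAVITY_MPS2",
]

GRAVITY_MPS2 = 9.80665

ACC_AXES = ("V", "ML", "AP")
GYRO_AXES = ("yaw", "pitch", "roll")

_CANONICAL_COLUMNS = (
    "time_s",
    "accV_g",
    "accML_g",
    "accAP_g",
    "gyroYaw_dps",
    "gyroPitch_dps",
    "gyroRoll_dps",
)


@dataclass(frozen=True)
class DialectConfig:
    """Declares how a delimited-text recording is laid out.

    ``decimal`` is fixed by the dialect and never inferred from the file,
    so parsing is locale independent.
    """

    delimiter: str = "\t"
    decimal: str = "."
    columns: tuple[str, ...] = _CANONICAL_COLUMNS
    has_time_column: bool = True
    header: bool = True
    acc_unit: str = "g"        # "g" or "m/s2"
    gyro_unit: str = "deg/s"   # "deg/s" or "rad/s"
    sample_rate: float = 100.0
    float_format: str = "%.6f"
    time_tolerance: float = 1e-4  # max deviation of sample spacing, seconds


CANONICAL_DIALECT = DialectConfig()


@dataclass
class IMURecording:
    """A uniformly sampled triaxial accelerometer + gyroscope recording.

    ``acc`` holds linear acceleration in g, columns ordered V (vertical),
    ML (mediolateral), AP (anteroposterior).  ``gyro`` holds angular rate
    in °/s, columns ordered yaw, pitch, roll.
    """

    acc: np.ndarray
    gyro: np.ndarray
    sample_rate: float = 100.0
    subject_id: str = "unknown"
    group: str = "control"
    trial_index: int = 1

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must be (n_samples, 3): V, ML, AP")
        if self.gyro.ndim != 2 or self.gyro.shape[1] != 3:
            raise ValueError("gyro must be (n_samples, 3): yaw, pitch, roll")
        if self.acc.shape[0] != self.gyro.shape[0]:
            raise ValueError(
                f"acc has {self.acc.shape[0]} samples but gyro has "
                f"{self.gyro.shape[0]}"
            )
        if self.acc.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.group not in ("PD", "control"):
            raise ValueError("group must be 'PD' or 'control'")
        if not 1 <= int(self.trial_index):
            raise ValueError("trial_index must be a positive integer")
        if np.nanmax(np.abs(self.acc)) > 8.0:
            warnings.warn(
                "acceleration exceeds the ±8 g sensor range", stacklevel=2
            )
        if np.nanmax(np.abs(self.gyro)) > 250.0:
            warnings.warn(
                "angular rate exceeds the ±250 °/s sensor range", stacklevel=2
            )

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration(self) -> float:
        """Elapsed time between first and last sample, seconds."""
        return (self.n_samples - 1) / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def acc_axis(self, axis: str) -> np.ndarray:
        return self.acc[:, ACC_AXES.index(axis)]

    def gyro_axis(self, axis: str) -> np.ndarray:
        return self.gyro[:, GYRO_AXES.index(axis)]


def acc_to_mps2(acc_g: np.ndarray) -> np.ndarray:
    """Convert acceleration from g to m/s² (explicit, never implicit)."""
    return np.asarray(acc_g, dtype=float) * GRAVITY_MPS2


def _meta_line(key: str, value) -> str:
    return f"# {key}: {value}\n"


def write_recording(
    rec: IMURecording, path: str | Path, dialect: DialectConfig = CANONICAL_DIALECT
) -> None:
    """Write a recording in the given dialect, with ``#`` metadata lines."""
    path = Path(path)
    n = rec.n_samples
    t = np.arange(n) / rec.sample_rate
    acc = rec.acc if dialect.acc_unit == "g" else acc_to_mps2(rec.acc)
    gyro = rec.gyro if dialect.gyro_unit == "deg/s" else np.deg2rad(rec.gyro)
    cols = [acc[:, 0], acc[:, 1], acc[:, 2], gyro[:, 0], gyro[:, 1], gyro[:, 2]]
    if dialect.has_time_column:
        cols = [t] + cols
    data = np.column_stack(cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_line("subject_id", rec.subject_id))
        fh.write(_meta_line("group", rec.group))
        fh.write(_meta_line("trial_index", rec.trial_index))
        fh.write(_meta_line("sample_rate_hz", rec.sample_rate))
        if dialect.header:
            names = dialect.columns if dialect.has_time_column else dialect.columns[1:]
            fh.write(dialect.delimiter.join(names) + "\n")
        fmt = dialect.float_format
        for row in data:
            cells = [fmt % v for v in row]
            if dialect.decimal != ".":
                cells = [c.replace(".", dialect.decimal) for c in cells]
            fh.write(dialect.delimiter.join(cells) + "\n")


def _parse_metadata(path: Path) -> tuple[dict, int]:
    meta: dict = {}
    n_meta = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            m = re.match(r"#\s*([\w.]+)\s*:\s*(.+?)\s*$", line)
            if m:
                meta[m.group(1)] = m.group(2)
    return meta, n_meta


def metadata_from_filename(path: str | Path) -> dict:
    """Parse the ``<subject>_<group>_trial<k>`` filename convention.

    Returns an empty dict when the stem does not match.
    """
    stem = Path(path).stem
    m = re.match(r"(?P<subject_id>.+)_(?P<group>PD|control)_trial(?P<trial>\d+)$", stem)
    if not m:
        return {}
    return {
        "subject_id": m.group("subject_id"),
        "group": m.group("group"),
        "trial_index": int(m.group("trial")),
    }


def read_recording(
    path: str | Path,
    dialect: DialectConfig = CANONICAL_DIALECT,
    **metadata,
) -> IMURecording:
    """Read one recording; explicit ``metadata`` kwargs override header/filename.

    Raises :class:`FormatError` for an empty file, missing columns, or a
    non-uniform time column.
    """
    path = Path(path)
    meta, n_meta = _parse_metadata(path)
    try:
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            decimal=dialect.decimal,
            skiprows=n_meta,
            header=0 if dialect.header else None,
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty recording file") from exc
    if df.empty:
        raise FormatError(f"{path}: recording contains no samples")

    expected = dialect.columns if dialect.has_time_column else dialect.columns[1:]
    if dialect.header:
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        df = df[list(expected)]
    else:
        if df.shape[1] != len(expected):
            raise FormatError(
                f"{path}: expected {len(expected)} columns, found {df.shape[1]}"
            )
        df.columns = list(expected)

    sample_rate = float(meta.get("sample_rate_hz", dialect.sample_rate))
    if dialect.has_time_column:
        t = df[dialect.columns[0]].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(np.abs(dt - 1.0 / sample_rate) > dialect.time_tolerance):
                raise FormatError(
                    f"{path}: non-uniform time column "
                    f"(expected step {1.0 / sample_rate:.6g} s)"
                )
        df = df.drop(columns=[dialect.columns[0]])

    vals = df.to_numpy(dtype=float)
    acc, gyro = vals[:, :3], vals[:, 3:6]
    if dialect.acc_unit == "m/s2":
        acc = acc / GRAVITY_MPS2
    if dialect.gyro_unit == "rad/s":
        gyro = np.rad2deg(gyro)

    resolved = dict(metadata_from_filename(path))
    resolved.update(
        {k: meta[k] for k in ("subject_id", "group") if k in meta}
    )
    if "trial_index" in meta:
        resolved["trial_index"] = int(meta["trial_index"])
    resolved.update({k: v for k, v in metadata.items() if v is not None})
    resolved.setdefault("subject_id", "unknown")
    resolved.setdefault("group", "control")
    resolved.setdefault("trial_index", 1)
    return IMURecording(acc=acc, gyro=gyro, sample_rate=sample_rate, **resolved)


def write_manifest(
    entries: Sequence[Mapping],
    path: str | Path,
    scores: pd.DataFrame | None = None,
) -> None:
    """Write a YAML/JSON manifest listing recordings and clinical scores.

    Each entry needs ``path``, ``subject_id``, ``group``, ``trial_index``.
    ``scores`` is an optional per-subject table (index or column
    ``subject_id``) of clinical scores (UPDRS III items, H&Y, FOG-Q, MMSE).
    """
    path = Path(path)
    doc: dict = {"recordings": [dict(e) for e in entries]}
    if scores is not None:
        tbl = scores.reset_index() if scores.index.name == "subject_id" else scores
        doc["scores"] = tbl.to_dict(orient="records")
    text = (
        json.dumps(doc, indent=2)
        if path.suffix == ".json"
        else yaml.safe_dump(doc, sort_keys=False)
    )
    path.write_text(text, encoding="utf-8")


def read_manifest(path: str | Path) -> tuple[list[dict], pd.DataFrame | None]:
    """Read a manifest; returns (recording entries, scores table or None)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict) or "recordings" not in doc:
        raise FormatError(f"{path}: manifest must contain a 'recordings' list")
    scores = None
    if doc.get("scores"):
        scores = pd.DataFrame(doc["scores"])
    return list(doc["recordings"]), scores
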