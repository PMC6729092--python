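"""End-to-end orchestration: simulate/read → segment → smoothness → stats.

A single config (YAML/JSON or :class:`PipelineConfig`) drives the run; all
randomness comes from one seed, and a config hash is logged so identical
configs reproduce identical outputs bit-for-bit on synthetic input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .errors import ItugError
from .io import IMURecording, read_manifest, read_recording
from .preprocessing import PreprocessConfig
from .segmentation import SegmentationConfig, segment_tug
from .smoothness import (
    CHANNELS,
    SmoothnessConfig,
    SmoothnessResult,
    analyze_recording,
    average_trials,
)
from .stats import anova_two_way_type2, cohen_d, correlation_map
from .synthetic import SyntheticCohortSpec, simulate_cohort

log = logging.getLogger("itug")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

WALK_DISTANCE_M = 3.0


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; exactly one input source.

    ``synthetic`` holds a :class:`SyntheticCohortSpec`; ``manifest`` points
    at a YAML/JSON manifest of recordings on disk.
    """

    out_dir: Path = Path("itug_out")
    seed: int = 0
    manifest: Path | None = None
    synthetic: SyntheticCohortSpec | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    smoothness: SmoothnessConfig = field(default_factory=SmoothnessConfig)
    sidak_correlations: bool = False
    use_ground_truth_segmentation: bool = False
    write_recordings: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.synthetic is None):
            raise ValueError("exactly one of manifest/synthetic must be set")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        seed = int(doc.get("seed", 0))
        synth = doc.pop("synthetic", None)
        if synth is not None:
            synth = dict(synth)
            synth.setdefault("seed", seed)
            synth = SyntheticCohortSpec(**synth)
        kwargs = {}
        for key, klass in (
            ("preprocess", PreprocessConfig),
            ("segmentation", SegmentationConfig),
            ("smoothness", SmoothnessConfig),
        ):
            if key in doc:
                section = doc.pop(key)
                if "zero_pad" in section and isinstance(section["zero_pad"], str) \
                        and section["zero_pad"].isdigit():
                    section["zero_pad"] = int(section["zero_pad"])
                kwargs[key] = klass(**section)
        manifest = doc.pop("manifest", None)
        return cls(
            out_dir=Path(doc.pop("out_dir", "itug_out")),
            seed=seed,
            manifest=None if manifest is None else Path(manifest),
            synthetic=synth,
            sidak_correlations=bool(doc.pop("sidak_correlations", False)),
            use_ground_truth_segmentation=bool(
                doc.pop("use_ground_truth_segmentation", False)
            ),
            write_recordings=bool(doc.pop("write_recordings", False)),
            log_level=str(doc.pop("log_level", "INFO")),
            **kwargs,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        doc.pop("seed_comment", None)
        return cls.from_dict(doc)

    def canonical_dict(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, Path):
                return str(v)
            if isinstance(v, tuple):
                return list(v)
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        Output location and log level do not affect results and are
        excluded, so reruns into different directories certify as identical.
        """
        doc = self.canonical_dict()
        doc.pop("out_dir", None)
        doc.pop("log_level", None)
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineReport:
    """Paths and in-memory tables produced by one pipeline run."""

    config: PipelineConfig
    segmentation: pd.DataFrame
    smoothness: pd.DataFrame
    smoothness_mean: pd.DataFrame
    anova: pd.DataFrame
    correlations: pd.DataFrame
    effects: pd.DataFrame
    summary: dict
    out_dir: Path


def _recording_id(rec: IMURecording) -> str:
    return f"{rec.subject_id}_trial{rec.trial_index}"


def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        cohort = simulate_cohort(cfg.synthetic)
        if cfg.write_recordings:
            cohort.write(cfg.out_dir / "recordings")
        return cohort.trials, cohort.scores
    entries, scores = read_manifest(cfg.manifest)
    base = Path(cfg.manifest).parent
    trials = []
    for e in entries:
        rec = read_recording(
            base / e["path"],
            subject_id=e.get("subject_id"),
            group=e.get("group"),
            trial_index=e.get("trial_index"),
        )
        trials.append((rec, None))
    return trials, scores


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Run the full analysis and write the report bundle to ``cfg.out_dir``.

    Outputs: ``segmentation.tsv``, ``smoothness.csv`` (per trial),
    ``smoothness_mean.csv`` (per subject, mean of trials), ``anova.csv``,
    ``correlations.csv``, ``effects.csv`` and ``summary.json``.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials, scores = _load_inputs(cfg)
    log.info("loaded %d recordings", len(trials))

    # --- segmentation --------------------------------------------------------
    seg_rows, analyses = [], []
    for rec, truth in trials:
        rid = _recording_id(rec)
        try:
            seg = (
                truth
                if (cfg.use_ground_truth_segmentation and truth is not None)
                else segment_tug(rec, cfg.preprocess, cfg.segmentation)
            )
        except ItugError as exc:
            raise ItugError(f"stage segmentation, recording {rid}: {exc}") from exc
        frame = seg.to_frame(rid)
        frame.insert(1, "subject_id", rec.subject_id)
        frame.insert(2, "group", rec.group)
        frame.insert(3, "trial", rec.trial_index)
        seg_rows.append(frame)
        analyses.append((rec, seg))
    segmentation = pd.concat(seg_rows, ignore_index=True)
    segmentation.to_csv(out / "segmentation.tsv", sep="\t", index=False)

    # --- smoothness -----------------------------------------------------------
    results: list[SmoothnessResult] = []
    for rec, seg in analyses:
        try:
            results.append(analyze_recording(rec, seg, cfg.smoothness))
        except (ItugError, ValueError) as exc:
            raise ItugError(
                f"stage smoothness, recording {_recording_id(rec)}: {exc}"
            ) from exc
    tidy = pd.concat([r.to_tidy() for r in results], ignore_index=True)
    tidy.to_csv(out / "smoothness.csv", index=False)

    by_subject: dict[str, list[SmoothnessResult]] = {}
    for r in results:
        by_subject.setdefault(r.subject_id, []).append(r)
    means = [average_trials(v) for v in by_subject.values()]
    tidy_mean = pd.concat([m.to_tidy() for m in means], ignore_index=True)
    tidy_mean.to_csv(out / "smoothness_mean.csv", index=False)

    # --- per-trial responses for the trial/group ANOVAs ----------------------
    wide = segmentation.pivot_table(
        index=["subject_id", "group", "trial"], columns="phase", values="duration_s"
    ).reset_index()
    per_trial = tidy[(tidy.channel == "AccL_total")].pivot_table(
        index=["subject_id", "group", "trial"], columns="phase", values="sparc"
    ).reset_index()
    merged = wide.merge(per_trial, on=["subject_id", "group", "trial"],
                        suffixes=("_dur", "_sparc"))
    anova_tables = []
    responses = {
        "walk1_speed_mps": WALK_DISTANCE_M / merged["walk1_dur"],
        "walk2_speed_mps": WALK_DISTANCE_M / merged["walk2_dur"],
        "tug_time_s": merged["full_dur"],
        "sparc_AccL_total_full": merged["full_sparc"],
        "sparc_AccL_total_walk1": merged["walk1_sparc"],
    }
    for name, vals in responses.items():
        res = anova_two_way_type2(
            vals.to_numpy(), merged["group"].to_numpy(), merged["trial"].to_numpy()
        )
        tab = res.table.reset_index(names="effect")
        tab.insert(0, "response", name)
        anova_tables.append(tab)
    anova = pd.concat(anova_tables, ignore_index=True)
    anova.to_csv(out / "anova.csv", index=False)

    # --- effects table (group contrasts on trial-averaged full-TUG SPARC) ----
    eff_rows = []
    mean_full = tidy_mean[tidy_mean.phase == "full"]
    dur_mean = (
        segmentation[segmentation.phase == "full"]
        .groupby(["subject_id", "group"], sort=False)["duration_s"]
        .mean()
        .reset_index()
    )

    def _ci(v: np.ndarray) -> tuple[float, float]:
        if len(v) < 2:
            return (np.nan, np.nan)
        half = 1.96 * v.std(ddof=1) / np.sqrt(len(v))
        return (float(v.mean() - half), float(v.mean() + half))

    def _effect_row(var: str, pd_vals: np.ndarray, hc_vals: np.ndarray) -> dict:
        from scipy import stats as sstats

        es = cohen_d(pd_vals, hc_vals)
        _, p = sstats.ttest_ind(pd_vals, hc_vals)
        return {
            "variable": var,
            "pd_mean": float(pd_vals.mean()),
            "pd_ci_low": _ci(pd_vals)[0],
            "pd_ci_high": _ci(pd_vals)[1],
            "hc_mean": float(hc_vals.mean()),
            "hc_ci_low": _ci(hc_vals)[0],
            "hc_ci_high": _ci(hc_vals)[1],
            "effect_size_d": es.d,
            "effect_class": es.label,
            "clinically_relevant": es.clinically_relevant,
            "p": float(p),
        }

    for ch in CHANNELS:
        sub = mean_full[mean_full.channel == ch]
        eff_rows.append(
            _effect_row(
                f"SPARC {ch} (full TUG)",
                sub[sub.group == "PD"]["sparc"].to_numpy(),
                sub[sub.group == "control"]["sparc"].to_numpy(),
            )
        )
    eff_rows.append(
        _effect_row(
            "TUG time (s)",
            dur_mean[dur_mean.group == "PD"]["duration_s"].to_numpy(),
            dur_mean[dur_mean.group == "control"]["duration_s"].to_numpy(),
        )
    )
    effects = pd.DataFrame(eff_rows)
    effects.to_csv(out / "effects.csv", index=False)

    # --- correlation map (clinical scores, PD subjects) ----------------------
    if scores is not None:
        correlations = correlation_map(
            tidy_mean, scores, sidak=cfg.sidak_correlations
        )
    else:
        correlations = pd.DataFrame()
    correlations.to_csv(out / "correlations.csv", index=False)

    summary = {
        "itug_version": _pkg_version,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_recordings": len(trials),
        "n_subjects": int(tidy_mean["subject_id"].nunique()),
        "outputs": [
            "segmentation.tsv",
            "smoothness.csv",
            "smoothness_mean.csv",
            "anova.csv",
            "correlations.csv",
            "effects.csv",
        ],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2), encoding="utf-8")
    log.info("pipeline complete: %s", out)
    return PipelineReport(
        config=cfg,
        segmentation=segmentation,
        smoothness=tidy,
        smoothness_mean=tidy_mean,
        anova=anova,
        correlations=correlations,
        effects=effects,
        summary=summary,
        out_dir=out,
    )
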