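"""End-to-end orchestration: cohort in, reports out.

One :class:`PipelineConfig` and one master seed drive the whole run:
simulate (or load) a cohort, select the cohort-wide filter cutoff, filter
and compute CoP tracks, extract features, apply staged QC, compute group
statistics and ANOVA tables, and run the classifier benchmark.  Per-stage
seeds are spawned deterministically from the master seed, so the full run is
reproducible from (config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .benchmark import BenchmarkReport, run_benchmark
from .config import PipelineConfig
from .core import CoPTrack, ForceRecording, SubjectRecord, band_column_name
from .features import extract_features
from .preprocessing import preprocess_recording, select_cutoff
from .qc import (
    ExclusionReport,
    filter_feature_table_iqr,
    filter_implausible,
    filter_protocol,
)
from .stats import age_band, anova_effects, anova_table, comparison_table
from .synthetic import CohortSpec, generate_cohort

log = logging.getLogger(__name__)

#: default ANOVA term lists (anthropometry x pain, up to 4-way; age excluded
#: because group age structures typically differ and would confound)
DEFAULT_ANOVA_TERMS = (
    "C(sex)",
    "weight_kg",
    "height_cm",
    "C(pain)",
    "C(sex):weight_kg",
    "C(sex):height_cm",
    "weight_kg:height_cm",
    "C(sex):C(pain)",
    "weight_kg:C(pain)",
    "height_cm:C(pain)",
    "C(sex):weight_kg:height_cm",
    "C(sex):weight_kg:C(pain)",
    "C(sex):height_cm:C(pain)",
    "weight_kg:height_cm:C(pain)",
    "C(sex):weight_kg:height_cm:C(pain)",
)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stage_timings_s: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "stage_timings_s": self.stage_timings_s,
            "outputs": self.outputs,
        }


@dataclass
class PipelineResult:
    """In-memory results of a full run."""

    cohort: list[SubjectRecord]
    cutoff_hz: float
    features: pd.DataFrame  # post-QC, with labels/anthropometry merged
    exclusions: list[ExclusionReport]
    comparisons: pd.DataFrame
    anova: dict[str, pd.DataFrame]
    benchmark: BenchmarkReport
    manifest: RunManifest


def features_from_recordings(
    recordings: Sequence[ForceRecording],
    cutoff_hz: float,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Filter each recording, compute its CoP track, extract features."""
    rows = []
    for rec in recordings:
        track = preprocess_recording(rec, cutoff_hz, config)
        rows.append(extract_features(track, config).to_dict())
    return pd.DataFrame(rows)


def assemble_table(
    features: pd.DataFrame, cohort: Sequence[SubjectRecord]
) -> pd.DataFrame:
    """Merge per-trial features with subject metadata."""
    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in cohort],
            "sex": [r.sex for r in cohort],
            "age_years": [r.age_years for r in cohort],
            "height_cm": [r.height_cm for r in cohort],
            "weight_kg": [r.weight_kg for r in cohort],
            "shoe_size_eu": [r.shoe_size_eu for r in cohort],
            "pain": [r.pain for r in cohort],
        }
    )
    return features.merge(meta, on="subject_id", validate="one_to_one")


def run_pipeline(
    config: PipelineConfig,
    cohort: Sequence[SubjectRecord] | None = None,
    recordings: Sequence[ForceRecording] | None = None,
    cohort_spec: CohortSpec | None = None,
    seed: int | None = None,
    run_classifier: bool = True,
) -> PipelineResult:
    """Full analysis run.

    Either pass a real (cohort, recordings) pair or let the pipeline
    simulate one from ``cohort_spec`` (defaults drawn from the config seed).
    """
    if seed is None:
        seed = config.rng_seed
    seeds = np.random.SeedSequence(seed).spawn(2)
    sim_seed = int(seeds[0].generate_state(1)[0] % (2**31 - 1))
    bench_seed = int(seeds[1].generate_state(1)[0] % (2**31 - 1))

    manifest = RunManifest(config=config.to_dict(), seed=seed)
    timings = manifest.stage_timings_s

    t0 = time.perf_counter()
    if recordings is None:
        if cohort_spec is None:
            cohort_spec = CohortSpec(
                duration_s=config.trial_duration_s,
                rate_hz=config.sampling_rate_hz,
                rng_seed=sim_seed,
            )
        cohort_list, recordings = generate_cohort(cohort_spec)
    else:
        if cohort is None:
            raise ValueError("recordings passed without a cohort table")
        cohort_list = list(cohort)
    timings["simulate_or_load"] = time.perf_counter() - t0

    # stage 1: protocol exclusions on subjects
    t0 = time.perf_counter()
    kept_subjects, protocol_report = filter_protocol(cohort_list)
    kept_ids = {r.subject_id for r in kept_subjects}
    recordings = [r for r in recordings if r.subject_id in kept_ids]

    cutoff = select_cutoff(recordings, config)
    feats = features_from_recordings(recordings, cutoff, config)
    timings["preprocess_features"] = time.perf_counter() - t0

    # stages 2-3: implausible values, then IQR fences, on derived features
    t0 = time.perf_counter()
    numeric_cols = [c for c in feats.columns if c != "subject_id"]
    feats, implausible_report = filter_implausible(
        feats, config.implausible_threshold, numeric_cols
    )
    analysis_cols = ["track_length_cm"] + [
        band_column_name(lo, hi) for lo, hi in config.band_set
    ]
    feats, iqr_report = filter_feature_table_iqr(feats, analysis_cols, config.iqr_fence_k)
    exclusions = [protocol_report, implausible_report, iqr_report]
    timings["quality_control"] = time.perf_counter() - t0

    table = assemble_table(feats, kept_subjects)
    table["age_band"] = age_band(table["age_years"].to_numpy())

    # group statistics
    t0 = time.perf_counter()
    comparisons = comparison_table(table, table["pain"], analysis_cols)
    anova = {}
    for response in ("track_length_cm", band_column_name(*config.band_set[0])):
        try:
            anova[response] = anova_table(
                anova_effects(table, response, DEFAULT_ANOVA_TERMS)
            )
        except (ValueError, np.linalg.LinAlgError) as exc:  # small-cohort designs
            log.warning("ANOVA for %s skipped: %s", response, exc)
    timings["group_stats"] = time.perf_counter() - t0

    # classifier benchmark
    t0 = time.perf_counter()
    benchmark = None
    if run_classifier:
        feat_cols = [c for c in config.classifier_features if c in table.columns]
        benchmark = run_benchmark(table[feat_cols], table["pain"], config, seed=bench_seed)
    timings["benchmark"] = time.perf_counter() - t0

    return PipelineResult(
        cohort=kept_subjects,
        cutoff_hz=cutoff,
        features=table,
        exclusions=exclusions,
        comparisons=comparisons,
        anova=anova,
        benchmark=benchmark,
        manifest=manifest,
    )


def write_reports(result: PipelineResult, outdir: str | Path) -> None:
    """Write feature table, exclusion report, statistics and benchmark."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(outdir / "features.csv", index=False)
    with open(outdir / "exclusions.json", "w") as fh:
        json.dump([r.to_dict() for r in result.exclusions], fh, indent=2)
    result.comparisons.to_csv(outdir / "group_comparisons.csv", index=False)
    for response, table in result.anova.items():
        table.to_csv(outdir / f"anova_{response}.csv", index=False)
    if result.benchmark is not None:
        with open(outdir / "benchmark.json", "w") as fh:
            json.dump(result.benchmark.to_dict(), fh, indent=2)
        result.benchmark.to_frame().to_csv(outdir / "benchmark.csv", index=False)
    result.manifest.outputs = {p.name: str(p) for p in sorted(outdir.iterdir())}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest.to_dict(), fh, indent=2)
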