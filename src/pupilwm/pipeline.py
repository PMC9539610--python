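"""End-to-end orchestration of the analysis behind a config file.

A run either ingests the three input tables (categorization records,
delayed-estimation trials, pupil samples — exactly one of input paths or
a simulation spec must be configured) or simulates them, then executes
the stage graph

    categories -> preprocess -> fit -> timeseries -> behavior

writing every stage output plus a manifest (config echo, seed, per-stage
sub-seeds, row and exclusion counts) from which the run can be reproduced
bit for bit.  The single global seed is expanded into independent
per-stage streams with ``numpy.random.SeedSequence(seed).spawn``.

Pupil-trial exclusion (baseline outliers) applies only to the pupil-side
analyses; the behavioral stages always see every trial.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from .categories import derive_categories, rater_agreement
from .mixture import fit_mixture_by_cell
from .pupil import TrialPupil, preprocess_traces, windowed_frame
from .synth import (COLOR_TYPES, LOADS, PupilEffectSpec, SimConfig,
                    generate_category_structure, simulate_categorization,
                    simulate_delayed_estimation, simulate_pupil)
from .timeseries import TimeSeriesTestConfig, run_time_series_analysis

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs",
           "load_config", "traces_from_frame", "traces_to_frame"]

log = logging.getLogger("pupilwm")

COLOR_LABEL_SET = {"red", "orange", "yellow", "green", "blue", "purple",
                   "pink"}


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of inputs/simulation is set."""

    out_dir: str = "pupilwm_out"
    seed: int = 0
    log_level: str = "INFO"
    simulation: SimConfig | None = None
    inputs: dict | None = None           # categorization/trials/pupil csv paths
    category_persistence: int = 3
    agreement_threshold: float = 0.5
    min_blink_ms: float = 20.0
    margin_ms: float = 50.0
    baseline_window: tuple = (0.0, 100.0)
    z_threshold: float = 2.0
    bin_ms: float = 10.0
    n_shuffles: int = 1
    density_bandwidth: float = 50.0
    mixture_min_n: int = 10
    timeseries: TimeSeriesTestConfig = field(default_factory=TimeSeriesTestConfig)

    def validate(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'simulation' and 'inputs' must be configured")
        if self.simulation is not None:
            self.simulation.validate()
        self.timeseries.validate()
        return self


def _intkeys(d: dict) -> dict:
    return {int(k): float(v) for k, v in d.items()}


def _sim_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "p_categorical" in d:
        pc = d["p_categorical"]
        if pc and not isinstance(next(iter(pc)), tuple):
            d["p_categorical"] = {(int(load), ctype): float(p)
                                  for ctype, by_load in pc.items()
                                  for load, p in by_load.items()}
    if "guess_rate_by_load" in d:
        d["guess_rate_by_load"] = _intkeys(d["guess_rate_by_load"])
    if "pupil_params" in d:
        pp = dict(d["pupil_params"])
        if "interaction_amplitude_by_load" in pp:
            pp["interaction_amplitude_by_load"] = _intkeys(
                pp["interaction_amplitude_by_load"])
        if "interaction_window" in pp:
            pp["interaction_window"] = tuple(pp["interaction_window"])
        if "trace_span_ms" in pp:
            pp["trace_span_ms"] = tuple(pp["trace_span_ms"])
        d["pupil_params"] = PupilEffectSpec(**pp)
    return SimConfig(**d)


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if kwargs.get("simulation") is not None:
        kwargs["simulation"] = _sim_from_dict(kwargs["simulation"])
    if kwargs.get("timeseries") is not None:
        kwargs["timeseries"] = TimeSeriesTestConfig(**kwargs["timeseries"])
    if kwargs.get("baseline_window") is not None:
        kwargs["baseline_window"] = tuple(kwargs["baseline_window"])
    return PipelineConfig(**kwargs).validate()


def traces_to_frame(traces) -> pd.DataFrame:
    """Raw pupil samples in long format (participant, trial, time_ms, pupil)."""
    return pd.concat(
        [pd.DataFrame({"participant": t.participant, "trial": t.trial,
                       "time_ms": t.times, "pupil": t.samples})
         for t in traces], ignore_index=True)


def traces_from_frame(df: pd.DataFrame) -> list:
    traces = []
    for (pp, trial), sub in df.groupby(["participant", "trial"], sort=True):
        sub = sub.sort_values("time_ms")
        traces.append(TrialPupil(participant=pp, trial=int(trial),
                                 times=sub["time_ms"].to_numpy(),
                                 samples=sub["pupil"].to_numpy()))
    return traces


def validate_inputs(paths: dict) -> dict:
    """Schema-check the three input CSVs; returns errors/warnings lists."""
    report = {"errors": [], "warnings": [], "row_counts": {}}

    def check(name, required, checks):
        path = paths.get(name)
        if path is None:
            return None
        if not Path(path).exists():
            report["errors"].append(f"{name}: file not found: {path}")
            return None
        df = pd.read_csv(path)
        report["row_counts"][name] = len(df)
        missing = set(required) - set(df.columns)
        if missing:
            report["errors"].append(
                f"{name}: missing columns {sorted(missing)}")
            return df
        for msg, bad in checks(df):
            if len(bad):
                row = int(bad.index[0])
                report["errors"].append(
                    f"{name}: {msg} (first offending row {row}: "
                    f"{bad.iloc[0].to_dict()})")
        return df

    check("categorization", ["participant", "hue", "label"], lambda df: [
        ("hue outside [0, 359]",
         df[(df.hue < 0) | (df.hue > 359)]),
        ("unknown color label",
         df[~df.label.isin(COLOR_LABEL_SET)]),
    ])
    check("trials", ["participant", "trial", "memory_load", "color_type",
                     "target_hue", "response_hue"], lambda df: [
        ("memory_load outside 1-4",
         df[~df.memory_load.isin(LOADS)]),
        ("color_type not prototypical/ambiguous",
         df[~df.color_type.isin(COLOR_TYPES)]),
        ("hue outside [0, 360)",
         df[(df.target_hue < 0) | (df.target_hue >= 360)
            | (df.response_hue < 0) | (df.response_hue >= 360)]),
    ])
    check("pupil", ["participant", "trial", "time_ms", "pupil"], lambda df: [
        ("negative pupil size", df[df.pupil < 0]),
    ])
    report["ok"] = not report["errors"]
    return report


def _stage(manifest, out_dir, name):
    """Context manager recording stage success/failure in the manifest."""
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                manifest["stages"][name] = "ok"
                log.info("stage %s: done", name)
                return False
            manifest["stages"][name] = f"FAILED: {exc}"
            (out_dir / "FAILED").write_text(f"stage {name}: {exc}\n")
            _write_manifest(manifest, out_dir)
            log.error("stage %s: FAILED (%s)", name, exc)
            return False
    return _Ctx()


def _jsonable(obj):
    """Stringify non-JSON dict keys (e.g. (load, color_type) tuples)."""
    if isinstance(obj, dict):
        return {(k if isinstance(k, str) else str(k)): _jsonable(v)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_manifest(manifest, out_dir):
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full stage graph; returns the manifest dict."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(config.seed).spawn(6)]
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "stages": {},
        "counts": {},
    }

    with _stage(manifest, out_dir, "ingest"):
        if config.simulation is not None:
            sim = config.simulation
            structure = generate_category_structure(
                sim.n_categories, seed=stage_seeds[0])
            categorization = simulate_categorization(
                structure, sim.n_participants, seed=stage_seeds[1])
            trials = simulate_delayed_estimation(structure, sim,
                                                 seed=stage_seeds[2])
            traces = simulate_pupil(trials, sim.pupil_params,
                                    seed=stage_seeds[3])
            categorization.to_csv(out_dir / "categorization.csv", index=False)
            trials.to_csv(out_dir / "trials.csv", index=False)
        else:
            report = validate_inputs(config.inputs)
            with open(out_dir / "validation.json", "w") as fh:
                json.dump(report, fh, indent=2)
            if not report["ok"]:
                raise ValueError(f"input validation failed: {report['errors']}")
            categorization = pd.read_csv(config.inputs["categorization"])
            trials = pd.read_csv(config.inputs["trials"])
            traces = traces_from_frame(pd.read_csv(config.inputs["pupil"]))
        manifest["counts"]["categorization_rows"] = len(categorization)
        manifest["counts"]["trials"] = len(trials)
        manifest["counts"]["traces"] = len(traces)

    with _stage(manifest, out_dir, "categories"):
        solution = derive_categories(categorization,
                                     persistence=config.category_persistence)
        solution.to_json(out_dir / "categories.json")
        agreement = rater_agreement(categorization,
                                    threshold=config.agreement_threshold)
        agreement.to_csv(out_dir / "agreement.csv", index=False)
        manifest["counts"]["flagged_raters"] = int(agreement.flagged.sum())

    with _stage(manifest, out_dir, "preprocess"):
        processed = preprocess_traces(
            traces, min_blink_ms=config.min_blink_ms,
            margin_ms=config.margin_ms,
            baseline_window=config.baseline_window,
            z_threshold=config.z_threshold, bin_ms=config.bin_ms)
        windowed = windowed_frame(processed, trials)
        windowed.to_csv(out_dir / "windowed.csv", index=False)
        excl = pd.Series([t.participant for t in processed if t.excluded])
        excl_counts = excl.value_counts().to_dict() if len(excl) else {}
        with open(out_dir / "exclusions.json", "w") as fh:
            json.dump({"n_excluded": int(len(excl)),
                       "by_participant": {str(k): int(v)
                                          for k, v in excl_counts.items()}},
                      fh, indent=2)
        manifest["counts"]["excluded_pupil_trials"] = int(len(excl))

    with _stage(manifest, out_dir, "fit"):
        fits = fit_mixture_by_cell(trials, min_n=config.mixture_min_n)
        fits.to_csv(out_dir / "fits.csv", index=False)
        manifest["counts"]["mixture_cells"] = len(fits)

    with _stage(manifest, out_dir, "timeseries"):
        result = run_time_series_analysis(windowed, config.timeseries)
        result.per_window.to_csv(out_dir / "per_window.tsv", sep="\t",
                                 index=False)
        with open(out_dir / "timeseries.json", "w") as fh:
            json.dump({"clusters": result.clusters,
                       "cv_winning_samples": result.cv_winning_samples,
                       "cv_statistic": result.cv_statistic,
                       "cv_p": result.cv_p,
                       "followup_window": list(result.followup_window),
                       "followups": result.followups}, fh, indent=2)

    with _stage(manifest, out_dir, "behavior"):
        perm = bh.permutation_above_chance(trials, n_shuffles=config.n_shuffles,
                                           seed=stage_seeds[4])
        anovas = {param: bh.rm_anova(fits, value=param).to_dict("records")
                  for param in ("precision", "guess_rate")}
        followups = {param: bh.paired_followups(fits, value=param)
                     .to_dict("records")
                     for param in ("precision", "guess_rate")}
        density = bh.circular_response_density(
            trials, bandwidth_kappa=config.density_bandwidth,
            group_cols=("target_hue", "memory_load"))
        density.to_csv(out_dir / "density.tsv", sep="\t", index=False)
        with open(out_dir / "behavior.json", "w") as fh:
            json.dump({"above_chance": perm.to_dict("records"),
                       "rm_anova": anovas, "paired_followups": followups},
                      fh, indent=2)
        manifest["counts"]["above_chance_participants"] = int(
            perm.above_chance.sum())

    manifest["status"] = "ok"
    _write_manifest(manifest, out_dir)
    return manifest
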