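"""End-to-end orchestration: simulate/ingest -> synchronize -> preprocess ->
COP projection -> per-window features -> surrogate tests -> mixed ANOVA.

``analyze_session`` handles one participant-day; ``run_pipeline`` loops over
a cohort, writes the tidy artifacts (window table, COP traces, feature
table, surrogate report, ANOVA report) and a manifest with the config hash
and per-stage sample counts, so a rerun with identical config and inputs is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anova as anova_mod
from . import cop as cop_mod
from . import features as feat_mod
from . import fractal as fractal_mod
from . import preprocess as prep_mod
from . import surrogate as surr_mod
from .config import RunConfig
from .ingest import (
    SensorStream,
    crop_to_common_interval,
    read_sensor_csv,
    resample_uniform,
    write_sensor_csv,
)
from .synthetic import Cohort, CohortSpec, Recording, RecordingTiming, generate_cohort

logger = logging.getLogger("trunksway")


class StageError(RuntimeError):
    """A pipeline stage failed; carries stage and session identity."""

    def __init__(self, stage: str, participant: str, day, cause: Exception):
        super().__init__(f"stage '{stage}' failed for {participant} day {day}: {cause}")
        self.stage = stage
        self.participant = participant
        self.day = day
        self.__cause__ = cause


@dataclass
class SessionResult:
    """Per-session artifacts: window bookkeeping and feature rows."""

    participant: str
    group: str
    day: int
    windows: pd.DataFrame  # label, start_s, end_s, retained_fraction, n_used
    features: pd.DataFrame  # tidy window-level rows
    counts: dict[str, int]  # per-stage sample ledger
    cop_trace: cop_mod.CopTrace


def analyze_session(
    streams: dict[str, SensorStream],
    config: RunConfig,
    participant: str = "P01",
    group: str = "PG",
    day: int = 1,
) -> SessionResult:
    """Run the full signal chain for one session's raw streams."""
    counts: dict[str, int] = {}
    cropped = crop_to_common_interval(list(streams.values()))
    cropped = {s.sensor_kind: s for s in cropped}
    acc = resample_uniform(cropped["accelerometer"], config.resample_rate_hz)
    rv = resample_uniform(cropped["rotation_vector"], config.resample_rate_hz)
    n = min(acc.n_samples, rv.n_samples)
    counts["resampled"] = n

    acc_p = prep_mod.preprocess_accelerometer(
        acc,
        lowpass_cutoff_hz=config.lowpass_cutoff_hz,
        gravity_cutoff_hz=config.gravity_cutoff_hz,
        smooth_samples=config.acc_smooth_samples,
    )
    mag = prep_mod.acceleration_magnitude(
        acc_p.values[:n, 0], acc_p.values[:n, 1], acc_p.values[:n, 2]
    )
    removal = prep_mod.detect_nonseated(
        mag,
        threshold=config.threshold_ms2,
        rate_hz=config.resample_rate_hz,
        guard_seconds=config.guard_seconds,
    )
    seated = prep_mod.retained_mask(n, removal)
    counts["seated"] = int(seated.sum())

    windows = prep_mod.segment_windows(n, config.resample_rate_hz, config.window_minutes)
    for w in windows:
        w.retained_mask = seated[w.start_index : w.end_index]

    rv_s = prep_mod.smooth_rotation_vector(rv, config.rv_smooth_samples)
    angles = cop_mod.quaternion_to_euler(rv_s.values[:n])
    keep = seated & ~angles.flagged
    idx = np.flatnonzero(keep)
    angles_kept = cop_mod.EulerAngles(
        pitch=angles.pitch[idx],
        roll=angles.roll[idx],
        yaw=angles.yaw[idx],
        flagged=angles.flagged[idx],
    )
    centered = cop_mod.center_angles(angles_kept)
    trace = cop_mod.angles_to_displacement(
        centered, config.lever_mm, config.resample_rate_hz, sample_index=idx
    )
    bounds = cop_mod.EllipseBounds(config.ellipse_ap_mm, config.ellipse_ml_mm)
    trace, removed_frac = cop_mod.ellipse_clip(trace, bounds)
    counts["in_ellipse"] = trace.n_samples

    mfdfa_params = fractal_mod.MfdfaParams(
        scale_min=config.mfdfa_scale_min,
        n_scales=config.mfdfa_n_scales,
        detrend_order=config.mfdfa_detrend_order,
        integrate_input=config.mfdfa_integrate_input,
    )
    sampen_params = fractal_mod.SampEnParams(m=config.sampen_m, r=config.sampen_r)

    feat_rows: list[dict] = []
    win_rows: list[dict] = []
    for w in windows:
        sub = trace.slice_by_index(w.start_index, w.end_index)
        win_rows.append(
            {
                "label": w.label,
                "period": w.period,
                "start_s": w.start_index / config.resample_rate_hz,
                "end_s": w.end_index / config.resample_rate_hz,
                "retained_fraction": w.retained_fraction,
                "n_used": sub.n_samples,
            }
        )
        if sub.n_samples < config.min_window_samples:
            continue
        rows = feat_mod.linear_feature_rows(sub, config.sway_area_raw)
        if sub.n_samples >= 8 * mfdfa_params.scale_min:
            rows += fractal_mod.nonlinear_feature_rows(
                {"AP": sub.cop_ap, "ML": sub.cop_ml}, mfdfa_params, sampen_params
            )
        for r in rows:
            r.update(
                participant=participant, group=group, day=day,
                window=w.label, period=w.period,
            )
        feat_rows.extend(rows)

    return SessionResult(
        participant=participant,
        group=group,
        day=day,
        windows=pd.DataFrame(win_rows),
        features=pd.DataFrame(feat_rows),
        counts=counts,
        cop_trace=trace,
    )


def analyze_cohort(
    cohort: Cohort,
    config: RunConfig,
    surrogate_statistics: tuple[str, ...] = ("hq_0", "sampen"),
) -> dict:
    """Analyze every session of a cohort; return feature/window/ANOVA tables."""
    all_feats, all_wins, manifest_sessions = [], [], []
    surr_rows: list[dict] = []
    for participant, group, day, rec in cohort.iter_sessions():
        try:
            res = analyze_session(rec.streams, config, participant, group, day)
        except Exception as exc:  # re-raise with session identity
            raise StageError("analyze_session", participant, day, exc) from exc
        res.windows.insert(0, "participant", participant)
        res.windows.insert(1, "day", day)
        all_wins.append(res.windows)
        all_feats.append(res.features)
        manifest_sessions.append(
            {"participant": participant, "group": group, "day": day, **res.counts}
        )
        if config.run_surrogates:
            surr_rows.extend(
                _surrogate_rows(res, config, surrogate_statistics)
            )
    features = pd.concat(all_feats, ignore_index=True)
    windows = pd.concat(all_wins, ignore_index=True)
    cells = anova_mod.aggregate_cells(features)
    report = anova_mod.anova_report(cells, config.sphericity_correction)
    normality = anova_mod.shapiro_wilk_screen(cells)
    return {
        "features": features,
        "windows": windows,
        "cells": cells,
        "anova": report,
        "normality": normality,
        "surrogates": pd.DataFrame(surr_rows),
        "sessions": manifest_sessions,
    }


def _surrogate_rows(res: SessionResult, config: RunConfig, statistics) -> list[dict]:
    mfdfa_params = fractal_mod.MfdfaParams(
        scale_min=config.mfdfa_scale_min,
        n_scales=config.mfdfa_n_scales,
        detrend_order=config.mfdfa_detrend_order,
        integrate_input=config.mfdfa_integrate_input,
    )
    sampen_params = fractal_mod.SampEnParams(m=config.sampen_m, r=config.sampen_r)
    stat_fns = {
        "hq_0": lambda x: fractal_mod.mfdfa(x, mfdfa_params).h_at(0.0),
        "sampen": lambda x: fractal_mod.sample_entropy(x, sampen_params),
    }
    rows = []
    trace = res.cop_trace
    for direction, series in (("AP", trace.cop_ap), ("ML", trace.cop_ml)):
        if series.size < 8 * mfdfa_params.scale_min:
            continue
        for name in statistics:
            tag = f"{res.participant}|{res.day}|{direction}|{name}".encode()
            seed = (config.seed * 7919 + zlib.crc32(tag)) % (2**31 - 1)
            try:
                out = surr_mod.surrogate_test(
                    series, stat_fns[name], name,
                    n_surrogates=config.n_surrogates,
                    level=config.surrogate_level,
                    seed=seed,
                )
            except surr_mod.SurrogateTestInvalidError:
                continue
            rows.append(
                {
                    "participant": res.participant,
                    "day": res.day,
                    "direction": direction,
                    "statistic": name,
                    "original": out.original_value,
                    "ci_low": out.ci_low,
                    "ci_high": out.ci_high,
                    "outside": out.outside,
                }
            )
    return rows


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline per the config and write all artifacts.

    Returns the output directory. With ``simulate=True`` a synthetic cohort
    is generated; otherwise raw CSVs are read from
    ``input_dir/<participant>/day<k>/<sensor>.csv``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    if config.simulate:
        spec = CohortSpec(
            n_pain_free=config.n_pain_free,
            n_csp=config.n_csp,
            days=tuple(config.days),
            session_minutes=config.session_minutes,
            window_minutes=config.window_minutes,
            seed=config.seed,
        )
        cohort = generate_cohort(spec)
        cohort.members.to_csv(out / "ground_truth_members.csv", index=False)
    else:
        if not config.input_dir or not Path(config.input_dir).is_dir():
            raise FileNotFoundError(
                f"input_dir {config.input_dir!r} does not exist and simulate=false"
            )
        cohort = _cohort_from_disk(config)
    logger.info(
        "pipeline start: lever_mm=%s lowpass=%s Hz gravity=%s Hz smooth=%s/%s "
        "window=%s min threshold=%s m/s^2 guard=%s s detrend_order=%s",
        config.lever_mm, config.lowpass_cutoff_hz, config.gravity_cutoff_hz,
        config.acc_smooth_samples, config.rv_smooth_samples,
        config.window_minutes, config.threshold_ms2, config.guard_seconds,
        config.mfdfa_detrend_order,
    )
    results = analyze_cohort(cohort, config)
    results["features"].to_csv(out / "features.csv", index=False)
    results["windows"].to_csv(out / "windows.csv", index=False)
    results["cells"].to_csv(out / "cells.csv", index=False)
    results["anova"].to_csv(out / "anova.csv", index=False)
    results["anova"].to_json(out / "anova.json", orient="records", indent=2)
    results["normality"].to_csv(out / "normality.csv", index=False)
    if not results["surrogates"].empty:
        results["surrogates"].to_csv(out / "surrogates.csv", index=False)
    manifest = {
        "config_hash": config.config_hash(),
        "n_participants": int(
            results["features"]["participant"].nunique()
        ),
        "n_sessions": len(results["sessions"]),
        "sessions": results["sessions"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _cohort_from_disk(config: RunConfig):
    """Minimal disk-backed cohort: directory layout
    input_dir/<participant>__<group>/day<k>/{accelerometer,rotation_vector,magnetometer}.csv
    """
    from dataclasses import dataclass as _dc

    root = Path(config.input_dir)
    sessions = []
    for pdir in sorted(root.iterdir()):
        if not pdir.is_dir() or "__" not in pdir.name:
            continue
        participant, group = pdir.name.split("__", 1)
        for ddir in sorted(pdir.glob("day*")):
            day = int(ddir.name[3:])
            streams = {
                kind: read_sensor_csv(ddir / f"{kind}.csv", kind, rate)
                for kind, rate in (
                    ("accelerometer", 100.0),
                    ("rotation_vector", 100.0),
                    ("magnetometer", 50.0),
                )
                if (ddir / f"{kind}.csv").exists()
            }
            sessions.append((participant, group, day, streams))
    if not sessions:
        raise FileNotFoundError(f"no sessions found under {root}")

    class DiskCohort:
        def iter_sessions(self):
            for participant, group, day, streams in sessions:
                yield participant, group, day, _StreamsOnly(streams)

    @_dc
    class _StreamsOnly:
        streams: dict

    return DiskCohort()


def export_cohort_csv(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort's raw streams in the ingest CSV dialect plus the
    ground-truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for participant, group, day, rec in cohort.iter_sessions():
        ddir = out / f"{participant}__{group}" / f"day{day}"
        ddir.mkdir(parents=True, exist_ok=True)
        for kind, stream in rec.streams.items():
            write_sensor_csv(stream, ddir / f"{kind}.csv")
    cohort.ground_truth().to_csv(out / "ground_truth.csv", index=False)
    return out
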