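"""Run configuration: every tunable the pipeline uses, serializable to YAML
so each output directory carries the exact settings that produced it."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # ingest / synchronization
    resample_rate_hz: float = 100.0
    # accelerometer / rotation-vector preprocessing
    lowpass_cutoff_hz: float = 10.0
    gravity_cutoff_hz: float = 0.3
    acc_smooth_samples: int = 150
    rv_smooth_samples: int = 5
    window_minutes: float = 15.0
    threshold_ms2: float = 2.0
    guard_seconds: float = 0.5
    # COP projection
    lever_mm: float = 500.0
    ellipse_ap_mm: float = 25.0
    ellipse_ml_mm: float = 18.0
    # features
    sway_area_raw: bool = False
    # nonlinear measures
    mfdfa_scale_min: int = 5
    mfdfa_n_scales: int = 30
    mfdfa_detrend_order: int = 1
    mfdfa_integrate_input: bool = True
    sampen_m: int = 4
    sampen_r: float = 0.2
    min_window_samples: int = 64  # windows with fewer retained samples skipped
    # surrogate testing
    n_surrogates: int = 100
    surrogate_level: float = 0.95
    run_surrogates: bool = False
    # statistics
    sphericity_correction: str = "auto"
    # cohort simulation
    simulate: bool = True
    n_pain_free: int = 6
    n_csp: int = 10
    days: tuple[int, ...] = (1, 3, 5)
    session_minutes: float = 300.0
    seed: int = 0
    # io
    input_dir: str | None = None
    output_dir: str = "trunksway_run"
    verbosity: int = 1

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "days" in kwargs:
            kwargs["days"] = tuple(kwargs["days"])
        return cls(**kwargs)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["days"] = list(d["days"])
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (io paths and verbosity
        excluded, so the same analysis in two directories hashes equally)."""
        d = self.as_dict()
        for key in ("input_dir", "output_dir", "verbosity"):
            d.pop(key)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
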