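"""Recording and report I/O, run configuration, and provenance hashing.

Recordings travel as two-column delimited text (time_s, amplitude) with
a CSV cohort manifest (subject_id, condition, vas, label, path).  The
bedside-monitor capture format of the original study is not publicly
specified, so generic delimited text is the interchange format.
Evaluation reports are JSON with the fully resolved run configuration
embedded, so every artifact records the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InvalidParameterError
from .model import CNNConfig, PainIndexSeries, TrainConfig
from .preprocess import FilterSpec
from .spectrogram import SpectrogramParams
from .synth import PPGRecording, SynthCohortParams

__all__ = [
    "RunConfig",
    "EvalSettings",
    "config_hash",
    "read_recording",
    "write_recording",
    "write_cohort",
    "read_manifest",
    "write_index_series",
    "write_eval_report",
    "validate_report_dict",
]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    return obj


def config_hash(obj) -> str:
    """SHA-256 of the canonical JSON form of a configuration object."""
    payload = json.dumps(_to_jsonable(obj), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class EvalSettings:
    k: int = 5
    val_fraction: float = 0.1
    n_perm: int = 100
    n_boot: int = 0
    level: str = "patch"


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved pipeline configuration, one section per stage."""

    cohort: SynthCohortParams = field(default_factory=SynthCohortParams)
    filter: FilterSpec = field(default_factory=FilterSpec)
    stft: SpectrogramParams = field(default_factory=SpectrogramParams)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalSettings = field(default_factory=EvalSettings)
    seed: int = 0

    def validate(self) -> None:
        """Cross-section consistency, checked before any stage runs."""
        self.cnn.validate()
        self.filter.validate_for_fs(self.cohort.fs)
        self.stft.validate(self.cohort.fs)
        if self.stft.n_freq_bins != self.cnn.input_size or \
                self.stft.n_time_frames != self.cnn.input_size:
            raise ConfigError(
                f"spectrogram yields {self.stft.n_freq_bins}x"
                f"{self.stft.n_time_frames} patches but the CNN expects "
                f"{self.cnn.input_size}x{self.cnn.input_size}")

    @property
    def hash(self) -> str:
        return config_hash(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {
            "cohort": SynthCohortParams, "filter": FilterSpec,
            "stft": SpectrogramParams, "cnn": CNNConfig,
            "train": TrainConfig, "eval": EvalSettings,
        }
        kwargs = {}
        for name, klass in sections.items():
            entries = dict(raw.get(name, {}))
            for key, value in entries.items():
                if isinstance(value, list):
                    entries[key] = tuple(value)
            kwargs[name] = klass(**entries)
        kwargs["seed"] = int(raw.get("seed", 0))
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return _to_jsonable(self)


def write_recording(rec: PPGRecording, path) -> None:
    t = np.arange(rec.samples.size) / rec.fs
    pd.DataFrame({"time_s": t, "amplitude": rec.samples}).to_csv(path, index=False)


def read_recording(path, format: str = "csv", *, subject_id: str | None = None,
                   condition: str = "baseline", vas: int | None = None) -> PPGRecording:
    """Load a recording from two-column delimited text.

    Sampling must be uniform: the maximum timestamp jitter against the
    inferred uniform grid must be below half a sample period.
    """
    if format != "csv":
        raise InvalidParameterError(
            f"unsupported recording format {format!r}; delimited text (csv) "
            "is the supported interchange format")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ConfigError(f"{path}: expected two columns (time_s, amplitude)")
    t = df.iloc[:, 0].to_numpy(dtype=np.float64)
    x = df.iloc[:, 1].to_numpy(dtype=np.float64)
    if t.size < 2:
        raise ConfigError(f"{path}: need at least two samples")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ConfigError(f"{path}: non-increasing timestamps")
    grid = t[0] + dt * np.arange(t.size)
    if np.max(np.abs(t - grid)) >= dt / 2:
        raise ConfigError(f"{path}: non-uniform sampling (jitter >= half a period)")
    return PPGRecording(samples=x, fs=1.0 / dt,
                        subject_id=subject_id or Path(path).stem,
                        condition=condition, vas=vas)


def write_cohort(recordings, out_dir) -> Path:
    """One CSV per recording plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        name = f"{rec.subject_id}_{rec.condition}.csv"
        write_recording(rec, out_dir / name)
        rows.append({"subject_id": rec.subject_id, "condition": rec.condition,
                     "vas": rec.vas, "label": rec.label, "path": name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path) -> list[PPGRecording]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    recordings = []
    for row in df.itertuples():
        vas = None if pd.isna(row.vas) else int(row.vas)
        recordings.append(read_recording(
            manifest_path.parent / row.path, subject_id=str(row.subject_id),
            condition=str(row.condition), vas=vas))
    return recordings


def write_index_series(series_list, path) -> None:
    """Index CSV: one row per scored 10-s patch."""
    if isinstance(series_list, PainIndexSeries):
        series_list = [series_list]
    rows = []
    for s in series_list:
        for i, (t0, v) in enumerate(zip(s.start_times_s, s.values)):
            rows.append({"subject_id": s.subject_id, "condition": s.condition,
                         "patch_index": i, "start_time_s": t0, "index": v})
    pd.DataFrame(rows).to_csv(path, index=False)


_REPORT_REQUIRED = {
    "level": str, "auc": float, "cutoff": float, "sensitivity": float,
    "specificity": float, "balanced_accuracy": float, "n_pos": int, "n_neg": int,
}


def validate_report_dict(d: dict) -> None:
    """Schema check for one serialized EvalReport."""
    for key, typ in _REPORT_REQUIRED.items():
        if key not in d:
            raise ConfigError(f"report missing required field {key!r}")
        if typ is float and not isinstance(d[key], (int, float)):
            raise ConfigError(f"report field {key!r} must be numeric")
        if typ is int and not isinstance(d[key], int):
            raise ConfigError(f"report field {key!r} must be an integer")
        if typ is str and not isinstance(d[key], str):
            raise ConfigError(f"report field {key!r} must be a string")


def write_eval_report(reports, path, config: RunConfig | None = None,
                      extra: dict | None = None) -> None:
    """JSON report with the resolved configuration embedded for provenance."""
    if hasattr(reports, "to_dict"):
        reports = reports.to_dict()
    payload = {"reports": _to_jsonable(reports)}
    if config is not None:
        payload["config"] = config.to_dict()
        payload["config_hash"] = config.hash
    if extra:
        payload["extra"] = _to_jsonable(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_eval_report(path) -> dict:
    return json.loads(Path(path).read_text())
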