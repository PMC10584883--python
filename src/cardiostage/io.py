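"""File formats, pipeline configuration and run manifests.

Delimited files are comma-separated UTF-8 with a mandatory header row and
Unix newlines; hypnograms are plain text (one label per line); metrics and
agreement results are JSON.  EDF reading is optional (synthetic CSV input
is the canonical path) and goes through :mod:`mne` when available.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hypnogram import Hypnogram, read_hypnogram, write_hypnogram  # re-export
from .features import FEATURE_COLUMNS
from .stager import StagerConfig
from .synthetic import CohortConfig, SignalBundle


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """Top-level run configuration, round-trippable through YAML."""

    input_dir: str = "."
    output_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"
    cohort: dict = field(default_factory=dict)     # CohortConfig overrides
    stager: dict = field(default_factory=dict)     # StagerConfig overrides
    fast: bool = True                              # desk-scale stager profile

    _KNOWN = ("input_dir", "output_dir", "seed", "log_level", "cohort",
              "stager", "fast")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls._KNOWN)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self._KNOWN}
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def cohort_config(self) -> CohortConfig:
        try:
            return CohortConfig(seed=self.seed, **self.cohort)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"cohort configuration: {exc}") from exc

    def stager_config(self) -> StagerConfig:
        try:
            base = StagerConfig.fast if self.fast else StagerConfig
            return base(seed=self.seed, **self.stager)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"stager configuration: {exc}") from exc


# -------------------------------------------------------------------------
# tables
# -------------------------------------------------------------------------

def write_features(features: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    if "stage" in features.columns:
        cols.append("stage")
    features[cols].to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing feature columns {sorted(missing)}")
    return df


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default,
                  allow_nan=True)
        fh.write("\n")


# -------------------------------------------------------------------------
# run manifest
# -------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Auditable record of one pipeline stage run."""

    stage: str
    config_hash: str
    version: str
    started: float = field(default_factory=time.time)
    outputs: dict[str, str] = field(default_factory=dict)
    status: str = "running"

    @classmethod
    def start(cls, stage: str, config: PipelineConfig) -> "RunManifest":
        from . import __version__

        blob = json.dumps({k: getattr(config, k) for k in config._KNOWN},
                          sort_keys=True, default=str).encode()
        return cls(stage=stage, config_hash=hashlib.sha256(blob).hexdigest(),
                   version=__version__)

    def record(self, *paths: str | Path) -> None:
        for p in paths:
            p = Path(p)
            if p.exists():
                self.outputs[str(p)] = _sha256(p)

    def finish(self, outdir: str | Path, status: str = "ok") -> None:
        self.status = status
        write_json(dataclasses.asdict(self), Path(outdir) / f"manifest_{self.stage}.json")


# -------------------------------------------------------------------------
# optional EDF input
# -------------------------------------------------------------------------

def read_psg_edf(path: str | Path, channel_map: dict[str, str],
                 beats_csv: str | Path | None = None) -> SignalBundle:
    """Read respiration and EMG channels from an EDF recording.

    ``channel_map`` must name the ``respiration`` and ``emg`` channels as
    stored in the file; beats come from a sidecar CSV (time_s, rri_ms)
    since R-peak detection from raw ECG is out of scope.  Requires
    :mod:`mne`; the synthetic CSV layout is the canonical input path.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is normally present
        raise RuntimeError("EDF support requires the optional mne dependency") from exc
    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    except Exception as exc:
        raise ValueError(f"could not parse EDF file {path}: {exc}") from exc
    available = list(raw.ch_names)
    for role in ("respiration", "emg"):
        if role not in channel_map:
            raise ValueError(f"channel_map must name a {role!r} channel")
        if channel_map[role] not in available:
            raise ValueError(
                f"channel {channel_map[role]!r} not in EDF; available: {available}"
            )
    resp_raw = raw.copy().pick([channel_map["respiration"]]).load_data()
    emg_raw = raw.copy().pick([channel_map["emg"]]).load_data()
    resp = resp_raw.get_data()[0]
    emg = emg_raw.get_data()[0]
    fs_r = float(resp_raw.info["sfreq"])
    fs_e = float(emg_raw.info["sfreq"])
    if beats_csv is not None:
        beats = pd.read_csv(beats_csv)
        rri = beats["rri_ms"].to_numpy(dtype=float)
        end_t = beats["time_s"].to_numpy(dtype=float)
        beat_times = np.concatenate([[end_t[0] - rri[0] / 1000.0], end_t])
    else:
        beat_times = np.array([])
        rri = np.array([])
    return SignalBundle(
        beat_times=beat_times, rri=rri, respiration=resp, emg=emg,
        resp_sampling_hz=fs_r, emg_sampling_hz=fs_e,
        lv_mask=np.zeros(resp.size, dtype=bool),
        lv_mask_emg=np.zeros(emg.size, dtype=bool),
        meta={"source": str(path)},
    )
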