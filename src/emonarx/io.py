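"""Dataset containers and run configuration.

Recordings are stored in an HDF5 container (one file per dataset, one group
per subject, one subgroup per trial, one dataset per channel; sampling rate,
quality label and stimulus annotations as attributes), with a long-format
CSV export (subject, trial, time_s, channel, value) for interoperability.
The run configuration round-trips through YAML and hashes itself so every
output can be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .features import FEATURE_NAMES, FeatureSet
from .protocol import ProtocolConfig
from .search import GaConfig
from .simulate import RawRecording, StimulusEvent

__all__ = ["save_recordings", "load_recordings", "recordings_to_long_csv",
           "save_feature_sets", "load_feature_sets", "RunConfig"]


class DatasetError(ValueError):
    """A container violates the documented layout."""


def save_recordings(path, recordings: Sequence[RawRecording]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layout"] = "emonarx-recordings-v1"
        for rec in recordings:
            g = f.require_group(rec.subject).create_group(f"trial_{rec.trial:03d}")
            for name in ("gsr", "pulse", "rsp", "intensity"):
                g.create_dataset(name, data=getattr(rec, name))
            g.attrs["fs"] = rec.fs
            g.attrs["quality"] = rec.quality
            g.attrs["trial"] = rec.trial
            g.attrs["practice"] = rec.practice
            g.attrs["trimmed"] = rec.trimmed
            g.attrs["annotations"] = json.dumps(
                [[a.onset_s, a.offset_s, a.level] for a in rec.annotations])


def load_recordings(path) -> list[RawRecording]:
    """Load a validated dataset; schema violations name the subject/trial."""
    out: list[RawRecording] = []
    with h5py.File(path, "r") as f:
        for subject in sorted(f):
            for trial_key in sorted(f[subject]):
                g = f[subject][trial_key]
                where = f"{subject}/{trial_key}"
                missing = [c for c in ("gsr", "pulse", "intensity")
                           if c not in g]
                if missing:
                    raise DatasetError(
                        f"{where}: missing channels {missing}")
                for attr in ("fs", "quality", "trial"):
                    if attr not in g.attrs:
                        raise DatasetError(f"{where}: missing attribute "
                                           f"{attr!r}")
                try:
                    raw = json.loads(g.attrs.get("annotations", "[]"))
                    annotations = tuple(StimulusEvent(*row) for row in raw)
                except (TypeError, ValueError) as exc:
                    raise DatasetError(
                        f"{where}: malformed annotations ({exc})") from exc
                n = g["gsr"].shape[0]
                bad = [c for c in ("pulse", "rsp", "intensity")
                       if c in g and g[c].shape[0] != n]
                if bad:
                    raise DatasetError(f"{where}: channel length mismatch "
                                       f"for {bad}")
                # a missing respiration belt is tolerated: the channel loads
                # as NaN and every RSP feature comes out pre-masked
                rsp = g["rsp"][()] if "rsp" in g else np.full(n, np.nan)
                out.append(RawRecording(
                    subject=subject, trial=int(g.attrs["trial"]),
                    quality=str(g.attrs["quality"]), fs=float(g.attrs["fs"]),
                    gsr=g["gsr"][()], pulse=g["pulse"][()], rsp=rsp,
                    intensity=g["intensity"][()], annotations=annotations,
                    practice=bool(g.attrs.get("practice", False)),
                    trimmed=bool(g.attrs.get("trimmed", False))))
    return out


def recordings_to_long_csv(path, recordings: Sequence[RawRecording]) -> None:
    frames = []
    for rec in recordings:
        t = rec.time_s
        for channel in ("gsr", "pulse", "rsp", "intensity"):
            frames.append(pd.DataFrame({
                "subject": rec.subject, "trial": rec.trial, "time_s": t,
                "channel": channel, "value": getattr(rec, channel)}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_feature_sets(path, feature_sets: Sequence[FeatureSet]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layout"] = "emonarx-features-v1"
        for fs in feature_sets:
            g = f.require_group(fs.subject).create_group(f"trial_{fs.trial:03d}")
            for name in FEATURE_NAMES:
                g.create_dataset(name, data=fs.features[name])
            g.create_dataset("intensity", data=fs.intensity)
            g.attrs["fs"] = fs.fs
            g.attrs["quality"] = fs.quality
            g.attrs["trial"] = fs.trial
            g.attrs["practice"] = fs.practice
            g.attrs["available"] = json.dumps(
                {k: bool(v) for k, v in fs.available.items()})


def load_feature_sets(path) -> list[FeatureSet]:
    out: list[FeatureSet] = []
    with h5py.File(path, "r") as f:
        for subject in sorted(f):
            for trial_key in sorted(f[subject]):
                g = f[subject][trial_key]
                out.append(FeatureSet(
                    subject=subject, trial=int(g.attrs["trial"]),
                    quality=str(g.attrs["quality"]), fs=float(g.attrs["fs"]),
                    features={n: g[n][()] for n in FEATURE_NAMES},
                    intensity=g["intensity"][()],
                    available=json.loads(g.attrs["available"]),
                    practice=bool(g.attrs.get("practice", False))))
    return out


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable description of an analysis run."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    ga: GaConfig = field(default_factory=GaConfig)
    bounds: tuple[int, int] = (1, 11)
    selection_delta: float = 0.01
    max_features: int = 3
    n_units: int = 8
    search_mode: str = "free-run"
    final_mode: str = "free-run"
    decimation_factor: int = 100
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["protocol"] = ProtocolConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw["protocol"].items()})
        raw["ga"] = GaConfig(**raw["ga"])
        raw["bounds"] = tuple(raw["bounds"])
        return cls(**raw)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
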