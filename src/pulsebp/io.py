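"""Readers/writers for waveform and tabular files, run configuration and
manifests.

The native interchange format is delimited text: waveforms as one
amplitude sample per row under a (subject_id, segment_id, fs_hz, sample)
header, demographics/targets/features/predictions as ordinary CSV
tables.  Every run writes a JSON manifest (config hash, seeds, package
version, column order) sufficient to reproduce its outputs exactly; the
manifest deliberately carries no timestamps so repeated runs are
byte-identical.

PulseDB's MAT v7.3 containers are out of scope; adapters should map a
container to ``list[RawSignal]`` plus demographics/targets DataFrames
matching the schemas below and feed them to the same pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .embedder import EmbedderConfig
from .modeling import BaseSearchSpace, CVConfig, MetaConfig, PipelineConfig
from .pipeline import PreprocessConfig
from .preprocess import RawSignal

__all__ = [
    "ParseError",
    "DEMOGRAPHICS_COLUMNS",
    "TARGETS_COLUMNS",
    "write_waveforms",
    "read_waveform_table",
    "read_tabular",
    "read_demographics",
    "read_targets",
    "RunConfig",
    "write_manifest",
]

DEMOGRAPHICS_COLUMNS = ["subject_id", "age", "gender", "height_cm",
                        "weight_kg", "bmi"]
TARGETS_COLUMNS = ["subject_id", "sbp", "dbp"]

_GENDER_TOKENS = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "0": "female",
}


class ParseError(ValueError):
    pass


def write_waveforms(records: Sequence[RawSignal], path) -> None:
    frames = []
    for rec in records:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "segment_id": rec.segment_id or "seg0",
                    "fs_hz": rec.fs_hz,
                    "sample": rec.samples,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_waveform_table(path) -> list[RawSignal]:
    """Parse a waveform CSV into RawSignals, citing line numbers on errors."""
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "segment_id": str},
        float_precision="round_trip",
    )
    required = {"subject_id", "fs_hz", "sample"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing header fields {sorted(missing)}")
    if "segment_id" not in df.columns:
        df["segment_id"] = "seg0"

    samples = pd.to_numeric(df["sample"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(samples.to_numpy(dtype=float)))
    if bad.size:
        line = int(bad[0]) + 2  # +1 header, +1 one-based
        raise ParseError(
            f"{path}: non-numeric or non-finite sample at line {line}"
        )
    fs = pd.to_numeric(df["fs_hz"], errors="coerce")
    bad_fs = np.flatnonzero(~(fs.to_numpy(dtype=float) > 0))
    if bad_fs.size:
        line = int(bad_fs[0]) + 2
        raise ParseError(f"{path}: fs_hz must be positive at line {line}")

    df["sample"] = samples
    df["fs_hz"] = fs
    records = []
    for (sid, seg), group in df.groupby(
        ["subject_id", "segment_id"], sort=False
    ):
        fs_vals = group["fs_hz"].unique()
        if fs_vals.size != 1:
            raise ParseError(
                f"{path}: inconsistent fs_hz within record {sid}/{seg}"
            )
        records.append(
            RawSignal(
                group["sample"].to_numpy(dtype=float),
                float(fs_vals[0]),
                subject_id=str(sid),
                segment_id=str(seg),
            )
        )
    return records


def _normalize_gender(value) -> str:
    token = str(value).strip().lower()
    if token in _GENDER_TOKENS:
        return _GENDER_TOKENS[token]
    raise ParseError(f"unknown gender token: {value!r}")


def read_tabular(path, schema: Sequence[str]) -> pd.DataFrame:
    """Typed CSV reader with schema check and gender normalization."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ParseError(f"{path}: duplicate subject_id {dupes}")
    if "gender" in df.columns:
        df["gender"] = [
            _normalize_gender(v) if pd.notna(v) else v for v in df["gender"]
        ]
    for c in schema:
        if c not in ("subject_id", "gender"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df[list(schema)]


def read_demographics(path) -> pd.DataFrame:
    return read_tabular(path, DEMOGRAPHICS_COLUMNS)


def read_targets(path) -> pd.DataFrame:
    return read_tabular(path, TARGETS_COLUMNS)


# ---------------------------------------------------------------------------
# run configuration


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ParseError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Every tunable default of the pipeline, YAML-round-trippable."""

    preprocess: PreprocessConfig = dataclasses.field(
        default_factory=PreprocessConfig
    )
    model: PipelineConfig = dataclasses.field(default_factory=PipelineConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples -> lists for YAML friendliness
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - {"preprocess", "model", "seed"}
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        pre = _build(PreprocessConfig, data.get("preprocess", {}))
        m = dict(data.get("model", {}))
        model = PipelineConfig(
            k_keep=m.pop("k_keep", 20),
            variants=tuple(m.pop("variants", ("xgboost", "lightgbm", "gbdt"))),
            embedder=_tupled(_build(EmbedderConfig, m.pop("embedder", {}))),
            base_space=_tupled(_build(BaseSearchSpace, m.pop("base_space", {}))),
            meta=_build(MetaConfig, m.pop("meta", {})),
            cv=_build(CVConfig, m.pop("cv", {})),
            min_pulses=m.pop("min_pulses", 3),
            seed=m.pop("seed", 0),
        )
        if m:
            raise ParseError(f"unknown config keys for model: {sorted(m)}")
        return cls(preprocess=pre, model=model, seed=int(data.get("seed", 0)))

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _tupled(obj):
    """Re-freeze list-valued fields (from YAML) back into tuples."""
    updates = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, list):
            updates[f.name] = tuple(v)
    return dataclasses.replace(obj, **updates) if updates else obj


def write_manifest(path, config: RunConfig, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "package": "pulsebp",
        "version": __version__,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
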