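"""Flat-file I/O: trial-log CSV round-tripping and YAML study config."""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .observer import CohortSpec
from .results import TrialRecord
from .scale import AcuityScale
from .study import StudyConfig

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "write_trial_log",
    "read_trial_log",
    "trial_records_to_frame",
    "load_config",
    "default_config_yaml",
]

TRIAL_LOG_COLUMNS = [
    "subject_id",
    "protocol",
    "eye",
    "test_rep",
    "trial",
    "phase",
    "distance_cm",
    "demand_logmar",
    "correct",
]


class SchemaError(ValueError):
    """A trial-log file does not match the expected schema."""


def trial_records_to_frame(
    records: list[TrialRecord],
    subject_id: int | str = 0,
    protocol: str = "",
    eye: str = "",
    test_rep: int = 1,
) -> pd.DataFrame:
    """Tag a protocol's trial log with its test identifiers."""
    rows = [
        {
            "subject_id": subject_id,
            "protocol": protocol,
            "eye": eye,
            "test_rep": test_rep,
            "trial": t.trial,
            "phase": t.phase,
            "distance_cm": t.distance_cm,
            "demand_logmar": t.demand_logmar,
            "correct": t.correct,
        }
        for t in records
    ]
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def write_trial_log(frame: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trial log missing column(s): {missing}")
    frame.to_csv(path, index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read a trial-log CSV, validating the schema.

    Empty files return an empty frame with a warning; a missing column
    raises :class:`SchemaError` naming it; unparseable values raise with
    the offending line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"trial log {path} is empty", stacklevel=2)
        return pd.DataFrame(columns=TRIAL_LOG_COLUMNS)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial log {path} missing column(s): {missing}")
    for col, kind in (("trial", int), ("demand_logmar", float)):
        try:
            df[col] = df[col].astype(kind)
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            lineno = int(bad[0]) + 2 if len(bad) else "?"  # header is line 1
            raise SchemaError(
                f"trial log {path}: malformed {col!r} value near line {lineno}"
            ) from exc
    df["correct"] = df["correct"].astype(bool)
    return df


def _dataclass_from_mapping(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**mapping)


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML study config (sections: study, cohort, scale)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    study_kwargs = dict(raw.get("study", {}))
    cohort = _dataclass_from_mapping(CohortSpec, raw.get("cohort", {}))
    scale = _dataclass_from_mapping(AcuityScale, raw.get("scale", {}))
    study_kwargs["cohort"] = cohort
    study_kwargs["scale"] = scale
    return _dataclass_from_mapping(StudyConfig, study_kwargs)


def default_config_yaml() -> str:
    """Fully resolved default configuration, as YAML text."""
    cfg = StudyConfig()
    doc = {
        "study": {
            f.name: getattr(cfg, f.name)
            for f in dataclasses.fields(StudyConfig)
            if f.name not in ("cohort", "scale")
        },
        "cohort": dataclasses.asdict(cfg.cohort),
        "scale": dataclasses.asdict(cfg.scale),
    }
    return yaml.safe_dump(doc, sort_keys=False)
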