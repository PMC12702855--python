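"""CSV/JSON artifact I/O with schema validation.

All artifacts are plain text so runs can be diffed.  Floats are written with
17 significant digits, which round-trips IEEE double exactly; every file
starts with a comment line embedding the configuration hash and seed so a
stored run is reconstructable.  Comment lines start with ``#`` and are
skipped on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import schema
from .errors import SchemaError
from .synthetic import TrialRecording

__all__ = [
    "read_trial",
    "write_trial",
    "read_manifest",
    "write_manifest",
    "read_features",
    "write_features",
    "write_json",
    "read_json",
]

_FLOAT_FMT = "%.17g"


def _write_csv(frame: pd.DataFrame, path: Path, meta: str | None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _check_columns(frame: pd.DataFrame, expected, path) -> None:
    missing = [c for c in expected if c not in frame.columns]
    extra = [c for c in frame.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: column mismatch (missing: {missing or 'none'}, "
            f"unexpected: {extra or 'none'})"
        )


def write_trial(trial: TrialRecording, path: str | Path, meta: str | None = None) -> None:
    _write_csv(trial.to_frame(), Path(path), meta)


def read_trial(path: str | Path, subject_id: str = "", trial_index: int = 0) -> TrialRecording:
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: cannot parse trial CSV ({exc})") from exc
    _check_columns(frame, schema.TRIAL_COLUMNS, path)
    return TrialRecording.from_frame(frame, subject_id=subject_id, trial_index=trial_index)


def write_manifest(manifest: pd.DataFrame, path: str | Path, meta: str | None = None) -> None:
    _check_columns(manifest, schema.MANIFEST_COLUMNS, path)
    _write_csv(manifest, Path(path), meta)


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    path = Path(path)
    try:
        manifest = pd.read_csv(path, comment="#", dtype={"fma_ul": "Int64"})
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: cannot parse manifest ({exc})") from exc
    _check_columns(manifest, schema.MANIFEST_COLUMNS, path)
    if check_paths:
        base = path.parent
        for row_i, row in manifest.iterrows():
            for k in range(1, 6):
                rel = row[f"trial_{k}"]
                if not (base / rel).exists():
                    raise SchemaError(
                        f"{path} row {row_i} (subject {row['subject_id']}): "
                        f"trial file {rel!r} not found"
                    )
    return manifest


def write_features(features: pd.DataFrame, path: str | Path, meta: str | None = None) -> None:
    expected = list(schema.FEATURE_TABLE_META) + list(schema.FEATURE_NAMES)
    _check_columns(features, expected, path)
    _write_csv(features[expected], Path(path), meta)


def read_features(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        features = pd.read_csv(path, comment="#", dtype={"fma_ul": "Int64"})
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: cannot parse feature table ({exc})") from exc
    expected = list(schema.FEATURE_TABLE_META) + list(schema.FEATURE_NAMES)
    _check_columns(features, expected, path)
    return features


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
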