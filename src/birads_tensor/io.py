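"""File formats: annotation CSV, model checkpoints, results JSON, YAML config.

All formats are documented in docs/FORMATS.md. Results JSON is written
with sorted keys and a fixed layout so that identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import CHARACTERISTICS, AnnotationRecord, SchemaError
from .tucker import TuckerModel

__all__ = [
    "read_annotations",
    "save_checkpoint",
    "load_checkpoint",
    "write_results",
    "load_config",
    "ConfigError",
    "CHECKPOINT_SCHEMA_VERSION",
]

_REQUIRED_COLUMNS = ("case_id", "image_id", "annotator", "pathology", *CHARACTERISTICS)
CHECKPOINT_SCHEMA_VERSION = 1


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation CSV into validated records.

    The file must have exactly the documented columns; unknown columns
    are rejected and malformed rows are reported with their line number.
    """
    df = pd.read_csv(path, dtype=str)
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    unknown = set(df.columns) - set(_REQUIRED_COLUMNS)
    if unknown:
        raise SchemaError(f"{path}: unknown columns {sorted(unknown)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        values = dict(zip(df.columns, row))
        chars = {c: values[c] for c in CHARACTERISTICS}
        bad = [c for c, v in chars.items() if not isinstance(v, str) or not v]
        if bad:
            raise SchemaError(f"{path}:{lineno}: missing characteristic value(s) {bad}")
        try:
            records.append(
                AnnotationRecord(
                    case_id=str(values["case_id"]),
                    image_id=str(values["image_id"]),
                    annotator=str(values["annotator"]),
                    pathology=str(values["pathology"]),
                    characteristics=chars,
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    return records


def save_checkpoint(model: TuckerModel, path: str | Path, config_echo: dict | None = None) -> None:
    """Save a model as a single-file npz container of named arrays."""
    np.savez(
        path,
        schema_version=np.array(CHECKPOINT_SCHEMA_VERSION),
        entity_embeddings=model.entity_embeddings,
        relation_embeddings=model.relation_embeddings,
        core=model.core,
        entities=np.array(model.entities, dtype=object),
        relations=np.array(model.relations, dtype=object),
        config_json=np.array(json.dumps(config_echo or {}, sort_keys=True)),
    )


def load_checkpoint(path: str | Path) -> tuple[TuckerModel, dict]:
    with np.load(path, allow_pickle=True) as data:
        version = int(data["schema_version"])
        if version != CHECKPOINT_SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema version {version}")
        model = TuckerModel(
            entity_embeddings=data["entity_embeddings"],
            relation_embeddings=data["relation_embeddings"],
            core=data["core"],
            entities=[str(e) for e in data["entities"]],
            relations=[str(r) for r in data["relations"]],
        )
        config = json.loads(str(data["config_json"]))
    return model, config


def write_results(results: dict, path: str | Path) -> None:
    """Deterministic results JSON: sorted keys, fixed float formatting."""
    Path(path).write_text(json.dumps(results, sort_keys=True, indent=2) + "\n")


class ConfigError(ValueError):
    """A YAML config file failed validation; the message names the key."""


def load_config(path: str | Path, required: tuple[str, ...] = ()) -> dict:
    """Load a YAML config mapping; ``required`` keys must be present."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for key in required:
        if key not in raw:
            raise ConfigError(f"{path}: missing required key {key!r}")
    return raw
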