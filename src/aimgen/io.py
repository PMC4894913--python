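"""Trial-table CSV dialect, flat config files, and run manifests.

The trial table is plain CSV with a versioned comment header on the first
line (``# aimgen.trials.v1``) followed by the standard columns.  Absent
values (no aim report, no cursor feedback) are empty fields.  Angles are
degrees in (-180, 180], CCW positive; out-of-range angles are normalized on
ingest with a warning.

Config files are flat ``key: value`` mappings (a YAML subset); keys mirror
the :class:`~aimgen.simulate.CohortConfig` fields plus ``seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .protocol import BLOCK_LABELS
from .simulate import CohortConfig, TRIAL_COLUMNS

TRIAL_TABLE_VERSION = "aimgen.trials.v1"

_ANGLE_COLUMNS = ("target_direction", "reach_angle", "cursor_angle")


class SchemaError(ValueError):
    """Trial table or config violates the documented schema."""


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table with the versioned header line."""
    missing = set(TRIAL_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"trial table missing columns: {sorted(missing)}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {TRIAL_TABLE_VERSION}\n")
        table.to_csv(fh, index=False, columns=list(TRIAL_COLUMNS))


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table; inverse of :func:`write_trial_table`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"# {TRIAL_TABLE_VERSION}":
            raise SchemaError(
                f"{path.name}: unrecognized trial-table header {header!r}; "
                f"expected '# {TRIAL_TABLE_VERSION}'"
            )
        table = pd.read_csv(fh)
    missing = set(TRIAL_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")
    table["reported_landmark"] = table["reported_landmark"].astype("Int64")
    validate_trial_table(table, name=path.name)
    return table[list(TRIAL_COLUMNS)]


def validate_trial_table(table: pd.DataFrame, name: str = "trial table") -> None:
    """Schema checks; raises :class:`SchemaError` naming row and column.

    Normalizes angle columns into (-180, 180] in place (with a warning) and
    warns about rotation trials missing an aim report.
    """
    bad_label = ~table["block_label"].isin(BLOCK_LABELS)
    if bad_label.any():
        row = int(table.index[bad_label][0])
        raise SchemaError(
            f"{name}: row {row}, column 'block_label': unknown label "
            f"{table.loc[row, 'block_label']!r}"
        )
    for col in ("subject_id", "group_name", "trial_index", "reach_angle"):
        null = table[col].isna()
        if null.any():
            row = int(table.index[null][0])
            raise SchemaError(f"{name}: row {row}, column {col!r}: missing value")
    for col in _ANGLE_COLUMNS:
        vals = table[col].to_numpy(dtype=float)
        out = ~np.isnan(vals) & ((vals <= -180.0) | (vals > 180.0))
        if out.any():
            warnings.warn(
                f"{name}: {int(out.sum())} angle(s) in {col!r} outside (-180, 180]; "
                "normalizing",
                stacklevel=2,
            )
            wrapped = (vals + 180.0) % 360.0 - 180.0
            wrapped[wrapped == -180.0] = 180.0
            table[col] = np.where(np.isnan(vals), vals, wrapped)
    unreported = (table["block_label"] == "rotation") & table["reported_landmark"].isna()
    if unreported.any():
        warnings.warn(
            f"{name}: {int(unreported.sum())} rotation trial(s) missing an aim "
            "report (flagged; implicit will be absent there)",
            stacklevel=2,
        )


def load_config(path) -> tuple[CohortConfig, dict]:
    """Load a flat key:value config file.

    Returns the cohort config plus a dict of non-simulator keys (``seed``,
    analysis options).  Unknown keys are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a flat key: value mapping")
    sim_fields = {f.name for f in dataclasses.fields(CohortConfig)}
    extra_allowed = {"seed", "min_subjects", "cosine_period"}
    unknown = set(raw) - sim_fields - extra_allowed
    if unknown:
        raise SchemaError(f"{path}: unknown config keys: {sorted(unknown)}")
    sim_kwargs = {k: v for k, v in raw.items() if k in sim_fields}
    if "groups" in sim_kwargs:
        sim_kwargs["groups"] = tuple(sim_kwargs["groups"])
    other = {k: v for k, v in raw.items() if k in extra_allowed}
    return CohortConfig(**sim_kwargs), other


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, *, config: CohortConfig, seed: int, artifacts: dict) -> dict:
    """Write a run manifest (config snapshot, seed, version, file digests)."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "artifacts": {name: file_digest(p) for name, p in artifacts.items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest
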