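"""Delimited-text table formats, Sankey export, and run manifests.

Tables are CSV with a single versioned comment header line, so they stay
inspectable and diff-able at desk scale.  Writing then reading then writing
reproduces identical bytes; unknown columns are preserved.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

TABLE_HEADER = "# sivskit-table v1"

#: Columns every cohort-derived table must carry.
REQUIRED_COLUMNS = ("cell_id", "animal", "tissue", "subset")


class SchemaError(ValueError):
    """A table is missing required structure."""


def table_to_bytes(table: pd.DataFrame) -> bytes:
    buf = _io.StringIO()
    buf.write(TABLE_HEADER + "\n")
    table.to_csv(buf, index=False)
    return buf.getvalue().encode()


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(table_to_bytes(table))
    return path


def read_table(
    path: str | Path, required_columns: tuple[str, ...] = REQUIRED_COLUMNS
) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if first != TABLE_HEADER:
            raise SchemaError(
                f"{path}: expected header line {TABLE_HEADER!r}, got {first!r}"
            )
        table = pd.read_csv(fh)
    for col in required_columns:
        if col not in table.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return table


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def config_digest(config_dict: dict) -> str:
    canonical = json.dumps(config_dict, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_manifest(
    out_dir: str | Path,
    study_name: str,
    seed: int,
    config_dict: dict,
    outputs: list[Path],
    version: str,
) -> Path:
    """Record enough to re-run bit-identically: seed, config hash, package
    version, and per-output checksums."""
    manifest = {
        "study": study_name,
        "seed": seed,
        "config_sha256": config_digest(config_dict),
        "sivskit_version": version,
        "outputs": {p.name: sha256_of(p) for p in sorted(outputs)},
    }
    return write_json(manifest, Path(out_dir) / "manifest.json")
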