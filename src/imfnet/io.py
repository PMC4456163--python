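"""TSV/JSON readers and writers and the run manifest.

All tabular formats are UTF-8, tab-separated, Unix newlines, header row,
first column = row ids.  Writer/reader pairs round-trip valid data exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd


def read_matrix_tsv(path) -> pd.DataFrame:
    """Rectangular numeric matrix with row ids in the first column.

    Errors name the duplicate id or the offending cell (row id, column).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        rows, ids = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise ValueError(f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {ncol})")
            ids.append(fields[0])
            rows.append(fields[1:])
    dup = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate row id {dup[0]!r}")
    values = np.empty((len(rows), ncol - 1))
    for j in range(ncol - 1):
        for i, row in enumerate(rows):
            try:
                values[i, j] = float(row[j])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: cell (row {ids[i]!r}, column {header[j + 1]!r}) "
                    f"is not numeric: {row[j]!r}"
                ) from exc
    return pd.DataFrame(values, index=pd.Index(ids, name=header[0]), columns=header[1:])


def write_matrix_tsv(df: pd.DataFrame, path, index_name: str = "id") -> None:
    out = df.copy()
    out.index.name = out.index.name or index_name
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_table_tsv(path) -> pd.DataFrame:
    """General (possibly non-numeric) table, first column as index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_groups_tsv(path) -> pd.Series:
    df = read_table_tsv(path)
    col = df.columns[0]
    groups = df[col]
    bad = set(groups.unique()) - {"high", "low"}
    if bad:
        raise ValueError(f"{path}: group labels must be 'high'/'low', found {sorted(bad)}")
    return groups


def write_groups_tsv(groups: pd.Series, path) -> None:
    df = pd.DataFrame({"group": groups})
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted once per pipeline run."""

    version: str
    seed: int | None
    config: dict
    started: str = ""
    finished: str = ""
    checksums: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)

    def start(self):
        self.started = datetime.now(timezone.utc).isoformat()

    def finish(self):
        self.finished = datetime.now(timezone.utc).isoformat()

    def record_file(self, path: Path):
        self.checksums[Path(path).name] = sha256_file(path)

    def write(self, path):
        write_json(asdict(self), path)
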