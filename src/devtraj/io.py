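"""Plain-text I/O: TSV tables, GMT gene sets, checksums, atomic JSON."""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path
from typing import Mapping

import pandas as pd

FLOAT_FMT = "%.10g"  # fixed formatting so reruns are byte-identical


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    return path


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_gmt(sets: Mapping[str, frozenset | set | list], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            genes = sorted(sets[name])
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, frozenset]:
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = frozenset(g for g in fields[2:] if g)
    return sets


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json_atomic(obj, path: str | Path) -> Path:
    """Write JSON via a temp file + rename so readers never see a partial file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    os.replace(tmp, path)
    return path
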