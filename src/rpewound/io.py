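"""Tab-delimited I/O for expression matrices, sample sheets, gene sets and Ct tables.

All matrices are written with the feature id in the first column and one
column per sample; files are UTF-8, unquoted, and may start with ``#``
comment lines carrying provenance (stage, seed, config hash). Readers skip
those lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

SAMPLE_SHEET_COLUMNS = ["sample_id", "donor", "passage", "day", "density", "treatment"]


def provenance_header(stage: str, seed: int | None = None, config: Mapping | None = None) -> str:
    """Build a one-line ``#`` comment recording stage, seed and a config hash."""
    parts = [f"# rpewound stage={stage}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        parts.append(f"config_sha={digest}")
    return " ".join(parts)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id",
                 header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(header_comment.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate feature ids in {path}: {dups}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a plain (non-indexed) table such as a sample sheet or annotation."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(header_comment.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = read_table(path)
    missing = [c for c in ("sample_id", "donor", "passage", "day") if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {path} lacks required columns: {missing}")
    return sheet


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write gene sets in GMT format: name, description, then one member per field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT file into ``{name: {"description": str, "members": [symbols]}}``."""
    out: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line in {path}: {line[:80]!r}")
            name, desc, *members = fields
            out[name] = {"description": desc, "members": [m for m in members if m]}
    return out


def read_ct_table(path: str | Path) -> pd.DataFrame:
    ct = read_table(path)
    missing = [c for c in ("gene", "sample", "ct") if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table {path} lacks required columns: {missing}")
    return ct
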