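"""File formats: wide TSV matrices, metadata/QC tables, GMT gene sets, YAML config.

All tabular output is TSV (UTF-8, ``NA`` for missing) to avoid escaping
commas in gene symbols.  Round trips are lossless including the missingness
pattern.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "read_config",
    "write_config",
]


def read_matrix(path) -> pd.DataFrame:
    """Read a wide samples x proteins TSV matrix with NA for missing."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = [c for i, c in enumerate(header) if c in header[:i]]
    if dup:
        raise ValueError(f"duplicate protein column(s): {sorted(set(dup))[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=True)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample id(s): {dup[:5]}")
    bad = df.dtypes[~df.dtypes.map(lambda t: np.issubdtype(t, np.number))]
    if len(bad):
        col = bad.index[0]
        row = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        where = row.index[0] if len(row) else "?"
        raise ValueError(f"non-numeric cell in column {col!r} at row {where!r}")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=index)


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: name <tab> description <tab> member...; trailing tabs tolerated."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {ln}: need name, description, members")
            name = parts[0]
            members = {m for m in parts[2:] if m.strip()}
            if not members:
                raise ValueError(f"empty gene set {name!r} at line {ln}")
            sets[name] = members
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "", *sorted(members)]) + "\n")


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8")
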