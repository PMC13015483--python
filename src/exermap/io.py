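"""Plain-text I/O: feature-by-sample TSV matrices, design tables, GMT set files."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_matrix", "write_matrix", "read_design", "write_design",
           "read_gmt", "write_gmt"]


def read_matrix(path) -> pd.DataFrame:
    """Read a feature (rows) x sample (columns) TSV with a feature-id index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(m: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    m.to_csv(path, sep="\t", index_label="feature_id")


def read_design(path) -> pd.DataFrame:
    d = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "participant_id": str})
    return d.set_index("sample_id", drop=False)


def write_design(design: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    design.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, tab-separated name, description, members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
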