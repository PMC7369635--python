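"""Readers and writers for the plain-text interchange formats.

All tabular artifacts are TSV with headers; gene sets use the standard GMT
layout (set name, description, then tab-separated gene ids, one set per
line); run summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def write_gmt(genesets: dict[str, set[str] | list[str]], path) -> None:
    lines = []
    for name in sorted(genesets):
        members = sorted(genesets[name])
        lines.append("\t".join([name, f"{len(members)} genes", *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    genesets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (needs >= 3 fields): {line[:80]!r}")
        genesets[fields[0]] = set(fields[2:])
    return genesets


def read_matrix_tsv(path, index_col: int = 0) -> pd.DataFrame:
    """Read a labelled numeric matrix (regions×genes or subjects×regions)."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
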