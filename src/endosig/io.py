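"""TSV / GMT / JSON readers and writers shared by all pipeline stages.

File dialects:

* expression TSV — first column ``feature_id``, remaining columns are sample
  IDs, values are log2 intensities;
* metadata TSV — columns ``sample_id``, ``study_id``, ``group``;
* probe-map TSV — columns ``probe_id``, ``gene_symbol``, ``entrez_id``
  (``NA`` allowed in ``entrez_id``);
* GMT — one gene set per line: name, description, then member genes,
  tab-separated.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV into a feature x sample DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    if df.isna().any().any():
        raise ValueError(f"missing values in expression matrix {path}")
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "study_id", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata {path} lacks columns {sorted(missing)}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probe_id", "gene_symbol", "entrez_id"}
    missing = required - set(pm.columns)
    if missing:
        raise ValueError(f"probe map {path} lacks columns {sorted(missing)}")
    return pm


def write_probe_map(pm: pd.DataFrame, path: str | Path) -> None:
    pm.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into {set name: member genes}; description discarded."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = []
    for name in sets:
        genes = list(sets[name])
        lines.append("\t".join([name, description, *genes]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gene_list(path: str | Path) -> list[str]:
    return [g for g in Path(path).read_text().splitlines() if g.strip()]


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + ("\n" if genes else ""))


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
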