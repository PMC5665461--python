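"""Tab-delimited readers and writers for the pipeline's external formats.

Formats
-------
matrix
    TSV; first column ``probe_id``, header row of sample ids, one float per
    cell, empty cell = missing.
design
    TSV with columns ``sample_id``, ``breed``, ``stage_dpc``, ``tech_group``
    and optionally ``sex``.
probe map
    two-column TSV ``probe_id <tab> gene_symbol`` (no header required).
gene set
    plain text, one symbol per line (``#`` comments and blank lines skipped).

A reader for the GEO series-matrix dialect (the tab-delimited layout used
by deposited microarray series) is included as a convenience; nothing in
the pipeline requires it.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .design import validate_design


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples log2-intensity matrix; empty cells become NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tech_group": str})
    df = df.rename(columns={"stage_dpc": "stage"}).set_index("sample_id")
    return validate_design(df)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    out = design.copy()
    out.index.name = "sample_id"
    out = out.rename(columns={"stage": "stage_dpc"})
    out.to_csv(path, sep="\t")


def read_probe_map(path: str | Path) -> pd.Series:
    """Read probe -> gene symbol as a Series indexed by probe id.

    A probe mapping to two different symbols is an error; exact duplicate
    lines are tolerated.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"probe map {path} must have two tab-separated columns")
    if isinstance(df.iloc[0, 0], str) and df.iloc[0, 0].lower() in ("probe_id", "probe"):
        df = df.iloc[1:]
    df = df.iloc[:, :2].drop_duplicates()
    if df.iloc[:, 0].duplicated().any():
        bad = df.iloc[:, 0][df.iloc[:, 0].duplicated()].tolist()
        raise ValueError(f"probes mapped to more than one symbol: {bad[:5]}")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="gene")
    ser.index.name = "probe_id"
    return ser


def write_probe_map(pmap: pd.Series, path: str | Path) -> None:
    pmap.rename("gene").rename_axis("probe_id").to_csv(path, sep="\t", header=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; symbols are uppercased for matching."""
    out = []
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym and not sym.startswith("#"):
            out.append(sym.upper())
    return out


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + ("\n" if len(list(genes)) else ""))


def read_series_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Parse a GEO series-matrix file into (matrix, metadata).

    Metadata lines start with ``!``; the expression table sits between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` with an
    ``ID_REF`` first column and quoted sample headers.
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table_lines.append(line)
        elif line.startswith("!"):
            key, _, rest = line[1:].partition("\t")
            values = [v.strip('"') for v in rest.split("\t")] if rest else []
            meta.setdefault(key, []).extend(values)
    if not table_lines:
        raise ValueError(f"{path}: no series-matrix table found")
    df = pd.read_csv(_io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    df.columns = [str(c).strip('"') for c in df.columns]
    return df.astype(float), meta
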