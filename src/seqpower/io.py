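"""Readers and writers for count matrices, gene sets and result tables.

Count matrices are genes-as-rows text tables (first column gene id, header
row of sample ids; tab or comma delimited, auto-detected) or MatrixMarket
files with row/column name sidecars.  Gene sets use either a plain list
(one id per line) or the GMT format (one set per line: name, description,
member ids, tab-separated).  Result tables are TSV with ``#``-prefixed
provenance headers recording every parameter, plus a machine-readable JSON
sidecar.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .empirical import GeneDistribution
from .params import InvalidParameterError

__all__ = [
    "read_counts",
    "read_gene_list",
    "read_gmt",
    "read_distribution",
    "write_distribution",
    "write_table",
    "write_json_sidecar",
]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_counts(path, *, row_names=None, col_names=None) -> pd.DataFrame:
    """Read a genes x samples count matrix (TSV/CSV or MTX + sidecars).

    For ``foo.mtx``, row and column names default to ``foo.rows.txt`` and
    ``foo.cols.txt`` (one id per line).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        m = mmread(str(path))
        mat = np.asarray(m.todense() if hasattr(m, "todense") else m)
        rows = Path(row_names) if row_names else path.with_suffix(".rows.txt")
        cols = Path(col_names) if col_names else path.with_suffix(".cols.txt")
        genes = rows.read_text().split()
        samples = cols.read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    arr = df.to_numpy()
    if arr.size and ((arr < 0).any() or not np.issubdtype(arr.dtype, np.number)):
        raise InvalidParameterError(f"{path}: counts must be nonnegative numbers")
    if not df.index.is_unique:
        raise InvalidParameterError(f"{path}: gene ids must be unique")
    return df


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    if not out:
        raise InvalidParameterError(f"{path}: empty gene list")
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> member ids..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InvalidParameterError(
                f"{path}: GMT lines need name, description and >= 1 member")
        sets[fields[0]] = [g for g in fields[2:] if g]
    if not sets:
        raise InvalidParameterError(f"{path}: no gene sets found")
    return sets


def write_distribution(dist: GeneDistribution, path) -> None:
    """Serialize a GeneDistribution as TSV with provenance header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in dist.provenance.items():
            fh.write(f"# {key}: {json.dumps(value)}\n")
        dist.table.rename_axis("gene").to_csv(fh, sep="\t")


def read_distribution(path) -> GeneDistribution:
    path = Path(path)
    provenance = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, value = line[1:].partition(":")
            provenance[key.strip()] = json.loads(value.strip())
    table = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    return GeneDistribution(table=table[["mu", "phi"]], provenance=provenance)


def write_table(df: pd.DataFrame, path, params: dict, *, index: bool = False) -> None:
    """TSV with '#'-prefixed parameter provenance headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in params.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_json_sidecar(path, params: dict, results) -> Path:
    """Deterministic JSON sidecar (<path>.json) with params and results."""
    sidecar = Path(str(path) + ".json")
    payload = {"params": params, "results": results}
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")
    return sidecar
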