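"""Readers and writers for the on-disk formats: GMT gene sets, edge-weight
matrices (wide and long TSV), covariate tables, and results tables.

Conventions
-----------
* GMT follows the MSigDB dialect: ``name<TAB>description<TAB>gene1<TAB>...``.
* Wide edge matrix: TSV with columns ``tf``, ``gene``, then one column per
  sample. Edge order on disk is preserved and round-trips bit-exactly.
* Long edge matrix: TSV with columns ``tf``, ``gene``, ``sample``, ``weight``;
  edges are sorted lexicographically by (tf, gene) on load.
* Missing weights are rejected by default (``on_missing="error"``); pass
  ``on_missing="drop"`` to discard the affected edges instead. Silent
  imputation is never performed, as it would bias the downstream PCA.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import CovariateTable, EdgeMatrix, PathwayCollection

__all__ = [
    "GmtFormatError",
    "read_gmt",
    "write_gmt",
    "read_edge_matrix",
    "write_edge_matrix",
    "read_covariates",
    "write_covariates",
    "write_results_table",
    "read_results_table",
    "RESULT_COLUMNS",
]


class GmtFormatError(ValueError):
    """Raised on a malformed GMT line; carries the 1-based line number."""


def read_gmt(path: str | os.PathLike) -> PathwayCollection:
    """Parse an MSigDB-style GMT file into a :class:`PathwayCollection`.

    Each non-empty line must have at least three tab-separated fields
    (name, description, one or more genes). Duplicate genes within a line
    are collapsed; duplicate pathway names raise an error.
    """
    pathways: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise GmtFormatError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            if name in pathways:
                raise GmtFormatError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            pathways[name] = genes
    return PathwayCollection(pathways, source_description=str(path))


def write_gmt(collection: PathwayCollection, path: str | os.PathLike) -> None:
    """Write a pathway collection in GMT format (genes sorted for stability)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for name, members in collection:
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_edge_matrix(
    path: str | os.PathLike,
    layout: str = "wide",
    on_missing: str = "error",
) -> EdgeMatrix:
    """Load an edge-weight matrix from TSV.

    Parameters
    ----------
    layout : {"wide", "long"}
        ``wide``: columns tf, gene, <sample...>; edge order preserved.
        ``long``: columns tf, gene, sample, weight; edges sorted by (tf, gene).
    on_missing : {"error", "drop"}
        Policy for edges with missing weight cells.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"unknown layout {layout!r}")
    if on_missing not in ("error", "drop"):
        raise ValueError(f"unknown missing-value policy {on_missing!r}")

    if layout == "wide":
        df = pd.read_csv(
            path, sep="\t", dtype={"tf": str, "gene": str},
            float_precision="round_trip",
        )
        if list(df.columns[:2]) != ["tf", "gene"]:
            raise ValueError(f"{path}: wide layout requires first columns 'tf','gene'")
        samples = list(df.columns[2:])
        weights = df[samples].to_numpy(dtype=float)
        tfs = df["tf"].tolist()
        genes = df["gene"].tolist()
    else:
        df = pd.read_csv(
            path, sep="\t", dtype={"tf": str, "gene": str, "sample": str},
            float_precision="round_trip",
        )
        required = ["tf", "gene", "sample", "weight"]
        if list(df.columns) != required:
            raise ValueError(f"{path}: long layout requires columns {required}")
        if df["weight"].isna().any():
            if on_missing == "error":
                raise ValueError(f"{path}: missing weight values")
            df = df.dropna(subset=["weight"])
        dup = df.duplicated(subset=["tf", "gene", "sample"])
        if dup.any():
            raise ValueError(f"{path}: duplicate (tf, gene, sample) records")
        wide = df.pivot_table(
            index=["tf", "gene"], columns="sample", values="weight", sort=True
        )
        if wide.isna().any().any():
            # an edge absent for some sample is a missing cell
            if on_missing == "error":
                raise ValueError(f"{path}: missing weight values (incomplete edge x sample grid)")
            wide = wide.dropna(axis=0)
        samples = list(wide.columns)
        tfs = [t for t, _ in wide.index]
        genes = [g for _, g in wide.index]
        weights = wide.to_numpy(dtype=float)

    if np.isnan(weights).any():
        if on_missing == "error":
            raise ValueError(f"{path}: missing weight values")
        keep = ~np.isnan(weights).any(axis=1)
        tfs = [t for t, k in zip(tfs, keep) if k]
        genes = [g for g, k in zip(genes, keep) if k]
        weights = weights[keep]
    return EdgeMatrix(tfs=tfs, genes=genes, samples=samples, weights=weights)


def write_edge_matrix(matrix: EdgeMatrix, path: str | os.PathLike) -> None:
    """Write the wide TSV layout; float repr round-trips bit-exactly."""
    matrix.to_frame().to_csv(
        path, sep="\t", index=False, float_format=lambda x: repr(float(x))
    )


def read_covariates(path: str | os.PathLike) -> CovariateTable:
    """Load a covariate TSV (first column ``sample``).

    Columns that parse fully as numbers are tagged numerical; everything
    else is categorical. A column name suffixed ``:categorical`` or
    ``:numerical`` overrides the inference (the suffix is stripped).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample":
        raise ValueError(f"{path}: first column must be 'sample'")
    df = df.set_index("sample")
    kinds: dict[str, str] = {}
    rename: dict[str, str] = {}
    for col in df.columns:
        name, kind = col, None
        for suffix in (":categorical", ":numerical"):
            if col.endswith(suffix):
                name, kind = col[: -len(suffix)], suffix[1:]
        if kind is None:
            try:
                df[col] = pd.to_numeric(df[col])
                kind = "numerical"
            except (ValueError, TypeError):
                kind = "categorical"
        elif kind == "numerical":
            df[col] = pd.to_numeric(df[col])
        rename[col] = name
        kinds[name] = kind
    df = df.rename(columns=rename)
    return CovariateTable(data=df, kinds=kinds)


def write_covariates(covars: CovariateTable, path: str | os.PathLike) -> None:
    df = covars.data.copy()
    df.columns = [f"{c}:{covars.kinds[c]}" for c in df.columns]
    df.to_csv(path, sep="\t", index_label="sample")


RESULT_COLUMNS = [
    "pathway",
    "n_genes_in_pathway",
    "n_genes_in_network",
    "n_edges",
    "pc1_var_observed",
    "null_mean",
    "null_sd",
    "p_value",
    "p_adjusted",
    "effect_size",
]


def write_results_table(results, path: str | os.PathLike) -> None:
    """Write per-pathway test results as TSV.

    `results` is a non-empty list of :class:`~porcupine.scan.PathwayTestResult`
    or an equivalent DataFrame; numbers are serialized with full precision
    (well beyond 6 significant digits).
    """
    if isinstance(results, pd.DataFrame):
        df = results[RESULT_COLUMNS]
        if df.empty:
            raise ValueError("results table is empty")
    else:
        results = list(results)
        if not results:
            raise ValueError("results list is empty")
        df = pd.DataFrame([r.to_row() for r in results], columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing result columns {missing}")
    return df
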