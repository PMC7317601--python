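"""Readers and writers for the plain-text formats the pipeline exchanges.

Every table is tab-separated. Expression matrices are genes x samples with the
gene identifier in the first column and sample identifiers in the header row.
Gene-set collections use the GMT line format (name, description, then members).
Data tables round-trip at full precision; derived result tables written by the
pipeline use ``FLOAT_FMT`` (six significant digits).
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# expression / trait tables


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x samples expression matrix (first column = gene ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def write_expression(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_trait(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample x trait table (first column = sample ID, numeric traits)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def write_trait(traits: pd.DataFrame, path: str | os.PathLike) -> None:
    traits.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# differential expression / target prediction tables


def read_diffexpr(path: str | os.PathLike) -> pd.DataFrame:
    """Read a differential-expression table: gene, logFC, pvalue[, qvalue]."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"gene", "logFC", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"differential-expression table missing columns: {sorted(missing)}")
    return df


def write_diffexpr(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_targets(path: str | os.PathLike) -> pd.DataFrame:
    """Read a target-prediction table: gene, n_databases."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if not {"gene", "n_databases"} <= set(df.columns):
        raise ValueError("target table needs columns 'gene' and 'n_databases'")
    return df


def write_targets(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# interaction edges


def read_edge_list(path: str | os.PathLike) -> pd.DataFrame:
    """Read a scored edge list: geneA, geneB, score."""
    df = pd.read_csv(path, sep="\t", dtype={"geneA": str, "geneB": str})
    if not {"geneA", "geneB", "score"} <= set(df.columns):
        raise ValueError("edge list needs columns geneA, geneB, score")
    return df


def write_edge_list(edges: pd.DataFrame, path: str | os.PathLike) -> None:
    edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# survival records


def read_survival(path: str | os.PathLike) -> pd.DataFrame:
    """Read survival records: sample, time, event (0/1), group."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if not {"sample", "time", "event", "group"} <= set(df.columns):
        raise ValueError("survival table needs columns sample, time, event, group")
    return df


def write_survival(records: pd.DataFrame, path: str | os.PathLike) -> None:
    records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# study tables for meta-analysis (long form)


def read_studies_long(path: str | os.PathLike) -> pd.DataFrame:
    """Read per-sample study values: study, group in {case, control}, value."""
    df = pd.read_csv(path, sep="\t", dtype={"study": str, "group": str})
    if not {"study", "group", "value"} <= set(df.columns):
        raise ValueError("study table needs columns study, group, value")
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return df


def write_studies_long(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_studies_summary(path: str | os.PathLike) -> pd.DataFrame:
    """Read summary-level studies: study, n_case, mean_case, sd_case, n_control, mean_control, sd_control."""
    df = pd.read_csv(path, sep="\t", dtype={"study": str})
    need = {"study", "n_case", "mean_case", "sd_case", "n_control", "mean_control", "sd_control"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"summary study table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping of set name -> member list."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            name, _desc, *members = fields
            sets[name] = [m for m in members if m]
    return sets


def write_gmt(
    sets: Mapping[str, Sequence[str]],
    path: str | os.PathLike,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na") if descriptions else "na"
            fh.write("\t".join([name, desc, *members]) + "\n")
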