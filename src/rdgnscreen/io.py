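"""Readers and writers for the tab-separated dialects the pipeline consumes.

Three TSV layouts are supported, all with ``#`` comment headers permitted:

* expression tables — ``gene_symbol, gene_id, kc_reads, s2_reads, kc_tpm,
  s2_tpm``; blank numeric fields mark genes without expression data,
* seed-network connectivity tables — ``gene_symbol, gene_id, node_conn``
  followed by the expression columns and an ``rdgn`` yes/no flag (the layout
  the published subnetwork tables use),
* interaction edge lists — ``node_a, node_b, score`` with STRING-style
  combined confidence scores on a 0-1000 scale; undirected, duplicate
  unordered pairs collapsed keeping the maximum score.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

EXPRESSION_COLUMNS = ["gene_symbol", "gene_id", "kc_reads", "s2_reads", "kc_tpm", "s2_tpm"]
NETWORK_COLUMNS = [
    "gene_symbol",
    "gene_id",
    "node_conn",
    "kc_tpm",
    "s2_tpm",
    "kc_reads",
    "s2_reads",
    "log2_kc_s2",
    "rdgn",
]
EDGE_COLUMNS = ["node_a", "node_b", "score"]

_EXPR_NUMERIC = ["kc_reads", "s2_reads", "kc_tpm", "s2_tpm"]


def _read_tsv(path: str | os.PathLike, expected: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_symbol": str})
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; expected header {expected}"
        )
    return df


def _validate_genes(df: pd.DataFrame, path) -> None:
    if df["gene_symbol"].isna().any() or (df["gene_symbol"].str.len() == 0).any():
        bad = df.index[df["gene_symbol"].isna() | (df["gene_symbol"].str.len() == 0)][0]
        raise ValueError(f"{path}: empty gene_symbol at data row {bad + 1}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene_id {int(dup.iloc[0])}")


def read_expression_table(path: str | os.PathLike) -> pd.DataFrame:
    """Load a two-condition expression table; blank rows become measured=False."""
    df = _read_tsv(path, EXPRESSION_COLUMNS)[EXPRESSION_COLUMNS].copy()
    _validate_genes(df, path)
    for col in _EXPR_NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col].dropna() < 0).any():
            bad = df.loc[df[col] < 0, "gene_symbol"].iloc[0]
            raise ValueError(f"{path}: negative {col} for {bad}")
    n_missing = df[_EXPR_NUMERIC].isna().sum(axis=1)
    if ((n_missing > 0) & (n_missing < 4)).any():
        bad = df.loc[(n_missing > 0) & (n_missing < 4), "gene_symbol"].iloc[0]
        raise ValueError(f"{path}: partially blank expression row for {bad}")
    df["measured"] = n_missing == 0
    df["gene_id"] = df["gene_id"].astype(int)
    return df


def write_expression_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_network_table(path: str | os.PathLike) -> pd.DataFrame:
    """Load a seed-network connectivity table (connectivity + expression + RDGN flag)."""
    df = _read_tsv(path, NETWORK_COLUMNS)[NETWORK_COLUMNS].copy()
    _validate_genes(df, path)
    df["gene_id"] = df["gene_id"].astype(int)
    df["node_conn"] = df["node_conn"].astype(int)
    if (df["node_conn"] < 0).any():
        raise ValueError(f"{path}: negative node_conn")
    for col in _EXPR_NUMERIC + ["log2_kc_s2"]:
        df[col] = pd.to_numeric(df[col], errors="raise")
    bad_flag = ~df["rdgn"].isin(["yes", "no"])
    if bad_flag.any():
        raise ValueError(
            f"{path}: rdgn flag must be yes/no, got "
            f"{df.loc[bad_flag, 'rdgn'].iloc[0]!r} for {df.loc[bad_flag, 'gene_symbol'].iloc[0]}"
        )
    df["rdgn"] = df["rdgn"] == "yes"
    # unmeasured = no expression data at all (log2 may also be blank for 0/0 rows)
    df["measured"] = df[_EXPR_NUMERIC].notna().all(axis=1)
    return df


def expression_from_network_tables(*tables: pd.DataFrame) -> pd.DataFrame:
    """Union the expression columns of one or more network tables.

    When a gene appears in several tables, the first measured occurrence
    wins (the published tables agree wherever they overlap).
    """
    frames = [t[["gene_symbol", "gene_id"] + _EXPR_NUMERIC + ["measured"]] for t in tables]
    merged = pd.concat(frames, ignore_index=True)
    merged = merged.sort_values("measured", ascending=False, kind="mergesort")
    merged = merged.drop_duplicates("gene_symbol", keep="first").reset_index(drop=True)
    return merged


def read_edge_list(path: str | os.PathLike) -> pd.DataFrame:
    """Load an undirected interaction edge list with 0-1000 confidence scores.

    Self-edges are rejected; duplicate unordered pairs are collapsed keeping
    the maximum score.
    """
    df = _read_tsv(path, EDGE_COLUMNS)[EDGE_COLUMNS].copy()
    df["node_a"] = df["node_a"].astype(str)
    df["node_b"] = df["node_b"].astype(str)
    df["score"] = df["score"].astype(int)
    return normalize_edges(df)


def normalize_edges(df: pd.DataFrame) -> pd.DataFrame:
    if ((df["score"] < 0) | (df["score"] > 1000)).any():
        raise ValueError("interaction score outside 0-1000")
    if (df["node_a"] == df["node_b"]).any():
        bad = df.loc[df["node_a"] == df["node_b"], "node_a"].iloc[0]
        raise ValueError(f"self-interaction for {bad!r}")
    lo = df[["node_a", "node_b"]].min(axis=1)
    hi = df[["node_a", "node_b"]].max(axis=1)
    canon = pd.DataFrame({"node_a": lo, "node_b": hi, "score": df["score"]})
    return (
        canon.groupby(["node_a", "node_b"], as_index=False)["score"]
        .max()
        .sort_values(["node_a", "node_b"])
        .reset_index(drop=True)
    )


def write_edge_list(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_aligned_sequences(path: str | os.PathLike) -> list[str]:
    """Read aligned binding sequences, one equal-length A/C/G/T string per line."""
    seqs: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            s = line.strip().upper()
            if not s or s.startswith("#"):
                continue
            if set(s) - set("ACGT"):
                raise ValueError(f"{path}:{i}: non-ACGT character in {s!r}")
            seqs.append(s)
    if not seqs:
        raise ValueError(f"{path}: no sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError(f"{path}: sequences have unequal lengths")
    return seqs


def write_aligned_sequences(seqs: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(s + "\n")
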