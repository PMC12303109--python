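"""Seed-centred interaction subnetworks and the candidate-gene screen.

A *seed network* is the subgraph induced on a seed gene plus all of its
direct interactors at or above a confidence cutoff (STRING combined score,
default >= 500).  A gene's *connectivity* is its degree within that induced
subgraph, so the seed's connectivity always equals the member count.

The candidate screen nominates potential new members of the retinal
determination gene network (RDGN): genes with at least ``conn_min`` node
connections in either the *ey* or the *toy* seed network, expressed at a
read count of at least ``reads_min`` in one of the two cell lines, and not
already on the curated 21-gene RDGN list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "known_rdgn_genes",
    "SeedNetwork",
    "build_seed_network",
    "seed_network_from_table",
    "connectivity_summary",
    "screen_candidates",
    "classify_specificity",
]

# Curated list of the 21 known molecular components of the RDGN: the core
# pathway, its transcription-factor regulators, and the extracellular
# signalling genes that feed into it.
_KNOWN_RDGN = frozenset(
    {
        "toy", "ey", "so", "eya", "dac", "tsh", "tio", "hth", "eyg", "toe",
        "Optix", "dan", "danr", "ato", "nmo", "gro", "hry", "N", "hh", "dpp", "wg",
    }
)

DEFAULT_MIN_SCORE = 500
DEFAULT_CONN_MIN = 14
DEFAULT_READS_MIN = 8.0
DEFAULT_TPM_MIN = 0.15


def known_rdgn_genes() -> frozenset[str]:
    """The 21 curated components of the retinal determination gene network."""
    return _KNOWN_RDGN


@dataclass(frozen=True)
class SeedNetwork:
    """A seed gene, its direct interactors, and within-subnetwork degrees."""

    seed: str
    members: frozenset[str]
    connectivity: dict[str, int] = field(compare=False)

    def __post_init__(self) -> None:
        if self.seed in self.members:
            raise ValueError("seed must not be listed among members")
        if self.connectivity.get(self.seed) != len(self.members):
            raise ValueError(
                f"seed connectivity {self.connectivity.get(self.seed)} "
                f"!= member count {len(self.members)}"
            )
        for g in self.members:
            c = self.connectivity.get(g)
            if c is None or not (1 <= c <= len(self.members)):
                raise ValueError(f"member {g!r} has invalid connectivity {c}")

    @property
    def n_members(self) -> int:
        return len(self.members)


def _edges_iter(edges) -> Iterable[tuple[str, str, int]]:
    if isinstance(edges, pd.DataFrame):
        return edges[["node_a", "node_b", "score"]].itertuples(index=False, name=None)
    return edges


def build_seed_network(edges, seed: str, min_score: int = DEFAULT_MIN_SCORE) -> SeedNetwork:
    """Extract the seed-centred subnetwork from an interaction edge list.

    Parameters
    ----------
    edges
        DataFrame with columns ``node_a, node_b, score`` or an iterable of
        ``(node_a, node_b, score)`` tuples; scores on the 0-1000 scale.
    seed
        Gene symbol at the centre of the subnetwork.
    min_score
        Minimum combined confidence score for an edge to count.
    """
    g = nx.Graph()
    for a, b, score in _edges_iter(edges):
        if a == b:
            raise ValueError(f"self-interaction for {a!r}")
        if score >= min_score:
            # duplicate pairs keep the strongest evidence
            if not g.has_edge(a, b) or g[a][b]["score"] < score:
                g.add_edge(a, b, score=score)
    if seed not in g or g.degree(seed) == 0:
        raise ValueError("seed not connected")
    members = frozenset(g.neighbors(seed))
    sub = g.subgraph(members | {seed})
    connectivity = {node: int(deg) for node, deg in sub.degree()}
    return SeedNetwork(seed=seed, members=members, connectivity=connectivity)


def seed_network_from_table(table: pd.DataFrame, seed: str) -> SeedNetwork:
    """Build a SeedNetwork from a published connectivity table.

    The table lists the seed row (whose ``node_conn`` is its own degree,
    i.e. the member count) and one row per member with its degree inside the
    subnetwork; the edges themselves are not recoverable from this layout.
    """
    if seed not in set(table["gene_symbol"]):
        raise ValueError(f"seed {seed!r} not present in table")
    connectivity = dict(zip(table["gene_symbol"], table["node_conn"].astype(int)))
    members = frozenset(g for g in connectivity if g != seed)
    return SeedNetwork(seed=seed, members=members, connectivity=connectivity)


def connectivity_summary(net: SeedNetwork) -> dict:
    """Member count plus the best-connected non-seed member (ties: first alphabetically)."""
    if not net.members:
        raise ValueError("empty network")
    max_conn = max(net.connectivity[g] for g in net.members)
    best = min(g for g in net.members if net.connectivity[g] == max_conn)
    return {"n_members": net.n_members, "max_nonseed_conn": max_conn, "argmax_gene": best}


def screen_candidates(
    ey_conn: Mapping[str, int] | pd.DataFrame,
    toy_conn: Mapping[str, int] | pd.DataFrame | None,
    expr: pd.DataFrame,
    conn_min: int = DEFAULT_CONN_MIN,
    reads_min: float = DEFAULT_READS_MIN,
    tpm_min: float = DEFAULT_TPM_MIN,
    seeds: tuple[str, ...] = ("ey", "toy"),
) -> pd.DataFrame:
    """Screen both seed networks for potential new RDGN components.

    A gene passes when it has ``conn_min`` or more node connections in either
    network (inclusive or), is not one of the 21 curated RDGN genes, has
    expression data, and shows a read count of at least ``reads_min`` in at
    least one cell line.  ``tpm_min`` is the published TPM equivalent of the
    read-count cutoff and is used instead only when the expression table
    carries no read counts.  Seed genes are never candidates.

    Returns the full evaluation table (one row per non-seed gene in either
    network), sorted by the larger of the two connectivities, descending,
    with gene symbol as tie-break; candidates are the rows with
    ``passes_screen``.
    """
    ey_map = _conn_map(ey_conn)
    toy_map = _conn_map(toy_conn) if toy_conn is not None else {}
    expr_idx = expr.set_index("gene_symbol")
    genes = sorted((set(ey_map) | set(toy_map)) - set(seeds))
    have_reads = "kc_reads" in expr_idx.columns and expr_idx["kc_reads"].notna().any()

    rows = []
    for gene in genes:
        e_conn = int(ey_map.get(gene, 0))
        t_conn = int(toy_map.get(gene, 0))
        if gene in expr_idx.index:
            rec = expr_idx.loc[gene]
            measured = bool(rec.get("measured", True)) and not pd.isna(rec["kc_tpm"])
        else:
            logger.info("gene %s present in a network but absent from expression; "
                        "treated as unmeasured", gene)
            rec, measured = None, False
        is_rdgn = gene in _KNOWN_RDGN
        if measured:
            if have_reads:
                expressed = rec["kc_reads"] >= reads_min or rec["s2_reads"] >= reads_min
            else:
                expressed = rec["kc_tpm"] >= tpm_min or rec["s2_tpm"] >= tpm_min
        else:
            expressed = False
        passes = (
            (e_conn >= conn_min or t_conn >= conn_min)
            and not is_rdgn
            and measured
            and bool(expressed)
        )
        rows.append(
            {
                "gene_symbol": gene,
                "ey_conn": e_conn,
                "toy_conn": t_conn,
                "kc_reads": None if rec is None else rec.get("kc_reads"),
                "s2_reads": None if rec is None else rec.get("s2_reads"),
                "kc_tpm": None if rec is None else rec.get("kc_tpm"),
                "s2_tpm": None if rec is None else rec.get("s2_tpm"),
                "measured": measured,
                "is_rdgn": is_rdgn,
                "passes_screen": passes,
            }
        )
    out = pd.DataFrame(rows)
    out["max_conn"] = out[["ey_conn", "toy_conn"]].max(axis=1)
    out = out.sort_values(
        ["max_conn", "gene_symbol"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def _conn_map(conn) -> dict[str, int]:
    if conn is None:
        return {}
    if isinstance(conn, pd.DataFrame):
        return dict(zip(conn["gene_symbol"], conn["node_conn"].astype(int)))
    return dict(conn)


def classify_specificity(candidates: pd.DataFrame) -> pd.DataFrame:
    """Label each gene shared / ey_specific / toy_specific by network presence.

    Presence means connectivity > 0 in that seed network — membership, not
    the screening threshold (a gene can be a candidate through one network
    while still being a *shared* member of both).
    """
    candidates = candidates.copy()
    labels = []
    for row in candidates.itertuples(index=False):
        if row.ey_conn > 0 and row.toy_conn > 0:
            labels.append("shared")
        elif row.ey_conn > 0:
            labels.append("ey_specific")
        elif row.toy_conn > 0:
            labels.append("toy_specific")
        else:
            raise ValueError(f"{row.gene_symbol}: not in either network")
    candidates["specificity"] = labels
    return candidates
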