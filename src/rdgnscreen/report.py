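"""End-to-end candidate screen: networks + expression -> screen report.

The report bundles the candidate table with the intermediate counts a
reader needs to audit the screen: per-network membership, how many
non-RDGN genes clear the connectivity cutoff, how many of those clear the
expression cutoff, and the shared/specific tallies.  ``render_report``
serialises it deterministically so identical inputs give byte-identical
output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import pandas as pd

from . import ppi
from .expression import round_half_up
from .io import expression_from_network_tables

__all__ = ["ScreenReport", "run_screen", "render_report"]


@dataclass
class ScreenReport:
    candidates: pd.DataFrame  # passing genes only, specificity filled
    evaluation: pd.DataFrame  # every screened gene with pass/fail flags
    counts: dict
    config: dict

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()
        ).hexdigest()[:12]


def _network_counts(
    table: pd.DataFrame, seed: str, conn_min: int, reads_min: float
) -> dict:
    nonseed = table[table["gene_symbol"] != seed]
    at_conn = nonseed[(nonseed["node_conn"] >= conn_min) & ~nonseed["rdgn"]]
    expressed = at_conn[
        at_conn["measured"]
        & ((at_conn["kc_reads"] >= reads_min) | (at_conn["s2_reads"] >= reads_min))
    ]
    net = ppi.seed_network_from_table(table, seed)
    summary = ppi.connectivity_summary(net)
    return {
        "n_members": summary["n_members"],
        "max_nonseed_conn": summary["max_nonseed_conn"],
        "argmax_gene": summary["argmax_gene"],
        "n_conn_min_nonrdgn": int(len(at_conn)),
        "n_conn_min_expressed": int(len(expressed)),
    }


def run_screen(
    ey_table: pd.DataFrame,
    toy_table: pd.DataFrame | None,
    expression: pd.DataFrame | None = None,
    conn_min: int = ppi.DEFAULT_CONN_MIN,
    reads_min: float = ppi.DEFAULT_READS_MIN,
    tpm_min: float = ppi.DEFAULT_TPM_MIN,
) -> ScreenReport:
    """Run the candidate screen from connectivity tables.

    ``expression`` defaults to the union of the expression columns carried
    by the network tables themselves.
    """
    tables = [t for t in (ey_table, toy_table) if t is not None]
    if expression is None:
        expression = expression_from_network_tables(*tables)
    evaluation = ppi.screen_candidates(
        ey_table,
        toy_table,
        expression,
        conn_min=conn_min,
        reads_min=reads_min,
        tpm_min=tpm_min,
    )
    candidates = evaluation[evaluation["passes_screen"]].reset_index(drop=True)
    candidates = ppi.classify_specificity(candidates)
    tallies = candidates["specificity"].value_counts().to_dict()
    counts = {
        "n_candidates": int(len(candidates)),
        "n_shared": int(tallies.get("shared", 0)),
        "n_ey_specific": int(tallies.get("ey_specific", 0)),
        "n_toy_specific": int(tallies.get("toy_specific", 0)),
        "ey_network": _network_counts(ey_table, "ey", conn_min, reads_min),
    }
    if toy_table is not None:
        counts["toy_network"] = _network_counts(toy_table, "toy", conn_min, reads_min)
    config = {
        "conn_min": conn_min,
        "reads_min": reads_min,
        "tpm_min": tpm_min,
        "classification": "threshold classification",
    }
    return ScreenReport(candidates=candidates, evaluation=evaluation, counts=counts, config=config)


def render_report(report: ScreenReport) -> str:
    """Deterministic TSV serialisation of a screen report."""
    lines = [
        "# candidate screen report",
        f"# config: {json.dumps(report.config, sort_keys=True)}",
        f"# config_hash: {report.config_hash}",
    ]
    for key in ("n_candidates", "n_shared", "n_toy_specific", "n_ey_specific"):
        lines.append(f"# {key}: {report.counts[key]}")
    for net in ("ey_network", "toy_network"):
        if net in report.counts:
            c = report.counts[net]
            lines.append(
                f"# {net}: members={c['n_members']} max_nonseed_conn={c['max_nonseed_conn']}"
                f" (at {c['argmax_gene']}) conn_min_nonrdgn={c['n_conn_min_nonrdgn']}"
                f" conn_min_expressed={c['n_conn_min_expressed']}"
            )
    cols = ["gene_symbol", "ey_conn", "toy_conn", "kc_tpm", "s2_tpm", "kc_reads", "s2_reads", "specificity"]
    lines.append("\t".join(cols))
    for row in report.candidates[cols].itertuples(index=False):
        cells = []
        for value in row:
            if isinstance(value, float):
                cells.append(f"{round_half_up(value, 2):g}")
            else:
                cells.append(str(value))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
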