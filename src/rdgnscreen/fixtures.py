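"""Loaders for the packaged reference tables.

The package ships transcriptions of the published Kc/S2 measurements: the
reciprocal Pax6 expression table, the *ey*- and *toy*-seed interaction
subnetwork tables (connectivity + expression + RDGN flag), and the
16-candidate result table used as the expected screen outcome.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_expression_table, read_network_table

__all__ = [
    "fixture_path",
    "load_pax6_expression",
    "load_ey_network",
    "load_toy_network",
    "load_candidate_genes",
]


def fixture_path(name: str):
    """Filesystem path of a packaged data file."""
    return resources.files("rdgnscreen").joinpath("data", name)


def load_pax6_expression() -> pd.DataFrame:
    with resources.as_file(fixture_path("pax6_expression.tsv")) as p:
        return read_expression_table(p)


def load_ey_network() -> pd.DataFrame:
    with resources.as_file(fixture_path("ey_network.tsv")) as p:
        return read_network_table(p)


def load_toy_network() -> pd.DataFrame:
    with resources.as_file(fixture_path("toy_network.tsv")) as p:
        return read_network_table(p)


def load_candidate_genes() -> pd.DataFrame:
    with resources.as_file(fixture_path("candidate_genes.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")
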