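"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators emulate the study's data sources:

* two-condition expression tables — negative-binomial read counts with
  designated log2 fold-change classes applied to the Kc-condition mean,
  TPM computed from the drawn gene lengths;
* interaction graphs — an Erdos-Renyi background with a planted dense,
  high-confidence cluster around a designated seed gene (the "RDGN-like"
  sub-cluster);
* training sequences — i.i.d. per-position draws from a known truth PWM
  (emulating bacterial one-hybrid binding-site sets);
* enhancers — i.i.d. background of stated base composition with
  non-overlapping consensus motif instances planted on random strands.

Every generator is driven by one integer seed through independent child
streams, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import compute_tpm
from .motifs import ALPHABET, PositionWeightMatrix, decode, encode, reverse_complement

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_ppi",
    "sample_training_sequences",
    "plant_sites_enhancer",
]

_STREAMS = {"expression": 1, "ppi": 2, "training": 3, "enhancer": 4}


def _default_pwm_truth() -> PositionWeightMatrix:
    # a moderately informative 6-mer: strong consensus ACGTCA with leakage
    counts = np.array(
        [
            [70, 10, 10, 10],
            [10, 70, 10, 10],
            [10, 10, 70, 10],
            [10, 10, 10, 70],
            [10, 70, 10, 10],
            [70, 10, 10, 10],
        ],
        dtype=float,
    )
    return PositionWeightMatrix(
        name="truth", counts=counts, background=np.full(4, 0.25), pseudocount=0.0
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the four generators; see module docstring for the models.

    ``fold_change_spec`` designates expression classes as
    ``(label, log2_effect, n_genes)`` triples applied to the leading genes;
    the remainder are null genes (effect 0).  ``planted_cluster`` is
    ``(size, within_edge_prob, (score_lo, score_hi))`` for the dense cluster
    planted around the seed node.
    """

    seed: int = 0
    # expression
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (500, 3000)
    nb_mean: float = 500.0
    nb_dispersion: float = 0.1
    fold_change_spec: tuple[tuple[str, float, int], ...] = (
        ("up", 4.0, 10),
        ("down", -4.0, 10),
    )
    # interaction graph
    graph_n_nodes: int = 100
    background_edge_prob: float = 0.02
    planted_cluster: tuple[int, float, tuple[int, int]] = (12, 0.9, (700, 1000))
    seed_gene: str = "seedG"
    # motifs
    pwm_truth: PositionWeightMatrix = field(default_factory=_default_pwm_truth)
    n_training: int = 20
    enhancer_length: int = 446
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    n_planted_sites: int = 3

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion phi (var = mu + phi mu^2)."""
    if dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_expression(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-condition expression table plus the ground-truth class key.

    Condition S2 counts are drawn at ``nb_mean``; Kc counts at
    ``nb_mean * 2**log2_effect`` for genes in a designated class.  Returns
    ``(expression_table, truth)`` where truth carries ``true_class`` and
    ``log2_effect`` per gene.
    """
    if config.n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    n_designated = sum(n for _, _, n in config.fold_change_spec)
    if n_designated > config.n_genes:
        raise ValueError("fold_change_spec designates more genes than n_genes")
    rng = config.rng("expression")
    effects = np.zeros(config.n_genes)
    labels = np.array(["null"] * config.n_genes, dtype=object)
    start = 0
    for label, effect, n in config.fold_change_spec:
        effects[start : start + n] = effect
        labels[start : start + n] = label
        start += n
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    kc_counts = _nb_draw(rng, config.nb_mean * 2.0**effects, config.nb_dispersion)
    s2_counts = _nb_draw(rng, np.full(config.n_genes, config.nb_mean), config.nb_dispersion)
    symbols = [f"g{i:05d}" for i in range(1, config.n_genes + 1)]
    table = pd.DataFrame(
        {
            "gene_symbol": symbols,
            "gene_id": np.arange(1, config.n_genes + 1),
            "kc_reads": kc_counts.astype(float),
            "s2_reads": s2_counts.astype(float),
            "kc_tpm": compute_tpm(kc_counts, lengths),
            "s2_tpm": compute_tpm(s2_counts, lengths),
            "measured": True,
        }
    )
    truth = pd.DataFrame(
        {
            "gene_symbol": symbols,
            "true_class": labels,
            "log2_effect": effects,
            "length": lengths,
        }
    )
    return table, truth


def simulate_ppi(config: SimulationConfig) -> tuple[pd.DataFrame, list[str]]:
    """Random interaction graph with a planted dense cluster around the seed.

    Background: every unordered node pair (outside the planted cluster)
    gains an edge with ``background_edge_prob`` and a score uniform on
    0-1000.  Planted cluster: the seed plus ``size`` designated members,
    each within-cluster pair wired with ``within_edge_prob`` at a score
    uniform on the configured high range.  Returns ``(edges, members)``
    with the ground-truth member list.
    """
    size, within_p, (score_lo, score_hi) = config.planted_cluster
    if config.graph_n_nodes < size + 1:
        raise ValueError("graph_n_nodes must exceed planted cluster size")
    rng = config.rng("ppi")
    others = [f"n{i:04d}" for i in range(1, config.graph_n_nodes)]
    nodes = [config.seed_gene] + others
    members = others[:size]
    cluster = {config.seed_gene, *members}

    rows: list[tuple[str, str, int]] = []
    cluster_sorted = sorted(cluster)
    for i, a in enumerate(cluster_sorted):
        for b in cluster_sorted[i + 1 :]:
            if rng.random() < within_p:
                rows.append((a, b, int(rng.integers(score_lo, score_hi + 1))))
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if a in cluster and b in cluster:
                continue
            if rng.random() < config.background_edge_prob:
                rows.append((a, b, int(rng.integers(0, 1001))))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
    return edges, members


def sample_training_sequences(
    pwm_truth: PositionWeightMatrix, n: int, seed: int
) -> list[str]:
    """n sequences with each position drawn i.i.d. from the truth frequencies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = pwm_truth.frequencies
    cols = [rng.choice(4, size=n, p=freqs[i]) for i in range(pwm_truth.width)]
    mat = np.stack(cols, axis=1)
    return [decode(row) for row in mat]


def plant_sites_enhancer(config: SimulationConfig) -> tuple[str, list[tuple[int, str]]]:
    """Background sequence with consensus sites planted at random positions.

    Sites are non-overlapping, on uniformly random strands (a minus-strand
    site is planted as the reverse complement of the consensus).  Returns
    the sequence and the ground truth as ``(1-based start, strand)`` pairs.
    """
    w = config.pwm_truth.width
    k = config.n_planted_sites
    L = config.enhancer_length
    if L < k * w:
        raise ValueError(f"cannot fit {k} sites of width {w} in {L} bases")
    rng = config.rng("enhancer")
    comp = np.asarray(config.base_composition, dtype=float)
    if np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("base_composition must be 4 probabilities summing to 1")
    seq = rng.choice(4, size=L, p=comp)
    consensus = config.pwm_truth.consensus
    truth: list[tuple[int, str]] = []
    if k:
        # uniform non-overlapping placement: sorted offsets into the free space
        free = L - k * w
        offsets = np.sort(rng.integers(0, free + 1, size=k))
        starts = offsets + np.arange(k) * w
        for s in starts:
            strand = "+" if rng.random() < 0.5 else "-"
            planted = consensus if strand == "+" else reverse_complement(consensus)
            seq[s : s + w] = encode(planted)
            truth.append((int(s) + 1, strand))
    return decode(seq), truth
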