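"""Two-condition expression profiling for the Kc/S2 cell-line contrast.

Expression tables carry raw mapped-read counts and TPM (transcripts per
million) for two conditions.  Differential status is a threshold
classification on the pseudocounted log2 TPM ratio: a gene is called *up*
when log2(Kc/S2) > 2, *down* when it is < -2, *neutral* otherwise.  This is
deliberately a threshold call, not a replicate-based significance test.

Tables are plain :class:`pandas.DataFrame` objects with the columns
``gene_symbol, gene_id, kc_reads, s2_reads, kc_tpm, s2_tpm`` plus a boolean
``measured`` column; unmeasured genes (blank source rows) hold NaN in all
four numeric columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionRecord",
    "compute_tpm",
    "fold_difference",
    "log2_tpm_ratio",
    "classify_differential",
    "rank_within_class",
    "round_half_up",
]

#: default pseudocount added to both TPM values before taking the ratio
DEFAULT_PSEUDOCOUNT = 0.01

#: default |log2| threshold separating up/down from neutral
DEFAULT_LOG2_THRESHOLD = 2.0


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's expression in the two conditions.

    ``measured=False`` marks genes whose source row was blank; their numeric
    fields are ``None`` and they never enter ratio arithmetic.
    """

    gene_symbol: str
    gene_id: int
    reads_a: float | None = None
    reads_b: float | None = None
    tpm_a: float | None = None
    tpm_b: float | None = None
    measured: bool = True

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if self.gene_id <= 0:
            raise ValueError("gene_id must be a positive integer")
        values = (self.reads_a, self.reads_b, self.tpm_a, self.tpm_b)
        if self.measured:
            if any(v is None for v in values):
                raise ValueError(f"{self.gene_symbol}: measured record with missing values")
            if any(v < 0 for v in values):  # type: ignore[operator]
                raise ValueError(f"{self.gene_symbol}: negative read count or TPM")
        elif any(v is not None for v in values):
            raise ValueError(f"{self.gene_symbol}: unmeasured record must have no values")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching how tabulated values are printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def compute_tpm(read_counts, lengths) -> np.ndarray:
    """Transcripts per million from read counts and transcript lengths.

    TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j): the per-base read rate of
    each gene as a share of one million.  The output always sums to 1e6.
    """
    counts = np.asarray(read_counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("read_counts and lengths must have equal length")
    if counts.size == 0:
        raise ValueError("empty input")
    if np.any(counts < 0):
        raise ValueError("negative read count")
    if np.any(lengths <= 0):
        raise ValueError("non-positive transcript length")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("no expressed genes")
    return rate / total * 1e6


def fold_difference(high_reads: float, low_reads: float) -> float:
    """Ratio of the higher to the lower read count, rounded half-up to 2 decimals.

    Undefined when the lower count is zero (the source tables leave those
    cells to the log2 ratio instead).
    """
    if high_reads < 0 or low_reads < 0:
        raise ValueError("negative read count")
    if low_reads == 0:
        raise ValueError("undefined fold difference")
    return round_half_up(high_reads / low_reads, 2)


def log2_tpm_ratio(tpm_a: float, tpm_b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2 of the pseudocounted TPM ratio, antisymmetric in its arguments.

    Computed as log2(a + eps) - log2(b + eps) so that swapping the two
    conditions flips the sign exactly.  ``pseudocount=0`` is allowed and
    yields +/-inf for zero TPMs (and NaN for 0/0).
    """
    if tpm_a < 0 or tpm_b < 0:
        raise ValueError("negative TPM")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    with np.errstate(divide="ignore"):
        return float(np.log2(tpm_a + pseudocount) - np.log2(tpm_b + pseudocount))


def classify_differential(
    records: pd.DataFrame,
    threshold: float = DEFAULT_LOG2_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Threshold classification of every gene in a two-condition table.

    Returns a table with ``gene_symbol, log2_ratio, direction`` where
    direction is ``up`` (log2 Kc/S2 > threshold), ``down`` (< -threshold),
    ``neutral`` otherwise, or ``unmeasured`` for blank rows (NaN ratio).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = []
    for row in records.itertuples(index=False):
        measured = bool(getattr(row, "measured", True)) and not (
            pd.isna(row.kc_tpm) or pd.isna(row.s2_tpm)
        )
        if not measured:
            out.append((row.gene_symbol, math.nan, "unmeasured"))
            continue
        ratio = log2_tpm_ratio(float(row.kc_tpm), float(row.s2_tpm), pseudocount)
        if ratio > threshold:
            direction = "up"
        elif ratio < -threshold:
            direction = "down"
        else:
            direction = "neutral"
        out.append((row.gene_symbol, ratio, direction))
    return pd.DataFrame(out, columns=["gene_symbol", "log2_ratio", "direction"])


def rank_within_class(calls: pd.DataFrame) -> pd.DataFrame:
    """Rank genes within the up and down classes by |log2 ratio|, largest first.

    Ties are broken by gene symbol (lexicographic).  Neutral and unmeasured
    genes receive no rank.  Ranks within each class are a permutation of
    1..class size.
    """
    calls = calls.copy()
    calls["rank_in_class"] = pd.array([pd.NA] * len(calls), dtype="Int64")
    for direction in ("up", "down"):
        mask = calls["direction"] == direction
        if not mask.any():
            continue
        sub = calls.loc[mask, ["gene_symbol", "log2_ratio"]].copy()
        sub["abs_ratio"] = sub["log2_ratio"].abs()
        order = sub.sort_values(
            ["abs_ratio", "gene_symbol"], ascending=[False, True], kind="mergesort"
        ).index
        calls.loc[order, "rank_in_class"] = np.arange(1, len(order) + 1)
    return calls
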