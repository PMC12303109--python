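"""Position-weight-matrix scanning with percentile thresholds and a scramble null.

The scanner replaces a p-value-based motif search with direct log-odds
threshold scanning, where the threshold is *calibrated on the motif's own
training sequences*: an Xth-percentile cutoff is the score that the top X%
of the aligned binding sequences used to build the PWM would themselves
reach.  A 100th-percentile cutoff therefore admits every training sequence
(the minimum training score) and is the permissive choice appropriate for
small Sanger-derived sets; a 25th-percentile cutoff keeps only windows
scoring with the top quarter of training sites ("high stringency").

Enrichment on an enhancer is judged against two controls: a neighbouring
genomic region of the same length, and the mean site count over ``n``
random scrambles of the enhancer (uniform permutations of its letters,
which preserve mononucleotide composition exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT integer coding

__all__ = [
    "PositionWeightMatrix",
    "SiteHit",
    "CalibratedThreshold",
    "EnrichmentResult",
    "build_pwm",
    "score_window",
    "calibrate_threshold",
    "scan_sequence",
    "scramble_null",
    "enrichment_report",
    "encode",
    "decode",
    "reverse_complement",
    "pwms_from_meme",
]


def encode(sequence: str) -> np.ndarray:
    """A/C/G/T string -> integer array (A=0, C=1, G=2, T=3)."""
    seq = sequence.upper()
    try:
        return np.array([_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in sequence") from None


def decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in arr)


def reverse_complement(sequence: str) -> str:
    return decode(_COMPLEMENT[encode(sequence)][::-1])


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Counts -> pseudocounted frequencies -> log2-odds over A/C/G/T.

    ``counts`` is a width x 4 matrix of observed base counts per motif
    position; ``background`` the genomic base composition the odds are taken
    against.  With ``pseudocount=0`` a zero frequency yields -inf log-odds.
    """

    name: str
    counts: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "background", background)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise ValueError("counts must be a width x 4 matrix")
        if np.any(counts < 0):
            raise ValueError("negative count")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if background.shape != (4,) or np.any(background < 0) or not math.isclose(
            background.sum(), 1.0, rel_tol=0, abs_tol=1e-9
        ):
            raise ValueError("background must be 4 probabilities summing to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @cached_property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        if np.any(totals + 4 * self.pseudocount == 0):
            raise ValueError("position with zero counts and zero pseudocount")
        return (self.counts + self.pseudocount) / (totals + 4 * self.pseudocount)

    @cached_property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.frequencies / self.background)

    @property
    def consensus(self) -> str:
        """Row-wise most frequent base (ties to the earlier base in ACGT order)."""
        return decode(np.argmax(self.frequencies, axis=1))

    @property
    def max_score(self) -> float:
        return float(np.max(self.log_odds, axis=1).sum())


@dataclass(frozen=True)
class SiteHit:
    """One predicted binding site, in 1-based forward-strand coordinates.

    ``matched_seq`` always gives the forward-strand bases of the window; for
    a minus-strand hit the motif matches its reverse complement.
    """

    start: int
    strand: str
    score: float
    matched_seq: str


@dataclass(frozen=True)
class CalibratedThreshold:
    percentile: float
    score: float
    n_training: int


@dataclass(frozen=True)
class EnrichmentResult:
    tf: str
    enhancer_count: int
    control_region_count: int | None
    scramble_mean: float
    n_scrambles: int
    rng_seed: int


def build_pwm(
    aligned_seqs: Sequence[str],
    pseudocount: float = 0.25,
    background: Sequence[float] | None = None,
    name: str = "pwm",
) -> PositionWeightMatrix:
    """Count matrix from equal-length aligned binding sequences.

    frequencies[i][b] = (count[i][b] + pseudocount) / (n + 4 * pseudocount);
    log-odds are log2(frequency / background).
    """
    if not aligned_seqs:
        raise ValueError("empty training set")
    if len({len(s) for s in aligned_seqs}) != 1:
        raise ValueError("aligned sequences must have equal lengths")
    width = len(aligned_seqs[0])
    counts = np.zeros((width, 4), dtype=float)
    for seq in aligned_seqs:
        enc = encode(seq)  # rejects ambiguity codes
        counts[np.arange(width), enc] += 1
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return PositionWeightMatrix(name=name, counts=counts, background=bg, pseudocount=pseudocount)


def score_window(pwm: PositionWeightMatrix, window: str, strand: str = "+") -> float:
    """Log-odds score of a single window; minus strand scores its reverse complement."""
    enc = encode(window)
    if enc.size != pwm.width:
        raise ValueError(f"window length {enc.size} != motif width {pwm.width}")
    if strand == "-":
        enc = _COMPLEMENT[enc][::-1]
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return float(pwm.log_odds[np.arange(pwm.width), enc].sum())


def calibrate_threshold(
    pwm: PositionWeightMatrix, training_seqs: Sequence[str], percentile: float
) -> CalibratedThreshold:
    """Nearest-rank percentile threshold over the training-sequence scores.

    The threshold is the k-th highest training score with
    k = ceil(percentile/100 * n), so percentile 100 admits every training
    sequence and smaller percentiles are more stringent.
    """
    if not training_seqs:
        raise ValueError("empty training set")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    scores = sorted(
        (score_window(pwm, s, "+") for s in training_seqs), reverse=True
    )
    k = math.ceil(percentile / 100 * len(scores))
    return CalibratedThreshold(
        percentile=percentile, score=scores[k - 1], n_training=len(scores)
    )


def _window_scores(pwm: PositionWeightMatrix, enc: np.ndarray) -> np.ndarray:
    """Scores of every forward-strand window of an encoded sequence."""
    w = pwm.width
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    return pwm.log_odds[np.arange(w), windows].sum(axis=1)


def scan_sequence(
    pwm: PositionWeightMatrix,
    sequence: str,
    threshold: float,
    strands: str = "both",
) -> list[SiteHit]:
    """All windows scoring >= threshold, on one or both strands.

    Overlapping hits are all reported (no masking).  Hits are sorted by
    1-based start, '+' before '-' at the same start.
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    enc = encode(sequence)
    w = pwm.width
    if enc.size < w:
        raise ValueError(f"sequence length {enc.size} < motif width {w}")
    seq = sequence.upper()
    hits: list[SiteHit] = []
    fwd = _window_scores(pwm, enc)
    for i in np.flatnonzero(fwd >= threshold):
        hits.append(SiteHit(int(i) + 1, "+", float(fwd[i]), seq[i : i + w]))
    if strands == "both":
        rc = _COMPLEMENT[enc][::-1]
        rev = _window_scores(pwm, rc)
        n_win = enc.size - w + 1
        for j in np.flatnonzero(rev >= threshold):
            i = n_win - 1 - int(j)  # forward-strand start of the rc window
            hits.append(SiteHit(i + 1, "-", float(rev[j]), seq[i : i + w]))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scramble_null(
    pwm: PositionWeightMatrix,
    sequence: str,
    threshold: float,
    n_scrambles: int = 100,
    seed: int = 0,
    strands: str = "both",
) -> tuple[float, np.ndarray]:
    """Mean site count over uniform permutations of the sequence's letters.

    Each scramble is an independent Fisher-Yates permutation (via numpy's
    generator), so mononucleotide composition is preserved exactly.  Returns
    the mean and the per-scramble counts.
    """
    if n_scrambles < 1:
        raise ValueError("n_scrambles must be >= 1")
    enc = encode(sequence)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_scrambles, dtype=np.int64)
    for i in range(n_scrambles):
        shuffled = rng.permutation(enc)
        counts[i] = len(scan_sequence(pwm, decode(shuffled), threshold, strands))
    return float(counts.mean()), counts


def enrichment_report(
    pwms: Mapping[str, PositionWeightMatrix],
    thresholds: Mapping[str, float],
    enhancer: str,
    control_region: str | None = None,
    n_scrambles: int = 100,
    seed: int = 0,
    strands: str = "both",
    tfs: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """Per-TF site counts on an enhancer versus both controls.

    Each TF scrambles independently with a child seed derived from ``seed``
    so results do not depend on the order TFs are listed in.
    """
    results = []
    for tf in tfs if tfs is not None else sorted(pwms):
        if tf not in pwms:
            raise KeyError(f"no PWM for requested TF {tf!r}")
        if tf not in thresholds:
            raise KeyError(f"no threshold for requested TF {tf!r}")
        pwm, thr = pwms[tf], thresholds[tf]
        # stable per-TF child seed so scrambles are independent of TF order
        child_seed = (seed + sum(ord(c) for c in tf)) % 2**31
        mean, _ = scramble_null(pwm, enhancer, thr, n_scrambles, child_seed, strands)
        results.append(
            EnrichmentResult(
                tf=tf,
                enhancer_count=len(scan_sequence(pwm, enhancer, thr, strands)),
                control_region_count=(
                    None
                    if control_region is None
                    else len(scan_sequence(pwm, control_region, thr, strands))
                ),
                scramble_mean=mean,
                n_scrambles=n_scrambles,
                rng_seed=child_seed,
            )
        )
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def pwms_from_meme(path) -> dict[str, PositionWeightMatrix]:
    """Load motifs from a MEME minimal-format file as pseudocount-free PWMs.

    The letter-probability matrix is scaled back to counts by ``nsites`` so
    downstream pseudocounting behaves as for raw aligned sequences.
    """
    from Bio import motifs as bio_motifs

    out: dict[str, PositionWeightMatrix] = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "minimal"):
            nsites = m.num_occurrences or 20
            counts = np.array(
                [[m.counts[b][i] for b in ALPHABET] for i in range(m.length)], dtype=float
            )
            bg = np.array([m.background[b] for b in ALPHABET], dtype=float)
            name = m.name or m.id
            out[name] = PositionWeightMatrix(
                name=name, counts=counts, background=bg / bg.sum(), pseudocount=0.0
            )
    if not out:
        raise ValueError(f"{path}: no motifs found")
    return out
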