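"""PWM construction, scanning, percentile calibration, and the scramble null."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdgnscreen.motifs import (
    build_pwm,
    calibrate_threshold,
    enrichment_report,
    pwms_from_meme,
    reverse_complement,
    scan_sequence,
    score_window,
    scramble_null,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestBuildPwm:
    def test_frequencies_and_log_odds_by_hand(self):
        pwm = build_pwm(["ACG", "ACG", "ACT"], pseudocount=0)
        assert pwm.frequencies[2, 2] == pytest.approx(2 / 3)  # G at position 3
        assert pwm.frequencies[2, 3] == pytest.approx(1 / 3)  # T at position 3
        assert pwm.log_odds[0, 0] == pytest.approx(2.0)  # log2(1 / 0.25)

    def test_degenerate_consensus_max_score(self):
        pwm = build_pwm(["AAAA"] * 5, pseudocount=0)
        assert pwm.consensus == "AAAA"
        assert pwm.max_score == pytest.approx(8.0)  # 4 * log2(4)

    def test_pseudocount_formula(self):
        pwm = build_pwm(["A"], pseudocount=0.25)
        assert pwm.frequencies[0, 0] == pytest.approx(1.25 / 2)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            build_pwm([])
        with pytest.raises(ValueError):
            build_pwm(["AC", "ACG"])
        with pytest.raises(ValueError, match="non-ACGT"):
            build_pwm(["ACN"])

    def test_zero_pseudocount_gives_minus_infinity(self):
        pwm = build_pwm(["AAC"], pseudocount=0)
        assert pwm.log_odds[0, 3] == -math.inf

    @given(st.lists(st.sampled_from(["ACGT", "AAGT", "ACCT", "TCGA"]), min_size=1, max_size=8))
    @settings(derandomize=True, max_examples=50)
    def test_rows_sum_to_one_and_consensus_is_maximal(self, seqs):
        pwm = build_pwm(seqs, pseudocount=0.25)
        np.testing.assert_allclose(pwm.frequencies.sum(axis=1), 1.0, atol=1e-9)
        assert score_window(pwm, pwm.consensus) == pytest.approx(pwm.max_score)
        for other in ("ACGT", "TTTT", "GGGG"):
            assert score_window(pwm, other) <= pwm.max_score + 1e-12

    def test_cross_check_against_biopython_pssm(self):
        """Independent oracle: Biopython's PSSM on the same counts/background."""
        from Bio.motifs import Motif
        from Bio.motifs.matrix import FrequencyPositionMatrix

        seqs = ["ACGTA", "ACGTC", "ATGTA", "CCGTA"]
        pwm = build_pwm(seqs, pseudocount=0.5)
        counts = FrequencyPositionMatrix(
            "ACGT",
            {b: [sum(1 for s in seqs if s[i] == b) for i in range(5)] for b in "ACGT"},
        )
        bio = Motif("ACGT", counts=counts).counts.normalize(pseudocounts=0.5).log_odds()
        for window in ("ACGTA", "TTTTT", "CCGTC"):
            expected = sum(bio[window[i]][i] for i in range(5))
            assert score_window(pwm, window) == pytest.approx(expected)


class TestScoreWindow:
    def test_minus_strand_equals_reverse_complement_forward(self):
        pwm = build_pwm(["ACGT", "ACGA", "TCGT"], pseudocount=0.25)
        rng = np.random.default_rng(0)
        for _ in range(50):
            window = "".join(rng.choice(list("ACGT"), 4))
            assert score_window(pwm, window, "-") == pytest.approx(
                score_window(pwm, reverse_complement(window), "+")
            )

    def test_palindrome_scores_equal_on_both_strands(self):
        pwm = build_pwm(["ACGT"], pseudocount=0.25)
        assert score_window(pwm, "ACGT", "+") == pytest.approx(score_window(pwm, "ACGT", "-"))

    def test_length_mismatch_and_bad_chars(self):
        pwm = build_pwm(["ACG"], pseudocount=0.25)
        with pytest.raises(ValueError):
            score_window(pwm, "AC")
        with pytest.raises(ValueError):
            score_window(pwm, "ACN")


def _graded_pwm():
    # four training sequences with strictly distinct scores
    return build_pwm(["AAAA", "AAAC", "AACC", "ACCC"], pseudocount=0.25)


class TestCalibration:
    @pytest.fixture()
    def graded_pwm(self):
        return _graded_pwm()

    def test_nearest_rank_thresholds(self, graded_pwm):
        training = ["AAAA", "AAAC", "AACC", "ACCC"]
        scores = sorted((score_window(graded_pwm, s) for s in training), reverse=True)
        assert calibrate_threshold(graded_pwm, training, 100).score == scores[3]
        assert calibrate_threshold(graded_pwm, training, 50).score == scores[1]
        assert calibrate_threshold(graded_pwm, training, 25).score == scores[0]

    @given(pct=st.floats(1, 100))
    @settings(derandomize=True, max_examples=60)
    def test_admitted_fraction_at_least_percentile(self, pct):
        pwm = _graded_pwm()
        training = ["AAAA", "AAAC", "AACC", "ACCC"]
        thr = calibrate_threshold(pwm, training, pct).score
        admitted = sum(score_window(pwm, s) >= thr for s in training)
        assert admitted / len(training) >= pct / 100 - 1e-12

    def test_percentile_100_admits_everything(self, graded_pwm):
        training = ["AAAA", "AAAC", "AACC", "ACCC"]
        thr = calibrate_threshold(graded_pwm, training, 100).score
        assert all(score_window(graded_pwm, s) >= thr for s in training)

    def test_empty_training_set(self, graded_pwm):
        with pytest.raises(ValueError):
            calibrate_threshold(graded_pwm, [], 50)


class TestScan:
    def test_consensus_hit_on_both_strands(self):
        pwm = build_pwm(["AAC"], pseudocount=0)
        hits = scan_sequence(pwm, "AACGTT", pwm.max_score)
        assert [(h.start, h.strand, h.matched_seq) for h in hits] == [
            (1, "+", "AAC"),
            (4, "-", "GTT"),  # GTT is the reverse complement of AAC
        ]

    def test_no_hits_in_mismatching_sequence(self):
        pwm = build_pwm(["AAC"], pseudocount=0)
        assert scan_sequence(pwm, "CCCCCC", pwm.max_score) == []

    def test_minus_infinity_threshold_hits_everywhere(self):
        pwm = build_pwm(["ACG", "TTG"], pseudocount=0.25)
        hits = scan_sequence(pwm, "ACGTACGT", -math.inf)
        assert len(hits) == (8 - 3 + 1) * 2

    def test_too_short_sequence(self):
        pwm = build_pwm(["ACGT"], pseudocount=0.25)
        with pytest.raises(ValueError):
            scan_sequence(pwm, "ACG", 0.0)

    @given(dna.filter(lambda s: len(s) >= 3))
    @settings(derandomize=True, max_examples=100)
    def test_strand_symmetry_under_reverse_complement(self, seq):
        """Scanning the reverse complement mirrors starts and flips strands."""
        pwm = build_pwm(["ACG", "ACC", "TCG"], pseudocount=0.25)
        w, L = 3, len(seq)
        fwd = scan_sequence(pwm, seq, -5.0)
        rc = scan_sequence(pwm, reverse_complement(seq), -5.0)
        mapped = sorted(
            (L - w + 2 - h.start, {"+": "-", "-": "+"}[h.strand], round(h.score, 9))
            for h in rc
        )
        assert mapped == sorted((h.start, h.strand, round(h.score, 9)) for h in fwd)

    @given(seq=dna.filter(lambda s: len(s) >= 3), thr=st.floats(-10, 10))
    @settings(derandomize=True, max_examples=100)
    def test_count_non_increasing_in_threshold(self, seq, thr):
        pwm = build_pwm(["ACG", "ACC"], pseudocount=0.25)
        assert len(scan_sequence(pwm, seq, thr)) >= len(scan_sequence(pwm, seq, thr + 1.0))

    def test_exhaustive_window_enumeration_oracle(self):
        """Hit set equals brute-force enumeration of every (window, strand)."""
        pwm = build_pwm(["ACGT", "ACGA", "TCGT"], pseudocount=0.25)
        seq = "ACGTACGATTCGTACGT"
        thr = 2.0
        expected = []
        for i in range(len(seq) - 3):
            window = seq[i : i + 4]
            for strand in "+-":
                s = score_window(pwm, window, strand)
                if s >= thr:
                    expected.append((i + 1, strand, round(s, 9)))
        got = [(h.start, h.strand, round(h.score, 9)) for h in scan_sequence(pwm, seq, thr)]
        assert got == sorted(expected)


class TestScrambleNull:
    def test_homopolymer_is_invariant(self):
        pwm = build_pwm(["AAAA"], pseudocount=0)
        mean, counts = scramble_null(pwm, "A" * 20, 0.0, n_scrambles=10, seed=3,
                                     strands="forward")
        assert mean == 17.0 and counts.std() == 0.0

    def test_impossible_site_mean_zero(self):
        pwm = build_pwm(["AG"], pseudocount=0)  # needs a G
        mean, _ = scramble_null(pwm, "ACACACAC", 0.0, n_scrambles=5, seed=0)
        assert mean == 0.0

    def test_matches_exact_permutation_expectation(self):
        """Two-letter toy case against brute-force enumeration of all orderings."""
        pwm = build_pwm(["AC"], pseudocount=0)
        seq = "AACCC"
        thr = pwm.max_score
        perms = set(itertools.permutations(seq))
        per_perm = [len(scan_sequence(pwm, "".join(p), thr)) for p in perms]
        exact_mean = np.mean(per_perm)
        exact_sd = np.std(per_perm)
        n = 4000
        mean, _ = scramble_null(pwm, seq, thr, n_scrambles=n, seed=11)
        assert abs(mean - exact_mean) <= 3 * exact_sd / math.sqrt(n)

    def test_mean_non_increasing_in_threshold(self):
        pwm = build_pwm(["ACG", "ACC"], pseudocount=0.25)
        seq = "ACGTACCGTACGGTACC"
        means = [
            scramble_null(pwm, seq, thr, n_scrambles=50, seed=5)[0]
            for thr in (-5.0, 0.0, 3.0)
        ]
        assert means[0] >= means[1] >= means[2]

    def test_seed_reproducibility(self):
        pwm = build_pwm(["ACG"], pseudocount=0.25)
        a = scramble_null(pwm, "ACGTACGTGG", 1.0, n_scrambles=20, seed=42)
        b = scramble_null(pwm, "ACGTACGTGG", 1.0, n_scrambles=20, seed=42)
        assert a[0] == b[0] and (a[1] == b[1]).all()


class TestEnrichmentReport:
    def test_identical_enhancer_and_control_counts_match(self):
        pwm = build_pwm(["ACGT", "ACGA"], pseudocount=0.25)
        seq = "ACGTACGATTACGTACGAGG"
        results = enrichment_report({"tf": pwm}, {"tf": 1.0}, seq, seq, n_scrambles=10, seed=1)
        (r,) = results
        assert r.enhancer_count == r.control_region_count
        assert r.n_scrambles == 10

    def test_missing_pwm_errors(self):
        pwm = build_pwm(["ACGT"], pseudocount=0.25)
        with pytest.raises(KeyError):
            enrichment_report({"a": pwm}, {"a": 0.0}, "ACGTACGT", tfs=["b"])

    def test_results_independent_of_tf_order(self):
        p1 = build_pwm(["ACGT"], pseudocount=0.25)
        p2 = build_pwm(["TTGA"], pseudocount=0.25)
        seq = "ACGTTTGACCACGTGGTTGA"
        fwd = enrichment_report({"x": p1, "y": p2}, {"x": 1.0, "y": 1.0}, seq,
                                n_scrambles=20, seed=9, tfs=["x", "y"])
        rev = enrichment_report({"x": p1, "y": p2}, {"x": 1.0, "y": 1.0}, seq,
                                n_scrambles=20, seed=9, tfs=["y", "x"])
        assert {r.tf: r.scramble_mean for r in fwd} == {r.tf: r.scramble_mean for r in rev}


class TestMemeMinimal:
    def test_roundtrip_counts_and_scan(self, tmp_path):
        meme = tmp_path / "motif.meme"
        meme.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF m1\nletter-probability matrix: alength= 4 w= 3 nsites= 4 E= 0\n"
            " 1.0 0.0 0.0 0.0\n 0.5 0.5 0.0 0.0\n 0.0 0.0 1.0 0.0\n"
        )
        pwms = pwms_from_meme(meme)
        assert set(pwms) == {"m1"}
        pwm = pwms["m1"]
        assert pwm.width == 3
        assert pwm.consensus == "AAG"
        np.testing.assert_allclose(pwm.frequencies[1], [0.5, 0.5, 0, 0], atol=1e-9)
        hits = scan_sequence(pwm, "AAGCCC", pwm.max_score)
        assert hits[0].start == 1 and hits[0].strand == "+"
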