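import io
import math

import numpy as np
import pytest

from funcmotif.intervals import reverse_complement
from funcmotif.motifs import (
    CalibrationError,
    MotifParseError,
    PWMModel,
    best_window_score,
    calibrate_cutoff,
    load_jaspar,
    scan,
    score_window,
    write_jaspar,
)
from tests.conftest import random_windows

TOY_JASPAR = """\
>TOY1\ttoy
A  [ 4 0 ]
C  [ 0 4 ]
G  [ 0 0 ]
T  [ 0 0 ]
"""


def toy_pwm(pseudocount=0.0):
    (pwm,) = load_jaspar(io.StringIO(TOY_JASPAR), pseudocount_fraction=pseudocount)
    return pwm


def uniform_pwm(width=4):
    return PWMModel("UNIF", np.full((width, 4), 25.0))


class TestLoadJaspar:
    def test_degenerate_columns_without_pseudocount(self):
        pwm = toy_pwm(0.0)
        assert pwm.width == 2
        assert np.allclose(pwm.freq[0], [1, 0, 0, 0])
        assert np.allclose(pwm.freq[1], [0, 1, 0, 0])

    def test_uniform_matrix_has_zero_log_odds(self):
        assert np.allclose(uniform_pwm().log_odds, 0.0)

    def test_roundtrip_preserves_frequencies(self, pwms, tmp_path):
        path = tmp_path / "rt.jaspar"
        write_jaspar(pwms, path)
        reread = load_jaspar(path)
        assert [p.motif_id for p in reread] == [p.motif_id for p in pwms]
        for a, b in zip(pwms, reread):
            assert np.allclose(a.freq, b.freq, atol=1e-9)

    def test_malformed_matrix_raises(self):
        bad = TOY_JASPAR.replace("A  [ 4 0 ]", "A  [ 4 0 1 ]")
        with pytest.raises(MotifParseError):
            load_jaspar(io.StringIO(bad))

    def test_negative_counts_raise(self):
        with pytest.raises(MotifParseError):
            PWMModel("neg", np.array([[-1, 1, 0, 0], [1, 0, 0, 0]]))


class TestScoreWindow:
    def test_zero_information_motif_scores_zero_everywhere(self, rng):
        pwm = uniform_pwm()
        for window in random_windows(rng, 10, 4):
            assert score_window(pwm, window) == pytest.approx(0.0)

    def test_consensus_score_equals_hand_summed_log_odds(self):
        # toy matrix, pseudocount fraction 0.01, uniform background:
        # each column total 4, pseudo mass 0.04 spread as 0.01 per cell
        pwm = toy_pwm(0.01)
        dominant = (4 + 0.01) / 4.04
        expected = 2 * math.log2(dominant / 0.25)
        assert score_window(pwm, "AC") == pytest.approx(expected, abs=1e-12)

    def test_minus_strand_is_score_of_reverse_complement(self, pwms, rng):
        pwm = pwms[0]
        for window in random_windows(rng, 10, pwm.width):
            # strand definition: the minus-strand score of w IS the
            # plus-strand score of revcomp(w); cross-check via scan
            hits = scan(pwm, window, cutoff=-np.inf)
            minus = [h for h in hits if h.strand == "-"]
            assert minus[0].score == pytest.approx(
                score_window(pwm, reverse_complement(window))
            )

    def test_window_with_n_is_undefined(self, pwms):
        with pytest.raises(ValueError):
            score_window(pwms[0], "N" * pwms[0].width)


class TestCalibration:
    def test_separable_background_gives_zero_fpr(self, pwms, rng):
        pwm = pwms[0]
        # AT-only windows score far below any plausible planted instance
        windows = ["".join(b) for b in np.random.default_rng(1).choice(
            list("AT"), size=(6000, 50))]
        cal = calibrate_cutoff(pwm, windows, target_fpr=0.002)
        recount = sum(
            best_window_score(pwm, w) >= cal.cutoff for w in windows
        )
        assert recount / len(windows) < 0.002
        assert cal.achieved_fpr < cal.target_fpr
        # the cutoff separates a strong planted instance from background
        assert score_window(pwm, pwm.consensus()) >= cal.cutoff

    def test_vacuous_target_returns_minimum_score(self, pwms, rng):
        windows = random_windows(rng, 50, 30)
        cal = calibrate_cutoff(pwms[0], windows, target_fpr=1.0)
        assert cal.cutoff == pytest.approx(
            min(best_window_score(pwms[0], w) for w in windows)
        )

    def test_too_few_windows_raises(self, pwms, rng):
        with pytest.raises(CalibrationError):
            calibrate_cutoff(pwms[0], random_windows(rng, 100, 30), 0.002)

    def test_lowering_target_never_lowers_cutoff(self, pwms, rng):
        windows = random_windows(rng, 2000, 100)
        cuts = [
            calibrate_cutoff(pwms[0], windows, target_fpr=f).cutoff
            for f in (0.05, 0.02, 0.01)
        ]
        assert cuts[0] <= cuts[1] <= cuts[2]


class TestScan:
    def test_infinite_cutoff_yields_nothing(self, pwms, rng):
        (window,) = random_windows(rng, 1, 100)
        assert scan(pwms[0], window, cutoff=np.inf) == []

    def test_sequence_shorter_than_motif_yields_nothing(self, pwms):
        assert scan(pwms[0], "ACGT", cutoff=-np.inf) == []

    def test_planted_consensus_is_the_only_hit_at_high_cutoff(self, pwms, rng):
        pwm = pwms[0]
        flank = random_windows(rng, 2, 30)
        seq = flank[0] + pwm.consensus() + flank[1]
        cutoff = pwm.max_score() - 1e-6
        hits = [h for h in scan(pwm, seq, cutoff) if h.strand == "+"]
        assert [h.interval.start for h in hits] == [30]

    def test_matches_exhaustive_enumeration(self, pwms, rng):
        # oracle: score every offset x strand window independently
        for pwm in pwms:
            for window in random_windows(rng, 10, 80):
                cutoff = 5.0
                got = {
                    (m.interval.start, m.strand, round(m.score, 9))
                    for m in scan(pwm, window, cutoff)
                }
                expected = set()
                for i in range(len(window) - pwm.width + 1):
                    sub = window[i : i + pwm.width]
                    for strand, seq in (("+", sub), ("-", reverse_complement(sub))):
                        s = score_window(pwm, seq)
                        if s >= cutoff:
                            expected.add((i, strand, round(s, 9)))
                assert got == expected

    def test_revcomp_scan_mirrors_matches(self, pwms, rng):
        pwm = pwms[0]
        (seq,) = random_windows(rng, 1, 50)
        fwd = scan(pwm, seq, cutoff=-50.0)
        rev = scan(pwm, reverse_complement(seq), cutoff=-50.0)
        L, W = len(seq), pwm.width
        mirrored = {
            (L - m.interval.end, {"+": "-", "-": "+"}[m.strand],
             round(m.score, 9))
            for m in rev
        }
        assert {
            (m.interval.start, m.strand, round(m.score, 9)) for m in fwd
        } == mirrored

    def test_genome_offset_shifts_coordinates(self, pwms):
        pwm = pwms[0]
        seq = "A" * 10 + pwm.consensus() + "A" * 10
        hits = scan(pwm, seq, pwm.max_score() - 1e-6, chrom="chr5", offset=1000)
        plus = [h for h in hits if h.strand == "+"]
        assert plus[0].interval.chrom == "chr5"
        assert plus[0].interval.start == 1010
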