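"""The windowed acidity scanner against direct per-window counting."""

import numpy as np
import pytest

from acidtrace.acidic import (AcidicScanParams, call_cter, classify_family,
                              scan_acidic_windows)
from acidtrace.errors import InputError, ValidationError
from acidtrace.seqio import ProteinRecord

from .conftest import AMINO_ACIDS, brute_force_acidic_hits, random_protein


def rec(residues, rid="s"):
    return ProteinRecord(id=rid, residues=residues)


class TestScan:
    def test_printed_mouse_motif(self, motif_records):
        # the acidic cluster DEDEEGEEDEE: its first 10 residues hold 9 D/E
        seq = motif_records["mouse_cter_motif"]
        hits = scan_acidic_windows(seq)
        motif_start = seq.length - 11 + 1
        first = [h for h in hits if h.start == motif_start]
        assert first and first[0].acidic_count == 9
        assert first[0].fraction == pytest.approx(0.9)

    def test_all_acidic_single_hit(self):
        hits = scan_acidic_windows(rec("DDDDDDDDDD"))
        assert len(hits) == 1
        assert hits[0].fraction == 1.0
        assert (hits[0].start, hits[0].end) == (1, 10)

    def test_repressor_endecapeptide_no_hits(self, motif_records):
        # LKFGVNAILSS carries zero D/E
        assert scan_acidic_windows(
            rec("LKFGVNAILSS"), AcidicScanParams(tail_len="all")) == []

    def test_short_sequence_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert scan_acidic_windows(rec("DDEEDDEED")) == []
        assert "shorter than window" in caplog.text

    @pytest.mark.parametrize("tail_len", [50, "all", 15])
    def test_matches_brute_force_random(self, tail_len):
        rng = np.random.default_rng(42 if tail_len == 50 else 43)
        params = AcidicScanParams(tail_len=tail_len)
        # enrich D/E so hits actually occur
        alphabet = list(AMINO_ACIDS) + list("DE" * 10)
        for i in range(130):
            length = int(rng.integers(10, 200))
            residues = "".join(rng.choice(alphabet, size=length))
            seq = rec(residues, f"r{i}")
            got = [(h.start, h.end, h.acidic_count)
                   for h in scan_acidic_windows(seq, params)]
            want = brute_force_acidic_hits(residues, 10, 0.8, set("DE"),
                                           tail_len)
            assert got == want

    def test_x_never_counts_as_acidic(self):
        # 7 D/E + one X: a hit only if X wrongly counted as acidic
        assert scan_acidic_windows(rec("DEDEDEDXLL")) == []
        assert len(scan_acidic_windows(rec("DEDEDEDDLL"))) == 1

    def test_inclusive_threshold_eight_of_ten(self):
        # "at least 80 %" with window 10 means exactly 8 acidic qualifies
        assert len(scan_acidic_windows(rec("DEDEDEDELL"))) == 1
        assert scan_acidic_windows(rec("DEDEDEDLLL")) == []


class TestCterCall:
    def test_tail_restriction_semantics(self):
        # the only D/E-rich stretch sits ~200 residues from the terminus
        residues = "D" * 12 + "LKVG" * 50 + "MKVLW" * 8
        seq = rec(residues)
        assert not call_cter(seq, AcidicScanParams(tail_len=50)).positive
        assert call_cter(seq, AcidicScanParams(tail_len="all")).positive

    def test_positive_with_dense_tail(self):
        seq = rec("MKVLW" * 20 + "DEDDEELDEDEEDE")  # 12 D/E of final 14
        call = call_cter(seq)
        assert call.positive and call.n_hits >= 1

    def test_best_hit_tie_breaks_rightmost(self):
        # two disjoint all-acidic windows: best hit must take the rightmost
        seq = rec("DDDDDDDDDD" + "LLLLL" + "EEEEEEEEEE",)
        call = call_cter(seq, AcidicScanParams(tail_len="all"))
        assert call.best_hit.start == 16

    def test_nine_residue_sequence_negative(self):
        assert not call_cter(rec("DDEEDDEED")).positive


class TestClassifyFamily:
    def test_counts_positives(self, rng):
        pos = [rec("MKVLW" * 10 + "E" * 12, f"p{i}") for i in range(3)]
        neg = [random_protein(rng, 60, f"n{i}") for i in range(2)]
        for n in neg:
            assert "E" * 8 not in n.residues  # keep fixture honest
        table = classify_family(pos + neg)
        assert int(table["positive"].sum()) == 3

    def test_empty_list(self):
        assert len(classify_family([])) == 0

    def test_identical_records_identical_calls(self):
        with pytest.raises(ValidationError):
            classify_family([rec("D" * 20, "a"), rec("D" * 20, "a")])
        table = classify_family([rec("D" * 20, "a"), rec("D" * 20, "b")])
        assert table.drop(columns="seq_id").iloc[0].equals(
            table.drop(columns="seq_id").iloc[1])


class TestProperties:
    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        alphabet = list(AMINO_ACIDS) + list("DE" * 6)
        for i in range(40):
            residues = "".join(rng.choice(alphabet,
                                          size=int(rng.integers(10, 120))))
            seq = rec(residues, f"r{i}")
            prev = None
            for f in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0):
                hits = {(h.start, h.end) for h in scan_acidic_windows(
                    seq, AcidicScanParams(min_fraction=f, tail_len="all"))}
                if prev is not None:
                    assert hits <= prev
                prev = hits

    def test_positive_calls_monotone_in_tail_len(self):
        seq = rec("D" * 12 + "MKVLW" * 30)
        positives = [call_cter(seq, AcidicScanParams(tail_len=t)).positive
                     for t in (20, 60, 120, "all")]
        assert positives == sorted(positives)  # never True -> False

    def test_translation_equivariance(self, rng):
        params = AcidicScanParams(tail_len="all")
        base = "MKVLW" * 4 + "DEDEEGEEDEE"
        hits0 = scan_acidic_windows(rec(base), params)
        for k in (1, 5, 17):
            shifted = "G" * k + base
            hits = scan_acidic_windows(rec(shifted), params)
            assert [(h.start - k, h.end - k, h.acidic_count) for h in hits] \
                == [(h.start, h.end, h.acidic_count) for h in hits0]


class TestHypothesisProperties:
    from hypothesis import given, settings, strategies as st

    sequences = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=120)

    @given(residues=sequences)
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_scan_always_matches_brute_force(self, residues):
        seq = rec(residues, "h")
        got = [(h.start, h.end, h.acidic_count)
               for h in scan_acidic_windows(seq)]
        assert got == brute_force_acidic_hits(residues, 10, 0.8,
                                              set("DE"), 50)

    @given(residues=sequences)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_every_hit_satisfies_its_own_invariants(self, residues):
        params = AcidicScanParams(tail_len="all")
        for h in scan_acidic_windows(rec(residues, "h"), params):
            assert h.end - h.start + 1 == params.window
            assert h.fraction == h.acidic_count / params.window
            assert h.fraction >= params.min_fraction


def test_param_validation():
    with pytest.raises(InputError):
        AcidicScanParams(window=0)
    with pytest.raises(InputError):
        AcidicScanParams(min_fraction=0.0)
    with pytest.raises(InputError):
        AcidicScanParams(window=20, tail_len=10)
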