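import pytest
from hypothesis import given, settings, strategies as st

from edcscan.protein_features import (
    aa_composition,
    detect_repeats,
    scan_cterminal_motif,
    segment_architecture,
)
from edcscan.synthetic_edc import CTERM_MOTIF, TAIL_BIAS_PAIRS, _sftp_tail

protein = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=200)


class TestComposition:
    def test_half_and_half(self):
        prof = aa_composition("RRREEE")
        assert prof.frequencies["R"] == 0.5
        assert prof.frequencies["E"] == 0.5
        assert prof.top2_fraction == 1.0

    def test_single_residue(self):
        assert aa_composition("G").frequencies["G"] == 1.0

    def test_x_excluded_from_denominator(self):
        prof = aa_composition("GXGX")
        assert prof.frequencies["G"] == 1.0
        assert prof.length == 2

    @given(protein)
    @settings(max_examples=50, deadline=None)
    def test_frequencies_sum_to_one(self, seq):
        assert sum(aa_composition(seq).frequencies.values()) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aa_composition("")


class TestRepeats:
    def test_perfect_triplet_repeat(self):
        anns = detect_repeats("GSQGSQGSQ", min_unit=3)
        assert len(anns) == 1
        a = anns[0]
        assert (a.unit_length, a.copy_number, a.mean_identity) == (3, 3, 100.0)
        assert a.span == (0, 9)

    def test_imperfect_copy_identity(self):
        anns = detect_repeats("GSQGSQGAQ", min_unit=3)
        a = anns[0]
        assert a.unit_length == 3 and a.consensus == "GSQ"
        assert a.mean_identity == pytest.approx(100 * 8 / 9)

    def test_random_proteins_rarely_called(self, rng):
        n_called = 0
        trials = 300
        for _ in range(trials):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
            n_called += bool(detect_repeats(seq, min_copies=3, min_identity=0.8))
        assert n_called / trials <= 0.05

    def test_known_unit_length_recovered(self, rng):
        from edcscan.synthetic_edc import _mutate_protein

        spice = "QSGVDNH"
        for i in range(10):
            bias = TAIL_BIAS_PAIRS[i % 4]
            unit_len = int(rng.integers(9, 22))
            unit = "".join(
                bias[rng.integers(0, 2)] if rng.random() < 0.8
                else spice[rng.integers(0, len(spice))]
                for _ in range(unit_len)
            )
            tail = "".join(
                _mutate_protein("M" + unit, 0.05, rng)[1:] for _ in range(12)
            )
            anns = detect_repeats(tail)
            assert anns, "no repeat found in synthetic tail"
            best = max(anns, key=lambda a: a.copy_number * (a.span[1] - a.span[0]))
            assert best.unit_length == unit_len
            assert best.copy_number >= 3

    def test_tail_bias_reflected_in_top2(self, rng):
        for i in range(8):
            bias = TAIL_BIAS_PAIRS[i % 4]
            body = _sftp_tail(rng, bias)[: -len(CTERM_MOTIF)]
            prof = aa_composition(body)
            assert abs(prof.top2_fraction - 0.8) <= 0.05
            assert {r for r, _ in prof.top2} == set(bias)


class TestMotif:
    def test_exact_terminal_match(self):
        m = scan_cterminal_motif("A" * 40 + CTERM_MOTIF, CTERM_MOTIF)
        assert m.found and m.distance_from_cterm == 0 and m.score == 1.0

    def test_absent_everywhere(self):
        m = scan_cterminal_motif("A" * 60, "WWWWWW")
        assert not m.found

    def test_nterminal_occurrence_outside_window(self):
        seq = CTERM_MOTIF + "A" * 100
        m = scan_cterminal_motif(seq, CTERM_MOTIF, window=50)
        assert not m.found

    def test_wildcards_match(self):
        m = scan_cterminal_motif("AAAQSVDRSGHQ", "QxVDxSGHQ")
        assert m.found and m.score == 1.0


class TestSegmentArchitecture:
    def mk(self, span):
        from edcscan.protein_features import RepeatAnnotation

        return RepeatAnnotation(3, "GSQ", (span[1] - span[0]) / 3, span, 100.0)

    def test_three_segments(self):
        n, r, c = segment_architecture("A" * 100, [self.mk((20, 80))])
        assert (n, r, c) == ((0, 20), (20, 80), (80, 100))

    def test_repeats_to_last_residue_empty_cterm(self):
        n, r, c = segment_architecture("A" * 100, [self.mk((20, 100))])
        assert c == (100, 100)

    def test_repeats_from_first_residue_empty_nterm(self):
        n, r, c = segment_architecture("A" * 100, [self.mk((0, 80))])
        assert n == (0, 0)

    def test_no_repeats_flagged(self):
        n, r, c = segment_architecture("A" * 100, [])
        assert n == (0, 100) and r is None and c is None
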