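import numpy as np
import pytest

from edcscan.io_formats import Scaffold, reverse_complement
from edcscan.homology_search import (
    SearchParams,
    mask_low_complexity,
    score_alignment,
    search_many,
    search_translated,
    shannon_entropy,
)
from edcscan.synthetic_edc import _encode, _random_dna


def embed(protein, seed=0, flank=4000):
    """Random scaffold with the protein's coding sequence embedded."""
    rng = np.random.default_rng(seed)
    cds = _encode(protein, rng)
    left = _random_dna(rng, flank)
    right = _random_dna(rng, flank)
    return Scaffold("s", left + cds + right), len(left), len(left) + len(cds)


class TestMasking:
    def test_disabled_is_identity(self):
        seq = "QQQQQQQQQQQQQQQQ"
        assert mask_low_complexity(seq, enabled=False) == seq

    def test_homopolymer_fully_masked(self):
        # window entropy of a homopolymer is 0 bits
        masked = mask_low_complexity("QQQQQQQQQQQQ", window=12, entropy_threshold=2.2)
        assert masked == "qqqqqqqqqqqq"

    def test_diverse_window_unmasked(self):
        # 12 distinct residues: entropy log2(12) ~ 3.58 bits > 2.2
        seq = "ACDEFGHIKLMN"
        assert shannon_entropy(seq) == pytest.approx(np.log2(12))
        assert mask_low_complexity(seq, window=12, entropy_threshold=2.2) == seq

    def test_window_precondition(self):
        with pytest.raises(ValueError):
            mask_low_complexity("ACDEFG", window=3)


class TestScoreAlignment:
    def test_blosum62_diagonal_mkv(self):
        # M:5 + K:5 + V:4 from the published BLOSUM62 diagonal
        assert score_alignment("MKV", "MKV") == 14

    def test_gap_costs_affine(self):
        # gap of length 2 costs open(11) + 2*extend(1) = 13
        assert score_alignment("MKV--LE", "MKVAALE") == pytest.approx(
            score_alignment("MKVLE", "MKVLE") - 13
        )


class TestSearchTranslated:
    QUERY = "MDALKCVEHWQRITSYPNGFKLMDEAVRHCW"  # 31 diverse residues

    def test_exact_embedded_exon_recovered(self):
        scaffold, start, end = embed(self.QUERY, seed=1)
        hits = search_translated("q", self.QUERY, [scaffold])
        top = hits[0]
        assert top.identity == 100.0
        assert top.strand == "+"
        assert (top.genomic.start, top.genomic.end) == (start, end)

    def test_reverse_strand_same_span(self):
        scaffold, start, end = embed(self.QUERY, seed=1)
        rc = Scaffold("s", reverse_complement(scaffold.sequence))
        hits = search_translated("q", self.QUERY, [rc])
        top = hits[0]
        assert top.strand == "-"
        assert (top.genomic.start, top.genomic.end) == (
            rc.length - end,
            rc.length - start,
        )

    def test_scores_recomputable_from_alignment(self, lesioned_cluster):
        cfg, scaffold, truth, _ = lesioned_cluster
        queries = {r.gene_name: r.protein for r in truth}
        params = SearchParams()
        for hsps in search_many(queries, [scaffold], params).values():
            for h in hsps:
                assert h.score == pytest.approx(
                    score_alignment(h.query_aln, h.target_aln, params)
                )

    def test_empty_scaffold_set(self):
        assert search_translated("q", self.QUERY, []) == []

    def test_query_shorter_than_seed_rejected(self):
        scaffold, _, _ = embed(self.QUERY, seed=1)
        with pytest.raises(ValueError):
            search_translated("q", "MK", [scaffold])


class TestMaskingChangesSearch:
    def test_biased_query_found_only_unmasked(self):
        # compositionally biased query, the motivating case for turning the
        # low-complexity filter off
        polyqp = "M" + "QP" * 40
        scaffold, start, end = embed(polyqp, seed=3)
        unmasked = search_translated("q", polyqp, [scaffold], SearchParams(mask=False))
        masked = search_translated("q", polyqp, [scaffold], SearchParams(mask=True))
        assert any(
            h.genomic.start >= start - 30 and h.genomic.end <= end + 30
            for h in unmasked
        )
        assert masked == []
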