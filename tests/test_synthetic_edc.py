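import numpy as np
import pytest

from edcscan.io_formats import translate
from edcscan.phylogenetics import is_monophyletic
from edcscan.synthetic_edc import (
    CTERM_MOTIF,
    ClusterConfig,
    amplify_tandem,
    generate_cluster,
    generate_species_pair,
    implant_lesion,
    left_align_indel,
)


def spliced_cds(scaffold, rec):
    parts = sorted(rec.cds, key=lambda iv: iv.start)
    seq = "".join(scaffold.sequence[iv.start : iv.end] for iv in parts)
    if rec.strand == "-":
        from edcscan.io_formats import reverse_complement

        seq = reverse_complement(seq)
    return seq


class TestGenerateCluster:
    def test_gene_count(self):
        cfg = ClusterConfig(seed=1, n_sedc=5, n_sftp=2, lce_array_size=10)
        _, truth, _ = generate_cluster(cfg)
        assert len(truth) == 5 + 2 + 10 + 2
        non_anchor = [r for r in truth if r.family != "anchor"]
        assert len(non_anchor) == 17

    def test_lesion_rate_zero_all_intact(self, null_cluster):
        _, scaffold, truth, _ = null_cluster
        assert all(r.true_status == "intact" for r in truth)
        assert all(not r.implanted_lesions for r in truth)
        # every intact gene translates to its recorded protein
        for r in truth:
            assert translate(spliced_cds(scaffold, r)) == r.protein + "*"

    def test_deterministic_given_seed(self):
        cfg = ClusterConfig(seed=7, n_sedc=3, n_sftp=1, lce_array_size=4, lesion_rate=0.5)
        s1, t1, _ = generate_cluster(cfg)
        s2, t2, _ = generate_cluster(cfg)
        assert s1.sequence == s2.sequence
        assert [(r.gene_name, r.true_status, r.interval) for r in t1] == [
            (r.gene_name, r.true_status, r.interval) for r in t2
        ]

    def test_structure_conventions(self, null_cluster):
        _, scaffold, truth, _ = null_cluster
        strands = {r.strand for r in truth}
        assert strands == {"+", "-"}
        for r in truth:
            # canonical splice sites on every intron flanking a coding exon
            for iv in r.cds:
                if r.strand == "+":
                    assert scaffold.sequence[iv.start - 2 : iv.start] == "AG"
                else:
                    assert scaffold.sequence[iv.end : iv.end + 2] == "CT"
            n_coding = len(r.cds)
            if r.family == "SFTP":
                assert n_coding == 2
                assert r.protein.endswith(CTERM_MOTIF)
            else:
                assert n_coding == 1
        # genes non-overlapping and ordered
        spans = sorted((r.interval.start, r.interval.end) for r in truth)
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))

    def test_scaffold_size_guard(self):
        with pytest.raises(ValueError):
            generate_cluster(ClusterConfig(seed=0, lce_array_size=9000, intergenic_mean=2000))

    def test_species_pair_shares_founders(self):
        cfg = ClusterConfig(seed=3, n_sedc=3, n_sftp=1, lce_array_size=3)
        (sa, ta, _), (sb, tb, _) = generate_species_pair(cfg, divergence=0.05)
        assert [r.gene_name for r in ta] == [r.gene_name for r in tb]
        assert sa.sequence != sb.sequence
        # orthologous proteins are similar but not identical
        pa = {r.gene_name: r.protein for r in ta}
        pb = {r.gene_name: r.protein for r in tb}
        for name in pa:
            ident = sum(a == b for a, b in zip(pa[name], pb[name])) / len(pa[name])
            assert 0.6 < ident < 1.0


class TestAmplifyTandem:
    def test_single_copy_identity(self):
        copies, tree = amplify_tandem("ACGTACGTACGT", 1, 0.1, 0)
        assert copies == [("copy1", "ACGTACGTACGT")]
        assert tree.is_tip()

    def test_zero_divergence_identical(self):
        copies, _ = amplify_tandem("ACGT" * 10, 6, 0.0, 1)
        assert {seq for _, seq in copies} == {"ACGT" * 10}

    def test_copies_monophyletic_vs_outgroups(self, rng):
        founder = "".join(rng.choice(list("ACGT"), 300))
        outgroups = {"og1": founder[::-1], "og2": founder[::-1], "og3": founder}
        copies, tree = amplify_tandem(founder, 8, 0.02, 5, outgroups=outgroups)
        flag, _ = is_monophyletic(tree, {n for n, _ in copies}, "og1")
        assert flag

    def test_genealogy_ultrametric_in_event_count(self):
        _, tree = amplify_tandem("ACGT" * 25, 7, 0.05, 9)
        depths = {
            tip.name: tip.accumulate_to_ancestor(tree) for tip in tree.tips()
        }
        assert len(set(depths.values())) == 1


class TestImplantLesion:
    def test_premature_stop_translates_to_stop(self, null_cluster):
        cfg, scaffold, truth, _ = null_cluster
        rec = next(r for r in truth if r.family == "SEDC")
        import copy

        rec2 = copy.deepcopy(rec)
        codons = 30
        pos = (
            rec2.cds[0].start + 3 * codons
            if rec2.strand == "+"
            else rec2.cds[0].end - 3 * codons - 1
        )
        mutated, rec2 = implant_lesion(scaffold, rec2, "premature_stop", position=pos)
        prot = translate(spliced_cds(mutated, rec2))
        codon_idx = int(rec2.implanted_lesions[0].detail.split("=")[1])
        assert prot[codon_idx] == "*"
        assert prot.index("*") == codon_idx

    def test_frameshift_changes_length_mod_three(self, null_cluster):
        cfg, scaffold, truth, _ = null_cluster
        import copy

        rec = copy.deepcopy(next(r for r in truth if r.family == "LCE"))
        before = sum(len(iv) for iv in rec.cds)
        rng = np.random.default_rng(0)
        mutated, rec = implant_lesion(scaffold, rec, "frameshift_del", rng=rng)
        after = sum(len(iv) for iv in rec.cds)
        assert (before - after) in (1, 2)
        assert rec.true_status == "pseudogene"

    def test_splice_loss_destroys_dinucleotide(self, null_cluster):
        cfg, scaffold, truth, _ = null_cluster
        import copy

        rec = copy.deepcopy(next(r for r in truth if r.family == "SFTP"))
        rng = np.random.default_rng(1)
        mutated, rec = implant_lesion(scaffold, rec, "splice_loss", rng=rng)
        les = rec.implanted_lesions[0]
        dinuc = mutated.sequence[les.coordinate : les.coordinate + 2]
        assert dinuc not in ("GT", "AG", "CT", "AC")

    def test_exon_deletion_shortens_scaffold(self, null_cluster):
        cfg, scaffold, truth, _ = null_cluster
        import copy

        rec = copy.deepcopy(next(r for r in truth if r.family == "SFTP"))
        exon2 = rec.exons[2]
        mutated, rec = implant_lesion(
            scaffold, rec, "exon_deletion", position=rec.cds[1].start
        )
        assert mutated.length == scaffold.length - len(exon2)
        assert len(rec.cds) == 1

    def test_position_outside_coding_rejected(self, null_cluster):
        cfg, scaffold, truth, _ = null_cluster
        rec = truth[1]
        with pytest.raises(ValueError):
            implant_lesion(scaffold, rec, "premature_stop", position=rec.interval.start)


class TestLeftAlignIndel:
    def test_homopolymer_shifts_left(self):
        #                        0123456789
        assert left_align_indel("ACGGGGGTTA", 6, 1) == 2

    def test_non_shiftable_stays_put(self):
        assert left_align_indel("ACGTACGT", 4, 2) == 4

    def test_tandem_unit_shifts_by_unit(self):
        # deleting the second "AC" of ACACACGT is equivalent to the first
        assert left_align_indel("ACACACGT", 2, 2) == 0
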