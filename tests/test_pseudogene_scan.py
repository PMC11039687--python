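import copy

import numpy as np
import pytest

from edcscan.gene_annotation import ExonTemplate, template_from_truth
from edcscan.pseudogene_scan import (
    DisruptionReport,
    Lesion,
    classify_status,
    detect_disruptions,
    measure_orf_runway,
    shortening_fraction,
)
from edcscan.synthetic_edc import implant_lesion


def scan_with_lesion(null_cluster, family, kind, seed=0, position=None):
    cfg, scaffold, truth, _ = null_cluster
    rec = copy.deepcopy(next(r for r in truth if r.family == family))
    template = template_from_truth(rec)
    mutated, rec = implant_lesion(
        scaffold, rec, kind, position=position, rng=np.random.default_rng(seed)
    )
    report = detect_disruptions(mutated, template, rec.interval)
    return rec, report


class TestDetectDisruptions:
    def test_unmutated_gene_reports_intact(self, null_cluster):
        cfg, scaffold, truth, _ = null_cluster
        for rec in truth:
            report = detect_disruptions(
                scaffold, template_from_truth(rec), rec.interval
            )
            assert report.lesions == [] and report.status == "intact"

    def test_implanted_stop_found_at_exact_codon(self, null_cluster):
        rec, report = scan_with_lesion(null_cluster, "SEDC", "premature_stop")
        truth_lesion = rec.implanted_lesions[0]
        assert [l.kind for l in report.lesions] == ["premature_stop"]
        assert report.lesions[0].coordinate == truth_lesion.coordinate
        assert report.lesions[0].codon_index == int(
            truth_lesion.detail.split("=")[1]
        )

    def test_one_bp_deletion_found_at_site(self, null_cluster):
        rec, report = scan_with_lesion(null_cluster, "LCE", "frameshift_del")
        truth_lesion = rec.implanted_lesions[0]
        assert [l.kind for l in report.lesions] == ["frameshift"]
        assert report.lesions[0].coordinate == truth_lesion.coordinate

    def test_splice_loss_found(self, null_cluster):
        rec, report = scan_with_lesion(null_cluster, "SFTP", "splice_loss")
        truth_lesion = rec.implanted_lesions[0]
        kinds = [l.kind for l in report.lesions]
        assert "splice_loss" in kinds
        found = next(l for l in report.lesions if l.kind == "splice_loss")
        assert found.coordinate == truth_lesion.coordinate

    def test_deleted_exon_reported_missing(self, null_cluster):
        cfg, scaffold, truth, _ = null_cluster
        rec = copy.deepcopy(next(r for r in truth if r.family == "SFTP"))
        template = template_from_truth(rec)  # template from the intact gene
        mutated, rec = implant_lesion(
            scaffold, rec, "exon_deletion", position=rec.cds[1].start
        )
        report = detect_disruptions(mutated, template, rec.interval)
        assert "missing_exon" in report.kinds
        assert report.status == "pseudogene"


class TestClassifyStatus:
    TEMPLATE = ExonTemplate(
        name="t", segments=[(0, "M" + "A" * 99, (294, 306))], cds_seqs=["ATG" + "GCT" * 99 + "TAA"]
    )

    def mk(self, lesions):
        return DisruptionReport(gene_name="g", lesions=lesions)

    def test_no_lesions_intact(self):
        assert classify_status(self.mk([]), self.TEMPLATE) == "intact"

    def test_stop_at_forty_percent_truncated(self):
        les = [Lesion("premature_stop", 1000, 40)]
        assert classify_status(self.mk(les), self.TEMPLATE) == "truncated"

    def test_early_stop_pseudogene(self):
        les = [Lesion("premature_stop", 1000, 5)]
        assert classify_status(self.mk(les), self.TEMPLATE) == "pseudogene"

    def test_stop_plus_frameshift_pseudogene(self):
        # both lesion kinds together mean loss of the reading frame, not a
        # clean truncation, even when the stop sits late in the gene
        les = [
            Lesion("premature_stop", 1000, 60),
            Lesion("frameshift", 2000, 80, "del1"),
        ]
        assert classify_status(self.mk(les), self.TEMPLATE) == "pseudogene"

    def test_stop_and_frameshift_in_distinct_exons_detected(self, null_cluster):
        cfg, scaffold, truth, _ = null_cluster
        rec = copy.deepcopy(next(r for r in truth if r.family == "SFTP"))
        template = template_from_truth(rec)
        rng = np.random.default_rng(4)
        # stop in the first coding exon (domain), frameshift in the second
        stop_pos = (
            rec.cds[0].start + 60 if rec.strand == "+" else rec.cds[0].end - 61
        )
        scaffold, rec = implant_lesion(scaffold, rec, "premature_stop", position=stop_pos)
        scaffold, rec = implant_lesion(scaffold, rec, "frameshift_del", rng=rng)
        report = detect_disruptions(scaffold, template, rec.interval)
        assert set(report.kinds) >= {"premature_stop", "frameshift"}
        assert report.status == "pseudogene"


class TestOrfRunway:
    def test_examples(self):
        assert measure_orf_runway("AAAAAATAA", 0) == (2, 6)
        assert measure_orf_runway("TAACCC", 0) == (0, 0)
        assert measure_orf_runway("AAAA", 0) == (1, None)

    def test_matches_brute_force_everywhere(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 3000))

        def brute(pos):
            n, p = 0, pos
            while p + 3 <= len(seq):
                if seq[p : p + 3] in ("TAA", "TAG", "TGA"):
                    return n, p
                n += 1
                p += 3
            return n, None

        for pos in range(len(seq)):
            assert measure_orf_runway(seq, pos) == brute(pos)

    def test_mean_runway_near_expectation(self, rng):
        # stop probability per codon is 3/64, so the mean runway ~ 64/3
        seq = "".join(rng.choice(list("ACGT"), 30000))
        runs = [measure_orf_runway(seq, p)[0] for p in range(0, 25000, 11)]
        assert np.mean(runs) == pytest.approx(64 / 3, rel=0.15)


class TestShorteningFraction:
    @pytest.mark.parametrize(
        "target,ref,expected,flag",
        [(100, 400, 0.75, False), (300, 300, 0.0, False), (500, 400, 0.0, True)],
    )
    def test_examples(self, target, ref, expected, flag):
        frac, flagged = shortening_fraction(target, ref)
        assert frac == pytest.approx(expected)
        assert flagged is flag

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            shortening_fraction(10, 0)
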