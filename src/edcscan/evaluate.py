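"""Compare pipeline output against a synthetic cluster's truth table.

Genes are matched by genomic overlap (same scaffold region and strand),
lesions by (kind, forward-strand coordinate) after mapping the simulator's
lesion vocabulary onto the detector's (frameshift_ins/del -> frameshift,
exon_deletion -> missing_exon).
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import SpeciesAnnotation
from .synthetic_edc import TruthRecord

KIND_MAP = {
    "premature_stop": "premature_stop",
    "frameshift_ins": "frameshift",
    "frameshift_del": "frameshift",
    "splice_loss": "splice_loss",
    "exon_deletion": "missing_exon",
}


def match_genes(truth: list[TruthRecord], annotation: SpeciesAnnotation):
    """Pair each truth gene with the annotated gene overlapping it most."""
    pairs = []
    for rec in truth:
        best, best_ov = None, 0
        for g in annotation.genes:
            ov = min(rec.interval.end, g.locus_span.end) - max(
                rec.interval.start, g.locus_span.start
            )
            if ov > best_ov:
                best, best_ov = g, ov
        pairs.append((rec, best))
    return pairs


def architecture_agreement(truth, annotation) -> float:
    """Fraction of truth genes whose recovered architecture matches."""
    pairs = match_genes(truth, annotation)
    ok = sum(
        1
        for rec, g in pairs
        if g is not None and g.model.architecture == rec.architecture
    )
    return ok / len(pairs)


def status_agreement(truth, annotation) -> float:
    """Fraction of truth genes with the correct intact/truncated/pseudogene call."""
    pairs = match_genes(truth, annotation)
    ok = sum(
        1
        for rec, g in pairs
        if g is not None and g.report.status == rec.true_status
    )
    return ok / len(pairs)


@dataclass
class LesionRecovery:
    n_truth: int
    n_recovered: int
    n_false_positive_on_intact: int
    missed: list
    false_positives: list

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else 1.0


def lesion_recovery(truth, annotation) -> LesionRecovery:
    """Exact kind+coordinate recovery of implanted lesions, plus false
    positives falling inside truth-intact genes."""
    detected = set()
    for g in annotation.genes:
        for les in g.report.lesions:
            detected.add((les.kind, les.coordinate))

    truth_keys = []
    for rec in truth:
        for les in rec.implanted_lesions:
            truth_keys.append((KIND_MAP[les.kind], les.coordinate))

    recovered = [k for k in truth_keys if k in detected]
    missed = [k for k in truth_keys if k not in detected]

    intact_spans = [
        rec.interval for rec in truth if not rec.implanted_lesions
    ]
    fp = [
        k
        for k in detected - set(truth_keys)
        if any(iv.start <= k[1] < iv.end for iv in intact_spans)
    ]
    return LesionRecovery(
        n_truth=len(truth_keys),
        n_recovered=len(recovered),
        n_false_positive_on_intact=len(fp),
        missed=missed,
        false_positives=fp,
    )


def total_detected_lesions(annotation) -> int:
    return sum(len(g.report.lesions) for g in annotation.genes)
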