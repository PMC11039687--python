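"""Detect inactivating lesions in a locus relative to an intact ortholog.

Each template coding exon is located inside the locus by infix alignment
and the aligned pair is walked column by column:

* an in-frame stop codon before the template's final codon -> premature_stop
  (reported only where the running indel offset is 0 mod 3, i.e. in the
  template reading frame — stops that merely appear downstream of a
  frameshift are consequences, not independent lesions);
* an indel run whose length is not a multiple of 3 -> frameshift;
* a damaged GT donor / AG acceptor flanking a located exon -> splice_loss;
* a template exon without an alignable counterpart -> missing_exon;
* a lost initiator ATG -> start_loss.

Indel coordinates are left-normalised on the forward strand (VCF style) so
they are comparable across detection runs and with simulator truth tables.
Lesions within 6 bp of an exon boundary are annotated ``boundary-uncertain``
because splice refinement can shift the local frame; sequencing or assembly
error cannot be excluded at such sites.

Status rules: zero lesions -> intact; lesions consisting solely of
premature stops, with an intact start and the first stop at >= 20% of the
template length -> truncated; any other lesion combination -> pseudogene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import Interval, Scaffold, STOP_CODONS, reverse_complement
from .gene_annotation import ExonTemplate, locate_template_exons
from .synthetic_edc import left_align_indel

BOUNDARY_UNCERTAIN_BP = 6
TRUNCATED_MIN_ORF_FRACTION = 0.2


@dataclass
class Lesion:
    kind: str  # premature_stop | frameshift | splice_loss | missing_exon | start_loss
    coordinate: int  # forward-strand scaffold position (0-based)
    codon_index: int  # codon index within the template protein
    detail: str = ""

    def __post_init__(self) -> None:
        self.coordinate = int(self.coordinate)
        self.codon_index = int(self.codon_index)


@dataclass
class DisruptionReport:
    gene_name: str
    lesions: list[Lesion] = field(default_factory=list)
    longest_orf_fraction: float = 1.0
    status: str = "intact"
    alignable_fraction: float = 1.0  # template bp with an aligned counterpart

    @property
    def kinds(self) -> list[str]:
        return [l.kind for l in self.lesions]


def detect_disruptions(
    scaffold: Scaffold,
    template: ExonTemplate,
    span: Interval,
    gene_name: str | None = None,
) -> DisruptionReport:
    """Scan the locus at ``span`` for lesions relative to ``template``."""
    name = gene_name or template.name
    total_codons = template.n_codons
    template_len_bp = sum(len(s) for s in template.cds_seqs)

    region, seq, located = locate_template_exons(scaffold, template, span)
    found_bp = sum(
        len(template.cds_seqs[le.index]) for le in located if le.interval is not None
    )
    lesions: list[Lesion] = []

    alignable = found_bp / max(1, template_len_bp)
    if alignable < 0.05:
        # nothing alignable: summarise as one missing_exon per template exon
        codon_offset = 0
        for i, cds in enumerate(template.cds_seqs):
            lesions.append(
                Lesion("missing_exon", span.start, codon_offset, detail=f"exon{i}")
            )
            codon_offset += len(cds) // 3
        return DisruptionReport(name, lesions, 0.0, "pseudogene", alignable)

    codon_offset = 0
    for le in located:
        exon_codons = len(template.cds_seqs[le.index]) // 3
        if le.interval is None:
            anchor = _missing_exon_anchor(located, le.index, span)
            lesions.append(
                Lesion("missing_exon", anchor, codon_offset, detail=f"exon{le.index}")
            )
        else:
            lesions.extend(
                _walk_exon_alignment(
                    scaffold, region, le, codon_offset, total_codons,
                    is_first=le.index == 0,
                    is_last=le.index == len(template.cds_seqs) - 1,
                )
            )
        codon_offset += exon_codons

    lesions.sort(key=lambda l: l.coordinate)
    report = DisruptionReport(name, lesions, alignable_fraction=alignable)
    report.longest_orf_fraction = _orf_fraction(lesions, total_codons)
    report.status = classify_status(report, template)
    return report


def _missing_exon_anchor(located, index, span) -> int:
    for le in located[:index][::-1]:
        if le.interval is not None:
            return le.interval.end if le.interval.strand == "+" else le.interval.start
    return span.start


def _orf_fraction(lesions, total_codons) -> float:
    disrupting = [
        l for l in lesions if l.kind in ("premature_stop", "frameshift", "start_loss")
    ]
    if not disrupting:
        return 1.0
    return min(l.codon_index for l in disrupting) / max(1, total_codons)


def classify_status(report: DisruptionReport, template: ExonTemplate) -> str:
    """intact / truncated / pseudogene per the rules in the module docstring."""
    if not report.lesions:
        return "intact"
    kinds = set(report.kinds)
    if kinds == {"premature_stop"}:
        first = min(
            l.codon_index for l in report.lesions if l.kind == "premature_stop"
        )
        if first / max(1, template.n_codons) >= TRUNCATED_MIN_ORF_FRACTION:
            return "truncated"
    return "pseudogene"


# ---------------------------------------------------------------------------
# Alignment walking
# ---------------------------------------------------------------------------


def _walk_exon_alignment(
    scaffold: Scaffold,
    region: Interval,
    le,
    codon_offset: int,
    total_codons: int,
    is_first: bool,
    is_last: bool,
) -> list[Lesion]:
    lesions: list[Lesion] = []
    q, t = le.query_aligned, le.target_aligned  # template / genome (oriented)
    strand = le.interval.strand
    exon = le.interval
    exon_len_local = sum(c != "-" for c in t)

    def fwd(local: int) -> int:
        """Forward-strand coordinate of genome offset ``local`` within the
        located exon (gene orientation)."""
        if strand == "+":
            return exon.start + local
        return exon.end - local - 1

    # --- splice sites -------------------------------------------------
    # every coding exon has an upstream acceptor (a non-coding first exon
    # precedes the CDS); donors exist between coding exons only
    sseq = scaffold.sequence
    if strand == "+":
        acc = sseq[exon.start - 2 : exon.start]
        don = sseq[exon.end : exon.end + 2]
        acc_coord, don_coord = exon.start - 2, exon.end
    else:
        acc = reverse_complement(sseq[exon.end : exon.end + 2])
        don = reverse_complement(sseq[exon.start - 2 : exon.start])
        acc_coord, don_coord = exon.end, exon.start - 2
    if acc != "AG":
        lesions.append(
            Lesion("splice_loss", acc_coord, codon_offset, detail="acceptor")
        )
    if not is_last and don != "GT":
        end_codon = codon_offset + exon_len_local // 3
        lesions.append(
            Lesion("splice_loss", don_coord, end_codon, detail="donor")
        )

    # --- start codon ----------------------------------------------------
    if is_first:
        first_bases = "".join(c for c in t if c != "-")[:3]
        if first_bases != "ATG":
            lesions.append(Lesion("start_loss", fwd(0), 0, detail=first_bases))

    # --- indels and in-frame stops ---------------------------------------
    tpos = 0  # template offset (bases consumed)
    gpos = 0  # genome offset within located exon
    offset = 0  # net genome - template bases so far
    i = 0
    n = len(q)
    codon_buf: list[tuple[str, int]] = []  # (genome base, local offset)
    codon_clean = offset % 3 == 0
    while i < n:
        if q[i] == "-" or t[i] == "-":
            j = i
            while j < n and (q[j] == "-" or t[j] == "-") and (q[j] == "-") == (q[i] == "-"):
                j += 1
            run = j - i
            if q[i] == "-":  # insertion in genome
                coord = _normalize_insertion(sseq, fwd(gpos), run, strand)
                gpos += run
                offset += run
            else:  # deletion from genome
                deleted = q[i:j]
                coord = _normalize_deletion(sseq, fwd(gpos), deleted, strand)
                offset -= run
            if run % 3 != 0:
                codon_idx = codon_offset + tpos // 3
                detail = ("ins" if q[i] == "-" else "del") + str(run)
                if min(gpos, exon_len_local - gpos) <= BOUNDARY_UNCERTAIN_BP:
                    detail += ";boundary-uncertain"
                lesions.append(Lesion("frameshift", coord, codon_idx, detail))
            if q[i] != "-":
                tpos += run
            codon_clean = False
            codon_buf = []
            i = j
            continue
        # aligned column
        if tpos % 3 == 0:
            codon_buf = []
            codon_clean = offset % 3 == 0
        codon_buf.append((t[i], gpos))
        if tpos % 3 == 2 and codon_clean and len(codon_buf) == 3:
            codon = "".join(b for b, _ in codon_buf)
            template_codon = q[i - 2 : i + 1]
            codon_idx = codon_offset + tpos // 3
            if (
                codon in STOP_CODONS
                and template_codon not in STOP_CODONS
                and codon_idx < total_codons - 1
            ):
                start_local = codon_buf[0][1]
                coords = [fwd(start_local + k) for k in range(3)]
                detail = ""
                if min(start_local, exon_len_local - start_local) <= BOUNDARY_UNCERTAIN_BP:
                    detail = "boundary-uncertain"
                lesions.append(
                    Lesion("premature_stop", min(coords), codon_idx, detail)
                )
        tpos += 1
        gpos += 1
        i += 1
    return lesions


def _normalize_insertion(sseq: str, raw_fwd: int, length: int, strand: str) -> int:
    """Leftmost forward-strand coordinate of an inserted run."""
    if strand == "+":
        start = raw_fwd
    else:
        # fwd() returned the coordinate of the first inserted base in gene
        # orientation, which is the *rightmost* forward base of the run
        start = raw_fwd - length + 1
    return left_align_indel(sseq, start, length)


def _normalize_deletion(sseq: str, raw_fwd: int, deleted_oriented: str, strand: str) -> int:
    """Leftmost forward-strand junction coordinate of a deletion.

    The deleted bases are reconstructed from the template and re-inserted
    locally so the same normalisation as the simulator's applies.
    """
    if strand == "+":
        junction = raw_fwd
        deleted_fwd = deleted_oriented
    else:
        junction = raw_fwd + 1  # base after the gap in forward space
        deleted_fwd = reverse_complement(deleted_oriented)
    ctx = 60
    lo = max(0, junction - ctx)
    local = sseq[lo:junction] + deleted_fwd + sseq[junction : junction + ctx]
    pos = left_align_indel(local, junction - lo, len(deleted_fwd))
    return lo + pos


# ---------------------------------------------------------------------------
# ORF runway and length comparisons
# ---------------------------------------------------------------------------


def measure_orf_runway(seq: str, position: int, strand: str = "+"):
    """Complete codons from ``position`` until the first in-frame stop.

    ``position`` indexes the strand-oriented sequence (for ``-``, the
    reverse complement). Returns ``(codon_count, stop_position)``;
    ``stop_position`` is None when the scaffold ends before a stop (the
    count then covers the codons read up to the end).
    """
    s = reverse_complement(seq) if strand == "-" else seq.upper()
    count = 0
    p = position
    while p + 3 <= len(s):
        codon = s[p : p + 3]
        if codon in STOP_CODONS:
            return count, p
        count += 1
        p += 3
    return count, None


def shortening_fraction(target_length: int, reference_length: int):
    """1 - target/reference, clipped to [0, 1]; flags a longer target."""
    if reference_length <= 0:
        raise ValueError("reference length must be positive")
    frac = 1.0 - target_length / reference_length
    flagged = frac < 0
    return max(0.0, min(1.0, frac)), flagged
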