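"""Chain HSPs into loci and reconstruct template-guided gene models.

A *locus* is a maximal set of HSPs from one query that is collinear in both
query and genome with genomic gaps no larger than a plausible intron.
Gene models are rebuilt against an :class:`ExonTemplate` describing an
intact ortholog: per coding exon, the template's coding sequence is located
inside the locus by infix alignment (edlib), boundaries are refined to the
nearest frame-preserving GT..AG pair, and the architecture is classified by
the coding-exon count plus an N-terminal S100-domain test:

* exactly one coding exon  -> SEDC
* two coding exons whose first segment matches the S100 consensus -> SFTP
* anything else -> other

Non-coding first exons are never predicted from sequence (the analysis
depends only on coding structure); they are recorded as absent with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import GeneModel, Interval, Scaffold, translate
from .homology_search import Hsp
from .synthetic_edc import S100_CONSENSUS

DEFAULT_MAX_INTRON = 10_000
LOCUS_PAD = 150  # bp of context kept around a locus for splice/indel checks
GAP_COST_PER_BP = 0.01  # chain-join cost per bp of genomic gap


@dataclass
class ExonTemplate:
    """Coding structure of an intact ortholog used as annotation guide.

    ``segments`` lists, per coding exon in transcription order, the protein
    segment it encodes and an accepted length range (bp). ``cds_seqs`` are
    the exon coding sequences (5'->3', including the terminal stop codon in
    the last exon) from the intact source gene.
    """

    name: str
    segments: list[tuple[int, str, tuple[int, int]]]
    cds_seqs: list[str]
    family: str = ""
    has_noncoding_first_exon: bool = True

    @property
    def protein(self) -> str:
        return "".join(seg for _, seg, _ in self.segments)

    @property
    def n_codons(self) -> int:
        return sum(len(s) for s in self.cds_seqs) // 3


def template_from_truth(rec) -> ExonTemplate:
    """Build a template from a synthetic TruthRecord's intact gene."""
    segments = []
    offset = 0
    for i, cds in enumerate(rec.cds_seqs):
        n_aa = len(cds) // 3 - (1 if i == len(rec.cds_seqs) - 1 else 0)
        segments.append(
            (i, rec.protein[offset : offset + n_aa], (len(cds) - 6, len(cds) + 6))
        )
        offset += n_aa
    return ExonTemplate(
        name=rec.gene_name,
        segments=segments,
        cds_seqs=list(rec.cds_seqs),
        family=rec.family,
    )


# ---------------------------------------------------------------------------
# HSP chaining
# ---------------------------------------------------------------------------


@dataclass
class Locus:
    query_id: str
    scaffold_id: str
    strand: str
    hsps: list[Hsp]

    @property
    def score(self) -> float:
        return sum(h.score for h in self.hsps)

    @property
    def genomic_span(self) -> Interval:
        return Interval(
            min(h.genomic.start for h in self.hsps),
            max(h.genomic.end for h in self.hsps),
            self.strand,
        )

    @property
    def query_span(self) -> tuple[int, int]:
        return (
            min(h.query_start for h in self.hsps),
            max(h.query_end for h in self.hsps),
        )


GENOMIC_OVERLAP_TOLERANCE = 150  # bp; extension overshoot across an indel


def chain_hsps(
    hsps: list[Hsp],
    max_intron: int = DEFAULT_MAX_INTRON,
    query_overlap_tolerance: int = 40,
) -> list[Locus]:
    """Group one query's HSPs into collinear loci.

    Within a scaffold+strand group, HSPs sorted along the transcription
    direction join the current chain while the genomic gap is at most
    ``max_intron`` and query coordinates keep advancing (small overlaps
    tolerated). Ties in placement resolve to the leftmost genomic start.
    Returned loci are sorted by descending summed score.
    """
    groups: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        groups.setdefault((h.scaffold_id, h.strand), []).append(h)

    loci: list[Locus] = []
    for (sid, strand), group in sorted(groups.items()):
        rev = strand == "-"
        group.sort(
            key=lambda h: (h.genomic.start, h.genomic.end),
            reverse=rev,
        )
        remaining = list(group)
        while remaining:
            chain = _best_chain(remaining, rev, max_intron, query_overlap_tolerance)
            loci.append(Locus(chain[0].query_id, sid, strand, chain))
            used = set(map(id, chain))
            remaining = [h for h in remaining if id(h) not in used]
    loci.sort(key=lambda l: (-l.score, l.genomic_span.start))
    return loci


def _best_chain(group: list[Hsp], rev: bool, max_intron: int, tol: int) -> list[Hsp]:
    """Highest-scoring collinear chain (dynamic programming over HSPs
    pre-sorted in transcription order).

    A join across a genomic gap is disallowed when the gap holds another
    substantial HSP of the same query aligning upstream query content —
    the signature of a tandem-paralog copy sitting between the two HSPs
    rather than an intron."""
    n = len(group)
    dp = [h.score for h in group]
    back = [-1] * n
    qmin = [h.query_start for h in group]  # query coverage start of chain
    for i in range(n):
        hi = group[i]
        for j in range(i):
            hj = group[j]
            if rev:
                gap_lo, gap_hi = hi.genomic.end, hj.genomic.start
            else:
                gap_lo, gap_hi = hj.genomic.end, hi.genomic.start
            gap = gap_hi - gap_lo
            if not (-GENOMIC_OVERLAP_TOLERANCE <= gap <= max_intron):
                continue
            # strict query progression: restarts and containments are
            # paralog copies or self-repeat artifacts, never exon splits
            if (
                hi.query_start < hj.query_end - tol
                or hi.query_start <= hj.query_start
                or hi.query_end <= hj.query_end
            ):
                continue
            if gap > 0 and _paralog_in_gap(
                group, gap_lo, gap_hi, hi, hj, chain_query_start=qmin[j]
            ):
                continue
            # small per-bp cost discourages long-range joins to weak HSPs
            cand = dp[j] + hi.score - GAP_COST_PER_BP * max(0, gap)
            if cand > dp[i]:
                dp[i] = cand
                back[i] = j
                qmin[i] = min(qmin[j], hi.query_start)
    best = max(range(n), key=lambda i: (dp[i], -i))
    chain = []
    i = best
    while i != -1:
        chain.append(group[i])
        i = back[i]
    return chain[::-1]


def _paralog_in_gap(
    group, gap_lo, gap_hi, hi, hj,
    chain_query_start=None, min_score=60, min_overlap=50,
):
    """True when the genomic gap between two HSPs holds another substantial
    HSP of the same query re-aligning query content the growing chain
    already covers — i.e. the 'intron' is actually a paralogous copy."""
    q_lo = min(hj.query_start, hi.query_start)
    if chain_query_start is not None:
        q_lo = min(q_lo, chain_query_start)
    q_hi = max(hj.query_end, hi.query_end)
    for k in group:
        if k is hi or k is hj or k.score < min_score:
            continue
        ov = min(k.genomic.end, gap_hi) - max(k.genomic.start, gap_lo)
        if ov < min_overlap:
            continue
        q_ov = min(k.query_end, q_hi) - max(k.query_start, q_lo)
        if q_ov >= 0.5 * (k.query_end - k.query_start):
            return True
    return False


# ---------------------------------------------------------------------------
# Template exon location within a locus
# ---------------------------------------------------------------------------


@dataclass
class LocatedExon:
    index: int
    interval: Interval | None  # forward-strand; None when unalignable
    edit_distance: int = 0
    query_aligned: str = ""  # template coding sequence, gapped
    target_aligned: str = ""  # genomic sequence (gene orientation), gapped


@lru_cache(maxsize=1)
def _dna_aligner() -> PairwiseAligner:
    # substitutions must be cheaper than paired indels so that a mutated
    # codon is reported as mismatches, not as a spurious ins+del pair;
    # end gaps on the genomic window side are free so terminal mismatches
    # stay inside the exon instead of being clipped off its boundary
    return PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-2,
        open_gap_score=-7,
        extend_gap_score=-2,
        end_insertion_score=0,
    )


def _dna_global_alignment(a: str, b: str) -> tuple[str, str]:
    """Gapped strings of a global DNA alignment of near-identical sequences
    (free end gaps on ``b``, the genomic window)."""
    aln = _dna_aligner().align(a, b)[0]
    ab, bb = aln.aligned
    a_parts, b_parts = [], []
    pa = pb = 0
    for (a0, a1), (b0, b1) in zip(ab, bb):
        a_parts.append(a[pa:a0])
        b_parts.append("-" * (a0 - pa))
        a_parts.append("-" * (b0 - pb))
        b_parts.append(b[pb:b0])
        a_parts.append(a[a0:a1])
        b_parts.append(b[b0:b1])
        pa, pb = a1, b1
    a_parts.append(a[pa:])
    b_parts.append("-" * (len(a) - pa))
    a_parts.append("-" * (len(b) - pb))
    b_parts.append(b[pb:])
    return "".join(a_parts), "".join(b_parts)


def _oriented_region(scaffold: Scaffold, span: Interval, pad: int = LOCUS_PAD):
    start = max(0, span.start - pad)
    end = min(scaffold.length, span.end + pad)
    region = Interval(start, end, span.strand)
    return region, scaffold.fetch(region)


def _local_to_forward(region: Interval, a: int, b: int) -> Interval:
    if region.strand == "+":
        return Interval(region.start + a, region.start + b, "+")
    return Interval(region.end - b, region.end - a, "-")


def locate_template_exons(
    scaffold: Scaffold,
    template: ExonTemplate,
    span: Interval,
    max_distance_frac: float = 0.2,
    pad: int = LOCUS_PAD,
) -> tuple[Interval, str, list[LocatedExon]]:
    """Locate each template coding exon inside a locus region.

    Returns the padded region interval, its gene-oriented sequence, and one
    :class:`LocatedExon` per template exon (interval None when the exon has
    no alignable counterpart). Exons are constrained to appear in order.
    """
    region, seq = _oriented_region(scaffold, span, pad)
    located: list[LocatedExon] = []
    cursor = 0
    for i, cds in enumerate(template.cds_seqs):
        window = seq[cursor:]
        res = edlib.align(cds, window, task="path", mode="HW")
        dist = res["editDistance"]
        if dist < 0 or not res["locations"] or dist > max_distance_frac * len(cds):
            located.append(LocatedExon(index=i, interval=None, edit_distance=dist))
            continue
        s, e = res["locations"][0]
        e += 1  # edlib end is inclusive
        # realign over a padded window; free end gaps let the alignment set
        # the true boundaries even when terminal bases are substituted
        ws, we = max(0, s - 8), min(len(window), e + 8)
        q_aln, t_aln = _dna_global_alignment(cds, window[ws:we])
        lead = 0
        while q_aln[lead] == "-":
            lead += 1
        trail = 0
        while q_aln[len(q_aln) - 1 - trail] == "-":
            trail += 1
        q_aln = q_aln[lead : len(q_aln) - trail]
        t_aln = t_aln[lead : len(t_aln) - trail]
        s, e = ws + lead, we - trail
        located.append(
            LocatedExon(
                index=i,
                interval=_local_to_forward(region, cursor + s, cursor + e),
                edit_distance=dist,
                query_aligned=q_aln,
                target_aligned=t_aln,
            )
        )
        cursor += e
    return region, seq, located


# ---------------------------------------------------------------------------
# Gene model building
# ---------------------------------------------------------------------------


def build_gene_model(
    locus: Locus,
    template: ExonTemplate,
    scaffold: Scaffold,
    refine_bp: int = 30,
) -> GeneModel:
    """Reconstruct a gene model for a locus against an intact template.

    Exon boundaries come from infix alignment of the template coding exons;
    internal boundaries are refined to the nearest frame-preserving GT..AG
    within ``refine_bp``. When no exon can be reconciled the model is
    returned with architecture ``other`` and a flag, never dropped.
    """
    region, seq, located = locate_template_exons(scaffold, template, locus.genomic_span)
    flags: list[str] = []
    cds: list[Interval] = []
    for le in located:
        if le.interval is None:
            flags.append(f"exon{le.index}_unalignable")
            continue
        cds.append(le.interval)
    strand = locus.strand
    if not cds:
        return GeneModel(
            name=template.name,
            scaffold_id=scaffold.id,
            strand=strand,
            exons=[],
            cds=[],
            architecture="other",
            source="template_guided",
            status="unresolved",
            family=template.family,
            flags=flags + ["no_alignable_exon"],
        )

    # splice-site refinement on internal boundaries (gene orientation)
    ordered = sorted(cds, key=lambda iv: iv.start, reverse=(strand == "-"))
    refined, splice_flags = _refine_splice_sites(seq, region, ordered, refine_bp)
    flags.extend(splice_flags)

    model = GeneModel(
        name=template.name,
        scaffold_id=scaffold.id,
        strand=strand,
        exons=list(refined),
        cds=list(refined),
        architecture="other",
        source="template_guided",
        family=template.family,
        flags=flags + ["noncoding_first_exon_not_predicted"],
    )
    cds_seq = model.coding_sequence(scaffold)
    if not cds_seq.startswith("ATG"):
        model.flags.append("start_codon_missing")
    model.protein = translate(cds_seq, 0, "+").rstrip("*")
    model.architecture = classify_architecture(model)
    return model


def _refine_splice_sites(seq, region, ordered_cds, refine_bp):
    """Snap internal exon boundaries to GT..AG, shifting in-frame only."""

    def to_local(iv: Interval) -> tuple[int, int]:
        if region.strand == "+":
            return iv.start - region.start, iv.end - region.start
        return region.end - iv.end, region.end - iv.start

    flags = []
    out = []
    locals_ = [to_local(iv) for iv in ordered_cds]
    for i, (s, e) in enumerate(locals_):
        ns, ne = s, e
        if i > 0 and not (s >= 2 and seq[s - 2 : s] == "AG"):
            # the aligned boundary carries no acceptor; a frame-preserving
            # candidate nearby is adopted but the move is always flagged,
            # because the alignment boundary itself was near-exact
            cand = _scan_dinuc(seq, s, "AG", refine_bp, before=True)
            if cand is None:
                flags.append(f"splice_acceptor_unrefined_exon{i}")
            else:
                ns = cand
                flags.append(f"splice_acceptor_shifted_exon{i}")
        if i < len(locals_) - 1 and seq[e : e + 2] != "GT":
            cand = _scan_dinuc(seq, e, "GT", refine_bp, before=False)
            if cand is None:
                flags.append(f"splice_donor_unrefined_exon{i}")
            else:
                ne = cand
                flags.append(f"splice_donor_shifted_exon{i}")
        out.append((ns, ne))
    result = []
    for s, e in out:
        if region.strand == "+":
            result.append(Interval(region.start + s, region.start + e, "+"))
        else:
            result.append(Interval(region.end - e, region.end - s, "-"))
    return result, flags


def _scan_dinuc(seq, pos, dinuc, refine_bp, before):
    """Nearest frame-preserving (step 3) boundary carrying the dinucleotide."""
    for delta in range(3, refine_bp + 1, 3):
        for cand in (pos - delta, pos + delta):
            if cand < 2 or cand + 2 > len(seq):
                continue
            if before and seq[cand - 2 : cand] == dinuc:
                return cand
            if not before and seq[cand : cand + 2] == dinuc:
                return cand
    return None


# ---------------------------------------------------------------------------
# Architecture classification
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def _s100_aligner() -> PairwiseAligner:
    return PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-12,
        extend_gap_score=-1,
    )


@lru_cache(maxsize=256)
def s100_domain_score(n_terminal: str, consensus: str = S100_CONSENSUS) -> float:
    """Local alignment score of a protein's N-terminus vs the S100 consensus,
    as a fraction of the consensus self-score."""
    if not n_terminal:
        return 0.0
    aligner = _s100_aligner()
    clean = "".join(c for c in n_terminal.upper() if c.isalpha())
    if not clean:
        return 0.0
    self_score = aligner.score(consensus, consensus)
    return float(aligner.score(consensus, clean)) / float(self_score)


S100_SCORE_THRESHOLD = 0.6


def classify_architecture(model: GeneModel) -> str:
    """SEDC / SFTP / other from coding-exon count and S100-domain presence."""
    n = len(model.cds)
    if n == 1:
        return "SEDC"
    if n == 2:
        head = model.protein[:120]
        if s100_domain_score(head) >= S100_SCORE_THRESHOLD:
            return "SFTP"
    return "other"
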