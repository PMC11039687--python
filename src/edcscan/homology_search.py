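"""Translated protein-vs-genome homology search (tBLASTn-like).

The genome is translated in all six frames; exact-match seed words in the
query are located in the translations, extended ungapped under an X-drop
rule, then refined by banded local dynamic programming (Biopython's
``PairwiseAligner`` provides the DP engine). Low-complexity query segments
can be masked by a Shannon-entropy filter before seeding — with an explicit
off switch, because compositionally biased epidermal proteins are exactly
the queries such filters throw away. Masked residues are excluded from
seeding only, never from extension.

Scores are raw substitution-matrix sums minus affine gap costs
(open + k*extend for a gap of length k) and are exactly reproducible from
the reported alignment strings via :func:`score_alignment`; no E-value
statistics are computed. Frames are numbered 0-2 per strand and
minus-strand hits are reported in forward-scaffold coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import Interval, Scaffold, reverse_complement, translate


@dataclass
class SearchParams:
    seed_length: int = 4
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    x_drop: int = 16
    min_score: int = 40
    min_identity: float = 45.0  # % floor; off-frame low-complexity noise sits lower
    mask: bool = False  # low-complexity query masking before seeding
    mask_window: int = 12
    mask_entropy: float = 2.2  # bits
    gapped: bool = True


@dataclass
class Hsp:
    """One high-scoring pair, with a recomputable alignment."""

    query_id: str
    query_start: int  # residue coordinates, half-open
    query_end: int
    scaffold_id: str
    genomic: Interval  # forward-strand scaffold coordinates
    frame: int
    strand: str
    score: float
    identity: float  # percent over alignment columns
    query_aln: str = ""
    target_aln: str = ""  # translated genomic sequence, gapped

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)


@lru_cache(maxsize=4)
def _matrix_dict(name: str) -> dict:
    m = substitution_matrices.load(name)
    alpha = m.alphabet
    return {
        (a, b): float(m[a, b]) for a in alpha for b in alpha
    }


def _pair_score(m: dict, a: str, b: str) -> float:
    return m.get((a, b), -4.0)


def score_alignment(
    query_aln: str, target_aln: str, params: SearchParams | None = None
) -> float:
    """Recompute an HSP's raw score from its gapped alignment strings."""
    params = params or SearchParams()
    m = _matrix_dict(params.matrix)
    score, gap_run = 0.0, 0
    for qa, ta in zip(query_aln.upper(), target_aln.upper()):
        if qa == "-" or ta == "-":
            gap_run += 1
        else:
            if gap_run:
                score -= params.gap_open + params.gap_extend * gap_run
                gap_run = 0
            score += _pair_score(m, qa, ta)
    if gap_run:
        score -= params.gap_open + params.gap_extend * gap_run
    return score


# ---------------------------------------------------------------------------
# Low-complexity masking
# ---------------------------------------------------------------------------


def shannon_entropy(window: str) -> float:
    counts: dict[str, int] = {}
    for c in window:
        counts[c] = counts.get(c, 0) + 1
    n = len(window)
    return -sum((k / n) * math.log2(k / n) for k in counts.values())


def mask_low_complexity(
    protein: str,
    window: int = 12,
    entropy_threshold: float = 2.2,
    enabled: bool = True,
) -> str:
    """Lowercase residues inside low-entropy windows; identity when disabled.

    A window of ``window`` residues whose Shannon entropy (bits, base-2 over
    residue frequencies) falls below ``entropy_threshold`` is masked in
    full. Masked residues are skipped during seeding but still participate
    in extension.
    """
    if not enabled:
        return protein
    if window < 4:
        raise ValueError("window must be >= 4 residues")
    n = len(protein)
    if n < window:
        return protein
    masked = [False] * n
    up = protein.upper()
    for i in range(n - window + 1):
        if shannon_entropy(up[i : i + window]) < entropy_threshold:
            for j in range(i, i + window):
                masked[j] = True
    return "".join(
        c.lower() if masked[i] else c for i, c in enumerate(protein)
    )


# ---------------------------------------------------------------------------
# Six-frame translation with coordinate mapping
# ---------------------------------------------------------------------------


@dataclass
class FrameTranslation:
    scaffold_id: str
    scaffold_len: int
    strand: str
    frame: int
    protein: str

    def residue_interval(self, i: int, j: int) -> Interval:
        """Forward-strand genomic interval of residues [i, j)."""
        if self.strand == "+":
            return Interval(self.frame + 3 * i, self.frame + 3 * j, "+")
        # residue coords count from the 5' end of the reverse complement
        end = self.scaffold_len - (self.frame + 3 * i)
        start = self.scaffold_len - (self.frame + 3 * j)
        return Interval(start, end, "-")


def six_frame_translations(scaffold: Scaffold) -> list[FrameTranslation]:
    out = []
    rc = reverse_complement(scaffold.sequence)
    for strand, seq in (("+", scaffold.sequence), ("-", rc)):
        for frame in range(3):
            if len(seq) < frame + 3:
                continue
            out.append(
                FrameTranslation(
                    scaffold_id=scaffold.id,
                    scaffold_len=scaffold.length,
                    strand=strand,
                    frame=frame,
                    protein=translate(seq, frame, "+"),
                )
            )
    return out


class TranslatedIndex:
    """Seed-word index over the six-frame translations of scaffolds."""

    def __init__(self, scaffolds: list[Scaffold], seed_length: int = 4):
        self.seed_length = seed_length
        self.frames: list[FrameTranslation] = []
        self.index: dict[str, list[tuple[int, int]]] = {}
        for sc in scaffolds:
            for ft in six_frame_translations(sc):
                fi = len(self.frames)
                self.frames.append(ft)
                prot = ft.protein
                for p in range(len(prot) - seed_length + 1):
                    word = prot[p : p + seed_length]
                    if "X" in word or "*" in word:
                        continue
                    self.index.setdefault(word, []).append((fi, p))

    def lookup(self, word: str) -> list[tuple[int, int]]:
        return self.index.get(word, [])


# ---------------------------------------------------------------------------
# Seeding, extension, refinement
# ---------------------------------------------------------------------------


def _ungapped_extend(q, t, qs, qe, ts, m, x_drop):
    """Extend a seed [qs, qe) on diagonal ts-qs both ways under X-drop."""
    score = sum(_pair_score(m, q[i], t[ts + (i - qs)]) for i in range(qs, qe))
    # right
    best, run = score, 0.0
    i, j = qe, ts + (qe - qs)
    bi = qe
    while i < len(q) and j < len(t):
        run += _pair_score(m, q[i], t[j])
        if score + run > best:
            best, bi = score + run, i + 1
        if best - (score + run) > x_drop:
            break
        i += 1
        j += 1
    qe, score = bi, best
    # left
    best, run = score, 0.0
    i, j = qs - 1, ts - 1
    bs = qs
    while i >= 0 and j >= 0:
        run += _pair_score(m, q[i], t[j])
        if score + run > best:
            best, bs = score + run, i
        if best - (score + run) > x_drop:
            break
        i -= 1
        j -= 1
    return bs, qe, best


def _trim_low_identity_ends(q, t, qs, qe, diag, window=15, min_ident=0.6):
    """Shrink an ungapped span until both ends are high-identity.

    Composition-biased queries extend net-positively through off-frame or
    intronic sequence; score-based X-drop cannot stop that, so ends are
    trimmed back while the terminal window identity is poor."""

    def win_ident(a, b):
        return sum(q[i] == t[i + diag] for i in range(a, b)) / max(1, b - a)

    changed = True
    while changed and qe - qs >= 4:
        changed = False
        w = min(window, qe - qs)
        if win_ident(qe - w, qe) < min_ident:
            qe -= 1
            changed = True
            continue
        if win_ident(qs, qs + w) < min_ident:
            qs += 1
            changed = True
    return qs, qe


_ALIGNER_CACHE: dict = {}


def _aligner(params: SearchParams) -> PairwiseAligner:
    key = (params.matrix, params.gap_open, params.gap_extend)
    if key not in _ALIGNER_CACHE:
        a = PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load(params.matrix),
            open_gap_score=-(params.gap_open + params.gap_extend),
            extend_gap_score=-params.gap_extend,
        )
        _ALIGNER_CACHE[key] = a
    return _ALIGNER_CACHE[key]


def _gapped_refine(q, t, qs, qe, ts, te, params, pad=15):
    """Local DP in a window around an ungapped HSP; returns
    (qs, qe, ts, te, score, q_aln, t_aln) or None if alignment is empty."""
    qlo, qhi = max(0, qs - pad), min(len(q), qe + pad)
    tlo, thi = max(0, ts - pad), min(len(t), te + pad)
    aligner = _aligner(params)
    try:
        res = aligner.align(q[qlo:qhi], t[tlo:thi])
        aln = res[0]
    except (ValueError, IndexError):
        return None
    qb, tb = aln.aligned
    if len(qb) == 0:
        return None
    q_parts, t_parts = [], []
    for k, ((q0, q1), (t0, t1)) in enumerate(zip(qb, tb)):
        if k > 0:
            pq0, pq1 = qb[k - 1]
            pt0, pt1 = tb[k - 1]
            q_parts.append(q[qlo + pq1 : qlo + q0])
            q_parts.append("-" * (t0 - pt1))
            t_parts.append("-" * (q0 - pq1))
            t_parts.append(t[tlo + pt1 : tlo + t0])
        q_parts.append(q[qlo + q0 : qlo + q1])
        t_parts.append(t[tlo + t0 : tlo + t1])
    q_aln, t_aln = "".join(q_parts), "".join(t_parts)
    return (
        qlo + qb[0][0],
        qlo + qb[-1][1],
        tlo + tb[0][0],
        tlo + tb[-1][1],
        float(aln.score),
        q_aln,
        t_aln,
    )


def search_many(
    queries: dict[str, str],
    scaffolds: list[Scaffold],
    params: SearchParams | None = None,
    index: TranslatedIndex | None = None,
) -> dict[str, list[Hsp]]:
    """Search several query proteins against shared scaffolds.

    Builds the six-frame seed index once; returns per-query HSP lists
    sorted by descending score.
    """
    params = params or SearchParams()
    if index is None:
        index = TranslatedIndex(scaffolds, params.seed_length)
    m = _matrix_dict(params.matrix)
    out = {}
    for qid, qseq in queries.items():
        out[qid] = _search_one(qid, qseq, index, m, params)
    return out


def search_translated(
    query_id: str,
    query: str,
    scaffolds: list[Scaffold],
    params: SearchParams | None = None,
) -> list[Hsp]:
    """Single-query convenience wrapper around :func:`search_many`."""
    params = params or SearchParams()
    return search_many({query_id: query}, scaffolds, params)[query_id]


def _search_one(qid, qseq, index, m, params) -> list[Hsp]:
    k = params.seed_length
    if len(qseq) < k:
        raise ValueError(f"query {qid!r} shorter than seed length {k}")
    masked = (
        mask_low_complexity(qseq, params.mask_window, params.mask_entropy)
        if params.mask
        else qseq
    )
    q = qseq.upper()

    # seeds grouped by (frame index, diagonal)
    diag_hits: dict[tuple[int, int], list[int]] = {}
    for p in range(len(masked) - k + 1):
        word = masked[p : p + k]
        if not word.isupper() or "X" in word or "*" in word:
            continue
        for fi, tp in index.lookup(word):
            diag_hits.setdefault((fi, tp - p), []).append(p)

    candidates: dict[int, list] = {}
    for (fi, diag), qps in diag_hits.items():
        t = index.frames[fi].protein
        qps.sort()
        covered_to = -1
        for qp in qps:
            if qp < covered_to:
                continue
            qs, qe, score = _ungapped_extend(
                q, t, qp, qp + k, qp + diag, m, params.x_drop
            )
            covered_to = qe
            nqs, nqe = _trim_low_identity_ends(q, t, qs, qe, diag)
            if (nqs, nqe) != (qs, qe):
                qs, qe = nqs, nqe
                score = sum(
                    _pair_score(m, q[i], t[i + diag]) for i in range(qs, qe)
                )
            # identity floor applies before overlap suppression so that a
            # low-identity extension can never shadow a genuine HSP
            ident = 100.0 * sum(
                q[i] == t[i + diag] for i in range(qs, qe)
            ) / max(1, qe - qs)
            if ident < params.min_identity:
                continue
            candidates.setdefault(fi, []).append((score, qs, qe, qs + diag, qe + diag))

    hsps: list[Hsp] = []
    for fi, cands in candidates.items():
        ft = index.frames[fi]
        t = ft.protein
        cands.sort(reverse=True)
        kept: list[tuple] = []
        for score, qs, qe, ts, te in cands:
            if any(ts < ke and ks < te for _, _, _, ks, ke in kept):
                continue  # overlapping HSP in the same frame: best wins
            kept.append((score, qs, qe, ts, te))
        for score, qs, qe, ts, te in kept:
            q_aln = q[qs:qe]
            t_aln = t[ts:te]
            if params.gapped:
                ref = _gapped_refine(q, t, qs, qe, ts, te, params)
                if ref is not None and ref[4] >= score:
                    qs, qe, ts, te, score, q_aln, t_aln = ref
            if score < params.min_score:
                continue
            ident = 100.0 * sum(
                a == b and a != "-" for a, b in zip(q_aln, t_aln)
            ) / max(1, len(q_aln))
            if ident < params.min_identity:
                continue
            hsps.append(
                Hsp(
                    query_id=qid,
                    query_start=qs,
                    query_end=qe,
                    scaffold_id=ft.scaffold_id,
                    genomic=ft.residue_interval(ts, te),
                    frame=ft.frame,
                    strand=ft.strand,
                    score=float(score),
                    identity=ident,
                    query_aln=q_aln,
                    target_aln=t_aln,
                )
            )
    # final same-strand/frame overlap suppression on *refined* coordinates
    # (gapped refinement can slide an HSP onto a better-scoring rival)
    hsps.sort(key=lambda h: (-h.score, h.genomic.start))
    kept: list[Hsp] = []
    for h in hsps:
        if any(
            k.strand == h.strand
            and k.frame == h.frame
            and k.scaffold_id == h.scaffold_id
            and k.genomic.overlaps(h.genomic)
            for k in kept
        ):
            continue
        kept.append(h)
    return kept


def hsps_to_rows(hsps: list[Hsp]) -> list[dict]:
    """BLAST outfmt-6-like tabular rows (1-based closed genomic span)."""
    rows = []
    for h in hsps:
        rows.append(
            {
                "qseqid": h.query_id,
                "sseqid": h.scaffold_id,
                "pident": round(h.identity, 2),
                "length": len(h.query_aln),
                "qstart": h.query_start + 1,
                "qend": h.query_end,
                "sstart": h.genomic.start + 1,
                "send": h.genomic.end,
                "strand": h.strand,
                "frame": h.frame,
                "score": h.score,
            }
        )
    return rows
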