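"""Protein feature profiling: composition, tandem repeats, C-terminal motif.

These are the computations behind comparative tables of epidermal protein
families: amino-acid content (ProtParam-style frequencies plus the combined
fraction of the two most frequent residues, which approaches 50% in
trichohyalin-like proteins), internal tandem-repeat arrays detected by
lagged self-comparison, presence of a short conserved C-terminal motif, and
the resulting N-terminal / repeat / C-terminal segment architecture.

X residues are excluded from composition denominators and count as
mismatches in repeat identity and motif scoring.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CompositionProfile:
    protein_id: str
    length: int  # residues counted (X excluded)
    frequencies: dict[str, float]

    @property
    def top2(self) -> list[tuple[str, float]]:
        return sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))[:2]

    @property
    def top2_fraction(self) -> float:
        return sum(f for _, f in self.top2)


@dataclass
class RepeatAnnotation:
    unit_length: int
    consensus: str
    copy_number: float
    span: tuple[int, int]  # residue interval, half-open
    mean_identity: float  # percent, copies vs consensus


@dataclass
class MotifMatch:
    pattern: str
    found: bool
    position: int = -1  # residue index of the best match
    distance_from_cterm: int = -1
    score: float = 0.0  # matched positions / pattern length


def aa_composition(protein: str, protein_id: str = "") -> CompositionProfile:
    """Exact residue frequencies over the 20-letter alphabet (X ignored)."""
    if not protein:
        raise ValueError("empty protein")
    seq = protein.upper()
    bad = set(seq) - set(AA20) - {"X"}
    if bad:
        raise ValueError(f"unexpected residues {sorted(bad)} in {protein_id or 'protein'}")
    counts = Counter(c for c in seq if c != "X")
    if not counts:
        raise ValueError("protein consists only of X residues")
    n = sum(counts.values())
    freqs = {aa: counts.get(aa, 0) / n for aa in AA20}
    return CompositionProfile(protein_id=protein_id, length=n, frequencies=freqs)


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------


def detect_repeats(
    protein: str,
    min_unit: int = 3,
    max_unit: int = 25,
    min_copies: int = 3,
    min_identity: float = 0.8,
) -> list[RepeatAnnotation]:
    """Detect internal tandem repeat arrays by lagged self-comparison.

    For each candidate unit length ``u``, positions where
    ``protein[i] == protein[i+u]`` are scored; maximal runs of unit-sized
    blocks whose running average identity stays at or above
    ``min_identity`` become arrays of ``blocks + 1`` copies. Overlapping
    calls are resolved to the highest copy_number * identity, preferring
    the smallest unit whose identity is within 2 points of the best
    (so a u-repeat is not reported as a 2u-repeat). X counts as mismatch.
    """
    seq = protein.upper()
    n = len(seq)
    candidates: list[RepeatAnnotation] = []
    for u in range(min_unit, min(max_unit, n // max(2, min_copies - 1)) + 1):
        m = [
            1 if (seq[i] == seq[i + u] and seq[i] != "X") else 0
            for i in range(n - u)
        ]
        i = 0
        while i + u <= len(m):
            # try to grow a run of blocks starting at i
            matches, length, blocks = 0, 0, 0
            j = i
            while j + u <= len(m):
                block = sum(m[j : j + u])
                if (matches + block) / (length + u) < min_identity:
                    break
                matches += block
                length += u
                blocks += 1
                j += u
            if blocks >= min_copies - 1:
                span = (i, i + blocks * u + u)
                ann = _annotate_array(seq, u, span)
                if ann.mean_identity >= 100.0 * min_identity:
                    candidates.append(ann)
                i = j
            else:
                i += 1
    return _resolve_overlaps(candidates)


def _annotate_array(seq: str, u: int, span: tuple[int, int]) -> RepeatAnnotation:
    s, e = span
    copies = [seq[p : p + u] for p in range(s, e, u)]
    full = [c for c in copies if len(c) == u]
    consensus = "".join(
        Counter(col).most_common(1)[0][0] for col in zip(*full)
    )
    idents = [
        100.0 * sum(a == b for a, b in zip(c, consensus)) / u for c in full
    ]
    copy_number = len(full) + (len(copies[-1]) / u if len(copies[-1]) != u else 0)
    return RepeatAnnotation(
        unit_length=u,
        consensus=consensus,
        copy_number=copy_number,
        span=span,
        mean_identity=sum(idents) / len(idents),
    )


def _resolve_overlaps(cands: list[RepeatAnnotation]) -> list[RepeatAnnotation]:
    def overlap(a, b):
        return a.span[0] < b.span[1] and b.span[0] < a.span[1]

    kept: list[RepeatAnnotation] = []
    # prefer small units when nearly as good, then strongest arrays
    for ann in sorted(
        cands,
        key=lambda a: (-(a.copy_number * a.mean_identity), a.unit_length),
    ):
        rivals = [k for k in kept if overlap(k, ann)]
        if not rivals:
            kept.append(ann)
            continue
        repl = []
        absorb = False
        for r in rivals:
            if (
                ann.unit_length < r.unit_length
                and r.unit_length % ann.unit_length == 0
                and ann.mean_identity >= r.mean_identity - 2.0
                and ann.span[0] <= r.span[0]
                and ann.span[1] >= r.span[1]
            ):
                repl.append(r)
            else:
                absorb = True
        if repl and not absorb:
            for r in repl:
                kept.remove(r)
            kept.append(ann)
    return sorted(kept, key=lambda a: a.span)


# ---------------------------------------------------------------------------
# C-terminal motif
# ---------------------------------------------------------------------------


def scan_cterminal_motif(
    protein: str,
    pattern: str,
    window: int = 50,
    min_score: float = 0.8,
) -> MotifMatch:
    """Best match of ``pattern`` within the last ``window`` residues.

    The pattern supports exact residues plus ``x`` wildcards (always
    matching, except against X residues). ``found`` requires the match
    score (matches / pattern length) to reach ``min_score``.
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    seq = protein.upper()
    pat = pattern.upper()
    L, P = len(seq), len(pat)
    start = max(0, L - window)
    best = MotifMatch(pattern=pattern, found=False)
    for i in range(start, L - P + 1):
        score = sum(
            1
            for a, b in zip(pat, seq[i : i + P])
            if (a == "X" and b != "X") or a == b != "X"
        ) / P
        if score > best.score:
            best = MotifMatch(
                pattern=pattern,
                found=False,
                position=i,
                distance_from_cterm=L - (i + P),
                score=score,
            )
    best.found = best.score >= min_score
    return best


# ---------------------------------------------------------------------------
# Segment architecture
# ---------------------------------------------------------------------------


def segment_architecture(protein: str, repeats: list[RepeatAnnotation]):
    """(N-terminal, repeat, C-terminal) residue spans around the repeat
    region; empty spans are permitted. With no repeats, the whole protein
    is returned as the N-terminal span together with a flag."""
    n = len(protein)
    if not repeats:
        return (0, n), None, None
    first = min(r.span[0] for r in repeats)
    last = max(r.span[1] for r in repeats)
    nterm = (0, first)
    rep = (first, last)
    cterm = (last, n)
    return nterm, rep, cterm
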