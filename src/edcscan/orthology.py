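"""Orthology calling: reciprocal best hits plus shared local synteny.

A query gene and a target locus are called orthologs only when both
criteria hold: the pair are each other's best-scoring match between the two
protein sets (ties disqualify — near-identical tandem paralogs produce tied
best hits and are deliberately left ambiguous), and the gene families
flanking the two loci overlap above a threshold fraction. Family identity
for synteny uses explicit family labels (name prefixes in synthetic data);
for unlabeled real proteins, :func:`infer_families` provides greedy
clustering at 50% identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

DEFAULT_K = 3
DEFAULT_SYNTENY_THRESHOLD = 0.5
SCORE_TIE_EPS = 1e-9


@dataclass
class OrthologyCall:
    query: str
    target: str | None
    rbh: bool
    synteny_score: float
    verdict: str  # ortholog | ambiguous | none
    flags: str = ""


@lru_cache(maxsize=1)
def _aligner() -> PairwiseAligner:
    return PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-12,
        extend_gap_score=-1,
    )


def best_hit(protein: str, proteome: dict[str, str]):
    """(best_id, best_score, tied) by local alignment score."""
    if not proteome:
        raise ValueError("empty search target")
    aligner = _aligner()
    scores = {pid: float(aligner.score(protein, seq)) for pid, seq in proteome.items()}
    best_id = max(scores, key=lambda p: (scores[p], p))
    best_score = scores[best_id]
    tied = sum(1 for s in scores.values() if abs(s - best_score) < SCORE_TIE_EPS) > 1
    return best_id, best_score, tied


def reciprocal_best_hit(
    query_id: str,
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
):
    """(rbh_flag, target_id, flags): true iff the query's best hit in B maps
    back to the query as the unique best hit in A. Ties either way fail."""
    fwd_id, _, fwd_tie = best_hit(proteome_a[query_id], proteome_b)
    if fwd_tie:
        return False, fwd_id, "forward_tie"
    back_id, _, back_tie = best_hit(proteome_b[fwd_id], proteome_a)
    if back_tie:
        return False, fwd_id, "back_tie"
    return back_id == query_id, fwd_id, ""


def synteny_score(
    gene: str,
    order_a: list[tuple[str, str]],
    target: str,
    order_b: list[tuple[str, str]],
    k: int = DEFAULT_K,
):
    """Fraction of the up-to-2k flanking families of ``gene`` present among
    the flanking families of ``target``, order-insensitive.

    ``order_a``/``order_b`` are the annotated gene lists (name, family) in
    genomic order. Fewer than k flanks on a side are used as available and
    flagged.
    """
    fa, flagged_a = _flanking_families(gene, order_a, k)
    fb, flagged_b = _flanking_families(target, order_b, k)
    if not fa:
        return 0.0, "no_flanks"
    shared = sum(1 for fam in fa if fam in set(fb))
    flags = "short_flanks" if (flagged_a or flagged_b) else ""
    return shared / len(fa), flags


def _flanking_families(gene, order, k):
    names = [n for n, _ in order]
    idx = names.index(gene)
    left = order[max(0, idx - k) : idx]
    right = order[idx + 1 : idx + 1 + k]
    flagged = len(left) < k or len(right) < k
    return [fam for _, fam in left + right], flagged


def call_ortholog(
    query_id: str,
    proteome_a: dict[str, str],
    order_a: list[tuple[str, str]],
    proteome_b: dict[str, str],
    order_b: list[tuple[str, str]],
    k: int = DEFAULT_K,
    synteny_threshold: float = DEFAULT_SYNTENY_THRESHOLD,
) -> OrthologyCall:
    """Combine RBH and synteny into a verdict.

    ortholog: RBH true and synteny >= threshold. ambiguous: RBH failed
    (tie or paralog cross-match) but synteny supports the placement.
    none: otherwise.
    """
    rbh, target, rbh_flags = reciprocal_best_hit(query_id, proteome_a, proteome_b)
    syn, syn_flags = synteny_score(query_id, order_a, target, order_b, k)
    if rbh and syn >= synteny_threshold:
        verdict = "ortholog"
    elif syn >= synteny_threshold:
        verdict = "ambiguous"
    else:
        verdict = "none"
    flags = ";".join(f for f in (rbh_flags, syn_flags) if f)
    return OrthologyCall(query_id, target, rbh, syn, verdict, flags)


def infer_families(
    proteins: dict[str, str], identity_threshold: float = 0.5
) -> dict[str, str]:
    """Greedy single-linkage family labels by pairwise identity.

    Intended for real (unlabeled) protein sets; synthetic data carries
    family labels already. Identity = matches / shorter sequence length
    over the best local alignment.
    """
    aligner = _aligner()
    ids = sorted(proteins, key=lambda p: -len(proteins[p]))
    families: dict[str, str] = {}
    reps: list[tuple[str, str]] = []  # (family label, representative seq)
    for pid in ids:
        seq = proteins[pid]
        placed = False
        for fam, rep in reps:
            aln = aligner.align(seq, rep)[0]
            # identity from aligned blocks
            m = 0
            for (q0, q1), (t0, t1) in zip(aln.aligned[0], aln.aligned[1]):
                m += sum(1 for x, y in zip(seq[q0:q1], rep[t0:t1]) if x == y)
            if m / min(len(seq), len(rep)) >= identity_threshold:
                families[pid] = fam
                placed = True
                break
        if not placed:
            fam = f"FAM{len(reps) + 1}"
            reps.append((fam, seq))
            families[pid] = fam
    return families


def family_from_name(name: str) -> str:
    """Family label for synthetic gene names: strip trailing digits/suffixes."""
    base = name.split("_")[0]
    return base.rstrip("0123456789")
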