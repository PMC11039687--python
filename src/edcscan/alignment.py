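"""Small multiple-alignment plumbing: star-progressive protein MSA.

Pairwise global alignments (BLOSUM62, affine gaps, free end gaps) are
merged around a center sequence — the one with the highest summed pairwise
score — under the usual "once a gap, always a gap" rule. This is utility
plumbing for distance-based tree building on closely related paralogs, not
a general-purpose aligner.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices


@lru_cache(maxsize=1)
def _global_aligner() -> PairwiseAligner:
    a = PairwiseAligner(
        mode="global",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-12,
        extend_gap_score=-1,
        end_insertion_score=0.0,
        end_deletion_score=0.0,
    )
    return a


def pairwise_global(a: str, b: str) -> tuple[str, str, float]:
    """Globally align two proteins; returns gapped strings and the score."""
    aligner = _global_aligner()
    aln = aligner.align(a, b)[0]
    # reconstruction from aligned blocks rather than text parsing
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
    return "".join(a_parts), "".join(b_parts), float(aln.score)


def progressive_align(seqs: dict[str, str]) -> dict[str, str]:
    """Star-progressive MSA of ``{label: sequence}``; equal-length rows."""
    labels = list(seqs)
    if len(labels) == 1:
        return dict(seqs)
    aligner = _global_aligner()
    # center = sequence with the highest total alignment score to the rest
    totals = {l: 0.0 for l in labels}
    for i, li in enumerate(labels):
        for lj in labels[i + 1 :]:
            s = float(aligner.score(seqs[li], seqs[lj]))
            totals[li] += s
            totals[lj] += s
    center = max(labels, key=lambda l: (totals[l], -labels.index(l)))

    c = seqs[center]
    # per center position: inserted residues of each row before that
    # position, and the residue aligned to it
    ins_before: dict[str, list[str]] = {}
    at_pos: dict[str, list[str]] = {}
    max_ins = [0] * (len(c) + 1)
    for label in labels:
        if label == center:
            continue
        c_aln, s_aln, _ = pairwise_global(c, seqs[label])
        ins = [""] * (len(c) + 1)
        at = [""] * len(c)
        ci = 0
        for ca, sa in zip(c_aln, s_aln):
            if ca == "-":
                ins[ci] += sa
            else:
                at[ci] = sa
                ci += 1
        ins_before[label] = ins
        at_pos[label] = at
        for i, chunk in enumerate(ins):
            max_ins[i] = max(max_ins[i], len(chunk))

    out: dict[str, list[str]] = {l: [] for l in labels}
    for i in range(len(c) + 1):
        for label in labels:
            if label == center:
                out[label].append("-" * max_ins[i])
            else:
                chunk = ins_before[label][i]
                out[label].append(chunk + "-" * (max_ins[i] - len(chunk)))
        if i < len(c):
            out[center].append(c[i])
            for label in labels:
                if label != center:
                    out[label].append(at_pos[label][i] or "-")
    return {l: "".join(parts) for l, parts in out.items()}
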