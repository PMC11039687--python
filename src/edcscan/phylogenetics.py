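"""Distance-based gene-family phylogenetics: p-distance, NJ, bootstrap,
and clade monophyly testing.

Trees are built by neighbor joining (Saitou-Nei, via scikit-bio) on
p-distances with pairwise deletion of gapped sites. Support values come
from nonparametric bootstrap over alignment columns. Monophyly of a label
set is tested against an outgroup: the set is monophyletic iff some branch
of the tree bipartitions the leaves into exactly that set versus the rest
(which contains the outgroup).

Negative NJ branch lengths, an artifact of the least-squares fit, are
clamped to zero and flagged.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj


def pdistance_matrix(alignment: dict[str, str]):
    """Pairwise p-distance with pairwise deletion of gapped sites.

    ``alignment`` maps label -> equal-length gapped sequence (>= 3 rows).
    Returns ``(labels, matrix)``; raises if any pair shares no ungapped
    column.
    """
    labels = list(alignment)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    arr = np.array([list(alignment[l].upper()) for l in labels])
    return labels, _pdist_from_array(labels, arr)


def _pdist_from_array(labels, arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    gap = arr == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable positions between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = float((arr[i, ok] != arr[j, ok]).sum()) / m
    return d


def neighbor_joining(labels: list[str], matrix: np.ndarray) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != matrix.shape[1] or not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) != matrix.shape[0]:
        raise ValueError("labels do not match matrix size")
    tree = nj(DistanceMatrix(matrix, labels))
    clamped = False
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    tree.negative_lengths_clamped = clamped
    return tree


def canonical_bipartition(all_leaves: frozenset, side: frozenset) -> frozenset:
    return min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial leaf bipartitions, each as the smaller/canonical side."""
    all_leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(all_leaves) - 2:
            parts.add(canonical_bipartition(all_leaves, side))
    return parts


def is_monophyletic(
    tree: TreeNode, label_set: set[str], outgroup: str
) -> tuple[bool, frozenset | None]:
    """Is ``label_set`` a clade when the tree is rooted on ``outgroup``?

    Returns (flag, supporting bipartition). A singleton set is trivially a
    clade; a set equal to all non-outgroup leaves is trivially true as well.
    """
    label_set = set(label_set)
    leaves = {t.name for t in tree.tips()}
    if outgroup in label_set:
        raise ValueError("outgroup must not be in the tested set")
    missing = (label_set | {outgroup}) - leaves
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    if len(label_set) == 1 or label_set == leaves - {outgroup}:
        return True, None
    target = frozenset(label_set)
    complement = frozenset(leaves - label_set)
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if side == target or side == complement:
            return True, target
    return False, None


def bootstrap_support(
    alignment: dict[str, str],
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset, float], bool]:
    """NJ tree on the full alignment with bootstrap supports per branch.

    Columns are resampled with replacement ``n_replicates`` times; each
    internal branch of the full-data tree is annotated (node.name and the
    returned dict) with the percentage of replicates whose NJ tree contains
    the same bipartition. Returns ``(tree, supports, informative)`` —
    ``informative`` is False when the alignment has no variable columns, in
    which case supports are reported as 0 and the tree is degenerate.
    """
    labels = list(alignment)
    arr = np.array([list(alignment[l].upper()) for l in labels])
    rng = np.random.default_rng(seed)
    full = neighbor_joining(labels, _pdist_from_array(labels, arr))
    informative = bool((arr != arr[0]).any())

    counts: dict[frozenset, int] = {}
    target_parts = tree_bipartitions(full)
    ncol = arr.shape[1]
    if informative:
        for _ in range(n_replicates):
            cols = rng.integers(0, ncol, size=ncol)
            rep = arr[:, cols]
            try:
                rep_tree = neighbor_joining(labels, _pdist_from_array(labels, rep))
            except ValueError:
                continue
            for part in tree_bipartitions(rep_tree):
                counts[part] = counts.get(part, 0) + 1

    all_leaves = frozenset(labels)
    supports: dict[frozenset, float] = {}
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = canonical_bipartition(all_leaves, side)
        pct = 100.0 * counts.get(canon, 0) / n_replicates if informative else 0.0
        supports[canon] = pct
        node.name = f"{pct:.0f}"
    return full, supports, informative


def build_tree(
    seqs: dict[str, str],
    bootstrap: int = 0,
    seed: int = 0,
):
    """Align (star-progressive), build the NJ tree, optionally bootstrap.

    Convenience entry point used by the CLI; returns
    ``(tree, supports | None)``.
    """
    from .alignment import progressive_align

    aln = progressive_align(seqs)
    if bootstrap > 0:
        tree, supports, _ = bootstrap_support(aln, bootstrap, seed)
        return tree, supports
    labels, d = pdistance_matrix(aln)
    return neighbor_joining(labels, d), None
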