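"""Synthetic EDC-like gene clusters with machine-readable ground truth.

The generator emulates the structural features of the mammalian epidermal
differentiation complex that the downstream pipeline must handle:

* an ordered cluster of genes between two S100-like *anchor* genes;
* single-coding-exon genes (SEDC-like: one non-coding exon, one intron,
  one coding exon);
* two-coding-exon genes (SFTP-like: a non-coding first exon, a coding exon
  carrying an N-terminal S100-like domain, and a second coding exon encoding
  a long tandem-repeat tail strongly biased to two amino acids, ending in a
  short conserved C-terminal motif);
* a tandemly amplified array of near-identical paralogs (LCE-like), grown
  by iterated duplication of random existing copies — the copy-number
  expansion mechanism of unequal crossing over — with a recorded true
  genealogy;
* implanted inactivating lesions (premature stops, frameshifts, splice-site
  loss, exon deletion) with exact coordinates in a truth table.

Intergenic spacers and introns are i.i.d. uniform random DNA with
geometrically distributed lengths. Substitutions applied to coding
sequence are conditioned never to create an in-frame stop, destroy the
start codon, or damage splice dinucleotides, so that the truth table's
``intact`` label is guaranteed by construction. All randomness flows
through one seeded :class:`numpy.random.Generator`.

The S100-like domain consensus and the C-terminal motif used here are
synthetic sequences invented for this test bed; they imitate the length
and composition of their biological counterparts but are not copies of any
real protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skbio import TreeNode

from .io_formats import (
    Interval,
    Scaffold,
    STOP_CODONS,
    reverse_complement,
    translate,
)

# Synthetic ~90-residue S100-like domain consensus (EF-hand-sized helical
# domain imitation; invented sequence, see module docstring).
S100_CONSENSUS = (
    "MASPLEKALDVMVSTFHKYSGKEGDKFKLNKSELKELLTRELPSFLGKRTDEAAFQKLMSNLDSNRDNEVDFQEYCVFLSCIAMMCNEFFEG"
)

# Synthetic C-terminal motif appended to every intact SFTP-like tail.
CTERM_MOTIF = "QSVDRSGHQ"

# Biased two-residue alphabets for SFTP-like repeat tails, rotated across
# genes (arginine/glutamate imitates a trichohyalin-like bias, glycine/
# serine a hornerin-like bias).
TAIL_BIAS_PAIRS = [("R", "E"), ("G", "S"), ("Q", "K"), ("P", "T")]

LESION_KINDS = (
    "premature_stop",
    "frameshift_ins",
    "frameshift_del",
    "splice_loss",
    "exon_deletion",
)

# Kinds drawn at random by generate_cluster. Exon deletion is supported by
# implant_lesion but excluded from the random menu because a deleted exon
# has no alignment-recoverable point coordinate.
RANDOM_LESION_MENU = (
    "premature_stop",
    "frameshift_ins",
    "frameshift_del",
    "splice_loss",
)

_BASES = np.array(list("ACGT"))

_CODONS_FOR_AA: dict[str, list[str]] = {}


def _codon_tables() -> dict[str, list[str]]:
    if not _CODONS_FOR_AA:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            if set(codon) <= set("ACGT"):
                _CODONS_FOR_AA.setdefault(aa, []).append(codon)
        for codons in _CODONS_FOR_AA.values():
            codons.sort()
    return _CODONS_FOR_AA


@dataclass
class ClusterConfig:
    """Study conditions for one synthetic cluster."""

    seed: int = 0
    n_sedc: int = 5
    n_sftp: int = 2
    lce_array_size: int = 10
    lce_divergence: float = 0.02  # substitutions/site per duplication
    lesion_rate: float = 0.0  # probability per non-anchor gene
    intergenic_mean: int = 800  # bp, geometric
    anchor_names: tuple[str, str] = ("S100A9", "S100A11")
    species: str = "synthA"

    def __post_init__(self) -> None:
        if min(self.n_sedc, self.n_sftp, self.lce_array_size) < 0:
            raise ValueError("gene counts must be >= 0")
        if not 0.0 <= self.lce_divergence <= 0.5:
            raise ValueError("lce_divergence must be in [0, 0.5]")
        if not 0.0 <= self.lesion_rate <= 1.0:
            raise ValueError("lesion_rate must be in [0, 1]")
        if self.intergenic_mean < 1:
            raise ValueError("intergenic_mean must be positive")


@dataclass
class Lesion:
    kind: str
    coordinate: int  # forward-strand scaffold position (0-based, mutated)
    detail: str = ""


@dataclass
class TruthRecord:
    """Ground truth for one synthetic gene.

    ``protein`` and ``cds_seqs`` describe the *intact* (pre-lesion) gene and
    double as the ortholog query/template set for pipeline runs. Intervals
    are forward-strand coordinates on the (possibly mutated) scaffold;
    ``exons``/``cds`` are listed in transcription order.
    """

    gene_name: str
    family: str  # anchor | SEDC | SFTP | LCE
    interval: Interval
    exons: list[Interval]
    cds: list[Interval]
    strand: str
    implanted_lesions: list[Lesion] = field(default_factory=list)
    true_status: str = "intact"
    architecture: str = "SEDC"
    protein: str = ""
    cds_seqs: list[str] = field(default_factory=list)

    @property
    def coding_exon_count(self) -> int:
        return len(self.cds)


# ---------------------------------------------------------------------------
# Gene unit construction (unit = local 5'->3' DNA with feature coordinates)
# ---------------------------------------------------------------------------


@dataclass
class _GeneUnit:
    name: str
    family: str
    architecture: str
    seq: str
    exons: list[tuple[int, int]]  # unit coords, transcription order
    cds: list[tuple[int, int]]
    protein: str


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _geom_len(rng: np.random.Generator, mean: int, minimum: int) -> int:
    return max(minimum, int(rng.geometric(1.0 / mean)))


def _intron(rng: np.random.Generator, mean: int = 400) -> str:
    body = _random_dna(rng, _geom_len(rng, mean, 80) - 4)
    return "GT" + body + "AG"


def _encode(protein: str, rng: np.random.Generator) -> str:
    """Encode a protein as DNA with random synonymous codons (no stop)."""
    table = _codon_tables()
    return "".join(
        table[aa][rng.integers(0, len(table[aa]))] for aa in protein
    )


def _mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    out = list(protein)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        if i == 0:  # keep the initiator methionine
            continue
        choices = [a for a in aas if a != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _random_protein(
    rng: np.random.Generator, length: int, alphabet: str, weights: list[float]
) -> str:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    body = "".join(
        np.array(list(alphabet))[rng.choice(len(alphabet), size=length - 1, p=w)]
    )
    return "M" + body


def _build_single_exon_gene(
    name: str, family: str, protein: str, rng: np.random.Generator
) -> _GeneUnit:
    """Non-coding exon + intron + coding exon (SEDC-like / anchor)."""
    cds = _encode(protein, rng) + "TAA"
    utr5 = _random_dna(rng, 80)
    intron = _intron(rng)
    utr3 = _random_dna(rng, 12)
    seq = utr5 + intron + cds + utr3
    c0 = len(utr5) + len(intron)
    return _GeneUnit(
        name=name,
        family=family,
        architecture="SEDC",
        seq=seq,
        exons=[(0, len(utr5)), (c0, len(seq))],
        cds=[(c0, c0 + len(cds))],
        protein=protein,
    )


def _build_sftp_gene(
    name: str,
    domain_protein: str,
    tail_protein: str,
    rng: np.random.Generator,
) -> _GeneUnit:
    """Non-coding exon + two coding exons; domain in the first coding exon."""
    cds1 = _encode(domain_protein, rng)  # multiple of 3, starts with ATG
    cds2 = _encode(tail_protein, rng) + "TAA"
    utr5 = _random_dna(rng, 80)
    i1, i2 = _intron(rng), _intron(rng)
    utr3 = _random_dna(rng, 12)
    seq = utr5 + i1 + cds1 + i2 + cds2 + utr3
    a = len(utr5) + len(i1)
    b = a + len(cds1) + len(i2)
    return _GeneUnit(
        name=name,
        family="SFTP",
        architecture="SFTP",
        seq=seq,
        exons=[(0, len(utr5)), (a, a + len(cds1)), (b, len(seq))],
        cds=[(a, a + len(cds1)), (b, b + len(cds2))],
        protein=domain_protein + tail_protein,
    )


# fraction of tail-body residues drawn from the biased two-letter alphabet
TAIL_BIAS_FRACTION = 0.8


def _sftp_tail(
    rng: np.random.Generator, bias: tuple[str, str]
) -> str:
    """Tandem-repeat tail biased to two residues, plus the C-terminal motif.

    A 9-21 residue unit is repeated with 5% per-copy substitution; the body
    is then rebalanced so its combined top-two residue fraction equals the
    configured bias exactly (a short random unit would otherwise set the
    realized bias of the whole tail with high variance)."""
    unit_len = int(rng.integers(9, 22))
    n_copies = int(rng.integers(8, 16))
    spice = "QSGVDNH"
    unit = "".join(
        bias[rng.integers(0, 2)] if rng.random() < TAIL_BIAS_FRACTION
        else spice[rng.integers(0, len(spice))]
        for _ in range(unit_len)
    )
    copies = [_mutate_protein("M" + unit, 0.05, rng)[1:] for _ in range(n_copies)]
    body = list("".join(copies))
    target = round(TAIL_BIAS_FRACTION * len(body))
    non_bias = [c for c in spice if c not in bias] or ["A"]
    biased_idx = [i for i, c in enumerate(body) if c in bias]
    other_idx = [i for i, c in enumerate(body) if c not in bias]
    rng.shuffle(biased_idx)
    rng.shuffle(other_idx)
    while len(biased_idx) > target:
        i = biased_idx.pop()
        body[i] = non_bias[rng.integers(0, len(non_bias))]
        other_idx.append(i)
    while len(biased_idx) < target and other_idx:
        i = other_idx.pop()
        body[i] = bias[rng.integers(0, 2)]
        biased_idx.append(i)
    return "".join(body) + CTERM_MOTIF


def _protected_and_codons(unit: _GeneUnit) -> tuple[set[int], list[tuple[int, int]]]:
    """Positions that substitutions must not touch, and codon spans.

    Protected: start codon, terminal stop codon, splice dinucleotides.
    Coding exons are constructed with lengths that are multiples of 3, so
    every codon lies within one exon.
    """
    protected: set[int] = set()
    first = unit.cds[0]
    protected.update(range(first[0], first[0] + 3))
    last = unit.cds[-1]
    protected.update(range(last[1] - 3, last[1]))
    for s, e in unit.exons[:-1]:
        protected.update((e, e + 1))  # donor GT
    for s, e in unit.exons[1:]:
        protected.update((s - 2, s - 1))  # acceptor AG
    codons = []
    for s, e in unit.cds:
        codons.extend((p, p + 3) for p in range(s, e, 3))
    return protected, codons


def _mutate_unit(
    unit: _GeneUnit, rate: float, rng: np.random.Generator
) -> _GeneUnit:
    """Per-site substitution that preserves the ORF and splice sites."""
    if rate <= 0:
        return replace(unit)
    protected, codons = _protected_and_codons(unit)
    codon_of = {}
    for cs, ce in codons:
        for p in range(cs, ce):
            codon_of[p] = (cs, ce)
    seq = list(unit.seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for p in hits:
        p = int(p)
        if p in protected:
            continue
        alts = [b for b in "ACGT" if b != seq[p]]
        new = alts[rng.integers(0, 3)]
        if p in codon_of:
            cs, ce = codon_of[p]
            codon = seq[cs:ce]
            codon[p - cs] = new
            if "".join(codon) in STOP_CODONS:
                continue  # skip rather than create an unintended stop
        seq[p] = new
    mutated = "".join(seq)
    cds = "".join(mutated[s:e] for s, e in unit.cds)
    return replace(unit, seq=mutated, protein=translate(cds).rstrip("*"))


# ---------------------------------------------------------------------------
# Tandem amplification
# ---------------------------------------------------------------------------


def amplify_tandem(
    founder_seq: str,
    n_copies: int,
    divergence: float,
    seed_or_rng,
    outgroups: dict[str, str] | None = None,
    mutator=None,
    label: str = "copy",
):
    """Grow a tandem array by iterated duplication of random existing copies.

    Each duplication event copies one randomly chosen existing unit and
    appends per-site substitutions at rate ``divergence`` to the new copy.
    Returns ``(copies, tree)``: the ordered list of ``(name, seq)`` units
    (array order = duplication order) and the true genealogy as a
    :class:`skbio.TreeNode`. Branch lengths count duplication events, so
    the genealogy is ultrametric: every leaf sits at depth ``n_copies``
    below the array root. Optional ``outgroups`` (label -> sequence) are
    attached basally and the array copies form a clade relative to them.

    ``mutator(seq, rate, rng) -> seq`` defaults to unconstrained per-site
    substitution; the cluster generator passes an ORF-preserving mutator.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if mutator is None:
        def mutator(seq, rate, r):
            s = list(seq)
            for p in np.nonzero(r.random(len(s)) < rate)[0]:
                alts = [b for b in "ACGT" if b != s[p]]
                s[p] = alts[r.integers(0, 3)]
            return "".join(s)

    seqs = [founder_seq]
    names = [f"{label}1"]
    nodes = [TreeNode(name=names[0])]
    times = {id(nodes[0]): 0}
    for event in range(1, n_copies):
        i = int(rng.integers(0, len(seqs)))
        new_seq = mutator(seqs[i], divergence, rng)
        seqs.append(new_seq)
        names.append(f"{label}{event + 1}")
        old_leaf = nodes[i]
        kept = TreeNode(name=old_leaf.name)
        times[id(kept)] = event
        new_leaf = TreeNode(name=names[-1])
        times[id(new_leaf)] = event
        # graft: old leaf becomes the duplication node
        old_leaf.name = None
        old_leaf.append(kept)
        old_leaf.append(new_leaf)
        times[id(old_leaf)] = event
        nodes[i] = kept
        nodes.append(new_leaf)
    root = nodes[0]
    while root.parent is not None:
        root = root.parent
    _set_ultrametric_lengths(root, times, total=n_copies)
    if outgroups:
        top = TreeNode(name=None)
        root.length = float(n_copies)
        top.append(root)
        for og_name in outgroups:
            leaf = TreeNode(name=og_name, length=float(2 * n_copies))
            top.append(leaf)
        root = top
    return list(zip(names, seqs)), root


def _set_ultrametric_lengths(root: TreeNode, times: dict, total: int) -> None:
    for node in root.traverse(include_self=True):
        t = times.get(id(node), 0)
        if node.is_tip():
            t = total
        if node.parent is None:
            node.length = None
        else:
            pt = times.get(id(node.parent), 0)
            node.length = float(t - pt)
        times[id(node)] = t


# ---------------------------------------------------------------------------
# Cluster generation
# ---------------------------------------------------------------------------


def _founder_units(config: ClusterConfig, rng: np.random.Generator):
    """Intact gene units in cluster order, plus the LCE genealogy."""
    units: list[_GeneUnit] = []

    def anchor(name: str) -> _GeneUnit:
        prot = _mutate_protein(S100_CONSENSUS, 0.05, rng)
        return _build_single_exon_gene(name, "anchor", prot, rng)

    left = anchor(config.anchor_names[0])

    sftps = []
    for i in range(config.n_sftp):
        domain = _mutate_protein(S100_CONSENSUS, 0.08, rng)
        bias = TAIL_BIAS_PAIRS[i % len(TAIL_BIAS_PAIRS)]
        tail = _sftp_tail(rng, bias)
        sftps.append(_build_sftp_gene(f"SFTP{i + 1}", domain, tail, rng))

    sedcs = []
    for i in range(config.n_sedc):
        length = int(rng.integers(90, 160))
        prot = _random_protein(
            rng, length, "PQSCKGVAHTRELDNY",
            [3, 3, 3, 2, 2, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
        )
        sedcs.append(_build_single_exon_gene(f"SEDC{i + 1}", "SEDC", prot, rng))

    lces: list[_GeneUnit] = []
    lce_tree = None
    if config.lce_array_size > 0:
        length = int(rng.integers(95, 120))
        prot = _random_protein(
            rng, length, "CQKPSGVAHT", [3, 3, 3, 3, 2, 2, 1, 1, 1, 1]
        )
        founder = _build_single_exon_gene("LCE1", "LCE", prot, rng)
        copies, lce_tree = amplify_tandem(
            founder.seq,
            config.lce_array_size,
            config.lce_divergence,
            rng,
            mutator=lambda s, r, g: _mutate_unit(replace(founder, seq=s), r, g).seq,
            label="LCE",
        )
        for name, seq in copies:
            u = replace(founder, name=name, seq=seq)
            u.protein = translate(
                seq[founder.cds[0][0] : founder.cds[0][1] - 3], 0, "+"
            )
            lces.append(u)

    right = anchor(config.anchor_names[1])
    units = [left] + sedcs + sftps + lces + [right]
    return units, lce_tree


def generate_cluster(config: ClusterConfig):
    """Generate one scaffold carrying the configured cluster plus truth.

    Returns ``(scaffold, truth_records, genealogy)`` where genealogy is the
    true LCE-array tree (None when the array is empty). Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    units, lce_tree = _founder_units(config, rng)
    return _render_cluster(config, units, lce_tree, rng)


def _render_cluster(config, units, lce_tree, rng):
    # strand per gene: anchors plus one strand each for determinism of
    # orientation mix; LCE array members share one strand (tandem copies).
    strands = {}
    lce_strand = "+" if rng.random() < 0.5 else "-"
    for u in units:
        if u.family == "LCE":
            strands[u.name] = lce_strand
        else:
            strands[u.name] = "+" if rng.random() < 0.5 else "-"

    pieces: list[str] = []
    offset = 0
    truth: list[TruthRecord] = []
    for u in units:
        gap = _geom_len(rng, config.intergenic_mean, 50)
        pieces.append(_random_dna(rng, gap))
        offset += gap
        strand = strands[u.name]
        seq = u.seq if strand == "+" else reverse_complement(u.seq)
        L = len(u.seq)

        def to_fwd(span: tuple[int, int]) -> Interval:
            s, e = span
            if strand == "+":
                return Interval(offset + s, offset + e, strand)
            return Interval(offset + L - e, offset + L - s, strand)

        exons = [to_fwd(x) for x in u.exons]
        cds = [to_fwd(x) for x in u.cds]
        truth.append(
            TruthRecord(
                gene_name=u.name,
                family=u.family,
                interval=Interval(offset, offset + L, strand),
                exons=exons,
                cds=cds,
                strand=strand,
                architecture=u.architecture,
                protein=u.protein,
                cds_seqs=[u.seq[s:e] for s, e in u.cds],
            )
        )
        pieces.append(seq)
        offset += L
    pieces.append(_random_dna(rng, _geom_len(rng, config.intergenic_mean, 50)))
    sequence = "".join(pieces)
    if len(sequence) > 10_000_000:
        raise ValueError("configuration would generate a scaffold > 10 Mbp")
    scaffold = Scaffold(id=f"{config.species}_EDC", sequence=sequence)

    if config.lesion_rate > 0:
        for rec in sorted(truth, key=lambda r: r.interval.start):
            if rec.family == "anchor":
                continue
            if rng.random() < config.lesion_rate:
                kind = RANDOM_LESION_MENU[rng.integers(0, len(RANDOM_LESION_MENU))]
                scaffold, _ = implant_lesion(scaffold, rec, kind, rng=rng, cohort=truth)
    return scaffold, truth, lce_tree


def generate_species_pair(
    config: ClusterConfig,
    divergence: float = 0.05,
    config_b: ClusterConfig | None = None,
):
    """Two clusters descended from one founder gene set.

    Species A is ``generate_cluster(config)`` re-rendered after applying
    per-site coding-safe substitutions at rate ``divergence`` independently
    per species, with species-specific intergenic DNA and gene orientations.
    ``config_b`` may change counts of SEDC/LCE genes (extra genes beyond the
    founder set get fresh founders; smaller counts drop trailing genes).
    Returns ``((scaffoldA, truthA, treeA), (scaffoldB, truthB, treeB))``.
    """
    rng = np.random.default_rng(config.seed)
    units, lce_tree = _founder_units(config, rng)
    if config_b is None:
        config_b = replace(config, species=config.species + "_B")
    out = []
    for sp_conf, sp_tag in ((config, "A"), (config_b, "B")):
        sp_rng = np.random.default_rng((config.seed, 7 + ord(sp_tag)))
        sp_units = [_mutate_unit(u, divergence, sp_rng) for u in units]
        conf = replace(sp_conf, species=sp_conf.species)
        out.append(_render_cluster(conf, sp_units, lce_tree, sp_rng))
    return tuple(out)


# ---------------------------------------------------------------------------
# Lesion implantation
# ---------------------------------------------------------------------------


def left_align_indel(seq: str, pos: int, length: int, insertion: str | None = None) -> int:
    """Leftmost-equivalent position of an indel (VCF-style normalisation).

    For a deletion, ``seq`` is the sequence *containing* the deleted bases
    at ``[pos, pos+length)``. For an insertion, ``seq`` is the sequence
    *after* inserting ``insertion`` at ``pos`` (so the inserted bases
    occupy ``[pos, pos+length)``). Both cases reduce to shifting the run
    left while the flanking base matches the run's last base.
    """
    while pos > 0 and seq[pos - 1] == seq[pos + length - 1]:
        pos -= 1
    return pos


def _shift_point(p: int, edit_pos: int, delta: int) -> int:
    return p + delta if p >= edit_pos else p


def _shift_interval(iv: Interval, edit_pos: int, delta: int) -> Interval:
    if iv.end <= edit_pos:
        return iv
    if iv.start >= edit_pos:
        return Interval(iv.start + delta, iv.end + delta, iv.strand)
    return Interval(iv.start, iv.end + delta, iv.strand)


def _apply_shift(truth: list[TruthRecord], edit_pos: int, delta: int) -> None:
    if delta == 0:
        return
    for rec in truth:
        rec.interval = _shift_interval(rec.interval, edit_pos, delta)
        rec.exons = [_shift_interval(iv, edit_pos, delta) for iv in rec.exons]
        rec.cds = [_shift_interval(iv, edit_pos, delta) for iv in rec.cds]
        for les in rec.implanted_lesions:
            les.coordinate = _shift_point(les.coordinate, edit_pos, delta)


def _codon_spans(rec: TruthRecord) -> list[tuple[int, int]]:
    """Forward-strand (start, end) of each codon, in translation order."""
    spans = []
    for iv in rec.cds:  # transcription order
        if rec.strand == "+":
            spans.extend((p, p + 3) for p in range(iv.start, iv.end, 3))
        else:
            spans.extend((p - 3, p) for p in range(iv.end, iv.start, -3))
    return spans


def implant_lesion(
    scaffold: Scaffold,
    gene: TruthRecord,
    kind: str,
    position: int | None = None,
    rng: np.random.Generator | None = None,
    cohort: list[TruthRecord] | None = None,
):
    """Implant one inactivating lesion into ``gene`` on ``scaffold``.

    ``position`` is a forward-strand coordinate inside a coding segment
    (or, for splice_loss/exon_deletion, inside the coding exon whose splice
    site / body is targeted); when omitted an eligible site is drawn from
    ``rng``. Coordinates of all records in ``cohort`` (defaulting to just
    ``gene``) are shifted for length-changing edits. Returns the mutated
    scaffold and the updated record; indel coordinates are left-normalised.
    """
    if kind not in LESION_KINDS:
        raise ValueError(f"unknown lesion kind {kind!r}")
    rng = rng or np.random.default_rng(0)
    cohort = cohort if cohort is not None else [gene]
    seq = scaffold.sequence
    codons = _codon_spans(gene)
    n_codons = len(codons)

    def _in_coding(p: int) -> bool:
        return any(iv.start <= p < iv.end for iv in gene.cds)

    if position is not None and kind != "splice_loss" and not _in_coding(position):
        raise ValueError(f"position {position} is outside coding segments of {gene.gene_name}")

    delta = 0
    edit_pos = None

    if kind == "premature_stop":
        if position is None:
            lo, hi = 4, max(5, n_codons - 6)
            ci = int(rng.integers(lo, hi))
        else:
            ci = next(
                i for i, (s, e) in enumerate(codons) if s <= position < e
            )
        s, e = codons[ci]
        stop = "TAA"
        block = stop if gene.strand == "+" else reverse_complement(stop)
        seq = seq[:s] + block + seq[e:]
        lesion = Lesion("premature_stop", s, detail=f"codon={ci}")
        frac = ci / n_codons
        gene.true_status = "truncated" if frac >= 0.2 else "pseudogene"

    elif kind in ("frameshift_ins", "frameshift_del"):
        length = int(rng.integers(1, 3))
        if position is None:
            # interior codon, away from exon boundaries and CDS termini
            ok = [
                i for i, (s, e) in enumerate(codons[5:-5], start=5)
                if all(
                    min(s - iv.start, iv.end - e) >= 9
                    for iv in gene.cds
                    if iv.start <= s < iv.end
                )
            ]
            ci = ok[int(rng.integers(0, len(ok)))]
            position = codons[ci][0]
        if kind == "frameshift_del":
            q = left_align_indel(seq, position, length)
            seq = seq[:q] + seq[q + length :]
            delta, edit_pos = -length, q
            lesion = Lesion("frameshift_del", q, detail=f"del{length}")
        else:
            ins = _random_dna(rng, length)
            cand = seq[:position] + ins + seq[position:]
            q = left_align_indel(cand, position, length)
            seq = cand
            delta, edit_pos = length, position
            lesion = Lesion("frameshift_ins", q, detail=f"ins{length}")
        gene.true_status = "pseudogene"

    elif kind == "splice_loss":
        sites = _splice_sites(gene)
        if not sites:
            raise ValueError(f"gene {gene.gene_name} has no targetable splice site")
        which, coord, dinuc = sites[int(rng.integers(0, len(sites)))]
        # mutate the second base of the forward-strand dinucleotide to C/G
        p = coord + 1
        old = seq[p]
        new = "C" if old != "C" else "G"
        seq = seq[:p] + new + seq[p + 1 :]
        lesion = Lesion("splice_loss", coord, detail=which)
        gene.true_status = "pseudogene"

    else:  # exon_deletion
        if position is None:
            iv = gene.cds[int(rng.integers(0, len(gene.cds)))]
        else:
            iv = next(i for i in gene.cds if i.start <= position < i.end)
        # delete the full exon containing this CDS
        exon = next(e for e in gene.exons if e.start <= iv.start and iv.end <= e.end)
        seq = seq[: exon.start] + seq[exon.end :]
        delta, edit_pos = -(len(exon)), exon.start
        gene.exons = [e for e in gene.exons if e != exon]
        gene.cds = [c for c in gene.cds if c != iv]
        lesion = Lesion("exon_deletion", exon.start, detail=f"len{len(exon)}")
        gene.true_status = "pseudogene"

    mutated = Scaffold(id=scaffold.id, sequence=seq, description=scaffold.description)
    if edit_pos is not None:
        _apply_shift(cohort, edit_pos, delta)
    # lesion coordinates are already expressed in mutated-scaffold space,
    # so the lesion is appended after the cohort shift
    gene.implanted_lesions.append(lesion)
    return mutated, gene


def _splice_sites(gene: TruthRecord) -> list[tuple[str, int, str]]:
    """Targetable splice dinucleotides flanking coding exons.

    Every gene has a non-coding first exon, so each first coding exon has an
    upstream acceptor; internal coding-coding junctions contribute a donor
    and an acceptor. Coordinates are the forward-strand start of the
    dinucleotide.
    """
    sites = []
    for i, iv in enumerate(gene.cds):
        if gene.strand == "+":
            sites.append(("acceptor", iv.start - 2, "AG"))
            if i < len(gene.cds) - 1:
                sites.append(("donor", iv.end, "GT"))
        else:
            sites.append(("acceptor", iv.end, "CT"))  # revcomp(AG)
            if i < len(gene.cds) - 1:
                sites.append(("donor", iv.start - 2, "AC"))  # revcomp(GT)
    return sites


# ---------------------------------------------------------------------------
# Truth export helpers
# ---------------------------------------------------------------------------


def truth_to_gene_models(truth: list[TruthRecord], scaffold_id: str):
    from .io_formats import GeneModel

    models = []
    for rec in truth:
        models.append(
            GeneModel(
                name=rec.gene_name,
                scaffold_id=scaffold_id,
                strand=rec.strand,
                exons=list(rec.exons),
                cds=list(rec.cds),
                architecture=rec.architecture,
                status=rec.true_status,
                family=rec.family,
                protein=rec.protein,
            )
        )
    return models


def truth_table_rows(truth: list[TruthRecord]) -> list[dict]:
    rows = []
    for rec in truth:
        rows.append(
            {
                "gene": rec.gene_name,
                "family": rec.family,
                "strand": rec.strand,
                "start": rec.interval.start,
                "end": rec.interval.end,
                "architecture": rec.architecture,
                "status": rec.true_status,
                "lesions": ";".join(
                    f"{l.kind}@{l.coordinate}({l.detail})"
                    for l in rec.implanted_lesions
                )
                or ".",
            }
        )
    return rows
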