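"""Sequence I/O and coordinate primitives shared by the whole pipeline.

Internal conventions
--------------------
* All genomic coordinates are 0-based, half-open intervals on the forward
  strand of a scaffold. GFF3 emission converts to the standard 1-based
  closed convention; report text uses 1-based closed ("GenBank style").
* DNA is restricted to the alphabet ``{A, C, G, T, N}`` and stored
  uppercase. Ambiguity codes other than N are rejected at load because
  codon-level logic downstream (translation, splice-site checks, lesion
  calling) is only defined over this alphabet.
* Frames are numbered 0-2 on each strand; minus-strand features are always
  reported in forward-scaffold coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

VALID_DNA = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FormatError(ValueError):
    """Raised for malformed input files or illegal sequence characters."""


@dataclass
class Scaffold:
    """A genome scaffold/contig: id plus uppercase DNA over {A,C,G,T,N}."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_DNA
        if bad:
            raise FormatError(
                f"scaffold {self.id!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, interval: "Interval") -> str:
        """Strand-aware subsequence: minus-strand intervals are
        reverse-complemented so the result reads 5'->3' on the feature."""
        seq = self.sequence[interval.start : interval.end]
        return reverse_complement(seq) if interval.strand == "-" else seq


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def shifted(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset, self.strand)


def read_fasta(path) -> list[Scaffold]:
    """Read a FASTA file into :class:`Scaffold` records, in file order.

    Sequences are uppercased; the description after the first whitespace of
    the header is retained separately. An empty file yields an empty list
    with a warning.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(Scaffold(id=rec.id, sequence=str(rec.seq), description=desc))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write (Scaffold | (id, seq) | (id, seq, description)) records, wrapped."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, Scaffold):
                rid, seq, desc = rec.id, rec.sequence, rec.description
            elif len(rec) == 3:
                rid, seq, desc = rec
            else:
                rid, seq = rec
                desc = ""
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N} (case-insensitive)."""
    seq = seq.upper()
    bad = set(seq) - VALID_DNA
    if bad:
        raise FormatError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 0, strand: str = "+") -> str:
    """Translate DNA in the given frame/strand with the standard code.

    Stops are ``*``; codons containing N translate to ``X``; a trailing
    partial codon is dropped. Minus strand means: reverse-complement first,
    then apply the frame.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = seq.upper()
    if strand == "-":
        seq = reverse_complement(seq)
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A located gene: exon intervals, coding segments, architecture, status.

    ``exons`` and ``cds`` are ordered 5'->3' along the gene (i.e. by
    ascending forward coordinate for plus-strand genes and descending for
    minus-strand genes). ``cds_phase`` follows GFF3 phase semantics.
    """

    name: str
    scaffold_id: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    cds_phase: list[int] = field(default_factory=list)
    architecture: str = "other"  # SEDC | SFTP | S100A | PGLYRP | other
    source: str = "annotated"  # annotated | template_guided
    status: str = "intact"  # intact | truncated | pseudogene | unresolved
    family: str = ""
    protein: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cds_phase:
            self.cds_phase = _default_phases(self.cds)
        fwd = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(fwd, fwd[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping CDS intervals in gene {self.name}")

    @property
    def span(self) -> Interval:
        parts = self.exons or self.cds
        return Interval(
            min(p.start for p in parts), max(p.end for p in parts), self.strand
        )

    def coding_sequence(self, scaffold: Scaffold) -> str:
        """Spliced CDS read 5'->3' on the coding strand."""
        parts = sorted(self.cds, key=lambda iv: iv.start)
        seq = "".join(scaffold.sequence[p.start : p.end] for p in parts)
        return reverse_complement(seq) if self.strand == "-" else seq


def _default_phases(cds: list[Interval]) -> list[int]:
    phases, consumed = [], 0
    for iv in cds:
        phases.append((3 - consumed % 3) % 3)
        consumed += len(iv)
    return phases


def write_gff3(models: list[GeneModel], path) -> None:
    """Emit gene/mRNA/exon/CDS features (1-based closed, phase on CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            attrs = f"ID={m.name};family={m.family};status={m.status};architecture={m.architecture}"
            fh.write(
                _gff_line(m.scaffold_id, "gene", span, m.strand, ".", attrs)
            )
            fh.write(
                _gff_line(
                    m.scaffold_id, "mRNA", span, m.strand, ".",
                    f"ID={m.name}.t1;Parent={m.name}",
                )
            )
            for i, ex in enumerate(m.exons, 1):
                fh.write(
                    _gff_line(
                        m.scaffold_id, "exon", ex, m.strand, ".",
                        f"ID={m.name}.exon{i};Parent={m.name}.t1",
                    )
                )
            for iv, phase in zip(m.cds, m.cds_phase):
                fh.write(
                    _gff_line(
                        m.scaffold_id, "CDS", iv, m.strand, str(phase),
                        f"ID={m.name}.cds;Parent={m.name}.t1",
                    )
                )


def _gff_line(seqid, ftype, iv: Interval, strand, phase, attrs) -> str:
    return (
        f"{seqid}\tedcscan\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
        f"{strand}\t{phase}\t{attrs}\n"
    )


def read_gff3(path) -> list[GeneModel]:
    """Read gene models written by :func:`write_gff3` (restricted subset)."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _, ftype, start, end, _, strand, phase, attrs = cols
            iv = Interval(int(start) - 1, int(end), strand)
            a = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                name = a["ID"]
                genes[name] = {
                    "scaffold": seqid,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "phase": [],
                    "family": a.get("family", ""),
                    "status": a.get("status", "intact"),
                    "architecture": a.get("architecture", "other"),
                }
                order.append(name)
            elif ftype in ("exon", "CDS"):
                parent = a["Parent"].rsplit(".t1", 1)[0]
                if parent not in genes:
                    raise FormatError(
                        f"{path}:{lineno}: feature parent {parent!r} unknown"
                    )
                if ftype == "exon":
                    genes[parent]["exons"].append(iv)
                else:
                    genes[parent]["cds"].append(iv)
                    genes[parent]["phase"].append(0 if phase == "." else int(phase))
    out = []
    for name in order:
        g = genes[name]
        rev = g["strand"] == "-"
        exons = sorted(g["exons"], key=lambda i: i.start, reverse=rev)
        pairs = sorted(
            zip(g["cds"], g["phase"]), key=lambda p: p[0].start, reverse=rev
        )
        out.append(
            GeneModel(
                name=name,
                scaffold_id=g["scaffold"],
                strand=g["strand"],
                exons=exons,
                cds=[p[0] for p in pairs],
                cds_phase=[p[1] for p in pairs],
                architecture=g["architecture"],
                status=g["status"],
                family=g["family"],
            )
        )
    return out
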