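"""Readers and writers for every external format the toolkit touches.

Dialects are strict and documented per function:

* PDB v3.3 fixed-column ATOM records (HETATM and altlocs other than ' '/'A'
  are dropped).
* Pose-score files: optional ``#`` header lines, one pose per line,
  whitespace-separated fields, the score in the LAST field, poses in rank
  order (rank 1 first).
* Pair lists: tab-separated, no header, unordered pair identity
  (canonicalized lexicographically), self-pairs rejected.
* VCF 4.x subset: only CHROM POS ID REF ALT are consumed; SNVs only, other
  records are skipped with a warning.
* GFF3 subset: only CDS features of the named gene; phase is recomputed
  from segment order rather than trusted.

Genomic positions are 1-based closed (VCF/GFF3 convention); residue indices
are 1-based.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import EmptyInputError, ParseError

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "VariantRecord",
    "GeneModel",
    "read_structure",
    "write_structure",
    "read_pose_scores",
    "write_pose_scores",
    "canonical_pair",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_gff3_cds",
    "write_gff3_gene",
]

_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# structure types


@dataclass
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def coord(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    number: int
    name: str  # 3-letter code
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def coords(self, heavy_only: bool = False):
        """All atom coordinates in file order as an (N, 3) list."""
        out = []
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    if heavy_only and not atom.is_heavy:
                        continue
                    out.append(atom.coord)
        return out


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    trait: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"non-SNV alleles {self.ref}>{self.alt} at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class GeneModel:
    """Minimal CDS-only gene model.

    ``cds_segments`` are 1-based closed genomic intervals, listed in
    translation order (ascending genomic coordinate on '+', descending
    on '-').
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        segs = sorted(self.cds_segments)
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            if a2 <= b1:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        for a, b in segs:
            if a > b:
                raise ValueError(f"inverted CDS segment ({a}, {b}) in {self.gene_id}")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length of {self.gene_id} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_segments)


# ---------------------------------------------------------------------------
# PDB


def read_structure(pdb_text: str, structure_id: str = "structure") -> Structure:
    """Parse ATOM records from PDB v3.3 fixed-column text.

    HETATM records and altlocs other than ' '/'A' are dropped; chain order
    and residue order are preserved. Residue numbers must be strictly
    increasing within each chain.
    """
    chains: dict[str, Chain] = {}
    last_resseq: dict[str, int] = {}
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "HETATM":
            continue
        if rec != "ATOM":
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: ATOM record shorter than coordinate columns")
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        try:
            atom_name = line[12:16].strip()
            resname = line[17:20].strip()
            chain_id = line[21]
            resseq = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed fixed-width field ({exc})") from None
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = next((c for c in atom_name if c.isalpha()), "C")
        if chain_id not in chains:
            chains[chain_id] = Chain(id=chain_id)
        chain = chains[chain_id]
        if chain.residues and chain.residues[-1].number == resseq:
            residue = chain.residues[-1]
        else:
            if chain_id in last_resseq and resseq <= last_resseq[chain_id]:
                raise ParseError(
                    f"line {lineno}: residue number {resseq} not strictly increasing "
                    f"in chain {chain_id}"
                )
            residue = Residue(number=resseq, name=resname)
            chain.residues.append(residue)
            last_resseq[chain_id] = resseq
        residue.atoms.append(Atom(atom_name, element, x, y, z))
    structure = Structure(id=structure_id, chains=list(chains.values()))
    if structure.n_atoms == 0:
        raise EmptyInputError("no ATOM records survived parsing (empty structure)")
    return structure


def write_structure(structure: Structure) -> str:
    lines = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
                lines.append(
                    f"ATOM  {serial:>5} {name:<4} {res.name:>3} {chain.id}"
                    f"{res.number:>4}    {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2}"
                )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pose scores


def read_pose_scores(text: str, pair=None):
    """Parse a ranked pose-score file into a PoseList.

    Dialect: optional '#'-prefixed header lines, then one pose per line with
    whitespace-separated fields and the score in the last field. The first
    pose line is rank 1.
    """
    from .docking import PoseList  # local import; docking depends on this module

    scores = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        try:
            scores.append(float(fields[-1]))
        except ValueError:
            raise ParseError(
                f"line {lineno}: last field {fields[-1]!r} is not a numeric score"
            ) from None
    if not scores:
        raise EmptyInputError("pose-score file contains no pose lines")
    return PoseList(pair=pair, scores=scores)


def write_pose_scores(poses, header: str | None = None) -> str:
    lines = []
    if header:
        for h in header.splitlines():
            lines.append(f"# {h}")
    for rank, s in enumerate(poses.scores, start=1):
        lines.append(f"{rank}\t{s:.6f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pair lists


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair identity, canonicalized lexicographically."""
    return (a, b) if a <= b else (b, a)


def read_pairs_tsv(text: str, with_scores: bool = False):
    """Read a headerless TSV pair list; pairs are canonicalized.

    Self-pairs (A == B) are rejected: the network carries no
    self-interactions.
    """
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t")
        need = 3 if with_scores else 2
        if len(fields) < need:
            raise ParseError(f"line {lineno}: expected {need} tab-separated fields")
        a, b = fields[0], fields[1]
        if a == b:
            raise ParseError(f"line {lineno}: self-pair {a!r} is not allowed")
        pair = canonical_pair(a, b)
        if with_scores:
            try:
                value = float(fields[2])
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric value {fields[2]!r}") from None
            out.append((*pair, value))
        else:
            out.append(pair)
    return out


def write_pairs_tsv(pairs: Iterable, header: str | None = None) -> str:
    lines = []
    if header:
        lines.append(f"# {header}")
    for entry in pairs:
        lines.append("\t".join(str(x) for x in entry))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(text: str) -> dict[str, str]:
    records = SeqIO.parse(io.StringIO(text), "fasta")
    return {rec.id: str(rec.seq).upper() for rec in records}


def write_fasta(sequences: dict[str, str], width: int = 60) -> str:
    chunks = []
    for name, seq in sequences.items():
        chunks.append(f">{name}")
        for i in range(0, len(seq), width):
            chunks.append(seq[i : i + width])
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# VCF subset


def read_vcf(text: str) -> list[VariantRecord]:
    """Read the SNV subset of a VCF: CHROM POS ID REF ALT.

    Non-SNV records (indels, MNVs, multiallelic sites) are skipped with a
    warning; the ID column is carried through as the trait annotation
    ('.' means none).
    """
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"line {lineno}: fewer than 5 VCF columns")
        chrom, pos_s, vid, ref, alt = fields[:5]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            warnings.warn(f"line {lineno}: skipping non-SNV record {ref}>{alt}", stacklevel=2)
            continue
        try:
            pos = int(pos_s)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer POS {pos_s!r}") from None
        records.append(
            VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, trait=None if vid == "." else vid)
        )
    return records


def write_vcf(records: Sequence[VariantRecord]) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in records:
        vid = v.trait if v.trait is not None else "."
        lines.append(f"{v.chrom}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\t.\t.")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GFF3 subset


def read_gff3_cds(text: str, gene_id: str) -> GeneModel:
    """Extract the CDS-only gene model for ``gene_id`` from GFF3 text.

    A CDS feature belongs to the gene when its ID or Parent attribute equals
    ``gene_id`` (or ``gene_id`` with a transcript suffix). Phase columns are
    ignored; translation order is recomputed from strand and coordinates.
    """
    segments = []
    chrom = None
    strand = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"line {lineno}: expected 9 GFF3 columns")
        if fields[2] != "CDS":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        owner = attrs.get("Parent", attrs.get("ID", ""))
        if owner != gene_id and not owner.startswith(gene_id + "."):
            continue
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer CDS coordinates") from None
        if chrom is None:
            chrom, strand = fields[0], fields[6]
        segments.append((start, end))
    if not segments:
        raise EmptyInputError(f"no CDS features found for gene {gene_id!r}")
    segments.sort(reverse=(strand == "-"))
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, cds_segments=tuple(segments))


def write_gff3_gene(gene: GeneModel) -> str:
    segs = sorted(gene.cds_segments)
    lines = [
        f"{gene.chrom}\tdocknet\tgene\t{segs[0][0]}\t{segs[-1][1]}\t.\t{gene.strand}\t.\t"
        f"ID={gene.gene_id}"
    ]
    for start, end in segs:
        lines.append(
            f"{gene.chrom}\tdocknet\tCDS\t{start}\t{end}\t.\t{gene.strand}\t.\t"
            f"Parent={gene.gene_id}"
        )
    return "\n".join(lines) + "\n"


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
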