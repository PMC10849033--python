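"""SNV consequence annotation, interface mapping and binding-affinity
perturbation classification.

The annotator is a minimal SNV-only consequence caller: it locates the
affected codon through cumulative CDS coordinates (reverse-complementing on
the '-' strand), translates with the standard genetic code, and emits a
protein substitution when the amino acid changes.

Binding-energy differences are consumed as input; ddG = dG_ref - dG_alt,
with strict +/-1 kcal/mol class boundaries (ties are neutral).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import seq3
from scipy.spatial import cKDTree

from .io_formats import GeneModel, Structure, VariantRecord, canonical_pair

__all__ = [
    "ProteinSubstitution",
    "AnnotationResult",
    "InterfaceResidueSet",
    "DdgRecord",
    "annotate_substitution",
    "find_interface_residues",
    "map_variants_to_interfaces",
    "classify_ddg",
    "summarize_perturbation",
]

logger = logging.getLogger(__name__)

STRENGTHEN = "strengthen"
WEAKEN = "weaken"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class ProteinSubstitution:
    gene_id: str
    position: int  # 1-based protein coordinate
    ref_residue: str  # 3-letter code
    alt_residue: str  # 3-letter code

    def __post_init__(self):
        if self.ref_residue == self.alt_residue:
            raise ValueError("synonymous change is not a substitution")

    @property
    def label(self) -> str:
        return f"p.{self.ref_residue}{self.position}{self.alt_residue}"


@dataclass(frozen=True)
class AnnotationResult:
    kind: str  # 'nonsynonymous' | 'synonymous' | 'non-coding'
    substitution: ProteinSubstitution | None = None
    codon_ref: str | None = None
    codon_alt: str | None = None


@dataclass
class InterfaceResidueSet:
    pair: tuple[str, str]
    interface: dict[str, set[int]]  # partner id -> interfacial residue numbers
    residues: dict[str, set[int]] | None = None  # partner id -> all residue numbers
    cutoff: float = 5.5


@dataclass(frozen=True)
class DdgRecord:
    variant: str
    pair: tuple[str, str]
    dg_ref: float
    dg_alt: float
    ddg: float
    perturbation: str

    def __post_init__(self):
        assert self.ddg == self.dg_ref - self.dg_alt


def _cds_positions(gene: GeneModel) -> list[int]:
    """Genomic position of every CDS base, in translation order."""
    out = []
    for start, end in gene.cds_segments:
        if gene.strand == "+":
            out.extend(range(start, end + 1))
        else:
            out.extend(range(end, start - 1, -1))
    return out


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def annotate_substitution(
    genome: Mapping[str, str],
    gene: GeneModel,
    variant: VariantRecord,
) -> AnnotationResult:
    """Classify an SNV as nonsynonymous / synonymous / non-coding for one
    gene model.

    The variant's ref allele must match the genome base (plus strand) at
    its position, or a ValueError is raised.
    """
    chrom_seq = genome[variant.chrom]
    if not 1 <= variant.pos <= len(chrom_seq):
        raise ValueError(f"position {variant.pos} outside chromosome {variant.chrom}")
    genome_base = chrom_seq[variant.pos - 1]
    if genome_base != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"VCF says {variant.ref}, genome has {genome_base}"
        )
    if variant.chrom != gene.chrom:
        return AnnotationResult(kind="non-coding")
    positions = _cds_positions(gene)
    try:
        cds_idx = positions.index(variant.pos)
    except ValueError:
        return AnnotationResult(kind="non-coding")
    codon_idx = cds_idx // 3
    within = cds_idx % 3
    codon_pos = positions[codon_idx * 3 : codon_idx * 3 + 3]
    if gene.strand == "+":
        ref_codon = "".join(chrom_seq[p - 1] for p in codon_pos)
        alt_base = variant.alt
    else:
        ref_codon = "".join(_COMPLEMENT[chrom_seq[p - 1]] for p in codon_pos)
        alt_base = _COMPLEMENT[variant.alt]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return AnnotationResult(kind="synonymous", codon_ref=ref_codon, codon_alt=alt_codon)
    sub = ProteinSubstitution(
        gene_id=gene.gene_id,
        position=codon_idx + 1,
        ref_residue=seq3(ref_aa),
        alt_residue=seq3(alt_aa),
    )
    return AnnotationResult(kind="nonsynonymous", substitution=sub,
                            codon_ref=ref_codon, codon_alt=alt_codon)


def find_interface_residues(complex_structure: Structure, cutoff: float = 5.5) -> InterfaceResidueSet:
    """Interface residues of a two-chain complex.

    A residue is interfacial iff at least one of its heavy atoms lies
    within ``cutoff`` Angstrom of any heavy atom of the partner chain.
    """
    if len(complex_structure.chains) != 2:
        raise ValueError(
            f"interface detection needs exactly 2 chains, got {len(complex_structure.chains)}"
        )
    a, b = complex_structure.chains

    def chain_atoms(chain):
        coords, res_nums = [], []
        for res in chain.residues:
            for atom in res.atoms:
                if atom.is_heavy:
                    coords.append(atom.coord)
                    res_nums.append(res.number)
        return np.asarray(coords, dtype=float), res_nums

    coords_a, nums_a = chain_atoms(a)
    coords_b, nums_b = chain_atoms(b)
    iface: dict[str, set[int]] = {a.id: set(), b.id: set()}
    if cutoff > 0 and len(coords_a) and len(coords_b):
        tree_b = cKDTree(coords_b)
        tree_a = cKDTree(coords_a)
        for i, hits in enumerate(tree_b.query_ball_point(coords_a, cutoff)):
            if hits:
                iface[a.id].add(nums_a[i])
        for j, hits in enumerate(tree_a.query_ball_point(coords_b, cutoff)):
            if hits:
                iface[b.id].add(nums_b[j])
    return InterfaceResidueSet(
        pair=canonical_pair(a.id, b.id),
        interface=iface,
        residues={a.id: set(nums_a), b.id: set(nums_b)},
        cutoff=cutoff,
    )


def map_variants_to_interfaces(
    substitutions: Iterable[ProteinSubstitution],
    interfaces: Iterable[InterfaceResidueSet],
    protein_of: Mapping[str, str] | None = None,
) -> list[dict]:
    """Cross every substitution with every interface it falls on.

    ``protein_of`` maps gene id to the protein/structure id used in the
    interface sets (identity when omitted). A hit is emitted for each
    (substitution, pair) where the substituted position is interfacial on
    the carrying protein; positions absent from the structure are skipped
    with a log message.
    """
    interfaces = list(interfaces)
    hits = []
    for sub in substitutions:
        prot = protein_of.get(sub.gene_id, sub.gene_id) if protein_of else sub.gene_id
        for iset in interfaces:
            if prot not in iset.interface:
                continue
            if iset.residues is not None and sub.position not in iset.residues[prot]:
                logger.info(
                    "substitution %s position %d absent from structure of %s in pair %s; skipped",
                    sub.label, sub.position, prot, iset.pair,
                )
                continue
            if sub.position in iset.interface[prot]:
                hits.append({"variant": sub.label, "gene": sub.gene_id,
                             "protein": prot, "pair": iset.pair,
                             "position": sub.position})
    return hits


def classify_ddg(
    dg_ref: float,
    dg_alt: float,
    magnitude: float = 1.0,
    variant: str = "",
    pair: tuple[str, str] = ("", ""),
) -> DdgRecord:
    """ddG = dG_ref - dG_alt; strengthen iff ddG > magnitude, weaken iff
    ddG < -magnitude, neutral otherwise (strict inequalities).

    Positive ddG means the alternative allele binds more strongly (more
    negative binding energy).
    """
    if not (np.isfinite(dg_ref) and np.isfinite(dg_alt)):
        raise ValueError("binding energies must be finite")
    ddg = dg_ref - dg_alt
    if ddg > magnitude:
        cls = STRENGTHEN
    elif ddg < -magnitude:
        cls = WEAKEN
    else:
        cls = NEUTRAL
    return DdgRecord(variant=variant, pair=pair, dg_ref=dg_ref, dg_alt=dg_alt,
                     ddg=ddg, perturbation=cls)


def summarize_perturbation(records: Iterable[DdgRecord]) -> dict:
    """Distinct-variant and distinct-PPI counts per perturbation class.

    A variant classified differently across its PPIs is counted in every
    class it reaches; the distinct union across the signed classes is also
    reported.
    """
    per_class: dict[str, dict[str, set]] = {
        cls: {"variants": set(), "pairs": set()} for cls in (STRENGTHEN, WEAKEN, NEUTRAL)
    }
    for rec in records:
        per_class[rec.perturbation]["variants"].add(rec.variant)
        per_class[rec.perturbation]["pairs"].add(rec.pair)
    signed_union = per_class[STRENGTHEN]["variants"] | per_class[WEAKEN]["variants"]
    return {
        cls: {"n_variants": len(v["variants"]), "n_pairs": len(v["pairs"])}
        for cls, v in per_class.items()
    } | {"significant_variants_union": len(signed_union)}
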