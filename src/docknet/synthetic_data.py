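"""Synthetic-input generators: parametric decoy-score sets with configurable
class separations, toy poly-alanine structures, and toy genomes with planted
SNVs of known consequence.

Every generator is a pure function of (configuration, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .benchmark_eval import LabeledPair, LabeledPairSet
from .docking import PoseList
from .io_formats import Atom, Chain, GeneModel, Residue, Structure, VariantRecord

__all__ = [
    "ScoreGenConfig",
    "BENCHMARK_PRESETS",
    "gen_pose_list",
    "gen_benchmark",
    "gen_toy_structures",
    "assemble_complex",
    "gen_toy_genome",
    "plant_codon_substitution",
]


@dataclass(frozen=True)
class ScoreGenConfig:
    n_pairs: int = 1
    n_poses: int = 2000
    decoy_mean: float = 20.0
    decoy_sd: float = 4.0
    z_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_poses < 3:
            raise ValueError("n_poses must be >= 3")
        if self.decoy_sd <= 0 or self.z_sd < 0:
            raise ValueError("spreads must be positive")


# class z-score means: (positives, negatives)
BENCHMARK_PRESETS = {
    "experimental": (10.0, 5.8),
    "model": (6.6, 5.9),
}


def gen_pose_list(
    cfg: ScoreGenConfig,
    z_target: float,
    rng: np.random.Generator | None = None,
    pair=None,
) -> PoseList:
    """Pose list whose decoy-referenced z equals ``z_target`` exactly.

    K-1 decoy scores are drawn from Normal(decoy_mean, decoy_sd); the
    rank-1 score is set to sample_mean + z_target * sample_sd so the
    (top-excluded, n-1 denominator) z recomputes to ``z_target``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    decoys = rng.normal(cfg.decoy_mean, cfg.decoy_sd, size=cfg.n_poses - 1)
    top = decoys.mean() + z_target * decoys.std(ddof=1)
    return PoseList(scores=[float(top)] + decoys.tolist(), pair=pair)


def gen_benchmark(
    n_pos: int,
    n_neg: int,
    preset: str | None = "experimental",
    z_pos_mean: float | None = None,
    z_neg_mean: float | None = None,
    cfg: ScoreGenConfig = ScoreGenConfig(),
    seed: int = 0,
) -> tuple[LabeledPairSet, dict]:
    """Labeled benchmark with per-class z targets drawn from
    Normal(class mean, cfg.z_sd).

    Presets: 'experimental' (class means 10.0 / 5.8) and 'model'
    (6.6 / 5.9); explicit ``z_pos_mean``/``z_neg_mean`` override. Returns
    the labeled set (with the realized z of each pair) and a dict of pose
    lists keyed by pair id.
    """
    if n_pos < 1 or n_neg < 0:
        raise ValueError("need n_pos >= 1 and n_neg >= 0")
    if z_pos_mean is None or z_neg_mean is None:
        if preset not in BENCHMARK_PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        z_pos_mean, z_neg_mean = BENCHMARK_PRESETS[preset]
    rng = np.random.default_rng(seed)
    entries = []
    pose_lists = {}
    for label, count, mean, tag in ((True, n_pos, z_pos_mean, "POS"),
                                    (False, n_neg, z_neg_mean, "NEG")):
        for i in range(count):
            z_target = float(rng.normal(mean, cfg.z_sd))
            pair = (f"{tag}{i}a", f"{tag}{i}b")
            poses = gen_pose_list(cfg, z_target, rng=rng, pair=pair)
            pose_lists[poses.pair] = poses
            entries.append(LabeledPair(pair=poses.pair, z=z_target, positive=label))
    return LabeledPairSet(entries=entries), pose_lists


# ---------------------------------------------------------------------------
# toy structures


def _poly_ala(structure_id: str, chain_id: str, ca_coords: np.ndarray,
              cb_dirs: np.ndarray | None = None) -> Structure:
    chain = Chain(id=chain_id)
    for i, ca in enumerate(ca_coords, start=1):
        res = Residue(number=i, name="ALA")
        res.atoms.append(Atom("CA", "C", float(ca[0]), float(ca[1]), float(ca[2])))
        if cb_dirs is not None:
            cb = ca + 1.5 * cb_dirs[i - 1]
            res.atoms.append(Atom("CB", "C", float(cb[0]), float(cb[1]), float(cb[2])))
        chain.residues.append(res)
    return Structure(id=structure_id, chains=[chain])


def _ball_lattice(n_points: int, spacing: float) -> np.ndarray:
    """First ``n_points`` cubic-lattice points by distance from the origin."""
    reach = 1
    while True:
        axis = np.arange(-reach, reach + 1) * spacing
        pts = np.array(np.meshgrid(axis, axis, axis)).reshape(3, -1).T
        if len(pts) >= n_points:
            order = np.argsort(np.sum(pts**2, axis=1), kind="stable")
            return pts[order][:n_points]
        reach += 1


def gen_toy_structures(kind: str, n_residues: int, seed: int = 0):
    """Toy poly-alanine CA+CB fixtures.

    kinds: 'helix' (ideal alpha-helical CA trace, ~3.8 A CA-CA), 'sphere'
    (a solid jittered ball — has a grid core, so full overlap clashes), and
    'half_sphere_pair' (a solid ball nested in a complementary
    hemispherical cup; returned as two structures whose current placement
    is the planted shape-complementary pose).
    """
    if n_residues < 3:
        raise ValueError("need n_residues >= 3")
    rng = np.random.default_rng(seed)
    if kind == "helix":
        i = np.arange(n_residues)
        theta = np.deg2rad(100.0) * i
        ca = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i], axis=1)
        dirs = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
        return _poly_ala("helix", "A", ca, dirs)
    if kind == "sphere":
        pts = _ball_lattice(n_residues, 2.4) + rng.normal(0, 0.08, size=(n_residues, 3))
        dirs = rng.normal(size=pts.shape)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        return _poly_ala("sphere", "A", pts, dirs)
    if kind == "half_sphere_pair":
        # complementary cup and ball: the ligand ball nests in a
        # hemispherical receptor pocket with one lattice spacing of
        # clearance, so the planted pose maximizes surface contact
        spacing = 2.4
        lig_pts = _ball_lattice(n_residues, spacing)
        pocket_radius = float(np.max(np.linalg.norm(lig_pts, axis=1))) + spacing
        reach = int(np.ceil((pocket_radius + 3 * spacing) / spacing))
        axis = np.arange(-reach, reach + 1) * spacing
        pts = np.array(np.meshgrid(axis, axis, axis)).reshape(3, -1).T
        cand = pts[(pts[:, 2] <= 0.01) & (np.linalg.norm(pts, axis=1) > pocket_radius)]
        cand = cand[np.argsort(np.linalg.norm(cand, axis=1), kind="stable")][:n_residues]
        lig_pts = lig_pts + rng.normal(0, 0.05, size=lig_pts.shape)
        cand = cand + rng.normal(0, 0.05, size=cand.shape)
        receptor = _poly_ala("receptor", "A", cand)
        ligand = _poly_ala("ligand", "B", lig_pts)
        return receptor, ligand
    raise ValueError(f"unknown structure kind {kind!r}")


def assemble_complex(a: Structure, b: Structure, complex_id: str = "complex") -> Structure:
    """Two single-chain structures at their current coordinates, as one
    two-chain complex (chain ids 'A' and 'B')."""
    ca = Chain(id="A", residues=[Residue(r.number, r.name, list(r.atoms))
                                 for r in a.chains[0].residues])
    cb = Chain(id="B", residues=[Residue(r.number, r.name, list(r.atoms))
                                 for r in b.chains[0].residues])
    return Structure(id=complex_id, chains=[ca, cb])


# ---------------------------------------------------------------------------
# toy genomes


_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _lay_out_gene(gene_id: str, chrom: str, cds: str, offset: int, strand: str,
                  n_exons: int, rng: np.random.Generator) -> tuple[str, GeneModel]:
    """Place a CDS (mRNA orientation) onto genomic sequence starting at
    ``offset`` (0-based), split into exons with random intron gaps.
    Returns (genomic text for the gene region, gene model)."""
    genomic = str(Seq(cds).reverse_complement()) if strand == "-" else cds
    cuts = sorted(rng.choice(np.arange(3, len(cds) - 3), size=n_exons - 1, replace=False)) \
        if n_exons > 1 else []
    bounds = [0, *cuts, len(cds)]
    pieces = [genomic[a:b] for a, b in zip(bounds, bounds[1:])]
    region = ""
    segments = []
    pos = offset
    for i, piece in enumerate(pieces):
        start = pos + len(region) + 1  # 1-based genomic
        region += piece
        segments.append((start, start + len(piece) - 1))
        if i < len(pieces) - 1:
            intron_len = int(rng.integers(5, 20))
            region += "".join(rng.choice(list(_BASES), size=intron_len))
    segments = tuple(sorted(segments, reverse=(strand == "-")))
    return region, GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                             cds_segments=segments)


def gen_toy_genome(
    n_genes: int,
    seed: int = 0,
    n_codons_range: tuple[int, int] = (20, 60),
    snvs_per_gene: int = 3,
):
    """Toy genome with genes on both strands and planted SNVs.

    Returns (genome: chrom -> sequence, genes, variants, truth) where
    ``truth`` rows record the constructed consequence of each variant
    ('nonsynonymous' with the substitution label, 'synonymous', or
    'non-coding'). Truth is derived by rebuilding the mutant mRNA and
    diffing the two translations — construction-level, independent of the
    annotator's codon arithmetic.
    """
    if n_genes < 1:
        raise ValueError("need n_genes >= 1")
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    variants: list[VariantRecord] = []
    truth: list[dict] = []
    for g in range(n_genes):
        chrom = f"chr{g + 1}"
        gene_id = f"gene{g + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = int(rng.integers(n_codons_range[0], n_codons_range[1] + 1))
        cds = _random_cds(n_codons, rng)
        flank5 = "".join(rng.choice(list(_BASES), size=int(rng.integers(10, 30))))
        n_exons = int(rng.integers(1, 4))
        region, gene = _lay_out_gene(gene_id, chrom, cds, len(flank5), strand,
                                     n_exons, rng)
        flank3 = "".join(rng.choice(list(_BASES), size=int(rng.integers(10, 30))))
        chrom_seq = flank5 + region + flank3
        genome[chrom] = chrom_seq
        genes.append(gene)
        cds_genomic = {p for a, b in gene.cds_segments for p in range(a, b + 1)}
        # plant coding SNVs plus one non-coding SNV per gene
        coding_pool = sorted(cds_genomic)
        picks = rng.choice(len(coding_pool), size=min(snvs_per_gene, len(coding_pool)),
                           replace=False)
        positions = [coding_pool[int(i)] for i in picks] + [1]
        for pos in positions:
            ref = chrom_seq[pos - 1]
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            v = VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt)
            variants.append(v)
            truth.append(_truth_row(chrom_seq, gene, v))
    return genome, genes, variants, truth


def _mrna(chrom_seq: str, gene: GeneModel) -> str:
    parts = []
    for start, end in gene.cds_segments:
        piece = chrom_seq[start - 1 : end]
        parts.append(str(Seq(piece).reverse_complement()) if gene.strand == "-" else piece)
    return "".join(parts)


def _truth_row(chrom_seq: str, gene: GeneModel, v: VariantRecord) -> dict:
    from Bio.SeqUtils import seq3

    row = {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
           "gene": gene.gene_id}
    in_cds = any(a <= v.pos <= b for a, b in gene.cds_segments)
    if not in_cds:
        row |= {"consequence": "non-coding", "label": None}
        return row
    mutated = chrom_seq[: v.pos - 1] + v.alt + chrom_seq[v.pos :]
    prot_ref = str(Seq(_mrna(chrom_seq, gene)).translate())
    prot_alt = str(Seq(_mrna(mutated, gene)).translate())
    diffs = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
    if not diffs:
        row |= {"consequence": "synonymous", "label": None}
    else:
        i = diffs[0]
        row |= {"consequence": "nonsynonymous",
                "label": f"p.{seq3(prot_ref[i])}{i + 1}{seq3(prot_alt[i])}"}
    return row


def plant_codon_substitution(
    genome: dict[str, str],
    gene: GeneModel,
    codon_number: int,
    ref_codon: str,
    alt_codon: str,
) -> tuple[dict[str, str], VariantRecord]:
    """Overwrite codon ``codon_number`` (1-based) of ``gene`` with
    ``ref_codon`` and return the updated genome plus the SNV turning it
    into ``alt_codon``. The codons must differ at exactly one base.
    """
    diffs = [i for i in range(3) if ref_codon[i] != alt_codon[i]]
    if len(diffs) != 1:
        raise ValueError("codons must differ at exactly one base for an SNV")
    within = diffs[0]
    positions = []
    for start, end in gene.cds_segments:
        rng_ = range(start, end + 1) if gene.strand == "+" else range(end, start - 1, -1)
        positions.extend(rng_)
    codon_pos = positions[(codon_number - 1) * 3 : (codon_number - 1) * 3 + 3]
    if len(codon_pos) != 3:
        raise ValueError(f"gene {gene.gene_id} has no codon {codon_number}")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    chrom_seq = list(genome[gene.chrom])
    for i, p in enumerate(codon_pos):
        base = ref_codon[i] if gene.strand == "+" else comp[ref_codon[i]]
        chrom_seq[p - 1] = base
    new_genome = dict(genome)
    new_genome[gene.chrom] = "".join(chrom_seq)
    var_pos = codon_pos[within]
    ref_base = ref_codon[within] if gene.strand == "+" else comp[ref_codon[within]]
    alt_base = alt_codon[within] if gene.strand == "+" else comp[alt_codon[within]]
    return new_genome, VariantRecord(chrom=gene.chrom, pos=var_pos, ref=ref_base, alt=alt_base)
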