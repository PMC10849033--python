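"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: rotation-grid search
instead of the SVD superposition, exhaustive pair counting instead of the
trapezoidal ROC sweep, full-mRNA rebuild-and-diff instead of codon
arithmetic, and exhaustive draw enumeration instead of the hypergeometric
tail.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import seq3
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_rmsd(coords_a, coords_b, grid_step_deg: float = 12.0) -> float:
    """Minimum RMSD over rigid motions by Euler-angle grid search plus
    local simplex refinement (translation handled by centering)."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def rmsd_at(angles):
        rot = Rotation.from_euler("zyz", angles).as_matrix()
        return float(np.sqrt(np.mean(np.sum((ac @ rot.T - bc) ** 2, axis=1))))

    grid = np.deg2rad(np.arange(0.0, 360.0, grid_step_deg))
    half = np.deg2rad(np.arange(0.0, 180.0 + grid_step_deg, grid_step_deg))
    best, best_angles = np.inf, None
    for a1 in grid:
        for a2 in half:
            for a3 in grid:
                v = rmsd_at((a1, a2, a3))
                if v < best:
                    best, best_angles = v, (a1, a2, a3)
    res = minimize(rmsd_at, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return min(best, float(res.fun))


def auc_pair_counting(pos_z, neg_z) -> float:
    """AUC = P(z_pos > z_neg) + 0.5 * P(z_pos = z_neg) by exhaustive
    counting over all positive x negative pairs."""
    wins = ties = 0
    for p in pos_z:
        for n in neg_z:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_z) * len(neg_z))


def mrna_diff_annotate(genome, gene, variant):
    """Consequence of an SNV by rebuilding the full mutant mRNA and diffing
    the two translated proteins. Returns (kind, label-or-None)."""
    chrom_seq = genome[variant.chrom]
    if variant.chrom != gene.chrom or not any(
        a <= variant.pos <= b for a, b in gene.cds_segments
    ):
        return "non-coding", None
    mutated = chrom_seq[: variant.pos - 1] + variant.alt + chrom_seq[variant.pos :]

    def protein(seq):
        parts = []
        for start, end in gene.cds_segments:
            piece = seq[start - 1 : end]
            parts.append(str(Seq(piece).reverse_complement()) if gene.strand == "-" else piece)
        return str(Seq("".join(parts)).translate())

    ref_prot = protein(chrom_seq)
    alt_prot = protein(mutated)
    diffs = [i for i, (x, y) in enumerate(zip(ref_prot, alt_prot)) if x != y]
    if not diffs:
        return "synonymous", None
    i = diffs[0]
    return "nonsynonymous", f"p.{seq3(ref_prot[i])}{i + 1}{seq3(alt_prot[i])}"


def hypergeom_upper_tail_enum(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by enumerating all C(N, n)
    draws from a universe with K marked items."""
    universe = list(range(N))
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if sum(1 for d in draw if d in marked) >= k:
            hits += 1
    assert total == comb(N, n)
    return hits / total
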