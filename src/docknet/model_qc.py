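"""Structure-model quality control.

Identity/coverage filtering of homology models against their templates, and
structural similarity measures (least-squares superposition RMSD and the
length-normalized topological similarity score).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateGeometryError, EmptyInputError

__all__ = [
    "AlignmentQC",
    "SuperpositionResult",
    "QcSummary",
    "percent",
    "kabsch_superpose",
    "tm_score",
    "qc_filter",
    "summarize_qc",
    "alignment_identity_coverage",
]


@dataclass(frozen=True)
class AlignmentQC:
    model_id: str
    identity: float  # fraction in [0, 1]
    coverage: float  # fraction in [0, 1]
    template_id: str = ""

    def __post_init__(self):
        for label, value in (("identity", self.identity), ("coverage", self.coverage)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {value}")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float
    tm_score: float | None = None
    d0: float | None = None
    n_aligned: int = 0


@dataclass
class QcSummary:
    mean_tm: float
    mean_rmsd: float
    pct_tm_above: float  # percent of models with TM > tm_cut
    pct_rmsd_below: float  # percent of models with RMSD < rmsd_cut
    n: int
    tm_cut: float = 0.5
    rmsd_cut: float = 2.0


def percent(k: int, n: int) -> float:
    """Half-up percentage rounded to one decimal, as reported in summaries."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    import math

    return math.floor(100.0 * k / n * 10 + 0.5) / 10


def _as_points(coords) -> np.ndarray:
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (N, 3) coordinate array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    return pts


def kabsch_superpose(coords_a, coords_b) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``coords_a`` onto
    ``coords_b`` with reflections excluded.

    Residue correspondence is positional. Raises on fewer than 3 points or
    on (near-)collinear point sets, where the optimal rotation is not
    unique.
    """
    a = _as_points(coords_a)
    b = _as_points(coords_b)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 points, got {n}")
    cent_a = a.mean(axis=0)
    cent_b = b.mean(axis=0)
    ac = a - cent_a
    bc = b - cent_b
    # Rank check on both sets: collinear points leave a free rotation axis.
    for pts in (ac, bc):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise DegenerateGeometryError("collinear (rank-deficient) point set")
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cent_b - rot @ cent_a
    moved = ac @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - bc) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_aligned=n)


def _d0(l_ref: int) -> float:
    # Clamped to 0.5 A so the score stays defined for short toy chains.
    return max(1.24 * max(l_ref - 15, 0) ** (1.0 / 3.0) - 1.8, 0.5)


def _score_at(model: np.ndarray, ref: np.ndarray, sup: SuperpositionResult, d0: float, l_ref: int):
    moved = model @ sup.rotation.T + sup.translation
    d = np.sqrt(np.sum((moved - ref) ** 2, axis=1))
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref), d


def tm_score(coords_model, coords_ref, l_ref: int | None = None) -> SuperpositionResult:
    """Length-normalized topological similarity in (0, 1].

    TM = (1/L_ref) * sum_i 1 / (1 + (d_i/d0)^2), maximized over rigid
    superpositions, with d0 = 1.24*(L_ref-15)^(1/3) - 1.8 (clamped at
    0.5 A). The search is an iterative cutoff refinement: start from the
    all-pair least-squares superposition, then re-superpose on residue
    pairs closer than a d0-scaled cutoff until the score converges
    (tolerance 1e-6, at most 20 iterations).
    """
    model = _as_points(coords_model)
    ref = _as_points(coords_ref)
    if model.shape != ref.shape:
        raise ValueError(f"coordinate sets differ in shape: {model.shape} vs {ref.shape}")
    n = model.shape[0]
    if l_ref is None:
        l_ref = n
    if l_ref < n:
        raise ValueError(f"L_ref ({l_ref}) must be >= number of aligned residues ({n})")
    d0 = _d0(l_ref)
    sup = kabsch_superpose(model, ref)
    score, dists = _score_at(model, ref, sup, d0, l_ref)
    best = SuperpositionResult(
        rotation=sup.rotation, translation=sup.translation, rmsd=sup.rmsd,
        tm_score=score, d0=d0, n_aligned=n,
    )
    prev = score
    cutoff = max(d0, 2.0)
    for _ in range(20):
        sel = dists < cutoff
        while sel.sum() < 3 and cutoff < 1e3:
            cutoff += 0.5
            sel = dists < cutoff
        try:
            sub = kabsch_superpose(model[sel], ref[sel])
        except DegenerateGeometryError:
            break
        score, dists = _score_at(model, ref, sub, d0, l_ref)
        if score > (best.tm_score or 0.0):
            best = SuperpositionResult(
                rotation=sub.rotation, translation=sub.translation,
                rmsd=best.rmsd, tm_score=score, d0=d0, n_aligned=n,
            )
        if abs(score - prev) < 1e-6:
            break
        prev = score
    return best


def qc_filter(qc: AlignmentQC, id_min: float = 0.50, cov_min: float = 0.80) -> bool:
    """High-quality verdict: identity strictly above ``id_min`` AND coverage
    strictly above ``cov_min``."""
    return qc.identity > id_min and qc.coverage > cov_min


def summarize_qc(
    results: Iterable[SuperpositionResult],
    tm_cut: float = 0.5,
    rmsd_cut: float = 2.0,
) -> QcSummary:
    """Mean TM/RMSD and one-decimal percentages above/below the cutoffs."""
    results = list(results)
    if not results:
        raise EmptyInputError("cannot summarize an empty result collection")
    tms = np.array([r.tm_score for r in results], dtype=float)
    rmsds = np.array([r.rmsd for r in results], dtype=float)
    n = len(results)
    return QcSummary(
        mean_tm=float(tms.mean()),
        mean_rmsd=float(rmsds.mean()),
        pct_tm_above=percent(int((tms > tm_cut).sum()), n),
        pct_rmsd_below=percent(int((rmsds < rmsd_cut).sum()), n),
        n=n,
        tm_cut=tm_cut,
        rmsd_cut=rmsd_cut,
    )


def alignment_identity_coverage(aln_model: str, aln_template: str) -> tuple[float, float]:
    """Identity and coverage fractions from a gapped pairwise alignment.

    Identity = identical columns / aligned (both non-gap) columns;
    coverage = aligned columns / ungapped model length.
    """
    if len(aln_model) != len(aln_template):
        raise ValueError("aligned strings must have equal length")
    aligned = sum(1 for a, b in zip(aln_model, aln_template) if a != "-" and b != "-")
    ident = sum(1 for a, b in zip(aln_model, aln_template) if a != "-" and a == b)
    model_len = sum(1 for a in aln_model if a != "-")
    if model_len == 0 or aligned == 0:
        raise ValueError("empty model sequence or alignment")
    return ident / aligned, aligned / model_len
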