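"""Decoy-referenced docking z-scores and the interaction decision rule.

The standardized docking score of a protein pair compares the top-ranked
pose score against the distribution of the remaining high-ranked decoy
scores: z = (top - decoy_mean) / decoy_sd. The decoy set excludes the top
pose by default (``include_top_in_decoys`` restores the inclusive reading);
the standard deviation uses the n-1 sample denominator.

A toy rigid-body grid-docking engine (surface +1 / core -9 occupancy
correlation over sampled rotations) produces realistic rank-ordered pose
lists without any external docking program. It is a fixture generator, not
a reproduction of any published scoring function.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
from scipy import ndimage, signal

from .errors import DegenerateScoreError, GridSizeError
from .io_formats import Structure, canonical_pair

__all__ = [
    "PoseList",
    "DockZ",
    "DEFAULT_Z_THRESHOLD",
    "dock_z_score",
    "is_interaction",
    "iter_pairs",
    "all_vs_all",
    "toy_dock",
    "score_pose",
]

DEFAULT_Z_THRESHOLD = 8.8


@dataclass
class PoseList:
    """Ranked pose scores for one protein pair; rank 1 first, never re-sorted."""

    scores: Sequence[float]
    pair: tuple[str, str] | None = None
    poses: list[tuple[int, tuple[float, float, float]]] | None = None

    def __post_init__(self):
        self.scores = list(float(s) for s in self.scores)
        if len(self.scores) < 2:
            raise ValueError(f"a pose list needs at least 2 poses, got {len(self.scores)}")
        if self.pair is not None:
            self.pair = canonical_pair(*self.pair)

    @property
    def n_poses(self) -> int:
        return len(self.scores)

    @property
    def top(self) -> float:
        return self.scores[0]


@dataclass(frozen=True)
class DockZ:
    pair: tuple[str, str] | None
    z: float
    top: float
    decoy_mean: float
    decoy_sd: float


def dock_z_score(
    poses: PoseList,
    include_top_in_decoys: bool = False,
    check_sorted: bool = False,
) -> DockZ:
    """Standardize the top pose score against the decoy score distribution.

    Decoys are ranks 2..n by default. Raises on zero decoy variance
    (constant scores) or fewer than 3 poses.
    """
    scores = np.asarray(poses.scores, dtype=float)
    if scores.size < 3:
        raise ValueError(f"need at least 3 poses (top + 2 decoys), got {scores.size}")
    if check_sorted and np.any(np.diff(scores) > 0):
        raise ValueError("pose scores are not in descending rank order")
    top = float(scores[0])
    decoys = scores if include_top_in_decoys else scores[1:]
    mean = float(decoys.mean())
    sd = float(decoys.std(ddof=1))
    if sd == 0.0:
        raise DegenerateScoreError("decoy scores have zero variance; z is undefined")
    return DockZ(pair=poses.pair, z=(top - mean) / sd, top=top, decoy_mean=mean, decoy_sd=sd)


def is_interaction(z: float, threshold: float = DEFAULT_Z_THRESHOLD) -> bool:
    """Interaction decision: z at or above the threshold (inclusive)."""
    return z >= threshold


def iter_pairs(proteins: Sequence[str]) -> Iterator[tuple[str, str]]:
    """All unordered pairs without self-pairs, in lexicographic-combination
    order. Raises on duplicate ids."""
    ids = list(proteins)
    if len(set(ids)) != len(ids):
        dupes = sorted({p for p in ids if ids.count(p) > 1})
        raise ValueError(f"duplicate protein ids: {dupes[:5]}")
    if len(ids) < 2:
        raise ValueError("need at least 2 proteins")
    for a, b in itertools.combinations(ids, 2):
        yield canonical_pair(a, b)


def all_vs_all(proteins: Sequence[str], scorer: Callable[[str, str], "DockZ | float"]):
    """Score every unordered pair: exactly n(n-1)/2 DockZ records.

    ``scorer(a, b)`` may return a DockZ or a bare z value.
    """
    out = []
    for a, b in iter_pairs(proteins):
        res = scorer(a, b)
        if not isinstance(res, DockZ):
            res = DockZ(pair=(a, b), z=float(res), top=float("nan"),
                        decoy_mean=float("nan"), decoy_sd=float("nan"))
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# toy rigid-body grid docking


def _structure_coords(s: Structure) -> np.ndarray:
    pts = np.asarray(s.coords(), dtype=float)
    if pts.size == 0:
        raise ValueError(f"structure {s.id!r} has no atoms")
    return pts


def _snap_origin(coords: np.ndarray, spacing: float, pad: float) -> np.ndarray:
    # Origins snap to a global lattice so a zero translation is on-grid.
    return np.floor((coords.min(axis=0) - pad) / spacing) * spacing


def _occupancy(coords: np.ndarray, origin: np.ndarray, shape, spacing: float,
               atom_radius: float) -> np.ndarray:
    grid = np.zeros(shape, dtype=bool)
    reach = int(np.ceil(atom_radius / spacing))
    offs = np.array(list(itertools.product(range(-reach, reach + 1), repeat=3)))
    centers = (offs * spacing)
    keep = np.sum(centers**2, axis=1) <= (atom_radius + 0.5 * spacing) ** 2
    offs = offs[keep]
    idx = np.round((coords - origin) / spacing).astype(int)
    cells = (idx[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    valid = np.all((cells >= 0) & (cells < np.array(shape)), axis=1)
    cells = cells[valid]
    grid[cells[:, 0], cells[:, 1], cells[:, 2]] = True
    return grid


def _weight_grid(occ: np.ndarray, surface_weight: float, core_weight: float) -> np.ndarray:
    core = ndimage.binary_erosion(occ)
    return np.where(core, core_weight, np.where(occ, surface_weight, 0.0))


def _make_grids(coords: np.ndarray, spacing: float, atom_radius: float, pad: float,
                max_grid_dim: int):
    origin = _snap_origin(coords, spacing, pad)
    extent = coords.max(axis=0) + pad - origin
    shape = tuple(int(np.ceil(e / spacing)) + 1 for e in extent)
    if max(shape) > max_grid_dim:
        raise GridSizeError(
            f"grid {shape} exceeds max dimension {max_grid_dim}; increase "
            f"grid_spacing or max_grid_dim (structure span "
            f"{np.ptp(coords, axis=0).round(1)} A)"
        )
    occ = _occupancy(coords, origin, shape, spacing, atom_radius)
    return origin, occ


def _random_rotations(n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Identity first, then uniform random rotation matrices."""
    rots = [np.eye(3)]
    for _ in range(max(n - 1, 0)):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rots.append(np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]))
    return rots


def toy_dock(
    receptor: Structure,
    ligand: Structure,
    n_rotations: int = 64,
    grid_spacing: float = 1.2,
    n_poses: int = 2000,
    seed: int = 0,
    atom_radius: float = 1.8,
    surface_weight: float = 1.0,
    core_weight: float = -9.0,
    max_grid_dim: int = 96,
) -> PoseList:
    """Exhaustive rigid-body grid docking on an occupancy correlation score.

    Each structure is discretized onto a 3D grid (surface cells +1, core
    cells -9 for the receptor; occupancy 1 for the ligand). For every
    sampled ligand rotation (identity always included, about the ligand
    centroid) all grid translations are scored by correlation; the best
    ``n_poses`` (rotation index, translation, score) are returned in
    descending score order. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rec_coords = _structure_coords(receptor)
    lig_coords = _structure_coords(ligand)
    pad = atom_radius + grid_spacing
    rec_origin, rec_occ = _make_grids(rec_coords, grid_spacing, atom_radius, pad, max_grid_dim)
    rec_w = _weight_grid(rec_occ, surface_weight, core_weight)
    centroid = lig_coords.mean(axis=0)

    candidates = []  # (score, rot_idx, flat_disp) kept small per rotation
    for rot_idx, rot in enumerate(_random_rotations(n_rotations, rng)):
        rotated = (lig_coords - centroid) @ rot.T + centroid
        lig_origin, lig_occ = _make_grids(rotated, grid_spacing, atom_radius, pad, max_grid_dim)
        corr = signal.correlate(rec_w, lig_occ.astype(float), mode="full", method="fft")
        corr = np.round(corr)  # scores are integer cell sums; kill FFT noise
        flat = corr.ravel()
        k = min(n_poses, flat.size)
        top_idx = np.argpartition(-flat, k - 1)[:k]
        lig_shape = np.array(lig_occ.shape)
        for fi in top_idx:
            m = np.array(np.unravel_index(fi, corr.shape))
            shift_cells = m - (lig_shape - 1)
            translation = rec_origin - lig_origin + shift_cells * grid_spacing
            candidates.append((float(flat[fi]), rot_idx, tuple(translation)))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    best = candidates[:n_poses]
    return PoseList(
        scores=[c[0] for c in best],
        pair=(receptor.id, ligand.id),
        poses=[(c[1], c[2]) for c in best],
    )


def score_pose(
    receptor: Structure,
    ligand: Structure,
    grid_spacing: float = 1.2,
    atom_radius: float = 1.8,
    surface_weight: float = 1.0,
    core_weight: float = -9.0,
    max_grid_dim: int = 96,
) -> float:
    """Grid-correlation score of the pose given by the structures' current
    coordinates (the 'planted' pose for pre-assembled fixtures)."""
    rec_coords = _structure_coords(receptor)
    lig_coords = _structure_coords(ligand)
    both = np.vstack([rec_coords, lig_coords])
    pad = atom_radius + grid_spacing
    origin = _snap_origin(both, grid_spacing, pad)
    extent = both.max(axis=0) + pad - origin
    shape = tuple(int(np.ceil(e / grid_spacing)) + 1 for e in extent)
    if max(shape) > max_grid_dim:
        raise GridSizeError(f"grid {shape} exceeds max dimension {max_grid_dim}")
    rec_occ = _occupancy(rec_coords, origin, shape, grid_spacing, atom_radius)
    lig_occ = _occupancy(lig_coords, origin, shape, grid_spacing, atom_radius)
    rec_w = _weight_grid(rec_occ, surface_weight, core_weight)
    return float(np.sum(rec_w * lig_occ))
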