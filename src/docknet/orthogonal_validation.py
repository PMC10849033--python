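"""Independent sanity checks on a predicted interaction network: ortholog
transfer of reference PPIs, subcellular co-localization enrichment, and a
coexpression shift test against random pairs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import canonical_pair

__all__ = [
    "OrthologMap",
    "EnrichmentResult",
    "interolog_predict",
    "winner_takes_all",
    "localization_enrichment",
    "coexpression_shift",
]


@dataclass
class OrthologMap:
    """Rice-protein-to-ortholog map for one reference organism. One protein
    may map to several orthologs (co-orthologs)."""

    organism: str
    pairs: list[tuple[str, str]]  # (rice id, ortholog id)

    def orthologs_of(self, protein: str) -> set[str]:
        return {o for p, o in self.pairs if p == protein}

    def by_protein(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p, o in self.pairs:
            out.setdefault(p, set()).add(o)
        return out


@dataclass(frozen=True)
class EnrichmentResult:
    compartment: str
    k: int  # co-localized interacting pairs
    n: int  # interacting pairs
    K: int  # co-localized pairs in the universe
    N: int  # universe pairs
    p: float  # hypergeometric upper-tail probability


def interolog_predict(
    maps: Sequence[OrthologMap],
    reference_ppis: Mapping[str, Iterable[tuple[str, str]]],
) -> dict[tuple[str, str], set[str]]:
    """Transfer reference PPIs through ortholog maps.

    A pair (r1, r2) is predicted iff in at least one organism some ortholog
    of r1 interacts with some ortholog of r2 in that organism's reference
    set. Returns predicted pairs with their supporting organisms.
    """
    predictions: dict[tuple[str, str], set[str]] = {}
    for omap in maps:
        refs = {canonical_pair(*p) for p in reference_ppis.get(omap.organism, ())}
        if not refs:
            continue
        lookup = omap.by_protein()
        proteins = sorted(lookup)
        for i, r1 in enumerate(proteins):
            for r2 in proteins[i + 1 :]:
                found = any(
                    canonical_pair(o1, o2) in refs
                    for o1 in lookup[r1]
                    for o2 in lookup[r2]
                    if o1 != o2
                )
                if found:
                    predictions.setdefault(canonical_pair(r1, r2), set()).add(omap.organism)
    return predictions


def winner_takes_all(
    assignments: Mapping[str, Mapping[str, float]],
    priority: Sequence[str] | None = None,
) -> dict[str, str]:
    """Single compartment per protein: the highest-scoring one; score ties
    break by the priority list (alphabetical by default)."""
    out = {}
    for protein, scored in assignments.items():
        if not scored:
            raise ValueError(f"protein {protein!r} has no scored compartments")
        best_score = max(scored.values())
        tied = sorted(c for c, s in scored.items() if s == best_score)
        if priority is not None:
            ranked = [c for c in priority if c in tied]
            out[protein] = ranked[0] if ranked else tied[0]
        else:
            out[protein] = tied[0]
    return out


def localization_enrichment(
    edges: Iterable[tuple[str, str]],
    locations: Mapping[str, str],
    compartment: str,
) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of co-localized edges.

    Universe: all unordered pairs over located proteins; a success is a
    pair with both partners in the named compartment;
    p = sum_{i>=k} C(K,i)C(N-K,n-i)/C(N,n).
    """
    proteins = sorted(locations)
    if compartment not in set(locations.values()):
        raise ValueError(f"compartment {compartment!r} absent from the location universe")
    edges = [canonical_pair(*e) for e in edges]
    for a, b in edges:
        if a not in locations or b not in locations:
            raise ValueError(f"edge protein without location: ({a}, {b})")
    m = len(proteins)
    N = m * (m - 1) // 2
    in_comp = {p for p in proteins if locations[p] == compartment}
    c = len(in_comp)
    K = c * (c - 1) // 2
    n = len(edges)
    k = sum(1 for a, b in edges if a in in_comp and b in in_comp)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(compartment=compartment, k=k, n=n, K=K, N=N, p=min(p, 1.0))


def coexpression_shift(
    network_values: Sequence[float],
    random_values: Sequence[float],
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """One-sided rank-sum comparison: are network-pair coexpression values
    shifted above random-pair values?

    Returns (U statistic of the network sample, p). Exact p when both
    samples are small (min(n, m) <= ``exact_max_n``) and tie-free; normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(network_values, dtype=float)
    y = np.asarray(random_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.unique(combined).size == 1:
        # every observation tied: no evidence of shift in either direction
        return x.size * y.size / 2.0, 0.5
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (min(x.size, y.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)
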