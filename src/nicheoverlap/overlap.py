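"""Pianka niche overlap: pairwise index, species means and assemblage mean.

For two species *j*, *k* with resource-utilization proportions
``p_ij``, ``p_ik`` over *n* resource states,

    O_jk = sum_i p_ij p_ik / sqrt(sum_i p_ij^2 * sum_i p_ik^2)

is a symmetric, [0, 1]-bounded, correlation-like measure of how similarly
the two species spread their use over the resource states: 0 for disjoint
supports, 1 when the profiles are proportional.  Because each row is
normalized to proportions, the index is invariant to rescaling any
species' abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CommunityMatrix, SpeciesMetadata, normalize_category


@dataclass(frozen=True)
class UtilizationProfile:
    """A species' resource-use proportion vector (non-negative, sums to 1)."""

    species_id: str
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.ndim != 1:
            raise ValueError("utilization profile must be 1-D")
        if np.any(p < 0):
            raise ValueError("utilization proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile of {self.species_id!r} sums to {p.sum()}, not 1")


@dataclass(frozen=True)
class OverlapResult:
    """Pairwise overlap matrix plus per-species and assemblage means.

    ``O`` is symmetric with unit diagonal; ``O_sp[j]`` is the mean of
    species *j*'s pairwise overlaps with every other species;
    ``mean_overall`` is the mean over the C(S, 2) unordered pairs.
    The diagonal never enters either average.
    """

    label: str
    species_ids: tuple[str, ...]
    O: np.ndarray = field(repr=False)
    O_sp: np.ndarray = field(repr=False)
    mean_overall: float

    def pair(self, a: str, b: str) -> float:
        i, j = self.species_ids.index(a), self.species_ids.index(b)
        return float(self.O[i, j])

    def species_mean(self, a: str) -> float:
        return float(self.O_sp[self.species_ids.index(a)])


def normalize(m: CommunityMatrix) -> list[UtilizationProfile]:
    """Convert abundance rows to utilization proportions (rows sum to 1).

    Species with zero total abundance are excluded beforehand; a zero-sum
    row reaching this point is an error.
    """
    mm = m.drop_empty()
    totals = mm.abundance.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("zero-sum species row; exclude empty species first")
    P = mm.abundance / totals[:, None]
    return [UtilizationProfile(s, P[i]) for i, s in enumerate(mm.species_ids)]


def pianka(pj: UtilizationProfile | np.ndarray, pk: UtilizationProfile | np.ndarray) -> float:
    """Pairwise Pianka overlap of two utilization profiles."""
    a = pj.p if isinstance(pj, UtilizationProfile) else np.asarray(pj, dtype=float)
    b = pk.p if isinstance(pk, UtilizationProfile) else np.asarray(pk, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    sa, sb = np.dot(a, a), np.dot(b, b)
    if sa == 0 or sb == 0:
        raise ValueError("all-zero utilization profile")
    return float(np.dot(a, b) / np.sqrt(sa * sb))


def _overlap_matrix(P: np.ndarray) -> np.ndarray:
    """Full symmetric Pianka matrix from a row-stochastic utilization matrix."""
    ss = np.einsum("ij,ij->i", P, P)
    O = (P @ P.T) / np.sqrt(np.outer(ss, ss))
    np.fill_diagonal(O, 1.0)
    return np.clip(O, 0.0, 1.0)


def overlap_result(m: CommunityMatrix) -> OverlapResult:
    """Pairwise overlap matrix, species means and assemblage mean overlap.

    Species with zero total abundance in this assemblage are excluded
    (their overlap is undefined).
    """
    mm = m.drop_empty()
    S = mm.n_species
    if S < 2:
        raise ValueError("need at least 2 species with positive abundance")
    P = mm.abundance / mm.abundance.sum(axis=1)[:, None]
    O = _overlap_matrix(P)
    off = O[~np.eye(S, dtype=bool)].reshape(S, S - 1)
    O_sp = off.mean(axis=1)
    iu = np.triu_indices(S, k=1)
    return OverlapResult(
        label=mm.label,
        species_ids=mm.species_ids,
        O=O,
        O_sp=O_sp,
        mean_overall=float(O[iu].mean()),
    )


def subset_overlap(m: CommunityMatrix, meta: SpeciesMetadata, category: str) -> OverlapResult:
    """Overlap restricted to one ecological category (e.g. stygobites only).

    Utilization proportions are per-species row proportions, so they are
    unchanged by subsetting; only the set of pairs changes.
    """
    category = normalize_category(category)
    keep = meta.of_category(category, universe=m.drop_empty().species_ids)
    if len(keep) < 2:
        raise ValueError(f"fewer than 2 {category} species present in {m.label!r}")
    return overlap_result(m.subset(keep))
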