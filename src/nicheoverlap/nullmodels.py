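"""RA1-RA4 randomization algorithms and the Monte-Carlo overlap test.

The four classic randomization algorithms for resource-utilization
matrices differ along two axes: whether each species' niche breadth is
retained (its observed utilization values are reshuffled) or relaxed
(values are replaced by uniform random draws), and whether the zero
structure of the matrix — which resources a species did not use at all —
is retained or destroyed:

=====  ==============  ==============
 tag   niche breadth    zero states
=====  ==============  ==============
 RA1    relaxed          destroyed
 RA2    relaxed          retained
 RA3    retained         destroyed
 RA4    retained         retained
=====  ==============  ==============

RA3 (reshuffle each row across all resource states) is the standard
choice for overlap null models; RA2 is its guild-structure-preserving
counterpart.  Randomization operates on the row-proportion (utilization)
scale; RA1/RA2 replacement rows are re-normalized to sum 1, which is
cosmetic because the Pianka index is row-scale-invariant.

The Monte-Carlo test compares the observed mean pairwise overlap with
the distribution of mean overlaps across simulated null assemblages and
reports the upper-tail probability P(observed >= expected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CommunityMatrix, SpeciesMetadata, normalize_category
from .overlap import _overlap_matrix, overlap_result

ALGORITHMS = ("RA1", "RA2", "RA3", "RA4")


@dataclass(frozen=True)
class NullModelResult:
    """Summary of one Monte-Carlo overlap test.

    ``expected_mean`` and ``null_variance`` are the mean and population
    variance of the null ensemble of mean overlaps; ``p_ge`` is the
    proportion of null assemblages whose mean overlap reaches or exceeds
    the observed one.
    """

    label: str
    algorithm: str
    iterations: int
    seed: int
    observed_mean: float
    expected_mean: float
    null_variance: float
    p_ge: float

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "algorithm": self.algorithm,
            "iterations": self.iterations,
            "seed": self.seed,
            "observed_mean": self.observed_mean,
            "expected_mean": self.expected_mean,
            "null_variance": self.null_variance,
            "p_ge": self.p_ge,
        }


def _randomize_rows(P: np.ndarray, algorithm: str, rng: np.random.Generator) -> np.ndarray:
    """Apply one RA algorithm to a row-stochastic utilization matrix."""
    S, n = P.shape
    if algorithm == "RA1":
        Q = rng.random((S, n))
    elif algorithm == "RA2":
        Q = np.where(P > 0, rng.random((S, n)), 0.0)
    elif algorithm == "RA3":
        # independent uniform permutation of each row across all n states
        order = np.argsort(rng.random((S, n)), axis=1)
        Q = np.take_along_axis(P, order, axis=1)
    elif algorithm == "RA4":
        Q = P.copy()
        for i in range(S):
            nz = np.flatnonzero(P[i])
            Q[i, nz] = P[i, rng.permutation(nz)]
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if algorithm in ("RA1", "RA2"):
        Q = Q / Q.sum(axis=1)[:, None]
    return Q


def randomize(
    m: CommunityMatrix, algorithm: str, rng: np.random.Generator | int | None = None
) -> CommunityMatrix:
    """Return one null assemblage drawn from the given RA algorithm.

    The result carries row-proportion (utilization) values rather than raw
    counts; every downstream overlap statistic is unaffected by this
    rescaling.
    """
    rng = np.random.default_rng(rng)
    mm = m.drop_empty()
    P = mm.abundance / mm.abundance.sum(axis=1)[:, None]
    Q = _randomize_rows(P, algorithm, rng)
    return CommunityMatrix(
        label=f"{mm.label}:{algorithm}",
        species_ids=mm.species_ids,
        resource_ids=mm.resource_ids,
        abundance=Q,
    )


def null_test(
    m: CommunityMatrix,
    algorithm: str = "RA3",
    iterations: int = 1000,
    seed: int = 0,
    *,
    add_one: bool = False,
) -> NullModelResult:
    """Monte-Carlo test of mean pairwise overlap against an RA null.

    Parameters
    ----------
    m
        Community matrix (species with zero totals are excluded first).
    algorithm
        One of ``RA1``/``RA2``/``RA3``/``RA4``.
    iterations
        Number of simulated null assemblages (default 1000).
    seed
        Seed for the randomization stream; fixed seed gives bit-identical
        results.
    add_one
        If true, report ``(count + 1) / (iterations + 1)`` instead of the
        raw proportion ``count / iterations`` for the tail probability.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    mm = m.drop_empty()
    obs = overlap_result(mm)
    P = mm.abundance / mm.abundance.sum(axis=1)[:, None]
    S = P.shape[0]
    iu = np.triu_indices(S, k=1)

    # per-iteration substreams from one seed, independent of execution order
    children = np.random.SeedSequence(seed).spawn(iterations)
    null_means = np.empty(iterations)
    for it, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        Q = _randomize_rows(P, algorithm, rng)
        null_means[it] = _overlap_matrix(Q)[iu].mean()

    count = int(np.sum(null_means >= obs.mean_overall))
    p_ge = (count + 1) / (iterations + 1) if add_one else count / iterations
    return NullModelResult(
        label=mm.label,
        algorithm=algorithm,
        iterations=iterations,
        seed=seed,
        observed_mean=obs.mean_overall,
        expected_mean=float(null_means.mean()),
        null_variance=float(null_means.var()),  # population variance (ddof=0)
        p_ge=float(p_ge),
    )


def null_test_subset(
    m: CommunityMatrix,
    meta: SpeciesMetadata,
    category: str,
    algorithm: str = "RA3",
    iterations: int = 1000,
    seed: int = 0,
    *,
    add_one: bool = False,
) -> NullModelResult:
    """Monte-Carlo overlap test on one ecological category only.

    Both the observed mean and the null ensembles are computed on the
    category subset, so the result equals :func:`null_test` run on the
    manually subsetted matrix with the same seed.
    """
    category = normalize_category(category)
    keep = meta.of_category(category, universe=m.drop_empty().species_ids)
    if len(keep) < 2:
        raise ValueError(f"fewer than 2 {category} species present in {m.label!r}")
    return null_test(m.subset(keep), algorithm, iterations, seed, add_one=add_one)
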