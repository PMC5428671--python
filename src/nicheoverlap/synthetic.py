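"""Synthetic spring-community generator.

Emulates the sampling design the analysis targets: ~22 copepod species
(~40% of them stygobites, i.e. obligate groundwater specialists) counted
at 8 spring sites, with strongly overdispersed abundances.  Each
species' spatial utilization profile is a Dirichlet draw whose
concentration (``breadth``) sets how specialised the species is, mixed
with a species-specific site block to impose interspecific segregation;
counts are then allocated multinomially from a negative-binomial total.

Multi-year scenarios keep the species roster fixed and vary segregation
and abundance between years — e.g. decreasing segregation mimics the
post-disturbance spatial redistribution that raises niche overlap and
lowers C-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import CommunityMatrix, SpeciesMetadata, STYGOBITE, NON_STYGOBITE


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic assemblage.

    Parameters
    ----------
    n_species, n_stygobites, n_sites
        Community shape; the first ``n_stygobites`` species are labelled
        stygobites.
    breadth
        Dirichlet concentration of each species' utilization profile;
        small values give specialists concentrated on few sites, large
        values near-uniform generalists.
    segregation
        In [0, 1]: fraction of each species' probability mass forced onto
        its own site block (1 = fully segregated blocks, 0 = none).
    n_blocks
        Number of site blocks species are cycled through; contiguous
        equal splits of the site range by default.  One block shared by
        all species (``n_blocks=1`` with a small ``block_size``) gives an
        aggregated community; many disjoint blocks give segregation.
    block_size
        Sites per block; defaults to an equal split of the site range.
    random_blocks
        Draw each block as a random site subset instead of a contiguous
        range.
    total_abundance
        Mean of the negative-binomial total count per species.
    dispersion
        Negative-binomial shape k (variance = mean + mean^2 / k); small k
        = strong overdispersion.
    seed
        Seed for this assemblage's random stream.
    """

    n_species: int = 22
    n_stygobites: int = 9
    n_sites: int = 8
    breadth: float = 0.5
    segregation: float = 0.5
    n_blocks: int = 2
    block_size: int | None = None
    random_blocks: bool = False
    total_abundance: float = 60.0
    dispersion: float = 1.0
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0 <= self.n_stygobites <= self.n_species):
            raise ValueError("need 0 <= n_stygobites <= n_species")
        if self.breadth <= 0:
            raise ValueError("breadth must be > 0")
        if not (0.0 <= self.segregation <= 1.0):
            raise ValueError("segregation must be in [0, 1]")
        if not (1 <= self.n_blocks <= self.n_sites):
            raise ValueError("need 1 <= n_blocks <= n_sites")
        if self.block_size is not None and not (1 <= self.block_size <= self.n_sites):
            raise ValueError("need 1 <= block_size <= n_sites")
        if self.total_abundance <= 0 or self.dispersion <= 0:
            raise ValueError("total_abundance and dispersion must be > 0")


def _blocks(cfg: SyntheticConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Site index sets, one per block."""
    if cfg.random_blocks:
        size = cfg.block_size or max(1, cfg.n_sites // cfg.n_blocks)
        return [
            rng.choice(cfg.n_sites, size=size, replace=False)
            for _ in range(cfg.n_blocks)
        ]
    if cfg.block_size is not None:
        starts = np.linspace(0, cfg.n_sites - cfg.block_size, cfg.n_blocks).astype(int)
        return [np.arange(s, s + cfg.block_size) for s in starts]
    bounds = np.linspace(0, cfg.n_sites, cfg.n_blocks + 1).astype(int)
    return [np.arange(bounds[b], bounds[b + 1]) for b in range(cfg.n_blocks)]


def generate_matrix(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[CommunityMatrix, SpeciesMetadata]:
    """Draw one synthetic community matrix plus its species metadata."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    blocks = _blocks(cfg, rng)
    counts = np.zeros((cfg.n_species, cfg.n_sites), dtype=float)
    for i in range(cfg.n_species):
        base = rng.dirichlet(np.full(cfg.n_sites, cfg.breadth))
        block = blocks[i % cfg.n_blocks]
        block_p = np.zeros(cfg.n_sites)
        block_p[block] = rng.dirichlet(np.full(len(block), cfg.breadth))
        p = (1.0 - cfg.segregation) * base + cfg.segregation * block_p
        p /= p.sum()
        # NB(mean mu, shape k) parameterized as numpy's (n, p)
        k, mu = cfg.dispersion, cfg.total_abundance
        total = int(rng.negative_binomial(k, k / (k + mu)))
        if total > 0:
            counts[i] = rng.multinomial(total, p)
    width = len(str(cfg.n_species))
    species = tuple(f"sp{i + 1:0{width}d}" for i in range(cfg.n_species))
    meta = SpeciesMetadata(
        {s: (STYGOBITE if i < cfg.n_stygobites else NON_STYGOBITE)
         for i, s in enumerate(species)}
    )
    m = CommunityMatrix(
        label=cfg.label,
        species_ids=species,
        resource_ids=tuple(f"site{j + 1}" for j in range(cfg.n_sites)),
        abundance=counts,
    )
    return m, meta


def generate_scenario(
    configs: dict[str, SyntheticConfig],
    *,
    shared_species: bool = True,
    zero_species: dict[str, tuple[str, ...]] | None = None,
) -> tuple[dict[str, CommunityMatrix], SpeciesMetadata]:
    """Draw a multi-year dataset with a shared species roster.

    ``configs`` maps year label -> per-year configuration; shapes
    (n_species, n_stygobites, n_sites) must agree when
    ``shared_species`` is true.  ``zero_species`` optionally zeroes out
    named species in named years, exercising the all-years-present
    filter downstream.
    """
    if len(configs) < 2:
        raise ValueError("a scenario needs at least 2 years")
    cfgs = list(configs.values())
    if shared_species:
        shapes = {(c.n_species, c.n_stygobites, c.n_sites) for c in cfgs}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent rosters across years: {shapes}")
    matrices: dict[str, CommunityMatrix] = {}
    meta: SpeciesMetadata | None = None
    for yr, cfg in configs.items():
        m, meta_yr = generate_matrix(replace(cfg, label=str(yr)))
        if meta is None:
            meta = meta_yr
        if zero_species and yr in zero_species:
            ab = m.abundance.copy()
            for sp in zero_species[yr]:
                ab[m.species_ids.index(sp)] = 0.0
            m = CommunityMatrix(m.label, m.species_ids, m.resource_ids, ab)
        matrices[yr] = m
    assert meta is not None
    return matrices, meta


def three_year_scenario(
    seed: int = 0,
    *,
    segregations: tuple[float, float, float] = (0.9, 0.7, 0.1),
    total_abundances: tuple[float, float, float] = (45.0, 125.0, 41.0),
    years: tuple[str, str, str] = ("year1", "year2", "year3"),
) -> tuple[dict[str, CommunityMatrix], SpeciesMetadata]:
    """Convenience scenario mirroring the study design.

    Three sampling years over a fixed 22-species roster; segregation
    relaxes in the final (post-disturbance) year, and per-species mean
    abundance follows the observed low / high / low totals.
    """
    ss = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    configs = {
        yr: SyntheticConfig(
            segregation=seg, total_abundance=tot, seed=int(s), label=yr
        )
        for yr, seg, tot, s in zip(years, segregations, total_abundances, ss)
    }
    return generate_scenario(configs)
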