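"""Domain containers and CSV readers for community matrices.

A community matrix records, for one assemblage (typically one sampling
year), how many individuals of each species were collected at each
resource state.  Here a resource state is a discrete spatial unit — a
spring outlet sampled as a "natural sampling unit" — and abundance at a
site is treated as a proxy for the amount of that resource used by the
species.  Species metadata assigns each species an ecological category:
``stygobite`` (obligate groundwater specialist) or ``non_stygobite``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("nicheoverlap")

STYGOBITE = "stygobite"
NON_STYGOBITE = "non_stygobite"
CATEGORIES = (STYGOBITE, NON_STYGOBITE)

#: accepted spellings for the two ecological categories (case-insensitive)
_CATEGORY_ALIASES = {
    "stygobite": STYGOBITE,
    "s": STYGOBITE,
    "non_stygobite": NON_STYGOBITE,
    "non-stygobite": NON_STYGOBITE,
    "nonstygobite": NON_STYGOBITE,
    "n": NON_STYGOBITE,
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class CommunityMatrix:
    """Species x resource-state abundance table for one assemblage.

    Parameters
    ----------
    label
        Assemblage identifier, e.g. a year such as ``"1997"``.
    species_ids
        Ordered, unique species identifiers (rows).
    resource_ids
        Ordered, unique resource-state identifiers (columns; spring sites).
    abundance
        Non-negative, finite abundances, shape ``(n_species, n_resources)``.
    """

    label: str
    species_ids: tuple[str, ...]
    resource_ids: tuple[str, ...]
    abundance: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundance, dtype=float)
        object.__setattr__(self, "abundance", ab)
        object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))
        object.__setattr__(self, "resource_ids", tuple(str(r) for r in self.resource_ids))
        if ab.ndim != 2:
            raise ValidationError("abundance must be a 2-D array")
        if ab.shape != (len(self.species_ids), len(self.resource_ids)):
            raise ValidationError(
                f"abundance shape {ab.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.resource_ids)} resources"
            )
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValidationError("duplicate species identifier")
        if len(set(self.resource_ids)) != len(self.resource_ids):
            raise ValidationError("duplicate resource identifier")
        # subsetting may legitimately leave a single species; readers
        # enforce the >= 2 species / >= 2 resources contract on ingest
        if len(self.species_ids) < 1 or len(self.resource_ids) < 2:
            raise ValidationError("need at least 1 species and 2 resource states")
        if not np.all(np.isfinite(ab)):
            raise ValidationError("non-finite abundance")
        if np.any(ab < 0):
            raise ValidationError("negative abundance")
        empty = [s for s, tot in zip(self.species_ids, ab.sum(axis=1)) if tot == 0]
        if empty:
            logger.warning(
                "%s: species with zero total abundance (excluded from overlap/C-score): %s",
                self.label, ", ".join(empty),
            )

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_resources(self) -> int:
        return len(self.resource_ids)

    def row(self, species_id: str) -> np.ndarray:
        return self.abundance[self.species_ids.index(species_id)]

    def retained_species(self) -> tuple[str, ...]:
        """Species with positive total abundance (usable in overlap/C-score)."""
        totals = self.abundance.sum(axis=1)
        return tuple(s for s, t in zip(self.species_ids, totals) if t > 0)

    def drop_empty(self) -> "CommunityMatrix":
        """Return a matrix restricted to species with positive totals."""
        keep = self.retained_species()
        if keep == self.species_ids:
            return self
        return self.subset(keep)

    def subset(self, species: Iterable[str]) -> "CommunityMatrix":
        species = tuple(species)
        missing = [s for s in species if s not in self.species_ids]
        if missing:
            raise KeyError(f"unknown species: {missing}")
        idx = [self.species_ids.index(s) for s in species]
        return CommunityMatrix(
            label=self.label,
            species_ids=species,
            resource_ids=self.resource_ids,
            abundance=self.abundance[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance, index=list(self.species_ids), columns=list(self.resource_ids)
        )


@dataclass(frozen=True)
class SpeciesMetadata:
    """Mapping species -> ecological category (stygobite / non_stygobite)."""

    category: Mapping[str, str]

    def __post_init__(self) -> None:
        norm = {}
        for sp, cat in self.category.items():
            norm[str(sp)] = normalize_category(cat)
        object.__setattr__(self, "category", norm)

    def __getitem__(self, species_id: str) -> str:
        try:
            return self.category[species_id]
        except KeyError:
            raise KeyError(f"species {species_id!r} missing from metadata") from None

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.category

    def of_category(self, category: str, universe: Iterable[str] | None = None) -> tuple[str, ...]:
        """Species of the given category, optionally restricted (and ordered) by a universe."""
        category = normalize_category(category)
        if universe is None:
            return tuple(s for s, c in self.category.items() if c == category)
        return tuple(s for s in universe if self[s] == category)

    def is_stygobite(self, species_id: str) -> bool:
        return self[species_id] == STYGOBITE


@dataclass(frozen=True)
class PresenceMatrix:
    """Species x sample binary incidence matrix (presence/absence)."""

    label: str
    species_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    incidence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence)
        if not np.isin(inc, (0, 1)).all():
            raise ValidationError("incidence entries must be 0 or 1")
        object.__setattr__(self, "incidence", inc.astype(np.int8))
        object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))

    def row(self, species_id: str) -> np.ndarray:
        try:
            return self.incidence[self.species_ids.index(species_id)]
        except ValueError:
            raise KeyError(f"unknown species {species_id!r}") from None


def normalize_category(token: str) -> str:
    key = str(token).strip().lower().replace(" ", "_")
    try:
        return _CATEGORY_ALIASES[key]
    except KeyError:
        raise ValidationError(
            f"unknown ecological category {token!r}; expected one of {CATEGORIES}"
        ) from None


def read_community_matrix(
    path: str | Path,
    label: str | None = None,
    *,
    long_format: bool = False,
    pool_periods: bool = True,
) -> CommunityMatrix:
    """Read a community matrix from CSV.

    Wide format (default): header row of resource (site) identifiers, first
    column species identifiers, cells numeric abundances.  The first header
    cell is ignored.

    Long format (``long_format=True``): columns ``species, site, period,
    count``.  Temporal replicates are summed per site when
    ``pool_periods`` is true (each site is one resource state); otherwise
    every site x period combination becomes its own resource state, for
    sensitivity analysis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label = label if label is not None else path.stem
    if long_format:
        df = pd.read_csv(path)
        required = {"species", "site", "period", "count"}
        if not required.issubset(df.columns):
            raise ValidationError(f"long-format CSV needs columns {sorted(required)}")
        if pool_periods:
            wide = df.pivot_table(index="species", columns="site", values="count",
                                  aggfunc="sum", fill_value=0)
        else:
            df = df.assign(state=df["site"].astype(str) + ":" + df["period"].astype(str))
            wide = df.pivot_table(index="species", columns="state", values="count",
                                  aggfunc="sum", fill_value=0)
        wide = wide.sort_index()
    else:
        try:
            wide = pd.read_csv(path, index_col=0)
        except ValueError as exc:
            raise ValidationError(f"malformed CSV {path}: {exc}") from exc
        if wide.index.has_duplicates:
            raise ValidationError("duplicate species identifier")
        if wide.columns.has_duplicates:
            raise ValidationError("duplicate resource identifier")
        non_numeric = wide.columns[
            [not pd.api.types.is_numeric_dtype(t) for t in wide.dtypes]
        ]
        if len(non_numeric):
            raise ValidationError(f"non-numeric cells in columns {list(non_numeric)}")
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValidationError("need at least 2 species and 2 resource states")
    return CommunityMatrix(
        label=label,
        species_ids=tuple(wide.index.astype(str)),
        resource_ids=tuple(wide.columns.astype(str)),
        abundance=wide.to_numpy(dtype=float),
    )


def write_community_matrix(m: CommunityMatrix, path: str | Path) -> None:
    """Write a matrix as wide CSV (round-trips bit-exactly for integers)."""
    df = m.to_frame()
    # keep integer formatting when all counts are whole numbers
    if np.all(df.to_numpy() == np.floor(df.to_numpy())):
        df = df.astype(int)
    df.to_csv(Path(path), index_label="species")


def read_species_metadata(path: str | Path) -> SpeciesMetadata:
    """Read a two-column CSV ``species_id,category``.

    Category tokens are case-insensitive; ``stygobite``/``s`` and
    ``non_stygobite``/``non-stygobite``/``n`` are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("metadata CSV needs two columns: species_id, category")
    sp_col, cat_col = df.columns[:2]
    if df[sp_col].duplicated().any():
        dups = df.loc[df[sp_col].duplicated(), sp_col].tolist()
        raise ValidationError(f"duplicate species_id in metadata: {dups}")
    return SpeciesMetadata(dict(zip(df[sp_col].astype(str), df[cat_col].astype(str))))


def write_species_metadata(meta: SpeciesMetadata, path: str | Path) -> None:
    pd.DataFrame(
        {"species_id": list(meta.category), "category": list(meta.category.values())}
    ).to_csv(Path(path), index=False)


def to_presence(m: CommunityMatrix, *, drop_empty: bool = False) -> PresenceMatrix:
    """Threshold abundance > 0 to a presence/absence matrix.

    With ``drop_empty``, species absent everywhere are removed, mirroring
    the overlap-module exclusion of zero-total species.
    """
    mm = m.drop_empty() if drop_empty else m
    return PresenceMatrix(
        label=mm.label,
        species_ids=mm.species_ids,
        sample_ids=mm.resource_ids,
        incidence=(mm.abundance > 0).astype(np.int8),
    )
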