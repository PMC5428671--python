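"""Stone-Roberts C-score as a descriptive segregation statistic.

For a species pair *j*, *k* on a presence/absence matrix, with row totals
``R_j``, ``R_k`` and ``SS`` the number of samples occupied by both,

    C_jk = (R_j - SS)(R_k - SS)

counts the "checkerboard units" formed by the pair: 0 when one species'
sites are nested in the other's (maximal aggregation), ``R_j * R_k`` when
they share no site (maximal segregation).  The matrix-wide score is the
plain average over all unordered pairs and is used here descriptively —
higher values mean stronger spatial segregation — without null-model
significance testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CommunityMatrix, PresenceMatrix, SpeciesMetadata, normalize_category, to_presence


@dataclass(frozen=True)
class CScoreResult:
    label: str
    species_ids: tuple[str, ...]
    pairwise_c: np.ndarray = field(repr=False)
    mean_c: float

    def pair(self, a: str, b: str) -> float:
        i, j = self.species_ids.index(a), self.species_ids.index(b)
        return float(self.pairwise_c[i, j])


def c_score_pair(pm: PresenceMatrix, j: str, k: str) -> float:
    """Checkerboard score (R_j - SS)(R_k - SS) for one species pair."""
    if j == k:
        raise ValueError("C-score needs two distinct species")
    rj, rk = pm.row(j), pm.row(k)
    Rj, Rk = int(rj.sum()), int(rk.sum())
    SS = int((rj & rk).sum())
    return float((Rj - SS) * (Rk - SS))


def matrix_c_score(pm: PresenceMatrix) -> CScoreResult:
    """Pairwise C-score matrix and its mean over all unordered pairs."""
    S = len(pm.species_ids)
    if S < 2:
        raise ValueError("need at least 2 species")
    inc = pm.incidence.astype(np.int64)
    R = inc.sum(axis=1)
    shared = inc @ inc.T  # SS for every pair
    C = (R[:, None] - shared) * (R[None, :] - shared)
    np.fill_diagonal(C, 0)
    iu = np.triu_indices(S, k=1)
    return CScoreResult(
        label=pm.label,
        species_ids=pm.species_ids,
        pairwise_c=C.astype(float),
        mean_c=float(C[iu].mean()),
    )


def community_c_score(
    m: CommunityMatrix,
    meta: SpeciesMetadata | None = None,
    category: str | None = None,
    *,
    drop_empty: bool = True,
) -> CScoreResult:
    """C-score straight from an abundance matrix (presence = abundance > 0).

    Species absent in the assemblage are excluded by default, mirroring
    the overlap module; an empty row would otherwise contribute C = 0
    with every partner.  Optionally restrict to one ecological category.
    """
    mm = m.drop_empty() if drop_empty else m
    if category is not None:
        if meta is None:
            raise ValueError("category filtering requires metadata")
        keep = meta.of_category(normalize_category(category), universe=mm.species_ids)
        if len(keep) < 2:
            raise ValueError(f"fewer than 2 {category} species present in {m.label!r}")
        mm = mm.subset(keep)
    return matrix_c_score(to_presence(mm))
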