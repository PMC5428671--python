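"""Between-year comparison of overlap and C-score values.

Pairwise overlaps (O) or per-species mean overlaps (O_sp) measured in
several years form a repeated-measures design: each species pair (for O)
or species (for O_sp) is a subject measured once per year, with a
between-subjects factor given by the pair type (both stygobites ``ss``,
mixed ``sn``, both non-stygobites ``nn``) or by the species'
specialisation.  The mixed-design ANOVA decomposes variation into a
between-subjects stratum (group effect, tested against subject-within-
group error) and a within-subjects stratum (year effect and year x group
interaction, tested against the residual).  Sums of squares are Type III:
each effect is adjusted for all others in a sum-to-zero-coded cell-means
model, so unequal group sizes test hypotheses about unweighted cell
means.  Greenhouse-Geisser epsilon is computed and reported alongside,
but the headline P values are the uncorrected univariate ones.

Subjects sharing a species are not independent; this known feature of
pairwise-index ANOVAs is documented, not corrected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CommunityMatrix, SpeciesMetadata
from .overlap import OverlapResult, overlap_result, subset_overlap
from .cooccurrence import CScoreResult, community_c_score
from .nullmodels import NullModelResult, null_test, null_test_subset

PAIR_TYPES = ("ss", "sn", "nn")


@dataclass(frozen=True)
class PairRecord:
    """One species pair with its O (or C) value in every compared year."""

    species_a: str
    species_b: str
    pair_type: str
    values: dict[str, float]  # year label -> value


@dataclass(frozen=True)
class SpeciesRecord:
    """One species with its O_sp value in every compared year."""

    species_id: str
    specialisation: str
    values: dict[str, float]


@dataclass(frozen=True)
class AnovaRow:
    effect: str
    ss: float
    df: int
    ms: float
    F: float | None
    p: float | None
    stratum: str  # "between" or "within"


@dataclass(frozen=True)
class AnovaTable:
    rows: tuple[AnovaRow, ...]
    gg_epsilon: float | None = None  # Greenhouse-Geisser sphericity estimate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"effect": r.effect, "SS": r.ss, "df": r.df, "MS": r.ms,
                 "F": r.F, "P": r.p, "stratum": r.stratum}
                for r in self.rows
            ]
        )

    def __getitem__(self, effect: str) -> AnovaRow:
        for r in self.rows:
            if r.effect == effect:
                return r
        raise KeyError(effect)


def classify_pair(a: str, b: str, meta: SpeciesMetadata) -> str:
    """Pair type: ss (both stygobites), nn (neither), sn (mixed); order-free."""
    sa, sb = meta.is_stygobite(a), meta.is_stygobite(b)
    if sa and sb:
        return "ss"
    if not sa and not sb:
        return "nn"
    return "sn"


def build_pair_table(
    results: dict[str, OverlapResult], meta: SpeciesMetadata
) -> list[PairRecord]:
    """Pairwise O values for species pairs present in *all* compared years.

    Species absent (zero total) in any year are excluded, together with
    every pair involving them — the all-years-present filter.  The O
    values themselves come from the per-year full overlap matrices, so a
    pair's partner set within a year is unaffected by the filter.
    """
    if len(results) < 2:
        raise ValueError("need results for at least 2 years")
    common = _common_species(results)
    records = [
        PairRecord(
            species_a=a,
            species_b=b,
            pair_type=classify_pair(a, b, meta),
            values={yr: res.pair(a, b) for yr, res in results.items()},
        )
        for a, b in itertools.combinations(common, 2)
    ]
    return records


def build_species_table(
    results: dict[str, OverlapResult], meta: SpeciesMetadata
) -> list[SpeciesRecord]:
    """O_sp values for species present in all years.

    Each year's O_sp is the species' mean pairwise overlap over *all*
    partners of that year, including partners later dropped by the
    all-years-present filter.
    """
    if len(results) < 2:
        raise ValueError("need results for at least 2 years")
    common = _common_species(results)
    return [
        SpeciesRecord(
            species_id=s,
            specialisation=meta[s],
            values={yr: res.species_mean(s) for yr, res in results.items()},
        )
        for s in common
    ]


def _common_species(results: dict[str, OverlapResult]) -> list[str]:
    years = list(results)
    common = [
        s for s in results[years[0]].species_ids
        if all(s in results[y].species_ids for y in years[1:])
    ]
    return common


def records_to_long(records: list[PairRecord] | list[SpeciesRecord]) -> pd.DataFrame:
    """Long-format frame with columns subject, group, time, value."""
    rows = []
    for rec in records:
        if isinstance(rec, PairRecord):
            subject, group = f"{rec.species_a}|{rec.species_b}", rec.pair_type
        else:
            subject, group = rec.species_id, rec.specialisation
        for yr, v in rec.values.items():
            rows.append({"subject": subject, "group": group, "time": yr, "value": v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed-design repeated-measures ANOVA, Type III SS
# ---------------------------------------------------------------------------

def _sum_code(labels: pd.Series, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: len(levels)-1 columns."""
    X = np.zeros((len(labels), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        X[:, j] = np.where(labels == lev, 1.0, np.where(labels == levels[-1], -1.0, 0.0))
    return X


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def rm_anova(
    data: pd.DataFrame | list,
    *,
    subject: str = "subject",
    within: str = "time",
    between: str | None = "group",
    value: str = "value",
) -> AnovaTable:
    """Mixed-design repeated-measures ANOVA with Type III sums of squares.

    Parameters
    ----------
    data
        Long-format table (or a list of :class:`PairRecord` /
        :class:`SpeciesRecord`, converted via :func:`records_to_long`)
        with one row per subject x within-level measurement.  The design
        must be complete within subjects: every subject measured at every
        level of the within factor.
    between
        Name of the between-subjects factor column, or ``None`` for a
        one-way repeated-measures design.

    Returns
    -------
    AnovaTable
        Between stratum: between-factor effect and subject-within-group
        error.  Within stratum: within effect, interaction (if a between
        factor is present) and residual error.  F for each effect uses
        its stratum's error mean square; P from the F distribution.
        ``gg_epsilon`` is the Greenhouse-Geisser sphericity estimate for
        the within-subject covariance (reported, not applied).
    """
    if not isinstance(data, pd.DataFrame):
        data = records_to_long(data)
    df = data.rename(columns={subject: "subject", within: "time", value: "value"})
    if between is not None:
        df = df.rename(columns={between: "group"})
    times = sorted(df["time"].unique())
    k = len(times)
    wide = df.pivot_table(index="subject", columns="time", values="value")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"subjects missing a within-level measurement: {bad}")
    N = wide.shape[0]

    if between is None:
        group_of = pd.Series("all", index=wide.index)
    else:
        g_map = df.drop_duplicates("subject").set_index("subject")["group"]
        if (df.groupby("subject")["group"].nunique() > 1).any():
            raise ValueError("a subject appears in more than one between-group")
        group_of = g_map.loc[wide.index]
        sizes = group_of.value_counts()
        if (sizes < 2).any():
            small = sizes[sizes < 2].index.tolist()
            raise ValueError(f"between-groups with fewer than 2 subjects: {small}")
    groups = sorted(group_of.unique())
    g = len(groups)

    Y = wide.to_numpy(dtype=float)  # N x k
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = {lev: subj_means[group_of.to_numpy() == lev].mean() for lev in groups}
    gm_per_subj = np.array([group_means[lev] for lev in group_of])

    # error strata, computed directly from cell/subject means
    ss_subj_within = k * float(np.sum((subj_means - gm_per_subj) ** 2))
    df_subj_within = N - g
    cell_means = np.vstack([
        Y[group_of.to_numpy() == lev].mean(axis=0) for lev in groups
    ])  # g x k
    cell_per_obs = np.vstack([cell_means[groups.index(lev)] for lev in group_of])
    resid = Y - cell_per_obs - subj_means[:, None] + gm_per_subj[:, None]
    ss_within_err = float(np.sum(resid ** 2))
    df_within_err = (N - g) * (k - 1)

    # Type III effect SS from sum-to-zero-coded model comparisons
    long = df.sort_values(["subject", "time"])
    y = long["value"].to_numpy(dtype=float)
    ones = np.ones((len(y), 1))
    Xt = _sum_code(long["time"], times)
    blocks: dict[str, np.ndarray] = {"time": Xt}
    if between is not None:
        Xg = _sum_code(long["group"], groups)
        Xi = np.column_stack(
            [Xg[:, a] * Xt[:, b] for a in range(Xg.shape[1]) for b in range(Xt.shape[1])]
        ) if (g > 1 and k > 1) else np.empty((len(y), 0))
        blocks["group"] = Xg
        blocks["interaction"] = Xi

    def model(exclude: str | None) -> np.ndarray:
        cols = [ones] + [X for name, X in blocks.items() if name != exclude]
        return np.column_stack(cols)

    rss_full = _rss(model(None), y)
    ss_effect = {name: _rss(model(name), y) - rss_full for name in blocks}

    def frow(effect, ss, dfe, ms_err, df_err, stratum):
        ms = ss / dfe
        if ms_err > 0:
            F = ms / ms_err
            p = float(stats.f.sf(F, dfe, df_err))
        elif ss == 0:
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
        return AnovaRow(effect, float(ss), dfe, float(ms), float(F), p, stratum)

    ms_subj = ss_subj_within / df_subj_within if df_subj_within else np.nan
    ms_err = ss_within_err / df_within_err if df_within_err else np.nan
    rows: list[AnovaRow] = []
    if between is not None:
        rows.append(frow("group", ss_effect["group"], g - 1, ms_subj, df_subj_within,
                         "between"))
    rows.append(AnovaRow("subject_error", ss_subj_within, df_subj_within,
                         float(ms_subj), None, None, "between"))
    rows.append(frow("time", ss_effect["time"], k - 1, ms_err, df_within_err, "within"))
    if between is not None:
        rows.append(frow("interaction", ss_effect["interaction"], (g - 1) * (k - 1),
                         ms_err, df_within_err, "within"))
    rows.append(AnovaRow("within_error", ss_within_err, df_within_err,
                         float(ms_err), None, None, "within"))

    return AnovaTable(rows=tuple(rows), gg_epsilon=_gg_epsilon(Y, group_of, groups))


def _gg_epsilon(Y: np.ndarray, group_of: pd.Series, groups: list) -> float | None:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    N, k = Y.shape
    if k < 3 or N <= len(groups):
        return None
    pooled = np.zeros((k, k))
    for lev in groups:
        Z = Y[group_of.to_numpy() == lev]
        pooled += (Z - Z.mean(axis=0)).T @ (Z - Z.mean(axis=0))
    pooled /= N - len(groups)
    # double-centre, then Box's epsilon on its eigenvalues
    Cn = np.eye(k) - np.ones((k, k)) / k
    M = Cn @ pooled @ Cn
    lam = np.linalg.eigvalsh(M)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return None
    return float(lam.sum() ** 2 / ((k - 1) * np.sum(lam ** 2)))


# ---------------------------------------------------------------------------
# post-hoc comparisons
# ---------------------------------------------------------------------------

def bonferroni_pairwise(
    data: pd.DataFrame | list,
    *,
    factor: str = "time",
    subject: str = "subject",
    value: str = "value",
) -> list[tuple[str, str, float]]:
    """All-pairs comparisons for one factor, Bonferroni-adjusted.

    For the within factor the comparison is a paired t-test across
    subjects; for a between factor it is a two-sample t-test on subject
    means.  Each raw two-sided P is multiplied by the number of
    comparisons in the family and capped at 1.
    """
    if not isinstance(data, pd.DataFrame):
        data = records_to_long(data)
    levels = sorted(data[factor].unique())
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    per_subject_levels = data.groupby(subject)[factor].nunique()
    paired = (per_subject_levels > 1).any()  # within-subject factor
    comparisons = list(itertools.combinations(levels, 2))
    m = len(comparisons)
    out = []
    for la, lb in comparisons:
        if paired:
            wide = data.pivot_table(index=subject, columns=factor, values=value)
            a, b = wide[la].to_numpy(), wide[lb].to_numpy()
            diff = a - b
            if np.allclose(diff.std(ddof=1), 0):
                p = 1.0 if np.allclose(diff.mean(), 0) else 0.0
            else:
                p = float(stats.ttest_rel(a, b).pvalue)
        else:
            means = data.groupby([subject, factor])[value].mean().reset_index()
            a = means.loc[means[factor] == la, value].to_numpy()
            b = means.loc[means[factor] == lb, value].to_numpy()
            if np.allclose(np.concatenate([a, b]).std(ddof=1), 0):
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b).pvalue)
        out.append((la, lb, min(1.0, p * m)))
    return out


def paired_t(
    records: list[PairRecord] | pd.DataFrame,
    pair_type: str | None,
    year_a: str,
    year_b: str,
) -> tuple[float, int, float]:
    """Paired t-test of one pair-type's O values between two years.

    Returns ``(t, df, p)``; a zero-variance difference vector is reported
    as the degenerate case ``(0.0, n - 1, 1.0)`` when the mean difference
    is also zero, and raises otherwise.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        if pair_type is not None:
            df = df[df["group"] == pair_type]
        wide = df.pivot_table(index="subject", columns="time", values="value")
        a, b = wide[year_a].to_numpy(), wide[year_b].to_numpy()
    else:
        sel = [r for r in records if pair_type is None or r.pair_type == pair_type]
        a = np.array([r.values[year_a] for r in sel])
        b = np.array([r.values[year_b] for r in sel])
    if len(a) < 2:
        raise ValueError("need at least 2 paired observations")
    diff = a - b
    n = len(diff)
    if np.allclose(diff.std(ddof=1), 0):
        if np.allclose(diff.mean(), 0):
            return 0.0, n - 1, 1.0
        raise ValueError("constant nonzero differences: t undefined (infinite)")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), n - 1, float(res.pvalue)


# ---------------------------------------------------------------------------
# abundance bookkeeping
# ---------------------------------------------------------------------------

def abundance_summary(
    matrices: dict[str, CommunityMatrix],
    meta: SpeciesMetadata,
    *,
    n_composite_samples: int | None = None,
) -> dict:
    """Per-year totals, per-sample means and the stygobite share of abundance.

    ``n_composite_samples`` defaults to the number of resource states
    (one composite sample per site); the per-sample mean is the yearly
    total divided by it.  The chi-square tests homogeneity of the
    stygobite vs non-stygobite abundance split across years
    (2 x n_years contingency table, no continuity correction).
    """
    out: dict = {"per_year": {}}
    contingency = []
    for yr, m in matrices.items():
        n_samples = n_composite_samples or m.n_resources
        total = float(m.abundance.sum())
        styg = [s for s in m.species_ids if meta.is_stygobite(s)]
        styg_total = float(m.subset(styg).abundance.sum()) if styg else 0.0
        out["per_year"][yr] = {
            "total": total,
            "mean_per_sample": total / n_samples,
            "stygobite_total": styg_total,
            "stygobite_share": styg_total / total if total else np.nan,
        }
        contingency.append([styg_total, total - styg_total])
    table = np.array(contingency).T
    if len(matrices) >= 2 and (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        out["chi2"] = {"chi2": float(chi2), "df": int(dof), "p": float(p)}
    return out


# ---------------------------------------------------------------------------
# orchestrated multi-year report
# ---------------------------------------------------------------------------

def year_report(
    matrices: dict[str, CommunityMatrix],
    meta: SpeciesMetadata,
    *,
    algorithms: tuple[str, ...] = ("RA2", "RA3"),
    iterations: int = 1000,
    seed: int = 0,
    add_one: bool = False,
) -> dict:
    """Full multi-year analysis bundle.

    Per year: overlap (all species / stygobites / non-stygobites),
    Monte-Carlo null tests for each requested algorithm on the same three
    assemblages, and the matrix-wide C-score.  Across years: the pair
    table and its mixed rANOVA (pair type x year), the species O_sp table
    and its rANOVA (specialisation x year), Bonferroni post-hocs, and
    per-pair-type paired t-tests between consecutive years.

    The result is a plain nested dict, JSON-serializable apart from the
    embedded numpy-backed result objects, which callers can flatten.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 years of matrices")
    years = list(matrices)
    per_year: dict[str, dict] = {}
    overlaps: dict[str, OverlapResult] = {}
    derived_seed = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
    for yi, yr in enumerate(years):
        m = matrices[yr]
        res = overlap_result(m)
        overlaps[yr] = res
        entry: dict = {"overlap": res, "cscore": community_c_score(m)}
        for cat in ("stygobite", "non_stygobite"):
            try:
                entry[f"overlap_{cat}"] = subset_overlap(m, meta, cat)
            except ValueError:
                entry[f"overlap_{cat}"] = None
        entry["null"] = {}
        for ai, alg in enumerate(algorithms):
            s = int((derived_seed + 1000 * yi + ai) % (2**31))
            entry["null"][alg] = {
                "all": null_test(m, alg, iterations, s, add_one=add_one)
            }
            for cat in ("stygobite", "non_stygobite"):
                try:
                    entry["null"][alg][cat] = null_test_subset(
                        m, meta, cat, alg, iterations, s + 1, add_one=add_one
                    )
                except ValueError:
                    entry["null"][alg][cat] = None
        per_year[yr] = entry

    pair_records = build_pair_table(overlaps, meta)
    species_records = build_species_table(overlaps, meta)
    report: dict = {"per_year": per_year, "pair_table": pair_records,
                    "species_table": species_records}
    if pair_records:
        long_pairs = records_to_long(pair_records)
        report["anova_O"] = rm_anova(long_pairs)
        report["posthoc_years_O"] = bonferroni_pairwise(long_pairs, factor="time")
        report["posthoc_pairtype_O"] = bonferroni_pairwise(long_pairs, factor="group")
        report["paired_t"] = {}
        for pt in PAIR_TYPES:
            if sum(r.pair_type == pt for r in pair_records) >= 2:
                for ya, yb in itertools.combinations(sorted(years), 2):
                    report["paired_t"][(pt, ya, yb)] = paired_t(pair_records, pt, ya, yb)
    if len(species_records) >= 4:
        long_sp = records_to_long(species_records)
        if long_sp.groupby("group")["subject"].nunique().ge(2).all():
            report["anova_Osp"] = rm_anova(long_sp)
            report["posthoc_years_Osp"] = bonferroni_pairwise(long_sp, factor="time")
    return report
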