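import itertools

import numpy as np
import pandas as pd
import pytest

from nicheoverlap import (
    CommunityMatrix,
    SpeciesMetadata,
    abundance_summary,
    bonferroni_pairwise,
    build_pair_table,
    build_species_table,
    classify_pair,
    overlap_result,
    paired_t,
    records_to_long,
    rm_anova,
    year_report,
)
from nicheoverlap.comparison import PairRecord
from nicheoverlap.synthetic import three_year_scenario


class TestClassifyPair:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("sp1", "sp2", "ss"), ("sp3", "sp1", "sn"),
         ("sp1", "sp3", "sn"), ("sp3", "sp4", "nn")],
    )
    def test_types_order_free(self, toy_meta, a, b, expected):
        assert classify_pair(a, b, toy_meta) == expected

    def test_missing_species(self, toy_meta):
        with pytest.raises(KeyError, match="missing from metadata"):
            classify_pair("sp1", "ghost", toy_meta)


def matrix_for(abund, label, species=("sp1", "sp2", "sp3", "sp4")):
    return CommunityMatrix(label, species, ("A", "B", "C"), np.array(abund, dtype=float))


class TestBuildPairTable:
    def test_all_years_present_filter(self, toy_meta):
        y1 = matrix_for([[1, 2, 0], [0, 3, 1], [2, 0, 2], [1, 1, 1]], "y1")
        y2 = matrix_for([[1, 2, 0], [0, 3, 1], [2, 0, 2], [0, 0, 0]], "y2")  # sp4 absent
        results = {"y1": overlap_result(y1), "y2": overlap_result(y2)}
        records = build_pair_table(results, toy_meta)
        names = {frozenset((r.species_a, r.species_b)) for r in records}
        assert len(records) == 3  # C(3,2): every sp4 pair dropped
        assert all("sp4" not in fs for fs in names)
        # values come from each year's full overlap matrix
        for r in records:
            assert r.values["y1"] == results["y1"].pair(r.species_a, r.species_b)

    def test_pair_count_with_18_common_species(self):
        rng = np.random.default_rng(1)
        species = tuple(f"s{i:02d}" for i in range(18))
        meta = SpeciesMetadata({s: ("s" if i < 8 else "n") for i, s in enumerate(species)})
        results = {}
        for yr in ("a", "b", "c"):
            ab = rng.integers(1, 20, size=(18, 5)).astype(float)
            results[yr] = overlap_result(
                CommunityMatrix(yr, species, tuple("vwxyz"), ab))
        assert len(build_pair_table(results, meta)) == 153  # C(18,2)

    def test_osp_uses_full_partner_set(self, toy_meta):
        y1 = matrix_for([[1, 2, 0], [0, 3, 1], [2, 0, 2], [1, 1, 1]], "y1")
        y2 = matrix_for([[1, 2, 0], [0, 3, 1], [2, 0, 2], [0, 0, 0]], "y2")
        results = {"y1": overlap_result(y1), "y2": overlap_result(y2)}
        table = build_species_table(results, toy_meta)
        assert [r.species_id for r in table] == ["sp1", "sp2", "sp3"]
        # in y1, sp1's O_sp still averages over sp4 although sp4 is filtered out
        expected = np.mean([results["y1"].pair("sp1", p) for p in ("sp2", "sp3", "sp4")])
        rec = next(r for r in table if r.species_id == "sp1")
        assert rec.values["y1"] == pytest.approx(expected, abs=1e-12)


def brute_force_balanced_decomposition(df):
    """Classical two-way mixed rANOVA SS by explicit sums over cells.

    Valid for balanced designs (equal group sizes), where Type III and
    sequential SS coincide.
    """
    groups = sorted(df["group"].unique())
    times = sorted(df["time"].unique())
    subjects = sorted(df["subject"].unique())
    grand = df["value"].mean()
    k, N = len(times), len(subjects)
    n_per = N // len(groups)
    gmean = {g: df[df.group == g]["value"].mean() for g in groups}
    tmean = {t: df[df.time == t]["value"].mean() for t in times}
    smean = {s: df[df.subject == s]["value"].mean() for s in subjects}
    gt = {(g, t): df[(df.group == g) & (df.time == t)]["value"].mean()
          for g in groups for t in times}
    sg = df.drop_duplicates("subject").set_index("subject")["group"]
    ss_group = n_per * k * sum((gmean[g] - grand) ** 2 for g in groups)
    ss_subj = k * sum((smean[s] - gmean[sg[s]]) ** 2 for s in subjects)
    ss_time = N * sum((tmean[t] - grand) ** 2 for t in times)
    ss_int = n_per * sum(
        (gt[g, t] - gmean[g] - tmean[t] + grand) ** 2 for g in groups for t in times
    )
    ss_err = sum(
        (row.value - gt[sg[row.subject], row.time] - smean[row.subject]
         + gmean[sg[row.subject]]) ** 2
        for row in df.itertuples()
    )
    return ss_group, ss_subj, ss_time, ss_int, ss_err


def balanced_dataset(seed=0, n_per_group=4, group_shift=0.0, time_slopes=(0.0, 0.0, 0.0)):
    rng = np.random.default_rng(seed)
    rows, sid = [], 0
    for gi, g in enumerate(("g1", "g2")):
        for _ in range(n_per_group):
            base = rng.normal(0, 1)
            for t, slope in zip(("t1", "t2", "t3"), time_slopes):
                rows.append({
                    "subject": f"s{sid}", "group": g, "time": t,
                    "value": base + slope + gi * group_shift + rng.normal(0, 0.4),
                })
            sid += 1
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_all_identical_values_zero_ss(self):
        df = balanced_dataset()
        df["value"] = 1.0
        tab = rm_anova(df)
        for eff in ("group", "time", "interaction"):
            assert tab[eff].ss == pytest.approx(0.0, abs=1e-12)

    def test_balanced_matches_brute_force_oracle(self):
        df = balanced_dataset(seed=3, group_shift=0.7, time_slopes=(0, 0.4, 0.9))
        tab = rm_anova(df)
        ssg, sss, sst, ssi, sse = brute_force_balanced_decomposition(df)
        assert tab["group"].ss == pytest.approx(ssg, rel=1e-8)
        assert tab["subject_error"].ss == pytest.approx(sss, rel=1e-8)
        assert tab["time"].ss == pytest.approx(sst, rel=1e-8)
        assert tab["interaction"].ss == pytest.approx(ssi, rel=1e-8)
        assert tab["within_error"].ss == pytest.approx(sse, rel=1e-8)

    def test_balanced_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = balanced_dataset(seed=5, group_shift=0.5, time_slopes=(0, 0.3, 0.8))
        tab = rm_anova(df)
        ref = pg.mixed_anova(data=df, dv="value", within="time",
                             between="group", subject="subject")
        ref = ref.set_index("Source")
        assert tab["group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-8)
        assert tab["time"].F == pytest.approx(ref.loc["time", "F"], rel=1e-8)
        assert tab["interaction"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-8)

    def test_unbalanced_type_iii_matches_R_car(self):
        # frozen oracle: car::Anova(lm(Y ~ group), idesign=~time, type=3) in R 4.3
        # on this exact deterministic dataset
        rng = np.random.default_rng(0)
        rows, sid = [], 0
        for g, n in [("a", 5), ("b", 8), ("c", 3)]:
            for _ in range(n):
                base = rng.normal(0, 1)
                for t, off in [("t1", 0), ("t2", 0.5), ("t3", 1.0)]:
                    rows.append({"subject": f"s{sid}", "group": g, "time": t,
                                 "value": base + off + (0.3 if g == "b" else 0)
                                 + rng.normal(0, 0.5)})
                sid += 1
        tab = rm_anova(pd.DataFrame(rows))
        assert tab["group"].ss == pytest.approx(15.9428, abs=1e-4)
        assert tab["time"].ss == pytest.approx(6.9204, abs=1e-4)
        assert tab["interaction"].ss == pytest.approx(0.3839, abs=1e-4)
        assert tab["subject_error"].ss == pytest.approx(31.916, abs=1e-3)
        assert tab["within_error"].ss == pytest.approx(5.341, abs=1e-3)
        assert tab["subject_error"].df == 13
        assert tab["within_error"].df == 26
        assert tab["group"].F == pytest.approx(3.2469, abs=1e-4)
        assert tab["time"].F == pytest.approx(16.8437, abs=1e-4)
        assert tab["time"].p == pytest.approx(2.033e-05, rel=1e-3)

    def test_stratum_ss_conservation(self):
        df = balanced_dataset(seed=7, group_shift=0.3, time_slopes=(0, 0.2, 0.5))
        tab = rm_anova(df)
        wide = df.pivot_table(index="subject", columns="time", values="value")
        Y = wide.to_numpy()
        between_total = Y.shape[1] * np.sum((Y.mean(axis=1) - Y.mean()) ** 2)
        within_total = np.sum((Y - Y.mean(axis=1)[:, None]) ** 2)
        assert tab["group"].ss + tab["subject_error"].ss == pytest.approx(
            between_total, rel=1e-8)
        assert (tab["time"].ss + tab["interaction"].ss
                + tab["within_error"].ss) == pytest.approx(within_total, rel=1e-8)

    def test_injected_effects_recovered(self):
        df = balanced_dataset(seed=11, n_per_group=20, group_shift=2.0,
                              time_slopes=(0.0, 0.0, 0.0))
        tab = rm_anova(df)
        assert tab["group"].p < 1e-4          # large additive group shift
        assert tab["time"].ss < tab["group"].ss / 10
        assert tab["time"].p > 0.01           # no year effect injected

    def test_subject_missing_a_year(self):
        df = balanced_dataset().iloc[1:]
        with pytest.raises(ValueError, match="missing a within-level"):
            rm_anova(df)

    def test_group_with_single_subject(self):
        df = balanced_dataset()
        df.loc[df.subject == "s0", "group"] = "g3"
        with pytest.raises(ValueError, match="fewer than 2 subjects"):
            rm_anova(df)

    def test_one_way_repeated_measures(self):
        df = balanced_dataset(seed=2, time_slopes=(0, 0.5, 1.0))
        tab = rm_anova(df, between=None)
        assert tab["time"].p < 0.01
        with pytest.raises(KeyError):
            tab["interaction"]


class TestPosthocs:
    def test_bonferroni_multiplies_and_caps(self):
        from scipy import stats
        df = balanced_dataset(seed=13, time_slopes=(0, 0.6, 1.2))
        out = dict(
            ((a, b), p) for a, b, p in bonferroni_pairwise(df, factor="time"))
        wide = df.pivot_table(index="subject", columns="time", values="value")
        raw = stats.ttest_rel(wide["t1"], wide["t2"]).pvalue
        assert out[("t1", "t2")] == pytest.approx(min(1.0, raw * 3), abs=1e-12)
        assert all(0 <= p <= 1 for p in out.values())

    def test_identical_groups_adjusted_one(self):
        df = balanced_dataset(seed=17)
        # same per-subject values in both groups -> zero group difference
        df["value"] = df["subject"].str.replace("s", "").astype(float) % 4
        out = bonferroni_pairwise(df, factor="group")
        assert all(p > 0.5 for *_unused, p in out)

    def test_needs_two_levels(self):
        df = balanced_dataset()
        df["time"] = "t1"
        with pytest.raises(ValueError, match="at least 2 levels"):
            bonferroni_pairwise(df.drop_duplicates(["subject"]), factor="time")


class TestPairedT:
    @staticmethod
    def records(values_a, values_b, pair_type="ss"):
        return [
            PairRecord(f"x{i}", f"y{i}", pair_type, {"y1": a, "y2": b})
            for i, (a, b) in enumerate(zip(values_a, values_b))
        ]

    def test_hand_sized_example_matches_formula(self):
        a, b = [0.2, 0.5, 0.4, 0.9], [0.1, 0.6, 0.2, 0.5]
        t, df, p = paired_t(self.records(a, b), "ss", "y1", "y2")
        d = np.array(a) - np.array(b)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy import stats
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == 3
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), 3), abs=1e-12)

    def test_identical_years_degenerate(self):
        t, df, p = paired_t(self.records([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]),
                            "ss", "y1", "y2")
        assert (t, p) == (0.0, 1.0)

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.3, 0.5, size=12)
        b = a + 0.2 + rng.normal(0, 0.005, size=12)
        _, _, p = paired_t(self.records(a, b), "ss", "y1", "y2")
        assert p < 1e-6


class TestAbundanceSummary:
    def test_totals_means_share_chi2(self, toy_meta):
        y1 = matrix_for([[10, 0, 0], [10, 0, 0], [20, 0, 0], [0, 0, 0]], "y1")
        y2 = matrix_for([[5, 0, 0], [0, 5, 0], [40, 0, 0], [30, 0, 0]], "y2")
        out = abundance_summary({"y1": y1, "y2": y2}, toy_meta,
                                n_composite_samples=4)
        assert out["per_year"]["y1"]["total"] == 40
        assert out["per_year"]["y1"]["mean_per_sample"] == 10.0
        assert out["per_year"]["y1"]["stygobite_share"] == pytest.approx(0.5)
        assert out["per_year"]["y2"]["stygobite_share"] == pytest.approx(10 / 80)
        from scipy import stats
        chi2 = stats.chi2_contingency(
            np.array([[20, 10], [20, 70]]), correction=False)[0]
        assert out["chi2"]["chi2"] == pytest.approx(chi2)
        assert out["chi2"]["df"] == 1


class TestYearReport:
    def test_smoke_all_sections(self):
        matrices, meta = three_year_scenario(seed=19)
        rep = year_report(matrices, meta, iterations=20, seed=3)
        assert set(rep["per_year"]) == set(matrices)
        for entry in rep["per_year"].values():
            assert entry["overlap"].mean_overall >= 0
            assert entry["cscore"].mean_c >= 0
            assert set(entry["null"]) == {"RA2", "RA3"}
        assert rep["pair_table"] and rep["species_table"]
        assert "anova_O" in rep and "anova_Osp" in rep
        assert rep["posthoc_years_O"]

    def test_reproducible_bit_exact(self):
        matrices, meta = three_year_scenario(seed=19)
        r1 = year_report(matrices, meta, iterations=20, seed=3)
        r2 = year_report(matrices, meta, iterations=20, seed=3)
        for yr in matrices:
            assert (r1["per_year"][yr]["null"]["RA3"]["all"]
                    == r2["per_year"][yr]["null"]["RA3"]["all"])
        assert r1["anova_O"].to_frame().equals(r2["anova_O"].to_frame())
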