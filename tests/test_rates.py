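"""Tests for direct age-standardisation and the comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from linkenhance.rates import (
    age_band,
    age_specific_rates,
    build_count_table,
    build_rate_table,
    direct_asr,
    gamma_interval,
    load_standard_population,
    proportion_of_total,
    relative_increase,
    round_half_up,
    site_predicate,
)


def toy_inputs(band_cases, band_py, years=(2010, 2010), sex="female"):
    """Cases and population frames realising given per-band counts/PY."""
    case_rows = []
    for band, n in band_cases.items():
        for i in range(n):
            case_rows.append({
                "person_id": f"T{band}-{i}", "age": band * 5, "sex": sex,
                "diagnosis_year": years[0],
            })
    cases = pd.DataFrame(case_rows, columns=["person_id", "age", "sex", "diagnosis_year"])
    n_years = years[1] - years[0] + 1
    pop = pd.DataFrame(
        [
            {"sex": sex, "age_band": band, "year": y, "group": "aboriginal",
             "persons": py / n_years}
            for band, py in band_py.items()
            for y in range(years[0], years[1] + 1)
        ]
    )
    return cases, pop


class TestAgeSpecific:
    def test_band_of_age_boundaries(self):
        assert age_band(0) == 0 and age_band(4) == 0
        assert age_band(5) == 1
        assert age_band(84) == 16
        assert age_band(85) == 17 and age_band(103) == 17

    def test_simple_rate(self):
        cases, pop = toy_inputs({10: 5}, {10: 100_000})
        table = age_specific_rates(cases, pop, "aboriginal", (2010, 2010))
        assert table.loc[table["age_band"] == 10, "rate"].item() == pytest.approx(5.0)

    def test_two_band_rates_and_zero_band(self):
        cases, pop = toy_inputs({0: 10, 1: 2}, {0: 50_000, 1: 200_000, 2: 1000})
        table = age_specific_rates(cases, pop, "aboriginal", (2010, 2010))
        rates = table.set_index("age_band")["rate"]
        assert rates[0] == pytest.approx(20.0)
        assert rates[1] == pytest.approx(1.0)
        assert rates[2] == 0.0

    def test_case_stratum_missing_from_population_errors(self):
        cases, pop = toy_inputs({3: 1}, {4: 1000})
        with pytest.raises(ValueError, match=r"\[3\]"):
            age_specific_rates(cases, pop, "aboriginal", (2010, 2010))

    def test_person_years_sum_over_diagnosis_years(self):
        cases, pop = toy_inputs({2: 6}, {2: 300_000}, years=(2010, 2012))
        table = age_specific_rates(cases, pop, "aboriginal", (2010, 2012))
        assert table["person_years"].item() == pytest.approx(300_000)
        assert table["rate"].item() == pytest.approx(2.0)


class TestDirectASR:
    def test_homogeneous_rates_give_common_rate(self):
        bands = {b: 40 for b in range(18)}
        pys = {b: 200_000 for b in range(18)}
        cases, pop = toy_inputs(bands, pys)
        std = load_standard_population()
        res = direct_asr(cases, pop, std, "aboriginal", (2010, 2010))
        assert res.asr == pytest.approx(20.0)
        assert res.ci_low <= res.asr <= res.ci_high

    def test_two_band_weighted_sum(self):
        cases, pop = toy_inputs({0: 10, 1: 2}, {0: 50_000, 1: 200_000})
        std = pd.Series({0: 0.6, 1: 0.4}, name="weight")
        res = direct_asr(cases, pop, std, "aboriginal", (2010, 2010))
        assert res.asr == pytest.approx(0.6 * 20.0 + 0.4 * 1.0)

    def test_zero_cases_zero_rate_with_positive_upper_bound(self):
        cases, pop = toy_inputs({}, {0: 10_000, 1: 10_000})
        std = pd.Series({0: 0.5, 1: 0.5})
        res = direct_asr(cases, pop, std, "aboriginal", (2010, 2010))
        assert res.asr == 0.0 and res.ci_low == 0.0 and res.ci_high > 0.0

    def test_empty_population_errors(self):
        cases, pop = toy_inputs({0: 1}, {0: 1000})
        std = pd.Series({0: 1.0})
        with pytest.raises(ValueError, match="no strata"):
            direct_asr(cases, pop[0:0], std, "aboriginal", (2010, 2010))

    def test_gamma_interval_matches_independent_formulation(self):
        """Dobson limits recomputed via gamma quantiles, not chi-square."""
        x = np.array([3.0, 0.0, 7.0, 1.0])
        py = np.array([40_000.0, 55_000.0, 30_000.0, 80_000.0])
        w = np.array([0.3, 0.2, 0.4, 0.1])
        lo, hi = gamma_interval(x, py, w)

        per_case = w / py * 1e5
        asr = (per_case * x).sum()
        var = (per_case**2 * x).sum()
        d = x.sum()
        # exact Poisson limits through the gamma distribution
        d_lo = stats.gamma.ppf(0.025, a=d)
        d_hi = stats.gamma.ppf(0.975, a=d + 1)
        factor = np.sqrt(var / d)
        assert lo == pytest.approx(asr + factor * (d_lo - d), abs=1e-9)
        assert hi == pytest.approx(asr + factor * (d_hi - d), abs=1e-9)

    def test_unknown_ci_method_rejected(self):
        cases, pop = toy_inputs({0: 1}, {0: 1000})
        with pytest.raises(ValueError, match="bootstrap"):
            direct_asr(cases, pop, pd.Series({0: 1.0}), "aboriginal",
                       (2010, 2010), ci_method="bootstrap")


class TestComparisonStats:
    @pytest.mark.parametrize("base,enhanced,dp,expected", [
        (1329, 1920, 1, 44.5),
        (126.1, 205.2, 1, 62.7),
        (100, 100, 1, 0.0),
        (559.9, 918.0, 1, 64.0),
    ])
    def test_relative_increase(self, base, enhanced, dp, expected):
        assert relative_increase(base, enhanced, dp).pct_increase == expected

    def test_relative_increase_zero_base_is_flagged_undefined(self):
        res = relative_increase(0, 5)
        assert not res.defined and res.pct_increase is None

    @pytest.mark.parametrize("part,total,dp,expected", [
        (2703, 204948, 1, 1.3),
        (651, 877, 0, 74.0),
        (0, 10, 1, 0.0),
    ])
    def test_proportion_of_total(self, part, total, dp, expected):
        assert proportion_of_total(part, total, dp) == expected

    def test_proportion_errors(self):
        with pytest.raises(ValueError):
            proportion_of_total(1, 0)
        with pytest.raises(ValueError):
            proportion_of_total(5, 4)

    def test_round_half_up_ties_go_up(self):
        assert round_half_up(2.25, 1) == 2.3
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(44.45, 1) == 44.5


class TestSitePredicate:
    def test_range_expansion(self):
        pred = site_predicate("C18-C20")
        codes = pd.Series(["C18", "C19.1", "C20", "C21", "C50"])
        assert pred(codes).tolist() == [True, True, True, False, False]

    def test_single_code(self):
        assert site_predicate("C50")(pd.Series(["c50.9"])).all()

    def test_unparseable_code_errors(self):
        with pytest.raises(ValueError, match="unparseable"):
            site_predicate("breast")


class TestTables:
    def test_count_table_partition_and_recount(self, small_cohort, small_statuses):
        cases = small_cohort.cases
        by_sex = build_count_table(cases, small_statuses, "sex")
        # column sums over a partitioning stratifier equal overall totals
        overall = build_count_table(
            cases.assign(all="all"), small_statuses, "all"
        ).iloc[0]
        for col in ("total_cases", "base_n", "ever_n", "weight_of_evidence_n"):
            assert by_sex[col].sum() == overall[col]
        # independent recount of one cell
        woe = small_statuses.set_index("person_id")["weight_of_evidence_status"]
        females = cases[cases["sex"] == "female"]
        expected = (females["person_id"].map(woe) == "aboriginal").sum()
        got = by_sex.set_index("stratum").loc["female", "weight_of_evidence_n"]
        assert got == expected

    def test_count_table_unknown_stratifier_lists_valid_names(self, small_cohort, small_statuses):
        with pytest.raises(ValueError, match="sex"):
            build_count_table(small_cohort.cases, small_statuses, "postcode")

    def test_rate_table_no_changes_means_zero_increase(self, small_cohort):
        cases = small_cohort.cases
        persons = cases[["person_id", "nswcr_status"]].drop_duplicates("person_id")
        # statuses identical to base for every method
        frozen = pd.DataFrame({"person_id": persons["person_id"]})
        base = persons["nswcr_status"].map(
            lambda s: "aboriginal" if s == "aboriginal" else "non_aboriginal"
        )
        frozen["base_status"] = base.values
        for m in ("ever", "most_recent", "weight_of_evidence", "multi_stage_median"):
            frozen[f"{m}_status"] = base.values
        std = load_standard_population()
        table = build_rate_table(cases, frozen, small_cohort.population, std, (2010, 2014))
        for m in ("ever", "most_recent", "weight_of_evidence", "multi_stage_median"):
            with_base = table.dropna(subset=[f"{m}_increase_pct"])
            assert (with_base[f"{m}_increase_pct"] == 0.0).all()
            assert (table[f"{m}_asr"] == table["base_asr"]).all()

    def test_rate_table_enhancement_never_lowers_aboriginal_asr(self, small_cohort, small_statuses):
        std = load_standard_population()
        table = build_rate_table(
            small_cohort.cases, small_statuses, small_cohort.population, std, (2010, 2014)
        )
        for m in ("ever", "most_recent", "weight_of_evidence", "multi_stage_median"):
            assert (table[f"{m}_asr"] >= table["base_asr"]).all()

    def test_rate_table_asr_matches_recomputation(self, small_cohort, small_statuses):
        """All-cancers ASR recomputed independently from age-specific rates."""
        std = load_standard_population()
        table = build_rate_table(
            small_cohort.cases, small_statuses, small_cohort.population, std, (2010, 2014)
        )
        cases = small_cohort.cases
        woe = small_statuses.set_index("person_id")["weight_of_evidence_status"]
        ab_cases = cases[cases["person_id"].map(woe) == "aboriginal"]
        spec = age_specific_rates(ab_cases, small_cohort.population, "aboriginal", (2010, 2014))
        w = std.reindex(spec["age_band"]).to_numpy()
        w = w / w.sum()
        expected = float((w * spec["rate"].to_numpy()).sum())
        got = table.set_index(["site", "cohort"]).loc[
            ("all_cancers", "persons"), "weight_of_evidence_asr"
        ]
        assert got == pytest.approx(round_half_up(expected, 1), abs=1e-9)
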