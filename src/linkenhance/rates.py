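"""Direct age-standardisation and the comparison statistics.

Age-specific incidence rates are computed over 18 five-year age bands
(0–4 … 80–84, 85+) as cases per 100,000 person-years, where person-years
are the stratum population summed over the diagnosis years.  The
directly age-standardised rate (ASR) weights those band rates by a fixed
standard population (default: the 2001 Australian standard population,
total 19,413,240 persons, packaged as a CSV).

The 95% confidence interval uses the gamma method of Dobson et al. for
directly standardised rates — exact Poisson limits on the total count,
rescaled by the ratio of the ASR's standard error to that of the count —
which behaves well at the small case counts typical of Indigenous-status
strata.  A normal approximation is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .statuses import Status

logger = logging.getLogger(__name__)

__all__ = [
    "N_AGE_BANDS",
    "AGE_BAND_LABELS",
    "age_band",
    "load_standard_population",
    "round_half_up",
    "RateResult",
    "IncreaseResult",
    "age_specific_rates",
    "direct_asr",
    "gamma_interval",
    "normal_interval",
    "relative_increase",
    "proportion_of_total",
    "site_predicate",
    "build_count_table",
    "build_rate_table",
]

N_AGE_BANDS = 18
AGE_BAND_LABELS = [f"{5 * i}-{5 * i + 4}" for i in range(17)] + ["85+"]


def age_band(age) -> int | np.ndarray:
    """Five-year age-band index (0–17; 85 and over pools into band 17)."""
    idx = np.floor_divide(np.asarray(age), 5)
    out = np.minimum(idx, N_AGE_BANDS - 1).astype(int)
    return out if out.ndim else int(out)


def load_standard_population(source: str | None = None) -> pd.Series:
    """Standard-population weights by age band, normalised to sum to 1.

    ``source`` is a CSV path with columns age_band,persons (or weight);
    None loads the packaged 2001 Australian standard population.
    """
    if source is None:
        ref = resources.files("linkenhance.data") / "aus_standard_population_2001.csv"
        with resources.as_file(ref) as path:
            table = pd.read_csv(path)
    else:
        table = pd.read_csv(source)
    col = "persons" if "persons" in table.columns else "weight"
    weights = table.set_index("age_band")[col].astype(float)
    if (weights <= 0).any():
        raise ValueError("standard population weights must be positive")
    weights = weights / weights.sum()
    weights.name = "weight"
    return weights


def round_half_up(x: float, dp: int = 1) -> float:
    """Round with ties away from zero at dp decimals (registry convention)."""
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RateResult:
    """A directly age-standardised rate per 100,000 with its 95% CI."""

    asr: float
    ci_low: float
    ci_high: float
    cases: int
    person_years: float
    label: str = ""

    def __post_init__(self):
        if not (self.ci_low <= self.asr <= self.ci_high):
            raise ValueError("confidence interval must bracket the rate")


@dataclass(frozen=True)
class IncreaseResult:
    """Relative change of an enhanced count or rate over its base value."""

    base_value: float
    enhanced_value: float
    pct_increase: float | None  # None when the base is zero

    @property
    def defined(self) -> bool:
        return self.pct_increase is not None


def _person_years(
    population: pd.DataFrame,
    group: str,
    years: tuple[int, int],
    sex: str | None,
) -> pd.Series:
    """Person-years by age band: stratum counts summed over the years."""
    mask = (
        (population["group"] == group)
        & population["year"].between(years[0], years[1])
    )
    if sex is not None:
        mask &= population["sex"] == sex
    py = population.loc[mask].groupby("age_band")["persons"].sum().astype(float)
    return py


def age_specific_rates(
    cases: pd.DataFrame,
    population: pd.DataFrame,
    group: str,
    years: tuple[int, int],
    sex: str | None = None,
) -> pd.DataFrame:
    """Cases, person-years and rate per 100,000 for each age band.

    ``cases`` must already be filtered to the numerator group; its
    ``age`` column is banded here.  Bands present in the population but
    without cases get rate 0; a band with cases but no person-years is a
    coverage error and is reported as such.
    """
    cs = cases if sex is None else cases[cases["sex"] == sex]
    counts = (
        pd.Series(age_band(cs["age"].to_numpy()), name="age_band")
        .value_counts()
        .sort_index()
        if len(cs)
        else pd.Series(dtype=int)
    )
    py = _person_years(population, group, years, sex)
    if py.empty:
        raise ValueError(f"population table has no strata for group {group!r}")
    missing = sorted(set(counts.index) - set(py[py > 0].index))
    if missing:
        raise ValueError(
            "case strata missing from population table (group "
            f"{group!r}, age bands {missing})"
        )
    out = pd.DataFrame({"person_years": py})
    out["cases"] = counts.reindex(py.index, fill_value=0)
    out["rate"] = out["cases"] / out["person_years"] * 1e5
    return out.reset_index().rename(columns={"index": "age_band"})


def gamma_interval(
    band_cases: np.ndarray, band_py: np.ndarray, weights: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """Dobson et al. gamma interval for a directly standardised rate.

    Exact Poisson limits on the total case count, shifted and scaled by
    sqrt(var(ASR)/var(count)).  With zero cases the lower limit is 0 and
    the upper limit uses the largest per-case weight, the conventional
    conservative choice.
    """
    x = np.asarray(band_cases, dtype=float)
    per_case = weights / band_py * 1e5  # contribution of one case in each band
    asr = float(np.sum(per_case * x))
    var = float(np.sum(per_case**2 * x))
    total = float(x.sum())
    if total == 0:
        upper_count = stats.chi2.ppf(1 - alpha / 2, 2) / 2.0
        return 0.0, float(np.max(per_case) * upper_count)
    lo_count = stats.chi2.ppf(alpha / 2, 2 * total) / 2.0
    hi_count = stats.chi2.ppf(1 - alpha / 2, 2 * total + 2) / 2.0
    scale = np.sqrt(var / total)
    return asr + scale * (lo_count - total), asr + scale * (hi_count - total)


def normal_interval(
    band_cases: np.ndarray, band_py: np.ndarray, weights: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """Normal-approximation interval for the ASR (non-negative lower bound)."""
    x = np.asarray(band_cases, dtype=float)
    per_case = weights / band_py * 1e5
    asr = float(np.sum(per_case * x))
    se = float(np.sqrt(np.sum(per_case**2 * x)))
    z = stats.norm.ppf(1 - alpha / 2)
    return max(0.0, asr - z * se), asr + z * se


_CI_METHODS = {"gamma": gamma_interval, "normal": normal_interval}


def direct_asr(
    cases: pd.DataFrame,
    population: pd.DataFrame,
    standard: pd.Series,
    group: str,
    years: tuple[int, int],
    sex: str | None = None,
    ci_method: str = "gamma",
    label: str = "",
) -> RateResult:
    """Directly age-standardised rate per 100,000 with 95% CI.

    ``cases`` must already be the numerator set for ``group``.  Standard
    weights are renormalised over the bands present in the population
    table (a warning is logged when any are dropped).
    """
    table = age_specific_rates(cases, population, group, years, sex=sex)
    w = standard.reindex(table["age_band"])
    if w.isna().any():
        raise ValueError("standard population missing weights for some age bands")
    if len(table) < N_AGE_BANDS:
        logger.warning(
            "population table covers %d/%d age bands; standard weights renormalised",
            len(table),
            N_AGE_BANDS,
        )
    w = (w / w.sum()).to_numpy()
    x = table["cases"].to_numpy(dtype=float)
    py = table["person_years"].to_numpy(dtype=float)
    asr = float(np.sum(w * x / py * 1e5))
    try:
        interval = _CI_METHODS[ci_method]
    except KeyError:
        raise ValueError(
            f"unknown ci_method {ci_method!r}; expected one of {sorted(_CI_METHODS)}"
        ) from None
    lo, hi = interval(x, py, w)
    return RateResult(
        asr=asr,
        ci_low=float(lo),
        ci_high=float(hi),
        cases=int(x.sum()),
        person_years=float(py.sum()),
        label=label,
    )


def relative_increase(base, enhanced, round_dp: int = 1) -> IncreaseResult:
    """Percent increase of an enhanced value over the base, half-up rounded.

    A non-positive base leaves the percentage undefined (flagged as
    ``None``) rather than raising: zero-count strata are routine.
    """
    if base <= 0:
        return IncreaseResult(float(base), float(enhanced), None)
    pct = round_half_up(100.0 * (enhanced - base) / base, round_dp)
    return IncreaseResult(float(base), float(enhanced), pct)


def proportion_of_total(part, total, round_dp: int = 1) -> float:
    """Percentage a part makes of its total, half-up rounded."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= part <= total:
        raise ValueError("part must lie between 0 and total")
    return round_half_up(100.0 * part / total, round_dp)


def site_predicate(code_spec: str):
    """Turn an ICD-10 site expression like 'C50' or 'C18-C20' into a filter.

    Matches on the three-character category of the diagnosis code.
    Returns a vectorised predicate over a Series of codes.
    """
    import re

    categories: set[str] = set()
    for part in str(code_spec).split(","):
        part = part.strip().upper()
        m = re.fullmatch(r"([A-Z])(\d{2})(?:\s*-\s*([A-Z])(\d{2}))?", part)
        if not m:
            raise ValueError(f"unparseable site code: {part!r}")
        letter, lo, letter2, hi = m.group(1), int(m.group(2)), m.group(3), m.group(4)
        if letter2 is None:
            categories.add(f"{letter}{lo:02d}")
        else:
            if letter2 != letter or int(hi) < lo:
                raise ValueError(f"unparseable site code range: {part!r}")
            categories.update(f"{letter}{i:02d}" for i in range(lo, int(hi) + 1))

    def predicate(codes: pd.Series) -> pd.Series:
        return codes.astype(str).str.upper().str[:3].isin(categories)

    return predicate


#: Reported sites: label -> (ICD-10 expression, sex restriction or None)
DEFAULT_SITES: dict[str, tuple[str | None, str | None]] = {
    "all_cancers": (None, None),
    "colorectal": ("C18-C20", None),
    "lung": ("C34", None),
    "melanoma": ("C43", None),
    "breast": ("C50", "female"),
    "cervix": ("C53", "female"),
    "prostate": ("C61", "male"),
}


def _status_lookup(statuses: pd.DataFrame, column: str) -> pd.Series:
    return statuses.set_index("person_id")[column]


def _aboriginal_mask(cases: pd.DataFrame, statuses: pd.DataFrame, column: str) -> pd.Series:
    """Person-level Aboriginal flag mapped onto the case rows."""
    flags = _status_lookup(statuses, column) == Status.ABORIGINAL.value
    mapped = cases["person_id"].map(flags)
    if mapped.isna().any():
        missing = cases.loc[mapped.isna(), "person_id"].unique()[:5]
        raise ValueError(f"cases with no status assignment, e.g. {list(missing)}")
    return mapped.astype(bool)


def build_count_table(
    cases: pd.DataFrame,
    statuses: pd.DataFrame,
    stratifier: str,
    methods: tuple[str, ...] = ("ever", "most_recent", "weight_of_evidence", "multi_stage_median"),
    round_dp: int = 1,
) -> pd.DataFrame:
    """Counts of Aboriginal cases by stratum: registry vs each method.

    One row per level of ``stratifier`` (a column of ``cases``), with
    the registry (base) count, each method's count, its percentage of
    all cases in the stratum, and the relative increase over the base.
    """
    if stratifier not in cases.columns:
        valid = sorted(c for c in cases.columns if cases[c].dtype == object or c in ("diagnosis_year",))
        raise ValueError(f"unknown stratifier {stratifier!r}; valid names: {valid}")
    work = cases[["person_id", stratifier]].copy()
    work["base"] = _aboriginal_mask(cases, statuses, "base_status")
    for m in methods:
        work[m] = _aboriginal_mask(cases, statuses, f"{m}_status")

    rows = []
    for level, g in work.groupby(stratifier, sort=True, observed=True):
        row: dict = {"stratum": level, "total_cases": len(g), "base_n": int(g["base"].sum())}
        row["base_pct"] = proportion_of_total(row["base_n"], row["total_cases"], round_dp)
        for m in methods:
            n = int(g[m].sum())
            row[f"{m}_n"] = n
            row[f"{m}_pct"] = proportion_of_total(n, row["total_cases"], round_dp)
            row[f"{m}_increase_pct"] = relative_increase(row["base_n"], n, round_dp).pct_increase
        rows.append(row)
    return pd.DataFrame(rows)


def build_rate_table(
    cases: pd.DataFrame,
    statuses: pd.DataFrame,
    population: pd.DataFrame,
    standard: pd.Series,
    years: tuple[int, int],
    sites: dict[str, tuple[str | None, str | None]] | None = None,
    methods: tuple[str, ...] = ("ever", "most_recent", "weight_of_evidence", "multi_stage_median"),
    ci_method: str = "gamma",
    round_dp: int = 1,
) -> pd.DataFrame:
    """ASRs by site and sex: non-Aboriginal, registry Aboriginal, enhanced.

    The non-Aboriginal comparison rate uses the registry variable only
    (unknown folded to non-Aboriginal).  Aboriginal denominators are held
    fixed across methods — enhancement changes numerators only.
    """
    sites = DEFAULT_SITES if sites is None else sites
    base_ab = _aboriginal_mask(cases, statuses, "base_status")
    method_ab = {m: _aboriginal_mask(cases, statuses, f"{m}_status") for m in methods}

    rows = []
    for site_label, (code_spec, sex_restriction) in sites.items():
        in_site = (
            pd.Series(True, index=cases.index)
            if code_spec is None
            else site_predicate(code_spec)(cases["site_code"])
        )
        sexes = [sex_restriction] if sex_restriction else [None, "female", "male"]
        for sex in sexes:
            row: dict = {"site": site_label, "cohort": sex or "persons"}

            def asr_of(mask: pd.Series, group: str) -> RateResult:
                return direct_asr(
                    cases[in_site & mask], population, standard, group,
                    years, sex=sex, ci_method=ci_method,
                )

            non_ab = asr_of(~base_ab, "non_aboriginal")
            base = asr_of(base_ab, "aboriginal")
            row["non_aboriginal_asr"] = round_half_up(non_ab.asr, round_dp)
            row["non_aboriginal_ci_low"] = round_half_up(non_ab.ci_low, round_dp)
            row["non_aboriginal_ci_high"] = round_half_up(non_ab.ci_high, round_dp)
            row["base_asr"] = round_half_up(base.asr, round_dp)
            row["base_ci_low"] = round_half_up(base.ci_low, round_dp)
            row["base_ci_high"] = round_half_up(base.ci_high, round_dp)
            row["base_cases"] = base.cases
            for m in methods:
                res = asr_of(method_ab[m], "aboriginal")
                row[f"{m}_asr"] = round_half_up(res.asr, round_dp)
                row[f"{m}_ci_low"] = round_half_up(res.ci_low, round_dp)
                row[f"{m}_ci_high"] = round_half_up(res.ci_high, round_dp)
                row[f"{m}_cases"] = res.cases
                row[f"{m}_increase_pct"] = relative_increase(
                    base.asr, res.asr, round_dp
                ).pct_increase
            rows.append(row)
    return pd.DataFrame(rows)
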