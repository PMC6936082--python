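# Methods

## The resolution problem

A person linked across a cancer registry (NSWCR), hospital admissions
(APDC), emergency presentations (EDDC) and death registrations (COD URF)
carries several observations of a three-valued Indigenous-status field
(Aboriginal / non-Aboriginal / unknown). The registry's own field is
assigned at person level and under-records Aboriginal people; the task
is to resolve the conflicting observations into one enhanced
person-level status and quantify the effect on case counts and
age-standardised incidence rates.

## Units of information and precedence

A **unit of information** is one record with a known (non-unknown)
status. The source methodology never defines the term precisely; this
package counts per record, following the multi-source enhancement
literature, which also makes per-record misrecording in the simulator
meaningful. Units come from APDC, EDDC and COD URF only: the registry
is the variable being corrected, and counting it as evidence would
double-count the quantity under evaluation (configurable via
`unit_sources`). Units are ordered by date, same-date ties by the fixed
source order APDC < EDDC < COD URF, then input order.

Before any algorithm runs: a person Aboriginal on the registry keeps
that status (only records marked non-Aboriginal or unknown are eligible
for change — the exercise corrects under-recording, not over-recording),
and a person Aboriginal on any death record is accepted as Aboriginal
(next-of-kin report, low false-positive risk). Consequently every
method's Aboriginal set contains the registry's, and `changed` is only
ever a move *to* Aboriginal, decomposed by `change_origin` into
from-non-Aboriginal vs from-unknown.

Rule details the source description leaves open, decided here and
covered by tests:

- **most-recent** skips unknown-status records (an unknown cannot
  "report" anyone Aboriginal) and resolves same-date ties to Aboriginal
  if any tied unit is Aboriginal — consistent with the registry's
  positive-identification stance.
- **weight of evidence** with zero units keeps the base status (the
  rule is silent at *n* = 0).
- **multi-stage median** stage-2 units are unweighted, one per source
  with ≥ 1 unit, regardless of how many records the source holds.
- Unknown final statuses are folded into non-Aboriginal at reporting
  time; the pre-fold base status is preserved for the change-origin
  decomposition.

These four rules satisfy provable structure used as test oracles:
ever-reported's Aboriginal set is a superset of every other method's;
with ≤ 2 units WoE ≡ ever-reported; with a single contributing source
MSM ≡ WoE; appending an Aboriginal unit never flips any method away
from Aboriginal. All four are checked exhaustively against
independently coded truth-table evaluators over every unit sequence of
length ≤ 6 across the three sources.

## Rates

Age-specific rates use 18 five-year bands (0–4 … 80–84, 85+);
person-years are stratum populations summed over the diagnosis years
(no mid-year interpolation). The ASR is the standard-population-
weighted sum of band rates, default weights from the 2001 Australian
standard population (total 19,413,240), packaged as CSV. Weights are
renormalised over the bands present in the population table, with a
logged warning when bands are missing.

The 95% CI uses the gamma method of Dobson et al.: exact chi-square
Poisson limits on the total count D, mapped through
ASR ± sqrt(Var(ASR)/D)·(limit − D). It is exact at zero counts (lower
limit 0; the upper limit uses the largest per-case weight) and
well-behaved at the small counts typical of Aboriginal-status strata.
A normal approximation is available (`ci_method="normal"`). Empirical
coverage is verified at 93–97% over 1000 seeded Poisson replicates.

Percentages and rates round half-up, 1 decimal in tables and 0 decimals
for summary-style statements (configurable). Relative increase is
100·(enhanced − base)/base, flagged undefined (not zero, not an error)
when the base is 0. Each cancer case counts once; a person's status is
shared across their cases. Denominators are never enhanced: the
Aboriginal population table is held fixed across methods, reproducing
the numerator-only design — and hence the numerator–denominator bias
that design carries (see Limitations).

## The synthetic cohort

Real linked registry data are restricted, so the simulator generates
the structure the analysis needs:

- a latent true status per person, Bernoulli(prevalence_true = 0.03 by
  default, near the NSW Aboriginal population share);
- per-source record counts: Poisson with configured mean for APDC (3.0)
  and EDDC (2.0); at most one registry status and one death record per
  person (death record only for simulated decedents,
  death_probability = 0.2);
- per-record misrecording, independent across records so within-person
  inconsistency — the signal the methods exploit — arises naturally:
  with probability unknown_rate the record is unknown; otherwise a truly
  Aboriginal person is marked Aboriginal with the source's sensitivity,
  a non-Aboriginal person with its false-positive rate;
- record dates uniform within each source's coverage window (APDC
  2001-07→2017-12, EDDC 2005-01→2017-12, COD URF 1985-01→2015-12;
  diagnoses 2010–2014) — only their ordering matters, to most-recent;
- one cancer case per person with sex, five-year age band (weights
  shaped like an incident-cancer age distribution), diagnosis year,
  ICD-10 site (prostate/breast/colorectal/lung/melanoma/cervix/other at
  realistic shares per sex), degree of spread, remoteness and
  socio-economic quintile;
- denominators per (sex, band, year, group): the simulated persons plus
  a deterministic background population — the expected stratum count
  under the configured distributions scaled by population_multiplier
  (default 100×) — keeping rates in a plausible range at desk scale.

No published per-source misrecording magnitudes exist; the defaults
(registry sensitivity 0.70 with 14% unknown, APDC 0.80/5%, EDDC
0.70/10%, death registration 0.95/2%, false positives 0.002 everywhere)
were chosen once as plausible registry-world values. The registry
unknown share matches the ~14% unknown actually observed in the NSW
registry for 2010–2014 diagnoses, and the resulting relative
enhancements (most-recent lowest, ever-reported highest, WoE/MSM
between) land in the reported range without any tuning toward it.

What the simulator does **not** emulate: linkage error (the person
identifier is taken as given), temporal trends in identification,
correlation of misrecording within a person (available via an optional
knob but off by default), migration between strata, multiple primaries
per person, and the census-side undercount of denominators. Passing
tests therefore demonstrate the algorithms and rate machinery are
correct and well-calibrated under the stated misrecording model — not
that any particular real-world sensitivity estimate is right.

## Problem sizes

The test suite and acceptance script use 50,000-person cohorts (about
310,000 source records), 1000 replicates for CI calibration, and
exhaustive rule enumeration to six units over three sources (55,987
sequences) — sizes at which every structural property can be checked
exactly while a full run stays inside a few minutes on one CPU.

## Known limitations

- Absolute synthetic ASRs sit near 150–300 per 100,000 — below the NSW
  all-cancers figures — because the background population is not
  age-matched to a real jurisdiction; relative enhancement statistics,
  which is what the package reports, are unaffected by that scale.
- The 2×2 recovery scoring treats the registry/death-certificate
  precedence as truth-compatible; a simulated false-positive death
  record can force an erroneous Aboriginal status that no method can
  undo, which is faithful to the methodology but caps specificity below
  1 when false-positive rates are non-zero.
- Torres Strait Islander status is not modelled separately (combined
  category throughout), and mortality/survival outcomes are out of
  scope.
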