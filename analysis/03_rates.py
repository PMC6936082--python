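#!/usr/bin/env python
"""Step 3 — age-standardised incidence rates by site and method.

Computes directly age-standardised rates (2001 Australian standard
population, gamma 95% CIs) for non-Aboriginal people and for Aboriginal
people under the registry variable and each enhancement method, holding
Aboriginal population denominators fixed — so enhancement moves
numerators only, as in registry practice.
"""

from pathlib import Path

import pandas as pd

from linkenhance.io import read_cases, read_population, write_table
from linkenhance.rates import build_rate_table, load_standard_population

SCRATCH = Path("scratch/sim")
RESULTS = Path("results")


def main():
    cases = read_cases(SCRATCH / "cases.csv")
    statuses = pd.read_csv(SCRATCH / "statuses.csv")
    population = read_population(SCRATCH / "population.csv")
    standard = load_standard_population()
    years = (int(cases["diagnosis_year"].min()), int(cases["diagnosis_year"].max()))
    table = build_rate_table(cases, statuses, population, standard, years)
    write_table(table, RESULTS / "rate_table.csv")

    overall = table.set_index(["site", "cohort"]).loc[("all_cancers", "persons")]
    print(f"all cancers, persons: non-Aboriginal ASR {overall['non_aboriginal_asr']}, "
          f"Aboriginal registry ASR {overall['base_asr']} "
          f"({overall['base_ci_low']}-{overall['base_ci_high']})")
    for m in ("ever", "most_recent", "weight_of_evidence", "multi_stage_median"):
        print(f"  {m}: ASR {overall[f'{m}_asr']} "
              f"({overall[f'{m}_ci_low']}-{overall[f'{m}_ci_high']}), "
              f"+{overall[f'{m}_increase_pct']}% over the registry variable")
    print("every method raises the Aboriginal ASR; denominators unchanged")


if __name__ == "__main__":
    main()
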