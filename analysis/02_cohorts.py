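#!/usr/bin/env python
"""Apply eligibility and build the study cohorts.

Reads the tables written by 01_simulate.py, applies the eligibility filters
(age strictly over 13, at least one year of history, valid zip), retains
drugs with more than 50 users (the desk-scale analog of the >5000-user
rule), and reports attrition plus per-contrast arm sizes.
"""

import pandas as pd

from _common import DATA, MIN_USERS, RESULTS
from ehrcausal import (
    apply_eligibility,
    build_any_drug_cohorts,
    build_nonuser_cohorts,
    retain_common_drugs,
)


def main() -> None:
    persons = pd.read_csv(DATA / "persons.csv", dtype={"zip3": str})
    exposures = pd.read_csv(DATA / "exposures.csv")

    eligible = apply_eligibility(persons)
    retained = retain_common_drugs(exposures, min_users=MIN_USERS)
    rows = [
        ("persons_total", len(persons)),
        ("eligible", len(eligible)),
        ("drugs_observed", exposures["drug"].nunique()),
        (f"drugs_retained_gt_{MIN_USERS}_users", len(retained)),
    ]

    any_pair = build_any_drug_cohorts(eligible, exposures, retained)
    rows.append(("any_drug_treated", len(any_pair.treated_ids)))
    rows.append(("any_drug_comparator", len(any_pair.comparator_ids)))

    arm_rows = []
    for drug in sorted(retained):
        pair = build_nonuser_cohorts(eligible, exposures, drug, retained=retained)
        arm_rows.append(
            {
                "contrast": pair.contrast_name,
                "n_treated": len(pair.treated_ids),
                "n_comparator": len(pair.comparator_ids),
            }
        )

    attrition = pd.DataFrame(rows, columns=["step", "count"])
    arms = pd.DataFrame(arm_rows)
    attrition.to_csv(RESULTS / "02_attrition.csv", index=False)
    arms.to_csv(RESULTS / "02_cohort_sizes.csv", index=False)
    print(attrition.to_string(index=False))
    print()
    print(arms.to_string(index=False))


if __name__ == "__main__":
    main()
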