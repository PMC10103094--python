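#!/usr/bin/env python
"""Negative-control outcomes: the pipeline should find nothing.

Runs the identical estimation pipeline with each of the five designated
control codes as the outcome (each generated independently of treatment, so
the true effect is exactly zero). CIs that exclude zero would signal
residual bias in the pipeline.
"""

import pandas as pd

from _common import DATA, MIN_USERS, RESULTS, SEED
from ehrcausal import (
    PropensityModelSpec,
    apply_eligibility,
    build_any_drug_cohorts,
    build_vocabulary,
    negative_control_suite,
    retain_common_drugs,
)


def main() -> None:
    persons = pd.read_csv(DATA / "persons.csv", dtype={"zip3": str})
    events = pd.read_csv(DATA / "code_events.csv")
    exposures = pd.read_csv(DATA / "exposures.csv")
    nc_codes = (DATA / "negative_controls.txt").read_text().split()

    eligible = apply_eligibility(persons)
    retained = retain_common_drugs(exposures, min_users=MIN_USERS)
    pair = build_any_drug_cohorts(eligible, exposures, retained)
    vocab = build_vocabulary(events, persons)

    suite = negative_control_suite(
        pair, persons, events, vocab, nc_codes,
        method="one_hot_lr",
        spec=PropensityModelSpec(family="lr", seed=SEED),
        B=100, seed=SEED,
    )
    rows = [
        {
            "control_outcome": e.contrast_name.removeprefix("nc:"),
            "ate": round(e.ate, 4),
            "ci_low": round(e.ci_low, 4),
            "ci_high": round(e.ci_high, 4),
            "covers_zero": e.covers_zero(),
        }
        for e in suite
    ]
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "05_negative_controls.csv", index=False)
    print(out.to_string(index=False))
    n_null = int(out["covers_zero"].sum())
    print(
        f"\n{n_null}/{len(out)} control CIs cover zero: the pipeline finds no "
        "spurious drug effect on outcomes it cannot causally touch"
    )


if __name__ == "__main__":
    main()
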