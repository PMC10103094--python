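"""Eligibility, outcome binarization, and treated/comparator cohort construction.

Three contrast designs are supported:

* user vs nonuser: users of one drug against persons exposed to no study drug;
* active comparator: users of drug A against users of drug B, dual users excluded;
* any-drug: users of at least one study drug against users of none.

Eligibility mirrors a standard pharmacoepidemiology baseline: age strictly
over 13 years, at least one full year of pre-index medical history, and a
usable 3-digit zip code.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class CohortPair:
    """Treated and comparator person-id sets for one causal contrast."""

    contrast_name: str
    treated_ids: frozenset
    comparator_ids: frozenset

    def __post_init__(self) -> None:
        overlap = self.treated_ids & self.comparator_ids
        if overlap:
            raise ValueError(
                f"{self.contrast_name}: {len(overlap)} persons appear in both arms"
            )


def apply_eligibility(
    persons: pd.DataFrame, min_age_exclusive: int = 13, min_history_days: int = 365
) -> set:
    """Person ids with age strictly over ``min_age_exclusive`` (default 13),
    at least ``min_history_days`` of record (default one year) and a nonempty
    zip3."""
    zip3 = persons["zip3"]
    has_zip = zip3.notna() & (zip3.astype(str).str.strip() != "")
    keep = (
        (persons["age"] > min_age_exclusive)
        & (persons["history_days"] >= min_history_days)
        & has_zip
    )
    return set(persons.loc[keep, "person_id"])


def binarize_outcome(level) -> int:
    """5-level severity -> hospitalization flag.

    Levels 3 (moderate, hospitalized), 4 (severe, hospitalized) and
    5 (hospital mortality) map to 1; levels 1-2 (mild, mild with ED visit)
    map to 0. A missing score maps to 0: any hospitalization would have been
    recorded, so absence of a score is read as nonhospitalized.
    """
    if level is None or pd.isna(level):
        return 0
    level = int(level)
    if level not in (1, 2, 3, 4, 5):
        raise ValueError(f"severity level must be in 1..5, got {level}")
    return 1 if level >= 3 else 0


def binarize_outcomes(severities: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`binarize_outcome` over a severity table, person-id indexed."""
    levels = pd.to_numeric(severities["level"], errors="coerce")
    bad = levels.notna() & ~levels.isin([1, 2, 3, 4, 5])
    if bad.any():
        raise ValueError(f"severity levels outside 1..5 for {int(bad.sum())} persons")
    out = (levels >= 3).fillna(False).astype(int)
    out.index = pd.Index(severities["person_id"])
    return out


def retain_common_drugs(exposures: pd.DataFrame, min_users: int = 5000) -> set:
    """Drugs used by strictly more than ``min_users`` distinct persons.

    The production threshold of 5000 users presumes an enclave-scale
    population; synthetic runs pass a scaled value (default 50 in RunConfig).
    """
    if min_users < 1:
        raise ValueError("min_users must be >= 1")
    counts = exposures.groupby("drug")["person_id"].nunique()
    return set(counts[counts > min_users].index)


def _users_of(exposures: pd.DataFrame, drug: str) -> set:
    return set(exposures.loc[exposures["drug"] == drug, "person_id"])


def build_nonuser_cohorts(
    eligible: set,
    exposures: pd.DataFrame,
    drug: str,
    retained: set | None = None,
    comparator: str = "clean",
) -> CohortPair:
    """User vs nonuser contrast for one drug.

    ``comparator="clean"`` (default) excludes users of every retained study
    drug from the comparator arm, so the null arm carries no same-class
    exposure. ``comparator="drug_only"`` keeps the literal reading — anyone
    not taking the drug of interest — admitting users of other study drugs.
    """
    treated = _users_of(exposures, drug) & eligible
    if retained is None:
        retained = set(exposures["drug"].unique())
    if comparator == "clean":
        any_user = set(exposures.loc[exposures["drug"].isin(retained), "person_id"])
        comp = eligible - any_user
    elif comparator == "drug_only":
        comp = eligible - _users_of(exposures, drug)
    else:
        raise ValueError(f"unknown comparator rule {comparator!r}")
    if not treated:
        raise ValueError(f"nonuser contrast for {drug}: treated arm is empty")
    return CohortPair(f"nonuser:{drug}", frozenset(treated), frozenset(comp))


def build_active_comparator_cohorts(
    eligible: set, exposures: pd.DataFrame, drug_a: str, drug_b: str
) -> CohortPair:
    """Head-to-head contrast: users of A vs users of B; dual users excluded."""
    if drug_a == drug_b:
        raise ValueError("active comparator needs two distinct drugs")
    users_a = _users_of(exposures, drug_a) & eligible
    users_b = _users_of(exposures, drug_b) & eligible
    treated = users_a - users_b
    comp = users_b - users_a
    name = f"active:{drug_a}_vs_{drug_b}"
    if not treated or not comp:
        raise ValueError(f"{name}: empty arm (treated={len(treated)}, comparator={len(comp)})")
    return CohortPair(name, frozenset(treated), frozenset(comp))


def build_any_drug_cohorts(eligible: set, exposures: pd.DataFrame, drug_set: set) -> CohortPair:
    """Users of at least one study drug vs users of none."""
    if not drug_set:
        raise ValueError("drug_set must be nonempty")
    users = set(exposures.loc[exposures["drug"].isin(drug_set), "person_id"]) & eligible
    comp = eligible - users
    if not users or not comp:
        raise ValueError(
            f"any-drug contrast: empty arm (treated={len(users)}, comparator={len(comp)})"
        )
    return CohortPair("any_drug", frozenset(users), frozenset(comp))
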