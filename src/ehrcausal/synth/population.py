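"""Confounded synthetic EHR population with stored potential outcomes.

The generative model
--------------------
Each person carries a latent health state ``z ~ N(0, I_k)``. Everything a
real pipeline could observe is a noisy expression of ``z``:

* concept codes: each non-control code belongs to one top-level subtree of
  the ontology; subtree ``j`` codes appear with probability
  ``sigmoid(b_c + s * z_j)``, so the code history is an informative but
  indirect readout of the latent state;
* demographics: age and gender are correlated with components of ``z`` (true
  confounders flowing through the same latent state); race, ethnicity and
  3-digit zip are exogenous;
* treatment: each drug ``d`` is taken with probability
  ``sigmoid(intercept_d + treat_coefs . z)``, so treatment is confounded by
  exactly the factors that also drive the outcome;
* outcome: potential outcomes are drawn by a shared-uniform coupling,
  ``y0 = 1{u < sigmoid(a + outcome_coefs . z)}`` and
  ``y1 = 1{u < sigmoid(a + outcome_coefs . z + treatment_effect)}``, with the
  intercept ``a`` calibrated so that ``mean(y0)`` matches the requested base
  hospitalization rate (default 20%). The observed outcome is ``y1`` for
  anyone exposed to at least one study drug and ``y0`` otherwise.

Because ``y0``/``y1`` are stored, the finite-sample true ATE
``mean(y1) - mean(y0)`` is an exact oracle for every estimator downstream.

Five designated negative-control codes are generated independently of both
``z`` and every treatment flag; any apparent "effect" of a drug on them is,
by construction, estimator bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .ontology import latent_factor_assignment

# 16 study drugs in 4 mechanism classes (SSRI / SNRI / atypical / tricyclic)
DEFAULT_DRUG_CLASSES: dict[str, str] = {
    "fluoxetine": "SSRI",
    "paroxetine": "SSRI",
    "sertraline": "SSRI",
    "citalopram": "SSRI",
    "escitalopram": "SSRI",
    "duloxetine": "SNRI",
    "venlafaxine": "SNRI",
    "desvenlafaxine": "SNRI",
    "trazodone": "atypical",
    "mirtazapine": "atypical",
    "vortioxetine": "atypical",
    "vilazodone": "atypical",
    "bupropion": "atypical",
    "nortriptyline": "tricyclic",
    "amitriptyline": "tricyclic",
    "doxepin": "tricyclic",
}

RACE_LEVELS = ["white", "black", "asian", "other", "unknown"]
RACE_PROBS = [0.62, 0.15, 0.06, 0.07, 0.10]
ETHNICITY_LEVELS = ["not_hispanic", "hispanic"]
ETHNICITY_PROBS = [0.82, 0.18]
ZIP3_LEVELS = [f"{z:03d}" for z in range(10, 260, 10)]  # 25 synthetic zip3 areas


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    Defaults describe the study conditions: ~20% hospitalization base rate,
    16 drugs in 4 classes, a 4-factor latent state with treatment and outcome
    sharing factors 0 and 3 (real confounding), and a log-odds treatment
    effect of -0.5, which at a 20% base rate is a risk difference near -0.07.
    """

    n_persons: int = 5000
    n_codes: int = 500
    n_latent: int = 4
    treat_coefs: tuple[float, ...] = (0.4, 0.4, 0.0, 0.2)
    outcome_coefs: tuple[float, ...] = (1.0, 0.0, 1.0, 0.5)
    treatment_effect: float = -0.5
    base_outcome_rate: float = 0.20
    n_drugs: int = 16
    drug_class_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DRUG_CLASSES))
    seed: int = 0
    # expression of the latent state in code histories
    code_signal: float = 1.5
    code_base_range: tuple[float, float] = (-3.5, -1.5)
    # per-drug intercepts; evenly spaced to mimic unequal prescription volumes
    drug_intercept_base: float = -4.0
    drug_intercept_step: float = 0.08
    # record-keeping realism
    missing_severity_frac: float = 0.3
    zip_missing_frac: float = 0.02
    max_history_days: int = 1825
    # negative controls
    n_negative_controls: int = 5
    nc_prevalence: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 < self.base_outcome_rate < 1.0):
            raise ValueError("base_outcome_rate must be in (0, 1)")
        if not (0.0 <= self.missing_severity_frac < 1.0):
            raise ValueError("missing_severity_frac must be in [0, 1)")
        if not (0.0 < self.nc_prevalence < 1.0):
            raise ValueError("nc_prevalence must be in (0, 1)")
        if self.n_drugs < 2:
            raise ValueError("n_drugs must be >= 2")
        if len(self.treat_coefs) != self.n_latent or len(self.outcome_coefs) != self.n_latent:
            raise ValueError(
                "treat_coefs and outcome_coefs must both have length n_latent "
                f"({self.n_latent}); got {len(self.treat_coefs)} and {len(self.outcome_coefs)}"
            )
        if len(self.drug_class_map) < self.n_drugs:
            raise ValueError("drug_class_map must cover at least n_drugs drugs")

    @property
    def drugs(self) -> list[str]:
        return list(self.drug_class_map)[: self.n_drugs]


@dataclass
class SyntheticTruth:
    """Per-person potential outcomes and the true treatment mechanism."""

    person_id: np.ndarray
    y0: np.ndarray
    y1: np.ndarray
    treated_any: np.ndarray
    p_treat_any: np.ndarray  # exact P(any study drug | z): oracle weights
    nc_codes: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person_id": self.person_id,
                "y0": self.y0.astype(int),
                "y1": self.y1.astype(int),
                "treated_any": self.treated_any.astype(int),
                "p_treat_any": self.p_treat_any,
            }
        )


def true_ate(truth: SyntheticTruth) -> float:
    """Finite-sample average treatment effect ``mean(y1) - mean(y0)``."""
    if len(truth.y0) == 0:
        raise ValueError("empty potential-outcome arrays")
    return float(np.mean(truth.y1) - np.mean(truth.y0))


def negative_control_codes(graph: nx.Graph, n: int = 5) -> list[str]:
    """Designated negative-control codes: the n highest-sorted concept codes."""
    return sorted(graph.nodes())[-n:]


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    """Intercept a such that mean(sigmoid(a + lin)) == target on this sample."""
    return brentq(lambda a: float(np.mean(expit(a + lin))) - target, -20.0, 20.0)


def generate_population(
    graph: nx.Graph, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw a full synthetic population from the ontology and config.

    Returns ``(persons, code_events, exposures, severities, truth)``.
    Identical config (including seed) gives byte-identical tables.
    """
    cfg = config
    if graph.number_of_nodes() < cfg.n_codes:
        raise ValueError(
            f"graph has {graph.number_of_nodes()} nodes but config requests {cfg.n_codes} codes"
        )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_persons
    k = cfg.n_latent
    person_id = np.arange(n)

    z = rng.standard_normal((n, k))
    treat_coefs = np.asarray(cfg.treat_coefs, dtype=float)
    outcome_coefs = np.asarray(cfg.outcome_coefs, dtype=float)

    # --- demographics (age and gender expressed through z: true confounders)
    age = np.clip(np.round(42 + 11 * z[:, 0] + 13 * rng.standard_normal(n)), 0, 95).astype(int)
    gender = np.where(rng.random(n) < expit(0.25 * z[:, 1 % k] + 0.1), "F", "M")
    race = rng.choice(RACE_LEVELS, size=n, p=RACE_PROBS)
    ethnicity = rng.choice(ETHNICITY_LEVELS, size=n, p=ETHNICITY_PROBS)
    zip3 = rng.choice(ZIP3_LEVELS, size=n)
    zip3 = np.where(rng.random(n) < cfg.zip_missing_frac, "", zip3)
    history_days = rng.integers(0, cfg.max_history_days, size=n)

    # --- code histories
    codes = sorted(graph.nodes())[: cfg.n_codes]
    nc_codes = negative_control_codes(graph.subgraph(codes), cfg.n_negative_controls)
    factor_of = latent_factor_assignment(graph, codes, k)
    code_arr = np.array(codes)
    is_nc = np.isin(code_arr, nc_codes)
    factors = np.array([factor_of[c] for c in codes])
    base = rng.uniform(*cfg.code_base_range, size=len(codes))
    # (n, n_codes) occurrence probabilities; NC codes are flat and exogenous
    p_code = expit(base[None, :] + cfg.code_signal * z[:, factors])
    p_code[:, is_nc] = cfg.nc_prevalence
    occurs = rng.random((n, len(codes))) < p_code
    pid_idx, code_idx = np.nonzero(occurs)
    days_before = rng.integers(1, 1461, size=len(pid_idx))
    code_events = pd.DataFrame(
        {
            "person_id": person_id[pid_idx],
            "code": code_arr[code_idx],
            "days_before_index": days_before,
        }
    )

    # --- treatment assignment, one flag per drug
    drugs = cfg.drugs
    lin_treat = z @ treat_coefs
    intercepts = cfg.drug_intercept_base + cfg.drug_intercept_step * np.arange(len(drugs))
    p_drug = expit(lin_treat[:, None] + intercepts[None, :])
    takes = rng.random((n, len(drugs))) < p_drug
    treated_any = takes.any(axis=1)
    p_treat_any = 1.0 - np.prod(1.0 - p_drug, axis=1)
    t_idx, d_idx = np.nonzero(takes)
    exposures = pd.DataFrame({"person_id": person_id[t_idx], "drug": np.array(drugs)[d_idx]})

    # --- potential outcomes with a shared-uniform coupling
    lin_out = z @ outcome_coefs
    alpha = _calibrate_intercept(lin_out, cfg.base_outcome_rate)
    u = rng.random(n)
    y0 = u < expit(alpha + lin_out)
    y1 = u < expit(alpha + lin_out + cfg.treatment_effect)
    hosp = np.where(treated_any, y1, y0)

    # --- 5-level severity consistent with the observed hospitalization flag
    level = np.zeros(n, dtype=object)
    sev_draw = rng.random(n)
    miss_draw = rng.random(n)
    hosp_levels = np.select([sev_draw < 0.6, sev_draw < 0.9], [3, 4], default=5)
    nonhosp_levels = np.where(sev_draw < 0.5, 1, 2)
    level[:] = np.where(hosp, hosp_levels, nonhosp_levels)
    missing = (~hosp) & (miss_draw < cfg.missing_severity_frac)
    level[missing] = pd.NA

    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "age": age,
            "gender": gender,
            "race": race,
            "ethnicity": ethnicity,
            "zip3": zip3,
            "history_days": history_days,
        }
    )
    severities = pd.DataFrame({"person_id": person_id, "level": level})
    truth = SyntheticTruth(
        person_id=person_id,
        y0=y0.astype(int),
        y1=y1.astype(int),
        treated_any=treated_any,
        p_treat_any=p_treat_any,
        nc_codes=nc_codes,
    )
    return persons, code_events, exposures, severities, truth


def write_tables(
    out_dir,
    persons: pd.DataFrame,
    code_events: pd.DataFrame,
    exposures: pd.DataFrame,
    severities: pd.DataFrame,
    truth: SyntheticTruth,
    graph: nx.Graph | None = None,
) -> None:
    """Write the pipeline input tables (CSV); truth goes to a separate file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    persons.to_csv(out / "persons.csv", index=False)
    code_events.to_csv(out / "code_events.csv", index=False)
    exposures.to_csv(out / "exposures.csv", index=False)
    severities.to_csv(out / "severities.csv", index=False)
    truth.as_frame().to_csv(out / "truth.csv", index=False)
    (out / "negative_controls.txt").write_text("\n".join(truth.nc_codes) + "\n")
    if graph is not None:
        from .ontology import write_edge_list

        write_edge_list(graph, out / "concept_edges.csv")
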