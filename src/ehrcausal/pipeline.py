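"""End-to-end orchestration: one validated config, one reproducible run directory.

Stages
------
``synth``     generate (or load) the input tables and, when the embedding
              method is requested, train concept embeddings on the graph;
``cohort``    eligibility, severity binarization, drug retention, cohort files;
``estimate``  per-contrast ATEs with bootstrap CIs, negative-control suite,
              active-comparator matrix, balance diagnostics.

All randomness flows from one root seed, expanded per stage; the manifest
written at the end is sufficient to reproduce every number in the results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import cohort as coh
from . import estimate as est
from . import features as feat
from .propensity import PropensityModelSpec, balance_diagnostics, compute_weights, fit_propensity, predict_propensity
from .synth import (
    EmbeddingTable,
    SimConfig,
    generate_ontology,
    generate_population,
    train_embeddings,
    true_ate,
)
from .synth.ontology import read_edge_list
from .synth.population import negative_control_codes

logger = logging.getLogger(__name__)

STAGES = ("synth", "cohort", "estimate")


class SynthParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_persons: int = 2000
    n_codes: int = 200
    n_latent: int = 4
    branching: int = 3
    treat_coefs: Optional[list[float]] = None
    outcome_coefs: Optional[list[float]] = None
    treatment_effect: float = -0.5
    base_outcome_rate: float = 0.20
    n_drugs: int = 16
    missing_severity_frac: float = 0.3

    def to_sim_config(self, seed: int) -> SimConfig:
        kw = self.model_dump()
        kw.pop("branching")
        for key in ("treat_coefs", "outcome_coefs"):
            if kw[key] is None:
                kw.pop(key)
            else:
                kw[key] = tuple(kw[key])
        return SimConfig(seed=seed, **kw)


class EmbeddingParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dim: int = 128
    walk_len: int = 40
    n_walks: int = 10
    window: int = 5


class LRParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    C_grid: list[float] = [0.03, 0.3, 3.0]


class RFParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_trees: int = 200
    max_depth: Optional[int] = None
    min_leaf: int = 25


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    synth: Optional[SynthParams] = None
    input_dir: Optional[str] = None
    contrasts: list[Literal["any_drug", "nonuser", "active_comparator"]] = ["any_drug"]
    nonuser_drugs: str | list[str] = "all"
    active_drugs: str | list[str] = "all"
    methods: list[Literal["unadjusted", "one_hot_lr", "embedding_rf"]] = [
        "unadjusted",
        "one_hot_lr",
    ]
    min_users: int = 50
    min_age_exclusive: int = 13
    min_history_days: int = 365
    comparator_rule: Literal["clean", "drug_only"] = "clean"
    eps: float = Field(default=0.01, gt=0, lt=0.5)
    n_bootstrap: int = Field(default=100, ge=2)
    negative_controls: bool = True
    embedding: EmbeddingParams = EmbeddingParams()
    lr: LRParams = LRParams()
    rf: RFParams = RFParams()

    @model_validator(mode="after")
    def _check_inputs(self) -> "RunConfig":
        if self.synth is None and self.input_dir is None:
            raise ValueError("config must provide either synth parameters or input_dir")
        if "embedding_rf" in self.methods and self.synth is None:
            d = Path(self.input_dir)
            if not (d / "embeddings.txt").exists() and not (d / "concept_edges.csv").exists():
                raise ValueError(
                    "method embedding_rf requires an embedding table or a concept graph; "
                    f"neither embeddings.txt nor concept_edges.csv found in {d}"
                )
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _spec_for(method: str, config: RunConfig, seed: int) -> PropensityModelSpec:
    if method == "one_hot_lr":
        return PropensityModelSpec(family="lr", C_grid=tuple(config.lr.C_grid), seed=seed)
    return PropensityModelSpec(
        family="rf",
        n_trees=config.rf.n_trees,
        max_depth=config.rf.max_depth,
        min_leaf=config.rf.min_leaf,
        seed=seed,
    )


def _load_tables(data_dir: Path):
    persons = pd.read_csv(data_dir / "persons.csv", dtype={"zip3": str})
    code_events = pd.read_csv(data_dir / "code_events.csv")
    exposures = pd.read_csv(data_dir / "exposures.csv")
    severities = pd.read_csv(data_dir / "severities.csv")
    return persons, code_events, exposures, severities


class RunResult:
    """Handle onto a completed (or partially completed) run directory."""

    def __init__(self, out_dir: Path):
        self.out_dir = Path(out_dir)
        self.estimates: list[est.ATEEstimate] = []
        self.nc_estimates: list[est.ATEEstimate] = []
        self.comparator: est.ComparatorMatrix | None = None
        self.attrition: dict[str, int] = {}

    def estimates_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contrast": e.contrast_name,
                "method": e.method,
                "ate": e.ate,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p": e.p_value,
                "p_sign": e.p_sign,
                "n_treated": e.n_treated,
                "n_comparator": e.n_comparator,
                "n_bootstrap": e.n_bootstrap,
                "estimable": e.estimable,
            }
            for e in self.estimates + self.nc_estimates
        ]
        return pd.DataFrame(rows)


def run(config: RunConfig, out_dir, stages=STAGES) -> RunResult:
    """Execute the requested stages into ``out_dir``.

    Deterministic given the config (including its seed). Any stage failure is
    re-raised annotated with the stage name; files written before the failure
    are left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_dir = out / "data"
    result = RunResult(out)

    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("ehrcausal")
    root_logger.addHandler(fh)
    root_logger.setLevel(logging.INFO)
    try:
        for stage in stages:
            try:
                if stage == "synth":
                    _run_synth(config, data_dir)
                elif stage == "cohort":
                    _run_cohort(config, data_dir, out, result)
                elif stage == "estimate":
                    _run_estimate(config, data_dir, out, result)
                else:
                    raise ValueError(f"unknown stage {stage!r}")
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _write_manifest(config, out, result)
    finally:
        root_logger.removeHandler(fh)
        fh.close()
    return result


def _run_synth(config: RunConfig, data_dir: Path) -> None:
    data_dir.mkdir(parents=True, exist_ok=True)
    if config.synth is None:
        src = Path(config.input_dir)
        for name in (
            "persons.csv", "code_events.csv", "exposures.csv", "severities.csv",
            "concept_edges.csv", "embeddings.txt", "truth.csv", "negative_controls.txt",
        ):
            if (src / name).exists() and src != data_dir:
                (data_dir / name).write_bytes((src / name).read_bytes())
        return
    seed = _stage_seed(config.seed, "synth")
    sim = config.synth.to_sim_config(seed)
    graph = generate_ontology(sim.n_codes, branching=config.synth.branching, seed=seed)
    persons, code_events, exposures, severities, truth = generate_population(graph, sim)
    from .synth.population import write_tables

    write_tables(data_dir, persons, code_events, exposures, severities, truth, graph)
    logger.info(
        "synth: %d persons, %d events, %d exposures, true ATE %.4f",
        len(persons), len(code_events), len(exposures), true_ate(truth),
    )
    if "embedding_rf" in config.methods:
        emb_seed = _stage_seed(config.seed, "embeddings")
        table = train_embeddings(
            graph,
            dim=config.embedding.dim,
            walk_len=config.embedding.walk_len,
            n_walks=config.embedding.n_walks,
            window=config.embedding.window,
            seed=emb_seed,
        )
        table.save(data_dir / "embeddings.txt")


def _run_cohort(config: RunConfig, data_dir: Path, out: Path, result: RunResult) -> None:
    persons, code_events, exposures, severities = _load_tables(data_dir)
    eligible = coh.apply_eligibility(
        persons, config.min_age_exclusive, config.min_history_days
    )
    retained = coh.retain_common_drugs(exposures, min_users=config.min_users)
    result.attrition = {
        "persons_total": len(persons),
        "eligible": len(eligible),
        "drugs_observed": int(exposures["drug"].nunique()),
        "drugs_retained": len(retained),
    }
    logger.info("cohort attrition: %s", result.attrition)

    rows = []
    for pair in _build_contrasts(config, eligible, exposures, retained):
        for pid in sorted(pair.treated_ids):
            rows.append((pair.contrast_name, pid, "treated"))
        for pid in sorted(pair.comparator_ids):
            rows.append((pair.contrast_name, pid, "comparator"))
    pd.DataFrame(rows, columns=["contrast_name", "person_id", "arm"]).to_csv(
        out / "cohorts.csv", index=False
    )


def _build_contrasts(config: RunConfig, eligible, exposures, retained) -> list[coh.CohortPair]:
    pairs: list[coh.CohortPair] = []
    retained_sorted = sorted(retained)
    if "any_drug" in config.contrasts:
        pairs.append(coh.build_any_drug_cohorts(eligible, exposures, set(retained)))
    if "nonuser" in config.contrasts:
        drugs = retained_sorted if config.nonuser_drugs == "all" else config.nonuser_drugs
        for d in drugs:
            pairs.append(
                coh.build_nonuser_cohorts(
                    eligible, exposures, d, retained=set(retained), comparator=config.comparator_rule
                )
            )
    return pairs


def _run_estimate(config: RunConfig, data_dir: Path, out: Path, result: RunResult) -> None:
    persons, code_events, exposures, severities = _load_tables(data_dir)
    eligible = coh.apply_eligibility(persons, config.min_age_exclusive, config.min_history_days)
    retained = coh.retain_common_drugs(exposures, min_users=config.min_users)
    outcomes_by_person = coh.binarize_outcomes(severities)
    vocab = feat.build_vocabulary(code_events, persons)
    table = None
    if "embedding_rf" in config.methods:
        table = EmbeddingTable.load(data_dir / "embeddings.txt")
    seed = _stage_seed(config.seed, "estimate")

    pairs = _build_contrasts(config, eligible, exposures, retained)
    balance_rows = []
    nonhosp_rows = []
    for ci, pair in enumerate(pairs):
        for mi, method in enumerate(config.methods):
            mode = "embedding" if method == "embedding_rf" else "one_hot"
            X, labels, ids = feat.build_design_matrices(
                pair, mode, persons, code_events, vocab, table=table
            )
            h = outcomes_by_person.loc[ids].to_numpy(dtype=float)
            spec = None if method == "unadjusted" else _spec_for(method, config, seed)
            e = est.estimate_contrast(
                X, labels, h,
                method=method, spec=spec, B=config.n_bootstrap,
                seed=(seed + 131 * ci + mi) % (2**31), eps=config.eps,
                contrast_name=pair.contrast_name,
            )
            result.estimates.append(e)
            logger.info(
                "%s / %s: ATE %.4f [%.4f, %.4f]", pair.contrast_name, method, e.ate, e.ci_low, e.ci_high
            )
            if method != "unadjusted":
                model = fit_propensity(X, labels, spec)
                p = predict_propensity(model, X, eps=config.eps)
                w = compute_weights(p, labels)
                scores_dir = out / "scores"
                scores_dir.mkdir(exist_ok=True)
                safe = pair.contrast_name.replace(":", "_")
                pd.DataFrame(
                    {"person_id": ids, "treated": labels, "propensity": p, "weight": w}
                ).to_csv(scores_dir / f"{safe}_{method}.csv", index=False)
                before, after, _ = balance_diagnostics(X, labels, w)
                balance_rows.append(
                    {
                        "contrast": pair.contrast_name,
                        "method": method,
                        "max_abs_smd_before": float(np.nanmax(np.abs(before))),
                        "max_abs_smd_after": float(np.nanmax(np.abs(after))),
                    }
                )
        # Fig 3 analog: average rate of NONhospitalization per arm
        t_ids = sorted(pair.treated_ids)
        c_ids = sorted(pair.comparator_ids)
        nonhosp_rows.append(
            {
                "contrast": pair.contrast_name,
                "nonhosp_rate_treated": 1.0 - float(outcomes_by_person.loc[t_ids].mean()),
                "nonhosp_rate_comparator": 1.0 - float(outcomes_by_person.loc[c_ids].mean()),
            }
        )
        if ci == 0 and config.negative_controls:
            nc_path = data_dir / "negative_controls.txt"
            if nc_path.exists():
                nc_codes = nc_path.read_text().split()
            else:
                graph = read_edge_list(data_dir / "concept_edges.csv")
                nc_codes = negative_control_codes(graph)
            nc_method = "one_hot_lr" if "one_hot_lr" in config.methods else config.methods[0]
            result.nc_estimates = est.negative_control_suite(
                pair, persons, code_events, vocab, nc_codes,
                method=nc_method,
                spec=None if nc_method == "unadjusted" else _spec_for(nc_method, config, seed),
                table=table,
                B=config.n_bootstrap,
                seed=(seed + 7919) % (2**31),
                eps=config.eps,
            )

    if "active_comparator" in config.contrasts:
        drugs = sorted(retained) if config.active_drugs == "all" else config.active_drugs
        method = "one_hot_lr" if "one_hot_lr" in config.methods else config.methods[0]
        result.comparator = est.comparator_matrix(
            eligible, exposures, persons, code_events, vocab, outcomes_by_person, drugs,
            method=method,
            spec=None if method == "unadjusted" else _spec_for(method, config, seed),
            table=table,
            B=config.n_bootstrap,
            seed=(seed + 104729) % (2**31),
            eps=config.eps,
        )
        result.comparator.to_frame().to_csv(out / "comparator_matrix.csv")

    result.estimates_frame().to_csv(out / "results.csv", index=False)
    if balance_rows:
        pd.DataFrame(balance_rows).to_csv(out / "balance.csv", index=False)
    pd.DataFrame(nonhosp_rows).to_csv(out / "nonhospitalization.csv", index=False)


def _write_manifest(config: RunConfig, out: Path, result: RunResult) -> None:
    cfg_json = json.dumps(config.model_dump(), sort_keys=True, default=str)
    manifest = {
        "config": config.model_dump(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in (*STAGES, "embeddings")},
        "attrition": result.attrition,
        "n_estimates": len(result.estimates),
        "n_negative_controls": len(result.nc_estimates),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
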