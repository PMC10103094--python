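"""Shared paths and the study configuration for the analysis drivers.

The drivers run a desk-scale version of the study: 5,000 persons, 500
concept codes, 16 drugs in 4 classes, ~20% hospitalization base rate, and a
treatment effect of -0.5 log-odds. Raw generated tables live under
``scratch/`` (regenerable); each driver writes its summary tables under
``results/``.
"""

from pathlib import Path

from ehrcausal.synth import SimConfig, generate_ontology

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis_run"
DATA = SCRATCH / "data"

SEED = 20230411
N_PERSONS = 5000
N_CODES = 500
MIN_USERS = 50


def study_graph():
    return generate_ontology(N_CODES, branching=3, seed=1)


def study_config(**overrides) -> SimConfig:
    kw = dict(n_persons=N_PERSONS, n_codes=N_CODES, seed=SEED)
    kw.update(overrides)
    return SimConfig(**kw)
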