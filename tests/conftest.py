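import numpy as np
import pandas as pd
import pytest

from ehrcausal import (
    SimConfig,
    apply_eligibility,
    build_any_drug_cohorts,
    build_vocabulary,
    generate_ontology,
    generate_population,
    retain_common_drugs,
)


@pytest.fixture(scope="session")
def small_graph():
    return generate_ontology(n_codes=60, branching=3, seed=3)


@pytest.fixture(scope="session")
def small_pop(small_graph):
    """Confounded population at desk scale: 2,000 persons, 60 codes, 16 drugs."""
    cfg = SimConfig(n_persons=2000, n_codes=60, seed=5)
    persons, events, exposures, severities, truth = generate_population(small_graph, cfg)
    return {
        "config": cfg,
        "graph": small_graph,
        "persons": persons,
        "events": events,
        "exposures": exposures,
        "severities": severities,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def randomized_pop(small_graph):
    """Same scale but treatment assignment independent of the latent state."""
    cfg = SimConfig(n_persons=5000, n_codes=60, seed=7, treat_coefs=(0.0, 0.0, 0.0, 0.0))
    persons, events, exposures, severities, truth = generate_population(small_graph, cfg)
    return {
        "config": cfg,
        "persons": persons,
        "events": events,
        "exposures": exposures,
        "severities": severities,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_cohort(small_pop):
    eligible = apply_eligibility(small_pop["persons"])
    retained = retain_common_drugs(small_pop["exposures"], min_users=20)
    pair = build_any_drug_cohorts(eligible, small_pop["exposures"], retained)
    vocab = build_vocabulary(small_pop["events"], small_pop["persons"])
    return {"pair": pair, "vocab": vocab, "retained": retained, "eligible": eligible}


@pytest.fixture()
def toy_persons():
    """Six persons covering the eligibility branches."""
    return pd.DataFrame(
        {
            "person_id": [1, 2, 3, 4, 5, 6],
            "age": [40, 13, 40, 40, 14, 70],
            "gender": ["F", "M", "F", "M", "F", "M"],
            "race": ["white", "white", "black", "black", "white", "white"],
            "ethnicity": ["not_hispanic"] * 6,
            "zip3": ["021", "021", "021", None, "110", "110"],
            "history_days": [400, 400, 364, 400, 365, 2000],
        }
    )
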