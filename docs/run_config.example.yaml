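# Example configuration for `ehrcausal run --config <this file> --out runs/demo/`.
# Unknown keys are rejected; every field below shows its default unless noted.

seed: 123                  # root seed; expanded per stage (synth/embeddings/estimate)

# Either `synth:` (generate data) or `input_dir:` (read persons.csv,
# code_events.csv, exposures.csv, severities.csv, and optionally
# embeddings.txt / concept_edges.csv / negative_controls.txt).
synth:
  n_persons: 2000
  n_codes: 200
  n_latent: 4
  branching: 3             # ontology tree branching factor
  treatment_effect: -0.5   # log-odds shift of hospitalization under exposure
  base_outcome_rate: 0.20
  n_drugs: 16
  missing_severity_frac: 0.3
  # treat_coefs / outcome_coefs: per-factor log-odds lists (defaults are the
  # calibrated confounded study conditions; all zeros = randomized arms)

contrasts: [any_drug]      # any of: any_drug | nonuser | active_comparator
nonuser_drugs: all         # or an explicit list of drug names
active_drugs: all          # drugs entering the head-to-head grid
methods: [unadjusted, one_hot_lr]   # plus: embedding_rf

min_users: 50              # drug retention: strictly more than this many users
min_age_exclusive: 13      # eligibility: age must exceed this
min_history_days: 365      # eligibility: at least this much pre-index record
comparator_rule: clean     # clean = nonuser arm excludes all study drugs; drug_only = literal
eps: 0.01                  # propensity clipping bound
n_bootstrap: 100           # replicates per CI (model refit in each)
negative_controls: true    # run the 5-control suite on the first contrast

embedding: {dim: 128, walk_len: 40, n_walks: 10, window: 5}
lr: {C_grid: [0.3, 3.0]}   # L1 strengths searched by 3-fold CV
rf: {n_trees: 200, max_depth: null, min_leaf: 25}
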