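"""Estimators: unadjusted and IPTW ATEs, bootstrap, negative controls, matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrcausal import (
    PropensityModelSpec,
    binarize_outcomes,
    bootstrap_estimate,
    comparator_matrix,
    compute_weights,
    estimate_contrast,
    iptw_ate,
    negative_control_suite,
    unadjusted_ate,
)
from ehrcausal.features import build_design_matrices


class TestPointEstimators:
    def test_hand_computed_unadjusted(self):
        assert unadjusted_ate([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0
        assert unadjusted_ate([1, 0, 1, 0], [1, 1, 0, 0]) == 0.0
        # treated [1,0,0] vs comparator [1,1,0,0]: 1/3 - 1/2
        est = unadjusted_ate([1, 0, 0, 1, 1, 0, 0], [1, 1, 1, 0, 0, 0, 0])
        assert est == pytest.approx(1 / 3 - 1 / 2)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            unadjusted_ate([1, 0], [1, 1])

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=4, max_size=30))
    def test_negating_labels_negates_the_estimate(self, rows):
        outcomes = np.array([r[0] for r in rows])
        labels = np.array([r[1] for r in rows])
        if labels.sum() in (0, len(labels)):
            return
        assert unadjusted_ate(outcomes, 1 - labels) == -unadjusted_ate(outcomes, labels)

    def test_unit_weights_reduce_to_unadjusted(self):
        rng = np.random.default_rng(0)
        outcomes = rng.integers(0, 2, 40)
        labels = np.array([1] * 15 + [0] * 25)
        w = np.full(40, 3.7)
        assert iptw_ate(outcomes, labels, w) == pytest.approx(
            unadjusted_ate(outcomes, labels), abs=1e-15
        )

    def test_single_pair_iptw_is_one_for_any_weights(self):
        for w, v in [(1.0, 1.0), (5.0, 0.2), (0.01, 7.0)]:
            assert iptw_ate([1, 0], [1, 0], [w, v]) == 1.0

    def test_hajek_differs_from_horvitz_thompson_under_unequal_weights(self):
        outcomes = np.array([1, 0, 1, 0])
        labels = np.array([1, 1, 0, 0])
        weights = np.array([4.0, 1.0, 1.0, 1.0])
        hajek = iptw_ate(outcomes, labels, weights, normalized=True)
        ht = iptw_ate(outcomes, labels, weights, normalized=False)
        assert hajek == pytest.approx(4 / 5 - 1 / 2)
        assert ht == pytest.approx(4 / 2 - 1 / 2)

    def test_oracle_weights_beat_unadjusted_on_confounded_data(self, small_graph):
        # the weighted estimator's advantage is asymptotic; n=10,000 puts its
        # sampling noise well below the confounding bias
        from ehrcausal import (
            SimConfig, apply_eligibility, build_any_drug_cohorts,
            generate_population, retain_common_drugs,
        )

        cfg = SimConfig(n_persons=10000, n_codes=60, seed=5)
        persons, events, exposures, severities, truth = generate_population(small_graph, cfg)
        eligible = apply_eligibility(persons)
        pair = build_any_drug_cohorts(eligible, exposures, retain_common_drugs(exposures, 50))
        ids = sorted(pair.treated_ids) + sorted(pair.comparator_ids)
        labels = np.concatenate(
            [np.ones(len(pair.treated_ids), int), np.zeros(len(pair.comparator_ids), int)]
        )
        h = binarize_outcomes(severities).loc[ids].to_numpy(float)
        mask = np.isin(truth.person_id, ids)
        tau = float(truth.y1[mask].mean() - truth.y0[mask].mean())
        id2p = dict(zip(truth.person_id, truth.p_treat_any))
        p = np.clip(np.array([id2p[i] for i in ids]), 0.01, 0.99)
        w = compute_weights(p, labels)
        assert abs(iptw_ate(h, labels, w) - tau) < abs(unadjusted_ate(h, labels) - tau)


class TestBootstrap:
    def test_degenerate_estimator_gives_zero_width_ci(self):
        labels = np.array([1] * 5 + [0] * 5)
        est = bootstrap_estimate(lambda idx: 0.42, labels, B=25, seed=1)
        assert est.ci_low == est.ci_high == 0.42
        assert est.ate == 0.42

    def test_same_seed_gives_identical_intervals(self):
        rng = np.random.default_rng(3)
        outcomes = rng.integers(0, 2, 60)
        labels = np.array([1] * 25 + [0] * 35)

        def f(idx):
            return unadjusted_ate(outcomes[idx], labels[idx])

        e1 = bootstrap_estimate(f, labels, B=50, seed=9)
        e2 = bootstrap_estimate(f, labels, B=50, seed=9)
        assert (e1.ci_low, e1.ci_high, e1.p_value) == (e2.ci_low, e2.ci_high, e2.p_value)

    def test_failing_replicates_are_redrawn_up_to_cap(self):
        labels = np.array([1] * 4 + [0] * 4)
        calls = {"n": 0}

        def flaky(idx):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise ValueError("degenerate replicate")
            return 1.0

        est = bootstrap_estimate(flaky, labels, B=10, seed=0)
        assert est.n_bootstrap == 10

        def always_fails(idx):
            raise ValueError("no")

        with pytest.raises(RuntimeError, match="bootstrap failed"):
            bootstrap_estimate(always_fails, labels, B=5, seed=0, point=0.0)

    def test_stratified_resampling_preserves_arm_sizes(self):
        labels = np.array([1] * 7 + [0] * 13)
        seen = []

        def spy(idx):
            seen.append((int(labels[idx].sum()), len(idx)))
            return 0.0

        bootstrap_estimate(spy, labels, B=5, seed=2)
        assert all(s == (7, 20) for s in seen[1:])  # first call is the full sample


class TestEstimateContrast:
    def test_full_pipeline_returns_consistent_metadata(self, small_pop, small_cohort):
        X, labels, ids = build_design_matrices(
            small_cohort["pair"], "one_hot", small_pop["persons"],
            small_pop["events"], small_cohort["vocab"],
        )
        h = binarize_outcomes(small_pop["severities"]).loc[ids].to_numpy(float)
        est = estimate_contrast(
            X, labels, h, method="one_hot_lr",
            spec=PropensityModelSpec(family="lr", C_grid=(0.3,), seed=0),
            B=20, seed=5, contrast_name="any_drug",
        )
        assert est.n_treated == int(labels.sum())
        assert est.ci_low <= est.ate <= est.ci_high
        assert 0 < est.p_value <= 1
        assert 2 / (est.n_bootstrap + 1) <= est.p_sign <= 1

    def test_same_outcome_through_nc_pipeline_matches_direct_estimate(
        self, small_pop, small_cohort
    ):
        """Feeding an outcome through the negative-control path equals running
        the main pipeline on that outcome with the same reduced vocabulary."""
        vocab = small_cohort["vocab"]
        nc = small_pop["truth"].nc_codes[0]
        suite = negative_control_suite(
            small_cohort["pair"], small_pop["persons"], small_pop["events"],
            vocab, [nc], method="one_hot_lr",
            spec=PropensityModelSpec(family="lr", C_grid=(0.3,), seed=0),
            B=10, seed=3,
        )
        ev = small_pop["events"][small_pop["events"]["code"] != nc]
        X, labels, ids = build_design_matrices(
            small_cohort["pair"], "one_hot", small_pop["persons"], ev, vocab.drop([nc])
        )
        has_nc = set(
            small_pop["events"].loc[small_pop["events"]["code"] == nc, "person_id"]
        )
        outcomes = np.array([pid in has_nc for pid in ids], dtype=float)
        direct = estimate_contrast(
            X, labels, outcomes, method="one_hot_lr",
            spec=PropensityModelSpec(family="lr", C_grid=(0.3,), seed=0),
            B=10, seed=3 + 1000, contrast_name=f"nc:{nc}",
        )
        assert suite[0].ate == pytest.approx(direct.ate)
        assert suite[0].ci_low == pytest.approx(direct.ci_low)

    def test_suite_length_and_inestimable_control(self, small_pop, small_cohort):
        nc_codes = list(small_pop["truth"].nc_codes[:2]) + ["C9999"]
        suite = negative_control_suite(
            small_cohort["pair"], small_pop["persons"], small_pop["events"],
            small_cohort["vocab"], nc_codes, method="one_hot_lr",
            spec=PropensityModelSpec(family="lr", C_grid=(0.3,), seed=0),
            B=5, seed=1,
        )
        assert len(suite) == 3
        assert suite[0].estimable and suite[1].estimable
        assert not suite[2].estimable  # code never occurs: zero prevalence


class TestComparatorMatrix:
    def _run(self, pop, cohort, drugs, B=3):
        from ehrcausal import apply_eligibility

        eligible = apply_eligibility(pop["persons"])
        h = binarize_outcomes(pop["severities"])
        return comparator_matrix(
            eligible, pop["exposures"], pop["persons"], pop["events"],
            cohort["vocab"], h, drugs, method="unadjusted", B=B, seed=0,
        )

    def test_two_drugs_give_two_cells_and_exact_antisymmetry(self, small_pop, small_cohort):
        drugs = sorted(small_cohort["retained"])[:2]
        mat = self._run(small_pop, small_cohort, drugs)
        assert len(mat.cells) == 2
        a, b = drugs
        assert mat.get(a, a) is None
        # unadjusted estimates on swapped arms are exactly antisymmetric
        assert mat.get(a, b).ate == pytest.approx(-mat.get(b, a).ate)
        report = mat.antisymmetry_report()
        assert report["asym"].max() == pytest.approx(0.0)

    def test_sixteen_drugs_give_240_ordered_cells(self, small_pop, small_cohort):
        drugs = sorted(small_cohort["retained"])
        assert len(drugs) == 16
        mat = self._run(small_pop, small_cohort, drugs, B=2)
        assert len(mat.cells) == 16 * 15
        frame = mat.to_frame()
        assert frame.shape == (16, 16)
        assert frame.isna().to_numpy().trace() == 16  # empty diagonal

    def test_missing_drug_yields_flagged_cell(self, small_pop, small_cohort):
        drugs = [sorted(small_cohort["retained"])[0], "not_a_drug"]
        mat = self._run(small_pop, small_cohort, drugs)
        assert mat.get(drugs[0], "not_a_drug") is None

    def test_fewer_than_two_drugs_rejected(self, small_pop, small_cohort):
        with pytest.raises(ValueError, match="two drugs"):
            self._run(small_pop, small_cohort, ["only_one"])
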