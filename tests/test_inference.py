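import numpy as np
import pandas as pd
import pytest

from abnet.inference import (CorrelationProfile, ExpressionDataset,
                             ThresholdSearchError, call_possible_interactions,
                             compute_correlation_profiles,
                             default_candidate_grid, find_max_threshold,
                             induced_network)
from abnet.network import AbstractNetwork, Component, Interaction


def dataset(genes, samples, label="d"):
    return ExpressionDataset(pd.DataFrame(samples, index=genes), label)


def profile_of(coeffs):
    p = CorrelationProfile(["A", "B"], len(coeffs))
    p.coefficients[("A", "B")] = np.array(coeffs, dtype=float)
    return p


class TestCorrelationProfiles:
    def test_proportional_genes_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        ds = []
        for _ in range(3):
            a = rng.uniform(1, 100, size=10)
            ds.append(dataset(["A", "B"], np.vstack([a, 2 * a])))
        prof = compute_correlation_profiles(ds)
        assert np.allclose(prof.pair("A", "B"), 1.0)

    def test_inverse_relation_gives_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(1, 2, size=12)
        # log-linear inversion so the default log10 transform sees -1 exactly
        ds = [dataset(["A", "B"], np.vstack([a, 100.0 / a]))]
        prof = compute_correlation_profiles(ds)
        assert prof.pair("A", "B")[0] == pytest.approx(-1.0)

    def test_noisy_linear_pair_close_to_analytic_value(self):
        # log10 B = log10 A + noise; analytic r = sd_A / sqrt(sd_A^2 + sd_e^2)
        rng = np.random.default_rng(2)
        n, sd_a, sd_e = 4000, 0.5, 0.1
        la = rng.normal(1.5, sd_a, size=n)
        lb = la + rng.normal(0, sd_e, size=n)
        ds = [dataset(["A", "B"], np.vstack([10 ** la, 10 ** lb]))]
        prof = compute_correlation_profiles(ds)
        expected = sd_a / np.hypot(sd_a, sd_e)
        assert prof.pair("A", "B")[0] == pytest.approx(expected, abs=0.05)

    def test_constant_gene_flagged_undefined(self):
        ds = [dataset(["A", "B"], [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])]
        prof = compute_correlation_profiles(ds)
        assert np.isnan(prof.pair("A", "B")[0])

    def test_mismatched_gene_sets_rejected(self):
        d1 = dataset(["A", "B"], [[1, 2], [3, 4]])
        d2 = dataset(["A", "C"], [[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            compute_correlation_profiles([d1, d2])


class TestCallRule:
    def test_one_high_coefficient_with_positive_majority(self):
        prof = profile_of([0.9, 0.2, 0.3, 0.1, 0.4, 0.2, 0.5])
        calls = call_possible_interactions(prof, 0.832)
        assert {(c.source, c.target, c.positive) for c in calls} == \
            {("A", "B", True), ("B", "A", True)}
        assert all(not c.definite for c in calls)

    def test_negative_majority_blocks_positive_trigger(self):
        prof = profile_of([0.9, -0.2, -0.3, -0.4, -0.1, -0.2, -0.5])
        assert call_possible_interactions(prof, 0.832) == []

    def test_all_zero_profile_silent(self):
        prof = profile_of([0.0] * 7)
        assert call_possible_interactions(prof, 0.5) == []

    def test_conflicting_triggers_resolved_by_majority(self):
        prof = profile_of([0.95, -0.95, 0.4, 0.3, 0.2, -0.1, 0.1])
        calls = call_possible_interactions(prof, 0.9)
        assert calls and all(c.positive for c in calls)
        tie = profile_of([0.95, -0.95, 0.4, -0.4])
        assert call_possible_interactions(tie, 0.9) == []

    def test_undefined_coefficients_excluded_from_majority(self):
        prof = profile_of([0.9, np.nan, np.nan, np.nan, np.nan, 0.2, 0.1])
        assert len(call_possible_interactions(prof, 0.85)) == 2
        all_nan = profile_of([np.nan] * 7)
        assert call_possible_interactions(all_nan, 0.5) == []

    def test_threshold_bounds_enforced(self):
        prof = profile_of([0.5])
        with pytest.raises(ValueError):
            call_possible_interactions(prof, 0.0)
        with pytest.raises(ValueError):
            call_possible_interactions(prof, 1.0)

    def test_lowering_threshold_never_removes_calls(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            genes = ["A", "B", "C"]
            p = CorrelationProfile(genes, 7)
            for i, a in enumerate(genes):
                for b in genes[i + 1:]:
                    p.coefficients[(a, b)] = rng.uniform(-1, 1, size=7)
            hi = {str(c) for c in call_possible_interactions(p, 0.8)}
            lo = {str(c) for c in call_possible_interactions(p, 0.4)}
            assert hi <= lo

    def test_calls_symmetric_in_gene_order(self):
        rng = np.random.default_rng(4)
        p = CorrelationProfile(["A", "B"], 5)
        p.coefficients[("A", "B")] = rng.uniform(-1, 1, size=5)
        calls = call_possible_interactions(p, 0.3)
        pairs = {(c.source, c.target) for c in calls}
        if pairs:
            assert pairs == {("A", "B"), ("B", "A")}


class TestThresholdSearch:
    def base_network(self, genes):
        return AbstractNetwork([Component(g) for g in genes], [])

    def test_empty_constraints_return_grid_maximum(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(1, 50, size=8)
        ds = [dataset(["A", "B"], np.vstack([a, a * rng.uniform(0.9, 1.1, 8)]),
                      label=f"d{i}") for i in range(3)]
        th, net, res = find_max_threshold(ds, self.base_network(["A", "B"]),
                                          [])
        prof = compute_correlation_profiles(ds)
        assert th == max(default_candidate_grid(prof))
        assert res.satisfiable

    def test_unsatisfiable_constraints_name_the_culprit(self):
        from abnet.constraints import Expectation, REACHED, experiment, \
            partial_state
        rng = np.random.default_rng(6)
        a = rng.uniform(1, 50, size=8)
        ds = [dataset(["A", "B"],
                      np.vstack([a, a * rng.uniform(0.8, 1.2, 8)]))]
        # B can never rise: no interactions exist at any threshold that
        # would activate it from an all-low start
        con = experiment("impossible", {}, {"A": False, "B": False},
                         [Expectation(REACHED, partial_state({"B": True}))],
                         bound=4)
        with pytest.raises(ThresholdSearchError) as exc:
            find_max_threshold(ds, self.base_network(["A", "B"]), [con])
        assert exc.value.violated == "impossible"

    def test_induced_network_keeps_definite_edges(self):
        prof = profile_of([0.9, 0.8, 0.7])
        base = AbstractNetwork(
            [Component("A"), Component("B")],
            [Interaction("A", "B", True, True)])
        net = induced_network(base, prof, 0.6)
        # the definite A->B stays definite; only the reverse is added
        kinds = {(i.source, i.target): i.definite for i in net.interactions}
        assert kinds[("A", "B")] is True
        assert kinds[("B", "A")] is False


class TestSyntheticRecovery:
    def pairs(self, edges):
        return {(frozenset((e.source, e.target)), e.positive) for e in edges}

    def test_matching_structure_sharp_recovery(self):
        # no indirect paths: precision and recall approach 1 at low noise
        from abnet.synthetic import sample_ground_truth, simulate_expression
        for seed in (1, 2, 3):
            gt = sample_ground_truth(12, 3, 25, seed=seed, noise_sd=0.02,
                                     structure="matching")
            gt.p_flip = 0.02
            planted = self.pairs(gt.planted_interactions())
            ds = simulate_expression(gt, 7, 100, seed=seed + 10)
            calls = self.pairs(call_possible_interactions(
                compute_correlation_profiles(ds), gt.planted_threshold))
            assert planted == calls

    def test_default_generator_recall_regression(self):
        # multi-regulator genes cap pairwise correlation at 1/sqrt(2), so
        # recall under the calling rule plateaus below 1; frozen floor for
        # the default configuration
        from abnet.synthetic import sample_ground_truth, simulate_expression
        gt = sample_ground_truth(12, 3, 25, seed=7)
        planted = self.pairs(gt.planted_interactions())
        ds = simulate_expression(gt, 7, 20, seed=3)
        calls = self.pairs(call_possible_interactions(
            compute_correlation_profiles(ds), gt.planted_threshold))
        recall = len(planted & calls) / len(planted)
        assert recall >= 0.65

    def test_recall_degrades_with_emission_noise(self):
        from abnet.synthetic import sample_ground_truth, simulate_expression
        gt = sample_ground_truth(12, 3, 25, seed=7)
        planted = self.pairs(gt.planted_interactions())
        recalls = []
        for sd in (0.05, 0.6, 1.2):
            gt.noise_sd = sd
            ds = simulate_expression(gt, 7, 20, seed=3)
            calls = self.pairs(call_possible_interactions(
                compute_correlation_profiles(ds), gt.planted_threshold))
            recalls.append(len(planted & calls) / len(planted))
        assert recalls[0] >= recalls[1] >= recalls[2]
        assert recalls[0] > recalls[2]
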