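import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairedsse import (
    DegenerateDataError,
    NoDataError,
    PairedCounts,
    constrained_nll,
    joint_prob_bounds,
    mle_joint_prob,
    naive_reestimate,
    prevalence_mle,
    reestimate,
    specificity_orientation,
    stratum_cell_probs,
)


from oracles import grid_argmin_nll


class TestConstrainedNLL:
    def test_direct_summation_oracle(self):
        """Independently coded arithmetic for the interim diseased cells."""
        p = 0.79
        expected = -(66 * math.log(p) + 3 * math.log(0.9 - p)
                     + 3 * math.log(0.81 - p) + 10 * math.log(1 - 0.9 - 0.81 + p))
        assert constrained_nll(p, (66, 3, 3, 10), 0.9, 0.81) == pytest.approx(
            expected, abs=1e-12)

    def test_boundary_with_positive_exponent_is_infinite(self):
        # at p1 = 0.71 the fourth factor vanishes but x4 = 10 > 0
        assert constrained_nll(0.71, (66, 3, 3, 10), 0.9, 0.81) == math.inf

    def test_zero_count_factor_contributes_nothing(self):
        # x = (1,0,0,0): only the p1 term remains, minimised at the upper bound
        assert constrained_nll(0.81, (1, 0, 0, 0), 0.9, 0.81) == pytest.approx(
            -math.log(0.81))
        lo_val = constrained_nll(0.71, (1, 0, 0, 0), 0.9, 0.81)
        assert lo_val > -math.log(0.81)


class TestMLE:
    def test_interim_tppr_estimate(self):
        est, boundary = mle_joint_prob((66, 3, 3, 10), 0.9, 0.81)
        assert round(est, 3) == 0.793
        assert not boundary

    def test_interim_tnnr_estimate(self):
        est, boundary = mle_joint_prob((69, 11, 4, 21), 0.8, 0.66)
        assert round(est, 3) == 0.635
        assert not boundary

    def test_counts_proportional_to_feasible_vector(self):
        """Counts drawn exactly proportional to a feasible probability vector
        recover its p1: the score vanishes at 0.75."""
        est, _ = mle_joint_prob((75, 15, 6, 4), 0.9, 0.81)
        assert est == pytest.approx(0.75, abs=1e-8)

    def test_single_both_positive_observation_hits_upper_bound(self):
        est, boundary = mle_joint_prob((1, 0, 0, 0), 0.9, 0.81)
        assert est == pytest.approx(0.81)
        assert boundary

    def test_no_discordant_no_negative_hits_lower_bound(self):
        # x4 = 0 permits the lower boundary where the fourth factor vanishes
        est, boundary = mle_joint_prob((10, 4, 2, 0), 0.9, 0.81)
        assert est == pytest.approx(0.71)
        assert boundary

    def test_all_zero_counts_rejected(self):
        with pytest.raises(NoDataError):
            mle_joint_prob((0, 0, 0, 0), 0.9, 0.81)

    def test_degenerate_interval_single_point(self):
        est, boundary = mle_joint_prob((3, 0, 0, 1), 1.0 - 1e-13, 0.5)
        assert est == pytest.approx(0.5)
        assert boundary

    @settings(max_examples=150, derandomize=True)
    @given(x=st.tuples(*[st.integers(0, 100)] * 4),
           ma=st.floats(0.3, 0.99), mb=st.floats(0.3, 0.99))
    def test_never_leaves_feasible_interval(self, x, ma, mb):
        if sum(x) == 0:
            return
        ma, mb = max(ma, mb), min(ma, mb)
        est, _ = mle_joint_prob(x, ma, mb)
        b = joint_prob_bounds(ma, mb)
        assert b.lower - 1e-9 <= est <= b.upper + 1e-9

    def test_grid_oracle_agreement_random_instances(self):
        rng = np.random.default_rng(20260926)
        for _ in range(100):
            ma = rng.uniform(0.4, 0.99)
            mb = rng.uniform(0.3, ma)
            x = tuple(rng.integers(0, 80, size=4))
            if sum(x) == 0:
                continue
            est, _ = mle_joint_prob(x, ma, mb)
            assert abs(est - grid_argmin_nll(x, ma, mb)) <= 1e-4

    def test_interior_score_stationarity(self):
        """At an interior optimum the score function vanishes."""
        for x, ma, mb in [((66, 3, 3, 10), 0.9, 0.81),
                          ((69, 11, 4, 21), 0.8, 0.66),
                          ((40, 12, 9, 13), 0.85, 0.7)]:
            p, boundary = mle_joint_prob(x, ma, mb)
            assert not boundary
            score = (x[0] / p - x[1] / (ma - p) - x[2] / (mb - p)
                     + x[3] / (1 - ma - mb + p))
            assert abs(score) <= 1e-6 * sum(x)

    @pytest.mark.parametrize("true_p1", [0.71, 0.76, 0.81])
    def test_parameter_recovery(self, true_p1):
        """Mean MLE over seeded multinomial replicates is close to truth."""
        probs = stratum_cell_probs(0.9, 0.81, true_p1)
        rng = np.random.default_rng(1234 + int(true_p1 * 100))
        ests = []
        for _ in range(500):
            x = rng.multinomial(500, probs.as_tuple())
            est, _ = mle_joint_prob(tuple(x), 0.9, 0.81)
            ests.append(est)
        assert abs(np.mean(ests) - true_p1) < 0.005


class TestOrientationAndPrevalence:
    def test_specificity_orientation(self, interim_counts):
        assert specificity_orientation(interim_counts) == (69, 11, 4, 21)

    def test_orientation_preserves_total(self, interim_counts):
        assert sum(specificity_orientation(interim_counts)) == 105

    def test_all_zero_stratum(self):
        c = PairedCounts(1, 1, 1, 1, 0, 0, 0, 0)
        assert specificity_orientation(c) == (0, 0, 0, 0)

    def test_prevalence_is_observed_fraction(self, interim_counts):
        assert prevalence_mle(interim_counts) == pytest.approx(82 / 187)
        assert round(prevalence_mle(interim_counts), 3) == 0.439

    @pytest.mark.parametrize("counts,expected", [
        (PairedCounts(0, 0, 0, 0, 4, 3, 2, 1), 0.0),
        (PairedCounts(4, 3, 2, 1, 4, 3, 2, 1), 0.5),
    ])
    def test_prevalence_edge_cases(self, counts, expected):
        assert prevalence_mle(counts) == expected

    def test_empty_table_rejected(self):
        with pytest.raises(NoDataError):
            prevalence_mle(PairedCounts(0, 0, 0, 0, 0, 0, 0, 0))


class TestReestimate:
    def test_application_revisited_roundup(self, interim_counts, app_hypotheses):
        r = reestimate(interim_counts, app_hypotheses, rounding="up")
        assert r.n_specificity == 136
        assert r.n_sensitivity == 275
        assert r.n_overall == 275
        assert r.prevalence_hat == pytest.approx(82 / 187)
        assert not r.already_sufficient

    def test_design_prevalence_option(self, interim_counts, app_hypotheses):
        r = reestimate(interim_counts, app_hypotheses,
                       prevalence_source="design")
        assert r.prevalence_hat == 0.47

    def test_overall_is_max_including_interim(self, app_hypotheses):
        # strong dependence + large interim: re-estimates below interim clamp
        c = PairedCounts(400, 45, 0, 50, 300, 0, 70, 630)
        r = reestimate(c, app_hypotheses)
        assert r.n_overall == max(r.n_sensitivity, r.n_specificity, r.interim_n)
        assert r.already_sufficient == (
            r.interim_n >= max(r.n_sensitivity, r.n_specificity))

    def test_degenerate_stratum_rejected(self, app_hypotheses):
        with pytest.raises(DegenerateDataError):
            reestimate(PairedCounts(1, 1, 1, 1, 0, 0, 0, 0), app_hypotheses)

    def test_monotone_pipeline(self, sim_hypotheses):
        """A larger TPPR MLE never yields a larger re-estimated size."""
        sizes = []
        for n_a in (55, 60, 65, 70):
            c = PairedCounts(n_a, 74 - n_a - 4, 4, 4, 20, 5, 10, 65)
            r = reestimate(c, sim_hypotheses, prevalence_source="design")
            sizes.append((r.tppr_mle, r.n_sensitivity))
        sizes.sort()
        ns = [n for _, n in sizes]
        assert ns == sorted(ns, reverse=True)


class TestNaiveReestimate:
    def test_two_decimal_plugin_matches_reported_values(
            self, interim_counts, app_hypotheses):
        r = naive_reestimate(interim_counts, app_hypotheses, rate_precision=2)
        assert r.n_sensitivity == 242
        assert r.n_specificity == 100
        assert r.sensitivity_feasible and r.specificity_feasible

    def test_full_precision_differs_from_rounded_report(
            self, interim_counts, app_hypotheses):
        r = naive_reestimate(interim_counts, app_hypotheses)
        assert r.tppr_hat == pytest.approx(66 / 82)
        assert r.n_sensitivity != 242  # rounding the rates matters

    def test_observed_equal_to_worst_case_reproduces_plan(self, app_hypotheses):
        # observed rates exactly at the hypothesised worst case
        c = PairedCounts(71, 19, 10, 0, 0, 20, 34, 46)
        r = naive_reestimate(c, app_hypotheses)
        assert r.tppr_hat == pytest.approx(0.71)
        assert r.tnnr_hat == pytest.approx(0.46)
        # prevalence differs from 0.47, so compare against the formula at pi-hat
        from pairedsse import DesignHypotheses, sensitivity_sample_size
        h2 = DesignHypotheses(alpha=0.05, beta=0.2, tpr_a=0.9, tpr_b=0.81,
                              tnr_a=0.8, tnr_b=0.66,
                              prevalence=r.prevalence_hat)
        assert r.n_sensitivity == sensitivity_sample_size(h2, r.tppr_hat)

    def test_infeasible_plugin_flagged_not_suppressed(self, app_hypotheses):
        # observed TPPR above both hypothesised sensitivities
        c = PairedCounts(86, 2, 2, 10, 21, 4, 11, 64)
        r = naive_reestimate(c, app_hypotheses)
        assert not r.sensitivity_feasible
        assert r.n_sensitivity < 0
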