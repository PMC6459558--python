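import math

import numpy as np
import pytest
from scipy.linalg import expm

from metanet import (
    Cohort,
    GrowthParams,
    MetastaticState,
    RateParameters,
    build_generator,
    enumerate_reachable_states,
    fit_mle,
    log_likelihood,
    parametric_bootstrap,
    sample_cohort,
    seed_soil_ratios,
    stage_to_time,
)
from metanet.synthetic import CohortDesign

from conftest import OVARIAN_THETA, TONGUE_THETA


class TestStageToTime:
    def test_linear_consecutive_integers(self):
        stm = stage_to_time("linear", ["T1", "T2", "T3", "T4"])
        assert stm.times == (1.0, 2.0, 3.0, 4.0)

    def test_linear_nine_stages(self):
        labels = ["T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3a", "T3b", "T3c"]
        stm = stage_to_time("linear", labels)
        assert stm.times == tuple(float(k) for k in range(1, 10))

    def test_exponential_growth_default_times(self):
        stm = stage_to_time("exponential_growth", ["T1", "T2", "T3", "T4"])
        assert [round(t, 2) for t in stm.times] == [3.17, 3.50, 3.69, 3.83]

    def test_exponential_growth_inversion(self):
        g = GrowthParams(stage_radii=(25e-6 * math.exp(GrowthParams.alpha / 3),))
        stm = stage_to_time("exponential_growth", ["T1"], growth=g)
        assert stm.times[0] == pytest.approx(1.0)

    def test_default_alpha_per_year(self):
        assert GrowthParams().alpha == pytest.approx(365 * math.log(2) / 40)

    def test_nonincreasing_radii_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            GrowthParams(stage_radii=(0.02, 0.02))

    def test_radius_below_initial_rejected(self):
        with pytest.raises(ValueError, match="initial radius"):
            GrowthParams(stage_radii=(1e-6, 2e-6))

    def test_radius_count_mismatch(self):
        with pytest.raises(ValueError, match="one stage radius"):
            stage_to_time("exponential_growth", ["T1", "T2"], growth=GrowthParams())

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            stage_to_time("quadratic", ["T1"])

    def test_unknown_stage_label(self, linear_map):
        with pytest.raises(KeyError, match="T9"):
            linear_map.time_of("T9")


def _single_site_cohort(states_and_stages):
    return Cohort(
        patients=tuple(
            (stage, MetastaticState.from_string(s)) for stage, s in states_and_stages
        ),
        sites=("A",),
    )


class TestLogLikelihood:
    def test_single_negative_patient_closed_form(self, single_site_net):
        lam, tau = 0.25, 3.0
        space = enumerate_reachable_states(single_site_net)
        stm = stage_to_time("linear", ["T1", "T2", "T3"])
        cohort = _single_site_cohort([("T3", "0")])
        ll = log_likelihood(cohort, single_site_net, space, RateParameters({"lam": lam}), stm)
        assert ll == pytest.approx(-lam * tau, abs=1e-9)

    def test_zero_rates_metastasis_free_cohort(self, tongue_net, tongue_space, linear_map):
        cohort = Cohort(
            patients=tuple(
                (stage, MetastaticState.from_string("0000"))
                for stage in ("T1", "T2", "T3", "T4")
            ),
            sites=tongue_net.sites,
        )
        theta = RateParameters({s: 0.0 for s in tongue_net.rate_symbols})
        assert log_likelihood(cohort, tongue_net, tongue_space, theta, linear_map) == 0.0

    def test_five_patients_match_expm_oracle(
        self, tongue_net, tongue_space, tongue_theta, linear_map
    ):
        patients = [
            ("T1", "0000"),
            ("T2", "1000"),
            ("T2", "1100"),
            ("T3", "0110"),
            ("T4", "1111"),
        ]
        cohort = Cohort(
            patients=tuple((st, MetastaticState.from_string(s)) for st, s in patients),
            sites=tongue_net.sites,
        )
        ll = log_likelihood(cohort, tongue_net, tongue_space, tongue_theta, linear_map)
        # independent product of state probabilities via direct expm
        q = build_generator(tongue_net, tongue_space, tongue_theta)
        p0 = np.zeros(tongue_space.n_states)
        p0[0] = 1.0
        expected = 0.0
        for stage, s in patients:
            tau = linear_map.time_of(stage)
            expected += math.log((expm(q * tau) @ p0)[tongue_space.index(s)])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_zero_probability_state_returns_neginf(self, tongue_net, tongue_space, linear_map):
        # lambda_I = 0 and phi-free: state 1000 unreachable dynamically
        theta = RateParameters({s: 0.0 for s in tongue_net.rate_symbols})
        cohort = Cohort(
            patients=(("T1", MetastaticState.from_string("1000")),),
            sites=tongue_net.sites,
        )
        assert log_likelihood(cohort, tongue_net, tongue_space, theta, linear_map) == -math.inf
        with pytest.raises(FloatingPointError):
            log_likelihood(
                cohort, tongue_net, tongue_space, theta, linear_map, on_zero="error"
            )

    def test_unreachable_state_rejected(self, tongue_net, tongue_space, tongue_theta, linear_map):
        cohort = Cohort(
            patients=(("T1", MetastaticState.from_string("0001")),),
            sites=tongue_net.sites,
        )
        with pytest.raises(ValueError, match="unreachable"):
            log_likelihood(cohort, tongue_net, tongue_space, tongue_theta, linear_map)

    def test_empty_cohort_rejected(self, tongue_net, tongue_space, tongue_theta, linear_map):
        with pytest.raises(ValueError, match="empty"):
            log_likelihood(
                Cohort(patients=(), sites=tongue_net.sites),
                tongue_net,
                tongue_space,
                tongue_theta,
                linear_map,
            )

    def test_invariant_under_patient_reordering(
        self, tongue_net, tongue_space, tongue_theta, linear_map
    ):
        design = CohortDesign(
            {"T1": 10, "T2": 10, "T3": 10, "T4": 10},
            tongue_theta,
            linear_map,
            seed=3,
        )
        cohort = sample_cohort(tongue_net, tongue_space, design)
        shuffled = Cohort(
            patients=tuple(reversed(cohort.patients)), sites=cohort.sites
        )
        a = log_likelihood(cohort, tongue_net, tongue_space, tongue_theta, linear_map)
        b = log_likelihood(shuffled, tongue_net, tongue_space, tongue_theta, linear_map)
        assert a == pytest.approx(b, rel=1e-12)

    def test_invariant_under_site_permutation(self, tongue_net, tongue_theta, linear_map):
        space = enumerate_reachable_states(tongue_net)
        design = CohortDesign(
            {"T1": 15, "T4": 15}, tongue_theta, linear_map, seed=5
        )
        cohort = sample_cohort(tongue_net, space, design)
        order = [3, 1, 0, 2]
        pnet = tongue_net.permuted(order)
        pspace = enumerate_reachable_states(pnet)
        pcohort = Cohort(
            patients=tuple(
                (
                    stage,
                    MetastaticState(
                        tuple(state.status[tongue_net.site_index(s)] for s in pnet.sites)
                    ),
                )
                for stage, state in cohort.patients
            ),
            sites=pnet.sites,
        )
        a = log_likelihood(cohort, tongue_net, space, tongue_theta, linear_map)
        b = log_likelihood(pcohort, pnet, pspace, tongue_theta, linear_map)
        assert a == pytest.approx(b, rel=1e-10)


class TestFitMle:
    def test_metastasis_free_cohort_drives_rates_to_zero(self, tongue_net, linear_map):
        cohort = Cohort(
            patients=tuple(
                (stage, MetastaticState.from_string("0000"))
                for stage in ("T1", "T2", "T3", "T4") * 5
            ),
            sites=tongue_net.sites,
        )
        fit = fit_mle(cohort, tongue_net, linear_map)
        # only the primary inflows enter P(all-negative); the phi rates are
        # flat directions of the likelihood and stay wherever they started
        for sym in ("lambda_I", "lambda_II", "lambda_III"):
            assert fit.theta_hat.values[sym] < 1e-3
        assert fit.log_likelihood > -0.1

    def test_recovery_smoke(self, tongue_net, tongue_space, tongue_theta, linear_map):
        design = CohortDesign(
            {s: 750 for s in ("T1", "T2", "T3", "T4")}, tongue_theta, linear_map, seed=11
        )
        cohort = sample_cohort(tongue_net, tongue_space, design)
        fit = fit_mle(cohort, tongue_net, linear_map, space=tongue_space)
        assert fit.converged
        # well-identified rates should land near the truth
        for sym in ("lambda_II", "phi_II"):
            assert fit.theta_hat.values[sym] == pytest.approx(
                TONGUE_THETA[sym], rel=0.35
            )

    def test_fit_is_local_optimum(self, tongue_net, tongue_space, tongue_theta, linear_map):
        design = CohortDesign(
            {s: 500 for s in ("T1", "T2", "T3", "T4")}, tongue_theta, linear_map, seed=13
        )
        cohort = sample_cohort(tongue_net, tongue_space, design)
        fit = fit_mle(cohort, tongue_net, linear_map, space=tongue_space)
        best = fit.log_likelihood
        for sym in tongue_net.rate_symbols:
            for factor in (0.9, 1.1):
                perturbed = dict(fit.theta_hat.values)
                perturbed[sym] *= factor
                ll = log_likelihood(
                    cohort,
                    tongue_net,
                    tongue_space,
                    RateParameters(perturbed),
                    linear_map,
                )
                assert ll <= best + 1e-6

    def test_deterministic_given_start(self, tongue_net, tongue_space, tongue_theta, linear_map):
        design = CohortDesign({"T2": 100, "T4": 100}, tongue_theta, linear_map, seed=17)
        cohort = sample_cohort(tongue_net, tongue_space, design)
        f1 = fit_mle(cohort, tongue_net, linear_map, space=tongue_space)
        f2 = fit_mle(cohort, tongue_net, linear_map, space=tongue_space)
        assert f1.theta_hat.values == f2.theta_hat.values

    def test_multistart_reports_best(self, tongue_net, tongue_space, tongue_theta, linear_map):
        design = CohortDesign({"T2": 60, "T4": 60}, tongue_theta, linear_map, seed=19)
        cohort = sample_cohort(tongue_net, tongue_space, design)
        plain = fit_mle(cohort, tongue_net, linear_map, space=tongue_space)
        multi = fit_mle(
            cohort, tongue_net, linear_map, space=tongue_space, multistart=3, seed=1
        )
        assert multi.log_likelihood >= plain.log_likelihood - 1e-6

    def test_empty_cohort_rejected(self, tongue_net, linear_map):
        with pytest.raises(ValueError, match="empty"):
            fit_mle(Cohort(patients=(), sites=tongue_net.sites), tongue_net, linear_map)


class TestParametricBootstrap:
    def test_intervals_are_ordered(self, tongue_net, tongue_space, tongue_theta, linear_map):
        design = CohortDesign(
            {s: 35 for s in ("T1", "T2", "T3", "T4")}, tongue_theta, linear_map, seed=23
        )
        cohort = sample_cohort(tongue_net, tongue_space, design)
        fit = fit_mle(cohort, tongue_net, linear_map, space=tongue_space)
        intervals = parametric_bootstrap(
            fit, cohort, tongue_net, linear_map, space=tongue_space, n_replicates=12, seed=1
        )
        assert set(intervals) == set(tongue_net.rate_symbols)
        for lo, hi in intervals.values():
            assert 0 <= lo <= hi

    def test_rare_positives_collapse_lower_quantile(self, single_site_net):
        # with very few expected positives some replicates see none at all,
        # so the refit collapses to ~0 and the lower quantile is near zero
        lam = 0.01
        space = enumerate_reachable_states(single_site_net)
        stm = stage_to_time("linear", ["T1", "T2"])
        design = CohortDesign(
            {"T1": 25, "T2": 25}, RateParameters({"lam": lam}), stm, seed=2
        )
        cohort = sample_cohort(single_site_net, space, design)
        fit = fit_mle(cohort, single_site_net, stm, space=space)
        intervals = parametric_bootstrap(
            fit, cohort, single_site_net, stm, space=space, n_replicates=30, seed=3
        )
        lo, hi = intervals["lam"]
        assert lo < 1e-6
        assert hi > lo

    def test_too_few_replicates_rejected(self, tongue_net, linear_map, tongue_theta):
        fit_stub = fit_mle(
            Cohort(
                patients=(("T1", MetastaticState.from_string("0000")),),
                sites=tongue_net.sites,
            ),
            tongue_net,
            linear_map,
        )
        with pytest.raises(ValueError, match="replicates"):
            parametric_bootstrap(
                fit_stub,
                Cohort(
                    patients=(("T1", MetastaticState.from_string("0000")),),
                    sites=tongue_net.sites,
                ),
                tongue_net,
                linear_map,
                n_replicates=1,
            )


class TestSeedSoilRatios:
    def test_ovarian_published_ratios(self, ovarian_net):
        theta = RateParameters(OVARIAN_THETA)
        flows = {"liver": 0.065, "bone": 0.05, "brain": 0.012}
        ratios = seed_soil_ratios(theta, flows, ovarian_net)
        assert round(ratios["liver"], 2) == 1.42
        assert round(ratios["bone"], 2) == 0.30
        assert round(ratios["brain"], 2) == 0.33

    def test_rate_equal_to_flow_gives_unity(self, ovarian_net):
        theta = RateParameters({**OVARIAN_THETA, "phi_2": 0.065})
        assert seed_soil_ratios(theta, {"liver": 0.065}, ovarian_net)["liver"] == pytest.approx(1.0)

    def test_zero_flow_rejected(self, ovarian_net):
        with pytest.raises(ValueError, match="relative flow"):
            seed_soil_ratios(RateParameters(OVARIAN_THETA), {"liver": 0.0}, ovarian_net)

    def test_ambiguous_inflow_rejected(self, ovarian_net):
        # lung has both a primary edge and the LN->lung edge
        with pytest.raises(ValueError, match="inbound"):
            seed_soil_ratios(RateParameters(OVARIAN_THETA), {"lung": 0.5}, ovarian_net)
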