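"""Risk engine: FRAX-like generative function and cohort population risk."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoburden import (
    FractureType,
    ManagementRates,
    RiskProfile,
    cap_probabilities,
    default_risk_function_params,
    frax_like_risk,
    population_risk,
)

TYPES = list(FractureType)


class TestFraxLikeRisk:
    def test_reference_point_recovers_baseline_rates(self):
        params = default_risk_function_params()
        out = frax_like_risk(70.0, 0.0, [0, 0, 0], params)
        for ft in TYPES:
            assert out[ft] == pytest.approx(params.baseline_rate[ft], abs=1e-12)

    def test_risk_increases_with_age_and_decreasing_t_score(self):
        params = default_risk_function_params()
        younger = frax_like_risk(70.0, -1.0, [0, 0, 0], params)
        older = frax_like_risk(80.0, -1.0, [0, 0, 0], params)
        denser = frax_like_risk(70.0, 0.0, [0, 0, 0], params)
        for ft in TYPES:
            assert older[ft] > younger[ft]
            assert younger[ft] > denser[ft]

    def test_three_covariate_case_matches_hand_formula(self):
        """Independent re-evaluation of the documented functional form."""
        params = default_risk_function_params()
        age, t = 83.0, -2.4
        flags = [1, 0, 1]
        out = frax_like_risk(age, t, flags, params)
        for ft in TYPES:
            hazard = (
                -math.log(1.0 - params.baseline_rate[ft])
                * math.exp(params.age_slope[ft] * (age - 70.0))
                * params.t_score_gradient[ft] ** (-t)
                * params.crf_multipliers[0]
                * params.crf_multipliers[2]
            )
            assert out[ft] == pytest.approx(1.0 - math.exp(-hazard), rel=1e-12)

    def test_vectorised_evaluation_matches_scalar(self):
        params = default_risk_function_params()
        ages = np.array([71.0, 85.0])
        ts = np.array([-1.0, -3.0])
        flags = np.array([[1, 0, 0], [0, 1, 1]])
        vec = frax_like_risk(ages, ts, flags, params)
        for i in range(2):
            scalar = frax_like_risk(ages[i], ts[i], flags[i], params)
            for ft in TYPES:
                assert vec[ft][i] == pytest.approx(np.ravel(scalar[ft])[0])

    def test_age_below_70_is_a_domain_error(self):
        with pytest.raises(ValueError, match="70"):
            frax_like_risk(65.0, 0.0, [0, 0, 0], default_risk_function_params())


def test_cap_probabilities_clips_and_preserves():
    risk = {FractureType.HIP: 0.5, FractureType.VERTEBRAL: 0.2, FractureType.NHNV: 1.3}
    capped = cap_probabilities(risk)
    assert capped[FractureType.NHNV] == 1.0
    assert capped[FractureType.HIP] == 0.5
    assert cap_probabilities({FractureType.HIP: -0.1})[FractureType.HIP] == 0.0
    ok = {ft: 0.1 for ft in TYPES}
    assert cap_probabilities(ok) == ok


def _profile(base=0.01, share=0.3, mult=4.0):
    return RiskProfile(
        baseline={ft: base for ft in TYPES}, at_risk_share=share, at_risk_multiplier=mult
    )


def _rr(value):
    return {ft: value for ft in TYPES}


def _enumerate_cells(profile, rates, rr, efficacy=0.0):
    """Brute-force oracle: weighted sum over stratum × treated × adherent cells."""
    s, tau, alpha = profile.at_risk_share, rates.treatment_rate, rates.adherence_rate
    w_at = min(tau, s)
    w_nt = tau - w_at
    out = {}
    for ft in TYPES:
        total = 0.0
        for at_risk, weight_stratum, treated_w in (
            (True, s, w_at), (False, 1 - s, w_nt),
        ):
            p = profile.stratum_probability(ft, at_risk)
            untreated_w = weight_stratum - treated_w
            total += untreated_w * p
            total += treated_w * alpha * p * rr[ft]
            total += treated_w * (1 - alpha) * p * (1 - efficacy * (1 - rr[ft]))
        out[ft] = total
    return out


class TestPopulationRisk:
    def test_no_treatment_identity(self):
        profile = _profile()
        rates = ManagementRates(assessment_rate=0.25, treatment_rate=0.0, adherence_rate=0.4)
        out = population_risk(profile, rates, _rr(0.6))
        expected = 0.3 * 0.04 + 0.7 * 0.01
        for ft in TYPES:
            assert out[ft] == pytest.approx(expected)

    def test_single_stratum_full_treatment_halves_risk(self):
        profile = _profile(base=0.02, share=0.0, mult=1.0)
        rates = ManagementRates(assessment_rate=1.0, treatment_rate=1.0, adherence_rate=1.0)
        out = population_risk(profile, rates, _rr(0.5))
        for ft in TYPES:
            assert out[ft] == pytest.approx(0.01)

    def test_two_strata_matches_cell_enumeration_oracle(self):
        profile = _profile(base=0.01, share=0.3, mult=4.0)
        rates = ManagementRates(assessment_rate=0.25, treatment_rate=0.2, adherence_rate=0.4)
        out = population_risk(profile, rates, _rr(0.62))
        oracle = _enumerate_cells(profile, rates, _rr(0.62))
        for ft in TYPES:
            assert out[ft] == pytest.approx(oracle[ft], rel=1e-12)

    @settings(deadline=None)
    @given(
        base=st.floats(1e-4, 0.2), share=st.floats(0, 1), mult=st.floats(1, 5),
        tau=st.floats(0, 1), alpha=st.floats(0, 1), rr=st.floats(0.05, 1.0),
        eff=st.floats(0, 1),
    )
    def test_randomised_agreement_with_oracle_and_monotonicity(
        self, base, share, mult, tau, alpha, rr, eff
    ):
        profile = _profile(base=base, share=share, mult=mult)
        rates = ManagementRates(assessment_rate=0.25, treatment_rate=tau, adherence_rate=alpha)
        out = population_risk(profile, rates, _rr(rr), nonadherent_efficacy=eff)
        oracle = _enumerate_cells(profile, rates, _rr(rr), efficacy=eff)
        untreated = population_risk(
            profile,
            ManagementRates(assessment_rate=0.25, treatment_rate=0.0, adherence_rate=alpha),
            _rr(rr),
        )
        for ft in TYPES:
            assert out[ft] == pytest.approx(min(max(oracle[ft], 0.0), 1.0), rel=1e-9, abs=1e-12)
            assert out[ft] <= untreated[ft] + 1e-12
            assert 0.0 <= out[ft] <= 1.0

    def test_treatment_spillover_beyond_at_risk_stratum(self):
        profile = _profile(base=0.01, share=0.1, mult=4.0)
        rr = _rr(0.5)
        rates_lo = ManagementRates(assessment_rate=0.25, treatment_rate=0.1, adherence_rate=1.0)
        rates_hi = ManagementRates(assessment_rate=0.25, treatment_rate=0.5, adherence_rate=1.0)
        lo, hi = population_risk(profile, rates_lo, rr), population_risk(profile, rates_hi, rr)
        for ft in TYPES:
            assert hi[ft] < lo[ft]  # extra treatment beyond the stratum still helps

    def test_combined_rates_dominate_single_levers(self, fixture_params):
        from osteoburden import GlobalAssumptions, InterventionSpec, Lever, apply_intervention

        profile = _profile()
        for params in fixture_params.values():
            outs = {}
            for lever in Lever:
                rates = apply_intervention(
                    InterventionSpec(lever=lever, improvement=0.5),
                    GlobalAssumptions(), params,
                )
                outs[lever] = population_risk(profile, rates, params.treatment_rr)
            for ft in TYPES:
                assert outs[Lever.COMBINED][ft] <= min(
                    outs[Lever.ASSESSMENT][ft], outs[Lever.ADHERENCE][ft]
                ) + 1e-15

    def test_rr_of_one_makes_treatment_burden_neutral(self):
        profile = _profile()
        rr = _rr(1.0)
        a = population_risk(
            profile,
            ManagementRates(assessment_rate=0.25, treatment_rate=0.0, adherence_rate=0.4),
            rr,
        )
        b = population_risk(
            profile,
            ManagementRates(assessment_rate=0.5, treatment_rate=0.9, adherence_rate=0.9),
            rr,
        )
        assert a == b
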