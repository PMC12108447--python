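"""PK engine: elimination-rate estimation, profile reconstruction, free
fraction, and time-above-threshold target attainment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betalactam_tdm.pk import (
    DRUG_PROFILES,
    ConcentrationSample,
    InfusionMode,
    PKError,
    Regimen,
    SampleKind,
    UnknownDrugError,
    concentration_at,
    continuous_attainment,
    estimate_elimination_rate,
    fraction_time_above,
    free_concentration,
    predict_steady_state,
    reconstruct_profile,
    target_attainment,
)
from oracles import grid_fraction_time_above


def sample(t, c, kind=SampleKind.RANDOM):
    return ConcentrationSample(t, c, kind)


class TestEliminationRate:
    def test_log_ratio_formula(self):
        ke, t_half = estimate_elimination_rate(sample(2, 40), sample(8, 10))
        assert ke == pytest.approx(math.log(4) / 6, rel=1e-12)
        assert t_half == pytest.approx(3.0, abs=0.01)
        # cross-check: the estimated ke actually maps C1 onto C2
        assert 40 * math.exp(-ke * 6) == pytest.approx(10, rel=1e-12)

    @given(t_half=st.floats(0.5, 12.0))
    @settings(max_examples=30, deadline=None)
    def test_half_life_definition(self, t_half):
        ke, est = estimate_elimination_rate(sample(2, 40), sample(2 + t_half, 20))
        assert ke == pytest.approx(math.log(2) / t_half, rel=1e-9)
        assert est == pytest.approx(t_half, rel=1e-9)

    def test_flat_and_rising_concentrations_rejected(self):
        with pytest.raises(PKError, match="rising or flat"):
            estimate_elimination_rate(sample(2, 30), sample(8, 30))
        with pytest.raises(PKError, match="rising or flat"):
            estimate_elimination_rate(sample(2, 10), sample(8, 40))

    def test_time_ordering_enforced(self):
        with pytest.raises(PKError, match="later"):
            estimate_elimination_rate(sample(8, 40), sample(2, 10))


class TestReconstructProfile:
    regimen = Regimen("cefepime", 2000, 8, 0.5)
    peak = sample(1.5, 60, SampleKind.PEAK)
    trough = sample(8, 12, SampleKind.TROUGH)

    def test_cefepime_worked_example(self):
        est = reconstruct_profile(self.regimen, self.peak, self.trough)
        ke = math.log(5) / 6.5
        assert est.ke_per_h == pytest.approx(ke, rel=1e-12)
        assert est.cmax_ss_total == pytest.approx(60 * math.exp(ke), rel=1e-6)
        assert est.cmin_ss_total == 12

    def test_profile_reproduces_both_measurements(self):
        # forward-simulating the reconstructed profile must pass through the
        # measured samples within 0.1 mg/L
        est = reconstruct_profile(self.regimen, self.peak, self.trough)
        assert concentration_at(est, self.regimen, 1.5) == pytest.approx(60, abs=0.1)
        assert concentration_at(est, self.regimen, 7.999) == pytest.approx(12, abs=0.1)

    def test_peak_at_end_of_infusion_needs_no_extrapolation(self):
        est = reconstruct_profile(self.regimen, sample(0.5, 60, SampleKind.PEAK),
                                  self.trough)
        assert est.cmax_ss_total == pytest.approx(60)

    def test_trough_consistent_with_decay(self):
        est = reconstruct_profile(self.regimen, self.peak, self.trough)
        predicted = est.cmax_ss_total * math.exp(-est.ke_per_h * (8 - 0.5))
        # measured trough at tau is the same as decaying Cmax over tau - tinf
        assert predicted == pytest.approx(
            60 * math.exp(-est.ke_per_h * 6.5), rel=1e-9)

    def test_peak_inside_infusion_rejected(self):
        with pytest.raises(PKError, match="before the end"):
            reconstruct_profile(self.regimen, sample(0.2, 60, SampleKind.PEAK),
                                self.trough)

    @pytest.mark.parametrize("cl,v,dose,tau,tinf", [
        (7.5, 20.0, 2000, 8, 0.5),
        (3.0, 25.0, 1000, 12, 4.0),
        (15.0, 30.0, 4000, 6, 0.5),
    ])
    def test_noise_free_round_trip(self, cl, v, dose, tau, tinf):
        """Simulated peak (1 h post-infusion) and trough recover ke, CL, V
        within 1% when noise-free."""
        regimen = Regimen("cefepime", dose, tau, tinf,
                          Regimen.classify_mode(tinf, tau))
        truth = predict_steady_state(cl, v, regimen)
        peak = sample(tinf + 1, concentration_at(truth, regimen, tinf + 1),
                      SampleKind.PEAK)
        trough = sample(tau - 1e-9, concentration_at(truth, regimen, tau - 1e-9),
                        SampleKind.TROUGH)
        est = reconstruct_profile(regimen, peak, trough)
        assert est.ke_per_h == pytest.approx(cl / v, rel=0.01)
        assert est.clearance_l_h == pytest.approx(cl, rel=0.01)
        assert est.volume_l == pytest.approx(v, rel=0.01)


class TestFreeConcentration:
    @pytest.mark.parametrize("drug,total,expected", [
        ("meropenem", 10, 9.8),       # 2% bound
        ("ceftriaxone", 100, 10.0),   # 90% bound
        ("cefepime", 50, 40.0),       # 20% bound
        ("oxacillin", 40, 2.0),       # 95% bound
        ("cefepime", 0, 0.0),
    ])
    def test_binding_fractions(self, drug, total, expected):
        assert free_concentration(total, drug) == pytest.approx(expected)

    def test_unknown_drug_is_configuration_error(self):
        with pytest.raises(UnknownDrugError, match="imipenem"):
            free_concentration(10, "imipenem")

    @given(a=st.floats(0, 500), b=st.floats(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_linear_and_order_preserving(self, a, b):
        fa, fb = free_concentration(a, "cefepime"), free_concentration(b, "cefepime")
        assert free_concentration(a + b, "cefepime") == pytest.approx(fa + fb)
        if a < b:
            assert fa <= fb


class TestFractionTimeAbove:
    regimen = Regimen("cefepime", 2000, 8, 0.5)
    est = reconstruct_profile(regimen, sample(1.5, 60, SampleKind.PEAK),
                              sample(8, 12, SampleKind.TROUGH))

    def test_cefepime_example_against_grid(self, cefepime):
        # threshold 32 mg/L = 4 x MIC 8; free peak ~61.5, free trough 9.6
        pct = fraction_time_above(self.est, self.regimen, cefepime, 32.0)
        oracle = grid_fraction_time_above(
            self.est.ke_per_h, self.est.cmax_ss_total, self.est.cmin_ss_total,
            8, 0.5, 0.8, 32.0)
        assert pct == pytest.approx(oracle, abs=0.5)
        # ~2.93 h above 32 mg/L out of the 8 h interval
        assert pct == pytest.approx(36.6, abs=1.0)

    def test_never_crossing_extremes(self, cefepime):
        assert fraction_time_above(self.est, self.regimen, cefepime, 5.0) == 100.0
        assert fraction_time_above(self.est, self.regimen, cefepime, 500.0) == 0.0

    @given(
        ke=st.floats(0.05, 1.5),
        cl=st.floats(1.0, 20.0),
        tau=st.sampled_from([6.0, 8.0, 12.0, 24.0]),
        tinf=st.sampled_from([0.5, 1.0, 3.0, 4.0]),
        threshold=st.floats(0.5, 200.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_closed_form_matches_grid(self, ke, cl, tau, tinf, threshold):
        regimen = Regimen("cefepime", 2000, tau, tinf,
                          Regimen.classify_mode(tinf, tau))
        est = predict_steady_state(cl, cl / ke, regimen)
        pct = fraction_time_above(est, regimen, "cefepime", threshold)
        oracle = grid_fraction_time_above(
            ke, est.cmax_ss_total, est.cmin_ss_total, tau, tinf, 0.8, threshold)
        assert pct == pytest.approx(oracle, abs=0.5)

    @given(ke=st.floats(0.05, 1.5), cl=st.floats(1.0, 20.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, ke, cl):
        regimen = Regimen("cefepime", 2000, 8, 0.5)
        est = predict_steady_state(cl, cl / ke, regimen)
        pcts = [fraction_time_above(est, regimen, "cefepime", thr)
                for thr in (1, 2, 4, 8, 16, 32, 64)]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))


class TestTargetAttainment:
    regimen = Regimen("cefepime", 2000, 8, 0.5)
    est = reconstruct_profile(regimen, sample(1.5, 60, SampleKind.PEAK),
                              sample(8, 12, SampleKind.TROUGH))

    def test_cefepime_example_mic8(self, cefepime):
        att = target_attainment(self.est, self.regimen, cefepime, 8.0)
        assert att.fcmin_over_mic == pytest.approx(1.2)   # 9.6 / 8
        assert att.ft_above[1] == 100.0                   # fCmin > MIC
        values = [att.ft_above[h] for h in (1, 2, 3, 4, 5)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_free_trough_at_mic_boundary_attained(self, cefepime):
        mic = self.est.cmin_ss_total * 0.8  # free trough == MIC exactly
        att = target_attainment(self.est, self.regimen, cefepime, mic)
        assert att.fcmin_over_mic == pytest.approx(1.0)
        assert att.ft_above[1] == 100.0

    def test_fcmin_ratio_inverse_in_mic(self, cefepime):
        a1 = target_attainment(self.est, self.regimen, cefepime, 4.0)
        a2 = target_attainment(self.est, self.regimen, cefepime, 8.0)
        assert a1.fcmin_over_mic == pytest.approx(2 * a2.fcmin_over_mic)

    def test_invalid_mic(self, cefepime):
        with pytest.raises(ValueError, match="MIC"):
            target_attainment(self.est, self.regimen, cefepime, 0.0)


class TestContinuousAttainment:
    def test_step_function_at_boundary(self):
        # free Css exactly 2 x MIC: above MIC all interval, not above 2 x MIC
        s = [sample(4.0, 20.0)]
        att = continuous_attainment(s, "meropenem", 20.0 * 0.98 / 2)
        assert att.ft_above[1] == 100.0
        assert att.ft_above[2] == 0.0
        assert att.fcmin_over_mic == pytest.approx(2.0)

    def test_mean_of_samples(self):
        att = continuous_attainment([sample(2, 30), sample(9, 50)],
                                    "piperacillin", 16.0)
        assert att.fcmin_over_mic == pytest.approx(40 * 0.7 / 16)
        assert att.ft_above[1] == 100.0  # free Css 28 > 16

    def test_subtherapeutic_plateau(self):
        att = continuous_attainment([sample(2, 10)], "ceftriaxone", 4.0)
        assert all(v == 0.0 for v in att.ft_above.values())

    def test_empty_sample_list(self):
        with pytest.raises(PKError, match="random sample"):
            continuous_attainment([], "meropenem", 1.0)


def test_drug_table_binding_fractions_complete():
    bound = {"ampicillin": 0.20, "aztreonam": 0.56, "cefazolin": 0.80,
             "cefepime": 0.20, "ceftriaxone": 0.90, "meropenem": 0.02,
             "oxacillin": 0.95, "piperacillin": 0.30}
    assert set(DRUG_PROFILES) == set(bound)
    for drug, b in bound.items():
        assert DRUG_PROFILES[drug].fraction_unbound == pytest.approx(1 - b)
        assert DRUG_PROFILES[drug].dose_menu  # non-empty recommendation menu
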