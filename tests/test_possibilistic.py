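"""Possibilistic measurement shaping, consistency LPs and interval estimates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pichia_mfa.possibilistic import (
    MeasurementSet,
    estimate_excluded_flux,
    flux_interval,
    max_possibility,
    measurement_possibility,
    minimal_full_band,
    shape_measurement,
)
from pichia_mfa.scenarios import to_measurements
from pichia_mfa.synthetic import perturb_measurements, sample_feasible_flux


class TestShaping:
    def test_reference_deviation_has_reference_possibility(self):
        m = shape_measurement(0, 1.0)
        assert measurement_possibility(m, 1.20) == pytest.approx(0.1)
        assert measurement_possibility(m, 0.80) == pytest.approx(0.1)

    def test_half_possibility_at_9p5_percent(self):
        m = shape_measurement(0, 1.0)
        assert measurement_possibility(m, 1.095) == pytest.approx(0.5, abs=0.005)

    def test_slope_value(self):
        # alpha = ln(10) / ((0.20 - 0.05) * w) for w = 1
        m = shape_measurement(0, 1.0)
        assert m.alpha == pytest.approx(math.log(10) / 0.15)
        assert m.beta == m.alpha

    def test_full_band_is_fully_possible(self):
        m = shape_measurement(0, 2.0)
        assert measurement_possibility(m, 2.0 * 1.049) == 1.0
        assert measurement_possibility(m, 2.0 * 0.951) == 1.0

    def test_zero_measurement_uses_floor(self):
        m = shape_measurement(0, 0.0, zero_floor=0.05)
        assert m.eps2_max == pytest.approx(0.05 * 0.05)
        assert m.alpha == pytest.approx(math.log(10) / (0.15 * 0.05))

    @pytest.mark.parametrize(
        "kwargs", [dict(full_band=-0.1), dict(full_band=0.3), dict(ref_possibility=1.5)]
    )
    def test_bad_arguments(self, kwargs):
        with pytest.raises(ValueError):
            shape_measurement(0, 1.0, **kwargs)

    @given(
        w=st.floats(-5, 5),
        value=st.floats(-10, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_possibility_peaks_at_measurement(self, w, value):
        m = shape_measurement(0, w)
        p = measurement_possibility(m, value)
        assert 0 <= p <= 1  # may underflow to 0 far from the measurement
        assert measurement_possibility(m, w) == 1.0


class TestMaxPossibility:
    def test_exact_feasible_measurements_fully_possible(self, pichia, pichia_ems):
        v = sample_feasible_flux(pichia, seed=3, ems=pichia_ems)
        ms = perturb_measurements(v, pichia, rel_noise=0.0, seed=0)
        res = max_possibility(pichia, ms)
        assert res.pi == pytest.approx(1.0)
        assert minimal_full_band(pichia, ms) == pytest.approx(0.0, abs=1e-8)

    def test_noise_inside_full_band_still_fully_possible(self, pichia, pichia_ems):
        v = sample_feasible_flux(pichia, seed=4, ems=pichia_ems)
        ms = perturb_measurements(v, pichia, rel_noise=0.04, seed=1)
        assert max_possibility(pichia, ms).pi == pytest.approx(1.0)

    def test_pi_equals_exp_minus_J(self, pichia, scenario_by_id):
        ms = to_measurements(scenario_by_id["A3"], pichia)
        res = max_possibility(pichia, ms)
        assert res.pi == pytest.approx(math.exp(-res.J_min))
        assert 0 < res.pi <= 1

    def test_widening_bands_never_decreases_pi(self, pichia, scenarios):
        for s in scenarios[:4]:
            ms = to_measurements(s, pichia)
            pi0 = max_possibility(pichia, ms).pi
            pi1 = max_possibility(pichia, ms.widen(2.0)).pi
            assert pi1 >= pi0 - 1e-9

    def test_dropping_a_measurement_never_decreases_pi(self, pichia, scenario_by_id):
        for sid in ("A3", "A4", "B3"):
            ms = to_measurements(scenario_by_id[sid], pichia)
            pi0 = max_possibility(pichia, ms).pi
            for q in ("o2", "co2", "methanol"):
                pi1 = max_possibility(pichia, ms.drop(q)).pi
                assert pi1 >= pi0 - 1e-9

    def test_full_possibility_iff_band_below_full_band(self, pichia, scenarios):
        for s in scenarios:
            ms = to_measurements(s, pichia)
            pi = max_possibility(pichia, ms).pi
            band = minimal_full_band(pichia, ms)
            if pi > 1 - 1e-6:
                assert band <= 0.05 + 1e-6
            else:
                assert band > 0.05 - 1e-6


class TestIntervals:
    def test_nesting_in_gamma(self, pichia, scenario_by_id):
        ms = to_measurements(scenario_by_id["C3"], pichia)
        j = pichia.reaction_index("v34")
        mp = max_possibility(pichia, ms)
        ivs = [
            flux_interval(pichia, ms, j, g, conditional=True, _cache=mp)
            for g in (0.8, 0.5, 0.1)
        ]
        assert ivs[0].lower >= ivs[1].lower >= ivs[2].lower
        assert ivs[0].upper <= ivs[1].upper <= ivs[2].upper
        for iv in ivs:
            assert iv.lower - 1e-9 <= iv.most_possible <= iv.upper + 1e-9

    def test_gamma_above_pi_flagged_empty(self, pichia, scenario_by_id):
        ms = to_measurements(scenario_by_id["A4"], pichia)  # pi ~ 0.09
        j = pichia.exchange_map["biomass"][0]
        iv = flux_interval(pichia, ms, j, 0.8, conditional=False)
        assert iv.empty

    def test_toy_chain_band_propagation(self, toy_chain):
        """With one 1-dof chain, the efflux interval is the uptake's band
        widened by the cost budget: +/- (0.05 + 0.15 * ln(1/gamma) / ln 10)."""
        ms = MeasurementSet([shape_measurement(0, 1.0, quantity="uptake")])
        for gamma in (0.8, 0.5, 0.1):
            iv = flux_interval(toy_chain, ms, 2, gamma)
            half = 0.05 + 0.15 * math.log(1 / gamma) / math.log(10)
            assert iv.lower == pytest.approx(1 - half, abs=1e-6)
            assert iv.upper == pytest.approx(1 + half, abs=1e-6)

    def test_excluded_flux_on_toy_chain(self, toy_chain):
        ms = MeasurementSet([shape_measurement(0, 1.0, quantity="uptake")])
        vmp, ivs = estimate_excluded_flux(toy_chain, ms, 2, gammas=(0.5,))
        # any value inside the fully-possible band is an optimal estimate
        assert vmp == pytest.approx(1.0, abs=0.05 + 1e-9)
        assert ivs[0].lower < 1.0 < ivs[0].upper

    def test_excluded_flux_rejects_measured_target(self, toy_chain):
        ms = MeasurementSet([shape_measurement(2, 1.0, quantity="efflux")])
        with pytest.raises(ValueError):
            estimate_excluded_flux(toy_chain, ms, 2)


class TestParameterRecovery:
    def test_small_noise_recovers_full_possibility(self, pichia, pichia_ems):
        """Measurements within the +/-5% band give pi = 1 and the ground
        truth inside every gamma interval."""
        n_ok = 0
        for seed in range(25):
            v = sample_feasible_flux(pichia, seed=100 + seed, ems=pichia_ems)
            ms = perturb_measurements(v, pichia, rel_noise=0.05, seed=seed)
            res = max_possibility(pichia, ms)
            assert res.pi == pytest.approx(1.0, abs=1e-6)
            n_ok += 1
        assert n_ok == 25

    def test_truth_inside_gamma_intervals_for_excluded_flux(self, pichia, pichia_ems):
        jbio = pichia.exchange_map["biomass"][0]
        for seed in (0, 1, 2, 3, 4):
            v = sample_feasible_flux(pichia, seed=200 + seed, ems=pichia_ems)
            ms = perturb_measurements(v, pichia, rel_noise=0.04, seed=seed)
            ms = ms.drop("biomass")
            _, ivs = estimate_excluded_flux(pichia, ms, jbio, gammas=(0.8,))
            assert ivs[0].lower - 1e-7 <= v[jbio] <= ivs[0].upper + 1e-7

    def test_large_noise_lowers_possibility(self, pichia, pichia_ems):
        pis = []
        for seed in range(20):
            v = sample_feasible_flux(pichia, seed=300 + seed, ems=pichia_ems, scale=3.0)
            ms = perturb_measurements(v, pichia, rel_noise=0.5, seed=seed)
            pis.append(max_possibility(pichia, ms).pi)
        assert np.median(pis) < 1.0
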