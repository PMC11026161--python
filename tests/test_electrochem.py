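"""Electrochemical analysis: EIS fitting, CSC, transients, CIC, CIL maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurelec.electrochem import (
    CyclicVoltammogram,
    ImpedanceSpectrum,
    analyze_transient,
    build_cil_map,
    cic_from_excursions,
    compute_cic,
    cpe_impedance,
    csc_from_cv,
    fit_eis,
    impedance_at,
    stability_series,
)
from neurelec.errors import DegenerateFitError, InvalidParameterError
from neurelec.synth import GeneratorConfig, gen_cv, gen_eis_spectrum, gen_pulse_trace

FREQS = np.logspace(0, 5, 41)  # includes 1 kHz exactly


class TestFitEis:
    def test_roundtrip_ideal_capacitor(self, cfg0, disc_area):
        sp = gen_eis_spectrum(20e3, 6.82e-8, 1.0, FREQS, cfg0, geometric_area=disc_area)
        fit = fit_eis(sp)
        assert fit.R_series == pytest.approx(20e3, rel=1e-3)
        assert fit.Q_cpe == pytest.approx(6.82e-8, rel=1e-3)
        assert fit.n_exponent == pytest.approx(1.0, abs=1e-3)
        assert fit.capacitance == pytest.approx(68.2e-9, rel=1e-3)

    def test_areal_capacitance_of_25um_disc(self, cfg0, disc_area):
        # 68.2 nF on a 25-um disc is an interfacial capacitance of 13.9 mF/cm^2
        sp = gen_eis_spectrum(20e3, 6.82e-8, 1.0, FREQS, cfg0, geometric_area=disc_area)
        fit = fit_eis(sp)
        assert fit.areal_capacitance * 1e3 == pytest.approx(13.9, rel=0.005)

    def test_pure_resistor_degenerate(self, cfg0):
        sp = ImpedanceSpectrum(FREQS, np.full(FREQS.size, 1e4 + 0j))
        with pytest.raises(DegenerateFitError):
            fit_eis(sp)

    def test_too_few_frequencies_rejected(self, cfg0):
        sp = gen_eis_spectrum(1e4, 1e-7, 1.0, np.logspace(0, 5, 5), cfg0)
        with pytest.raises(InvalidParameterError):
            fit_eis(sp)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(
        r=st.floats(1e3, 1e5),
        logq=st.floats(-8.5, -6.5),
        n=st.floats(0.7, 1.0),
    )
    def test_roundtrip_property(self, r, logq, n):
        cfg = GeneratorConfig(seed=0, noise_level=0.0)
        sp = gen_eis_spectrum(r, 10.0 ** logq, n, FREQS, cfg)
        fit = fit_eis(sp)
        assert fit.R_series == pytest.approx(r, rel=1e-3)
        assert fit.Q_cpe == pytest.approx(10.0 ** logq, rel=1e-3)
        assert fit.n_exponent == pytest.approx(n, abs=1e-3)


class TestImpedanceAt:
    def test_exact_grid_point(self, cfg0):
        sp = gen_eis_spectrum(1e4, 1e-7, 0.9, FREQS, cfg0)
        assert impedance_at(sp, FREQS[10]) == pytest.approx(abs(sp.impedance[10]))

    def test_pure_capacitor_1khz(self, cfg0):
        sp = gen_eis_spectrum(0.0, 68.2e-9, 1.0, FREQS, cfg0)
        expected = 1.0 / (2 * np.pi * 1000 * 68.2e-9)
        assert impedance_at(sp, 1000.0) == pytest.approx(expected, rel=1e-6)

    def test_series_rc_modulus_1khz(self, cfg0):
        sp = gen_eis_spectrum(20e3, 68.2e-9, 1.0, FREQS, cfg0)
        expected = abs(20e3 + 1.0 / (1j * 2 * np.pi * 1000 * 68.2e-9))
        assert impedance_at(sp, 1000.0) == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(20.136e3, rel=1e-3)

    def test_out_of_range_rejected(self, cfg0):
        sp = gen_eis_spectrum(1e4, 1e-7, 1.0, FREQS, cfg0)
        with pytest.raises(InvalidParameterError):
            impedance_at(sp, 1e7)


class TestCsc:
    def test_zero_current(self):
        pot = np.concatenate([np.linspace(-0.9, 0.8, 500), np.linspace(0.8, -0.9, 500)])
        cv = CyclicVoltammogram(pot, np.zeros(1000), 0.1, 1e-5, (-0.9, 0.8))
        res = csc_from_cv(cv)
        assert res.cCSC == 0 and res.aCSC == 0

    @pytest.mark.parametrize("scan_rate", [0.05, 0.1, 0.5])
    def test_ideal_capacitor_equals_ca_dv(self, cfg0, scan_rate):
        # cCSC = aCSC = C_A * window span, independent of scan rate
        cv = gen_cv(10e-3, (-0.9, 0.8), scan_rate, 1e-5, cfg0, samples_per_cycle=4000)
        res = csc_from_cv(cv)
        assert res.cCSC == pytest.approx(17.0, rel=0.01)
        assert res.aCSC == pytest.approx(17.0, rel=0.01)

    def test_incomplete_cycle_rejected(self, cfg0):
        cv = gen_cv(10e-3, (-0.9, 0.8), 0.1, 1e-5, cfg0)
        half = CyclicVoltammogram(cv.potential[:800], cv.current[:800], 0.1,
                                  1e-5, (-0.9, 0.8))
        with pytest.raises(InvalidParameterError, match="incomplete"):
            csc_from_cv(half)


class TestAnalyzeTransient:
    def test_charge_density_arithmetic(self, cfg0, disc_area):
        # 15 uA x 1 ms on a 25-um disc is ~3 mC/cm^2 per phase
        tr = gen_pulse_trace(20e3, 68e-9, 1.0, 15e-6, 1e-3, 1e6, disc_area, cfg0)
        m = analyze_transient(tr)
        assert m.charge_density == pytest.approx(15e-6 * 1e-3 / disc_area * 1e3, rel=1e-12)
        assert m.charge_density == pytest.approx(3.06, abs=0.005)

    def test_ohmic_drop_and_excursion(self, cfg0, disc_area):
        tr = gen_pulse_trace(20e3, 68e-9, 1.0, 15e-6, 1e-3, 1e6, disc_area, cfg0)
        m = analyze_transient(tr)
        assert m.ohmic_drop == pytest.approx(0.300, abs=1e-6)
        assert m.access_resistance == pytest.approx(20e3, rel=1e-6)
        assert abs(m.cathodic_excursion) == pytest.approx(0.2206, abs=1e-3)

    def test_zero_amplitude_all_zero(self, cfg0, disc_area):
        tr = gen_pulse_trace(20e3, 68e-9, 1.0, 0.0, 1e-3, 1e6, disc_area, cfg0)
        m = analyze_transient(tr)
        assert (m.ohmic_drop, m.cathodic_excursion, m.anodic_excursion,
                m.charge_density) == (0, 0, 0, 0)

    def test_backextrapolation_matches_naive_on_sharp_edge(self, cfg0, disc_area):
        tr = gen_pulse_trace(20e3, 68e-9, 1.0, 15e-6, 1e-3, 1e6, disc_area, cfg0)
        naive = analyze_transient(tr).ohmic_drop
        extrap = analyze_transient(tr, backextrap_samples=3).ohmic_drop
        assert extrap == pytest.approx(naive, rel=1e-3)


class TestCic:
    def test_interpolation_oracle(self):
        # -0.6 V at 2 and -1.2 V at 4 mC/cm^2 cross -0.9 V at exactly 3
        res = cic_from_excursions([2.0, 4.0], cathodic_excursions=[-0.6, -1.2])
        assert res.cic == pytest.approx(3.0, abs=1e-12)
        assert res.limiting_side == "cathodic"

    def test_ideal_capacitor_closed_form(self, cfg0, disc_area):
        # Q = C*V: CIC = 0.9 V x areal capacitance
        c_areal = 13.9e-3
        amps = np.linspace(5e-6, 80e-6, 16)
        traces = [gen_pulse_trace(20e3, c_areal * disc_area, 1.0, a, 1e-3, 2e5,
                                  disc_area, cfg0) for a in amps]
        res = compute_cic(traces)
        assert res.limiting_side == "cathodic"
        assert res.cic == pytest.approx(0.9 * c_areal * 1e3, rel=0.02)

    def test_below_grid_flagged(self):
        res = cic_from_excursions([2.0, 4.0], cathodic_excursions=[-1.0, -2.0])
        assert res.below_grid

    def test_out_of_grid_lower_bound(self):
        res = cic_from_excursions([2.0, 4.0], cathodic_excursions=[-0.1, -0.2])
        assert res.out_of_grid and res.cic == 4.0 and res.limiting_side == "none"

    def test_last_safe_method(self):
        res = cic_from_excursions([2.0, 3.0, 4.0],
                                  cathodic_excursions=[-0.6, -0.85, -1.2],
                                  method="last_safe")
        assert res.cic == 3.0


class TestCilMap:
    MODEL = {"R": 20e3, "Q": 13.9e-3 * 4.909e-6, "n": 1.0, "area": 4.909e-6}

    def test_ideal_capacitor_columns_constant(self):
        cil = build_cil_map(self.MODEL, [1e-4, 3e-4, 1e-3], [1.0, 2.0, 4.0])
        # excursion = charge density / areal capacitance, pulse-width free
        expected = np.array([1.0, 2.0, 4.0]) / 13.9
        assert np.allclose(cil.excursion_matrix, expected[None, :], rtol=0.02)

    def test_monotone_in_charge_density(self):
        cil = build_cil_map(self.MODEL, [1e-4, 1e-3], np.linspace(0.5, 5, 8))
        assert np.all(np.diff(cil.excursion_matrix, axis=1) >= 0)

    def test_max_safe_density_query(self):
        cil = build_cil_map(self.MODEL, [1e-3], np.linspace(1, 20, 20))
        safe = cil.max_safe_density((-0.9, 0.8))
        assert safe[0] == pytest.approx(12.0, abs=1.01)  # 0.9 * 13.9 = 12.51

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_cil_map(self.MODEL, [1e-3], [])


class TestStability:
    def test_constant_series_zero_drift(self):
        st_ = stability_series([(0, 25.0), (1_000_000, 25.0)])
        assert st_.max_abs_drift == 0.0

    def test_two_percent_drift(self):
        st_ = stability_series([(0, 25.0), (1, 25.5), (2, 24.8)])
        assert st_.max_abs_drift == pytest.approx(0.02, abs=1e-12)

    def test_unsorted_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            stability_series([(2, 25.0), (1, 25.5)])

    def test_single_point_rejected(self):
        with pytest.raises(InvalidParameterError):
            stability_series([(0, 25.0)])
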