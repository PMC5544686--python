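"""Microphysics checks against hand-evaluated and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aeromarine.core_io import EUKARYOTE, PROKARYOTE, MeteoState
from aeromarine.microphysics import (DepositionParams, SpraySourceParams,
                                     air_viscosity, deposition_velocity,
                                     settling_velocity, slip_correction,
                                     spray_number_flux_density,
                                     spray_volume_velocity)


def gong_reference(r80, u10, theta=30.0):
    """Independent transcription of the published spray source function,
    written directly from the formula and kept separate from the
    implementation it checks."""
    import math
    A = 4.7 * math.pow(1.0 + theta * r80, -0.017 * math.pow(r80, -1.44))
    B = (0.433 - math.log10(r80)) / 0.433
    return (1.373 * math.pow(u10, 3.41) * math.pow(r80, -A)
            * (1.0 + 0.057 * math.pow(r80, 3.45))
            * math.pow(10.0, 1.607 * math.exp(-B * B)))


def riemann_volume_flux(u10, r_min=0.2, r_max=10.0, n=1_000_000):
    """Midpoint-Riemann oracle for the spray volume integral."""
    edges = np.linspace(r_min, r_max, n + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    dr = np.diff(edges)
    A = 4.7 * (1 + 30.0 * mid) ** (-0.017 * mid ** -1.44)
    B = (0.433 - np.log10(mid)) / 0.433
    dF = (1.373 * u10 ** 3.41 * mid ** -A * (1 + 0.057 * mid ** 3.45)
          * 10.0 ** (1.607 * np.exp(-B ** 2)))
    return float(np.sum(dF * (4.0 / 3.0) * np.pi * (mid * 1e-6) ** 3 * dr))


class TestSlipCorrection:
    def test_continuum_limit_large_particle(self):
        assert slip_correction(100e-6, 298.0, 101325.0) == pytest.approx(
            1.0, abs=0.01)

    @pytest.mark.parametrize("d_um,expected", [(0.5, 1.336), (5.0, 1.033)])
    def test_hand_evaluated_cunningham(self, d_um, expected):
        # lambda = 0.0665 um at 298.15 K / 1013.25 hPa, coeffs 1.257/0.4/1.1
        cc = slip_correction(d_um * 1e-6, 298.0, 101300.0)
        assert cc == pytest.approx(expected, abs=0.005)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            slip_correction(0.0, 298.0, 101325.0)

    def test_scales_with_pressure(self):
        low_p = slip_correction(0.5e-6, 298.0, 50000.0)
        assert low_p > slip_correction(0.5e-6, 298.0, 101325.0)


class TestSettling:
    def test_zero_density_gives_zero(self, open_ocean_meteo):
        ghost = PROKARYOTE.__class__("ghost", 0.5e-6, 1e-12, 0.0)
        assert settling_velocity(ghost, open_ocean_meteo) < 1e-15

    def test_hand_stokes_prokaryote(self, open_ocean_meteo):
        # rho d^2 g Cc / (18 mu) with mu(298 K) = 1.84e-5 Pa s
        assert settling_velocity(PROKARYOTE, open_ocean_meteo) == \
            pytest.approx(1.1e-5, rel=0.05)

    def test_hand_stokes_spore(self, open_ocean_meteo):
        v5 = settling_velocity(EUKARYOTE, open_ocean_meteo)
        assert v5 == pytest.approx(8.5e-4, rel=0.05)
        ratio = v5 / settling_velocity(PROKARYOTE, open_ocean_meteo)
        assert ratio == pytest.approx(77.0, rel=0.05)

    def test_viscosity_sutherland_at_298(self):
        assert air_viscosity(298.15) == pytest.approx(1.84e-5, rel=0.005)


class TestDepositionVelocity:
    def test_no_wind_reduces_to_settling(self):
        calm = MeteoState(0.0, 298.15, 80.0, 101325.0)
        v_d = deposition_velocity(EUKARYOTE, calm)
        v_g = settling_velocity(EUKARYOTE, calm)
        assert v_d == pytest.approx(v_g, rel=0.05)

    def test_large_class_deposits_faster(self, open_ocean_meteo):
        assert (deposition_velocity(EUKARYOTE, open_ocean_meteo)
                > deposition_velocity(PROKARYOTE, open_ocean_meteo))

    def test_never_below_settling_and_monotone_in_wind(self):
        for particle in (PROKARYOTE, EUKARYOTE):
            prev = 0.0
            for u in np.linspace(0.0, 30.0, 31):
                m = MeteoState(u, 298.15, 80.0, 101325.0)
                v = deposition_velocity(particle, m)
                assert v >= settling_velocity(particle, m) * (1 - 1e-12)
                assert v >= prev - 1e-15
                prev = v

    def test_cruise_wind_envelope_brackets_observed_median(self):
        # the cruise-median residence time of 17 d in an 817 m layer implies
        # v_d = 3.9e-4 m/s for prokaryotes; the model spans that value
        # within the range of winds encountered at sea
        vds = [deposition_velocity(PROKARYOTE,
                                   MeteoState(u, 298.15, 80.0, 101325.0))
               for u in np.linspace(2.0, 15.0, 27)]
        assert min(vds) < 3.9e-4 < max(vds)

    @given(u=st.floats(0.0, 30.0), T=st.floats(270.0, 310.0),
           rh=st.floats(40.0, 100.0))
    def test_finite_nonnegative_over_envelope(self, u, T, rh):
        m = MeteoState(u, T, rh, 101325.0)
        for particle in (PROKARYOTE, EUKARYOTE):
            v = deposition_velocity(particle, m)
            assert np.isfinite(v) and v > 0

    def test_whitecap_fraction_bounded(self):
        p = DepositionParams()
        assert p.whitecap_fraction(0.0) == 0.0
        assert p.whitecap_fraction(60.0) == 1.0


class TestSpraySource:
    def test_zero_wind_gives_zero(self):
        assert spray_number_flux_density(1.0, 0.0) == 0.0
        calm = MeteoState(0.0, 298.15, 80.0, 101325.0)
        assert spray_volume_velocity(calm) == 0.0

    def test_wind_power_law_scaling(self):
        r = np.array([0.3, 1.0, 5.0, 9.0])
        ratio = (spray_number_flux_density(r, 12.0)
                 / spray_number_flux_density(r, 6.0))
        assert ratio == pytest.approx(2.0 ** 3.41, rel=1e-9)

    def test_point_values_match_independent_transcription(self):
        for r in (0.2, 0.5, 1.0, 3.0, 10.0):
            for u in (4.0, 9.0):
                assert spray_number_flux_density(r, u) == pytest.approx(
                    gong_reference(r, u), rel=1e-12)

    def test_radius_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            spray_number_flux_density(0.05, 8.0)
        with pytest.raises(ValueError):
            spray_number_flux_density(20.0, 8.0)

    def test_volume_flux_scaling_law(self):
        m6 = MeteoState(6.0, 298.15, 80.0, 101325.0)
        m12 = MeteoState(12.0, 298.15, 80.0, 101325.0)
        assert (spray_volume_velocity(m12) / spray_volume_velocity(m6)
                == pytest.approx(2.0 ** 3.41, rel=1e-6))

    @pytest.mark.parametrize("u10", [4.0, 8.0, 16.0])
    def test_quadrature_matches_riemann_oracle(self, u10):
        m = MeteoState(u10, 298.15, 80.0, 101325.0)
        assert spray_volume_velocity(m) == pytest.approx(
            riemann_volume_flux(u10), rel=1e-3)

    def test_monotone_in_rmax(self):
        m = MeteoState(8.0, 298.15, 80.0, 101325.0)
        v_small = spray_volume_velocity(m, SpraySourceParams(r_max=5.0))
        v_full = spray_volume_velocity(m)
        assert v_full > v_small > 0

    def test_invalid_radius_bounds_rejected(self):
        with pytest.raises(ValueError):
            SpraySourceParams(r_min=5.0, r_max=1.0)
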