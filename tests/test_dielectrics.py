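"""Complex permittivities, the Clausius-Mossotti factor and the shell model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deptrap.dielectrics import (
    VACUUM_PERMITTIVITY,
    DielectricMedium,
    HomogeneousCell,
    ShelledCell,
    cm_factor,
    cm_factor_at,
    complex_permittivity,
    crossover_frequency,
    effective_cell_permittivity,
    re_cm_spectrum,
)

OMEGA_10MHZ = 2 * math.pi * 1e7


class TestComplexPermittivity:
    def test_cytoplasm_at_operating_frequency(self):
        # eps* = eps - j sigma/omega with the cytoplasm parameters
        val = complex_permittivity(7.1e-10, 0.75, OMEGA_10MHZ)
        assert val.real == 7.1e-10
        assert val.imag == pytest.approx(-1.19366e-8, rel=1e-5)

    def test_zero_conductivity_is_purely_real(self):
        assert complex_permittivity(3e-10, 0.0, 1e5) == 3e-10 + 0j

    def test_high_frequency_limit_kills_conductive_part(self):
        assert complex_permittivity(3e-10, 10.0, 1e30).imag == pytest.approx(0.0, abs=1e-29)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            complex_permittivity(3e-10, 1.0, 0.0)
        with pytest.raises(ValueError):
            complex_permittivity(3e-10, 1.0, -5.0)


class TestCmFactor:
    def test_identical_media_gives_zero(self):
        e = complex_permittivity(7e-10, 0.5, OMEGA_10MHZ)
        assert cm_factor(e, e) == 0j

    def test_highly_polarizable_limit_approaches_one(self):
        assert cm_factor(1e30 + 0j, 7e-10 + 0j).real == pytest.approx(1.0, abs=1e-12)

    def test_vanishing_particle_limit_approaches_minus_half(self):
        assert cm_factor(1e-30 + 0j, 7e-10 + 0j).real == pytest.approx(-0.5, abs=1e-12)

    def test_vanishing_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            cm_factor(-2.0 + 0j, 1.0 + 0j)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        eps_p=st.floats(1.0, 100.0),
        eps_m=st.floats(1.0, 100.0),
        sig_p=st.floats(-7.0, 1.0),
        sig_m=st.floats(-7.0, 1.0),
        log_f=st.floats(3.0, 9.0),
    )
    def test_real_part_bounded_for_physical_inputs(self, eps_p, eps_m, sig_p, sig_m, log_f):
        """Re[f_CM] lies in [-0.5, 1] for any physical particle/medium pair."""
        w = 2 * math.pi * 10**log_f
        fcm = cm_factor(
            complex_permittivity(eps_p * VACUUM_PERMITTIVITY, 10**sig_p, w),
            complex_permittivity(eps_m * VACUUM_PERMITTIVITY, 10**sig_m, w),
        )
        assert -0.5 - 1e-12 <= fcm.real <= 1.0 + 1e-12

    @pytest.mark.parametrize(
        "omega,expected",
        [
            # conductivity-dominated and permittivity-dominated limits
            (1e-6, (0.01 - 0.1) / (0.01 + 2 * 0.1)),
            (1e18, (80.0 - 50.0) / (80.0 + 2 * 50.0)),
        ],
    )
    def test_frequency_limits_match_closed_forms(self, omega, expected):
        e0 = VACUUM_PERMITTIVITY
        fcm = cm_factor(
            complex_permittivity(80 * e0, 0.01, omega),
            complex_permittivity(50 * e0, 0.1, omega),
        )
        assert fcm.real == pytest.approx(expected, rel=1e-6)


class TestShellModel:
    def test_degenerate_shell_equals_cytoplasm(self):
        cell = ShelledCell(5e-6, 5e-9, 7.1e-10, 0.75, 7.1e-10, 0.75)
        expected = complex_permittivity(7.1e-10, 0.75, OMEGA_10MHZ)
        got = effective_cell_permittivity(cell, OMEGA_10MHZ)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_vanishing_shell_limit_recovers_cytoplasm(self):
        cell = ShelledCell(5e-6, 1e-15, 1.8e-12, 1e-7, 7.1e-10, 0.75)
        expected = complex_permittivity(7.1e-10, 0.75, OMEGA_10MHZ)
        got = effective_cell_permittivity(cell, OMEGA_10MHZ)
        assert got.real == pytest.approx(expected.real, rel=1e-6)
        assert got.imag == pytest.approx(expected.imag, rel=1e-6)

    def test_against_coated_sphere_oracle(self, default_cell):
        # frozen from an independent evaluation of the coated-sphere
        # polarizability-equivalence formula (explicit numerator/denominator form)
        got = effective_cell_permittivity(default_cell, OMEGA_10MHZ)
        assert got.real == pytest.approx(1.743151233428792e-09, rel=1e-10)
        assert got.imag == pytest.approx(-2.6114136852762197e-10, rel=1e-10)

    def test_effective_permittivity_is_continuous(self, default_cell):
        base = effective_cell_permittivity(default_cell, OMEGA_10MHZ)
        for fld in (
            "radius",
            "membrane_thickness",
            "membrane_permittivity",
            "cytoplasm_conductivity",
        ):
            kwargs = {
                "radius": default_cell.radius,
                "membrane_thickness": default_cell.membrane_thickness,
                "membrane_permittivity": default_cell.membrane_permittivity,
                "membrane_conductivity": default_cell.membrane_conductivity,
                "cytoplasm_permittivity": default_cell.cytoplasm_permittivity,
                "cytoplasm_conductivity": default_cell.cytoplasm_conductivity,
            }
            kwargs[fld] *= 1 + 1e-9
            perturbed = effective_cell_permittivity(ShelledCell(**kwargs), OMEGA_10MHZ)
            assert abs(perturbed - base) / abs(base) < 1e-6

    def test_invalid_membrane_thickness_rejected(self):
        with pytest.raises(ValueError):
            ShelledCell(5e-6, 5e-6, 1.8e-12, 1e-7, 7.1e-10, 0.75)


class TestSpectrum:
    def test_empty_frequency_list_yields_empty_table(self, default_cell, default_medium):
        table = re_cm_spectrum(default_cell, default_medium, [])
        assert list(table.columns) == ["frequency_hz", "re_fcm", "im_fcm"]
        assert len(table) == 0

    def test_matched_particle_gives_zero(self):
        med = DielectricMedium(7.1e-10, 0.75)
        cell = HomogeneousCell(5e-6, 7.1e-10, 0.75)
        table = re_cm_spectrum(cell, med, [1e7])
        assert table["re_fcm"].iloc[0] == pytest.approx(0.0, abs=1e-15)

    def test_default_cell_is_ndep_at_operating_point(self, default_cell, default_medium):
        """The shelled cell in culture-conductivity medium sees nDEP at 10 MHz."""
        table = re_cm_spectrum(default_cell, default_medium, [1e7])
        assert table["re_fcm"].iloc[0] < 0

    def test_structure_preserved_and_bounded(self, default_cell, default_medium):
        freqs = np.logspace(4, 9, 30)
        table = re_cm_spectrum(default_cell, default_medium, freqs)
        assert len(table) == 30
        assert np.all(np.diff(table["frequency_hz"]) > 0)
        assert table["re_fcm"].between(-0.5, 1.0).all()

    def test_nonpositive_frequency_rejected(self, default_cell, default_medium):
        with pytest.raises(ValueError):
            re_cm_spectrum(default_cell, default_medium, [1e5, -1e6])


class TestCrossover:
    def test_no_sign_change_returns_none(self, default_cell):
        # high-conductivity medium keeps Re[f_CM] negative throughout
        med = DielectricMedium(7.1e-10, 5.0)
        assert crossover_frequency(default_cell, med, 1e5, 1e9) is None

    def test_matches_dense_scan(self):
        e0 = VACUUM_PERMITTIVITY
        cell = HomogeneousCell(5e-6, 80 * e0, 0.01)
        med = DielectricMedium(50 * e0, 0.1)
        f_star = crossover_frequency(cell, med, 1e3, 1e10)
        # independent oracle: vectorized dense scan of the CM factor
        f = np.logspace(3, 10, 1_000_000)
        w = 2 * np.pi * f
        ep = cell.permittivity - 1j * cell.conductivity / w
        em = med.permittivity - 1j * med.conductivity / w
        re = ((ep - em) / (ep + 2 * em)).real
        crossings = np.nonzero(np.diff(np.sign(re)))[0]
        assert len(crossings) == 1
        bracket = (f[crossings[0]], f[crossings[0] + 1])
        assert bracket[0] <= f_star <= bracket[1]
        # residual at the returned root
        assert abs(cm_factor_at(cell, med, f_star).real) < 1e-9

    def test_invalid_bracket_rejected(self, default_cell, default_medium):
        with pytest.raises(ValueError):
            crossover_frequency(default_cell, default_medium, 1e9, 1e3)
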