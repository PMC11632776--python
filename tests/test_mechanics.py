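"""Stress-strain smoothing and elastic-constant extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mdprops as m
from mdprops.types import AnalysisError


def windowed_mean_oracle(eps, sig, half_width):
    """Brute-force reflect-and-average smoother (double loop)."""
    sig = [0.0 if e == 0 else s for e, s in zip(eps, sig)]  # odd-symmetry at 0
    aug_e = list(eps) + [-e for e in eps if e > 0]
    aug_s = list(sig) + [-s for e, s in zip(eps, sig) if e > 0]
    out = []
    for e in eps:
        h = min(half_width, eps[-1] - e)
        vals = [s for ee, s in zip(aug_e, aug_s) if abs(ee - e) <= h + 1e-12]
        out.append(sum(vals) / len(vals))
    return np.array(out)


class TestStressFromPressure:
    def _table(self, strain, pz, unit="bar"):
        return m.TimeSeriesTable(
            columns=[("strain", "dimensionless"), ("P_z", unit)],
            values=np.column_stack([strain, pz]),
        )

    def test_sign_and_unit_conversion(self):
        c = m.stress_from_pressure(self._table([0.0, 0.5], [-30000.0, 0.0]))
        assert c.stress[0] == pytest.approx(3.0)
        assert c.stress[1] == 0.0

    def test_missing_strain_column_errors(self):
        t = m.TimeSeriesTable(
            columns=[("time", "ns"), ("P_z", "bar")], values=[[0.0, 1.0], [1.0, 2.0]]
        )
        with pytest.raises(AnalysisError, match="strain"):
            m.stress_from_pressure(t)

    def test_round_trip_with_generator(self):
        strains = np.linspace(0, 1, 50)
        ss = m.gen_stress_strain(2.0, 2.0, 1e3, strains)
        pz_bar = -ss.column("stress") / 1e-4
        c = m.stress_from_pressure(self._table(strains, pz_bar))
        assert np.allclose(c.stress, ss.column("stress"))


class TestStrainSeries:
    @pytest.mark.parametrize("lt,expected", [(5.0, 0.0), (10.0, 1.0), (5.15, 0.03)])
    def test_engineering_strain(self, lt, expected):
        t = m.TimeSeriesTable(columns=[("time", "ns"), ("L", "nm")],
                              values=[[0.0, 5.0], [1.0, lt]])
        assert m.strain_series(t, 5.0)[1] == pytest.approx(expected)

    def test_nonpositive_reference_errors(self):
        t = m.TimeSeriesTable(columns=[("time", "ns"), ("L", "nm")],
                              values=[[0.0, 5.0]])
        with pytest.raises(AnalysisError):
            m.strain_series(t, 0.0)


class TestSmoothReflect:
    def test_linear_data_is_a_fixed_point(self):
        eps = np.linspace(0, 1, 400)
        curve = m.StressStrainCurve(strains=eps, stress=3.1 * eps)
        sm = m.smooth_reflect(curve)
        assert np.max(np.abs(sm.smoothed - 3.1 * eps)) < 1e-12
        assert sm.smoothed[0] == 0.0

    def test_zero_stress_at_zero_strain_for_any_data(self, rng):
        eps = np.linspace(0, 0.5, 201)
        curve = m.StressStrainCurve(strains=eps, stress=rng.standard_normal(201))
        sm = m.smooth_reflect(curve)
        assert abs(sm.smoothed[0]) < 1e-12

    def test_matches_brute_force_window_oracle(self, rng):
        eps = np.linspace(0, 0.2, 81)
        sig = 2.0 * eps + rng.normal(0, 0.05, 81)
        sm = m.smooth_reflect(m.StressStrainCurve(strains=eps, stress=sig),
                              half_width=0.025)
        oracle = windowed_mean_oracle(eps, sig, 0.025)
        assert np.allclose(sm.smoothed, oracle, atol=1e-12)

    def test_half_width_spanning_data_errors(self):
        eps = np.linspace(0, 0.04, 10)
        with pytest.raises(AnalysisError):
            m.smooth_reflect(m.StressStrainCurve(strains=eps, stress=eps),
                             half_width=0.05)


class TestYoungsModulus:
    def _smoothed(self, eps, sig):
        return m.smooth_reflect(m.StressStrainCurve(strains=eps, stress=sig))

    def test_exact_on_linear_curve(self):
        eps = np.linspace(0, 0.1, 200)
        E = m.youngs_modulus(self._smoothed(eps, 2.5 * eps))
        assert E.value == pytest.approx(2.5, abs=1e-12)

    def test_zero_stress_gives_zero_modulus(self):
        eps = np.linspace(0, 0.1, 200)
        assert m.youngs_modulus(self._smoothed(eps, np.zeros_like(eps))).value == 0.0

    def test_matches_closed_form_slope_oracle(self):
        ss = m.gen_stress_strain(3.0, 2.0, 1e3, np.linspace(0, 1, 400),
                                 m.GeneratorSpec(seed=5, noise_sd=0.05))
        sm = self._smoothed(ss.column("strain"), ss.column("stress"))
        E = m.youngs_modulus(sm, 0.003, 0.99)
        mask = (sm.strains >= 0.003) & (sm.strains <= 0.99)
        oracle = np.sum(sm.smoothed[mask] * sm.strains[mask]) / np.sum(
            sm.strains[mask] ** 2
        )
        assert E.value == pytest.approx(oracle, abs=1e-12)
        assert abs(E.value - 3.0) / 3.0 < 0.02

    def test_insufficient_window_points_errors(self):
        eps = np.linspace(0, 0.1, 5)
        sm = self._smoothed(eps, 2.0 * eps)
        with pytest.raises(AnalysisError):
            m.youngs_modulus(sm, 0.0001, 0.0002)


class TestMaxStress:
    def _smoothed_parabola(self):
        eps = np.linspace(0, 1, 1001)
        sig = 4 * eps * (1 - eps)
        curve = m.StressStrainCurve(strains=eps, stress=sig)
        curve.smoothed = sig  # analytic curve, no smoothing needed
        return curve

    def test_parabola_peak(self):
        r = m.max_stress(self._smoothed_parabola())
        assert r.value == pytest.approx(1.0, abs=1e-6)
        assert r.provenance["strain_at_max"] == pytest.approx(0.5, abs=1e-3)

    def test_tie_breaks_to_smaller_strain(self):
        eps = np.linspace(0, 1, 11)
        sig = np.zeros(11)
        sig[4] = sig[7] = 2.0
        curve = m.StressStrainCurve(strains=eps, stress=sig)
        curve.smoothed = sig
        r = m.max_stress(curve)
        assert r.provenance["strain_at_max"] == pytest.approx(0.4)

    def test_monotone_curve_peaks_at_upper_edge(self):
        eps = np.linspace(0, 1, 101)
        curve = m.StressStrainCurve(strains=eps, stress=eps)
        curve.smoothed = eps.copy()
        r = m.max_stress(curve)
        assert r.provenance["strain_at_max"] <= 0.97
        assert r.value == pytest.approx(0.97)

    def test_empty_interval_errors(self):
        curve = self._smoothed_parabola()
        with pytest.raises(AnalysisError):
            m.max_stress(curve, 0.9992, 0.9998)


class TestPoissonRatio:
    def test_linear_convention_exact(self):
        d = m.gen_box_deformation(0.3, 5.0, np.linspace(0, 0.1, 101))
        assert m.poisson_ratio(d).value == pytest.approx(0.300, abs=1e-12)

    def test_constant_transverse_gives_zero(self):
        d = m.gen_box_deformation(0.0, 5.0, np.linspace(0, 0.1, 101))
        assert m.poisson_ratio(d).value == pytest.approx(0.0, abs=1e-12)

    def test_volume_preserving_response_near_half(self):
        # analytic slope of (1+e)^(-1/2) over the 1-2% window gives ~0.489
        d = m.gen_box_deformation(0.3, 5.0, np.linspace(0, 0.1, 1001),
                                  volume_preserving=True)
        assert m.poisson_ratio(d).value == pytest.approx(0.489, abs=0.002)

    def test_empty_window_errors(self):
        d = m.gen_box_deformation(0.3, 5.0, np.linspace(0.5, 0.6, 20))
        with pytest.raises(AnalysisError):
            m.poisson_ratio(d)


class TestBulkModulus:
    @pytest.mark.parametrize("E,nu,K", [(3.0, 1 / 3, 3.0), (3.0, 0.0, 1.0)])
    def test_lame_relation(self, E, nu, K):
        assert m.bulk_modulus(E, nu).value == pytest.approx(K)

    def test_near_incompressible_is_flagged(self):
        r = m.bulk_modulus(3.0, 0.4999)
        assert any("near-incompressible" in f for f in r.flags)

    def test_above_half_errors(self):
        with pytest.raises(AnalysisError):
            m.bulk_modulus(3.0, 0.51)

    @given(nu=st.floats(0.0, 0.49), dnu=st.floats(1e-4, 0.009))
    def test_monotone_increasing_in_nu(self, nu, dnu):
        if nu + dnu < 0.4985:
            assert m.bulk_modulus(2.0, nu + dnu).value > m.bulk_modulus(2.0, nu).value


class TestAggregateDirections:
    def _ec(self, nu):
        return m.ElasticConstants(E=3.0, sigma_max=0.2, nu=nu, K=1.0)

    def test_identical_directions_have_zero_spread(self):
        agg = m.aggregate_directions([self._ec(0.30)] * 3)
        assert agg.nu == 0.30 and agg.nu_err == 0.0

    def test_population_std(self):
        agg = m.aggregate_directions([self._ec(v) for v in (0.29, 0.30, 0.31)])
        assert agg.nu == pytest.approx(0.30)
        assert agg.nu_err == pytest.approx(0.0082, abs=2e-4)

    def test_wrong_count_errors(self):
        with pytest.raises(AnalysisError):
            m.aggregate_directions([self._ec(0.3)] * 2)


class TestDeltaEnergy:
    def test_first_row_zero_and_differences(self):
        t = m.TimeSeriesTable(
            columns=[("strain", "dimensionless"), ("LJ", "kJ/mol")],
            values=[[0.0, 10.0], [0.1, 12.0], [0.2, 9.0]],
        )
        d = m.delta_energy(t)
        assert list(d.values[:, 1]) == [0.0, 2.0, -1.0]

    def test_constant_column_maps_to_zero(self):
        t = m.TimeSeriesTable(
            columns=[("strain", "dimensionless"), ("bond", "kJ/mol")],
            values=[[0.0, 7.0], [0.5, 7.0]],
        )
        assert np.all(m.delta_energy(t).values[:, 1] == 0.0)


class TestFullRecovery:
    def test_elastic_constants_recovered_at_zero_noise(self):
        strains = np.linspace(0, 1, 400)
        ss = m.gen_stress_strain(3.0, 2.0, 1e3, strains)
        sm = m.smooth_reflect(
            m.StressStrainCurve(strains=ss.column("strain"), stress=ss.column("stress"))
        )
        E = m.youngs_modulus(sm)
        nu = m.poisson_ratio(m.gen_box_deformation(0.3, 5.0, strains))
        K = m.bulk_modulus(E.value, nu.value)
        assert E.value == pytest.approx(3.0, abs=1e-9)
        assert nu.value == pytest.approx(0.3, abs=1e-9)
        assert K.value == pytest.approx(3.0 / (3 * (1 - 0.6)), abs=1e-9)
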