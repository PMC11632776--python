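"""Hydrogen-bond detection geometry and existence-function kinetics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mdprops as m
from mdprops.types import AnalysisError


def bisection_halflife_oracle(k1, t1, k2, t2, lo=0.0, hi=1e4, iters=200):
    """Plain bisection on C(t) = 0.5, independent of the package solver."""
    f = lambda t: k1 * np.exp(-t / t1) + k2 * np.exp(-t / t2) - 0.5
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestDetectHBonds:
    def test_strict_distance_boundary_excluded(self):
        frame = m.gen_hbond_geometry(0.35, 10.0, [2, 2, 2])
        assert m.detect_hbonds(frame) == []

    def test_bond_across_periodic_boundary(self):
        # donor at x=0.05, acceptor at x=1.75 in a 2 nm box: min-image 0.30 nm
        frame = m.ConfigurationFrame(
            elements=["O", "H", "O"],
            names=["OD", "HD", "OA"],
            mol_index=[0, 0, 1],
            positions=[[0.05, 1.0, 1.0], [1.95, 1.0, 1.0], [1.75, 1.0, 1.0]],
            box=[2.0, 2.0, 2.0],
        )
        assert m.detect_hbonds(frame) == [(0, 1, 2)]

    def test_translation_invariance_modulo_box(self):
        frame = m.gen_hbond_geometry(0.30, 20.0, [2, 2, 2])
        shifted = m.ConfigurationFrame(
            elements=frame.elements, names=frame.names, mol_index=frame.mol_index,
            positions=np.mod(frame.positions + [1.7, 0.4, 1.1], frame.box),
            box=frame.box,
        )
        assert m.detect_hbonds(shifted) == m.detect_hbonds(frame)

    def test_explicit_donor_without_hydrogen_errors(self):
        frame = m.ConfigurationFrame(
            elements=["O", "O"], names=["OD", "OA"], mol_index=[0, 1],
            positions=[[1.0, 1.0, 1.0], [1.3, 1.0, 1.0]], box=[2, 2, 2],
        )
        with pytest.raises(AnalysisError, match="OD"):
            m.detect_hbonds(frame, selection=m.HBondSelection(donor_names=["OD"]))


class TestTrackBonds:
    def test_single_frame_matches_detect(self):
        frame = m.gen_hbond_geometry(0.30, 10.0, [2, 2, 2])
        ev = m.track_bonds([frame, frame], times=[0.0, 0.01])
        assert ev.bonds == m.detect_hbonds(frame)
        assert np.all(ev.indicators == 1)

    def test_atom_count_mismatch_errors(self):
        a = m.gen_hbond_geometry(0.30, 10.0, [2, 2, 2])
        b = m.gen_packing(2, 0.1, [2, 2, 2])
        with pytest.raises(AnalysisError, match="atoms"):
            m.track_bonds([a, b], times=[0.0, 0.01])

    def test_group_labels_from_molecule_kinds(self):
        frame = m.gen_hbond_geometry(0.30, 10.0, [2, 2, 2])
        ev = m.track_bonds([frame, frame], times=[0, 0.01],
                           mol_kind={0: "polymer", 1: "water"})
        assert ev.groups == ["polymer-water"]

    def test_bonds_per_monomer_arithmetic(self):
        frame = m.gen_hbond_geometry(0.30, 10.0, [2, 2, 2])
        ev = m.track_bonds([frame, frame], times=[0, 0.01])
        from mdprops.hbond import bonds_per_monomer

        assert bonds_per_monomer(ev, 4) == pytest.approx(0.25)


class TestExistenceFunction:
    def test_all_ones_gives_unity(self):
        ev = m.gen_bond_events(10, 50, 0.01, 0.0, 0.0)
        c = m.existence_function(ev)
        assert np.allclose(c.values[:, 1], 1.0)

    def test_instant_breaking_gives_delta_at_zero(self):
        ind = np.zeros((5, 20), dtype=np.int8)
        ind[:, 0] = 1
        ev = m.BondEventMatrix(
            bonds=[(i, i, i) for i in range(5)],
            times=np.arange(20) * 0.01, indicators=ind,
        )
        c = m.existence_function(ev)
        assert c.values[0, 1] == 1.0
        assert np.all(c.values[1:, 1] == 0.0)

    def test_empty_population_errors(self):
        ev = m.BondEventMatrix(
            bonds=[(0, 0, 0)], times=[0.0, 0.01],
            indicators=np.zeros((1, 2), dtype=np.int8),
        )
        with pytest.raises(AnalysisError, match="empty bond population"):
            m.existence_function(ev)

    def test_markov_decay_matches_survival_oracle(self):
        # k_reform = 0: C(t) = exp(-k t) exactly in expectation
        ev = m.gen_bond_events(10_000, 101, 0.01, 1.0, 0.0, m.GeneratorSpec(seed=11))
        c = m.existence_function(ev)
        t = c.values[:, 0]
        expected = np.exp(-t)
        se = np.sqrt(expected * (1 - expected) / 10_000) + 1e-9
        assert np.all(np.abs(c.values[:, 1] - expected) < 3 * se + 0.01)

    def test_bounded_in_unit_interval_with_reforming_bonds(self):
        ev = m.gen_bond_events(500, 301, 0.01, 1.0, 0.5, m.GeneratorSpec(seed=2))
        c = m.existence_function(ev)
        assert c.values[0, 1] == 1.0
        assert np.all((c.values[:, 1] >= 0) & (c.values[:, 1] <= 1.0 + 1e-12))


class TestFitDecay:
    def _table(self, t, y):
        return m.TimeSeriesTable(
            columns=[("time", "ns"), ("C_HB", "dimensionless")],
            values=np.column_stack([t, y]),
        )

    def test_single_exponential_integral_recovered(self):
        t = np.linspace(0, 10, 201)
        fit = m.fit_decay(self._table(t, np.exp(-t)))
        assert fit.converged
        assert fit.K1 * fit.tau1 + fit.K2 * fit.tau2 == pytest.approx(1.0, abs=1e-3)

    def test_constant_one_is_flagged_no_decay(self):
        t = np.linspace(0, 10, 50)
        fit = m.fit_decay(self._table(t, np.ones_like(t)))
        assert not fit.converged
        with pytest.raises(AnalysisError):
            m.lifetime_halflife(fit)

    def test_two_term_truth_recovered_from_noisy_curve(self):
        rng = np.random.default_rng(17)
        t = np.linspace(0, 10, 401)
        y = 0.6 * np.exp(-t / 0.5) + 0.4 * np.exp(-t / 8.0)
        y = np.clip(y + rng.normal(0, 0.005, t.shape), 0, 1)
        fit = m.fit_decay(self._table(t, y))
        integral = fit.K1 * fit.tau1 + fit.K2 * fit.tau2
        assert abs(integral - 3.5) / 3.5 < 0.05

    def test_too_few_points_errors(self):
        t = np.linspace(0, 1, 5)
        with pytest.raises(AnalysisError):
            m.fit_decay(self._table(t, np.exp(-t)))


class TestLifetimeHalflife:
    def test_single_term_closed_form(self):
        fit = m.DecayFit(K1=1.0, tau1=2.0, K2=0.0, tau2=1.0,
                         residual_norm=0.0, converged=True)
        res = m.lifetime_halflife(fit)
        assert res.lifetime == pytest.approx(2.0)
        assert res.half_life == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_two_term_against_bisection_oracle(self):
        fit = m.DecayFit(K1=0.5, tau1=1.0, K2=0.5, tau2=10.0,
                         residual_norm=0.0, converged=True)
        res = m.lifetime_halflife(fit)
        assert res.lifetime == pytest.approx(5.5)
        oracle = bisection_halflife_oracle(0.5, 1.0, 0.5, 10.0)
        assert res.half_life == pytest.approx(oracle, abs=1e-8)
        assert res.half_life == pytest.approx(1.80, abs=0.01)

    def test_low_initial_amplitude_flagged(self):
        fit = m.DecayFit(K1=0.2, tau1=1.0, K2=0.2, tau2=5.0,
                         residual_norm=0.0, converged=True)
        res = m.lifetime_halflife(fit)
        assert res.half_life == 0.0
        assert "C(0)<0.5" in res.flags

    def test_partial_integral_mode_is_smaller_than_crossing(self):
        fit = m.DecayFit(K1=0.5, tau1=1.0, K2=0.5, tau2=10.0,
                         residual_norm=0.0, converged=True)
        crossing = m.lifetime_halflife(fit, mode="crossing")
        partial = m.lifetime_halflife(fit, mode="partial_integral")
        assert partial.half_life < crossing.half_life

    @given(
        total=st.floats(0.5, 1.0), split=st.floats(0.0, 1.0),
        t1=st.floats(0.05, 5.0), t2=st.floats(0.05, 50.0),
    )
    def test_half_life_never_exceeds_lifetime(self, total, split, t1, t2):
        # median <= mean for completely monotone survival mixtures
        fit = m.DecayFit(K1=total * split, tau1=t1, K2=total * (1 - split), tau2=t2,
                         residual_norm=0.0, converged=True)
        res = m.lifetime_halflife(fit)
        assert res.half_life <= res.lifetime + 1e-12


class TestEndToEndKinetics:
    def test_lifetime_within_ten_percent_of_rate_inverse(self):
        ev = m.gen_bond_events(10_000, 1001, 0.01, 1.0, 0.0, m.GeneratorSpec(seed=21))
        c = m.existence_function(ev)
        fit = m.fit_decay(c)
        res = m.lifetime_halflife(fit)
        assert abs(res.lifetime - 1.0) < 0.1
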