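"""Binding experiments: mass-balance solvers, ITC and FRET forward models
and their fitters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import doubledrug as dd
from doubledrug.binding import free_concentrations_competitive


def oracle_bound(p_total, l_total, kd):
    """Independent [PL] via scalar root of (P-x)(L-x) = kd*x."""
    if p_total == 0 or l_total == 0:
        return 0.0
    hi = min(p_total, l_total)
    f = lambda x: (p_total - x) * (l_total - x) - kd * x
    return brentq(f, 0.0, hi, xtol=1e-300, rtol=1e-15)


class TestBoundComplex:
    @pytest.mark.parametrize("p,l,kd,expected", [
        (10.0, 0.0, 50.0, 0.0),
        (0.0, 100.0, 50.0, 0.0),
        (10.0, 100.0, 1e-12, 10.0),       # stoichiometric limit
    ])
    def test_limits(self, p, l, kd, expected):
        assert dd.bound_complex(p, l, kd) == pytest.approx(expected, abs=1e-9)

    def test_against_mass_balance_root(self):
        assert dd.bound_complex(10.0, 100.0, 100.0) == pytest.approx(
            oracle_bound(10.0, 100.0, 100.0), rel=1e-12)
        assert dd.bound_complex(10.0, 100.0, 100.0) == pytest.approx(4.875, abs=1e-3)

    def test_negative_input_rejected(self):
        with pytest.raises(dd.DomainError):
            dd.bound_complex(-1.0, 10.0, 5.0)

    @settings(derandomize=True, max_examples=200)
    @given(p=st.floats(0, 1e6), l=st.floats(0, 1e6), kd=st.floats(1e-9, 1e9))
    def test_bounds_and_conservation(self, p, l, kd):
        pl = dd.bound_complex(p, l, kd)
        assert 0.0 <= pl <= min(p, l) + 1e-9
        if pl > 0:  # detailed balance: free P * free L / PL == kd
            assert (p - pl) * (l - pl) / pl == pytest.approx(
                kd, rel=1e-6, abs=1e-9)


class TestCompetitiveSolver:
    def test_reduces_exactly_to_one_ligand_quadratic(self, rng):
        for _ in range(100):
            p, l, kd = 10.0 ** rng.uniform(-2, 3, size=3)
            fp, fl, fc = free_concentrations_competitive(p, l, 0.0, kd, 7.0)
            pl = dd.bound_complex(p, l, kd)
            assert fl == pytest.approx(l - pl, rel=1e-12, abs=1e-15)
            assert fc == 0.0

    def test_conserves_mass_randomised(self, rng):
        for _ in range(1000):
            p, l, c = 10.0 ** rng.uniform(-2, 3, size=3)
            kd_l, kd_c = 10.0 ** rng.uniform(-3, 2, size=2)
            fp, fl, fc = free_concentrations_competitive(p, l, c, kd_l, kd_c)
            pl, pc = fp * fl / kd_l, fp * fc / kd_c
            assert fp + pl + pc == pytest.approx(p, rel=1e-10)
            assert fl + pl == pytest.approx(l, rel=1e-10)
            assert fc + pc == pytest.approx(c, rel=1e-10)

    def test_no_protein_leaves_ligands_free(self):
        fp, fl, fc = free_concentrations_competitive(0.0, 5.0, 9.0, 1.0, 1.0)
        assert (fp, fl, fc) == (0.0, 5.0, 9.0)

    def test_half_saturation_matches_competitive_shift_formula(self):
        # tight ligand Kd 1 nM vs 10 uM competitor at 100 uM: apparent 11 nM
        p_tot, kd_l, kd_c, c_tot = 0.01, 0.001, 10.0, 100.0  # uM

        def occupancy(l_tot):
            _, fl, _ = free_concentrations_competitive(p_tot, l_tot, c_tot,
                                                       kd_l, kd_c)
            return (l_tot - fl) / p_tot

        l_half = brentq(lambda lt: occupancy(lt) - 0.5, 1e-6, 10.0)
        _, fl_half, fc_half = free_concentrations_competitive(
            p_tot, l_half, c_tot, kd_l, kd_c)
        expected = dd.apparent_kd_competitive(kd_l, kd_c, fc_half)
        assert fl_half == pytest.approx(expected, rel=0.01)


class TestApparentKdCompetitive:
    @pytest.mark.parametrize("kd_s,kd_w,c_free,expected", [
        (5.0, 10.0, 0.0, 5.0),
        (5.0, 10.0, 10.0, 10.0),               # competitor at its Kd doubles
        (0.87, 10e3, 100e3, 9.57),             # nM: tight inhibitor vs nucleotide
    ])
    def test_closed_form(self, kd_s, kd_w, c_free, expected):
        assert dd.apparent_kd_competitive(kd_s, kd_w, c_free) == \
            pytest.approx(expected, rel=1e-12)


class TestSimulateItc:
    def test_zero_enthalpy_gives_pure_offset(self, itc_protocol):
        th = dd.simulate_itc(itc_protocol,
                             dd.ITCOnesiteParams(kd=40.0, dh=0.0, q_offset=2.5))
        assert np.allclose(th.heats, 2.5)

    def test_total_heat_approaches_site_saturation(self):
        # 200 uL cell at 20 uM, dh -40 kJ/mol: n*dh*V0*cell = -160 uJ
        protocol = dd.ITCProtocol.uniform(200.0, 20.0, 200.0, 25, 2.0)
        th = dd.simulate_itc(protocol, dd.ITCOnesiteParams(kd=100.0, dh=-40.0))
        assert th.heats.sum() == pytest.approx(-160.0, rel=0.01)

    def test_cumulative_heat_converges_at_titrant_excess(self):
        protocol = dd.ITCProtocol.uniform(200.0, 5.0, 100.0, 40, 2.0)
        for n in (0.8, 1.0, 1.3):
            th = dd.simulate_itc(protocol,
                                 dd.ITCOnesiteParams(kd=20.0, dh=-40.0, n=n))
            assert th.heats.sum() == pytest.approx(n * -40.0 * 200.0 * 5.0 * 1e-3,
                                                   rel=0.01)

    def test_weak_binding_gives_featureless_small_heats(self, itc_protocol):
        # kd far above the syringe concentration: no sigmoid inflection
        th = dd.simulate_itc(itc_protocol,
                             dd.ITCOnesiteParams(kd=5e6, dh=-40.0))
        q = th.heats
        assert np.all(np.abs(q) < 2.0)
        assert np.all(np.diff(np.abs(q)) < np.abs(q[:-1]) * 0.2)

    def test_competition_scheme_with_no_competitor_is_direct(self, itc_protocol):
        params = dd.ITCOnesiteParams(kd=40.0, dh=-40.0)
        direct = dd.simulate_itc(itc_protocol, params)
        scheme = dd.CompetitionScheme(kd_weak=10.0, dh_weak=-10.0,
                                      competitor_total=0.0)
        assert np.allclose(dd.simulate_itc(itc_protocol, params, scheme).heats,
                           direct.heats, rtol=1e-12, atol=0)

    def test_competitor_weakens_apparent_binding(self, itc_protocol):
        """With a weak competitor pre-loaded, the titration sigmoid broadens
        as if the ligand were weaker by 1 + [C]/Kd_weak."""
        params = dd.ITCOnesiteParams(kd=10.0, dh=-40.0)
        scheme = dd.CompetitionScheme(kd_weak=10.0, dh_weak=0.0,
                                      competitor_total=500.0)
        competitive = dd.simulate_itc(itc_protocol, params, scheme)
        shifted = dd.simulate_itc(
            itc_protocol,
            dd.ITCOnesiteParams(kd=10.0 * (1 + 500.0 / 10.0), dh=-40.0))
        # same enthalpy budget, broadened shape close to the shifted Kd curve
        assert competitive.heats.sum() == pytest.approx(shifted.heats.sum(),
                                                        rel=0.05)
        assert np.max(np.abs(competitive.heats - shifted.heats)) < \
            0.1 * np.max(np.abs(shifted.heats))


class TestFitItc:
    def test_noiseless_round_trip(self, itc_protocol):
        truth = dd.ITCOnesiteParams(kd=40.0, dh=-40.0, n=1.0)
        fit = dd.fit_itc_onesite(dd.simulate_itc(itc_protocol, truth),
                                 itc_protocol)
        assert fit.converged
        assert fit.params["kd"] == pytest.approx(40.0, rel=1e-3)
        assert fit.params["dh"] == pytest.approx(-40.0, rel=1e-3)
        assert fit.params["n"] == pytest.approx(1.0, rel=1e-3)

    def test_noisy_monte_carlo_recovery(self, itc_protocol):
        truth = dd.ITCOnesiteParams(kd=40.0, dh=-40.0)
        clean = dd.simulate_itc(itc_protocol, truth)
        sd = 0.01 * np.max(np.abs(clean.heats))
        kds = []
        for seed in range(1, 21):
            noisy = dd.gen_itc(truth, itc_protocol,
                               noise=dd.NoiseSpec(itc_heat_sd_uj=sd, seed=seed))
            kds.append(dd.fit_itc_onesite(noisy, itc_protocol).params["kd"])
        assert np.median(kds) == pytest.approx(40.0, rel=0.05)

    def test_all_zero_heats_rejected(self, itc_protocol):
        th = dd.ITCThermogram(np.zeros(25))
        with pytest.raises(dd.FitError):
            dd.fit_itc_onesite(th, itc_protocol)

    def test_low_c_value_flagged(self):
        # cell 0.5 uM with kd 5 uM: c = 0.1, shape cannot pin the Kd
        protocol = dd.ITCProtocol.uniform(200.0, 0.5, 50.0, 25, 2.0)
        th = dd.simulate_itc(protocol, dd.ITCOnesiteParams(kd=5000.0, dh=-40.0))
        fit = dd.fit_itc_onesite(th, protocol)
        assert any("c-value" in m for m in fit.messages)


class TestFretSignal:
    def test_baseline_and_plateau(self):
        p = dd.FretParams(f0=100.0, amp=50.0, e_total=10.0, kd=40.0)
        assert dd.fret_signal(0.0, p) == pytest.approx(100.0)
        assert dd.fret_signal(1e9, p) == pytest.approx(150.0, rel=1e-4)

    def test_matches_bound_fraction_oracle(self):
        p = dd.FretParams(f0=100.0, amp=50.0, e_total=10.0, kd=40.0)
        bound = oracle_bound(10.0, 50.0, 40.0)
        assert dd.fret_signal(50.0, p) == pytest.approx(
            100.0 + 50.0 * bound / 10.0, rel=1e-12)
        assert dd.fret_signal(50.0, p) == pytest.approx(126.4, abs=0.05)

    def test_monotone_when_amplitude_positive(self):
        p = dd.FretParams(f0=100.0, amp=50.0, e_total=10.0, kd=40.0)
        grid = np.linspace(0, 500, 200)
        assert np.all(np.diff(dd.fret_signal(grid, p)) >= 0)

    def test_zero_enzyme_rejected(self):
        with pytest.raises(dd.DomainError):
            dd.FretParams(f0=0.0, amp=1.0, e_total=0.0, kd=40.0)


class TestFitFret:
    def test_noiseless_round_trip(self):
        truth = dd.FretParams(f0=100.0, amp=50.0, e_total=10.0, kd=40.0)
        curve = dd.gen_fret(truth, np.geomspace(1, 2000, 12))
        fit = dd.fit_fret(curve, 10.0)
        assert fit.params["kd"] == pytest.approx(40.0, rel=1e-3)
        assert fit.params["f0"] == pytest.approx(100.0, rel=1e-3)
        assert fit.params["amp"] == pytest.approx(50.0, rel=1e-3)

    def test_noisy_monte_carlo_recovery(self):
        truth = dd.FretParams(f0=100.0, amp=50.0, e_total=10.0, kd=40.0)
        grid = np.geomspace(1, 2000, 12)
        kds = [dd.fit_fret(
            dd.gen_fret(truth, grid,
                        dd.NoiseSpec(fret_fractional=0.02, seed=s)),
            10.0).params["kd"] for s in range(1, 21)]
        assert np.median(kds) == pytest.approx(40.0, rel=0.10)

    def test_stoichiometric_regime_flagged(self):
        truth = dd.FretParams(f0=100.0, amp=50.0, e_total=10.0, kd=0.1)
        curve = dd.gen_fret(truth, np.geomspace(0.5, 200, 10))
        with pytest.warns(dd.IdentifiabilityWarning):
            fit = dd.fit_fret(curve, 10.0)
        assert any("near-stoichiometric" in m for m in fit.messages)

    def test_too_few_points_rejected(self):
        curve = dd.TitrationCurve(np.array([1.0, 10.0, 100.0]),
                                  np.array([1.0, 2.0, 3.0]))
        with pytest.raises(dd.FitError):
            dd.fit_fret(curve, 10.0)
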