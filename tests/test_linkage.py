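"""Linkage core: species populations, apparent Kds and cooperativity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import doubledrug as dd
from doubledrug.linkage import apparent_kd_numeric

from conftest import random_model


def brute_force_populations(k_eq, kd_o, kd_a, c, free_o, free_a):
    """Independent enumeration of the 8 statistical weights in plain Python.

    kd_o/kd_a are (inactive, active) pairs; c is the (inactive, active)
    coupling pair.  Returns a dict keyed by (state, o_bound, a_bound).
    """
    weights = {}
    for s, w_state in ((0, 1.0), (1, k_eq)):
        ro = 0.0 if math.isinf(kd_o[s]) else free_o / kd_o[s]
        ra = 0.0 if math.isinf(kd_a[s]) else free_a / kd_a[s]
        weights[(s, 0, 0)] = w_state
        weights[(s, 1, 0)] = w_state * ro
        weights[(s, 0, 1)] = w_state * ra
        weights[(s, 1, 1)] = w_state * ro * ra * c[s]
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


class TestStatisticalWeights:
    def test_apo_two_state_ratio(self):
        m = dd.DoubleDrugModel(dd.StateEnsemble(0.67),
                               dd.SiteAffinities(math.inf, 10.0),
                               dd.SiteAffinities(math.inf, 100.0))
        dist = dd.statistical_weights(m, 0.0, 0.0)
        assert dist.fraction_active == pytest.approx(0.67 / 1.67, abs=1e-12)

    def test_matches_brute_force_enumeration(self, mb1_like_model):
        # inactive-exclusive orthosteric ligand at its Kd: three species
        # carry weight {active:0.67, inactive:1, inactive.O:1}
        dist = dd.statistical_weights(mb1_like_model, 10.0, 0.0)
        oracle = brute_force_populations(
            0.67, (10.0, math.inf), (100.0, math.inf), (1.0, 1.0), 10.0, 0.0)
        assert dist[0, 1, 0] == pytest.approx(1 / 2.67, rel=1e-12)
        for (s, o, a), pop in oracle.items():
            assert dist[s, o, a] == pytest.approx(pop, abs=1e-14)

    def test_no_ligand_means_no_bound_species(self, rng):
        m = random_model(rng)
        dist = dd.statistical_weights(m, 0.0, 0.0)
        assert dist.occupancy_orthosteric == 0.0
        assert dist.occupancy_allosteric == 0.0

    def test_negative_concentration_rejected(self, mb1_like_model):
        with pytest.raises(dd.DomainError):
            dd.statistical_weights(mb1_like_model, -1.0, 0.0)

    def test_populations_sum_to_one_randomised(self, rng):
        for _ in range(1000):
            m = random_model(rng)
            conc = 10.0 ** rng.uniform(-2, 5, size=2)
            dist = dd.statistical_weights(m, *conc)
            assert abs(dist.populations.sum() - 1.0) < 1e-12
            assert np.all(dist.populations >= 0)

    @settings(derandomize=True, max_examples=50)
    @given(k_eq=st.floats(1e-3, 1e3), free_o=st.floats(0, 1e6),
           free_a=st.floats(0, 1e6))
    def test_populations_are_a_distribution(self, k_eq, free_o, free_a):
        m = dd.DoubleDrugModel(dd.StateEnsemble(k_eq),
                               dd.SiteAffinities(50.0, 5.0),
                               dd.SiteAffinities(2.0, 200.0))
        p = dd.statistical_weights(m, free_o, free_a).populations
        assert abs(p.sum() - 1.0) < 1e-12 and np.all(p >= 0)


class TestFractionActive:
    def test_apo_value(self, mb1_like_model):
        assert dd.fraction_active(mb1_like_model, 0, 0) == pytest.approx(
            0.67 / 1.67, abs=1e-12)

    def test_inactive_binder_at_its_kd(self, mb1_like_model):
        # the bound branch doubles the inactive weight: 0.67 / 2.67
        assert dd.fraction_active(mb1_like_model, 10.0, 0.0) == pytest.approx(
            0.67 / 2.67, rel=1e-12)

    def test_saturating_inactive_binder_silences_active_state(self, mb1_like_model):
        assert dd.fraction_active(mb1_like_model, 1e12, 0.0) < 1e-9


class TestApparentKd:
    def test_apo_closed_form(self, mb1_like_model):
        # (1 + k_eq) * kd_inactive for an inactive-exclusive ligand
        assert dd.apparent_kd(mb1_like_model, "allosteric", 0.0) == \
            pytest.approx(167.0, rel=1e-12)

    def test_partner_saturation_recovers_state_kd(self, mb1_like_model):
        assert dd.apparent_kd(mb1_like_model, "allosteric", math.inf) == \
            pytest.approx(100.0, rel=1e-12)

    def test_state_independent_ligand_is_partner_blind(self, rng):
        m = dd.DoubleDrugModel(dd.StateEnsemble(0.67),
                               dd.SiteAffinities(5.0, 500.0),
                               dd.SiteAffinities(50.0, 50.0))
        for partner in (0.0, 3.0, 1e4, math.inf):
            assert dd.apparent_kd(m, "allosteric", partner) == \
                pytest.approx(50.0, rel=1e-12)

    def test_closed_form_agrees_with_numeric_half_occupancy(self, rng):
        for _ in range(200):
            m = random_model(rng)
            for site in ("orthosteric", "allosteric"):
                if m.site(site).binds_nothing:
                    continue
                for partner in (0.0, 10.0 ** rng.uniform(-1, 4), math.inf):
                    closed = dd.apparent_kd(m, site, partner)
                    if math.isinf(closed):
                        continue
                    numeric = apparent_kd_numeric(m, site, partner)
                    assert closed == pytest.approx(numeric, rel=1e-9)

    def test_non_binder_signalled(self):
        m = dd.DoubleDrugModel(dd.StateEnsemble(1.0),
                               dd.SiteAffinities(math.inf, math.inf),
                               dd.SiteAffinities(50.0, 50.0))
        with pytest.raises(dd.NonBinderError):
            dd.apparent_kd(m, "orthosteric", 0.0)

    def test_saturation_consistency_with_large_finite_partner(self, rng):
        # raising an already-saturating partner concentration tenfold leaves
        # the measured apparent Kd unchanged within 1 % (simultaneous-binding
        # control); "saturating" is judged against the partner's apparent Kd
        for _ in range(50):
            m = random_model(rng, allow_inf=False)
            scale = max(dd.apparent_kd(m, "orthosteric", 0.0),
                        dd.apparent_kd(m, "orthosteric", math.inf))
            kd_100 = dd.apparent_kd(m, "allosteric", 100.0 * scale)
            kd_1000 = dd.apparent_kd(m, "allosteric", 1000.0 * scale)
            assert kd_100 == pytest.approx(kd_1000, rel=0.01)

    def test_monotone_in_partner_for_matched_preferences(self, mb1_like_model):
        # both ligands prefer the inactive state: more partner, tighter site
        partner = np.concatenate([[0.0], np.geomspace(0.1, 1e6, 30)])
        kds = [dd.apparent_kd(mb1_like_model, "allosteric", p) for p in partner]
        assert np.all(np.diff(kds) <= 1e-12)


class TestCooperativityFactor:
    def test_pure_selection_limit_law(self, mb1_like_model):
        res = dd.cooperativity_factor(mb1_like_model, "allosteric")
        assert res.alpha == pytest.approx(1.67, rel=1e-12)
        assert res.direction == "positive"

    def test_state_independent_ligand_gives_unity(self):
        m = dd.DoubleDrugModel(dd.StateEnsemble(0.67),
                               dd.SiteAffinities(math.inf, 10.0),
                               dd.SiteAffinities(50.0, 50.0))
        res = dd.cooperativity_factor(m, "allosteric")
        assert res.alpha == pytest.approx(1.0, abs=1e-12)
        assert res.direction == "none"

    def test_intrastate_coupling_multiplies_alpha(self, mb1_like_model):
        from dataclasses import replace

        m = replace(mb1_like_model, coupling_inactive=3.0)
        res = dd.cooperativity_factor(m, "allosteric")
        assert res.alpha == pytest.approx(1.67 * 3.0, rel=1e-12)

    def test_thermodynamic_cycle_closure_randomised(self, rng):
        checked = 0
        while checked < 1000:
            m = random_model(rng)
            a_o = dd.cooperativity_factor(m, "orthosteric").alpha
            a_a = dd.cooperativity_factor(m, "allosteric").alpha
            if a_o == 0.0:  # mutually exclusive limit: both must agree on it
                assert a_a == 0.0
            else:
                assert abs(a_o / a_a - 1.0) < 1e-9
            checked += 1

    def test_order_of_binding_is_irrelevant(self, rng):
        # the fold measured by titrating the orthosteric ligand equals the
        # fold measured by titrating the allosteric one
        for _ in range(20):
            m = random_model(rng, allow_inf=False)
            f_o = dd.cooperativity_factor(m, "orthosteric").fold
            f_a = dd.cooperativity_factor(m, "allosteric").fold
            assert f_o == pytest.approx(f_a, rel=1e-9)

    def test_non_binder_rejected(self):
        m = dd.DoubleDrugModel(dd.StateEnsemble(1.0),
                               dd.SiteAffinities(math.inf, math.inf),
                               dd.SiteAffinities(50.0, 50.0))
        with pytest.raises(dd.NonBinderError):
            dd.cooperativity_factor(m, "allosteric")


class TestFreeConcentrations:
    def test_mass_conservation_randomised(self, rng):
        for _ in range(200):
            m = random_model(rng)
            o_t, a_t = 10.0 ** rng.uniform(-1, 4, size=2)
            e_t = 10.0 ** rng.uniform(0, 2)
            fo, fa = dd.free_concentrations(m, o_t, a_t, e_t)
            dist = dd.statistical_weights(m, fo, fa)
            assert fo + e_t * dist.occupancy_orthosteric == \
                pytest.approx(o_t, rel=1e-10, abs=1e-12)
            assert fa + e_t * dist.occupancy_allosteric == \
                pytest.approx(a_t, rel=1e-10, abs=1e-12)

    def test_no_depletion_limit(self, mb1_like_model):
        fo, fa = dd.free_concentrations(mb1_like_model, 100.0, 200.0, 1e-6)
        assert fo == pytest.approx(100.0, rel=1e-6)
        assert fa == pytest.approx(200.0, rel=1e-6)
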