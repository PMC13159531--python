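"""Condensed local descriptors, the R_k classifier and site ranking."""

import logging
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdftkit.global_indices import compute_global
from cdftkit.local_indices import (compute_sites, dual_descriptor, fukui,
                                   hypersoftness, parr_local,
                                   philicity_and_softness, rank_sites,
                                   reactivity_difference)
from cdftkit.species_io import AtomSite
from cdftkit.synthetic_data import SynthConfig, make_species


def atom(index=1, element="C", **kw):
    return AtomSite(index=index, element=element, **kw)


class TestFukui:
    def test_two_atom_hand_arithmetic(self):
        a1 = atom(1, p_neutral=1.0, p_anion=1.6, p_cation=0.7)
        a2 = atom(2, p_neutral=1.0, p_anion=1.4, p_cation=1.3)
        f1, f2_ = fukui(a1), fukui(a2)
        assert f1 == pytest.approx((0.6, 0.3), abs=1e-12)
        assert f2_ == pytest.approx((0.4, -0.3), abs=1e-12)
        assert f1[0] + f2_[0] == pytest.approx(1.0, abs=1e-12)

    def test_inert_atom_has_zero_fukui(self):
        f = fukui(atom(1, p_neutral=2.0, p_anion=2.0, p_cation=2.0))
        assert f == (0.0, 0.0)

    def test_missing_population_reports_unavailable(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert fukui(atom(1, p_neutral=2.0)) is None
        assert "unavailable" in caplog.text

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(st.floats(0.1, 8.0), st.floats(0.1, 8.0),
                     st.floats(0.1, 8.0)))
    def test_dual_descriptor_is_second_finite_difference(self, pops):
        pn, pa, pc = pops
        a = atom(1, p_neutral=pn, p_anion=pa, p_cation=pc)
        f_plus, f_minus = fukui(a)
        assert dual_descriptor(f_plus, f_minus) == pytest.approx(
            pa - 2 * pn + pc, abs=1e-9)


class TestDualDescriptor:
    @pytest.mark.parametrize("fp,fm,expected,site", [
        (0.011, 0.180, -0.169, "nucleophilic"),   # diazo carbon
        (0.184, 0.017, 0.167, "electrophilic"),   # exocyclic beta-carbon
        (0.3, 0.3, 0.0, None),
    ])
    def test_sign_marks_site_character(self, fp, fm, expected, site):
        f2 = dual_descriptor(fp, fm)
        assert f2 == pytest.approx(expected, abs=1e-12)
        if site:
            assert (f2 < 0) == (site == "nucleophilic")


class TestPhilicityAndSoftness:
    def test_diazo_carbon_with_printed_globals(self):
        ps = philicity_and_softness(0.011, 0.180, omega=1.974, softness=7.218)
        assert ps.dw == pytest.approx(-0.334, abs=1e-2)
        assert ps.s2 == pytest.approx(-8.805, abs=1e-2)

    def test_methoxy_alkene_beta_carbon_hypersoftness(self):
        assert hypersoftness(0.167, 8.123) == pytest.approx(11.019, abs=1e-2)

    def test_inert_site_gives_all_zeros(self):
        ps = philicity_and_softness(0.0, 0.0, omega=2.0, softness=8.0)
        assert all(v == 0.0 for v in ps)

    def test_sign_agreement_of_dual_family(self):
        for fp, fm in [(0.2, 0.05), (0.01, 0.18), (0.3, 0.2)]:
            ps = philicity_and_softness(fp, fm, omega=2.5, softness=8.0)
            f2 = dual_descriptor(fp, fm)
            if f2 != 0:
                assert math.copysign(1, ps.dw) == math.copysign(1, f2)
                assert math.copysign(1, ps.ds) == math.copysign(1, f2)
                assert math.copysign(1, ps.s2) == math.copysign(1, f2)


class TestParrLocal:
    def test_beta_carbon_local_electrophilicity(self):
        w_k, _ = parr_local(0.424, -0.018, omega=3.061, n_index=3.290)
        assert w_k == pytest.approx(1.298, abs=1e-2)

    def test_diazo_carbon_local_nucleophilicity(self):
        _, n_k = parr_local(-0.056, 0.233, omega=1.974, n_index=3.664)
        assert n_k == pytest.approx(0.854, abs=1e-2)

    def test_zero_spin_density_gives_zero(self):
        assert parr_local(0.0, 0.0, 2.0, 3.0) == (0.0, 0.0)


class TestReactivityDifference:
    def test_electrophilic_site(self):
        r, cls = reactivity_difference(1.298, -0.059)
        assert cls == "electrophilic"
        assert r == pytest.approx(1.36, abs=1e-2)

    def test_ambiphilic_window(self):
        r, cls = reactivity_difference(1.327, 1.363)
        assert cls == "ambiphilic"
        assert r == pytest.approx(1.345, abs=1e-2)

    def test_one_sided_nucleophilic(self):
        r, cls = reactivity_difference(0.0, 5.0)
        assert (r, cls) == (-5.0, "nucleophilic")

    def test_ratio_exactly_two_falls_to_difference_branch(self):
        r, cls = reactivity_difference(2.0, 1.0)
        assert (r, cls) == (1.0, "electrophilic")

    def test_equal_positive_inputs_are_ambiphilic_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            r, cls = reactivity_difference(1.0, 1.0)
        assert (r, cls) == (0.0, "ambiphilic")

    def test_negative_local_electrophilicity_skips_ratio(self):
        # ratio of mixed-sign quantities must not trigger ambiphilicity
        r, cls = reactivity_difference(-0.111, 0.854)
        assert cls == "nucleophilic"
        assert r == pytest.approx(-0.965, abs=1e-2)


class TestSumIdentities:
    def test_philicity_and_softness_sums_on_synthetic_record(self):
        (rec,) = make_species(SynthConfig(seed=11, n_species=1, n_atoms=6))
        g = compute_global(rec.orbitals)
        sites = compute_sites(rec, g)
        assert sum(s.w_plus for s in sites) == pytest.approx(g.omega,
                                                             abs=1e-9)
        assert sum(s.s_plus for s in sites) == pytest.approx(g.softness,
                                                             abs=1e-9)
        assert sum(s.dw for s in sites) == pytest.approx(0.0, abs=1e-9)
        assert sum(s.ds for s in sites) == pytest.approx(0.0, abs=1e-9)

    def test_sign_agreement_on_synthetic_sites(self):
        (rec,) = make_species(SynthConfig(seed=12, n_species=1, n_atoms=8))
        for s in compute_sites(rec, compute_global(rec.orbitals)):
            if s.f2:
                for v in (s.dw, s.ds, s.s2):
                    assert math.copysign(1, v) == math.copysign(1, s.f2)


class TestRankSites:
    def test_diazo_dipole_most_nucleophilic_is_committed_carbon(
            self, ref_records):
        rec = ref_records["4"]
        sites = compute_sites(rec, compute_global(rec.orbitals))
        ranked = rank_sites(sites, "nucleophilic")
        assert ranked[0].label == "C3"

    def test_alkene_most_electrophilic_is_beta_carbon(self, ref_records):
        rec = ref_records["Z-3a"]
        sites = compute_sites(rec, compute_global(rec.orbitals))
        assert rank_sites(sites, "electrophilic")[0].label == "C2"

    def test_tie_breaks_toward_lower_index(self):
        a = atom(1, asd_anion=0.4, asd_cation=-0.1)
        b = atom(2, asd_anion=0.4, asd_cation=-0.1)
        rec_sites = []
        from cdftkit.local_indices import compute_site
        from cdftkit.species_io import OrbitalEnergies
        g = compute_global(OrbitalEnergies(e_homo=-6.0, e_lumo=-2.0))
        rec_sites = [compute_site(x, g) for x in (b, a)]
        ranked = rank_sites(rec_sites, "electrophilic")
        assert [s.atom.index for s in ranked] == [1, 2]

    def test_no_classified_sites_returns_empty(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert rank_sites([], "nucleophilic") == []
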