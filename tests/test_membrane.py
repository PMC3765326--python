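"""Membrane probabilities, protocell life cycle and the movement phase."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ribocell as rc
from ribocell.core import RNAMolecule
from ribocell.membrane import (
    _divide,
    division_probability,
    membrane_formation_probability,
    movement_phase,
    permeation_in_probability,
    protocell_phase,
)

from conftest import zero_probability_params


class TestMembraneFormation:
    def test_probability_at_the_assembly_limit_is_P_MF(self, params):
        assert membrane_formation_probability(600, params) == pytest.approx(0.1)

    def test_one_extra_amphiphile_compounds_the_chance(self, params):
        assert membrane_formation_probability(601, params) == \
            pytest.approx(1 - 0.9 ** 2)

    def test_below_the_limit_no_membrane(self, params):
        assert membrane_formation_probability(599, params) == 0.0

    def test_successful_formation_encloses_the_room(self, params):
        world = rc.init_world(params.replace(P_MF=1.0, N=2, T_NPPB=0, T_APB=0),
                              seed=0)
        world.am[0] = 700
        protocell_phase(world)
        assert world.occupied[0]
        assert int(world.memb[0]) == 700
        assert int(world.am[0]) == 0


class TestAmphiphileLeave:
    def test_empty_interior_gives_bare_P_ALM(self, params):
        assert rc.amphiphile_leave_probability(1200, 0, params) == \
            pytest.approx(5e-5)

    def test_osmotic_damping_at_reference_concentration(self, params):
        b = 1200
        n = int((b / 2) ** 1.5)
        assert rc.amphiphile_leave_probability(b, n, params) == \
            pytest.approx(5e-5 / 6, rel=1e-3)

    @given(st.integers(600, 5000), st.integers(0, 5000), st.integers(1, 5000))
    @settings(max_examples=100, deadline=None)
    def test_monotone_nonincreasing_in_interior_content(self, b, n1, dn):
        p = rc.ParameterSet()
        assert rc.amphiphile_leave_probability(b, n1 + dn, p) <= \
            rc.amphiphile_leave_probability(b, n1, p)

    def test_membraneless_cell_is_an_error(self, params):
        with pytest.raises(ValueError):
            rc.amphiphile_leave_probability(0, 10, params)


class TestPermeationIn:
    def test_nucleotide_precursor_at_reference_membrane(self, params):
        assert permeation_in_probability("Np", 600, 0, params) == \
            pytest.approx(0.01)

    def test_uncharged_amphiphile_precursor_skips_donnan_damping(self, params):
        # y = (2400/600)^(3/2) = 8; Donnan must not apply even at high n
        expected = 1 - 0.95 ** 8
        assert permeation_in_probability("Ap", 2400, 0, params) == \
            pytest.approx(expected)
        assert permeation_in_probability("Ap", 2400, 10_000, params) == \
            pytest.approx(expected)

    def test_donnan_factor_of_one_halves_the_influx(self, params):
        b = 600
        n = int((b / 2) ** 1.5 / params.F_DE)
        undamped = 1 - (1 - params.P_NPP) ** 1.0
        assert permeation_in_probability("Np", b, n, params) == \
            pytest.approx(undamped / 2, rel=1e-2)

    @given(st.sampled_from(["Np", "Npp", "Ap"]),
           st.integers(600, 10_000), st.integers(0, 100_000))
    @settings(max_examples=200, deadline=None)
    def test_always_a_probability(self, species, b, n):
        p = permeation_in_probability(species, b, n, rc.ParameterSet())
        assert 0.0 <= p <= 1.0

    @given(st.sampled_from(["Np", "Npp"]),
           st.integers(600, 5000), st.integers(0, 5000), st.integers(1, 5000))
    @settings(max_examples=100, deadline=None)
    def test_influx_nonincreasing_in_interior_content(self, species, b, n, dn):
        p = rc.ParameterSet()
        assert permeation_in_probability(species, b, n + dn, p) <= \
            permeation_in_probability(species, b, n, p)

    def test_impermeable_species_rejected(self, params):
        with pytest.raises(ValueError):
            permeation_in_probability("Nt", 600, 0, params)


class TestDivision:
    def test_at_twice_the_limit_division_is_impossible(self, params):
        assert division_probability(1200, params) == 0.0

    def test_closed_form_above_the_limit(self, params):
        assert division_probability(1800, params) == pytest.approx(0.02 / 3)

    def test_limit_for_a_huge_cell_is_P_CD(self, params):
        assert division_probability(10_000_000, params) == \
            pytest.approx(0.02, rel=1e-3)

    def test_division_conserves_membrane_and_interior(self, params):
        world = rc.init_world(params.replace(N=3, T_NPPB=0, T_APB=0), seed=3)
        room = world.room_index((1, 1))
        world.occupied[room] = True
        world.memb[room] = 3000
        world.npp[room] = 200
        world.nt[room, 0] = 40
        world.rna[room] = [RNAMolecule(seq="GAGUCUCU") for _ in range(10)]
        _divide(world, room)
        assert int(world.occupied.sum()) == 2
        assert rc.amphiphile_mass_audit(world) == 3000
        assert rc.nucleotide_mass_audit(world) == 200 + 40 + 80


class TestFusionAndBreak:
    def test_adjacent_cells_fuse_and_pool_their_membranes(self, params):
        p = zero_probability_params(P_CF=1.0).replace(N=3, T_NPPB=0, T_APB=0)
        world = rc.init_world(p, seed=0)
        a, b = world.room_index((0, 0)), world.room_index((0, 1))
        for room, mem in ((a, 700), (b, 900)):
            world.occupied[room] = True
            world.memb[room] = mem
        protocell_phase(world)
        assert int(world.occupied.sum()) == 1
        assert int(world.memb.max()) == 1600
        assert rc.amphiphile_mass_audit(world) == 1600

    def test_breaking_releases_the_membrane_as_free_amphiphiles(self, params):
        p = zero_probability_params(P_CB=1.0).replace(N=3, T_NPPB=0, T_APB=0)
        world = rc.init_world(p, seed=0)
        room = world.room_index((1, 1))
        world.occupied[room] = True
        world.memb[room] = 800
        world.nt[room, 2] = 30
        protocell_phase(world)
        assert not world.occupied.any()
        assert int(world.am[room]) == 800
        assert int(world.nt[room, 2]) == 30   # interior released into the room


class TestMovement:
    def test_rna_movement_slows_with_the_cube_root_of_mass(self, params):
        # one-step move fraction of many 8-mers ~ 0.5 / 8^(1/3) = 0.25
        p = zero_probability_params(P_MV=0.5).replace(N=5, T_NPPB=0, T_APB=0)
        world = rc.init_world(p, seed=9)
        room = world.room_index((2, 2))
        world.rna[room] = [RNAMolecule(seq="GAGUCUCU") for _ in range(4000)]
        movement_phase(world)
        stayed = len(world.rna[room])
        assert 4000 - stayed == pytest.approx(1000, abs=120)  # ~5 sigma

    def test_molecules_do_not_cross_membranes_by_diffusion(self):
        p = zero_probability_params(P_MV=1.0).replace(N=3, T_NPPB=0, T_APB=0)
        world = rc.init_world(p, seed=1)
        center = world.room_index((1, 1))
        for nb in world.neighbor_idx[center]:
            world.occupied[int(nb)] = True
            world.memb[int(nb)] = 600
        world.npp[center] = 500
        movement_phase(world)
        assert int(world.npp[center]) == 500   # every exit blocked

    def test_long_run_distribution_is_uniform_across_the_torus(self):
        p = zero_probability_params(P_MV=0.5).replace(N=5, T_NPPB=0, T_APB=0)
        world = rc.init_world(p, seed=4)
        world.npp[0] = 10_000
        for _ in range(300):
            movement_phase(world)
        observed = world.npp.astype(float)
        assert stats.chisquare(observed).pvalue > 1e-3
        assert int(observed.sum()) == 10_000
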