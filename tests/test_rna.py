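"""Sequence machinery, degradation, ligation, template-directed copying."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ribocell as rc
from ribocell.core import RNAMolecule, Segment
from ribocell.rna import (
    attract_substrate,
    bond_breaking,
    canonical_rotation,
    classify_molecule,
    dissociation,
    end_decay,
    random_ligation_and_cyclization,
    rna_phase,
    template_ligation,
)

from conftest import zero_probability_params

rna_seq = st.text(alphabet="AUGC", min_size=1, max_size=40)


def one_room_world(params=None, seed=0, occupied=True):
    p = (params or rc.ParameterSet()).replace(N=1, T_NPPB=0, T_APB=0)
    world = rc.init_world(p, seed=seed)
    world.occupied[0] = occupied
    if occupied:
        world.memb[0] = p.L_AM
    return world


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [
        ("GAGUCUCU", "AGAGACUC"),
        ("A", "U"),
        ("GC", "GC"),
    ])
    def test_examples(self, seq, expected):
        assert rc.reverse_complement(seq) == expected

    @given(rna_seq)
    @settings(max_examples=100, deadline=None)
    def test_involution(self, seq):
        assert rc.reverse_complement(rc.reverse_complement(seq)) == seq

    def test_antisense_chain_is_reverse_complement_of_sense(self, design):
        assert rc.reverse_complement(design.sense_sequence) == design.antisense_sequence

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            rc.reverse_complement("GAT")


class TestActiveRibozymeRoles:
    def test_exact_domain_is_active(self, design):
        assert rc.active_ribozyme_roles(RNAMolecule(seq="GAGUCUCU"), design) == {"Rep"}

    def test_chain_at_1_5x_domain_length_is_inactive(self, design):
        mol = RNAMolecule(seq="GAGUCUCU" + "AAAA")  # 12 nt, 12 is not < 12
        assert rc.active_ribozyme_roles(mol, design) == set()

    def test_embedded_domains_in_circular_chromosome_are_silenced(self, design):
        mol = RNAMolecule(seq=design.sense_sequence, circular=True)
        assert rc.active_ribozyme_roles(mol, design) == set()

    def test_template_state_suppresses_activity(self, design):
        mol = RNAMolecule(seq="GAGUCUCU", is_template=True)
        assert rc.active_ribozyme_roles(mol, design) == set()

    def test_slightly_longer_chain_still_active(self, design):
        mol = RNAMolecule(seq="AGAGUCUCUAA")  # 11 nt < 12
        assert rc.active_ribozyme_roles(mol, design) == {"Rep"}


class TestCleavageSites:
    def test_full_length_sense_transcript_has_three_sites(self, design):
        mol = RNAMolecule(seq=design.sense_sequence)
        assert rc.cleavage_sites(mol) == [7, 15, 23]

    def test_antisense_transcript_has_no_sites(self, design):
        mol = RNAMolecule(seq=design.antisense_sequence)
        assert rc.cleavage_sites(mol) == []

    def test_single_domain_has_no_sites(self):
        assert rc.cleavage_sites(RNAMolecule(seq="GAGUCUCU")) == []

    def test_circular_chromosome_has_no_sites(self, design):
        mol = RNAMolecule(seq=design.sense_sequence, circular=True)
        assert rc.cleavage_sites(mol) == []

    def test_cleaving_all_sites_regenerates_the_four_domains(self, design):
        s = design.sense_sequence
        cuts = [0] + [b + 1 for b in (7, 15, 23)] + [32]
        fragments = [s[a:b] for a, b in zip(cuts, cuts[1:])]
        assert fragments == list(design.domains.values())


class TestBondBreaking:
    def test_fragment_count_matches_binomial_oracle(self, rng):
        # with a uniform per-bond probability the number of breaks in a
        # linear 32-mer is Binomial(31, p); fragments = breaks + 1
        p = 0.08
        params = rc.ParameterSet().replace(P_BB=p, F_IB=1.0 + 1e-9)
        seq = "AUGC" * 8
        counts = []
        for _ in range(2000):
            frags = bond_breaking(RNAMolecule(seq=seq), True, params, rng)
            counts.append(sum(len(f.seq) for f in frags) and len(frags) - 1)
            assert sum(len(f.seq) for f in frags) == 32   # residue conservation
        observed = np.bincount(counts, minlength=10)[:10]
        expected = stats.binom.pmf(np.arange(10), 31, p) * len(counts)
        mask = expected > 5
        chi2 = ((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum()
        assert stats.chi2.sf(chi2, mask.sum() - 1) > 1e-3

    def test_single_break_linearizes_a_circle(self, rng):
        params = rc.ParameterSet().replace(P_BB=1e-3, F_IB=1.0 + 1e-9)
        seen_linear = 0
        for _ in range(500):
            mol = RNAMolecule(seq="AUGC" * 8, circular=True)
            frags = bond_breaking(mol, True, params, rng)
            assert sum(len(f.seq) for f in frags) == 32
            if len(frags) == 1 and not frags[0].circular and len(frags[0].seq) == 32:
                seen_linear += 1
        assert seen_linear > 0

    def test_cleavage_sites_break_F_IB_times_faster(self, design, rng):
        # at P_BB * F_IB = 0.2 the three U|G bonds of the sense transcript
        # break far more often than the 28 plain bonds at 0.002
        params = rc.ParameterSet().replace(P_BB=2e-3, F_IB=100.0)
        domain_hits = 0
        for _ in range(300):
            frags = bond_breaking(RNAMolecule(seq=design.sense_sequence),
                                  True, params, rng)
            domain_hits += sum(1 for f in frags if f.seq in design.domains.values())
        assert domain_hits > 100


class TestEndDecay:
    def test_circular_chromosome_is_exempt(self, design, rng):
        params = rc.ParameterSet().replace(P_NDE=1.0)
        mol = RNAMolecule(seq=design.sense_sequence, circular=True)
        out, released = end_decay(mol, True, params, rng)
        assert out.seq == design.sense_sequence
        assert released == 0

    def test_both_termini_decay_independently(self, rng):
        params = rc.ParameterSet().replace(P_NDE=1.0)
        out, released = end_decay(RNAMolecule(seq="AUGC"), True, params, rng)
        assert out.seq == "UG"
        assert released == 2

    def test_released_residues_become_precursors_in_phase(self, design):
        world = one_room_world(rc.ParameterSet().replace(P_NDE=1.0))
        world.rna[0].append(RNAMolecule(seq="AU"))
        rna_phase(world, 0)
        # 2-mer loses both ends -> two nucleotide precursors
        assert int(world.np_[0]) == 2
        assert world.rna[0] == []


class TestLigationAndCyclization:
    def test_two_chains_ligate_end_to_end(self):
        world = one_room_world(zero_probability_params(P_RL=1.0))
        world.rna[0] = [RNAMolecule(seq="GAGUCUCU"), RNAMolecule(seq="GCUCGUAU")]
        random_ligation_and_cyclization(world, 0)
        assert len(world.rna[0]) == 1
        assert len(world.rna[0][0].seq) == 16

    def test_full_length_sense_chain_cyclizes_into_a_chromosome(self, design):
        world = one_room_world(zero_probability_params(P_EL=1.0))
        rotated = design.sense_sequence[5:] + design.sense_sequence[:5]
        world.rna[0] = [RNAMolecule(seq=rotated)]
        random_ligation_and_cyclization(world, 0)
        mol = world.rna[0][0]
        assert mol.circular
        assert classify_molecule(mol, design) == "sense_chromosome"

    def test_zero_probabilities_change_nothing(self):
        world = one_room_world(zero_probability_params())
        world.rna[0] = [RNAMolecule(seq="GAGUCUCU")]
        world.nt[0] = [5, 5, 5, 5]
        random_ligation_and_cyclization(world, 0)
        assert len(world.rna[0]) == 1
        assert world.nt[0].sum() == 20

    def test_chains_below_minimum_loop_cannot_cyclize(self):
        world = one_room_world(zero_probability_params(P_EL=1.0))
        world.rna[0] = [RNAMolecule(seq="AU")]
        random_ligation_and_cyclization(world, 0)
        assert not world.rna[0][0].circular


class TestDissociation:
    def test_closed_form_over_r_1_to_64(self, params):
        for r in range(1, 65):
            assert rc.dissociation_probability(r, params) == \
                pytest.approx(0.5 ** np.sqrt(r))

    def test_single_pair_separates_half_the_time(self, params):
        assert rc.dissociation_probability(1, params) == pytest.approx(0.5)

    def test_strictly_decreasing_in_duplex_length(self, params):
        probs = [rc.dissociation_probability(r, params) for r in range(1, 65)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_released_product_reenters_the_pool(self, design):
        world = one_room_world(zero_probability_params(P_SP=1.0))
        tpl = RNAMolecule(seq=design.sense_sequence, circular=True,
                          is_template=True)
        tpl.segments.append(Segment(start=0, bases="CUCAGAGA"[::-1],
                                    mismatch=(False,) * 8))
        world.rna[0] = [tpl]
        dissociation(world, 0, tpl)
        assert tpl.segments == []
        assert len(world.rna[0]) == 2


class TestTemplateCopying:
    def run_replication(self, design, seed, p_fp):
        params = rc.ParameterSet().replace(P_FP=p_fp, P_FLR=0.0)
        world = one_room_world(params, seed=seed)
        tpl = RNAMolecule(seq=design.sense_sequence, circular=True)
        world.rna[0] = [tpl] + [RNAMolecule(seq=design.domain_Rep)
                                for _ in range(3)]
        world.nt[0] = [150, 150, 150, 150]
        for _ in range(2500):
            rna_phase(world, 0)
        return world

    def test_perfect_fidelity_products_are_exact_reverse_complements(self, design):
        """With no false pairing tolerated, every full-length circular copy
        of the sense chromosome is its exact (rotated) reverse complement."""
        world = self.run_replication(design, seed=11, p_fp=0.0)
        copies = [m for m in world.rna[0]
                  if m.circular and len(m.seq) == 32
                  and canonical_rotation(m.seq) != canonical_rotation(design.sense_sequence)]
        assert copies, "replication produced no full-length circular copies"
        target = canonical_rotation(design.antisense_sequence)
        for m in copies:
            assert canonical_rotation(m.seq) == target

    def test_replication_conserves_residues(self, design):
        world = self.run_replication(design, seed=12, p_fp=0.01)
        assert rc.nucleotide_mass_audit(world) == 600 + 32 + 3 * 8

    def test_no_rep_means_essentially_no_complete_copies(self, design):
        """Without the replicase the aligned pieces are almost never
        consolidated (P_TL = 5e-4), so circular copies do not appear."""
        params = rc.ParameterSet().replace(P_FP=0.0, P_FLR=0.0)
        world = one_room_world(params, seed=13)
        tpl = RNAMolecule(seq=design.sense_sequence, circular=True)
        world.rna[0] = [tpl]
        world.nt[0] = [150, 150, 150, 150]
        for _ in range(1500):
            rna_phase(world, 0)
        anti = [m for m in world.rna[0] if m.circular and len(m.seq) == 32
                and canonical_rotation(m.seq)
                == canonical_rotation(design.antisense_sequence)]
        assert len(anti) == 0


class TestRepBindingRules:
    def test_no_rep_in_compartment_means_no_binding(self, design):
        world = one_room_world(zero_probability_params(P_RB=1.0))
        tpl = RNAMolecule(seq=design.sense_sequence, circular=True,
                          is_template=True)
        world.rna[0] = [tpl]
        from ribocell.rna import rep_binding
        rep_binding(world, 0, tpl)
        assert not tpl.rep_bound

    def test_bound_rep_is_sequestered_from_the_free_pool(self, design):
        from ribocell.rna import rep_binding
        world = one_room_world(zero_probability_params(P_RB=1.0))
        tpl = RNAMolecule(seq=design.sense_sequence, circular=True,
                          is_template=True)
        rep = RNAMolecule(seq=design.domain_Rep)
        world.rna[0] = [tpl, rep]
        rep_binding(world, 0, tpl)
        assert tpl.rep_bound and tpl.bound_rep is rep
        assert rep not in world.rna[0]
        # sequestered rep no longer catalyses
        from ribocell.chemistry import room_catalysts
        assert "Rep" not in room_catalysts(world, 0)


class TestClassifyMolecule:
    def test_rotated_circular_sense_is_the_chromosome(self, design):
        s = design.sense_sequence
        mol = RNAMolecule(seq=s[5:] + s[:5], circular=True)
        assert classify_molecule(mol, design) == "sense_chromosome"

    def test_linear_sense_chain_is_not_a_chromosome(self, design):
        mol = RNAMolecule(seq=design.sense_sequence)
        assert classify_molecule(mol, design) == "other"

    def test_circular_control_is_the_control(self, design):
        mol = RNAMolecule(seq=design.control_sequence, circular=True)
        assert classify_molecule(mol, design) == "control"

    def test_free_ribozyme_classified_by_role(self, design):
        assert classify_molecule(RNAMolecule(seq="GCUCGUAU"), design) == \
            frozenset({"Nsr"})
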