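"""Energy model: parsing, structure and duplex energies vs hand sums and an
independent term-enumeration oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnatarget.energy_model import (
    DotBracketError,
    EnergyParameters,
    RnaSequence,
    SecondaryStructure,
    ValidityError,
    default_parameters,
    duplex_energy,
    load_parameters,
    pair_index,
    parse_dotbracket,
    structure_energy,
)
from srnatarget.ensemble import sample_structures

from oracles import naive_structure_energy

GC_HAIRPIN = RnaSequence(id="hp", seq="GGGAAAUCCC")


class TestRnaSequence:
    def test_t_converted_and_recorded(self):
        seq = RnaSequence(id="dna", seq="ACGT")
        assert seq.seq == "ACGU" and seq.converted_t

    def test_rejects_empty_and_bad_alphabet(self):
        with pytest.raises(ValueError):
            RnaSequence(id="x", seq="")
        with pytest.raises(ValueError):
            RnaSequence(id="x", seq="ACGX")

    def test_start_codon_relative_coordinates_skip_zero(self):
        # AUG starts at 0-based offset 20: position 21 is +1, position 20 is -1.
        seq = RnaSequence(id="m", seq="A" * 30 + "AUG" + "A" * 10, start_codon_offset=30)
        assert seq.to_relative(31) == 1
        assert seq.to_relative(30) == -1
        assert seq.to_relative(11) == -20
        assert seq.from_relative(-20) == 11
        for rel in (-20, -1, 1, 5):
            assert seq.to_relative(seq.from_relative(rel)) == rel
        with pytest.raises(ValueError):
            seq.from_relative(0)

    def test_start_codon_offset_bounds(self):
        with pytest.raises(ValueError):
            RnaSequence(id="m", seq="ACGU", start_codon_offset=7)


class TestParseDotbracket:
    @pytest.mark.parametrize("text,seq,expected", [
        ("..........", "ACGUACGUAC", set()),
        ("(((....)))", "GGGAAAUCCC", {(0, 9), (1, 8), (2, 7)}),
    ])
    def test_examples(self, text, seq, expected):
        st_ = parse_dotbracket(text, RnaSequence(id="s", seq=seq))
        assert set(st_.pairs) == expected

    def test_unbalanced_raises_with_position(self):
        with pytest.raises(DotBracketError, match="position"):
            parse_dotbracket("((.", RnaSequence(id="s", seq="GGC"))
        with pytest.raises(DotBracketError):
            parse_dotbracket(").(", RnaSequence(id="s", seq="GGC"))

    def test_disallowed_pair_and_small_hairpin_rejected(self):
        with pytest.raises(ValidityError):
            parse_dotbracket("(....)", RnaSequence(id="s", seq="AAAAAC"))  # A-C
        with pytest.raises(ValidityError):
            parse_dotbracket("(..)", RnaSequence(id="s", seq="GAAC"))


class TestStructureEnergy:
    def test_empty_structure_scores_zero(self, params):
        assert structure_energy(GC_HAIRPIN, SecondaryStructure([])) == 0.0

    def test_hand_summed_gc_hairpin(self, params):
        # (((....))): two GC/GC stacks plus the 4-nt hairpin penalty, summed
        # by hand from the shipped table; no terminal AU penalties (GC ends).
        st_ = parse_dotbracket("(((....)))", GC_HAIRPIN)
        gc = pair_index("G", "C")
        expected = 2 * params.stack[gc][gc] + params.hairpin[4]
        assert structure_energy(GC_HAIRPIN, st_, params) == pytest.approx(expected)

    def test_additive_over_disjoint_hairpins(self, params):
        single = GC_HAIRPIN
        double = RnaSequence(id="hp2", seq=GC_HAIRPIN.seq + "AA" + GC_HAIRPIN.seq)
        st1 = parse_dotbracket("(((....)))", single)
        st2 = parse_dotbracket("(((....))).." + "(((....)))", double)
        e1 = structure_energy(single, st1, params)
        assert structure_energy(double, st2, params) == pytest.approx(2 * e1)

    def test_energy_is_set_semantics(self, params):
        a = SecondaryStructure([(0, 9), (1, 8), (2, 7)])
        b = SecondaryStructure([(2, 7), (0, 9), (1, 8)])
        assert a == b
        assert structure_energy(GC_HAIRPIN, a, params) == \
            structure_energy(GC_HAIRPIN, b, params)

    def test_agrees_with_term_enumeration_oracle_on_sampled_structures(self, params, rng):
        # 200 random valid structures over random sequences up to 30 nt,
        # drawn from the Boltzmann sampler (then re-validated).
        checked = 0
        while checked < 200:
            n = int(rng.integers(12, 31))
            seq = RnaSequence(id="r", seq="".join(rng.choice(list("ACGU"), size=n)))
            ens = sample_structures(seq, params, n=20, seed=int(rng.integers(2**31)))
            for st_ in ens.structures[:10]:
                st_.validate(seq)
                assert structure_energy(seq, st_, params) == pytest.approx(
                    naive_structure_energy(seq, st_, params), abs=1e-9
                )
                checked += 1

    def test_invalid_structure_rejected(self, params):
        crossing = SecondaryStructure([(0, 9), (4, 14)])
        seq = RnaSequence(id="x", seq="GGGGGAAAACCCCCU")
        with pytest.raises(ValidityError):
            structure_energy(seq, crossing, params)


class TestDuplexEnergy:
    def test_empty_pairing_scores_duplex_init(self, params):
        assert duplex_energy("ACGU", "ACGU", [], params) == params.duplex_init

    def test_fully_complementary_eight_mer_hand_sum(self, params):
        w = "GGGGCCCC"
        m = "GGGGCCCC"  # reverse complement of w read 5'->3'
        pairs = [(i, 7 - i) for i in range(8)]
        expected = params.duplex_init
        for (i, j), (k, l) in zip(pairs, pairs[1:]):
            expected += params.stack[pair_index(w[i], m[j])][pair_index(w[k], m[l])]
        # GC at both ends: no terminal penalties.
        assert duplex_energy(w, m, pairs, params) == pytest.approx(expected)

    def test_terminal_au_penalties_charged_at_both_ends(self, params):
        w, m = "AGGGCCCU", "AGGGCCCU"
        pairs = [(i, 7 - i) for i in range(8)]
        dG = duplex_energy(w, m, pairs, params)
        expected = params.duplex_init + 2 * params.terminal_AU
        for (i, j), (k, l) in zip(pairs, pairs[1:]):
            expected += params.stack[pair_index(w[i], m[j])][pair_index(w[k], m[l])]
        assert dG == pytest.approx(expected)

    def test_one_by_one_internal_loop_hand_check(self, params):
        # Perfect 7-pair duplex vs the same with the middle pair replaced by
        # a 1x1 loop: lose two stacks, gain one stack-across + internal(2).
        w_perfect = "GGGCGGG"
        m_perfect = "CCCGCCC"[::-1]
        pairs_p = [(i, 6 - i) for i in range(7)]
        w_loop, m_loop = "GGGAGGG", ("CCCACCC")[::-1]
        pairs_l = [(i, 6 - i) for i in range(7) if i != 3]
        gc, cg = pair_index("G", "C"), pair_index("C", "G")
        d_perfect = duplex_energy(w_perfect, m_perfect, pairs_p, params)
        d_loop = duplex_energy(w_loop, m_loop, pairs_l, params)
        delta = (d_loop - d_perfect)
        hand = params.internal[2] - params.stack[gc][cg] - params.stack[cg][gc]
        assert delta == pytest.approx(hand)

    def test_crossing_pairs_rejected(self, params):
        with pytest.raises(ValidityError):
            duplex_energy("GGGG", "CCCC", [(0, 1), (1, 2)], params)


class TestParameterTable:
    def test_roundtrip_through_text_format(self, params):
        from importlib import resources
        text = (resources.files("srnatarget") / "data" / "nn_params_37C.txt").read_text()
        again = load_parameters(text)
        assert again.stack == params.stack
        assert again.hairpin == params.hairpin
        assert again.terminal_AU == params.terminal_AU

    def test_stack_table_physical_symmetry(self, params):
        # E(outer p, inner q) must equal E(outer rev(q), inner rev(p)).
        order = ("CG", "GC", "GU", "UG", "AU", "UA")
        rev = {p: p[::-1] for p in order}
        idx = {p: k for k, p in enumerate(order)}
        for p in order:
            for q in order:
                assert params.stack[idx[p]][idx[q]] == \
                    params.stack[idx[rev[q]]][idx[rev[p]]]

    def test_loop_tables_extrapolate_logarithmically(self, params):
        h30 = params.hairpin[30]
        assert params.hairpin_energy(60) == pytest.approx(
            h30 + params.lxc * math.log(2.0))

    @given(st.floats(min_value=-50, max_value=0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_temperature_must_be_positive(self, temp):
        with pytest.raises(ValueError):
            EnergyParameters(
                temperature=temp, stack=[[0.0] * 6] * 6,
                hairpin={3: 5.0}, bulge={1: 3.0}, internal={2: 1.0},
                multiloop_closing=9.3, multiloop_branch=-0.9,
                multiloop_unpaired=0.0, terminal_AU=0.5, duplex_init=0.0,
                lxc=1.07856,
            )
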