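"""Partition function, exact pair probabilities, stochastic sampling,
profiles, centroid and clustering — checked against exhaustive enumeration."""

import math

import numpy as np
import pytest

from srnatarget.energy_model import (
    RnaSequence,
    SecondaryStructure,
    ValidityError,
    parse_dotbracket,
    structure_energy,
)
from srnatarget.ensemble import (
    CapacityError,
    StructureEnsemble,
    centroid_structure,
    cluster_ensemble,
    pair_probabilities,
    partition_function,
    sample_structures,
    ss_profile,
)

from conftest import random_rna
from oracles import (
    enumeration_pair_probabilities,
    enumeration_partition,
)

BISTABLE_12 = RnaSequence(id="bi", seq="GGGAAACCCAAA")
RICH_15 = RnaSequence(id="rich", seq="GGCAUUUGCCGCAAA")


def manual_ensemble(seq, structures, params):
    n = len(seq)
    counts = np.zeros((n, n))
    for st in structures:
        for i, j in st.pairs:
            counts[i, j] += 1
    pair_prob = (counts + counts.T) / len(structures)
    return StructureEnsemble(
        seq=seq, structures=list(structures), sample_size=len(structures),
        seed=0, pair_prob=pair_prob, ss_profile=1.0 - pair_prob.sum(axis=1),
        ensemble_energies=np.array(
            [structure_energy(seq, st, params) for st in structures]),
    )


class TestPartitionFunction:
    def test_unpairable_sequence_gives_unit_z(self, params):
        res = partition_function(RnaSequence(id="a", seq="AAAA"), params)
        assert res.Z == 1.0 and res.ensemble_free_energy == 0.0

    def test_matches_enumeration_on_random_15mers(self, params, rng):
        for _ in range(5):
            seq = random_rna(rng, 15)
            Zdp = partition_function(seq, params).Z
            Zenum, _ = enumeration_partition(seq, params)
            assert Zdp == pytest.approx(Zenum, rel=1e-6)

    def test_appending_unpairable_run_leaves_z_unchanged(self, params):
        # U-free base sequence: appended A's have no possible partner.
        seq = RnaSequence(id="s", seq="GGGCAAAGCCC")
        longer = RnaSequence(id="s3", seq=seq.seq + "AAA")
        assert partition_function(longer, params).Z == pytest.approx(
            partition_function(seq, params).Z, rel=1e-12)

    def test_z_at_least_one(self, params, rng):
        for _ in range(5):
            assert partition_function(random_rna(rng, 12), params).Z >= 1.0

    def test_capacity_error(self, params):
        seq = RnaSequence(id="long", seq="A" * 50)
        with pytest.raises(CapacityError):
            partition_function(seq, params, max_len=40)


class TestExactPairProbabilities:
    @pytest.mark.parametrize("s", [
        "GGGAAACCCAAGGGAAACCC",  # multiloop-capable
        "GCGCAAAGCGCAAAGCGC",
        "GGCAUUUGCCGCAAAGGC",
        "UAUUCGAUGCAUAA",
    ])
    def test_outside_recursion_matches_enumeration(self, s, params):
        seq = RnaSequence(id="t", seq=s)
        P = pair_probabilities(seq, params)
        Pe = enumeration_pair_probabilities(seq, params)
        assert np.abs(P - Pe).max() < 1e-9

    def test_exact_ss_profile_complements_pair_probability(self, params):
        seq = RICH_15
        P = pair_probabilities(seq, params)
        prof = ss_profile(P)
        full = P + P.T
        assert np.allclose(prof, 1.0 - full.sum(axis=1))


class TestSampling:
    def test_seed_determinism(self, params):
        a = sample_structures(BISTABLE_12, params, n=5, seed=7)
        b = sample_structures(BISTABLE_12, params, n=5, seed=7)
        assert a.structures == b.structures
        assert np.array_equal(a.ensemble_energies, b.ensemble_energies)

    def test_different_seeds_differ(self, params):
        a = sample_structures(RICH_15, params, n=50, seed=1)
        b = sample_structures(RICH_15, params, n=50, seed=2)
        assert a.structures != b.structures

    def test_unpairable_sequence_samples_only_empty(self, params):
        ens = sample_structures(RnaSequence(id="a", seq="AAAA"), params, n=10, seed=3)
        assert all(len(st) == 0 for st in ens.structures)
        assert np.all(ens.ss_profile == 1.0)

    def test_requires_positive_sample_size(self, params):
        with pytest.raises(ValueError):
            sample_structures(RICH_15, params, n=0, seed=1)

    def test_frequencies_match_boltzmann_within_3se(self, params):
        # 12-mer with competing hairpins: every structure with appreciable
        # probability must appear at its Boltzmann frequency (3 SE).
        seq = BISTABLE_12
        _, probs = enumeration_partition(seq, params)
        ens = sample_structures(seq, params, n=10000, seed=11)
        counts: dict[frozenset, int] = {}
        for st in ens.structures:
            counts[st.pairs] = counts.get(st.pairs, 0) + 1
        n = ens.sample_size
        for pairs, p in probs.items():
            if p < 0.01:
                continue
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts.get(pairs, 0) / n - p) <= 3 * se + 1e-12, pairs

    def test_empirical_profile_approaches_exact(self, params):
        seq = RICH_15
        exact = ss_profile(pair_probabilities(seq, params))
        ens = sample_structures(seq, params, n=10000, seed=5)
        assert np.abs(ens.ss_profile - exact).max() < 0.03

    def test_empirical_pair_probability_error_shrinks_with_n(self, params):
        seq = RICH_15
        Pe = enumeration_pair_probabilities(seq, params)
        errs = []
        for n in (100, 1000, 10000):
            ens = sample_structures(seq, params, n=n, seed=42)
            errs.append(np.abs(np.triu(ens.pair_prob) - Pe).max())
        # Monotone in expectation; allow slack for sampling noise.
        assert errs[2] < errs[0] + 0.01
        assert errs[2] < 0.02

    def test_sampled_structures_are_valid_and_energies_match(self, params, rng):
        seq = random_rna(rng, 25)
        ens = sample_structures(seq, params, n=50, seed=9)
        for st, e in zip(ens.structures, ens.ensemble_energies):
            st.validate(seq)
            assert e == pytest.approx(structure_energy(seq, st, params))

    def test_ss_profile_is_complement_of_pair_prob(self, params):
        ens = sample_structures(RICH_15, params, n=200, seed=4)
        assert np.allclose(ens.ss_profile, 1.0 - ens.pair_prob.sum(axis=1),
                           atol=1e-9)


class TestCentroid:
    def test_single_structure_ensemble_returns_it(self, params):
        seq = RnaSequence(id="hp", seq="GGGGAAAACCCC")
        st = parse_dotbracket("((((....))))", seq)
        ens = manual_ensemble(seq, [st], params)
        assert centroid_structure(ens).structure == st

    def test_majority_rule(self, params):
        seq = RnaSequence(id="hp", seq="GGGGAAAACCCC")
        hp = parse_dotbracket("((((....))))", seq)
        empty = SecondaryStructure([])
        ens = manual_ensemble(seq, [empty, empty, hp], params)
        assert len(centroid_structure(ens).structure) == 0

    def test_centroid_pairs_subset_of_sampled_pairs(self, params, rng):
        seq = random_rna(rng, 20)
        ens = sample_structures(seq, params, n=200, seed=6)
        sampled = {p for st in ens.structures for p in st.pairs}
        assert set(centroid_structure(ens).structure.pairs) <= sampled

    def test_forced_hairpin_profile_values(self, params):
        seq = RnaSequence(id="hp", seq="GGGGAAAACCCC")
        st = parse_dotbracket("((((....))))", seq)
        ens = manual_ensemble(seq, [st], params)
        assert np.all(ens.ss_profile[4:8] == 1.0)
        assert np.all(ens.ss_profile[:4] == 0.0) and np.all(ens.ss_profile[8:] == 0.0)


class TestClustering:
    def test_identical_structures_single_cluster(self, params):
        seq = RnaSequence(id="hp", seq="GGGGAAAACCCC")
        st = parse_dotbracket("((((....))))", seq)
        ens = manual_ensemble(seq, [st] * 10, params)
        clusters = cluster_ensemble(ens, max_clusters=3)
        assert len(clusters) == 1
        assert clusters[0][0] == list(range(10))
        assert clusters[0][1].structure == st

    def test_two_disjoint_populations_recovered_exactly(self, params):
        seq = RnaSequence(id="two", seq="GGGGAAAACCCCAAAGGGGAAAACCCC")
        left = parse_dotbracket("((((....))))...............", seq)
        right = parse_dotbracket("...............((((....))))", seq)
        ens = manual_ensemble(seq, [left] * 6 + [right] * 4, params)
        clusters = cluster_ensemble(ens, max_clusters=4)
        assert len(clusters) == 2
        assert clusters[0][0] == list(range(6))
        assert clusters[1][0] == list(range(6, 10))
        assert clusters[0][1].structure == left
        assert clusters[1][1].structure == right

    def test_dominant_structure_dominates_largest_cluster(self, params):
        # Strong GC hairpin: one structure holds most of the ensemble.
        seq = RnaSequence(id="dom", seq="GGGGGAAAACCCCC")
        ens = sample_structures(seq, params, n=200, seed=13)
        clusters = cluster_ensemble(ens, max_clusters=4)
        assert len(clusters[0][0]) > 100
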