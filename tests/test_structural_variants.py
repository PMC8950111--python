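"""Single-deletion calling: examples, left-alignment, brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagetup._util import DomainError
from phagetup.structural_variants import (
    ComplexVariantError,
    DeletionCall,
    NoIndelError,
    annotate_deletion,
    call_single_deletion,
    deletion_to_vcf,
)
from phagetup.synthetic import generate_genomes


def brute_force_leftmost(reference: str, mutant: str):
    """Independent oracle: enumerate every excision reproducing the mutant."""
    length = len(reference) - len(mutant)
    placements = [
        (p + 1, p + length)
        for p in range(len(mutant) + 1)
        if reference[:p] + reference[p + length:] == mutant
    ]
    return placements


class TestCallSingleDeletion:
    def test_unambiguous_small_case(self):
        call = call_single_deletion("AAATTTCCC", "AAACCC")
        assert (call.start, call.end, call.length) == (4, 6, 3)
        assert call.homology_len == 0

    def test_homopolymer_left_aligned(self):
        call = call_single_deletion("AAAAA", "AAA")
        assert (call.start, call.end, call.length, call.homology_len) == (1, 2, 2, 3)
        assert brute_force_leftmost("AAAAA", "AAA")[0] == (1, 2)

    def test_fixture_genome_pair(self, genome_pair):
        call = call_single_deletion(genome_pair.reference, genome_pair.mutant)
        assert (call.start, call.end, call.length) == (5879, 6705, 827)

    def test_mutant_length_conserved(self, genome_pair):
        assert len(genome_pair.mutant) == 7222 - 827 == 6395

    def test_homology_flank_still_left_aligned(self):
        sim = generate_genomes(seed=4, homology_len=5)
        call = call_single_deletion(sim.reference, sim.mutant)
        placements = brute_force_leftmost(sim.reference, sim.mutant)
        assert (call.start, call.end) == placements[0]
        assert call.homology_len == 5
        assert len(placements) == 6  # 5 nt of homology -> 6 valid placements

    def test_equal_length_is_no_indel(self):
        with pytest.raises(NoIndelError):
            call_single_deletion("ACGT", "ACGT")

    def test_two_separate_deletions_are_complex(self):
        #      ACGTACGTAC minus pos 2 and pos 9
        ref, mut = "ACGTACGTAC", "AGTACGTC"
        assert brute_force_leftmost(ref, mut) == []
        with pytest.raises(ComplexVariantError):
            call_single_deletion(ref, mut)

    def test_insertion_rejected(self):
        with pytest.raises(DomainError):
            call_single_deletion("ACG", "ACGT")

    def test_reconstruction_invariant(self, genome_pair):
        call = call_single_deletion(genome_pair.reference, genome_pair.mutant)
        ref = genome_pair.reference
        assert ref[: call.start - 1] + ref[call.end :] == genome_pair.mutant

    def test_oracle_equivalence_random_instances(self):
        """1,000 random single deletions agree with the enumeration oracle."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(4, 201))
            ref = "".join("ACGT"[i] for i in rng.integers(4, size=n))
            length = int(rng.integers(1, n))
            start0 = int(rng.integers(0, n - length + 1))
            mut = ref[:start0] + ref[start0 + length:]
            call = call_single_deletion(ref, mut)
            placements = brute_force_leftmost(ref, mut)
            assert (call.start, call.end) == placements[0]
            assert call.homology_len == len(placements) - 1

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        ref=st.text(alphabet="ACGT", min_size=2, max_size=60),
        data=st.data(),
    )
    def test_oracle_equivalence_property(self, ref, data):
        length = data.draw(st.integers(1, len(ref) - 1))
        start0 = data.draw(st.integers(0, len(ref) - length))
        mut = ref[:start0] + ref[start0 + length:]
        call = call_single_deletion(ref, mut)
        placements = brute_force_leftmost(ref, mut)
        assert (call.start, call.end) == placements[0]
        # left-alignment: no valid placement with a smaller start
        assert all(call.start <= s for s, _ in placements)


class TestAnnotateDeletion:
    def test_fixture_annotation(self, genome_pair):
        call = call_single_deletion(genome_pair.reference, genome_pair.mutant)
        ann = annotate_deletion(call, genome_pair.model)
        rel = {f.name: (r, d) for f, r, d in ann.affected_features}
        assert rel["lacZalpha"] == ("contains", 0)
        assert rel["Ori"] == ("downstream_of", 11)
        assert ann.genome_fraction_percent == 11.5

    def test_single_base_deletion_rounds_to_zero(self, m13ke):
        ann = annotate_deletion(DeletionCall(1, 1, 1), m13ke)
        assert ann.genome_fraction_percent == 0.0

    def test_exact_feature_excision_overlaps(self, m13ke):
        ann = annotate_deletion(DeletionCall(5487, 5867, 381), m13ke)
        rel = {f.name: r for f, r, _ in ann.affected_features}
        assert rel["Ori"] == "overlaps"  # identical intervals

    def test_call_outside_genome_rejected(self, m13ke):
        with pytest.raises(DomainError):
            annotate_deletion(DeletionCall(7000, 8000, 1001), m13ke)


class TestVCFRecord:
    def test_anchor_base_convention(self):
        ref = "AAATTTCCC"
        call = call_single_deletion(ref, "AAACCC")
        fields = deletion_to_vcf(call, ref).split("\t")
        assert fields[1] == "3"
        assert fields[3] == "ATTT"
        assert fields[4] == "A"
        assert "SVLEN=-3" in fields[7]

    def test_deletion_at_position_one(self):
        ref = "TTTACGT"
        call = call_single_deletion(ref, "ACGT")
        fields = deletion_to_vcf(call, ref).split("\t")
        assert fields[1] == "1"
        assert fields[3] == "TTTA"
        assert fields[4] == "A"
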