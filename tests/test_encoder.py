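import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mldppi import (
    DESCRIPTORS_PER_REGION,
    EncoderConfig,
    EncodingError,
    ProteinRecord,
    RegionMask,
    SEVEN_GROUP_ALPHABET,
    build_region_masks,
    composition,
    ctd_descriptor,
    distribution,
    encode_pair,
    encode_protein,
    extract_region,
    group_encode,
    n_binary_region_codes,
    segment_boundaries,
    transition,
)
from mldppi.encoder import TRANSITION_PAIRS, feature_names

from conftest import (
    WORKED_COMPOSITION,
    WORKED_DISTRIBUTION,
    WORKED_GROUP_STRING,
    WORKED_SEQUENCE,
    WORKED_TRANSITION,
    random_region,
)

region_codes = st.lists(st.integers(1, 7), min_size=1, max_size=60).map(
    lambda xs: np.array(xs, dtype=np.int8)
)


class TestGroupEncode:
    def test_worked_example(self):
        assert "".join(map(str, group_encode(WORKED_SEQUENCE))) == WORKED_GROUP_STRING

    @pytest.mark.parametrize("aa,group", [("A", 1), ("E", 7), ("C", 2), ("R", 6)])
    def test_single_residues(self, aa, group):
        assert group_encode(aa).tolist() == [group]

    def test_random_sequences_match_per_character_lookup(self):
        rng = np.random.default_rng(42)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            seq = "".join(rng.choice(list(alphabet), size=100))
            expected = [SEVEN_GROUP_ALPHABET[c] for c in seq]
            assert group_encode(seq).tolist() == expected

    def test_unmapped_character_names_position(self):
        with pytest.raises(EncodingError, match="'X' at position 3"):
            group_encode("AAXAA")


class TestRegionMasks:
    def test_standard_four_segment_order(self):
        masks = build_region_masks(4)
        assert [str(m) for m in masks] == [
            "1000", "0100", "0010", "0001",
            "1100", "0110", "0011",
            "1110", "0111",
        ]

    def test_two_segments(self):
        assert [str(m) for m in build_region_masks(2)] == ["10", "01"]

    @pytest.mark.parametrize("n", range(2, 9))
    def test_count_and_exhaustive_contiguity_oracle(self, n):
        """Masks equal the exhaustive enumeration of contiguous bit vectors."""
        def contiguous(bits):
            ones = [i for i, b in enumerate(bits) if b]
            return bool(ones) and ones == list(range(ones[0], ones[-1] + 1))

        oracle = {
            bits
            for bits in itertools.product((0, 1), repeat=n)
            if contiguous(bits) and any(b == 0 for b in bits)
        }
        masks = build_region_masks(n)
        assert len(masks) == n * (n + 1) // 2 - 1
        assert {m.bits for m in masks} == oracle

    def test_include_full_appends_all_ones(self):
        masks = build_region_masks(4, include_full=True)
        assert len(masks) == 10
        assert str(masks[-1]) == "1111"

    @pytest.mark.parametrize("n", [1, 9])
    def test_out_of_range(self, n):
        with pytest.raises(ValueError):
            build_region_masks(n)

    def test_noncontiguous_mask_rejected(self):
        with pytest.raises(ValueError):
            RegionMask((1, 0, 1, 0))

    def test_binary_code_count_five_segments(self):
        # all non-degenerate 5-bit codes, discontinuous included
        assert n_binary_region_codes(5) == 30


class TestSegmentBoundaries:
    def test_worked_example_length(self):
        assert segment_boundaries(22, 4) == [(1, 5), (6, 11), (12, 16), (17, 22)]

    def test_exact_division(self):
        assert segment_boundaries(8, 4) == [(1, 2), (3, 4), (5, 6), (7, 8)]

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(2, 9))
            L = int(rng.integers(n, 500))
            bounds = segment_boundaries(L, n)
            covered = [p for s, e in bounds for p in range(s, e + 1)]
            assert covered == list(range(1, L + 1))
            assert all(s <= e for s, e in bounds)

    def test_too_short(self):
        with pytest.raises(EncodingError):
            segment_boundaries(3, 4)


class TestExtractRegion:
    codes = group_encode(WORKED_SEQUENCE)
    bounds = segment_boundaries(22, 4)

    def test_final_half(self):
        region = extract_region(self.codes, RegionMask((0, 0, 1, 1)), self.bounds)
        assert region.tolist() == self.codes[11:22].tolist()

    def test_final_three_quarters(self):
        region = extract_region(self.codes, RegionMask((0, 1, 1, 1)), self.bounds)
        assert region.tolist() == self.codes[5:22].tolist()

    def test_full_mask_is_identity(self):
        region = extract_region(self.codes, RegionMask((1, 1, 1, 1)), self.bounds)
        assert region.tolist() == self.codes.tolist()

    def test_mask_width_mismatch(self):
        with pytest.raises(ValueError):
            extract_region(self.codes, RegionMask((1, 0)), self.bounds)


class TestComposition:
    def test_worked_example(self):
        comp = composition(group_encode(WORKED_SEQUENCE))
        for g, expected in WORKED_COMPOSITION.items():
            assert round(comp[g - 1], 2) == expected
        assert comp[3:].tolist() == [0.0] * 4

    def test_homogeneous_region(self):
        comp = composition(np.ones(17, dtype=np.int8))
        assert comp.tolist() == [100.0] + [0.0] * 6

    def test_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            region = random_region(rng)
            comp = composition(region)
            for g in range(1, 8):
                assert comp[g - 1] == pytest.approx(
                    100.0 * (region == g).sum() / region.size
                )
            assert comp.sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_region_error(self):
        with pytest.raises(EncodingError):
            composition(np.array([], dtype=np.int8))


class TestTransition:
    def test_worked_example(self):
        trans = transition(group_encode(WORKED_SEQUENCE))
        for pair, expected in WORKED_TRANSITION.items():
            assert round(trans[TRANSITION_PAIRS.index(pair)], 2) == expected
        zero_pairs = [p for p in TRANSITION_PAIRS if p not in WORKED_TRANSITION]
        for pair in zero_pairs:
            assert trans[TRANSITION_PAIRS.index(pair)] == 0.0

    def test_homopolymer_is_all_zero(self):
        assert transition(np.full(30, 5, dtype=np.int8)).tolist() == [0.0] * 21

    def test_length_one_region(self):
        assert transition(np.array([3], dtype=np.int8)).tolist() == [0.0] * 21

    def test_sliding_window_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            region = random_region(rng, min_len=2)
            trans = transition(region)
            for i, (g, h) in enumerate(TRANSITION_PAIRS):
                count = sum(
                    1
                    for a, b in zip(region[:-1], region[1:])
                    if (a, b) in ((g, h), (h, g))
                )
                assert trans[i] == pytest.approx(100.0 * count / (region.size - 1))


class TestDistribution:
    def test_worked_example(self):
        dist = distribution(group_encode(WORKED_SEQUENCE))
        for g, expected in WORKED_DISTRIBUTION.items():
            assert tuple(round(v, 2) for v in dist[(g - 1) * 5 : g * 5]) == expected

    def test_single_occurrence_at_last_position(self):
        region = np.full(10, 2, dtype=np.int8)
        region[-1] = 5
        dist = distribution(region)
        assert dist[4 * 5 : 5 * 5].tolist() == [100.0] * 5

    def test_absent_group_is_all_zero(self):
        dist = distribution(np.ones(10, dtype=np.int8))
        assert dist[5:].tolist() == [0.0] * 30

    def test_milestone_oracle(self):
        """Positions of the first and floor-quantile occurrences, / region length."""
        import math

        rng = np.random.default_rng(2)
        for _ in range(50):
            region = random_region(rng)
            dist = distribution(region)
            for g in range(1, 8):
                pos = [i + 1 for i, c in enumerate(region) if c == g]
                got = dist[(g - 1) * 5 : g * 5]
                if not pos:
                    assert got.tolist() == [0.0] * 5
                    continue
                idx = [1] + [max(1, math.floor(q * len(pos))) for q in (0.25, 0.5, 0.75, 1.0)]
                expected = [100.0 * pos[i - 1] / region.size for i in idx]
                assert got.tolist() == pytest.approx(expected)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(region_codes)
def test_ctd_invariants(region):
    """Composition sums to 100, transitions sum to at most 100, per-group
    distribution values are non-decreasing and zero iff the group is absent."""
    comp, trans, dist = composition(region), transition(region), distribution(region)
    assert comp.sum() == pytest.approx(100.0, abs=1e-9)
    assert trans.sum() <= 100.0 + 1e-9
    assert ((comp >= 0) & (comp <= 100)).all()
    for g in range(1, 8):
        block = dist[(g - 1) * 5 : g * 5]
        assert (np.diff(block) >= 0).all()
        assert ((block >= 0) & (block <= 100)).all()
        if (region == g).any():
            assert (block > 0).all()
        else:
            assert (block == 0).all()


class TestEncodeProtein:
    def test_default_dimension(self):
        vec = encode_protein(WORKED_SEQUENCE)
        assert vec.shape == (567,)
        assert EncoderConfig().protein_dim == 567

    def test_first_block_is_first_segment_descriptor(self):
        vec = encode_protein(WORKED_SEQUENCE)
        codes = group_encode(WORKED_SEQUENCE)
        s1 = codes[:5]  # boundaries (1,5) for L=22, S=4
        assert vec[:DESCRIPTORS_PER_REGION].tolist() == ctd_descriptor(s1).tolist()

    def test_values_bounded_for_random_proteins(self):
        rng = np.random.default_rng(5)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(100):
            seq = "".join(rng.choice(alphabet, size=int(rng.integers(4, 200))))
            vec = encode_protein(seq)
            assert ((vec >= 0) & (vec <= 100)).all()

    def test_pure_function(self):
        rec = ProteinRecord("p", WORKED_SEQUENCE)
        a, b = encode_protein(rec), encode_protein(rec)
        assert (a == b).all()

    def test_include_full_adds_one_region(self):
        cfg = EncoderConfig(include_full=True)
        assert encode_protein(WORKED_SEQUENCE, cfg).shape == (630,)

    def test_too_short_sequence(self):
        with pytest.raises(EncodingError):
            encode_protein("ACD")

    def test_feature_names_match_dimension(self):
        assert len(feature_names(EncoderConfig())) == 567


class TestEncodePair:
    vec = encode_protein(WORKED_SEQUENCE)

    def test_dimension(self):
        assert encode_pair(self.vec, self.vec).shape == (1134,)

    def test_self_pair_halves_equal(self):
        pair = encode_pair(self.vec, self.vec)
        assert (pair[:567] == pair[567:]).all()

    def test_swap_is_half_permutation(self):
        other = encode_protein("ACDEFGHIKLMNPQRSTVWY" * 2)
        ab, ba = encode_pair(self.vec, other), encode_pair(other, self.vec)
        assert (ab[:567] == ba[567:]).all()
        assert (ab[567:] == ba[:567]).all()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            encode_pair(self.vec, self.vec[:63])


def test_dimension_law_across_segment_counts():
    """dim = 63 × region count for every segment count and full-mask choice."""
    seq = "ACDEFGHIKLMNPQRSTVWY" * 3
    for n in range(2, 9):
        for full in (False, True):
            cfg = EncoderConfig(n_segments=n, include_full=full)
            expected = DESCRIPTORS_PER_REGION * len(build_region_masks(n, full))
            assert cfg.protein_dim == expected
            assert encode_protein(seq, cfg).shape == (expected,)
            assert cfg.pair_dim == 2 * expected
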