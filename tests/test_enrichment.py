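import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mirshift.enrichment import (
    empirical_p,
    run_permutation_test,
    shift_mask,
    target_fraction,
)
from mirshift.mapping import GeneIndex
from mirshift.model import (
    GeneRecord,
    GenomeLayout,
    SelectionMask,
    SnpArray,
    TargetSet,
    TierConfig,
)


def make_targets(gene_ids):
    return TargetSet(frozenset(gene_ids), 2, 2, frozenset({"m1", "m2"}))


class TestTargetFraction:
    def test_observed_study_scale_counts(self):
        mapped = {f"g{i}" for i in range(72)}
        targets = make_targets({f"g{i}" for i in range(12)})
        frac, hits, genes = target_fraction(mapped, targets)
        assert (hits, genes) == (12, 72)
        assert frac == pytest.approx(12 / 72)

    def test_empty_mapped_set_flagged_as_zero(self):
        assert target_fraction(set(), make_targets({"g"})) == (0.0, 0, 0)

    def test_all_mapped_in_targets(self):
        frac, _, _ = target_fraction({"a", "b"}, make_targets({"a", "b", "c"}))
        assert frac == 1.0


class TestShiftMask:
    def test_worked_rotation(self):
        mask = SelectionMask(np.array([1, 0, 0, 1], dtype=bool))
        assert list(shift_mask(mask, 1).bits.astype(int)) == [1, 1, 0, 0]

    def test_offset_zero_is_identity(self):
        mask = SelectionMask(np.array([0, 1, 1, 0, 1], dtype=bool))
        assert np.array_equal(shift_mask(mask, 0).bits, mask.bits)

    def test_offset_out_of_range_rejected(self):
        mask = SelectionMask(np.zeros(4, dtype=bool))
        for off in (-1, 4):
            with pytest.raises(ValueError):
                shift_mask(mask, off)

    @settings(max_examples=200, derandomize=True)
    @given(
        arrays(bool, st.integers(1, 64)),
        st.integers(0, 1_000_000),
        st.integers(0, 1_000_000),
    )
    def test_rotation_algebra(self, bits, a, b):
        """Popcount preserved; composing offsets a then b equals (a+b) mod n."""
        mask = SelectionMask(bits)
        n = len(mask)
        a, b = a % n, b % n
        shifted = shift_mask(mask, a)
        assert shifted.popcount == mask.popcount
        composed = shift_mask(shifted, b)
        assert np.array_equal(composed.bits, shift_mask(mask, (a + b) % n).bits)


class TestEmpiricalP:
    def test_ties_counted_as_extreme(self):
        assert empirical_p([0.1, 0.2, 0.3], 0.2) == (1 + 2) / (3 + 1)

    def test_add_one_floor(self):
        assert empirical_p([0.0] * 99, 0.5) == 1 / 100

    def test_never_zero_even_when_observed_tops_everything(self):
        assert empirical_p([], 1.0) == 1.0


LAYOUT = GenomeLayout((("chr1", 2_000_000),))
GENES = [GeneRecord(f"g{i}", "chr1", 100_000 * i, 100_000 * i + 10_000) for i in range(1, 19)]
TIERS = TierConfig((25_000,))


def small_setup(k=4, n=40):
    positions = np.linspace(5_000, 1_900_000, n).astype(int)
    array = SnpArray.from_arrays([f"s{i}" for i in range(n)], ["chr1"] * n, positions, LAYOUT)
    bits = np.zeros(n, dtype=bool)
    bits[:k] = True
    index = GeneIndex(GENES, LAYOUT)
    targets = make_targets({"g1", "g5", "g9", "g13"})
    return array, SelectionMask(bits), index, targets


class TestRunPermutationTest:
    def test_identity_offsets_reproduce_observed(self):
        array, mask, index, targets = small_setup()
        res = run_permutation_test(array, mask, index, TIERS, targets, offsets=[0, 0, 0])
        assert res.p_value == 1.0
        assert np.all(res.null_fractions == res.observed_fraction)
        assert np.all(res.null_gene_counts == res.observed_gene_count)

    def test_same_seed_bit_identical(self):
        array, mask, index, targets = small_setup()
        r1 = run_permutation_test(array, mask, index, TIERS, targets, n_sims=50, seed=42)
        r2 = run_permutation_test(array, mask, index, TIERS, targets, n_sims=50, seed=42)
        assert np.array_equal(r1.offsets_used, r2.offsets_used)
        assert np.array_equal(r1.null_fractions, r2.null_fractions)
        assert r1.p_value == r2.p_value

    def test_offsets_recorded_and_within_range(self):
        array, mask, index, targets = small_setup()
        res = run_permutation_test(array, mask, index, TIERS, targets, n_sims=200, seed=1)
        assert len(res.offsets_used) == 200
        assert res.offsets_used.min() >= 1
        assert res.offsets_used.max() <= len(array) - 1
        assert res.offset_range == (1, len(array) - 1)

    def test_p_value_from_null_fractions_by_documented_estimator(self):
        array, mask, index, targets = small_setup()
        res = run_permutation_test(array, mask, index, TIERS, targets, n_sims=300, seed=3)
        assert res.p_value == pytest.approx(
            empirical_p(res.null_fractions, res.observed_fraction)
        )

    def test_null_vectors_have_length_n_sims(self):
        array, mask, index, targets = small_setup()
        res = run_permutation_test(array, mask, index, TIERS, targets, n_sims=17, seed=0)
        assert len(res.null_fractions) == len(res.null_gene_counts) == 17
        assert res.n_sims == 17

    def test_empty_mask_rejected(self):
        array, _, index, targets = small_setup()
        with pytest.raises(ValueError):
            run_permutation_test(
                array, SelectionMask(np.zeros(len(array), dtype=bool)), index, TIERS, targets
            )

    def test_result_round_trips_to_dict(self):
        array, mask, index, targets = small_setup()
        res = run_permutation_test(array, mask, index, TIERS, targets, n_sims=5, seed=9)
        d = res.to_dict()
        assert d["n_sims"] == 5 and len(d["null_fractions"]) == 5
        assert d["metadata"]["n_selected"] == mask.popcount
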