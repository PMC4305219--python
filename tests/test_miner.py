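"""The level-wise interval miner: supports, merging, pruning, maximality."""

import numpy as np
import pytest

from cnvminer import (
    BinaryMatrix,
    Interval,
    MiningParams,
    ProbeTrack,
    ValidationError,
)
from cnvminer.datatypes import MergeReason
from cnvminer.miner import (
    is_adjacent,
    is_recursive_weak,
    merge_dissimilarity,
    mine_chromosome,
    mine_genome,
    mine_matrix,
    singleton_support,
    weak_eti_support,
)
from cnvminer.simulate import ImplantSpec, generate_binary_cohort

from conftest import random_binary


def _B(cells, **kw):
    cells = np.asarray(cells, dtype=np.uint8)
    return BinaryMatrix(cells, track=ProbeTrack.default(cells.shape[0]), **kw)


class TestSingletonSupport:
    def test_below_threshold_pruned(self):
        # present in 4 of 10 samples at sup_min=0.5 -> not frequent
        B = _B([[1, 1, 1, 1, 0, 0, 0, 0, 0, 0]])
        assert singleton_support(B, 0, 0.5) is None

    def test_ubiquitous_probe(self):
        B = _B([np.ones(10)])
        pat = singleton_support(B, 0, 0.5)
        assert pat.support == 1.0 and pat.support_set == tuple(range(10))

    def test_absent_probe_none_for_any_threshold(self):
        B = _B([np.zeros(10)])
        assert singleton_support(B, 0, 0.01) is None

    def test_exact_no_tolerance(self, toy_example):
        B, _ = toy_example
        assert singleton_support(B, 0, 0.4).support == pytest.approx(0.4)
        assert singleton_support(B, 0, 0.5) is None


class TestWeakEtiSupport:
    def test_nested_ten_five_configuration(self, toy_example):
        """Probe in all 10 merged with probe in a nested 5: weak support 0.8
        at eps=0.2 (13 ones over a 2x8 submatrix is 0.8125 >= 0.8; a 9th
        sample drops it to 14/18 < 0.8)."""
        B, _ = toy_example
        support, tset = weak_eti_support(B, Interval(5, 6), 0.2)
        assert support == pytest.approx(0.8)
        assert len(tset) == 8
        sub = B.cells[5:7][:, list(tset)]
        assert sub.mean() >= 0.8

    def test_zero_tolerance_is_classical_support(self, rng):
        B = random_binary(rng, 10, 12)
        iv = Interval(2, 6)
        support, tset = weak_eti_support(B, iv, 0.0)
        carriers = np.flatnonzero(B.cells[2:7].all(axis=0))
        assert tset == tuple(carriers.tolist())
        assert support == pytest.approx(len(carriers) / 12)

    def test_singleton_interval_forces_zero_tolerance(self):
        B = _B([[1, 1, 0, 0]])
        support, tset = weak_eti_support(B, Interval(0, 0), 0.9)
        assert support == 0.5 and tset == (0, 1)

    def test_empty_when_nothing_feasible(self):
        B = _B(np.zeros((3, 4)))
        assert weak_eti_support(B, Interval(0, 2), 0.2) == (0.0, ())

    def test_tie_break_prefers_low_sample_index(self):
        B = _B([[1, 1, 1, 1]])
        _, tset = weak_eti_support(B, Interval(0, 0), 0.0)
        assert tset == (0, 1, 2, 3)


class TestAdjacencyAndMerge:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (Interval(2, 3), Interval(3, 4), True),
            (Interval(3, 4), Interval(2, 3), True),   # symmetric
            (Interval(2, 3), Interval(4, 5), False),  # gap
            (Interval(2, 2), Interval(3, 3), True),   # singleton parents
            (Interval(2, 3), Interval(2, 3), False),  # identical
            (Interval(2, 4), Interval(3, 4), False),  # size mismatch
        ],
    )
    def test_is_adjacent(self, a, b, expected):
        assert is_adjacent(a, b) is expected

    def test_different_chromosomes_never_adjacent(self):
        assert not is_adjacent(Interval(2, 3, "chr1"), Interval(3, 4, "chr2"))

    def test_dissimilarity_worked_example_values(self):
        all10 = range(10)
        five = range(5)
        assert merge_dissimilarity(all10, five) == pytest.approx(0.5)
        assert merge_dissimilarity(five, five) == 0.0
        assert merge_dissimilarity(range(3), range(5, 8)) == 1.0

    def test_dissimilarity_requires_nonempty(self):
        with pytest.raises(ValidationError):
            merge_dissimilarity([], [1])


class TestRecursiveWeak:
    def test_interior_hole_blocks_superset(self):
        """An interval can pass the weak density bound while an interior
        sub-interval fails it; the recursion must reject it."""
        cells = np.zeros((4, 4), dtype=np.uint8)
        cells[0] = cells[3] = 1           # flanks in every sample
        cells[1, :2] = cells[2, :2] = 1   # interior only in half
        B = _B(cells)
        params = MiningParams(sup_min=0.75, epsilon=0.25)
        support, tset = weak_eti_support(B, Interval(0, 3), 0.25)
        assert support == 1.0  # overall density 12/16 = 0.75 passes
        table = {(0, 0): object(), (3, 3): object()}  # what level-wise found
        assert not is_recursive_weak(B, Interval(0, 3), params, table)
        pats = mine_chromosome(B, params)
        assert [p.interval for p in pats] == [Interval(0, 0), Interval(3, 3)]

    def test_pruned_parent_blocks_candidate(self):
        B = _B([[1, 1, 0, 0], [1, 1, 1, 1]])
        params = MiningParams(sup_min=0.75, epsilon=0.5)
        # probe 0 pruned (support 0.5 < 0.75) so no size-2 candidate exists
        pats = mine_chromosome(B, params)
        assert [p.interval for p in pats] == [Interval(1, 1)]


class TestMineChromosome:
    def test_worked_example(self, toy_example):
        """The reconstructed toy run: i1 pruned, i6+i7 merge rejected on the
        support-overlap criterion, i2..i6 coalesce, i7 survives alone."""
        B, params = toy_example
        pats = mine_chromosome(B, params)
        intervals = [p.interval for p in pats]
        assert Interval(1, 5) in intervals  # i2..i6 as one maximal pattern
        assert Interval(6, 6) in intervals  # i7 kept
        for iv in intervals:
            assert iv.start > 0  # i1 appears in no pattern
            assert not (iv.start <= 5 and iv.end >= 6)  # no i6+i7 span
        assert all(p.support >= params.sup_min for p in pats)

    def test_merge_decisions_record_delta_rejection(self, toy_example):
        B, params = toy_example
        decisions = []
        mine_chromosome(B, params, decisions=decisions)
        rej = [
            d for d in decisions
            if d.left == Interval(5, 5) and d.right == Interval(6, 6)
        ]
        assert len(rej) == 1
        assert rej[0].reason is MergeReason.DELTA_EXCEEDED and not rej[0].accepted
        assert rej[0].dissimilarity == pytest.approx(0.5)
        # the would-be support the level would have seen is still recorded
        assert rej[0].candidate_support == pytest.approx(0.8)

    def test_all_zero_matrix_yields_nothing(self):
        B = _B(np.zeros((6, 8)))
        assert mine_chromosome(B, MiningParams(0.2, 0.2, 0.5)) == []

    def test_clean_implanted_block_recovered_exactly(self):
        B, truth = generate_binary_cohort(
            30, 20, 0.0, [ImplantSpec(Interval(10, 19), 0.4)], seed=5
        )
        pats = mine_chromosome(B, MiningParams(0.3, 0.1, 0.2))
        assert len(pats) == 1
        assert pats[0].interval == Interval(10, 19)
        assert pats[0].support_set == truth.implants[0].samples

    def test_reported_subintervals_were_frequent(self, rng):
        """Every contiguous sub-interval of a reported pattern meets the
        weak support bound (recursive-weak soundness), and no reported
        probe has singleton support below sup_min."""
        B = random_binary(rng, 15, 10, density=0.5)
        params = MiningParams(0.3, 0.2, 1.0)
        need = params.min_count(10)
        for p in mine_chromosome(B, params):
            iv = p.interval
            for a in range(iv.start, iv.end + 1):
                assert singleton_support(B, a, params.sup_min) is not None
                for b in range(a, iv.end + 1):
                    _, tset = weak_eti_support(B, Interval(a, b), params.epsilon)
                    assert len(tset) >= need

    def test_determinism(self, rng):
        B = random_binary(rng, 20, 12, density=0.5)
        params = MiningParams(0.25, 0.2, 0.5)
        assert mine_chromosome(B, params) == mine_chromosome(B, params)

    def test_sup_min_monotone_probe_coverage(self, rng):
        """Raising the support threshold never covers new probes."""
        from cnvminer.stats import covered_probes

        B, _ = generate_binary_cohort(
            60, 30, 0.05,
            [ImplantSpec(Interval(5, 14), 0.6), ImplantSpec(Interval(30, 44), 0.35)],
            seed=11,
        )
        prev = None
        for sup in (0.1, 0.2, 0.3, 0.4, 0.6):
            cov = covered_probes(mine_chromosome(B, MiningParams(sup, 0.2, 1.0)))
            if prev is not None:
                assert cov <= prev
            prev = cov

    def test_epsilon_monotone_frequent_set_at_delta_one(self, rng):
        B = random_binary(rng, 18, 10, density=0.45)
        prev = None
        for eps in (0.0, 0.1, 0.2, 0.3):
            from cnvminer.oracle import mine_bruteforce

            table, _ = mine_bruteforce(B, MiningParams(0.3, eps, 1.0))
            keys = set(table)
            if prev is not None:
                assert prev <= keys
            prev = keys


class TestMineGenome:
    def test_two_chromosomes_keep_labels(self):
        mats = []
        for i, chrom in enumerate(("chr1", "chr2")):
            cells = np.zeros((12, 10), dtype=np.uint8)
            cells[3:7, :6] = 1
            mats.append(
                BinaryMatrix(cells, track=ProbeTrack.default(12, chrom))
            )
        pats = mine_genome(mats, MiningParams(0.5, 0.1, 0.5))
        assert sorted(p.interval.chromosome for p in pats) == ["chr1", "chr2"]
        assert all(p.interval == Interval(3, 6, p.interval.chromosome) for p in pats)

    def test_split_outside_pattern_changes_nothing(self):
        B, _ = generate_binary_cohort(
            40, 16, 0.03,
            [ImplantSpec(Interval(4, 9), 0.5), ImplantSpec(Interval(25, 33), 0.5)],
            seed=3,
        )
        params = MiningParams(0.3, 0.2, 0.5)
        whole = {
            (p.interval.start, p.interval.end, p.support_set)
            for p in mine_chromosome(B, params)
        }
        split_at = 18  # between the implants
        parts = []
        for lo, hi in ((0, split_at), (split_at, 40)):
            parts.append(
                BinaryMatrix(
                    B.cells[lo:hi],
                    sample_ids=B.sample_ids,
                    track=ProbeTrack.default(hi - lo),
                )
            )
        halves = set()
        for offset, part in zip((0, split_at), parts):
            for p in mine_chromosome(part, params):
                halves.add(
                    (p.interval.start + offset, p.interval.end + offset, p.support_set)
                )
        assert whole == halves

    def test_multichromosome_matrix_never_crosses_boundary(self):
        cells = np.ones((6, 4), dtype=np.uint8)
        track = ProbeTrack(
            [f"p{i}" for i in range(6)],
            ["chr1"] * 3 + ["chr2"] * 3,
            [10, 20, 30, 10, 20, 30],
        )
        B = BinaryMatrix(cells, track=track)
        pats = mine_matrix(B, MiningParams(0.5, 0.0, 1.0))
        assert [(p.interval.start, p.interval.end, p.interval.chromosome) for p in pats] == [
            (0, 2, "chr1"),
            (3, 5, "chr2"),
        ]

    def test_inconsistent_sample_ids_rejected(self):
        a = _B(np.ones((2, 3)))
        b = BinaryMatrix(
            np.ones((2, 3), dtype=np.uint8),
            sample_ids=["x", "y", "z"],
            track=ProbeTrack.default(2, "chr2"),
        )
        with pytest.raises(ValidationError, match="sample_ids"):
            mine_genome([a, b], MiningParams(0.5))


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(sup_min=0.0),
            dict(sup_min=1.5),
            dict(sup_min=0.5, epsilon=1.0),
            dict(sup_min=0.5, epsilon=-0.1),
            dict(sup_min=0.5, delta=1.2),
        ],
    )
    def test_out_of_range_rejected(self, kw):
        with pytest.raises(ValidationError):
            MiningParams(**kw)

    def test_min_count_is_ceiling(self):
        assert MiningParams(0.5).min_count(10) == 5
        assert MiningParams(0.5).min_count(9) == 5
        assert MiningParams(0.101).min_count(10) == 2
        assert MiningParams(0.1).min_count(10) == 1
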