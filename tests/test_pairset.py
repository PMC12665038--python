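"""Dataset construction: positive pairing, negative sampling, splits."""

import numpy as np
import pytest

from etnet.genomio import GenomicRegion, LoopRecord
from etnet.pairset import (
    EnhancerPair,
    categorize_super_enhancer,
    find_positive_pairs,
    frame_to_pairs,
    pairs_to_frame,
    sample_negatives_distance_matched,
    sample_negatives_fixed_end,
    sample_negatives_random,
    split_enhancer_level,
    split_kfold,
    split_ratio,
)


def region(chrom, start, end, name):
    return GenomicRegion(chrom, start, end, id=name)


def make_pair(left_name, right_name, label=1, offset=0):
    left = region("chr1", 100 + offset, 400 + offset, left_name)
    right = region("chr1", 5000 + offset, 5300 + offset, right_name)
    return EnhancerPair(left, right, label=label, loop_id="L" if label else None)


class TestPositivePairs:
    loop = LoopRecord(GenomicRegion("chr1", 0, 1000), GenomicRegion("chr1", 5000, 6000), "L1")

    def test_containment_pairing(self):
        e1 = region("chr1", 100, 500, "E1")
        e2 = region("chr1", 5100, 5400, "E2")
        pairs = find_positive_pairs([self.loop], [e1, e2])
        assert len(pairs) == 1
        assert {pairs[0].left.key, pairs[0].right.key} == {"E1", "E2"}
        assert pairs[0].label == 1 and pairs[0].loop_id == "L1"

    def test_straddling_enhancer_not_paired(self):
        straddle = region("chr1", 900, 1100, "S")  # crosses the left anchor boundary
        e2 = region("chr1", 5100, 5400, "E2")
        assert find_positive_pairs([self.loop], [straddle, e2]) == []

    def test_duplicate_loops_deduplicated(self):
        e1 = region("chr1", 100, 500, "E1")
        e2 = region("chr1", 5100, 5400, "E2")
        dup = LoopRecord(self.loop.anchor_left, self.loop.anchor_right, "L2")
        pairs = find_positive_pairs([self.loop, dup], [e1, e2])
        assert len(pairs) == 1

    def test_multiple_enhancers_cross_product(self):
        enhancers = [region("chr1", 100, 300, "A1"), region("chr1", 400, 600, "A2"),
                     region("chr1", 5100, 5300, "B1")]
        pairs = find_positive_pairs([self.loop], enhancers)
        assert {p.key for p in pairs} == {("A1", "B1"), ("A2", "B1")}


class TestRandomNegatives:
    positives = [make_pair("E1", "E2"), make_pair("E3", "E4", offset=10_000)]

    def test_forced_exclusion(self):
        negs = sample_negatives_random(self.positives, 2, seed=0)
        assert {n.key for n in negs} == {("E1", "E4"), ("E2", "E3")}
        assert all(n.label == 0 for n in negs)

    def test_capacity_error_names_maximum(self):
        with pytest.raises(ValueError, match="2"):
            sample_negatives_random(self.positives, 3, seed=0)

    def test_deterministic(self):
        a = sample_negatives_random(self.positives, 2, seed=5)
        b = sample_negatives_random(self.positives, 2, seed=5)
        assert [p.key for p in a] == [p.key for p in b]


class TestFixedEndNegatives:
    def test_keeping_one_side_forced(self):
        positives = [make_pair("E1", "E2")]
        # only candidates: (E1, x) or (x, E2) — but the pool is just E1/E2, so none
        with pytest.raises(ValueError):
            sample_negatives_fixed_end(positives, 1, seed=0)

    def test_shares_exactly_one_enhancer_with_a_positive(self):
        positives = [make_pair("E1", "E2"), make_pair("E3", "E4", offset=10_000)]
        negs = sample_negatives_fixed_end(positives, 2, seed=1)
        pos_ids = {p.left.key for p in positives} | {p.right.key for p in positives}
        pos_keys = {p.key for p in positives}
        for n in negs:
            assert n.key not in pos_keys
            shared = {n.left.key, n.right.key} & pos_ids
            assert len(shared) == 2  # both ends come from the pools
            # shares a full side with some positive
            assert any(n.left.key in (p.left.key, p.right.key)
                       or n.right.key in (p.left.key, p.right.key) for p in positives)

    def test_deterministic(self):
        positives = [make_pair("E1", "E2"), make_pair("E3", "E4", offset=10_000)]
        a = sample_negatives_fixed_end(positives, 2, seed=9)
        b = sample_negatives_fixed_end(positives, 2, seed=9)
        assert [p.key for p in a] == [p.key for p in b]


def random_positives(rng, n_enh=30, n_pairs=25, chrom="chr1"):
    enhancers = []
    pos = 1000
    for i in range(n_enh):
        start = pos + int(rng.integers(0, 2000))
        enhancers.append(region(chrom, start, start + 300, f"E{i}"))
        pos = start + 2500
    pairs = {}
    while len(pairs) < n_pairs:
        i, j = rng.choice(n_enh, size=2, replace=False)
        p = EnhancerPair(enhancers[i], enhancers[j], label=1, loop_id=f"L{len(pairs)}")
        pairs.setdefault(p.key, p)
    return list(pairs.values())


class TestDistanceMatchedNegatives:
    def test_single_bin_range_forced(self):
        rng = np.random.default_rng(0)
        positives = random_positives(rng, n_enh=20, n_pairs=10)
        negs = sample_negatives_distance_matched(positives, 10, n_bins=1, seed=0)
        assert len(negs) == 10
        assert all(n.label == 0 for n in negs)

    def test_empty_positives_error(self):
        with pytest.raises(ValueError):
            sample_negatives_distance_matched([], 5, seed=0)

    def test_no_positive_overlap_and_no_duplicates(self):
        rng = np.random.default_rng(3)
        positives = random_positives(rng)
        negs = sample_negatives_distance_matched(positives, len(positives), seed=4)
        keys = [n.key for n in negs]
        assert len(set(keys)) == len(keys)
        assert not set(keys) & {p.key for p in positives}


class TestSplits:
    def test_ratio_arithmetic_and_stratification(self):
        pairs = [make_pair(f"P{i}", f"Q{i}", label=1, offset=100 * i) for i in range(50)]
        pairs += [make_pair(f"R{i}", f"S{i}", label=0, offset=100 * i) for i in range(50)]
        split = split_ratio(pairs, (8, 1, 1), seed=0)
        sizes = split.audit()["sizes"]
        assert sizes == {"train": 80, "validation": 10, "test": 10}
        train_pos = sum(pairs[i].label for i in split.indices("train"))
        assert train_pos == 40

    def test_kfold_sizes(self):
        pairs = [make_pair(f"P{i}", f"Q{i}", offset=100 * i) for i in range(95)]
        split = split_kfold(pairs, k=10, seed=1)
        sizes = [len(split.indices(f)) for f in range(10)]
        assert set(sizes) <= {9, 10} and sum(sizes) == 95

    def test_kfold_partition(self):
        pairs = [make_pair(f"P{i}", f"Q{i}", offset=100 * i) for i in range(37)]
        split = split_kfold(pairs, k=5, seed=2)
        all_idx = sorted(i for f in range(5) for i in split.indices(f))
        assert all_idx == list(range(37))

    def test_kfold_too_many_folds(self):
        with pytest.raises(ValueError):
            split_kfold([make_pair("A", "B")], k=2, seed=0)


class TestEnhancerLevelSplit:
    def test_forced_example(self):
        a, b, c, d, e = (region("chr1", 100 * i, 100 * i + 50, n)
                         for i, n in enumerate("ABCDE", start=1))
        pairs = [EnhancerPair(a, b, 1), EnhancerPair(b, c, 1), EnhancerPair(d, e, 1)]
        # whichever pair enters the test set, the dual constraints force the rest
        split = split_enhancer_level(pairs, test_fraction=1 / 3, seed=0)
        test_idx = split.indices("test")
        assert len(test_idx) == 1
        if test_idx == [2]:  # (D,E) in test: both others trainable
            assert sorted(split.indices("train")) == [0, 1]
        else:  # (A,B) or (B,C) in test: the one sharing B is dropped
            other = {0: 1, 1: 0}[test_idx[0]]
            assert split.labels[other] == "dropped"
            assert split.indices("train") == [2]

    def test_invariants_on_random_datasets(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            positives = random_positives(rng, n_enh=25, n_pairs=20)
            split = split_enhancer_level(positives, test_fraction=0.25,
                                         seed=int(rng.integers(2**31)))
            test_ids, train_ids = [], set()
            for i in split.indices("test"):
                test_ids += [positives[i].left.key, positives[i].right.key]
            for i in split.indices("train"):
                train_ids |= {positives[i].left.key, positives[i].right.key}
            assert not set(test_ids) & train_ids          # constraint (i)
            assert len(test_ids) == len(set(test_ids))    # constraint (ii)


class TestSuperEnhancerCategories:
    se1 = region("chr1", 0, 1000, "SE1")
    se2 = region("chr1", 5000, 6000, "SE2")

    def test_categories(self):
        inside1a = region("chr1", 100, 300, "A")
        inside1b = region("chr1", 500, 700, "B")
        inside2 = region("chr1", 5100, 5300, "C")
        outside = region("chr1", 9000, 9200, "D")
        pairs = [EnhancerPair(inside1a, inside1b, 1),
                 EnhancerPair(inside1a, inside2, 1),
                 EnhancerPair(outside, inside2, 1),
                 EnhancerPair(outside, region("chr1", 9400, 9600, "E"), 0)]
        out = categorize_super_enhancer(pairs, [self.se1, self.se2])
        assert [p.se_category for p in out] == ["SE_intra", "SE_inter", "SE_out", "SE_out"]

    def test_largest_overlap_wins(self):
        # enhancer overlapping both SEs maps to the larger overlap (SE2 side)
        bridging = region("chr1", 900, 5200, "X")
        partner = region("chr1", 5300, 5400, "Y")
        (p,) = categorize_super_enhancer(
            [EnhancerPair(bridging, partner, 1)], [self.se1, self.se2])
        # bridging overlaps SE1 by 100 and SE2 by 200 -> same SE as partner
        assert p.se_category == "SE_intra"


class TestManifestRoundTrip:
    def test_frame_round_trip(self):
        pairs = [make_pair("E1", "E2"), make_pair("E3", "E4", label=0, offset=7000)]
        split = split_ratio(pairs, (1, 0, 1), seed=0)
        df = pairs_to_frame(pairs, split)
        back = frame_to_pairs(df)
        assert [p.key for p in back] == [p.key for p in pairs]
        assert [p.label for p in back] == [1, 0]
        assert df.shape[0] == 2 and "split" in df.columns
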