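"""Labeled enhancer-pair dataset construction.

Positives come from chromatin-interaction loops: every enhancer fully
contained in the left anchor is paired with every enhancer fully contained
in the right anchor, and duplicate unordered pairs are removed. Negatives
are generated under three strategies (random pairing, distance-matched,
fixed-end shuffling), always excluding the positive set. Splits include a
stratified ratio split, k-fold, and a dual-constraint enhancer-level split
that eliminates enhancer sharing between train and test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomio import GenomicRegion, LoopRecord

logger = logging.getLogger(__name__)

SE_CATEGORIES = ("SE_intra", "SE_inter", "SE_out", "unassigned")


@dataclass(frozen=True)
class EnhancerPair:
    """Two enhancer regions with an interaction label and provenance."""

    left: GenomicRegion
    right: GenomicRegion
    label: int  # 1 positive, 0 negative
    loop_id: str | None = None
    se_category: str = "unassigned"

    @property
    def distance(self) -> int | None:
        """Midpoint distance in bp; defined only for same-chromosome pairs."""
        if self.left.chrom != self.right.chrom:
            return None
        return abs(self.left.midpoint - self.right.midpoint)

    @property
    def key(self) -> tuple[str, str]:
        """Unordered identity of the pair."""
        return tuple(sorted((self.left.key, self.right.key)))  # type: ignore[return-value]


@dataclass
class SplitAssignment:
    """Partition of pair indices into train/validation/test or k folds.

    ``labels[i]`` is 'train'/'validation'/'test'/'dropped' in ratio and
    enhancer-level modes, or an integer fold index in k-fold mode.
    """

    mode: str
    labels: list
    k: int | None = None

    def indices(self, name) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == name]

    def audit(self) -> dict:
        vals, counts = np.unique(np.asarray(self.labels, dtype=object), return_counts=True)
        return {"mode": self.mode, "sizes": {str(v): int(c) for v, c in zip(vals, counts)}}


def _ordered(a: GenomicRegion, b: GenomicRegion) -> tuple[GenomicRegion, GenomicRegion]:
    return (a, b) if (a.chrom, a.start, a.end) <= (b.chrom, b.start, b.end) else (b, a)


def find_positive_pairs(loops: list[LoopRecord],
                        enhancers: list[GenomicRegion]) -> list[EnhancerPair]:
    """Pair enhancers fully contained in opposite anchors of each loop.

    Full containment is required (an enhancer straddling an anchor boundary
    is not paired). Duplicate unordered pairs arising from multiple loops
    are removed, keeping the first loop's id.
    """
    pairs: dict[tuple[str, str], EnhancerPair] = {}
    for loop in loops:
        lefts = [e for e in enhancers if loop.anchor_left.contains(e)]
        rights = [e for e in enhancers if loop.anchor_right.contains(e)]
        for el in lefts:
            for er in rights:
                if el.key == er.key:
                    continue
                pair = EnhancerPair(el, er, label=1, loop_id=loop.loop_id)
                pairs.setdefault(pair.key, pair)
    return list(pairs.values())


def _pools(positives: list[EnhancerPair]) -> tuple[list[GenomicRegion], list[GenomicRegion]]:
    left = {p.left.key: p.left for p in positives}
    right = {p.right.key: p.right for p in positives}
    return list(left.values()), list(right.values())


def _candidate_pairs(positives: list[EnhancerPair],
                     same_chrom_only: bool = False) -> list[tuple[GenomicRegion, GenomicRegion]]:
    """All unordered left-pool x right-pool combinations outside the positive set."""
    lefts, rights = _pools(positives)
    taken = {p.key for p in positives}
    seen: set[tuple[str, str]] = set()
    out = []
    for el in lefts:
        for er in rights:
            if el.key == er.key:
                continue
            if same_chrom_only and el.chrom != er.chrom:
                continue
            key = tuple(sorted((el.key, er.key)))
            if key in taken or key in seen:
                continue
            seen.add(key)
            out.append(_ordered(el, er))
    return out


def _require(positives: list[EnhancerPair], n: int) -> None:
    if not positives:
        raise ValueError("positive set is empty")
    if n < 1:
        raise ValueError("n must be >= 1")


def sample_negatives_random(positives: list[EnhancerPair], n: int,
                            seed: int, same_chrom_only: bool = False) -> list[EnhancerPair]:
    """Random enhancer re-pairing, excluding the positive set.

    ``same_chrom_only`` restricts the pool to intra-chromosomal pairs
    (used by the synthetic fixtures, where sequence content alone must
    determine the label)."""
    _require(positives, n)
    candidates = _candidate_pairs(positives, same_chrom_only=same_chrom_only)
    if n > len(candidates):
        raise ValueError(f"requested {n} negatives but only {len(candidates)} "
                         f"candidate pairs are available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [EnhancerPair(*candidates[i], label=0) for i in sorted(idx)]


def sample_negatives_distance_matched(positives: list[EnhancerPair], n: int,
                                      n_bins: int = 10, seed: int = 0) -> list[EnhancerPair]:
    """Negatives whose genomic-distance distribution matches the positives'.

    The positive midpoint-distance distribution is partitioned into
    ``n_bins`` quantile intervals; same-chromosome candidate pairs are
    sampled per bin proportionally to the positive bin counts. Bins with
    too few candidates redistribute their quota to neighboring bins with a
    warning.
    """
    _require(positives, n)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    pos_d = np.array([p.distance for p in positives], dtype=float)
    if np.any(np.isnan(pos_d)):
        raise ValueError("distance-matched sampling requires intra-chromosomal positives")
    edges = np.unique(np.quantile(pos_d, np.linspace(0, 1, n_bins + 1)))
    edges[0], edges[-1] = -np.inf, np.inf
    nb = len(edges) - 1

    candidates = _candidate_pairs(positives, same_chrom_only=True)
    if n > len(candidates):
        raise ValueError(f"requested {n} negatives but only {len(candidates)} "
                         f"same-chromosome candidates are available")
    cand_d = np.array([abs(a.midpoint - b.midpoint) for a, b in candidates], dtype=float)
    cand_bin = np.clip(np.searchsorted(edges, cand_d, side="right") - 1, 0, nb - 1)
    pos_bin = np.clip(np.searchsorted(edges, pos_d, side="right") - 1, 0, nb - 1)

    # per-bin quota proportional to positive counts (largest remainder)
    pos_counts = np.bincount(pos_bin, minlength=nb).astype(float)
    raw = n * pos_counts / pos_counts.sum()
    quota = np.floor(raw).astype(int)
    rem = n - quota.sum()
    for i in np.argsort(-(raw - quota))[:rem]:
        quota[i] += 1

    rng = np.random.default_rng(seed)
    avail = [list(np.flatnonzero(cand_bin == b)) for b in range(nb)]
    chosen: list[int] = []
    shortfall = 0
    for b in range(nb):
        take = min(quota[b], len(avail[b]))
        if take < quota[b]:
            logger.warning("distance bin %d short of candidates (%d < %d); "
                           "redistributing to neighbors", b, len(avail[b]), quota[b])
            shortfall += quota[b] - take
        if take:
            picked = rng.choice(avail[b], size=take, replace=False)
            chosen.extend(int(i) for i in picked)
            avail[b] = [i for i in avail[b] if i not in set(picked.tolist())]
    if shortfall:  # neighbor redistribution: nearest bins with spare candidates
        spare = [i for b in range(nb) for i in avail[b]]
        extra = rng.choice(spare, size=shortfall, replace=False)
        chosen.extend(int(i) for i in extra)
    return [EnhancerPair(*candidates[i], label=0) for i in sorted(chosen)]


def sample_negatives_fixed_end(positives: list[EnhancerPair], n: int,
                               seed: int) -> list[EnhancerPair]:
    """Keep one enhancer of a positive pair, shuffle the partner.

    Which side is kept alternates uniformly at random; every negative
    therefore shares exactly one enhancer with some positive pair.
    """
    _require(positives, n)
    lefts, rights = _pools(positives)
    taken = {p.key for p in positives}
    # enumerate the full fixed-end candidate space for exact capacity checks
    seen: set[tuple[str, str]] = set()
    keep_left: list[tuple[GenomicRegion, GenomicRegion]] = []
    keep_right: list[tuple[GenomicRegion, GenomicRegion]] = []
    for p in positives:
        for er in rights:
            key = tuple(sorted((p.left.key, er.key)))
            if er.key != p.left.key and key not in taken and key not in seen:
                seen.add(key)
                keep_left.append(_ordered(p.left, er))
        for el in lefts:
            key = tuple(sorted((el.key, p.right.key)))
            if el.key != p.right.key and key not in taken and key not in seen:
                seen.add(key)
                keep_right.append(_ordered(el, p.right))
    total = len(keep_left) + len(keep_right)
    if n > total:
        raise ValueError(f"requested {n} negatives but only {total} fixed-end "
                         f"candidates are available")
    rng = np.random.default_rng(seed)
    chosen: list[tuple[GenomicRegion, GenomicRegion]] = []
    pool_l, pool_r = keep_left[:], keep_right[:]
    for _ in range(n):
        side = rng.integers(2)
        pool = pool_l if (side == 0 and pool_l) or not pool_r else pool_r
        i = int(rng.integers(len(pool)))
        chosen.append(pool.pop(i))
    return [EnhancerPair(a, b, label=0) for a, b in chosen]


def split_ratio(pairs: list[EnhancerPair], ratios: tuple[int, int, int] = (8, 1, 1),
                seed: int = 0) -> SplitAssignment:
    """Stratified train/validation/test split at the given ratio."""
    if not pairs:
        raise ValueError("no pairs to split")
    rng = np.random.default_rng(seed)
    total = float(sum(ratios))
    names = ("train", "validation", "test")
    labels: list[str | None] = [None] * len(pairs)
    for cls in (0, 1):
        idx = [i for i, p in enumerate(pairs) if p.label == cls]
        if not idx:
            continue
        idx = list(rng.permutation(idx))
        raw = np.array([len(idx) * r / total for r in ratios])
        counts = np.floor(raw).astype(int)
        for j in np.argsort(-(raw - counts))[: len(idx) - counts.sum()]:
            counts[j] += 1
        pos = 0
        for name, c in zip(names, counts):
            for i in idx[pos:pos + c]:
                labels[i] = name
            pos += c
    return SplitAssignment(mode="ratio", labels=labels)


def split_kfold(pairs: list[EnhancerPair], k: int = 10, seed: int = 0) -> SplitAssignment:
    """Random partition into k folds of near-equal size."""
    if not pairs:
        raise ValueError("no pairs to split")
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the number of pairs ({len(pairs)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    labels = [0] * len(pairs)
    for fold in range(k):
        for i in order[fold::k]:
            labels[i] = fold
    return SplitAssignment(mode="kfold", labels=labels, k=k)


def split_enhancer_level(pairs: list[EnhancerPair], test_fraction: float = 0.1,
                         seed: int = 0, val_fraction: float = 0.0) -> SplitAssignment:
    """Dual-constraint enhancer-level split.

    (i) no enhancer id occurs in both train and test; (ii) within test,
    each enhancer id occurs exactly once. The test set is built greedily
    from a random pair order until the quota is reached or no admissible
    pair remains; pairs sharing an enhancer with the test set but not
    selected are dropped entirely.
    """
    if not pairs:
        raise ValueError("no pairs to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    quota = int(round(test_fraction * len(pairs)))
    test_enh: set[str] = set()
    labels: list[str] = ["train"] * len(pairs)
    n_test = 0
    for i in order:
        if n_test >= quota:
            break
        p = pairs[i]
        if p.left.key in test_enh or p.right.key in test_enh:
            continue
        labels[i] = "test"
        test_enh.update((p.left.key, p.right.key))
        n_test += 1
    if n_test < quota:
        logger.warning("enhancer-level test quota unreachable: %d < %d", n_test, quota)
    val_enh: set[str] = set()
    n_val_quota = int(round(val_fraction * len(pairs)))
    n_val = 0
    for i in order:
        p = pairs[i]
        if labels[i] != "train":
            continue
        if p.left.key in test_enh or p.right.key in test_enh:
            labels[i] = "dropped"
        elif n_val < n_val_quota and p.left.key not in val_enh and p.right.key not in val_enh:
            labels[i] = "validation"
            val_enh.update((p.left.key, p.right.key))
            n_val += 1
        elif p.left.key in val_enh or p.right.key in val_enh:
            labels[i] = "dropped"
    return SplitAssignment(mode="enhancer-level", labels=labels)


def categorize_super_enhancer(pairs: list[EnhancerPair],
                              super_enhancers: list[GenomicRegion]) -> list[EnhancerPair]:
    """Assign SE_intra / SE_inter / SE_out per pair.

    An enhancer maps to the super-enhancer with the largest overlap
    (ties: leftmost SE); SE_intra if both map to the same SE, SE_inter if
    to different SEs, SE_out otherwise.
    """
    def best_se(enh: GenomicRegion) -> str | None:
        best, best_len = None, 0
        for se in sorted(super_enhancers, key=lambda s: (s.chrom, s.start)):
            ov = se.overlap_length(enh)
            if ov > best_len:
                best, best_len = se.key, ov
        return best

    out = []
    cache: dict[str, str | None] = {}
    for p in pairs:
        for e in (p.left, p.right):
            if e.key not in cache:
                cache[e.key] = best_se(e)
        a, b = cache[p.left.key], cache[p.right.key]
        if a is not None and a == b:
            cat = "SE_intra"
        elif a is not None and b is not None:
            cat = "SE_inter"
        else:
            cat = "SE_out"
        out.append(replace(p, se_category=cat))
    return out


# ---------------------------------------------------------------------------
# dataset manifest (TSV) round trip

_MANIFEST_COLS = ["left_chrom", "left_start", "left_end", "left_id",
                  "right_chrom", "right_start", "right_end", "right_id",
                  "label", "loop_id", "distance", "se_category", "split"]


def pairs_to_frame(pairs: list[EnhancerPair],
                   split: SplitAssignment | None = None) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(pairs):
        rows.append({
            "left_chrom": p.left.chrom, "left_start": p.left.start,
            "left_end": p.left.end, "left_id": p.left.key,
            "right_chrom": p.right.chrom, "right_start": p.right.start,
            "right_end": p.right.end, "right_id": p.right.key,
            "label": p.label, "loop_id": p.loop_id if p.loop_id else ".",
            "distance": p.distance if p.distance is not None else -1,
            "se_category": p.se_category,
            "split": split.labels[i] if split is not None else ".",
        })
    return pd.DataFrame(rows, columns=_MANIFEST_COLS)


def frame_to_pairs(df: pd.DataFrame) -> list[EnhancerPair]:
    pairs = []
    for _, r in df.iterrows():
        left = GenomicRegion(r.left_chrom, int(r.left_start), int(r.left_end), id=str(r.left_id))
        right = GenomicRegion(r.right_chrom, int(r.right_start), int(r.right_end), id=str(r.right_id))
        loop_id = None if str(r.loop_id) == "." else str(r.loop_id)
        pairs.append(EnhancerPair(left, right, label=int(r.label), loop_id=loop_id,
                                  se_category=str(r.se_category)))
    return pairs


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
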