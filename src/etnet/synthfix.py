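"""Self-contained synthetic fixtures with known ground truth.

Generates a toy genome in which interaction labels are recoverable from
sequence: enhancers carry planted motif A, motif B, or no motif, and loops
form preferentially (probability ``p_pos``) between enhancer pairs where A
and B co-occur across the two anchors, rarely otherwise (``p_neg``). Every
same-chromosome A-B enhancer pair is a loop candidate, plus an equal-sized
random sample of non-co-occurring pairs, so a perfect co-occurrence detector
can recover the labels up to the planted label noise.

Also provides direct sequence-pair fixtures (no genome) for fast training
sanity checks, and closed-form surrogate scorers used as oracles for the
greedy-search and super-additivity machinery.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomio import Genome, GenomicRegion, LoopRecord, write_bed, write_bedpe
from .interpret import PairScorer
from .motifs import PwmMotif, write_jaspar


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study system."""

    n_chroms: int = 2
    chrom_length: int = 200_000
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif_a: str = "TGACGTCATG"   # planted in 'A' enhancers
    motif_b: str = "GGATTACCGG"   # planted in 'B' enhancers
    n_enhancers: int = 120
    enhancer_len_range: tuple[int, int] = (300, 600)
    frac_a: float = 0.2
    frac_b: float = 0.2
    central_span: int = 240       # motifs planted within this central span
    p_pos: float = 0.9
    p_neg: float = 0.05
    anchor_pad_range: tuple[int, int] = (200, 700)
    n_se_per_chrom: int = 3
    se_cluster_size: int = 3      # consecutive enhancers per super-enhancer
    n_effect_variants: int = 6
    n_null_variants: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_pos <= self.p_neg:
            raise ValueError("p_pos must exceed p_neg")
        max_w = max(len(self.motif_a), len(self.motif_b))
        if max_w > self.enhancer_len_range[0]:
            raise ValueError("motif longer than the shortest enhancer")


@dataclass
class Fixture:
    """In-memory synthetic dataset with its ground truth."""

    spec: FixtureSpec
    genome: Genome
    enhancers: list[GenomicRegion]
    motif_class: dict[str, str]            # enhancer id -> 'A' | 'B' | 'none'
    motif_position: dict[str, int]         # enhancer id -> motif start (genomic)
    loops: list[LoopRecord]
    loop_truth: pd.DataFrame               # candidate pairs with co-occurrence flag
    super_enhancers: list[GenomicRegion]
    variants: pd.DataFrame                 # chrom, pos, ref, alt, kind, enhancer_id


def _random_seq(rng: np.random.Generator, length: int, probs) -> str:
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=list(probs))])


def make_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Generate the full synthetic study system from a spec."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    seqs = {c: list(_random_seq(rng, spec.chrom_length, spec.base_probs))
            for c in chrom_names}

    # enhancer placement: jittered regular slots per chromosome
    per_chrom = spec.n_enhancers // spec.n_chroms
    enhancers: list[GenomicRegion] = []
    for c in chrom_names:
        margin = 2000
        slot = (spec.chrom_length - 2 * margin) // per_chrom
        for k in range(per_chrom):
            length = int(rng.integers(*spec.enhancer_len_range, endpoint=True))
            lo = margin + k * slot
            start = int(rng.integers(lo, max(lo + slot - length, lo + 1)))
            enhancers.append(GenomicRegion(c, start, start + length,
                                           id=f"E{len(enhancers):03d}"))

    # motif class assignment and planting
    n = len(enhancers)
    n_a, n_b = int(spec.frac_a * n), int(spec.frac_b * n)
    classes = ["A"] * n_a + ["B"] * n_b + ["none"] * (n - n_a - n_b)
    rng.shuffle(classes)
    motif_class = {e.key: cls for e, cls in zip(enhancers, classes)}
    motif_position: dict[str, int] = {}
    for e in enhancers:
        cls = motif_class[e.key]
        if cls == "none":
            continue
        motif = spec.motif_a if cls == "A" else spec.motif_b
        span = min(spec.central_span, e.width) - len(motif)
        mid = e.midpoint
        start = int(mid - span // 2 + rng.integers(0, max(span, 1)))
        motif_position[e.key] = start
        seqs[e.chrom][start:start + len(motif)] = list(motif)
    genome = Genome({c: "".join(s) for c, s in seqs.items()})

    # loop candidates: all same-chromosome A-B pairs + matched non-co-occurring sample
    ab_pairs, other_pairs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enhancers[i], enhancers[j]
            if a.chrom != b.chrom:
                continue
            kinds = {motif_class[a.key], motif_class[b.key]}
            (ab_pairs if kinds == {"A", "B"} else other_pairs).append((a, b))
    k_other = min(len(ab_pairs), len(other_pairs))
    other_idx = rng.choice(len(other_pairs), size=k_other, replace=False)
    candidates = [(p, True) for p in ab_pairs]
    candidates += [(other_pairs[i], False) for i in sorted(other_idx)]

    loops, truth_rows = [], []
    for (a, b), co in candidates:
        p = spec.p_pos if co else spec.p_neg
        is_loop = bool(rng.random() < p)
        truth_rows.append({"left_id": a.key, "right_id": b.key,
                           "co_occurrence": co, "loop": is_loop})
        if not is_loop:
            continue
        left, right = (a, b) if a.start <= b.start else (b, a)
        pads = rng.integers(*spec.anchor_pad_range, size=4, endpoint=True)
        anchor_l = GenomicRegion(left.chrom, max(0, left.start - int(pads[0])),
                                 left.end + int(pads[1]))
        anchor_r = GenomicRegion(right.chrom, max(0, right.start - int(pads[2])),
                                 right.end + int(pads[3]))
        loops.append(LoopRecord(anchor_l, anchor_r, loop_id=f"L{len(loops):04d}"))

    # super-enhancers: clusters of consecutive enhancers
    super_enhancers = []
    for c in chrom_names:
        on_c = sorted([e for e in enhancers if e.chrom == c], key=lambda e: e.start)
        starts = rng.choice(max(1, len(on_c) - spec.se_cluster_size),
                            size=spec.n_se_per_chrom, replace=False)
        for s in sorted(int(x) for x in starts):
            block = on_c[s:s + spec.se_cluster_size]
            super_enhancers.append(GenomicRegion(c, block[0].start - 100,
                                                 block[-1].end + 100,
                                                 id=f"SE{len(super_enhancers):02d}"))

    # variants: effect variants hit planted motif centers, null variants sit
    # inside motif-bearing enhancers but away from the motif
    var_rows = []
    carriers = [e for e in enhancers if motif_class[e.key] != "none"]
    chosen = rng.choice(len(carriers), size=min(spec.n_effect_variants + spec.n_null_variants,
                                                len(carriers)), replace=False)
    for v_idx, ci in enumerate(chosen):
        e = carriers[int(ci)]
        motif = spec.motif_a if motif_class[e.key] == "A" else spec.motif_b
        if v_idx < spec.n_effect_variants:
            pos = motif_position[e.key] + len(motif) // 2
            kind = "effect"
        else:
            pos = motif_position[e.key] - 60
            kind = "null"
        ref = genome.fetch(e.chrom, pos, pos + 1)
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        var_rows.append({"chrom": e.chrom, "pos": pos, "ref": ref, "alt": alt,
                         "kind": kind, "enhancer_id": e.key})

    return Fixture(spec=spec, genome=genome, enhancers=enhancers,
                   motif_class=motif_class, motif_position=motif_position,
                   loops=loops, loop_truth=pd.DataFrame(truth_rows),
                   super_enhancers=super_enhancers,
                   variants=pd.DataFrame(var_rows))


def motif_database(spec: FixtureSpec, n_decoys: int = 4, seed: int = 99) -> list[PwmMotif]:
    """JASPAR-style database: the two planted motifs plus random decoys."""
    rng = np.random.default_rng(seed)
    db = [PwmMotif.from_consensus(spec.motif_a, "MOTIF_A", pseudo=0.05, nsites=20),
          PwmMotif.from_consensus(spec.motif_b, "MOTIF_B", pseudo=0.05, nsites=20)]
    for i in range(n_decoys):
        w = int(rng.integers(8, 11))
        db.append(PwmMotif.from_consensus(_random_seq(rng, w, (0.25,) * 4),
                                          f"DECOY_{i}", pseudo=0.05, nsites=20))
    return db


def write_fixture(fixture: Fixture, outdir: str | os.PathLike) -> dict[str, str]:
    """Emit FASTA, BED, BEDPE, SE BED, variants TSV, motif DB, truth table."""
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "fasta": "genome.fa", "enhancers": "enhancers.bed", "loops": "loops.bedpe",
        "super_enhancers": "super_enhancers.bed", "variants": "variants.tsv",
        "motifs": "motifs.jaspar", "truth": "truth.tsv"}.items()}
    with open(paths["fasta"], "w") as fh:
        for c in fixture.genome.chromosomes():
            seq = fixture.genome.fetch(c, 0, fixture.genome.chrom_length(c))
            fh.write(f">{c}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_bed(fixture.enhancers, paths["enhancers"])
    write_bedpe(fixture.loops, paths["loops"])
    write_bed(fixture.super_enhancers, paths["super_enhancers"])
    fixture.variants.to_csv(paths["variants"], sep="\t", index=False)
    write_jaspar(motif_database(fixture.spec), paths["motifs"])
    truth = fixture.loop_truth.copy()
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# direct sequence-pair fixtures (no genome)

@dataclass
class SequencePairs:
    """Sequence-pair fixture with planted-motif ground truth.

    Iterating yields (lefts, rights, labels) so the common three-way unpack
    works; ``positions`` records the planted (left, right) motif starts per
    pair (None where that side carries no motif).
    """

    lefts: list[str]
    rights: list[str]
    labels: np.ndarray
    positions: list[tuple[int | None, int | None]]

    def __iter__(self):
        return iter((self.lefts, self.rights, self.labels))

    def __getitem__(self, i):
        return (self.lefts, self.rights, self.labels)[i]


def make_sequence_pairs(n: int, length: int, motif_a: str = "TGACGTCATG",
                        motif_b: str = "GGATTACCGG", seed: int = 0,
                        base_probs=(0.25,) * 4,
                        decoy_fraction: float = 2 / 3) -> SequencePairs:
    """Balanced sequence pairs whose label is the planted-motif co-occurrence.

    Positive pairs carry motif A in the left sequence and motif B in the
    right one, planted uniformly within the central half of each sequence
    (mirroring the genome fixture's central planting). A ``decoy_fraction``
    of the negatives carries exactly one of the two motifs (A-left or
    B-right, alternating), so single-motif detection cannot separate the
    classes — the label is the A-and-B co-occurrence, as in the genome
    fixture. The remaining negatives are pure background.
    """
    rng = np.random.default_rng(seed)
    labels = np.array([1] * (n // 2) + [0] * (n - n // 2))
    rng.shuffle(labels)
    lefts, rights, positions = [], [], []
    decoy_side = 0

    def plant_site(width: int) -> int:
        lo = length // 4
        hi = max(3 * length // 4 - width, lo + 1)
        return int(rng.integers(lo, hi))

    for lab in labels:
        l = _random_seq(rng, length, base_probs)
        r = _random_seq(rng, length, base_probs)
        pa = pb = None
        plant_a = plant_b = False
        if lab:
            plant_a = plant_b = True
        elif rng.random() < decoy_fraction:
            if decoy_side == 0:
                plant_a = True
            else:
                plant_b = True
            decoy_side = 1 - decoy_side
        if plant_a:
            pa = plant_site(len(motif_a))
            l = l[:pa] + motif_a + l[pa + len(motif_a):]
        if plant_b:
            pb = plant_site(len(motif_b))
            r = r[:pb] + motif_b + r[pb + len(motif_b):]
        lefts.append(l)
        rights.append(r)
        positions.append((pa, pb))
    return SequencePairs(lefts, rights, labels, positions)


def make_snp_system(spec: FixtureSpec | None = None, n_sites: int = 4,
                    n_partners: int = 4, seed: int = 0,
                    site_spacing: int = 1200):
    """Genome + variant table for the SNP effect analysis.

    One toy chromosome carries ``n_sites`` copies of motif A at known
    positions and ``n_partners`` partner enhancers carrying motif B. Each
    motif-A site yields one *effect* variant (motif center) and one *null*
    variant (25 bp downstream of the motif start, inside the scoring
    window but outside the motif). Returns (genome, variants DataFrame,
    partner regions).
    """
    import pandas as pd
    from .genomio import Genome, GenomicRegion

    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    total = (n_sites + n_partners + 2) * site_spacing
    seq = list(_random_seq(rng, total, spec.base_probs))
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    rows, partners = [], []
    for i in range(n_sites):
        p = (i + 1) * site_spacing
        seq[p:p + len(spec.motif_a)] = list(spec.motif_a)
        center = p + len(spec.motif_a) // 2
        null_pos = p + 25
        rows.append({"chrom": "chr1", "pos": center, "kind": "effect",
                     "motif_start": p})
        rows.append({"chrom": "chr1", "pos": null_pos, "kind": "null",
                     "motif_start": p})
    for j in range(n_partners):
        p = (n_sites + 1 + j) * site_spacing
        seq[p:p + len(spec.motif_b)] = list(spec.motif_b)
        half = 150
        partners.append(GenomicRegion("chr1", p - half, p + half,
                                      id=f"PARTNER{j}"))
    genome = Genome({"chr1": "".join(seq)})
    for row in rows:
        ref = genome.fetch(row["chrom"], row["pos"], row["pos"] + 1)
        row["ref"] = ref
        row["alt"] = flip[ref]
    return genome, pd.DataFrame(rows), partners


# ---------------------------------------------------------------------------
# surrogate scorers (oracles for greedy / synergy machinery)

class SurrogateScorer(PairScorer):
    """Closed-form scorer over region intactness of a reference pair.

    Regions of ``region_size`` bp tile the left then the right reference
    sequence. 'additive' scores sum(w_i * intact_i); 'and_gate' returns 1.0
    unless BOTH designated regions (one per side) are disrupted, in which
    case 0.0 — so the prediction falls only under the joint perturbation;
    'constant' ignores its input.
    """

    def __init__(self, kind: str, left_ref: str, right_ref: str,
                 region_size: int, weights=None,
                 gate_regions: tuple[int, int] | None = None,
                 constant: float = 0.5):
        if kind not in ("additive", "and_gate", "constant"):
            raise ValueError(f"unknown surrogate kind {kind!r}")
        if len(left_ref) % region_size or len(right_ref) % region_size:
            raise ValueError("region_size must divide both reference lengths")
        self.kind = kind
        self.left_ref, self.right_ref = left_ref, right_ref
        self.region_size = region_size
        self.n_left = len(left_ref) // region_size
        self.n_right = len(right_ref) // region_size
        total = self.n_left + self.n_right
        if kind == "additive":
            if weights is None or len(weights) != total:
                raise ValueError(f"additive surrogate needs {total} region weights")
            self.weights = np.asarray(weights, dtype=float)
            if not np.all(np.isfinite(self.weights)):
                raise ValueError("weights must be finite")
        if kind == "and_gate":
            if gate_regions is None:
                gate_regions = (0, 0)
            self.gate_left, self.gate_right = gate_regions
        self.constant = constant

    def _intact(self, seq: str, ref: str) -> np.ndarray:
        rs = self.region_size
        return np.array([seq[i:i + rs] == ref[i:i + rs]
                         for i in range(0, len(ref), rs)], dtype=float)

    def score(self, left: str, right: str) -> float:
        if self.kind == "constant":
            return self.constant
        il = self._intact(left, self.left_ref)
        ir = self._intact(right, self.right_ref)
        if self.kind == "additive":
            return float(self.weights @ np.concatenate([il, ir]))
        both_broken = il[self.gate_left] == 0 and ir[self.gate_right] == 0
        return 0.0 if both_broken else 1.0


def make_surrogate_scorer(kind: str, left_ref: str, right_ref: str,
                          region_size: int, weights=None,
                          gate_regions: tuple[int, int] | None = None,
                          constant: float = 0.5) -> SurrogateScorer:
    return SurrogateScorer(kind, left_ref, right_ref, region_size,
                           weights=weights, gate_regions=gate_regions,
                           constant=constant)


# ---------------------------------------------------------------------------
# end-to-end dataset assembly on the fixture

def fixture_dataset(fixture: Fixture, neg_strategy: str = "random",
                    seed: int = 0, split: str = "ratio") -> pd.DataFrame:
    """Build the balanced labeled manifest from the fixture's files in memory."""
    from . import pairset

    positives = pairset.find_positive_pairs(fixture.loops, fixture.enhancers)
    n = len(positives)
    if neg_strategy == "random":
        # same-chromosome pool: cross-chromosome co-occurring pairs would be
        # mislabeled by construction (loops are intra-chromosomal only)
        negatives = pairset.sample_negatives_random(positives, n, seed=seed,
                                                    same_chrom_only=True)
    elif neg_strategy == "distance":
        negatives = pairset.sample_negatives_distance_matched(positives, n, seed=seed)
    elif neg_strategy == "fixed-end":
        negatives = pairset.sample_negatives_fixed_end(positives, n, seed=seed)
    else:
        raise ValueError(f"unknown negative sampling strategy {neg_strategy!r}")
    pairs = positives + negatives
    pairs = pairset.categorize_super_enhancer(pairs, fixture.super_enhancers)
    if split == "ratio":
        assignment = pairset.split_ratio(pairs, seed=seed)
    elif split == "kfold":
        assignment = pairset.split_kfold(pairs, seed=seed)
    elif split == "enhancer-level":
        assignment = pairset.split_enhancer_level(pairs, test_fraction=0.1,
                                                  seed=seed, val_fraction=0.1)
    else:
        raise ValueError(f"unknown split {split!r}")
    return pairset.pairs_to_frame(pairs, assignment)
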