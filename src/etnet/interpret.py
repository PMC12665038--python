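"""Perturbation and attribution analysis of trained pair classifiers.

Everything here treats the model as a scorer of sequence pairs, so the same
machinery runs on the neural classifier and on closed-form surrogate scorers:

* exact dinucleotide shuffling (Eulerian-path construction) for reference
  sequences and region perturbations;
* reference-based attribution: gradient x (input - reference), averaged over
  interpolation steps and over several dinucleotide-shuffled references;
* greedy search over non-overlapping sub-regions, iteratively fixing the
  perturbation with the largest (or smallest) effect on the prediction;
* super-additivity: S = delta_joint - (delta_left + delta_right) comparing a
  joint two-sided perturbation against the summed one-sided effects;
* conversion of attribution tracks to position weight matrices and cosine
  matching against a motif database, with MEME-format output;
* SNP effect deltas: reference vs alternate allele predictions for a 150 bp
  upstream anchor paired with candidate partner enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from ._autodiff import Tensor
from .genomio import Genome, GenomicRegion, one_hot_encode, standardize_window
from .model import EtnetModel
from .motifs import PwmMotif, write_meme

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# dinucleotide shuffling

def _shuffle_run(seq: str, rng: np.random.Generator, max_tries: int = 10000) -> str:
    """Altschul-Erickson shuffle of an ACGT string.

    Preserves the exact dinucleotide count multiset and the first and last
    base. The sequence is a walk on the 4-vertex base graph; a random
    spanning arborescence toward the final vertex fixes each vertex's last
    outgoing edge, the remaining edges are permuted, and the Eulerian walk
    is re-read.
    """
    if len(seq) <= 2 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    sources = [v for v in edges if v != last]
    for _ in range(max_tries):
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in sources}
        ok = True
        for v in sources:
            hops, cur = 0, v
            while cur != last:
                cur = last_edge.get(cur)
                hops += 1
                if cur is None or hops > 4:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - arborescence sampling converges quickly
        raise RuntimeError("dinucleotide shuffle failed to find an arborescence")

    walk_edges: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        walk_edges[v] = pool
    out = [seq[0]]
    ptr = {v: 0 for v in walk_edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = walk_edges[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_shuffle(sequence: str, seed: int | np.random.Generator = 0) -> str:
    """Shuffle a DNA string preserving its exact dinucleotide composition.

    N positions are held fixed; each maximal ACGT run is shuffled
    independently (first and last base of each run preserved).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = sequence.upper()
    out: list[str] = []
    i = 0
    while i < len(seq):
        if seq[i] not in _BASES:
            out.append(seq[i])
            i += 1
            continue
        j = i
        while j < len(seq) and seq[j] in _BASES:
            j += 1
        out.append(_shuffle_run(seq[i:j], rng))
        i = j
    return "".join(out)


def dinucleotide_counts(sequence: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(sequence, sequence[1:]):
        if a in _BASES and b in _BASES:
            counts[a + b] = counts.get(a + b, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# scorer protocol

class PairScorer:
    """Anything that maps a (left, right) sequence pair to a score."""

    def score(self, left: str, right: str) -> float:
        raise NotImplementedError

    def score_batch(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        return np.array([self.score(l, r) for l, r in pairs])


class ModelScorer(PairScorer):
    """Adapts the neural classifier to the string-pair scorer protocol."""

    def __init__(self, model: EtnetModel, batch_size: int = 100):
        self.model = model
        self.batch_size = batch_size

    def _check(self, seq: str) -> None:
        if len(seq) != self.model.config.seq_len:
            raise ValueError(f"sequence length {len(seq)} != model window "
                             f"{self.model.config.seq_len}")

    def score(self, left: str, right: str) -> float:
        return float(self.score_batch([(left, right)])[0])

    def score_batch(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        for l, r in pairs:
            self._check(l)
            self._check(r)
        xl = np.stack([one_hot_encode(l) for l, _ in pairs])
        xr = np.stack([one_hot_encode(r) for _, r in pairs])
        return self.model.predict(xl, xr, batch_size=self.batch_size)


def as_scorer(obj) -> PairScorer:
    if isinstance(obj, EtnetModel):
        return ModelScorer(obj)
    if hasattr(obj, "score") and hasattr(obj, "score_batch"):
        return obj
    if hasattr(obj, "score"):
        class _Wrapped(PairScorer):  # batch via the scalar path
            def score(self, left, right, _s=obj.score):
                return _s(left, right)
        return _Wrapped()
    raise TypeError(f"cannot interpret {type(obj)!r} as a pair scorer")


# ---------------------------------------------------------------------------
# attribution

@dataclass
class AttributionTrack:
    """Per-base contribution scores for one enhancer pair."""

    left: np.ndarray   # (L, 4)
    right: np.ndarray  # (L, 4)
    left_sequence: str
    right_sequence: str
    n_references: int
    seed: int
    model_trained: bool = True

    def importance(self, side: str) -> np.ndarray:
        """Per-position importance: the contribution at the observed base."""
        mat = self.left if side == "left" else self.right
        seq = self.left_sequence if side == "left" else self.right_sequence
        onehot = one_hot_encode(seq)
        return (mat * onehot).sum(axis=1)


def attribute(model: EtnetModel, left_seq: str, right_seq: str,
              n_references: int = 10, seed: int = 0, n_steps: int = 8,
              model_trained: bool = True) -> AttributionTrack:
    """Reference-based attribution for one pair.

    For each of ``n_references`` dinucleotide-shuffled references the
    contribution is (input - reference) times the input gradient averaged
    over ``n_steps`` points along the reference-to-input contrast (an
    integrated-gradients path from each reference); tracks are the mean
    over references. Several steps are needed because motif detectors are
    ReLU-gated: their gradient appears only part-way along the path, so a
    two-point estimate underweights motif positions.
    """
    rng = np.random.default_rng(seed)
    x_l, x_r = one_hot_encode(left_seq), one_hot_encode(right_seq)
    total_l = np.zeros_like(x_l, dtype=float)
    total_r = np.zeros_like(x_r, dtype=float)
    alphas = np.linspace(0.0, 1.0, n_steps) if n_steps > 1 else np.array([1.0])
    for _ in range(n_references):
        ref_l = one_hot_encode(dinucleotide_shuffle(left_seq, rng))
        ref_r = one_hot_encode(dinucleotide_shuffle(right_seq, rng))
        batch_l = np.stack([ref_l + a * (x_l - ref_l) for a in alphas])
        batch_r = np.stack([ref_r + a * (x_r - ref_r) for a in alphas])
        tl, tr = Tensor(batch_l, requires_grad=True), Tensor(batch_r, requires_grad=True)
        prob = model.forward_logits(tl, tr).sigmoid()
        prob.sum().backward()
        grad_l = tl.grad.mean(axis=0)
        grad_r = tr.grad.mean(axis=0)
        total_l += (x_l - ref_l) * grad_l
        total_r += (x_r - ref_r) * grad_r
    return AttributionTrack(left=total_l / n_references, right=total_r / n_references,
                            left_sequence=left_seq, right_sequence=right_seq,
                            n_references=n_references, seed=seed,
                            model_trained=model_trained)


# ---------------------------------------------------------------------------
# greedy region search

@dataclass
class PerturbationRecord:
    """Effect of dinucleotide-shuffling one sub-region."""

    side: str           # 'left' or 'right'
    start: int          # window-local bp offsets
    end: int
    baseline: float     # prediction before this iteration's perturbation
    delta: float        # baseline - mean(shuffled replicate predictions)
    replicate_deltas: np.ndarray
    n_shuffles: int
    iteration: int


def _replace(seq: str, start: int, end: int, sub: str) -> str:
    return seq[:start] + sub + seq[end:]


def greedy_region_search(scorer, left_seq: str, right_seq: str,
                         region_size: int = 100, n_shuffles: int = 10,
                         max_iters: int | None = None,
                         objective: str = "maximize_drop",
                         seed: int = 0) -> list[PerturbationRecord]:
    """Iteratively fix the region whose shuffling most changes the score.

    Both sides' non-overlapping regions form one candidate pool. Each
    iteration shuffles every remaining region ``n_shuffles`` times on top
    of the already-perturbed sequences, fixes the region optimizing the
    objective (ties: leftmost region, left side before right), and removes
    it from the pool. The retained perturbation is the replicate whose
    prediction is closest to the replicate mean.
    """
    if objective not in ("maximize_drop", "minimize_drop"):
        raise ValueError(f"unknown objective {objective!r}")
    scorer = as_scorer(scorer)
    for name, seq in (("left", left_seq), ("right", right_seq)):
        if len(seq) % region_size:
            raise ValueError(f"region_size {region_size} does not divide the "
                             f"{name} sequence length {len(seq)}")
    rng = np.random.default_rng(seed)
    candidates = [("left", s, s + region_size) for s in range(0, len(left_seq), region_size)]
    candidates += [("right", s, s + region_size) for s in range(0, len(right_seq), region_size)]
    if max_iters is None:
        max_iters = len(candidates)
    if max_iters > len(candidates):
        import warnings
        warnings.warn(f"max_iters clipped to the number of regions ({len(candidates)})")
        max_iters = len(candidates)

    cur_l, cur_r = left_seq, right_seq
    records: list[PerturbationRecord] = []
    for iteration in range(max_iters):
        baseline = scorer.score(cur_l, cur_r)
        variants: list[tuple[str, str]] = []
        shuffles: list[list[str]] = []
        for side, s, e in candidates:
            seq = cur_l if side == "left" else cur_r
            subs = [dinucleotide_shuffle(seq[s:e], rng) for _ in range(n_shuffles)]
            shuffles.append(subs)
            for sub in subs:
                mutated = _replace(seq, s, e, sub)
                variants.append((mutated, cur_r) if side == "left" else (cur_l, mutated))
        preds = scorer.score_batch(variants).reshape(len(candidates), n_shuffles)
        deltas = baseline - preds
        mean_delta = deltas.mean(axis=1)
        best = int(np.argmax(mean_delta) if objective == "maximize_drop"
                   else np.argmin(mean_delta))
        side, s, e = candidates[best]
        # retain the most representative replicate (closest to the mean)
        rep = int(np.argmin(np.abs(preds[best] - preds[best].mean())))
        retained = shuffles[best][rep]
        if side == "left":
            cur_l = _replace(cur_l, s, e, retained)
        else:
            cur_r = _replace(cur_r, s, e, retained)
        records.append(PerturbationRecord(side=side, start=s, end=e,
                                          baseline=float(baseline),
                                          delta=float(mean_delta[best]),
                                          replicate_deltas=deltas[best].copy(),
                                          n_shuffles=n_shuffles,
                                          iteration=iteration))
        candidates.pop(best)
    return records


# ---------------------------------------------------------------------------
# super-additivity

@dataclass
class SynergyScore:
    delta_left: float
    delta_right: float
    delta_joint: float
    n_shuffles: int
    tau: float = 0.0

    @property
    def S(self) -> float:
        return self.delta_joint - (self.delta_left + self.delta_right)

    @property
    def classification(self) -> str:
        # 1e-12 guard absorbs floating-point noise around exact additivity
        return ("super-additive" if self.S > self.tau + 1e-12
                else "additive-or-sub-additive")


def synergy(scorer, left_seq: str, right_seq: str,
            region_left: tuple[int, int], region_right: tuple[int, int],
            n_shuffles: int = 10, seed: int = 0, tau: float = 0.0) -> SynergyScore:
    """Joint vs summed single-region perturbation effects for one pair."""
    scorer = as_scorer(scorer)
    rng = np.random.default_rng(seed)
    baseline = scorer.score(left_seq, right_seq)
    ls, le = region_left
    rs, re = region_right
    subs_l = [dinucleotide_shuffle(left_seq[ls:le], rng) for _ in range(n_shuffles)]
    subs_r = [dinucleotide_shuffle(right_seq[rs:re], rng) for _ in range(n_shuffles)]
    variants = ([( _replace(left_seq, ls, le, s), right_seq) for s in subs_l]
                + [(left_seq, _replace(right_seq, rs, re, s)) for s in subs_r]
                + [(_replace(left_seq, ls, le, sl), _replace(right_seq, rs, re, sr))
                   for sl, sr in zip(subs_l, subs_r)])
    preds = scorer.score_batch(variants)
    d_left = float(baseline - preds[:n_shuffles].mean())
    d_right = float(baseline - preds[n_shuffles:2 * n_shuffles].mean())
    d_joint = float(baseline - preds[2 * n_shuffles:].mean())
    return SynergyScore(d_left, d_right, d_joint, n_shuffles=n_shuffles, tau=tau)


def top_region(scorer, left_seq: str, right_seq: str, side: str,
               region_size: int = 100, n_shuffles: int = 10,
               seed: int = 0) -> tuple[int, int]:
    """The single region on one side whose shuffling drops the score most."""
    scorer = as_scorer(scorer)
    rng = np.random.default_rng(seed)
    seq = left_seq if side == "left" else right_seq
    baseline = scorer.score(left_seq, right_seq)
    starts = list(range(0, len(seq), region_size))
    variants = []
    for s in starts:
        for _ in range(n_shuffles):
            sub = dinucleotide_shuffle(seq[s:s + region_size], rng)
            mutated = _replace(seq, s, s + region_size, sub)
            variants.append((mutated, right_seq) if side == "left" else (left_seq, mutated))
    preds = scorer.score_batch(variants).reshape(len(starts), n_shuffles)
    best = int(np.argmax(baseline - preds.mean(axis=1)))
    return starts[best], starts[best] + region_size


def kmer_cosine_similarity(a: str, b: str, k: int = 4) -> float:
    """Cosine similarity of k-mer count vectors of two sequences."""
    def counts(seq: str) -> np.ndarray:
        v = np.zeros(4 ** k)
        idx = {c: i for i, c in enumerate(_BASES)}
        for i in range(len(seq) - k + 1):
            sub = seq[i:i + k]
            if all(c in idx for c in sub):
                code = 0
                for c in sub:
                    code = code * 4 + idx[c]
                v[code] += 1
        return v
    va, vb = counts(a.upper()), counts(b.upper())
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return float("nan")
    return float(va @ vb / (na * nb))


@dataclass
class SynergySurvey:
    scores: list[SynergyScore]
    similarities: np.ndarray
    fraction_super_additive: float
    pearson_r: float
    pearson_p: float


def synergy_survey(scorer, pairs: list[tuple[str, str]], region_size: int = 100,
                   n_shuffles: int = 10, seed: int = 0, tau: float = 0.0,
                   kmer: int = 4) -> SynergySurvey:
    """Population-level super-additivity statistics.

    For each pair the top-1 region per side (by single-region drop) defines
    the perturbation; the survey reports the super-additive fraction and
    the Pearson correlation between synergy strength S and pairwise
    sequence similarity (cosine over k-mer counts).
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    scores, sims = [], []
    for i, (l, r) in enumerate(pairs):
        rl = top_region(scorer, l, r, "left", region_size, n_shuffles, seed=seed + 3 * i)
        rr = top_region(scorer, l, r, "right", region_size, n_shuffles, seed=seed + 3 * i + 1)
        scores.append(synergy(scorer, l, r, rl, rr, n_shuffles, seed=seed + 3 * i + 2, tau=tau))
        sims.append(kmer_cosine_similarity(l, r, k=kmer))
    sims_arr = np.array(sims)
    svals = np.array([s.S for s in scores])
    frac = float(np.mean([s.classification == "super-additive" for s in scores]))
    if np.nanstd(sims_arr) == 0 or np.nanstd(svals) == 0:
        r, p = float("nan"), float("nan")
    else:
        r, p = pearsonr(svals, sims_arr)
    return SynergySurvey(scores=scores, similarities=sims_arr,
                         fraction_super_additive=frac,
                         pearson_r=float(r), pearson_p=float(p))


# ---------------------------------------------------------------------------
# attribution -> PWM and motif matching

def attribution_to_pwms(tracks: list[AttributionTrack], window: int,
                        quantile: float = 0.95) -> list[PwmMotif]:
    """Extract PWMs from high-importance attribution windows.

    Sliding windows of the given size are scored by their summed positive
    per-position importance; windows strictly above the per-track quantile
    are kept and overlapping windows are merged (highest score wins). Each
    window's PWM carries the positive attribution mass at the observed base
    of every position, normalized per position (positions with no positive
    importance become uniform rows). On one-hot inputs the observed base is
    where the attribution of the real sequence lives; spreading mass over
    the reference bases would encode the shuffled baselines instead.
    """
    pwms: list[PwmMotif] = []
    for t_idx, track in enumerate(tracks):
        for side in ("left", "right"):
            imp = np.clip(track.importance(side), 0.0, None)
            seq = track.left_sequence if side == "left" else track.right_sequence
            onehot = one_hot_encode(seq)
            if len(imp) < window:
                continue
            sums = np.convolve(imp, np.ones(window), mode="valid")
            thr = np.quantile(sums, quantile)
            order = np.argsort(-sums, kind="mergesort")
            chosen: list[int] = []
            for s in order:
                if sums[s] <= thr:
                    break
                if all(abs(s - c) >= window for c in chosen):
                    chosen.append(int(s))
            for s in sorted(chosen):
                pos_mass = imp[s:s + window, None] * onehot[s:s + window]
                rows = pos_mass.sum(axis=1, keepdims=True)
                pwm = np.where(rows > 0, pos_mass / np.maximum(rows, 1e-300), 0.25)
                pwms.append(PwmMotif(pwm, name=f"track{t_idx}_{side}_{s}",
                                     source="attribution", nsites=1))
    return pwms


def pwm_cosine(a: np.ndarray, b: np.ndarray, max_shift: int = 3) -> float:
    """Max cosine similarity over alignment offsets.

    Besides full-coverage offsets, overhanging alignments shifted by up to
    ``max_shift`` positions are scanned (attribution windows rarely land
    exactly on a motif boundary); the overlap must keep at least
    ``min_width - max_shift`` columns, and the cosine is computed over the
    overlapping columns only.
    """
    wa, wb = len(a), len(b)
    min_overlap = max(4, min(wa, wb) - max_shift)
    best = -1.0
    for off in range(-(wa - min_overlap), wb - min_overlap + 1):
        sa, sb = max(0, -off), max(0, off)
        ov = min(wa - sa, wb - sb)
        if ov < min_overlap:
            continue
        x = a[sa:sa + ov].ravel()
        y = b[sb:sb + ov].ravel()
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx > 0 and ny > 0:
            best = max(best, float(x @ y / (nx * ny)))
    return best


def _revcomp_pwm(m: np.ndarray) -> np.ndarray:
    return m[::-1, ::-1]


@dataclass
class MotifMatch:
    query: str
    motif: str
    similarity: float


def match_motifs(query_pwms: list[PwmMotif], database_pwms: list[PwmMotif],
                 threshold: float = 0.8, both_orientations: bool = False
                 ) -> tuple[list[MotifMatch], dict[str, int]]:
    """Best-database-match per query PWM by cosine similarity.

    A query is retained iff its best match reaches the threshold; the
    returned counts aggregate retained occurrences per database motif.
    Forward orientation only by default.
    """
    if not database_pwms:
        raise ValueError("empty motif database")
    matches: list[MotifMatch] = []
    counts: dict[str, int] = {m.name: 0 for m in database_pwms}
    for q in query_pwms:
        best_name, best_sim = None, -1.0
        for db in database_pwms:
            sim = pwm_cosine(q.matrix, db.matrix)
            if both_orientations:
                sim = max(sim, pwm_cosine(q.matrix, _revcomp_pwm(db.matrix)))
            if sim > best_sim:
                best_name, best_sim = db.name, sim
        if best_name is not None and best_sim >= threshold:
            matches.append(MotifMatch(q.name, best_name, best_sim))
            counts[best_name] += 1
    return matches, counts


def write_matched_meme(database_pwms: list[PwmMotif], counts: dict[str, int],
                       path) -> None:
    """MEME minimal output of matched motifs with nsites = occurrence count."""
    hit = [PwmMotif(m.matrix, m.name, source=m.source, nsites=counts[m.name])
           for m in database_pwms if counts.get(m.name, 0) > 0]
    write_meme(hit, path)


# ---------------------------------------------------------------------------
# SNP effect deltas

@dataclass
class SnpEffect:
    partner_id: str
    p_ref: float
    p_alt: float

    @property
    def delta(self) -> float:
        return self.p_alt - self.p_ref


@dataclass
class SnpReport:
    snp: tuple[str, int, str, str]
    effects: list[SnpEffect]

    @property
    def mean_abs_delta_percent(self) -> float:
        return float(np.mean([abs(e.delta) for e in self.effects]) * 100.0)


def snp_delta(model: EtnetModel, genome: Genome, snp: tuple[str, int, str, str],
              partner_enhancers: list[GenomicRegion], flank: int = 150,
              batch_size: int = 100) -> SnpReport:
    """Predicted interaction change between reference and alternate alleles.

    anchor1 is the ``flank`` bp immediately upstream of the SNP position
    plus the SNP base, standardized to the model window; anchor2 iterates
    over the partner enhancers. Delta = p_alt - p_ref per partner.
    """
    chrom, pos, ref, alt = snp
    ref, alt = ref.upper(), alt.upper()
    if alt not in _BASES:
        raise ValueError(f"alt allele {alt!r} is not one of A/C/G/T")
    if not partner_enhancers:
        raise ValueError("partner enhancer list is empty")
    observed = genome.fetch(chrom, pos, pos + 1)
    if observed != ref:
        raise ValueError(f"reference mismatch at {chrom}:{pos}: genome has "
                         f"{observed!r}, expected {ref!r}")
    width = model.config.seq_len
    anchor1 = GenomicRegion(chrom, pos - flank, pos + 1, id="anchor1")
    window = standardize_window(anchor1, width)
    seq_ref = genome.fetch_region(window)
    offset = pos - window.start
    if not 0 <= offset < width:
        raise ValueError(f"SNP at offset {offset} falls outside the {width} bp "
                         f"model window; reduce flank or widen the model")
    seq_alt = seq_ref[:offset] + alt + seq_ref[offset + 1:]
    x_ref, x_alt = one_hot_encode(seq_ref), one_hot_encode(seq_alt)
    partners = [one_hot_encode(genome.fetch_region(standardize_window(e, width)))
                for e in partner_enhancers]
    xp = np.stack(partners)
    p_ref = model.predict(np.repeat(x_ref[None], len(partners), axis=0), xp,
                          batch_size=batch_size)
    p_alt = model.predict(np.repeat(x_alt[None], len(partners), axis=0), xp,
                          batch_size=batch_size)
    effects = [SnpEffect(e.key, float(r), float(a))
               for e, r, a in zip(partner_enhancers, p_ref, p_alt)]
    return SnpReport(snp=(chrom, pos, ref, alt), effects=effects)
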