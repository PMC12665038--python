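"""Perturbation, attribution, synergy, motif-matching oracles."""

import itertools

import numpy as np
import pytest

from etnet.genomio import Genome, GenomicRegion
from etnet.interpret import (
    attribute,
    attribution_to_pwms,
    dinucleotide_counts,
    dinucleotide_shuffle,
    greedy_region_search,
    kmer_cosine_similarity,
    match_motifs,
    pwm_cosine,
    snp_delta,
    synergy,
    synergy_survey,
    top_region,
    write_matched_meme,
)
from etnet.model import build_model, reduced_config
from etnet.motifs import PwmMotif, read_meme
from etnet.synthfix import make_surrogate_scorer


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestDinucleotideShuffle:
    def test_homopolymer_fixed_point(self):
        assert dinucleotide_shuffle("AAAA", seed=0) == "AAAA"

    def test_alternating_fixed_point_via_enumeration(self):
        # oracle: enumerate all length-6 AT-strings, confirm ATATAT is the
        # unique sequence with its dinucleotide counts and endpoints
        target = "ATATAT"
        want = dinucleotide_counts(target)
        matches = [
            "".join(s) for s in itertools.product("AT", repeat=6)
            if dinucleotide_counts("".join(s)) == want
            and s[0] == target[0] and s[-1] == target[-1]
        ]
        assert matches == [target]
        for seed in range(5):
            assert dinucleotide_shuffle(target, seed=seed) == target

    def test_counts_conserved_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            seq = random_seq(rng, int(rng.integers(2, 500)))
            shuf = dinucleotide_shuffle(seq, seed=int(rng.integers(2**31)))
            assert dinucleotide_counts(shuf) == dinucleotide_counts(seq)
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def test_n_positions_held_fixed(self):
        seq = "ACGTACGT" + "NN" + "TTGACGTA"
        shuf = dinucleotide_shuffle(seq, seed=3)
        assert shuf[8:10] == "NN"
        assert dinucleotide_counts(shuf) == dinucleotide_counts(seq)

    def test_shuffle_changes_long_sequences(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 300)
        assert dinucleotide_shuffle(seq, seed=2) != seq


class TestGreedySearch:
    rng = np.random.default_rng(10)
    left = "".join(rng.choice(list("ACGT"), size=120))
    right = "".join(rng.choice(list("ACGT"), size=120))

    def test_additive_surrogate_orders_by_weight(self):
        weights = [3.0, 2.0, 1.0, 0.5, 5.0, 4.0]  # 3 regions per side
        scorer = make_surrogate_scorer("additive", self.left, self.right, 40,
                                       weights=weights)
        records = greedy_region_search(scorer, self.left, self.right,
                                       region_size=40, n_shuffles=3, seed=0)
        picked = [(r.side, r.start // 40) for r in records]
        region_ids = [{"left": 0, "right": 3}[s] + i for s, i in picked]
        assert region_ids == list(np.argsort(weights)[::-1])
        for rec, region in zip(records, region_ids):
            assert rec.delta == pytest.approx(weights[region])

    def test_greedy_matches_exhaustive_subset_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            weights = list(np.round(rng.random(6) * 10, 3))
            scorer = make_surrogate_scorer("additive", self.left, self.right, 40,
                                           weights=weights)
            records = greedy_region_search(scorer, self.left, self.right,
                                           region_size=40, n_shuffles=2,
                                           max_iters=3, seed=1)
            greedy_set = {("left", r.start // 40) if r.side == "left"
                          else ("right", r.start // 40) for r in records}
            # exhaustive: best 3-subset by total drop
            regions = [("left", i) for i in range(3)] + [("right", i) for i in range(3)]
            best = max(itertools.combinations(range(6), 3),
                       key=lambda c: sum(weights[i] for i in c))
            assert greedy_set == {regions[i] for i in best}

    def test_constant_scorer_ties_broken_leftmost(self):
        scorer = make_surrogate_scorer("constant", self.left, self.right, 40)
        records = greedy_region_search(scorer, self.left, self.right,
                                       region_size=40, n_shuffles=2, seed=0)
        assert all(r.delta == 0.0 for r in records)
        assert [(r.side, r.start) for r in records[:4]] == [
            ("left", 0), ("left", 40), ("left", 80), ("right", 0)]

    def test_selected_regions_pairwise_disjoint(self):
        weights = list(np.random.default_rng(5).random(6))
        scorer = make_surrogate_scorer("additive", self.left, self.right, 40,
                                       weights=weights)
        records = greedy_region_search(scorer, self.left, self.right,
                                       region_size=40, n_shuffles=2, seed=2)
        seen = {(r.side, r.start) for r in records}
        assert len(seen) == len(records) == 6

    def test_indivisible_region_size_errors(self):
        scorer = make_surrogate_scorer("constant", self.left, self.right, 40)
        with pytest.raises(ValueError, match="region_size"):
            greedy_region_search(scorer, self.left, self.right, region_size=50)


class TestSynergy:
    rng = np.random.default_rng(20)
    left = "".join(rng.choice(list("ACGT"), size=100))
    right = "".join(rng.choice(list("ACGT"), size=100))

    def test_additive_surrogate_zero_interaction(self):
        scorer = make_surrogate_scorer("additive", self.left, self.right, 50,
                                       weights=[2.0, 1.0, 4.0, 3.0])
        s = synergy(scorer, self.left, self.right, (0, 50), (50, 100),
                    n_shuffles=5, seed=0)
        assert s.S == pytest.approx(0.0, abs=1e-12)
        assert s.classification == "additive-or-sub-additive"

    def test_and_gate_super_additive(self):
        scorer = make_surrogate_scorer("and_gate", self.left, self.right, 50,
                                       gate_regions=(0, 1))
        s = synergy(scorer, self.left, self.right, (0, 50), (50, 100),
                    n_shuffles=5, seed=0)
        assert s.delta_left == pytest.approx(0.0)
        assert s.delta_right == pytest.approx(0.0)
        assert s.delta_joint == pytest.approx(1.0)
        assert s.S == pytest.approx(1.0)
        assert s.classification == "super-additive"

    def test_s_recomputable_from_deltas(self):
        scorer = make_surrogate_scorer("additive", self.left, self.right, 50,
                                       weights=[2.0, 1.0, 4.0, 3.0])
        s = synergy(scorer, self.left, self.right, (0, 50), (0, 50), n_shuffles=3, seed=1)
        assert s.S == s.delta_joint - (s.delta_left + s.delta_right)

    def test_top_region_finds_heaviest(self):
        scorer = make_surrogate_scorer("additive", self.left, self.right, 50,
                                       weights=[2.0, 7.0, 4.0, 3.0])
        assert top_region(scorer, self.left, self.right, "left", 50, 3, seed=0) == (50, 100)
        assert top_region(scorer, self.left, self.right, "right", 50, 3, seed=0) == (0, 50)


class TestSynergySurvey:
    def _pairs(self, n=6, length=100, seed=30):
        rng = np.random.default_rng(seed)
        return [(random_seq(rng, length), random_seq(rng, length)) for _ in range(n)]

    def test_additive_population_fraction_zero(self):
        pairs = self._pairs()
        rng = np.random.default_rng(0)
        frac_flags = []
        for l, r in pairs:
            scorer = make_surrogate_scorer("additive", l, r, 50,
                                           weights=list(rng.random(4) * 3))
            s = synergy(scorer, l, r, (0, 50), (50, 100), n_shuffles=4, seed=1)
            frac_flags.append(s.classification == "super-additive")
        assert sum(frac_flags) == 0

    def test_and_gate_population_fraction_one(self):
        pairs = self._pairs()
        results = []
        for l, r in pairs:
            scorer = make_surrogate_scorer("and_gate", l, r, 50, gate_regions=(0, 0))
            s = synergy(scorer, l, r, (0, 50), (0, 50), n_shuffles=4, seed=2)
            results.append(s.classification)
        assert all(c == "super-additive" for c in results)

    def test_survey_reports_fraction_and_correlation(self):
        pairs = self._pairs(n=5)
        scorer = make_surrogate_scorer("constant", pairs[0][0], pairs[0][1], 50)

        class AnyConstant:
            def score(self, l, r):
                return 0.5
            def score_batch(self, batch):
                return np.full(len(batch), 0.5)

        survey = synergy_survey(AnyConstant(), pairs, region_size=50,
                                n_shuffles=2, seed=0)
        assert survey.fraction_super_additive == 0.0
        assert len(survey.scores) == 5
        assert np.isnan(survey.pearson_r)  # S constant -> correlation undefined

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            synergy_survey(None, [("A", "C")])


class TestKmerSimilarity:
    def test_identical_sequences_similarity_one(self):
        seq = random_seq(np.random.default_rng(3), 100)
        assert kmer_cosine_similarity(seq, seq) == pytest.approx(1.0)

    def test_disjoint_kmer_content_zero(self):
        assert kmer_cosine_similarity("AAAAAAAA", "CCCCCCCC") == pytest.approx(0.0)


@pytest.fixture
def small_model():
    cfg = reduced_config(seq_len=80, conv_channels=8, mlp_hidden=16,
                         d_value_total=16, d_qk_total=16, ffn_dim=32, head_hidden=8)
    return build_model(cfg, seed=3)


class TestAttribution:
    def test_constant_output_model_attributes_zero(self, small_model):
        # zero the head weights: the output no longer depends on the input
        for name in ("head_left.w1", "head_left.w2", "head_right.w1", "head_right.w2"):
            small_model.params[name].data[:] = 0.0
        rng = np.random.default_rng(0)
        track = attribute(small_model, random_seq(rng, 80), random_seq(rng, 80),
                          n_references=3, seed=1)
        assert np.abs(track.left).max() < 1e-12
        assert np.abs(track.right).max() < 1e-12

    def test_shape_matches_input(self, small_model):
        rng = np.random.default_rng(1)
        track = attribute(small_model, random_seq(rng, 80), random_seq(rng, 80),
                          n_references=2, seed=1)
        assert track.left.shape == (80, 4)
        assert track.right.shape == (80, 4)
        assert track.importance("left").shape == (80,)

    def test_deterministic_given_seed(self, small_model):
        rng = np.random.default_rng(2)
        l, r = random_seq(rng, 80), random_seq(rng, 80)
        a = attribute(small_model, l, r, n_references=2, seed=9)
        b = attribute(small_model, l, r, n_references=2, seed=9)
        np.testing.assert_array_equal(a.left, b.left)


class TestAttributionToPwms:
    def _track(self, importance_left):
        from etnet.interpret import AttributionTrack
        L = len(importance_left)
        seq = "A" * L
        mat = np.zeros((L, 4))
        mat[:, 0] = importance_left  # importance lands on the observed base A
        return AttributionTrack(left=mat, right=np.zeros((L, 4)),
                                left_sequence=seq, right_sequence=seq,
                                n_references=1, seed=0)

    def test_concentrated_importance_yields_one_pwm(self):
        imp = np.zeros(60)
        imp[20:28] = 5.0
        pwms = attribution_to_pwms([self._track(imp)], window=8, quantile=0.9)
        assert len(pwms) == 1
        assert "left" in pwms[0].name
        np.testing.assert_allclose(pwms[0].matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_uniform_track_gives_empty_list(self):
        pwms = attribution_to_pwms([self._track(np.ones(60))], window=8, quantile=0.5)
        assert pwms == []


class TestMotifMatching:
    def test_self_match_similarity_one(self):
        m = PwmMotif.from_consensus("TGACGTCA", "SELF", pseudo=0.1)
        matches, counts = match_motifs([m], [m], threshold=0.8)
        assert len(matches) == 1
        assert matches[0].similarity == pytest.approx(1.0)
        assert counts["SELF"] == 1

    def test_complementary_onehot_orthogonal(self):
        a = PwmMotif.from_consensus("AAAA", "polyA")
        t = PwmMotif.from_consensus("TTTT", "polyT")
        assert pwm_cosine(a.matrix, t.matrix) == pytest.approx(0.0)
        matches, counts = match_motifs([a], [t], threshold=0.8)
        assert matches == [] and counts["polyT"] == 0

    def test_reverse_orientation_flag(self):
        fwd = PwmMotif.from_consensus("AACG", "q")
        rc = PwmMotif.from_consensus("CGTT", "db_rc")
        assert match_motifs([fwd], [rc], threshold=0.9)[0] == []
        matches, _ = match_motifs([fwd], [rc], threshold=0.9, both_orientations=True)
        assert matches[0].similarity == pytest.approx(1.0)

    def test_empty_database_errors(self):
        with pytest.raises(ValueError):
            match_motifs([PwmMotif.from_consensus("ACGT", "q")], [])

    def test_meme_output_round_trip(self, tmp_path):
        db = [PwmMotif.from_consensus("TGACGTCA", "M1", pseudo=0.1),
              PwmMotif.from_consensus("GGGGCCCC", "M2", pseudo=0.1)]
        counts = {"M1": 7, "M2": 0}
        path = tmp_path / "matched.meme"
        write_matched_meme(db, counts, path)
        back = read_meme(path)
        assert [m.name for m in back] == ["M1"]
        assert back[0].nsites == 7
        np.testing.assert_allclose(back[0].matrix, db[0].matrix, atol=1e-5)


class TestSnpDelta:
    def _setup(self, small_model):
        rng = np.random.default_rng(7)
        genome = Genome({"chr1": random_seq(rng, 3000)})
        partners = [GenomicRegion("chr1", 2000, 2300, id="P1"),
                    GenomicRegion("chr1", 2400, 2700, id="P2")]
        return genome, partners

    def test_alt_equal_ref_gives_zero_delta(self, small_model):
        genome, partners = self._setup(small_model)
        pos = 500
        ref = genome.fetch("chr1", pos, pos + 1)
        report = snp_delta(small_model, genome, ("chr1", pos, ref, ref), partners, flank=30)
        assert all(e.delta == 0.0 for e in report.effects)
        assert report.mean_abs_delta_percent == 0.0

    def test_ref_mismatch_names_observed_base(self, small_model):
        genome, partners = self._setup(small_model)
        pos = 500
        observed = genome.fetch("chr1", pos, pos + 1)
        wrong = "A" if observed != "A" else "C"
        with pytest.raises(ValueError, match=observed):
            snp_delta(small_model, genome, ("chr1", pos, wrong, "G"), partners, flank=30)

    def test_invalid_alt_rejected(self, small_model):
        genome, partners = self._setup(small_model)
        with pytest.raises(ValueError, match="alt"):
            snp_delta(small_model, genome, ("chr1", 500, "A", "X"), partners, flank=30)

    def test_deterministic(self, small_model):
        genome, partners = self._setup(small_model)
        pos = 500
        ref = genome.fetch("chr1", pos, pos + 1)
        alt = "A" if ref != "A" else "C"
        r1 = snp_delta(small_model, genome, ("chr1", pos, ref, alt), partners, flank=30)
        r2 = snp_delta(small_model, genome, ("chr1", pos, ref, alt), partners, flank=30)
        assert [e.delta for e in r1.effects] == [e.delta for e in r2.effects]
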