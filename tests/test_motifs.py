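"""PSSM construction, scanning and split-motif assembly."""

import math

import numpy as np
import pytest

import calmscape as cs
from calmscape.alphabet import AA_INDEX
from helpers import split_motif_recovery


@pytest.fixture
def toy_split_model():
    """Segments with consensus WWWW / HHHH / KKKK, spacers (3,3) and (7,7)."""
    segs = [cs.build_pssm([c * 4] * 3) for c in "WHK"]
    return cs.SplitMotifModel(segments=segs, spacer_ranges=[(3, 3), (7, 7)])


class TestBuildPssm:
    def test_two_instance_hand_value(self):
        # ("A","A"), q=1, uniform background:
        # score(A) = log2((2 + 0.05) / (3 * 0.05)) = log2(13.666...)
        pssm = cs.build_pssm(["A", "A"])
        assert pssm.log_odds[0, AA_INDEX["A"]] == pytest.approx(
            math.log2(2.05 / 0.15), abs=1e-12)
        assert pssm.log_odds[0, AA_INDEX["A"]] == pytest.approx(3.773, abs=5e-4)

    def test_identical_instances_consensus_positive_others_negative(self):
        pssm = cs.build_pssm(["ACD", "ACD", "ACD"])
        assert pssm.consensus() == "ACD"
        for c, aa in enumerate("ACD"):
            scores = pssm.log_odds[c]
            assert scores[AA_INDEX[aa]] > 0
            off = np.delete(scores, AA_INDEX[aa])
            assert np.all(off < 0)

    def test_observed_weighted_mean_score_non_negative(self):
        # KL non-negativity: averaging each column's scores under the
        # observed column frequencies gives a relative entropy >= 0
        rng = np.random.default_rng(17)
        instances = ["".join(rng.choice(list(cs.AA_ORDER), size=6))
                     for _ in range(10)]
        pssm = cs.build_pssm(instances)
        for c in range(pssm.width):
            freqs = np.zeros(20)
            for inst in instances:
                freqs[AA_INDEX[inst[c]]] += 1 / len(instances)
            assert float(freqs @ pssm.log_odds[c]) >= -1e-9

    @pytest.mark.parametrize("bad", [["AC"], ["AC", "ACD"], ["A-", "AC"]])
    def test_invalid_seeds_rejected(self, bad):
        with pytest.raises(cs.MotifInputError):
            cs.build_pssm(bad)


class TestScan:
    def test_exact_consensus_found_at_planted_offset(self):
        pssm = cs.build_pssm(["WHKY", "WHKY", "WHKY"])
        seq = "A" * 10 + "WHKY" + "A" * 10
        hits = cs.scan(pssm, seq, score_threshold=pssm.max_score - 1e-9)
        assert len(hits) == 1
        assert hits[0].offsets == [10]
        assert hits[0].score == pytest.approx(pssm.max_score)

    def test_threshold_above_max_gives_no_hits(self):
        pssm = cs.build_pssm(["WHKY", "WHKY"])
        hits = cs.scan(pssm, "WHKY" * 5, score_threshold=pssm.max_score + 1.0)
        assert hits == []

    def test_sequence_shorter_than_width_empty(self):
        pssm = cs.build_pssm(["WHKY", "WHKY"])
        assert cs.scan(pssm, "WH", score_threshold=-100.0) == []

    def test_x_positions_score_zero(self):
        pssm = cs.build_pssm(["WW", "WW"])
        full = pssm.score_window("WW")
        half = pssm.score_window("WX")
        assert half == pytest.approx(full / 2)

    def test_overlap_pruning_prefers_best_then_leftmost(self):
        pssm = cs.build_pssm(["WW", "WW"])
        hits = cs.scan(pssm, "WWW", score_threshold=0.0)
        assert len(hits) == 1 and hits[0].offsets == [0]

    def test_shift_equivariance(self):
        pssm = cs.build_pssm(["WHKY", "WHKY"])
        seq = "GGGGWHKYGGGG"
        base = cs.scan(pssm, seq, 0.5 * pssm.max_score)
        for k in (1, 5, 17):
            shifted = cs.scan(pssm, "G" * k + seq, 0.5 * pssm.max_score)
            assert [h.offsets[0] for h in shifted] == \
                [h.offsets[0] + k for h in base]

    def test_threshold_monotonicity(self):
        pssm = cs.build_pssm(["WHKY", "WHKA", "WHKY"])
        seq = "WHKY" + "G" * 5 + "WHKA" + "G" * 5 + "WAKA"
        counts = [len(cs.scan(pssm, seq, thr))
                  for thr in np.linspace(0, pssm.max_score, 12)]
        assert counts == sorted(counts, reverse=True)


class TestScanSplit:
    def test_planted_triple_with_exact_spacers(self, toy_split_model):
        seq = "G" * 5 + "WWWW" + "AAA" + "HHHH" + "CCCCCCC" + "KKKK" + "G" * 5
        hits = cs.scan_split(toy_split_model, seq)
        assert len(hits) == 1
        assert hits[0].offsets == [5, 12, 23]
        assert hits[0].spacers == [3, 7]
        assert hits[0].score == pytest.approx(
            sum(h for h in hits[0].segment_scores))

    def test_spacer_outside_range_blocks_assembly(self, toy_split_model):
        # spacer1 = 4 violates the (3,3) gate although all segments match
        # exactly (thresholds demand full-score segment matches)
        seq = "G" * 5 + "WWWW" + "AAAA" + "HHHH" + "CCCCCCC" + "KKKK"
        exact = [p.max_score - 1e-9 for p in toy_split_model.segments]
        assert cs.scan_split(toy_split_model, seq, exact) == []
        for pssm, off in zip(toy_split_model.segments, (5, 13, 24)):
            assert cs.scan(pssm, seq, pssm.max_score - 1e-9) != []

    def test_five_planted_copies_all_recovered(self, toy_split_model):
        unit = "WWWW" + "AAA" + "HHHH" + "CCCCCCC" + "KKKK" + "GG"
        seq = unit * 5
        hits = cs.scan_split(toy_split_model, seq)
        assert len(hits) == 5
        assert [h.offsets[0] for h in hits] == [i * len(unit)
                                                for i in range(5)]

    def test_spacer_range_validation(self):
        segs = [cs.build_pssm(["AA", "AA"])] * 3
        with pytest.raises(cs.MotifInputError):
            cs.SplitMotifModel(segments=segs, spacer_ranges=[(5, 2), (0, 1)])


class TestRepeatArchitecture:
    widths = [4, 4, 4]

    def hit(self, start):
        return cs.MotifHit(sequence_id="s", offsets=[start, start + 7,
                                                     start + 14],
                           spacers=[3, 3], score=10.0)

    def test_no_hits_empty_architecture(self):
        arch = cs.repeat_architecture([], 100, self.widths)
        assert arch["architecture"] == "" and arch["n_copies"] == 0

    def test_three_copies_one_based_spans(self):
        hits = [self.hit(0), self.hit(30), self.hit(60)]
        arch = cs.repeat_architecture(hits, 100, self.widths)
        assert arch["architecture"] == "CALM×3"
        assert arch["spans"] == [(1, 18), (31, 48), (61, 78)]

    def test_out_of_order_hits_sorted(self):
        arch = cs.repeat_architecture([self.hit(30), self.hit(0)], 100,
                                      self.widths)
        assert arch["spans"][0] == (1, 18)

    def test_overlapping_hits_rejected(self):
        with pytest.raises(RuntimeError, match="overlap"):
            cs.repeat_architecture([self.hit(0), self.hit(10)], 100,
                                   self.widths)


class TestModelPersistence:
    def test_pssm_round_trip(self, tmp_path):
        pssm = cs.build_pssm(["WHKY", "WHKA"])
        path = tmp_path / "m.json"
        cs.save_model(pssm, path)
        back = cs.load_model(path)
        np.testing.assert_allclose(back.log_odds, pssm.log_odds)

    def test_split_model_round_trip(self, toy_split_model, tmp_path):
        path = tmp_path / "m.json"
        cs.save_model(toy_split_model, path)
        back = cs.load_model(path)
        assert back.spacer_ranges == toy_split_model.spacer_ranges
        seq = "WWWW" + "AAA" + "HHHH" + "CCCCCCC" + "KKKK"
        assert [h.offsets for h in cs.scan_split(back, seq)] == \
            [h.offsets for h in cs.scan_split(toy_split_model, seq)]


class TestSyntheticRecovery:
    def test_planted_copies_recovered_without_false_positives(self):
        recovery, n_fp, n_truth = split_motif_recovery(seed=1, copies=3,
                                                       conservation=0.9)
        assert n_truth == 30
        assert recovery >= 0.9
        assert n_fp == 0

    def test_recovery_non_decreasing_in_conservation(self):
        rates = [split_motif_recovery(seed=4, copies=3, conservation=c)[0]
                 for c in (0.6, 0.8, 1.0)]
        assert rates[0] <= rates[1] + 0.05 <= rates[2] + 0.1

    def test_full_conservation_perfect_recovery(self):
        recovery, n_fp, _ = split_motif_recovery(seed=2, copies=5,
                                                 conservation=1.0)
        assert recovery == 1.0 and n_fp == 0
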