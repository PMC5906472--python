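import math
import re

import numpy as np
import pytest

from denovoprom._util import BASES, revcomp
from denovoprom.io_formats import NucSequence
from denovoprom.promoter_model import (
    CoreMotifCriterion,
    PromoterHit,
    PromoterModel,
    batch_core_min_mismatch,
    best_window_score,
    build_pwm,
    calibrate_threshold,
    core_motif_hits,
    count_mismatches_to_core,
    default_pwm,
)
from denovoprom._util import encode

from conftest import naive_best_window, random_bases

CORE_RE = re.compile(r"(?=TTG.{18,22}TA.{3}T)")

TOY_WINDOWS = [
    ("TTGACA", 17, "TATAAT"),
    ("TTGACA", 17, "TATAAT"),
    ("TTGACA", 16, "TATAAT"),
    ("TTGACT", 17, "TACAAT"),
    ("TTGATA", 18, "TATACT"),
    ("TAGACA", 17, "TATAAT"),
    ("TTGCCA", 17, "CATAAT"),
    ("TTGACA", 15, "TATAAT"),
    ("TTGACA", 19, "TATGAT"),
    ("CTGACA", 17, "TATAAT"),
]


class TestBuildPwm:
    def test_weights_match_hand_computed_logodds(self):
        """Spreadsheet-style recomputation of the log-odds on a 10-window toy."""
        pc = 0.5
        model = build_pwm(TOY_WINDOWS, pseudocount=pc)
        n = len(TOY_WINDOWS)
        for pos in range(6):
            for bi, base in enumerate(BASES):
                c35 = sum(1 for w in TOY_WINDOWS if w[0][pos] == base)
                c10 = sum(1 for w in TOY_WINDOWS if w[2][pos] == base)
                assert model.w35[pos, bi] == pytest.approx(
                    math.log2(((c35 + pc) / (n + 4 * pc)) / 0.25)
                )
                assert model.w10[pos, bi] == pytest.approx(
                    math.log2(((c10 + pc) / (n + 4 * pc)) / 0.25)
                )
        for sp in range(15, 20):
            c = sum(1 for w in TOY_WINDOWS if w[1] == sp)
            assert model.spacer_weight[sp] == pytest.approx(
                math.log2(((c + pc) / (n + 5 * pc)) / (1 / 5))
            )

    def test_consensus_training_set_recovers_consensus(self):
        model = build_pwm([("TTGACA", 17, "TATAAT")] * 3)
        assert model.consensus == ("TTGACA", "TATAAT")
        assert max(model.spacer_weight, key=model.spacer_weight.get) == 17

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([("TTGACA", 17, "TATAAT")])

    def test_training_spacer_outside_range_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([("TTGACA", 25, "TATAAT")] * 3)


class TestCalibration:
    @pytest.mark.parametrize("n_cal", [5, 4])
    def test_threshold_is_median_of_independent_scores(self, rng, n_cal):
        model = build_pwm(TOY_WINDOWS)
        seqs = [NucSequence(f"c{i}", random_bases(rng, 60)) for i in range(n_cal)]
        calibrated = calibrate_threshold(model, seqs)
        oracle = sorted(naive_best_window(model, s.bases)[0] for s in seqs)
        mid = len(oracle) // 2
        expected = oracle[mid] if n_cal % 2 else (oracle[mid - 1] + oracle[mid]) / 2
        assert calibrated.threshold == pytest.approx(expected)

    def test_short_calibration_sequence_named(self):
        model = build_pwm(TOY_WINDOWS)
        with pytest.raises(ValueError, match="shorty"):
            calibrate_threshold(model, [NucSequence("shorty", "ACGTACGT")])


class TestBestWindowScore:
    def test_embedded_consensus_found_at_offset(self, rng):
        model = build_pwm(TOY_WINDOWS)
        window = "TTGACA" + random_bases(rng, 17) + "TATAAT"
        bases = "C" * 20 + window + "C" * 20
        score, hit = best_window_score(model, NucSequence("x", bases))
        assert (hit.pos35, hit.spacer) == (20, 17)
        assert hit.pos10 == 20 + 6 + 17
        # element scores are maximal; total is max only up to flank chance
        assert score >= model.w35.max(axis=1).sum() + model.w10.max(axis=1).sum() \
            + model.spacer_weight[17] - 1e-9

    def test_polyA_ties_break_leftmost_optimal_spacer(self):
        model = build_pwm(TOY_WINDOWS)
        score, hit = best_window_score(model, NucSequence("a", "A" * 103))
        assert hit.pos35 == 0
        assert hit.spacer == 17  # spacer weight peaks at 17, breaking the tie
        assert np.isfinite(score)

    def test_matches_bruteforce_placement_oracle(self, rng):
        model = build_pwm(TOY_WINDOWS)
        for _ in range(50):
            bases = random_bases(rng, 30)
            score, hit = best_window_score(model, NucSequence("x", bases))
            o_score, o_pos35, o_sp, _ = naive_best_window(model, bases)
            assert score == pytest.approx(o_score)
            assert (hit.pos35, hit.spacer) == (o_pos35, o_sp)

    def test_reverse_complement_strand_symmetry(self, rng):
        model = build_pwm(TOY_WINDOWS)
        for _ in range(20):
            bases = random_bases(rng, 60)
            s_minus, _ = best_window_score(model, NucSequence("x", bases), strands=("-",))
            s_plus_rc, _ = best_window_score(
                model, NucSequence("x", revcomp(bases)), strands=("+",)
            )
            assert s_minus == pytest.approx(s_plus_rc)

    def test_consensus_substitution_never_decreases_score(self, rng):
        model = build_pwm(TOY_WINDOWS)
        hex35, hex10 = model.consensus
        for _ in range(20):
            bases = random_bases(rng, 50)
            score, hit = best_window_score(model, NucSequence("x", bases))
            for start, cons in ((hit.pos35, hex35), (hit.pos10, hex10)):
                for j in range(6):
                    mutated = bases[: start + j] + cons[j] + bases[start + j + 1 :]
                    s2, _ = best_window_score(model, NucSequence("x", mutated))
                    assert s2 >= score - 1e-9

    def test_too_short_sequence_rejected(self):
        model = build_pwm(TOY_WINDOWS)
        with pytest.raises(ValueError):
            best_window_score(model, NucSequence("x", "ACGT"))


class TestCoreMotif:
    def test_planted_core_found(self, rng):
        crit = CoreMotifCriterion()
        bases = "C" * 10 + "TTGAAA" + "C" * 16 + "TAGGGT" + "C" * 10
        hits = core_motif_hits(crit, NucSequence("x", bases))
        assert len(hits) == 1
        assert (hits[0].pos35, hits[0].spacer, hits[0].pos10) == (10, 16, 32)

    def test_polyC_has_no_hits(self):
        assert core_motif_hits(CoreMotifCriterion(), NucSequence("x", "C" * 103)) == []

    def test_hit_presence_matches_regex_matcher(self, rng):
        """Independent regex-style matcher agrees sequence-by-sequence."""
        crit = CoreMotifCriterion()
        for _ in range(2000):
            bases = random_bases(rng, 50)
            mine = bool(core_motif_hits(crit, NucSequence("x", bases)))
            assert mine == bool(CORE_RE.search(bases))

    def test_hits_equal_zero_mismatch_placements(self, rng):
        crit = CoreMotifCriterion()
        for _ in range(50):
            bases = random_bases(rng, 60)
            hits = {(h.pos35, h.spacer) for h in core_motif_hits(crit, NucSequence("x", bases))}
            mm, best = count_mismatches_to_core(crit, NucSequence("x", bases))
            if hits:
                assert mm == 0
                assert (best.pos35, best.spacer) == min(hits)
            else:
                assert mm > 0


class TestMismatchCount:
    def test_exact_match_is_zero(self):
        crit = CoreMotifCriterion()
        bases = "C" * 5 + "TTGACA" + "A" * 17 + "TATAAT" + "C" * 5
        assert count_mismatches_to_core(crit, NucSequence("x", bases))[0] == 0

    def test_single_corrupted_core_base_is_one(self):
        crit = CoreMotifCriterion()
        bases = "C" * 5 + "TTCACA" + "C" * 17 + "TATAAT" + "C" * 5
        mm, hit = count_mismatches_to_core(crit, NucSequence("x", bases))
        assert mm == 1
        assert (hit.pos35, hit.spacer) == (5, 17)

    def test_matches_bruteforce_over_all_placements(self, rng):
        crit = CoreMotifCriterion()
        fixed35 = [(0, "T"), (1, "T"), (2, "G")]
        fixed10 = [(0, "T"), (1, "A"), (5, "T")]
        for _ in range(100):
            bases = random_bases(rng, 40)
            best = 12
            for pos35 in range(len(bases)):
                for sp in range(15, 20):
                    pos10 = pos35 + 6 + sp
                    if pos10 + 6 > len(bases):
                        continue
                    mm = sum(bases[pos35 + o] != b for o, b in fixed35)
                    mm += sum(bases[pos10 + o] != b for o, b in fixed10)
                    best = min(best, mm)
            assert count_mismatches_to_core(crit, NucSequence("x", bases))[0] == best

    def test_batch_scan_agrees_with_scalar_scan(self, rng):
        crit = CoreMotifCriterion()
        seqs = [random_bases(rng, 45) for _ in range(200)]
        batch = batch_core_min_mismatch(np.stack([encode(s) for s in seqs]), crit)
        for s, b in zip(seqs, batch):
            assert count_mismatches_to_core(crit, NucSequence("x", s))[0] == b


class TestModelSerialization:
    def test_json_roundtrip(self, tmp_path, model):
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PromoterModel.from_json(path)
        assert np.allclose(back.w35, model.w35)
        assert np.allclose(back.w10, model.w10)
        assert back.spacer_weight == pytest.approx(model.spacer_weight)
        assert back.threshold == pytest.approx(model.threshold)


def test_default_pwm_is_canonical_and_calibratable(model):
    raw = default_pwm()
    assert raw.consensus == ("TTGACA", "TATAAT")
    assert raw.threshold is None
    assert model.threshold is not None
    assert 0 < model.threshold < model.max_score


def test_promoter_hit_geometry_enforced():
    with pytest.raises(ValueError):
        PromoterHit(strand="+", pos35=0, pos10=10, spacer=17)
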