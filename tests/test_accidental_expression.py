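import math

import numpy as np
import pytest
from scipy import stats

from denovoprom._util import revcomp
from denovoprom.accidental_expression import (
    NullEnsemble,
    RankResult,
    build_null_ensemble,
    decile_histogram,
    group_ks,
    paired_sign_test,
    rank_gene,
    score_gene,
)
from denovoprom.io_formats import NucSequence
from denovoprom.promoter_model import default_pwm

from conftest import random_bases


def _consensus_cassette(rng, spacer=17):
    return "TTGACA" + random_bases(rng, spacer) + "TATAAT"


@pytest.fixture(scope="module")
def strict_model():
    """Sharp model: only near-maximal windows pass, so planted-site
    arithmetic is exact against a silent background."""
    from denovoprom.pipeline import default_model

    m = default_model(seed=0)
    return m.with_threshold(m.max_score - 3.0)


class TestScoreGene:
    def test_uncalibrated_model_rejected(self):
        with pytest.raises(ValueError):
            score_gene(NucSequence("g", "A" * 120), default_pwm())

    def test_silent_background_scores_zero(self, strict_model):
        res = score_gene(NucSequence("g", "AC" * 500), strict_model)
        assert res.total_per_kb == 0.0
        assert res.hits == ()

    def test_single_planted_hit_arithmetic(self, strict_model, rng):
        """One planted consensus promoter in a 1000-nt silent background:
        total == (s35 + s10) * (1 + total_score - threshold), antisense 0."""
        cassette = _consensus_cassette(rng)
        bases = "AC" * 100 + cassette + "AC" * ((1000 - 200 - len(cassette)) // 2)
        bases = bases.ljust(1000, "A")[:1000]
        res = score_gene(NucSequence("g", bases), strict_model)
        sense_hits = [h for h in res.hits if h.strand == "+"]
        assert len(sense_hits) == 1
        h = sense_hits[0]
        assert (h.pos35, h.spacer) == (200, 17)
        expected = (h.s35 + h.s10) * (1.0 + h.total - strict_model.threshold)
        assert res.sense_per_kb == pytest.approx(expected * 1000 / 1000)
        assert res.antisense_per_kb == 0.0
        assert res.total_per_kb == pytest.approx(res.sense_per_kb)

    def test_two_distant_promoters_add_up(self, strict_model, rng):
        """Well-separated planted sites contribute additively."""
        background = "AC" * 1000
        c1, c2 = _consensus_cassette(rng), _consensus_cassette(rng)

        def plant(bg, pos_cassettes):
            b = list(bg)
            for pos, c in pos_cassettes:
                b[pos : pos + len(c)] = c
            return NucSequence("g", "".join(b))

        s_a = score_gene(plant(background, [(100, c1)]), strict_model).total_per_kb
        s_b = score_gene(plant(background, [(1200, c2)]), strict_model).total_per_kb
        s_ab = score_gene(plant(background, [(100, c1), (1200, c2)]), strict_model).total_per_kb
        assert s_ab == pytest.approx(s_a + s_b)

    def test_reverse_complement_antisymmetry(self, model, rng):
        for _ in range(10):
            bases = random_bases(rng, 300)
            fwd = score_gene(NucSequence("g", bases), model)
            rev = score_gene(NucSequence("g", revcomp(bases)), model)
            assert fwd.sense_per_kb == pytest.approx(rev.antisense_per_kb)
            assert fwd.antisense_per_kb == pytest.approx(rev.sense_per_kb)
            assert fwd.total_per_kb == pytest.approx(rev.total_per_kb)

    def test_nms_suppresses_overlapping_calls(self, strict_model, rng):
        """A single planted site yields exactly one retained sense hit even
        though adjacent spacer placements may also clear the threshold."""
        cassette = _consensus_cassette(rng)
        bases = "AC" * 50 + cassette + "AC" * 50
        res = score_gene(NucSequence("g", bases), strict_model)
        sense = [h for h in res.hits if h.strand == "+"]
        assert len(sense) == 1


class TestRankGene:
    def _ens(self, wt, nulls):
        return NullEnsemble(gene_id="g", mode="usage", null_scores=tuple(nulls), wt_score=wt)

    def test_wt_below_all_nulls(self):
        r = rank_gene(self._ens(0.0, [1.0 + i for i in range(1000)]))
        assert (r.percentile, r.decile) == (0.0, 1)

    def test_wt_above_all_nulls(self):
        r = rank_gene(self._ens(5000.0, [1.0 + i for i in range(1000)]))
        assert (r.percentile, r.decile) == (1.0, 10)

    def test_all_tied_scores_mid_rank(self):
        r = rank_gene(self._ens(0.0, [0.0] * 1000))
        assert r.percentile == pytest.approx(0.5)
        assert r.decile == 6

    def test_small_ensemble_has_no_decile(self):
        r = rank_gene(self._ens(1.0, [0.0, 2.0]))
        assert r.decile is None
        assert r.percentile == pytest.approx(0.5)

    def test_percentile_invariant_under_monotone_transform(self, rng):
        nulls = list(rng.normal(size=100))
        wt = float(rng.normal())
        base = rank_gene(self._ens(wt, nulls)).percentile
        trans = rank_gene(self._ens(math.exp(wt), [math.exp(x) for x in nulls])).percentile
        assert trans == pytest.approx(base)


class TestDecileHistogram:
    def _ranks(self, deciles):
        return [
            RankResult(gene_id=f"g{i}", percentile=(d - 0.5) / 10, decile=d)
            for i, d in enumerate(deciles)
        ]

    def test_all_first_decile(self):
        hist = decile_histogram(self._ranks([1] * 7))
        assert hist.loc[hist["decile"] == 1, "percentage"].item() == 100.0
        assert hist["percentage"].sum() == pytest.approx(100.0)

    def test_uniform_ranks_are_flat(self):
        hist = decile_histogram(self._ranks(list(range(1, 11)) * 5))
        assert (hist["percentage"] == 10.0).all()

    def test_subset_selection(self):
        ranks = self._ranks([1, 1, 10, 10])
        hist = decile_histogram(ranks, subset={"g0", "g1"})
        assert hist.loc[hist["decile"] == 1, "percentage"].item() == 100.0

    def test_empty_subset_named_in_error(self):
        with pytest.raises(ValueError, match="ghost"):
            decile_histogram(self._ranks([1, 2]), subset={"ghost"})


class TestGroupKs:
    def test_identical_samples(self):
        d, p = group_ks([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = group_ks([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert d == pytest.approx(1.0)

    def test_matches_bruteforce_ecdf_gap(self, rng):
        for _ in range(10):
            a = rng.normal(size=20)
            b = rng.normal(loc=0.5, size=20)
            d, _ = group_ks(a, b)
            grid = np.concatenate([a, b])
            gap = max(
                abs((a <= x).mean() - (b <= x).mean()) for x in grid
            )
            assert d == pytest.approx(gap)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            group_ks([1.0], [1.0, 2.0])


class TestPairedSignTest:
    def test_five_of_five(self):
        k, n, p = paired_sign_test([(2.0, 1.0)] * 5)
        assert (k, n) == (5, 5)
        assert p == pytest.approx(0.0625)

    def test_two_of_four_symmetric(self):
        pairs = [(2, 1), (2, 1), (1, 2), (1, 2)]
        assert paired_sign_test(pairs)[2] == pytest.approx(1.0)

    def test_ties_dropped(self):
        k, n, p = paired_sign_test([(1, 1), (2, 1), (2, 1), (2, 1), (2, 1), (2, 1)])
        assert (k, n) == (5, 5)
        assert p == pytest.approx(0.0625)

    def test_matches_exhaustive_enumeration(self):
        """k=16, n=20 against full 2^20 enumeration of equally likely
        outcomes (minimum-likelihood two-sided rule)."""
        k_obs, n = 16, 20
        from math import comb

        p_obs = comb(n, k_obs)
        total = sum(
            1 for outcome in range(2**n) if comb(n, outcome.bit_count()) <= p_obs
        )
        expected = total / 2**n
        pairs = [(2.0, 1.0)] * k_obs + [(1.0, 2.0)] * (n - k_obs)
        assert paired_sign_test(pairs)[2] == pytest.approx(expected)

    def test_agrees_with_scipy_binomtest(self):
        for k, n in [(5, 5), (16, 20), (12, 15), (7, 14)]:
            pairs = [(2.0, 1.0)] * k + [(1.0, 2.0)] * (n - k)
            mine = paired_sign_test(pairs)[2]
            ref = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
            assert mine == pytest.approx(ref)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            paired_sign_test([(1.0, 1.0), (2.0, 2.0)])


class TestBuildNullEnsemble:
    def test_scores_and_reproducibility(self, model, usage508):
        from denovoprom.synthetic_data import SyntheticGenomeSpec, synth_genome

        genes, _ = synth_genome(
            SyntheticGenomeSpec(n_genes=2, length_range=(80, 120), seed=17), usage508
        )
        ens = build_null_ensemble(genes[0], model, "usage", 15, usage=usage508, seed=4)
        again = build_null_ensemble(genes[0], model, "usage", 15, usage=usage508, seed=4)
        assert ens == again
        assert len(ens.null_scores) == 15
        assert ens.wt_score == score_gene(genes[0], model).total_per_kb
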