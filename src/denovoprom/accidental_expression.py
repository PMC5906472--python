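"""Accidental intragenic promoter scoring and null-ensemble ranking.

A gene's accidental-expression score sums, over every retained promoter
prediction inside its coding sequence (both orientations), the product of
the element scores and a discriminant-margin factor, normalized to the
gene length (predicted expression per kb):

    contribution = (s35 + s10) * (1 + total - threshold)
    score_per_kb = 1000 / L * sum(contributions)

The margin factor is a monotone surrogate for the linear-discriminant
confidence that promoter-prediction software reports for each call; only
comparative statistics (WT vs recoded nulls, group contrasts) are
meaningful, not absolute magnitudes. Overlapping predictions are collapsed
by non-maximum suppression so a single site is not double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, floor
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import encode, revcomp
from .io_formats import GeneRecord, NucSequence
from .promoter_model import (
    ELEMENT_LEN,
    PromoterHit,
    PromoterModel,
    _window_scores,
)
from .recoding_null import CodonUsageTable, make_ensemble

#: two retained hits on one strand must have -10 starts >= this far apart
NMS_RADIUS = 10


@dataclass(frozen=True)
class AccidentalExpressionScore:
    gene_id: str
    total_per_kb: float
    sense_per_kb: float
    antisense_per_kb: float
    hits: tuple[PromoterHit, ...]


@dataclass(frozen=True)
class NullEnsemble:
    gene_id: str
    mode: str
    null_scores: tuple[float, ...]
    wt_score: float

    def __post_init__(self) -> None:
        if len(self.null_scores) < 1:
            raise ValueError("ensemble must contain at least one null score")
        if not np.isfinite(list(self.null_scores) + [self.wt_score]).all():
            raise ValueError("scores must be finite")


@dataclass(frozen=True)
class RankResult:
    gene_id: str
    percentile: float
    decile: int | None


def _strand_hits(codes: np.ndarray, model: PromoterModel, strand: str) -> list[PromoterHit]:
    """All above-threshold placements on one strand, after NMS."""
    L = codes.size
    lo, hi = model.spacer_range
    s35 = _window_scores(codes, model.w35)
    s10 = _window_scores(codes, model.w10)
    cand: list[tuple] = []  # (total, pos10, pos35, spacer, s35, s10)
    for sp in range(lo, hi + 1):
        nplc = L - (2 * ELEMENT_LEN + sp) + 1
        if nplc < 1:
            continue
        tot = s35[:nplc] + s10[ELEMENT_LEN + sp : ELEMENT_LEN + sp + nplc] + model.spacer_weight[sp]
        for i in np.flatnonzero(tot >= model.threshold):
            i = int(i)
            p10 = i + ELEMENT_LEN + sp
            cand.append((float(tot[i]), p10, i, sp, float(s35[i]), float(s10[p10])))
    # non-maximum suppression: strongest first, leftmost on ties
    cand.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    kept: list[tuple] = []
    for c in cand:
        if all(abs(c[1] - k[1]) >= NMS_RADIUS for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: (c[2], c[3]))
    return [
        PromoterHit(
            strand=strand, pos35=c[2], pos10=c[1], spacer=c[3],
            s35=c[4], s10=c[5], total=c[0], margin=c[0] - model.threshold,
        )
        for c in kept
    ]


def score_gene(cds: NucSequence | GeneRecord, model: PromoterModel) -> AccidentalExpressionScore:
    """Accidental-expression score of one coding sequence under a calibrated model.

    Pure function of (cds bases, model): sense and antisense strands are
    scanned independently; ``sense_per_kb(cds) == antisense_per_kb(revcomp(cds))``.
    """
    if model.threshold is None:
        raise ValueError("model threshold is not calibrated")
    if isinstance(cds, GeneRecord):
        cds = cds.cds
    if len(cds) < model.min_window:
        raise ValueError(f"cds {cds.id!r} shorter than the minimal window")
    per_strand = {}
    all_hits: list[PromoterHit] = []
    for strand, bases in (("+", cds.bases), ("-", revcomp(cds.bases))):
        hits = _strand_hits(encode(bases), model, strand)
        contrib = sum(
            max(0.0, h.s35 + h.s10) * (1.0 + h.total - model.threshold) for h in hits
        )
        per_strand[strand] = contrib * 1000.0 / len(cds)
        all_hits.extend(hits)
    return AccidentalExpressionScore(
        gene_id=cds.id,
        total_per_kb=per_strand["+"] + per_strand["-"],
        sense_per_kb=per_strand["+"],
        antisense_per_kb=per_strand["-"],
        hits=tuple(all_hits),
    )


def build_null_ensemble(
    gene: GeneRecord | NucSequence,
    model: PromoterModel,
    mode: str,
    n: int,
    usage: CodonUsageTable | None = None,
    seed: int = 0,
) -> NullEnsemble:
    """Score a gene and n recoded/shuffled versions of it."""
    wt = score_gene(gene, model).total_per_kb
    nulls = tuple(
        score_gene(v, model).total_per_kb
        for v in make_ensemble(gene, mode, n, usage=usage, seed=seed)
    )
    gid = gene.gene_id if isinstance(gene, GeneRecord) else gene.id
    return NullEnsemble(gene_id=gid, mode=mode, null_scores=nulls, wt_score=wt)


def rank_gene(ensemble: NullEnsemble) -> RankResult:
    """Mid-rank percentile of the WT score in its null ensemble, plus decile.

    percentile = (#{null < wt} + 0.5 #{null == wt}) / N; low percentile
    means fewer predicted accidental promoters than the null. Deciles are
    reported only for N >= 10.
    """
    nulls = np.asarray(ensemble.null_scores)
    n = nulls.size
    below = int((nulls < ensemble.wt_score).sum())
    ties = int((nulls == ensemble.wt_score).sum())
    percentile = (below + 0.5 * ties) / n
    decile = min(10, floor(10 * percentile) + 1) if n >= 10 else None
    return RankResult(gene_id=ensemble.gene_id, percentile=percentile, decile=decile)


def decile_histogram(ranks: Sequence[RankResult], subset: set[str] | None = None):
    """Percentage of genes per decile (1..10); the neutral expectation is a
    flat 10% per decile."""
    import pandas as pd

    if not ranks:
        raise ValueError("no ranks to histogram")
    if subset is not None:
        sel = [r for r in ranks if r.gene_id in subset]
        if not sel:
            raise ValueError(f"subset matches no ranked genes: {sorted(subset)[:5]}")
    else:
        sel = list(ranks)
    missing = [r.gene_id for r in sel if r.decile is None]
    if missing:
        raise ValueError(f"genes without decile (ensemble too small): {missing[:5]}")
    n = len(sel)
    counts = {d: 0 for d in range(1, 11)}
    for r in sel:
        counts[r.decile] += 1
    return pd.DataFrame(
        {
            "decile": list(range(1, 11)),
            "count": [counts[d] for d in range(1, 11)],
            "percentage": [100.0 * counts[d] / n for d in range(1, 11)],
            "expected_percentage": [10.0] * 10,
        }
    )


def group_ks(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov D and asymptotic p-value."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must have size >= 2")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def paired_sign_test(pairs: Sequence[tuple[float, float]]) -> tuple[int, int, float]:
    """Exact two-sided sign test on paired scores.

    Ties are dropped; k = #{a > b} among the remaining n pairs; the
    p-value is the exact two-sided binomial probability at p0 = 1/2 by the
    minimum-likelihood rule (sum of the probabilities of all outcomes no
    more probable than the observed k).
    """
    kept = [(a, b) for a, b in pairs if a != b]
    if not kept:
        raise ValueError("all pairs are exactly tied")
    n = len(kept)
    k = sum(1 for a, b in kept if a > b)
    pmf = [comb(n, j) / 2.0**n for j in range(n + 1)]
    cutoff = pmf[k] * (1 + 1e-12)
    p = min(1.0, sum(q for q in pmf if q <= cutoff))
    return k, n, p
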