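"""σ70 promoter scoring.

Two criteria are provided:

* a position weight matrix (PWM) over the −35 and −10 hexamers with an
  additive spacer-length weight and a threshold calibrated as the median
  score of a constitutive-promoter set — windows scoring at or above the
  threshold qualify as promoters, and the amount by which a window clears
  the threshold (the ``margin``) serves as a discriminant-style confidence;
* the simpler core-motif criterion: an exact match to TTGnnn and TAnnnT
  (the most conserved bases of the −35/−10 consensus) at a valid spacer.

Positions are 0-based on the scanned strand; the spacer is the gap between
the end of the −35 hexamer and the start of the −10 hexamer, optimal at
17 nt. Tie-breaking is fully deterministic: smaller −35 position, then
smaller spacer, then the sense strand.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._util import BASE_INDEX, BASES, encode, revcomp
from .io_formats import NucSequence

ELEMENT_LEN = 6
DEFAULT_SPACER_RANGE = (15, 19)

#: scores closer than this are treated as tied, so the documented
#: tie-break (leftmost -35 start, then shortest spacer, then sense strand)
#: applies to mathematically equal placements regardless of float
#: summation order
TIE_EPS = 1e-9

CONSENSUS_35 = "TTGACA"
CONSENSUS_10 = "TATAAT"


@dataclass(frozen=True)
class PromoterHit:
    """One located promoter placement on the scanned strand."""

    strand: str
    pos35: int
    pos10: int
    spacer: int
    s35: float | None = None
    s10: float | None = None
    total: float | None = None
    margin: float = 0.0

    def __post_init__(self) -> None:
        if self.pos10 != self.pos35 + ELEMENT_LEN + self.spacer:
            raise ValueError("inconsistent hit geometry: pos10 != pos35 + 6 + spacer")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclass
class PromoterModel:
    """PWM model: 6x4 log-odds for each element plus spacer-length weights."""

    w35: np.ndarray
    w10: np.ndarray
    spacer_weight: dict[int, float]
    spacer_range: tuple[int, int] = DEFAULT_SPACER_RANGE
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.w35 = np.asarray(self.w35, dtype=float)
        self.w10 = np.asarray(self.w10, dtype=float)
        if self.w35.shape != (ELEMENT_LEN, 4) or self.w10.shape != (ELEMENT_LEN, 4):
            raise ValueError("element matrices must be 6x4")
        if not (np.isfinite(self.w35).all() and np.isfinite(self.w10).all()):
            raise ValueError("log-odds weights must be finite (use a pseudocount)")
        lo, hi = self.spacer_range
        for sp in range(lo, hi + 1):
            if sp not in self.spacer_weight:
                raise ValueError(f"spacer_weight missing length {sp}")
        best = max(self.spacer_weight, key=self.spacer_weight.get)
        if best != 17 and 17 in self.spacer_weight:
            raise ValueError("spacer_weight must peak at the optimal 17 nt")

    @property
    def min_window(self) -> int:
        return 2 * ELEMENT_LEN + self.spacer_range[0]

    @property
    def max_score(self) -> float:
        return (
            self.w35.max(axis=1).sum()
            + self.w10.max(axis=1).sum()
            + max(self.spacer_weight.values())
        )

    @property
    def consensus(self) -> tuple[str, str]:
        return (
            "".join(BASES[i] for i in self.w35.argmax(axis=1)),
            "".join(BASES[i] for i in self.w10.argmax(axis=1)),
        )

    def with_threshold(self, threshold: float) -> "PromoterModel":
        return PromoterModel(
            self.w35.copy(), self.w10.copy(), dict(self.spacer_weight),
            self.spacer_range, threshold,
        )

    def to_json(self, path=None) -> str:
        payload = {
            "w35": self.w35.tolist(),
            "w10": self.w10.tolist(),
            "spacer_weight": {str(k): v for k, v in self.spacer_weight.items()},
            "spacer_range": list(self.spacer_range),
            "threshold": self.threshold,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PromoterModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            w35=np.array(payload["w35"]),
            w10=np.array(payload["w10"]),
            spacer_weight={int(k): float(v) for k, v in payload["spacer_weight"].items()},
            spacer_range=tuple(payload["spacer_range"]),
            threshold=payload["threshold"],
        )


@dataclass(frozen=True)
class CoreMotifCriterion:
    """Exact-match criterion on the six most conserved promoter bases."""

    pattern35: str = "TTGnnn"
    pattern10: str = "TAnnnT"
    spacer_range: tuple[int, int] = DEFAULT_SPACER_RANGE

    def __post_init__(self) -> None:
        for pat in (self.pattern35, self.pattern10):
            if len(pat) != ELEMENT_LEN:
                raise ValueError("patterns must be hexamers")
            if set(pat.upper()) - (set(BASES) | {"N"}):
                raise ValueError(f"bad pattern {pat!r}")

    @property
    def min_window(self) -> int:
        return 2 * ELEMENT_LEN + self.spacer_range[0]

    @property
    def fixed35(self) -> tuple[tuple[int, int], ...]:
        return _fixed_positions(self.pattern35)

    @property
    def fixed10(self) -> tuple[tuple[int, int], ...]:
        return _fixed_positions(self.pattern10)


def _fixed_positions(pattern: str) -> tuple[tuple[int, int], ...]:
    return tuple(
        (i, BASE_INDEX[b]) for i, b in enumerate(pattern.upper()) if b != "N"
    )


# ---------------------------------------------------------------------------
# PWM construction and calibration
# ---------------------------------------------------------------------------

def build_pwm(
    windows: Sequence[tuple[str, int, str]],
    pseudocount: float = 0.5,
    spacer_range: tuple[int, int] = DEFAULT_SPACER_RANGE,
) -> PromoterModel:
    """Build an uncalibrated PWM from aligned training windows.

    Each window is a ``(hex35, spacer, hex10)`` triple. Log-odds are
    log2((count + pc) / (N + 4 pc) / 0.25) per base and position; the
    spacer weight is the log2 ratio of the pseudocount-smoothed empirical
    spacer-length frequency to a uniform distribution over spacer_range.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 training windows")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    lo, hi = spacer_range
    n = len(windows)
    counts35 = np.zeros((ELEMENT_LEN, 4))
    counts10 = np.zeros((ELEMENT_LEN, 4))
    spacer_counts = {sp: 0 for sp in range(lo, hi + 1)}
    for hex35, spacer, hex10 in windows:
        if len(hex35) != ELEMENT_LEN or len(hex10) != ELEMENT_LEN:
            raise ValueError("training elements must be hexamers")
        if not lo <= spacer <= hi:
            raise ValueError(f"training spacer {spacer} outside {spacer_range}")
        for i, b in enumerate(hex35.upper()):
            counts35[i, BASE_INDEX[b]] += 1
        for i, b in enumerate(hex10.upper()):
            counts10[i, BASE_INDEX[b]] += 1
        spacer_counts[spacer] += 1

    def _logodds(counts: np.ndarray) -> np.ndarray:
        freq = (counts + pseudocount) / (n + 4 * pseudocount)
        return np.log2(freq / 0.25)

    k = hi - lo + 1
    spacer_weight = {
        sp: math.log2(((spacer_counts[sp] + pseudocount) / (n + k * pseudocount)) / (1 / k))
        for sp in range(lo, hi + 1)
    }
    return PromoterModel(
        w35=_logodds(counts35),
        w10=_logodds(counts10),
        spacer_weight=spacer_weight,
        spacer_range=spacer_range,
    )


def calibrate_threshold(
    model: PromoterModel, calibration_set: Sequence[NucSequence]
) -> PromoterModel:
    """Set the threshold to the median best-window score of the calibration set.

    Mirrors benchmarking against constitutive promoters: a window qualifies
    as a promoter when it scores at least as well as the median constitutive
    promoter. Even-sized sets use the mean of the two central values.
    """
    if not calibration_set:
        raise ValueError("calibration set is empty")
    scores = []
    for seq in calibration_set:
        if len(seq) < model.min_window:
            raise ValueError(
                f"calibration sequence {seq.id!r} shorter than the minimal "
                f"window ({model.min_window} nt)"
            )
        scores.append(best_window_score(model, seq)[0])
    return model.with_threshold(float(np.median(scores)))


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _window_scores(codes: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-start hexamer PWM sums for one strand; length len(codes)-5."""
    if codes.size < ELEMENT_LEN:
        return np.empty(0)
    win = sliding_window_view(codes, ELEMENT_LEN)
    return w[np.arange(ELEMENT_LEN)[None, :], win].sum(axis=1)


def _iter_strand_codes(seq: NucSequence, strands: Iterable[str]):
    order = [s for s in ("+", "-") if s in set(strands)]
    if not order:
        raise ValueError("strands must contain '+' and/or '-'")
    for strand in order:
        bases = seq.bases if strand == "+" else revcomp(seq.bases)
        yield strand, encode(bases)


def best_window_score(
    model: PromoterModel, seq: NucSequence, strands: Iterable[str] = ("+",)
) -> tuple[float, PromoterHit]:
    """Maximal s35 + s10 + spacer_weight over all placements on the
    requested strands, with deterministic tie-breaking."""
    L = len(seq)
    if L < model.min_window:
        raise ValueError(f"sequence {seq.id!r} shorter than {model.min_window} nt")
    lo, hi = model.spacer_range
    scans = []  # (rank, sp, tot, s35, s10, strand)
    top = -np.inf
    for strand, codes in _iter_strand_codes(seq, strands):
        s35 = _window_scores(codes, model.w35)
        s10 = _window_scores(codes, model.w10)
        rank = 0 if strand == "+" else 1
        for sp in range(lo, hi + 1):
            nplc = L - (2 * ELEMENT_LEN + sp) + 1
            if nplc < 1:
                continue
            tot = s35[:nplc] + s10[ELEMENT_LEN + sp : ELEMENT_LEN + sp + nplc]
            tot = tot + model.spacer_weight[sp]
            scans.append((rank, sp, tot, s35, s10, strand))
            top = max(top, float(tot.max()))
    best = None  # (pos35, spacer, rank) minimized among near-ties
    for rank, sp, tot, s35, s10, strand in scans:
        for i in np.flatnonzero(tot >= top - TIE_EPS):
            i = int(i)
            key = (i, sp, rank)
            if best is None or key < best[0]:
                best = (
                    key, float(tot[i]), i, sp,
                    float(s35[i]), float(s10[i + ELEMENT_LEN + sp]), strand,
                )
    _, score, pos35, sp, v35, v10, strand = best
    margin = max(0.0, score - model.threshold) if model.threshold is not None else 0.0
    hit = PromoterHit(
        strand=strand, pos35=pos35, pos10=pos35 + ELEMENT_LEN + sp, spacer=sp,
        s35=v35, s10=v10, total=score, margin=margin,
    )
    return score, hit


def _pattern_match_counts(codes: np.ndarray, fixed) -> np.ndarray:
    """Number of fixed-base mismatches of a pattern at every window start."""
    if codes.size < ELEMENT_LEN:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(codes, ELEMENT_LEN)
    mm = np.zeros(win.shape[0], dtype=np.int64)
    for off, base in fixed:
        mm += win[:, off] != base
    return mm


def core_motif_hits(
    criterion: CoreMotifCriterion, seq: NucSequence, strands: Iterable[str] = ("+",)
) -> list[PromoterHit]:
    """All exact core-motif placements with a valid spacer, ordered by
    (strand rank, pos35, spacer) with the sense strand first."""
    L = len(seq)
    if L < criterion.min_window:
        raise ValueError(f"sequence {seq.id!r} shorter than {criterion.min_window} nt")
    lo, hi = criterion.spacer_range
    hits: list[PromoterHit] = []
    for strand, codes in _iter_strand_codes(seq, strands):
        mm35 = _pattern_match_counts(codes, criterion.fixed35)
        mm10 = _pattern_match_counts(codes, criterion.fixed10)
        strand_hits = []
        for sp in range(lo, hi + 1):
            nplc = L - (2 * ELEMENT_LEN + sp) + 1
            if nplc < 1:
                continue
            good = np.flatnonzero(
                (mm35[:nplc] == 0) & (mm10[ELEMENT_LEN + sp : ELEMENT_LEN + sp + nplc] == 0)
            )
            for i in good:
                strand_hits.append(
                    PromoterHit(strand=strand, pos35=int(i),
                                pos10=int(i) + ELEMENT_LEN + sp, spacer=sp)
                )
        strand_hits.sort(key=lambda h: (h.pos35, h.spacer))
        hits.extend(strand_hits)
    return hits


def count_mismatches_to_core(
    criterion: CoreMotifCriterion, seq: NucSequence, strands: Iterable[str] = ("+",)
) -> tuple[int, PromoterHit]:
    """Minimum number of fixed-base mismatches over all placements, plus the
    best placement under the standard tie-break."""
    L = len(seq)
    if L < criterion.min_window:
        raise ValueError(f"sequence {seq.id!r} shorter than {criterion.min_window} nt")
    lo, hi = criterion.spacer_range
    best: tuple | None = None  # (mm, rank, pos35, spacer, strand)
    for strand, codes in _iter_strand_codes(seq, strands):
        mm35 = _pattern_match_counts(codes, criterion.fixed35)
        mm10 = _pattern_match_counts(codes, criterion.fixed10)
        rank = 0 if strand == "+" else 1
        for sp in range(lo, hi + 1):
            nplc = L - (2 * ELEMENT_LEN + sp) + 1
            if nplc < 1:
                continue
            mm = mm35[:nplc] + mm10[ELEMENT_LEN + sp : ELEMENT_LEN + sp + nplc]
            m = mm.min()
            i = int(np.flatnonzero(mm == m)[0])
            cand = (int(m), rank, i, sp, strand)
            if best is None or (cand[0], cand[2], cand[3], cand[1]) < (
                best[0], best[2], best[3], best[1]
            ):
                best = cand
    m, _, pos35, sp, strand = best
    hit = PromoterHit(strand=strand, pos35=pos35, pos10=pos35 + ELEMENT_LEN + sp, spacer=sp)
    return m, hit


def batch_core_min_mismatch(codes2d: np.ndarray, criterion: CoreMotifCriterion) -> np.ndarray:
    """Sense-strand minimum core mismatches for a (n_seqs, L) code matrix.

    Vectorized equivalent of count_mismatches_to_core restricted to '+';
    used for scanning tens of thousands of equal-length sequences at once.
    """
    nseq, L = codes2d.shape
    lo, hi = criterion.spacer_range
    if L < criterion.min_window:
        raise ValueError("sequences shorter than the minimal window")
    win = sliding_window_view(codes2d, ELEMENT_LEN, axis=1)  # (n, L-5, 6)
    mm35 = np.zeros(win.shape[:2], dtype=np.int64)
    mm10 = np.zeros(win.shape[:2], dtype=np.int64)
    for off, base in criterion.fixed35:
        mm35 += win[:, :, off] != base
    for off, base in criterion.fixed10:
        mm10 += win[:, :, off] != base
    best = np.full(nseq, np.iinfo(np.int64).max)
    for sp in range(lo, hi + 1):
        nplc = L - (2 * ELEMENT_LEN + sp) + 1
        if nplc < 1:
            continue
        mm = mm35[:, :nplc] + mm10[:, ELEMENT_LEN + sp : ELEMENT_LEN + sp + nplc]
        np.minimum(best, mm.min(axis=1), out=best)
    return best


# ---------------------------------------------------------------------------
# Default model
# ---------------------------------------------------------------------------

#: Packaged training alignment for the default PWM: 20 canonical-like
#: (hex35, spacer, hex10) windows. The column conservation follows the
#: σ70 literature — the core bases (TTG of the −35; T, A and the final T of
#: the −10) are nearly invariant, the remaining positions much less so, and
#: spacers concentrate on the optimal 17 nt. The alignment is synthetic
#: (written to encode those conservation levels, not copied from any
#: database) and is replaceable by a user-trained model.
DEFAULT_TRAINING_WINDOWS: tuple[tuple[str, int, str], ...] = (
    ("TTGACA", 17, "CATAAT"),
    ("TTGACA", 17, "TGTAAT"),
    ("TTGACA", 17, "TATAAA"),
    ("TTGACA", 17, "TATAAT"),
    ("TTGACA", 17, "TATAAT"),
    ("TTGACA", 17, "TATAAT"),
    ("TTGACA", 17, "TATAAT"),
    ("TTGACA", 17, "TATAAT"),
    ("TTGACA", 17, "TATAAT"),
    ("TTGACA", 17, "TATAAT"),
    ("TTGACT", 16, "TAAAAT"),
    ("TTGAAT", 16, "TAAATT"),
    ("TTGAAT", 16, "TAATTT"),
    ("TTGTAT", 16, "TAATTT"),
    ("TTGTAC", 18, "TACTTT"),
    ("TTGTTC", 18, "TACTGT"),
    ("TTTGTC", 18, "TACCGT"),
    ("TTAGTG", 18, "TAGCGT"),
    ("TAGCGG", 15, "TAGGCT"),
    ("CTGCGG", 19, "TAGGCT"),
)


def default_pwm() -> PromoterModel:
    """The packaged uncalibrated default model."""
    return build_pwm(DEFAULT_TRAINING_WINDOWS)
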