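"""In-silico mutational distance from a sequence to promoter activity.

Two notions of distance are computed, mirroring the two promoter criteria:

* ``core_distance`` — the exact minimal number of substitutions to an
  exact core-motif match. Because each fixed-base mismatch is repaired by
  exactly one substitution and placements are independent, the minimum
  mismatch count over all placements *is* the minimal distance.
* ``greedy_pwm_evolve`` — a greedy hill climb under the PWM criterion:
  at each step every single-base substitution is evaluated and the one
  giving the largest new best-window score is applied, until the score
  reaches the calibrated threshold (or a step cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import BASES
from .io_formats import NucSequence
from .promoter_model import (
    CoreMotifCriterion,
    PromoterModel,
    best_window_score,
    count_mismatches_to_core,
)

BINS = ("0", "1", ">=2")

#: scores closer than this are treated as tied when selecting a mutation,
#: so the leftmost-position / alphabetical-base tie-break is applied to
#: mathematically equal mutants regardless of float summation order
TIE_EPS = 1e-9


@dataclass(frozen=True)
class MutationalDistanceResult:
    seq_id: str
    criterion: str  # "core" | "pwm"
    exact_distance: int | None  # None when the search was capped
    capped: bool = False
    path: tuple[tuple[int, str, str], ...] = field(default_factory=tuple)
    final_score: float | None = None

    @property
    def distance_bin(self) -> str:
        if self.capped or self.exact_distance >= 2:
            return ">=2"
        return str(self.exact_distance)

    def apply_path(self, seq: NucSequence) -> NucSequence:
        bases = list(seq.bases)
        for pos, from_b, to_b in self.path:
            if bases[pos] != from_b:
                raise ValueError(f"path inconsistent at position {pos}")
            bases[pos] = to_b
        return NucSequence(seq.id + "|evolved", "".join(bases))


def core_distance(
    seq: NucSequence, criterion: CoreMotifCriterion | None = None
) -> MutationalDistanceResult:
    """Exact minimal substitution distance to an exact core-motif match."""
    criterion = criterion or CoreMotifCriterion()
    mm, hit = count_mismatches_to_core(criterion, seq)
    path = []
    for start, fixed in ((hit.pos35, criterion.fixed35), (hit.pos10, criterion.fixed10)):
        for off, base_code in fixed:
            pos = start + off
            want = BASES[base_code]
            if seq.bases[pos] != want:
                path.append((pos, seq.bases[pos], want))
    path.sort()
    return MutationalDistanceResult(
        seq_id=seq.id, criterion="core", exact_distance=mm, path=tuple(path)
    )


def greedy_pwm_evolve(
    seq: NucSequence, model: PromoterModel, max_steps: int = 5
) -> MutationalDistanceResult:
    """Greedy single-substitution hill climb until the PWM threshold is met.

    Ties among equally good substitutions break to the leftmost position,
    then the alphabetically first target base, so trajectories are seed-free.
    """
    if model.threshold is None:
        raise ValueError("model threshold is not calibrated")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    current = seq.bases
    path: list[tuple[int, str, str]] = []
    score, _ = best_window_score(model, NucSequence(seq.id, current))
    for _step in range(max_steps):
        if score >= model.threshold:
            return MutationalDistanceResult(
                seq_id=seq.id, criterion="pwm", exact_distance=len(path),
                path=tuple(path), final_score=score,
            )
        best = None  # (new_score, pos, to_base)
        for pos, cur_b in enumerate(current):
            for to_b in BASES:
                if to_b == cur_b:
                    continue
                mutant = current[:pos] + to_b + current[pos + 1 :]
                s, _ = best_window_score(model, NucSequence(seq.id, mutant))
                if best is None or s > best[0] + TIE_EPS:
                    best = (s, pos, to_b)
        s, pos, to_b = best
        path.append((pos, current[pos], to_b))
        current = current[:pos] + to_b + current[pos + 1 :]
        score = s
    if score >= model.threshold:
        return MutationalDistanceResult(
            seq_id=seq.id, criterion="pwm", exact_distance=len(path),
            path=tuple(path), final_score=score,
        )
    return MutationalDistanceResult(
        seq_id=seq.id, criterion="pwm", exact_distance=None, capped=True,
        path=tuple(path), final_score=score,
    )


def distance_histogram(results) -> pd.DataFrame:
    """Percentage of sequences per distance bin {0, 1, >=2}; sums to 100."""
    results = list(results)
    if not results:
        raise ValueError("no results to histogram")
    n = len(results)
    counts = {b: 0 for b in BINS}
    for r in results:
        counts[r.distance_bin] += 1
    rows = []
    for b in BINS:
        p = counts[b] / n
        rows.append(
            {
                "bin": b,
                "count": counts[b],
                "percentage": 100.0 * p,
                "se_percentage": 100.0 * (p * (1 - p) / n) ** 0.5,
            }
        )
    return pd.DataFrame(rows)
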