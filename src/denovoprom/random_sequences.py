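"""Random candidate-promoter sequences.

Sequences are drawn i.i.d. uniform over {A,C,G,T} and rejection-filtered to
match the composition constraints used when constructing the experimental
random-sequence library: GC content within [45.6%, 56.0%] (the bounds are
kept inclusive) and no homopolymer run longer than five bases. Defaults
give 103-nt sequences, the length of the replaced lac intergenic region.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._util import decode
from .io_formats import NucSequence

#: attempts per requested sequence before a spec is declared infeasible
ATTEMPT_CAP_FACTOR = 10_000


@dataclass(frozen=True)
class RandomSequenceSpec:
    n: int
    length: int = 103
    gc_min: float = 0.456
    gc_max: float = 0.560
    max_run: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def gc_fraction(seq) -> float:
    bases = seq.bases if isinstance(seq, NucSequence) else seq
    return (bases.count("G") + bases.count("C")) / len(bases)


def max_homopolymer_run(seq) -> int:
    bases = seq.bases if isinstance(seq, NucSequence) else seq
    return max(len(list(run)) for _, run in groupby(bases))


def _passes_mask(codes: np.ndarray, spec: RandomSequenceSpec) -> np.ndarray:
    """Vectorized filter for a (batch, length) array of base codes."""
    gc_count = ((codes == 1) | (codes == 2)).sum(axis=1)
    gc = gc_count / spec.length
    ok = (gc >= spec.gc_min - 1e-12) & (gc <= spec.gc_max + 1e-12)
    if spec.length > spec.max_run:
        eq = codes[:, 1:] == codes[:, :-1]
        # a run of max_run+1 identical bases == max_run consecutive equalities
        windows = sliding_window_view(eq, spec.max_run, axis=1)
        ok &= ~windows.all(axis=2).any(axis=1)
    return ok


def generate_random_sequences(spec: RandomSequenceSpec) -> list[NucSequence]:
    """Exactly ``spec.n`` filtered sequences by rejection sampling.

    Deterministic given ``spec.seed``: one PCG64 stream, fixed batch size.
    Raises RuntimeError for specs that stay empty after the attempt cap.
    """
    rng = np.random.default_rng(spec.seed)
    batch = max(2 * spec.n, 256)
    cap = ATTEMPT_CAP_FACTOR * spec.n
    accepted: list[np.ndarray] = []
    n_acc = 0
    drawn = 0
    while n_acc < spec.n:
        if drawn >= cap:
            raise RuntimeError(
                f"rejection sampling produced {n_acc}/{spec.n} sequences after "
                f"{drawn} draws; the filter specification appears infeasible"
            )
        codes = rng.integers(0, 4, size=(batch, spec.length), dtype=np.uint8)
        drawn += batch
        good = codes[_passes_mask(codes, spec)]
        accepted.append(good)
        n_acc += len(good)
    pool = np.concatenate(accepted)[: spec.n]
    return [NucSequence(f"randseq{i:05d}", decode(row)) for i, row in enumerate(pool)]
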