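"""Six-mer occurrence counting and WT-vs-null enrichment flags.

All 4096 hexanucleotides are counted in overlapping windows within each
coding sequence (coding strand only, no cross-gene windows). Motifs whose
WT count deviates from the recoded-null ensemble mean by at least
``z_cut`` empirical standard deviations are flagged depleted or
overrepresented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._util import BASES, encode
from .io_formats import NucSequence

K = 6
N_MOTIFS = 4 ** K
_POW = 4 ** np.arange(K - 1, -1, -1)


def sixmer_index(motif: str) -> int:
    if len(motif) != K:
        raise ValueError("motif must be a hexamer")
    return int(encode(motif.upper()) @ _POW)


def motif_from_index(index: int) -> str:
    out = []
    for p in _POW:
        out.append(BASES[index // p])
        index %= p
    return "".join(out)


@dataclass(frozen=True)
class SixmerProfile:
    counts: np.ndarray  # length 4096, lexicographic index
    total_windows: int
    source: str = "wt"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_MOTIFS,) or (c < 0).any():
            raise ValueError("counts must be a non-negative vector of length 4096")
        if int(c.sum()) != self.total_windows:
            raise ValueError("counts do not sum to total_windows")
        object.__setattr__(self, "counts", c)


def count_sixmers(seqs, source: str = "wt") -> SixmerProfile:
    """Overlapping six-mer counts over a sequence set.

    Sequences shorter than six contribute zero windows; each sequence of
    length L contributes max(0, L - 5) windows.
    """
    counts = np.zeros(N_MOTIFS, dtype=np.int64)
    total = 0
    for seq in seqs:
        bases = seq.bases if isinstance(seq, NucSequence) else seq
        if len(bases) < K:
            continue
        codes = encode(bases)
        idx = sliding_window_view(codes, K).astype(np.int64) @ _POW
        counts += np.bincount(idx, minlength=N_MOTIFS)
        total += idx.size
    return SixmerProfile(counts=counts, total_windows=total, source=source)


def sixmer_enrichment(
    wt: SixmerProfile, nulls: list[SixmerProfile], z_cut: float = 3.0
) -> pd.DataFrame:
    """Per-motif z-score of the WT count against the null ensemble.

    z = (wt_count - null_mean) / null_sd with the sample (ddof=1) standard
    deviation; sorted by z ascending, so the most depleted motifs lead the
    table. Motifs with null_sd == 0 are flagged neutral (z = 0 when the WT
    count equals the constant null count, missing otherwise). At least ~30
    replicates are recommended for a stable sd; fewer than 2 is an error.
    """
    if len(nulls) < 2:
        raise ValueError("need at least 2 null profiles")
    mat = np.stack([p.counts for p in nulls]).astype(float)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    wt_counts = wt.counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (wt_counts - mean) / sd
    z[(sd == 0) & (wt_counts == mean)] = 0.0
    z[(sd == 0) & (wt_counts != mean)] = np.nan
    flag = np.full(N_MOTIFS, "neutral", dtype=object)
    flag[np.nan_to_num(z) <= -z_cut] = "depleted"
    flag[np.nan_to_num(z) >= z_cut] = "overrepresented"
    flag[np.isnan(z)] = "neutral"
    df = pd.DataFrame(
        {
            "motif": [motif_from_index(i) for i in range(N_MOTIFS)],
            "wt_count": wt.counts,
            "null_mean": mean,
            "null_sd": sd,
            "z": z,
            "flag": flag,
        }
    )
    return df.sort_values("z", ascending=True, kind="stable").reset_index(drop=True)
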