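import numpy as np
import pytest

from denovoprom.pipeline import default_model
from denovoprom.promoter_model import ELEMENT_LEN
from denovoprom.synthetic_data import synth_usage_table
from denovoprom._util import BASES


@pytest.fixture(scope="session")
def model():
    """The packaged PWM calibrated on the default synthetic promoter set."""
    return default_model(seed=0)


@pytest.fixture(scope="session")
def usage508():
    """Codon-usage table tuned to the E. coli-like 50.8% GC target."""
    return synth_usage_table(0.508)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def random_bases(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def naive_best_window(model, bases, strands=("+",)):
    """Independent brute-force PWM scan: enumerate every placement in pure
    Python dictionaries. Oracle for best_window_score."""
    from denovoprom._util import revcomp

    lo, hi = model.spacer_range
    placements = []  # (score, pos35, spacer, rank, strand)
    for strand in strands:
        s = bases if strand == "+" else revcomp(bases)
        rank = 0 if strand == "+" else 1
        for pos35 in range(len(s)):
            for sp in range(lo, hi + 1):
                pos10 = pos35 + ELEMENT_LEN + sp
                if pos10 + ELEMENT_LEN > len(s):
                    continue
                score = model.spacer_weight[sp]
                for j in range(ELEMENT_LEN):
                    score += model.w35[j][BASES.index(s[pos35 + j])]
                    score += model.w10[j][BASES.index(s[pos10 + j])]
                placements.append((score, pos35, sp, rank, strand))
    top = max(p[0] for p in placements)
    near = [p for p in placements if p[0] >= top - 1e-9]
    best = min(near, key=lambda p: (p[1], p[2], p[3]))
    return best[0], best[1], best[2], best[4]
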