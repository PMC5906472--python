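"""Fully synthetic genomes and promoter sets with known ground truth.

The generator emulates the inputs of the genome-scale analysis at desk
scale: protein-coding genes drawn codon-by-codon from a codon-usage table
tuned to a target GC content, optional gene groups (essential, toxin,
antitoxin), and per-group promoter handling:

* neutral — plain usage sampling (the same distribution the usage-mode
  recoding null draws from, so WT and nulls are exchangeable);
* avoid — codon choices that create a core-motif promoter (either strand)
  are locally resampled, emulating purifying selection against accidental
  promoters through synonymous codon choice;
* enrich — full canonical promoter cassettes (TTGACA + 17-nt spacer +
  TATAAT) are planted at ~1 site per kb on a chosen strand; antisense
  planting on toxin genes emulates interfering promoters restraining
  toxin expression.

Truth labels record group membership, avoidance outcome and every planted
site, so planted-truth recovery is checkable downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import revcomp, spawn_rng
from .io_formats import GeneRecord, NucSequence
from .promoter_model import (
    CONSENSUS_10,
    CONSENSUS_35,
    CoreMotifCriterion,
    PromoterModel,
)
from .recoding_null import (
    AA_LETTERS,
    CODON_TO_AA,
    CodonUsageTable,
    codon_indices,
    _CODON_OF_INDEX,
)

logger = logging.getLogger(__name__)

_CODING_AAS = tuple(aa for aa in AA_LETTERS if aa != "*")
_SPACER_CHOICES = (15, 16, 17, 18, 19)
_SPACER_PROBS = (0.05, 0.20, 0.50, 0.20, 0.05)

#: bounded local-resampling rounds for promoter avoidance
AVOID_ROUNDS = 10


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    n_genes: int = 200
    length_range: tuple[int, int] = (100, 500)  # codons, inclusive
    gc_target: float = 0.508
    group_fractions: dict = field(
        default_factory=lambda: {"essential": 0.0, "toxin": 0.0, "antitoxin": 0.0, "none": 1.0}
    )
    avoidance_by_group: dict = field(default_factory=dict)  # group -> neutral|avoid|enrich
    antisense_bias_for_toxins: bool = False
    enrich_per_kb: float = 1.0
    avoid_patterns: tuple[str, ...] | None = None  # hexamers; None = core pair
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        total = sum(self.group_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group fractions sum to {total}, not 1")
        for mode in self.avoidance_by_group.values():
            if mode not in {"neutral", "avoid", "enrich"}:
                raise ValueError(f"unknown avoidance mode {mode!r}")


def synth_usage_table(gc_target: float) -> CodonUsageTable:
    """Codon-usage table whose implied GC (uniform amino-acid composition)
    is within one percentage point of ``gc_target``.

    Within each synonymous family P(codon) is proportional to
    w**(#GC bases); w is solved by bisection.
    """
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must be in (0, 1)")

    def table_for(logw: float) -> CodonUsageTable:
        w = np.exp(logw)
        probs: dict[str, dict[str, float]] = {}
        for aa in AA_LETTERS:
            fam = [c for c, a in CODON_TO_AA.items() if a == aa]
            raw = {c: w ** sum(c.count(x) for x in "GC") for c in fam}
            tot = sum(raw.values())
            probs[aa] = {c: v / tot for c, v in raw.items()}
        return CodonUsageTable(probs)

    lo, hi = -12.0, 12.0
    gc_lo, gc_hi = table_for(lo).implied_gc(), table_for(hi).implied_gc()
    if not gc_lo - 1e-9 <= gc_target <= gc_hi + 1e-9:
        raise ValueError(
            f"gc_target {gc_target:.3f} outside the codon-achievable range "
            f"[{gc_lo:.3f}, {gc_hi:.3f}]"
        )
    for _ in range(80):
        mid = (lo + hi) / 2
        if table_for(mid).implied_gc() < gc_target:
            lo = mid
        else:
            hi = mid
    table = table_for((lo + hi) / 2)
    assert abs(table.implied_gc() - gc_target) < 0.01
    return table


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _sample_cds(n_codons: int, usage: CodonUsageTable, rng: np.random.Generator) -> str:
    """ATG + (n_codons - 1) usage-sampled coding codons + a sampled stop."""
    sampler = usage.sampler()
    aa_idx = np.array(
        [sampler.aa_index[a] for a in rng.choice(_CODING_AAS, size=n_codons - 1)],
        dtype=np.int64,
    )
    body = sampler.sample(aa_idx, rng)
    stop_idx = sampler.sample(np.array([sampler.aa_index["*"]]), rng)
    codons = ["ATG"] + [_CODON_OF_INDEX[i] for i in body] + [_CODON_OF_INDEX[stop_idx[0]]]
    return "".join(codons)


def _find_core_spans(bases: str, criterion: CoreMotifCriterion) -> list[tuple[int, int]]:
    """Half-open spans of all core-pair hits on either strand, in coding
    coordinates."""
    spans = []
    L = len(bases)
    for strand_bases, flip in ((bases, False), (revcomp(bases), True)):
        for sp in range(criterion.spacer_range[0], criterion.spacer_range[1] + 1):
            width = 12 + sp
            for i in range(L - width + 1):
                ok35 = (
                    strand_bases[i] == "T"
                    and strand_bases[i + 1] == "T"
                    and strand_bases[i + 2] == "G"
                )
                j = i + 6 + sp
                ok10 = (
                    strand_bases[j] == "T"
                    and strand_bases[j + 1] == "A"
                    and strand_bases[j + 5] == "T"
                )
                if ok35 and ok10:
                    lo, hi = i, j + 6
                    if flip:
                        lo, hi = L - hi, L - lo
                    spans.append((lo, hi))
    return spans


def _find_pattern_spans(bases: str, patterns: tuple[str, ...]) -> list[tuple[int, int]]:
    spans = []
    for pat in patterns:
        start = bases.find(pat)
        while start != -1:
            spans.append((start, start + len(pat)))
            start = bases.find(pat, start + 1)
    return spans


def _resample_spans(
    cds: str, spans, usage: CodonUsageTable, rng: np.random.Generator
) -> str:
    """Synonymously resample every codon overlapping a span (never the start
    codon or the terminal stop)."""
    sampler = usage.sampler()
    idx = codon_indices(cds)
    n = idx.size
    target = sorted(
        {
            ci
            for lo, hi in spans
            for ci in range(lo // 3, (hi + 2) // 3 + 1)
            if 1 <= ci < n - 1
        }
    )
    if not target:
        return cds
    t = np.array(target, dtype=np.int64)
    idx[t] = sampler.sample(sampler.codon_aa[idx[t]], rng)
    return "".join(_CODON_OF_INDEX[i] for i in idx)


def _avoid_promoters(
    cds: str,
    usage: CodonUsageTable,
    rng: np.random.Generator,
    patterns: tuple[str, ...] | None,
) -> tuple[str, str]:
    """Bounded greedy local resampling; returns (cds, 'avoid'|'partial')."""
    criterion = CoreMotifCriterion()
    for _ in range(AVOID_ROUNDS):
        spans = (
            _find_pattern_spans(cds, patterns)
            if patterns is not None
            else _find_core_spans(cds, criterion)
        )
        if not spans:
            return cds, "avoid"
        cds = _resample_spans(cds, spans, usage, rng)
    spans = (
        _find_pattern_spans(cds, patterns)
        if patterns is not None
        else _find_core_spans(cds, criterion)
    )
    if spans:
        logger.warning("avoidance incomplete: %d residual sites", len(spans))
        return cds, "partial"
    return cds, "avoid"


def _plant_cassettes(
    cds: str, strand: str, per_kb: float, rng: np.random.Generator
) -> tuple[str, list[dict]]:
    """Overwrite bases with canonical promoter cassettes on the given strand."""
    L = len(cds)
    cassette_len = 12 + 17
    k = max(1, int(round(per_kb * L / 1000.0)))
    planted: list[dict] = []
    occupied: list[tuple[int, int]] = []
    bases = list(cds)
    for _ in range(k):
        for _try in range(100):
            pos = int(rng.integers(3, L - cassette_len - 3))
            if all(pos + cassette_len <= lo or pos >= hi for lo, hi in occupied):
                break
        else:
            continue
        spacer = "".join(rng.choice(list("ACGT"), size=17))
        cassette = CONSENSUS_35 + spacer + CONSENSUS_10
        if strand == "-":
            cassette = revcomp(cassette)
        bases[pos : pos + cassette_len] = cassette
        occupied.append((pos, pos + cassette_len))
        planted.append({"strand": strand, "pos": pos, "cassette": cassette})
    return "".join(bases), planted


def _assign_groups(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> list[str]:
    n = spec.n_genes
    fr = spec.group_fractions
    n_pair = int(round(min(fr.get("toxin", 0.0), fr.get("antitoxin", 0.0)) * n))
    n_ess = int(round(fr.get("essential", 0.0) * n))
    groups = (
        ["toxin"] * n_pair
        + ["antitoxin"] * n_pair
        + ["essential"] * min(n_ess, n - 2 * n_pair)
    )
    groups += ["none"] * (n - len(groups))
    perm = rng.permutation(n)
    return [groups[i] for i in perm]


def synth_genome(spec: SyntheticGenomeSpec, usage: CodonUsageTable | None = None):
    """Generate a synthetic genome; returns (genes, truth).

    truth = {"genes": {gene_id: {"group", "avoidance", "planted", "partner"}},
             "pairs": [(toxin_id, antitoxin_id), ...]}.
    Deterministic given ``spec.seed``; per-gene streams are derived from
    (seed, gene index) so genes are independent of generation order.
    """
    usage = usage or synth_usage_table(spec.gc_target)
    group_rng = spawn_rng(spec.seed, "groups")
    groups = _assign_groups(spec, group_rng)
    genes: list[GeneRecord] = []
    truth: dict = {"genes": {}, "pairs": []}
    toxins: list[str] = []
    antitoxins: list[str] = []
    cursor = 0
    for i in range(spec.n_genes):
        rng = spawn_rng(spec.seed, "gene", i)
        gid = f"g{i:04d}"
        group = groups[i]
        n_codons = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        cds = _sample_cds(n_codons, usage, rng)
        mode = spec.avoidance_by_group.get(group, "neutral")
        planted: list[dict] = []
        outcome = mode
        if mode == "avoid":
            cds, outcome = _avoid_promoters(cds, usage, rng, spec.avoid_patterns)
        elif mode == "enrich":
            cds, planted = _plant_cassettes(cds, "+", spec.enrich_per_kb, rng)
        if group == "toxin" and spec.antisense_bias_for_toxins:
            cds, extra = _plant_cassettes(cds, "-", spec.enrich_per_kb, rng)
            planted.extend(extra)
        flags = frozenset([group]) if group != "none" else frozenset()
        genes.append(
            GeneRecord(
                gene_id=gid,
                cds=NucSequence(gid, cds),
                strand="+",
                genome_start=cursor,
                genome_end=cursor + len(cds),
                flags=flags,
            )
        )
        cursor += len(cds) + 50
        truth["genes"][gid] = {
            "group": group,
            "avoidance": outcome,
            "planted": planted,
            "partner": None,
        }
        if group == "toxin":
            toxins.append(gid)
        elif group == "antitoxin":
            antitoxins.append(gid)
    for tox, anti in zip(toxins, antitoxins):
        truth["genes"][tox]["partner"] = anti
        truth["genes"][anti]["partner"] = tox
        truth["pairs"].append((tox, anti))
    return genes, truth


def synth_promoter_set(
    model_or_consensus=None,
    n: int = 556,
    noise_per_position: float = 0.15,
    seed: int = 0,
    length: int = 103,
) -> list[NucSequence]:
    """Synthetic constitutive-promoter set: consensus −35/spacer/−10 windows
    with per-position mutation probability ``noise_per_position``, embedded
    in random flanks. Stands in for a real constitutive-promoter list when
    calibrating the scoring threshold."""
    if n < 2:
        raise ValueError("need n >= 2 promoters")
    if not 0.0 <= noise_per_position < 1.0:
        raise ValueError("noise_per_position must be in [0, 1)")
    if isinstance(model_or_consensus, PromoterModel):
        hex35, hex10 = model_or_consensus.consensus
    elif model_or_consensus is None:
        hex35, hex10 = CONSENSUS_35, CONSENSUS_10
    else:
        hex35, hex10 = model_or_consensus
    min_len = 12 + max(_SPACER_CHOICES)
    if length < min_len:
        raise ValueError(f"length must be >= {min_len}")
    rng = np.random.default_rng(seed)
    out = []
    alphabet = np.array(list("ACGT"))
    for i in range(n):
        spacer = int(rng.choice(_SPACER_CHOICES, p=_SPACER_PROBS))
        window = list(hex35 + "".join(rng.choice(alphabet, size=spacer)) + hex10)
        core_positions = list(range(6)) + list(range(6 + spacer, 12 + spacer))
        for pos in core_positions:
            if rng.random() < noise_per_position:
                others = [b for b in "ACGT" if b != window[pos]]
                window[pos] = others[int(rng.integers(3))]
        offset = int(rng.integers(0, length - len(window) + 1))
        flanks = rng.choice(alphabet, size=length - len(window))
        bases = (
            "".join(flanks[:offset]) + "".join(window) + "".join(flanks[offset:])
        )
        out.append(NucSequence(f"prom{i:04d}", bases))
    return out
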