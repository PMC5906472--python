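"""Synonymous-recoding and codon-shuffling null models for coding sequences.

Two nulls, matching the two randomizations used for the genome analysis:

* usage mode — every codon is replaced by a synonymous codon drawn
  independently from the genome-wide codon-usage distribution conditional
  on its amino acid. The protein sequence is preserved exactly; codon bias
  is preserved in expectation.
* shuffle mode — the gene's codons are permuted uniformly at random. The
  codon multiset, and therefore the exact GC content, is preserved; the
  protein sequence is not.

The terminal stop codon is kept verbatim in both modes. Replicates are
sub-seeded from ``(root seed, gene_id, replicate index)`` so any replicate
is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from ._util import BASES, derive_seed
from .io_formats import GeneRecord, NucSequence

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: codon string -> amino acid letter, stops as '*'; all 64 codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

AA_LETTERS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))
STOP_CODONS: frozenset = frozenset(_TABLE.stop_codons)

_CODON_OF_INDEX = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)  # lexicographic, A<C<G<T
_INDEX_OF_CODON = {c: i for i, c in enumerate(_CODON_OF_INDEX)}


@dataclass
class CodonUsageTable:
    """P(codon | amino acid) for every amino acid including stop ('*')."""

    probs: dict[str, dict[str, float]]
    _sampler: "_Sampler | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for aa, fam in self.probs.items():
            total = sum(fam.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities for {aa!r} sum to {total}, not 1")
            for codon in fam:
                if CODON_TO_AA.get(codon) != aa:
                    raise ValueError(f"codon {codon} listed under wrong amino acid {aa!r}")
                seen.add(codon)
        if seen != set(CODON_TO_AA):
            missing = sorted(set(CODON_TO_AA) - seen)
            raise ValueError(f"usage table missing codons: {missing[:5]}...")

    @classmethod
    def from_counts(cls, counts: dict[str, dict[str, float]], pseudocount: float = 0.0
                    ) -> "CodonUsageTable":
        """Normalize per-family counts; families with zero total fall back to
        uniform over their synonymous codons (with a warning)."""
        probs: dict[str, dict[str, float]] = {}
        for aa in AA_LETTERS:
            fam_codons = [c for c, a in CODON_TO_AA.items() if a == aa]
            fam = {c: counts.get(aa, {}).get(c, 0.0) + pseudocount for c in fam_codons}
            total = sum(fam.values())
            if total <= 0:
                logger.warning("amino acid %r unobserved; using uniform codon usage", aa)
                probs[aa] = {c: 1.0 / len(fam_codons) for c in fam_codons}
            else:
                probs[aa] = {c: v / total for c, v in fam.items()}
        return cls(probs)

    def implied_gc(self, aa_weights: dict[str, float] | None = None) -> float:
        """Expected GC fraction of a codon when amino acids are drawn with
        ``aa_weights`` (default: uniform over the 20 amino acids)."""
        if aa_weights is None:
            aa_weights = {aa: 1.0 / 20 for aa in AA_LETTERS if aa != "*"}
        gc = 0.0
        for aa, w in aa_weights.items():
            for codon, p in self.probs[aa].items():
                gc += w * p * sum(codon.count(x) for x in "GC") / 3.0
        return gc

    def sampler(self) -> "_Sampler":
        if self._sampler is None:
            self._sampler = _Sampler(self)
        return self._sampler


class _Sampler:
    """Vectorized inverse-CDF sampler over synonymous codon families."""

    def __init__(self, usage: CodonUsageTable):
        n_aa = len(AA_LETTERS)
        max_fam = max(
            sum(1 for c in CODON_TO_AA if CODON_TO_AA[c] == aa) for aa in AA_LETTERS
        )
        self.aa_index = {aa: i for i, aa in enumerate(AA_LETTERS)}
        self.codon_aa = np.array(
            [self.aa_index[CODON_TO_AA[c]] for c in _CODON_OF_INDEX], dtype=np.int64
        )
        self.fam_codons = np.zeros((n_aa, max_fam), dtype=np.int64)
        self.fam_cum = np.ones((n_aa, max_fam), dtype=float)
        self.zero_family = np.zeros(n_aa, dtype=bool)
        for aa, i in self.aa_index.items():
            fam = sorted(usage.probs[aa].items())
            codons = [_INDEX_OF_CODON[c] for c, _ in fam]
            p = np.array([v for _, v in fam], dtype=float)
            if p.sum() <= 0:
                self.zero_family[i] = True
                continue
            cum = np.cumsum(p)
            cum[-1] = 1.0
            self.fam_codons[i, : len(fam)] = codons
            self.fam_codons[i, len(fam) :] = codons[-1]
            self.fam_cum[i, : len(fam)] = cum

    def sample(self, aa_idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one codon index per amino-acid index."""
        if self.zero_family[aa_idx].any():
            bad = AA_LETTERS[int(aa_idx[self.zero_family[aa_idx]][0])]
            raise ValueError(f"amino acid {bad!r} has zero total usage probability")
        u = rng.random(aa_idx.shape[0])
        choice = (u[:, None] > self.fam_cum[aa_idx]).sum(axis=1)
        return self.fam_codons[aa_idx, choice]


def _cds_string(gene: GeneRecord | NucSequence) -> tuple[str, str]:
    if isinstance(gene, GeneRecord):
        return gene.gene_id, gene.cds.bases
    return gene.id, gene.bases


def codon_indices(cds: str) -> np.ndarray:
    """Lexicographic codon indices (0..63) of a CDS string."""
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    return np.array(
        [_INDEX_OF_CODON[cds[i : i + 3]] for i in range(0, len(cds), 3)], dtype=np.int64
    )


def _codons_to_string(idx: np.ndarray) -> str:
    return "".join(_CODON_OF_INDEX[i] for i in idx)


def usage_from_genes(genes) -> CodonUsageTable:
    """Genome-wide codon usage table from a gene set (standard table 11)."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    counts: dict[str, dict[str, float]] = {aa: {} for aa in AA_LETTERS}
    for gene in genes:
        gid, cds = _cds_string(gene)
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            aa = CODON_TO_AA[codon]
            if aa == "*" and i < len(cds) - 3:
                logger.warning("internal stop codon in %s at codon %d", gid, i // 3)
            counts[aa][codon] = counts[aa].get(codon, 0.0) + 1.0
    return CodonUsageTable.from_counts(counts)


def recode_gene(
    gene: GeneRecord | NucSequence, usage: CodonUsageTable, seed: int
) -> NucSequence:
    """Synonymously recode a gene, preserving its translation exactly.

    Every codon except a terminal stop is replaced by a draw from the
    usage distribution conditional on its amino acid. Deterministic given
    ``seed``.
    """
    gid, cds = _cds_string(gene)
    idx = codon_indices(cds)
    sampler = usage.sampler()
    rng = np.random.default_rng(seed)
    keep_last = _CODON_OF_INDEX[idx[-1]] in STOP_CODONS
    body = idx[:-1] if keep_last else idx
    new_body = sampler.sample(sampler.codon_aa[body], rng)
    new_idx = np.concatenate([new_body, idx[-1:]]) if keep_last else new_body
    return NucSequence(gid, _codons_to_string(new_idx))


def shuffle_codons(gene: GeneRecord | NucSequence, seed: int) -> NucSequence:
    """Uniform random permutation of the gene's codons (terminal stop fixed).

    Preserves the codon multiset and hence the exact GC content.
    """
    gid, cds = _cds_string(gene)
    idx = codon_indices(cds)
    rng = np.random.default_rng(seed)
    keep_last = _CODON_OF_INDEX[idx[-1]] in STOP_CODONS
    body = idx[:-1] if keep_last else idx
    perm = rng.permutation(body.shape[0])
    new_idx = np.concatenate([body[perm], idx[-1:]]) if keep_last else body[perm]
    return NucSequence(gid, _codons_to_string(new_idx))


def make_ensemble(
    gene: GeneRecord | NucSequence,
    mode: str,
    n: int,
    usage: CodonUsageTable | None = None,
    seed: int = 0,
) -> list[NucSequence]:
    """n independent null versions of a gene, reproducible per replicate.

    Replicate i uses the sub-seed derived from (seed, gene_id, i), so a
    single replicate regenerated alone is identical to its in-batch copy.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    if mode not in {"usage", "shuffle"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "usage" and usage is None:
        raise ValueError("usage mode requires a CodonUsageTable")
    gid, _ = _cds_string(gene)
    out = []
    for i in range(n):
        sub = derive_seed(seed, gid, i)
        if mode == "usage":
            null = recode_gene(gene, usage, sub)
        else:
            null = shuffle_codons(gene, sub)
        out.append(NucSequence(f"{gid}|{mode}|{i}", null.bases))
    return out
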