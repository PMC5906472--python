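# Methods

## Random-sequence generation

Random candidate promoters are i.i.d. uniform over {A,C,G,T} and
rejection-filtered: GC fraction within [0.456, 0.560] (bounds inclusive —
"kept" is read as the closed interval) and no homopolymer run longer than
5 nt. Defaults give 103-nt sequences. One PCG64 stream with a fixed batch
size makes the whole batch reproducible from the seed; the attempt cap is
10,000 draws per requested sequence, which only pathological filter
settings can reach (the defaults accept roughly two thirds of draws).

## Promoter model

Two criteria are used throughout, and they deliberately bracket the
biology:

* **Core motif** — an exact match to `TTGnnn` and `TAnnnT` at spacer
  15–19. These six bases are the most conserved positions of the σ70
  consensus; the criterion is parameter-free and is the default for
  mutational-distance histograms.
* **PWM** — 6×4 log₂-odds matrices for the −35 and −10 hexamers plus an
  additive spacer-length weight, built with pseudocount 0.5. The shipped
  default matrix is trained on a packaged 20-window synthetic alignment
  written to encode the conservation profile of σ70 promoter collections:
  near-invariant core bases (TTG; T, A and the closing T of the −10),
  much weaker preferences elsewhere, spacers concentrated on 17 nt. Any
  user alignment can replace it via `build_pwm`.

The PWM threshold is the median best-window score of a constitutive
promoter set (`calibrate_threshold`). Lacking a bundled promoter list,
the default model calibrates on a synthetic constitutive set: consensus
cassettes embedded in random flanks with per-position divergence 0.35.
That divergence was chosen to match real constitutive σ70 promoters,
which align to the consensus at roughly 45–80% identity per position;
it yields a permissive threshold (7.31 for the default matrix, maximum
attainable score 18.58) under which a typical few-hundred-codon gene
carries a handful of above-threshold windows — the regime in which
promoter-prediction software operates on real genomes. Calibrating on a
nearly clean set (divergence 0.15) instead produces a threshold so strict
that intragenic hits all but vanish and rank statistics degenerate into
ties; 0.15 remains available and is exercised in the tests where a sharp
model is wanted.

Scanning maximizes s35 + s10 + spacer weight over all placements.
Tie-breaking is deterministic: leftmost −35 start, then shortest spacer,
then the sense strand; scores within 1e-9 are treated as tied so the rule
is insensitive to float summation order. Strand handling is validated by
the identity score(seq, −) = score(revcomp(seq), +). Random-sequence
analyses scan the sense strand only (a promoter must face the downstream
reporter); intragenic scans use both strands. The extended −10 (TGn)
element is not modeled.

## Mutational distance

Under the core criterion the minimal distance is exact: each fixed-base
mismatch costs exactly one substitution and placements are independent,
so the minimum mismatch count over placements is the minimum edit count
(verified against exhaustive 0/1/2-substitution enumeration). Under the
PWM criterion the distance is the length of a greedy trajectory: all 3L
single substitutions are evaluated each step and the best (ties: leftmost
position, then alphabetical base) is applied until the score clears the
threshold, or a step cap (default 5) marks the result "capped". The
trajectory is strictly increasing by construction. Histograms use bins
{0, 1, ≥2} with binomial standard errors.

## Null ensembles

* **usage mode** — each codon is resampled i.i.d. from the genome-wide
  codon-usage distribution conditional on its amino acid: the protein is
  preserved exactly, codon bias in expectation (not per-gene counts; the
  shuffle null provides the exact-count alternative).
* **shuffle mode** — a uniform permutation of the gene's codons: codon
  multiset and hence exact GC preserved, protein not.

The terminal stop codon is never resampled or moved. Replicate i of gene
g derives its RNG seed from SHA-256 of (root seed, gene id, i), so any
replicate is reproducible in isolation and ensembles are order-independent.
Amino-acid families never observed in the input get uniform codon usage
with a warning; internal stop codons are counted toward stop usage with a
warning.

## Accidental-expression score

Per strand, all placements with S ≥ θ are collected and non-maximum
suppression removes overlapping calls: hits are taken strongest-first and
a hit is dropped if its −10 start lies within 10 nt of a retained hit on
the same strand. The 10-nt radius is a documented choice — it implements
"sum all promoters, overlapping or distinct, without double-counting one
site". Each retained hit contributes (s35 + s10)·(1 + S − θ); the margin
factor is a monotone stand-in for the linear-discriminant confidence that
promoter-prediction software attaches to each call, so only comparative
statistics (WT vs nulls, group contrasts) are meaningful, never absolute
magnitudes. Scores are normalized per kb and split into sense and
antisense components; the whole function is a pure map from (sequence,
model) and obeys sense(x) = antisense(revcomp(x)).

Ranking uses the mid-rank percentile (#{null < wt} + ½ ties)/N and decile
⌊10p⌋+1 clipped to [1, 10]; deciles require N ≥ 10. For density-style
summaries each gene's ensemble is represented by its null median. Group
contrasts: two-sample Kolmogorov–Smirnov (scipy, asymptotic p) for
essential-vs-rest and sense-vs-antisense comparisons, and an exact
two-sided sign test (minimum-likelihood rule, ties dropped) for
toxin/antitoxin couples. No multiple-testing correction is applied; the
pipeline reports single planned tests.

## Six-mer analysis

All 4096 hexamers are counted in overlapping windows within each coding
sequence (coding strand only; no cross-gene windows), so counts sum to
Σ(L−5) — asserted on every profile. Enrichment uses the empirical z-score
against the null ensemble (sample sd, ddof 1) with default flag cutoff
|z| ≥ 3; an sd of zero yields z = 0 when WT equals the constant null and
a missing z otherwise, flagged neutral either way. The cutoff is a
distribution-free convention, not a calibrated error rate; at least ~30
replicates are recommended for a stable sd.

## Synthetic data

`synth_usage_table` builds a usage table with P(codon|aa) ∝ w^(#GC),
solving w by bisection so the implied GC under uniform amino-acid
composition hits the target (default 0.508, the *E. coli* genome value)
within one percentage point. `synth_genome` samples genes codon-by-codon
from the table (ATG start, sampled stop) — exactly the distribution the
usage-mode null resamples from, so neutral WT genes are exchangeable with
their nulls and decile histograms are flat by construction. Per-group
promoter handling:

* *avoid* — bounded greedy local resampling: codons overlapping any
  core-pair hit (either strand) are synonymously resampled, up to 10
  rounds; residual genes are truth-labelled "partial". An
  `avoid_patterns` option avoids listed hexamers (coding strand) instead,
  which is the right null for six-mer depletion checks — pair-avoidance
  alone removes too few single-motif occurrences to move a z-score.
* *enrich* — full consensus cassettes (TTGACA + 17-nt random spacer +
  TATAAT) planted at ~1 per kb on a chosen strand, positions recorded in
  the truth labels. A planted site emulates a real promoter, i.e. the
  strongest form of the core motif; planting overwrites codons, so
  synthetic enrich genes do not encode a conserved protein at those
  positions.
* toxin genes optionally receive antisense cassettes, emulating
  interfering promoters that restrain toxin expression.

What the generator does **not** emulate: operon structure, ribosome
binding sites, mRNA secondary structure, dicodon bias, strand asymmetry
of real genomes, or real gene-length and amino-acid distributions
(lengths are uniform 100–500 codons, amino acids uniform). Passing tests
therefore demonstrate that the statistical machinery recovers planted
truth under its own assumptions, not that real genomes behave this way.

## Problem sizes and determinism

The accessibility analysis runs at its full size (30,000 sequences,
vectorized core scan, ~1 s). Genome-scale defaults are desk-sized: 200
genes × 100 null replicates for the decile analyses and 100 simulated
genomes for the sign-test power check; full-genome runs (thousands of
genes × 1000 replicates) use the same code path and simply take hours on
one CPU. Every stochastic stage takes an explicit seed and derives
sub-streams by stable hashing, so reruns with the same configuration are
bit-identical (timestamps live only in run metadata).

## Known limitations

* Absolute accidental-expression scores are not comparable to published
  promoter-software outputs; only ranks, deciles and contrasts are.
* The greedy PWM trajectory is a lower-bound-style heuristic for the true
  PWM mutational distance; only its first step is provably optimal.
* GenBank parsing keeps one record per non-pseudogene CDS and skips
  frame-broken features with a warning; genes spanning the origin are
  supported through compound (join) locations.
* The KS p-values are asymptotic; for the very small toxin/antitoxin
  groups of a toy genome they are indicative only.
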