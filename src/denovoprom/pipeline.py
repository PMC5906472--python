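"""End-to-end orchestration of the two analyses.

* accessibility — how many mutations separate random sequences from
  promoter activity (distance histogram over bins {0, 1, >=2}, plus PWM
  score histograms before/after the first selected mutation);
* minimization — are WT coding sequences depleted of accidental promoters
  relative to synonymous-recoding nulls (per-gene decile ranks, essential
  contrast, toxin/antitoxin paired test, six-mer enrichment).

All randomness funnels through one root seed recorded in the run metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import derive_seed, encode
from .accidental_expression import (
    NullEnsemble,
    decile_histogram,
    group_ks,
    paired_sign_test,
    rank_gene,
    score_gene,
)
from .insilico_evolution import (
    distance_histogram,
    greedy_pwm_evolve,
    MutationalDistanceResult,
)
from .io_formats import GeneRecord, NucSequence
from .promoter_model import (
    CoreMotifCriterion,
    PromoterModel,
    batch_core_min_mismatch,
    best_window_score,
    calibrate_threshold,
    default_pwm,
)
from .random_sequences import RandomSequenceSpec, generate_random_sequences
from .recoding_null import make_ensemble, usage_from_genes
from .sixmer_analysis import N_MOTIFS, SixmerProfile, count_sixmers, sixmer_enrichment
from .synthetic_data import synth_promoter_set

logger = logging.getLogger(__name__)

#: size of the synthetic constitutive-promoter calibration set
DEFAULT_CALIBRATION_SIZE = 556
#: per-position divergence of the calibration promoters from the consensus;
#: chosen to match the per-position conservation of real sigma70
#: constitutive promoter alignments (roughly 45-80% consensus identity)
DEFAULT_CALIBRATION_NOISE = 0.35


def default_model(
    seed: int = 0,
    calibration_noise: float = DEFAULT_CALIBRATION_NOISE,
    n_calibration: int = DEFAULT_CALIBRATION_SIZE,
) -> PromoterModel:
    """The packaged PWM calibrated on a synthetic constitutive-promoter set."""
    model = default_pwm()
    cal = synth_promoter_set(
        model, n=n_calibration, noise_per_position=calibration_noise,
        seed=derive_seed(seed, "calibration"),
    )
    return calibrate_threshold(model, cal)


# ---------------------------------------------------------------------------
# accessibility
# ---------------------------------------------------------------------------

@dataclass
class AccessibilityResult:
    histogram: pd.DataFrame
    per_sequence: pd.DataFrame
    criterion: str
    scores_before: np.ndarray | None = None
    scores_after_first: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def run_accessibility(
    spec: RandomSequenceSpec,
    criterion: str = "core",
    model: PromoterModel | None = None,
    max_steps: int = 5,
    out_dir=None,
) -> AccessibilityResult:
    """Generate random sequences and measure their mutational distance to
    promoter activity under the chosen criterion."""
    if criterion not in {"core", "pwm"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion == "pwm" and (model is None or model.threshold is None):
        raise ValueError("pwm criterion requires a calibrated model")
    t0 = time.time()
    seqs = generate_random_sequences(spec)
    if criterion == "core":
        core = CoreMotifCriterion()
        codes = np.stack([encode(s.bases) for s in seqs])
        mm = batch_core_min_mismatch(codes, core)
        results = [
            MutationalDistanceResult(seq_id=s.id, criterion="core", exact_distance=int(d))
            for s, d in zip(seqs, mm)
        ]
        scores_before = scores_after = None
    else:
        results = []
        scores_before = np.empty(len(seqs))
        scores_after = np.empty(len(seqs))
        for i, s in enumerate(seqs):
            scores_before[i] = best_window_score(model, s)[0]
            res = greedy_pwm_evolve(s, model, max_steps=max_steps)
            results.append(res)
            if res.path:
                first = res.path[0]
                mutated = s.bases[: first[0]] + first[2] + s.bases[first[0] + 1 :]
                scores_after[i] = best_window_score(model, NucSequence(s.id, mutated))[0]
            else:
                scores_after[i] = scores_before[i]
    hist = distance_histogram(results)
    per_seq = pd.DataFrame(
        {
            "seq_id": [r.seq_id for r in results],
            "criterion": criterion,
            "distance_bin": [r.distance_bin for r in results],
            "exact_distance": [r.exact_distance for r in results],
        }
    )
    meta = {
        "n": spec.n, "length": spec.length, "seed": spec.seed,
        "criterion": criterion, "runtime_s": round(time.time() - t0, 2),
    }
    out = AccessibilityResult(
        histogram=hist, per_sequence=per_seq, criterion=criterion,
        scores_before=scores_before, scores_after_first=scores_after, metadata=meta,
    )
    if out_dir is not None:
        _write_accessibility(out, Path(out_dir))
    return out


def _write_accessibility(result: AccessibilityResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.histogram.to_csv(out_dir / "distance_histogram.tsv", sep="\t", index=False)
    result.per_sequence.to_csv(out_dir / "per_sequence.tsv", sep="\t", index=False)
    with (out_dir / "metadata.json").open("w") as fh:
        json.dump(result.metadata, fh, indent=1)
    if result.scores_before is not None:
        _plot_score_histograms(result, out_dir / "score_histograms.png")


def _plot_score_histograms(result: AccessibilityResult, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(result.scores_before, bins=40, alpha=0.6, label="before evolution")
    ax.hist(result.scores_after_first, bins=40, alpha=0.6, label="after first mutation")
    ax.set_xlabel("best-window PWM score")
    ax.set_ylabel("sequences")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

@dataclass
class MinimizationResult:
    per_gene: pd.DataFrame
    decile_hist: pd.DataFrame
    decile_hist_subsets: dict
    group_stats: dict
    sixmer: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def run_minimization(
    genes: list[GeneRecord],
    model: PromoterModel,
    mode: str = "usage",
    n_nulls: int = 100,
    ta_pairs: list[tuple[str, str]] | None = None,
    seed: int = 0,
    z_cut: float = 3.0,
    out_dir=None,
    make_plots: bool = False,
) -> MinimizationResult:
    """Rank every WT gene against its null ensemble and compute the group
    contrasts and the six-mer enrichment table.

    Essential/toxin/antitoxin membership is taken from GeneRecord.flags
    (attach via io_formats.attach_flags when using external label lists);
    toxin-antitoxin couples come from ``ta_pairs``. Contrasts whose groups
    are missing are skipped with a warning rather than failing the run.
    """
    if model.threshold is None:
        raise ValueError("model threshold is not calibrated")
    if len(genes) < 10:
        raise ValueError("genome must contain at least 10 genes")
    t0 = time.time()
    usage = usage_from_genes(genes) if mode == "usage" else None

    rows = []
    ranks = []
    wt_profile_parts = []
    null_counts = np.zeros((n_nulls, N_MOTIFS), dtype=np.int64)
    null_windows = np.zeros(n_nulls, dtype=np.int64)
    scores_by_gene: dict[str, dict] = {}
    for gene in genes:
        wt = score_gene(gene, model)
        nulls = make_ensemble(gene, mode, n_nulls, usage=usage, seed=seed)
        null_scores = []
        for r, null_seq in enumerate(nulls):
            null_scores.append(score_gene(null_seq, model).total_per_kb)
            prof = count_sixmers([null_seq])
            null_counts[r] += prof.counts
            null_windows[r] += prof.total_windows
        ens = NullEnsemble(
            gene_id=gene.gene_id, mode=mode,
            null_scores=tuple(null_scores), wt_score=wt.total_per_kb,
        )
        rank = rank_gene(ens)
        ranks.append(rank)
        wt_profile_parts.append(gene.cds)
        scores_by_gene[gene.gene_id] = {
            "wt": wt, "percentile": rank.percentile, "decile": rank.decile,
        }
        rows.append(
            {
                "gene_id": gene.gene_id,
                "length_nt": len(gene.cds),
                "flags": ",".join(sorted(gene.flags)),
                "sense_per_kb": wt.sense_per_kb,
                "antisense_per_kb": wt.antisense_per_kb,
                "total_per_kb": wt.total_per_kb,
                "null_median": float(np.median(null_scores)),
                "percentile": rank.percentile,
                "decile": rank.decile,
            }
        )
    per_gene = pd.DataFrame(rows)

    decile_hist = decile_histogram(ranks)
    subsets = {}
    for label in ("essential", "toxin", "antitoxin"):
        ids = {g.gene_id for g in genes if label in g.flags}
        if ids:
            subsets[label] = decile_histogram(ranks, subset=ids)

    group_stats: dict = {}
    ess = [r.percentile for r, g in zip(ranks, genes) if "essential" in g.flags]
    rest = [r.percentile for r, g in zip(ranks, genes) if "essential" not in g.flags]
    if len(ess) >= 2 and len(rest) >= 2:
        d, p = group_ks(ess, rest)
        group_stats["essential_vs_rest_ks"] = {"D": d, "p": p, "n_a": len(ess), "n_b": len(rest)}
    else:
        logger.warning("essential contrast skipped: group too small")

    if ta_pairs:
        pairs = [
            (scores_by_gene[t]["wt"].total_per_kb, scores_by_gene[a]["wt"].total_per_kb)
            for t, a in ta_pairs
            if t in scores_by_gene and a in scores_by_gene
        ]
        if pairs:
            k, n, p = paired_sign_test(pairs)
            group_stats["toxin_vs_antitoxin_sign"] = {
                "k_toxin_higher": k, "n_pairs": n, "p": p, "fraction": k / n,
            }
    for label in ("toxin", "antitoxin"):
        sense = [
            scores_by_gene[g.gene_id]["wt"].sense_per_kb for g in genes if label in g.flags
        ]
        anti = [
            scores_by_gene[g.gene_id]["wt"].antisense_per_kb for g in genes if label in g.flags
        ]
        if len(sense) >= 2:
            d, p = group_ks(sense, anti)
            group_stats[f"{label}_sense_vs_antisense_ks"] = {"D": d, "p": p, "n": len(sense)}

    wt_prof = count_sixmers(wt_profile_parts, source="wt")
    null_profiles = [
        SixmerProfile(counts=null_counts[r], total_windows=int(null_windows[r]),
                      source=f"null replicate {r}")
        for r in range(n_nulls)
    ]
    sixmer = sixmer_enrichment(wt_prof, null_profiles, z_cut=z_cut)

    model_hash = hashlib.sha256(model.to_json().encode()).hexdigest()[:16]
    meta = {
        "seed": seed, "n_nulls": n_nulls, "mode": mode, "n_genes": len(genes),
        "model_hash": model_hash, "threshold": model.threshold,
        "runtime_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    result = MinimizationResult(
        per_gene=per_gene, decile_hist=decile_hist, decile_hist_subsets=subsets,
        group_stats=group_stats, sixmer=sixmer, metadata=meta,
    )
    if out_dir is not None:
        _write_minimization(result, Path(out_dir), make_plots=make_plots)
    return result


def _write_minimization(result: MinimizationResult, out_dir: Path, make_plots: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.per_gene.to_csv(out_dir / "per_gene.tsv", sep="\t", index=False)
    result.decile_hist.to_csv(out_dir / "decile_histogram.tsv", sep="\t", index=False)
    for label, df in result.decile_hist_subsets.items():
        df.to_csv(out_dir / f"decile_histogram_{label}.tsv", sep="\t", index=False)
    result.sixmer.to_csv(out_dir / "sixmer_enrichment.tsv", sep="\t", index=False)
    with (out_dir / "group_stats.json").open("w") as fh:
        json.dump(result.group_stats, fh, indent=1)
    with (out_dir / "metadata.json").open("w") as fh:
        json.dump(result.metadata, fh, indent=1)
    if make_plots:
        _plot_minimization(result, out_dir)


def _plot_minimization(result: MinimizationResult, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(result.decile_hist["decile"], result.decile_hist["percentage"],
           color="seagreen", label="all WT genes")
    if "essential" in result.decile_hist_subsets:
        sub = result.decile_hist_subsets["essential"]
        ax.plot(sub["decile"], sub["percentage"], "m-o", label="essential")
    ax.axhline(10.0, ls="--", c="k", lw=1, label="neutral expectation")
    ax.set_xlabel("decile of WT score within its null ensemble")
    ax.set_ylabel("% of genes")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "decile_histogram.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(result.per_gene["null_median"], bins=40, alpha=0.5, color="gray",
            label="null medians", density=True)
    ax.hist(result.per_gene["total_per_kb"], bins=40, alpha=0.5, color="seagreen",
            label="WT genes", density=True)
    ax.set_xlabel("accidental expression (score per kb)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "density.png", dpi=120)
    plt.close(fig)
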