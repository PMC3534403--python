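"""End-to-end orchestration of the evaluation stages.

One :class:`RunConfig` drives everything: simulate (or load) the study
data, then run coverage summarisation, genotype calling, concordance and
Mendelian checks per sample, and the pooled-detection analysis with its
threshold sweep, predicted-versus-observed correlation and MAF-bin
summaries. Fixed seeds make every report byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from . import io_formats
from .concordance_eval import (
    ConcordanceReport,
    MendelianResult,
    PositiveControlSite,
    concordance_summary,
    infer_positive_controls,
    mendelian_check,
    pearson_r2,
)
from .coverage_metrics import CoverageReport, summarize_coverage
from .genotype_caller import CallerConfig, GenotypeCall, call_sample
from .io_formats import ReferenceGenotype, SiteAlleleCounts, TargetPanel, Trio, write_report
from .pool_analysis import (
    MafBinSummary,
    PoolCallerConfig,
    PoolDetectionResult,
    PoolSpec,
    call_pool_variants,
    maf_bin_summary,
    predict_pool_frequencies,
    predicted_vs_observed,
    sensitivity_fdr,
)
from .synthetic_data import (
    SimConfig,
    TruthSet,
    default_trios,
    make_panel,
    make_truth,
    simulate_pool_pileup,
    simulate_sample_pileup,
)

__all__ = [
    "RunConfig",
    "SampleEvaluation",
    "PoolEvaluation",
    "run_sample_evaluation",
    "run_pool_evaluation",
    "write_sample_reports",
    "write_pool_reports",
]

logger = logging.getLogger(__name__)

Site = tuple[str, int]


@dataclass
class RunConfig:
    """Configuration of one full evaluation run."""

    mode: str = "simulate"  # "simulate" | "files"
    sim: SimConfig = field(default_factory=lambda: SimConfig(mean_depth=500.0))
    caller: CallerConfig = field(default_factory=CallerConfig)
    trios: list[Trio] = field(default_factory=default_trios)
    pool_min_counts: tuple[int, ...] = (5, 10, 20)
    pool_min_fraction: float = 0.01
    pool_mean_depth: float = 2400.0
    #: pooled libraries see more handling (pooling + library prep), modelled
    #: as a higher per-base error than the individually sequenced samples
    pool_per_base_error: float = 0.01
    pool_replicates: int = 2
    min_samples_positive: int = 2
    # files mode inputs
    panel_path: Optional[str] = None
    pileup_paths: dict[str, str] = field(default_factory=dict)
    pileup_dialect: str = "simple-tsv"
    genotype_table_path: Optional[str] = None
    pedigree_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        if not self.pool_min_counts:
            raise ValueError("pool_min_counts sweep may not be empty")

    @property
    def samples(self) -> list[str]:
        return [m for trio in self.trios for m in trio.members]


@dataclass
class SampleEvaluation:
    panel: TargetPanel
    truth: Optional[TruthSet]
    coverage: dict[str, CoverageReport]
    calls: dict[str, list[GenotypeCall]]
    concordance: dict[str, ConcordanceReport]
    mendelian: list[MendelianResult]


@dataclass
class PoolEvaluation:
    spec: PoolSpec
    controls: list[PositiveControlSite]
    predicted: dict[Site, float]
    positives: list[Site]
    observations: list[dict[Site, float]]  # one map per replicate
    results: list[PoolDetectionResult]  # pools x thresholds grid
    r2_predicted_observed: list[float]  # one per replicate
    r2_between_replicates: Optional[float]
    maf_bins: list[list[MafBinSummary]]  # one list per replicate


def _load_files(cfg: RunConfig) -> tuple[TargetPanel, dict[str, list[SiteAlleleCounts]], list[ReferenceGenotype], list[Trio]]:
    if cfg.panel_path is None or cfg.genotype_table_path is None:
        raise ValueError("files mode requires panel_path and genotype_table_path")
    panel = io_formats.read_target_panel(cfg.panel_path)
    pileups = {
        sample: list(io_formats.read_pileup(path, dialect=cfg.pileup_dialect))
        for sample, path in cfg.pileup_paths.items()
    }
    refs = io_formats.read_genotype_table(cfg.genotype_table_path)
    trios = (
        io_formats.read_pedigree(cfg.pedigree_path)
        if cfg.pedigree_path
        else cfg.trios
    )
    return panel, pileups, refs, trios


def run_sample_evaluation(cfg: RunConfig) -> SampleEvaluation:
    """Coverage, calling, concordance and Mendelian stages for every sample."""
    if cfg.mode == "simulate":
        panel = make_panel(cfg.sim)
        truth = make_truth(panel, cfg.sim, cfg.trios)
        refs = truth.reference_genotypes()
        trios = cfg.trios
        samples = cfg.samples
    else:
        panel, pileups, refs, trios = _load_files(cfg)
        truth = None
        samples = list(cfg.pileup_paths)
        for trio in trios:
            missing = [m for m in trio.members if m not in samples]
            if missing:
                raise ValueError(
                    f"pedigree members {missing} have no pileup input"
                )

    coverage: dict[str, CoverageReport] = {}
    calls: dict[str, list[GenotypeCall]] = {}
    for sample in samples:
        logger.info("evaluating sample %s", sample)
        if cfg.mode == "simulate":
            pileup, reads = simulate_sample_pileup(truth, panel, cfg.sim, sample)
            coverage[sample] = summarize_coverage(reads, panel, sample_id=sample)
            del reads
        else:
            pileup = pileups[sample]
        calls[sample] = call_sample(pileup, panel, cfg.caller)
        logger.info(
            "sample %s: %d sites called, %d detected",
            sample, len(calls[sample]), sum(c.detected for c in calls[sample]),
        )

    refs_by_sample: dict[str, list[ReferenceGenotype]] = {}
    for ref in refs:
        refs_by_sample.setdefault(ref.sample_id, []).append(ref)

    concordance: dict[str, ConcordanceReport] = {}
    for sample in samples:
        sample_refs = refs_by_sample.get(sample)
        if not sample_refs:
            logger.warning("sample %s has no reference genotypes; skipping concordance", sample)
            continue
        concordance[sample] = concordance_summary(calls[sample], sample_refs, panel)

    mendelian = [
        mendelian_check(
            calls[trio.child_id], calls[trio.father_id], calls[trio.mother_id], trio
        )
        for trio in trios
        if all(m in calls for m in trio.members)
    ]
    return SampleEvaluation(panel, truth, coverage, calls, concordance, mendelian)


def run_pool_evaluation(
    cfg: RunConfig, sample_eval: SampleEvaluation | None = None
) -> PoolEvaluation:
    """Pooled-detection stage: threshold sweep, correlations, MAF bins.

    Positive-control genotypes are inferred by cross-validating the
    individual samples' calls (replicate-consistent, Mendelian-consistent);
    the positive-control *SNP* set for sensitivity scoring is the subset
    whose predicted composite non-reference fraction is > 0.
    """
    if cfg.mode != "simulate":
        raise NotImplementedError("pool evaluation currently runs on simulated pools")
    if sample_eval is None:
        sample_eval = run_sample_evaluation(cfg)
    panel, truth = sample_eval.panel, sample_eval.truth
    spec = PoolSpec(tuple(cfg.samples))
    missing = [m for m in spec.member_ids if m not in sample_eval.calls]
    if missing:
        raise ValueError(f"pool members without call sets: {missing}")

    controls = infer_positive_controls(
        {s: sample_eval.calls[s] for s in spec.member_ids},
        trios=cfg.trios,
        min_samples=cfg.min_samples_positive,
    )
    predicted = predict_pool_frequencies(controls, spec)
    positives = sorted(site for site, frac in predicted.items() if frac > 0)
    logger.info(
        "%d control sites inferred, %d positive-control SNPs (fraction > 0)",
        len(controls), len(positives),
    )

    pool_sim = replace(
        cfg.sim, mean_depth=cfg.pool_mean_depth, per_base_error=cfg.pool_per_base_error
    )
    observations: list[dict[Site, float]] = []
    results: list[PoolDetectionResult] = []
    r2s: list[float] = []
    bins: list[list[MafBinSummary]] = []
    for rep in range(cfg.pool_replicates):
        pool_id = f"pool_rep{rep + 1}"
        pileup = simulate_pool_pileup(truth, spec, panel, pool_sim, replicate=rep)
        for min_count in cfg.pool_min_counts:
            pool_cfg = PoolCallerConfig(cfg.pool_min_fraction, min_count)
            site_calls = call_pool_variants(pileup, panel, pool_cfg)
            detected = [c.site for c in site_calls if c.detected]
            results.append(
                sensitivity_fdr(detected, positives, pool_id=pool_id, min_nonref_count=min_count)
            )
        obs = {
            c.site: c.nonref_fraction
            for c in call_pool_variants(pileup, panel, PoolCallerConfig(cfg.pool_min_fraction, 1))
        }
        observations.append(obs)
        _, _, r2 = predicted_vs_observed(predicted, obs)
        r2s.append(r2)
        bins.append(maf_bin_summary(predicted, obs))

    rep_r2: Optional[float] = None
    if len(observations) >= 2:
        shared = sorted(set(observations[0]) & set(observations[1]))
        if len(shared) >= 2:
            rep_r2 = pearson_r2(
                [observations[0][s] for s in shared],
                [observations[1][s] for s in shared],
            )
    return PoolEvaluation(
        spec, controls, predicted, positives, observations, results, r2s, rep_r2, bins
    )


# ---------------------------------------------------------------------------
# report emission
# ---------------------------------------------------------------------------


def write_sample_reports(ev: SampleEvaluation, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report(list(ev.coverage.values()), outdir / "coverage.tsv")
    write_report(list(ev.concordance.values()), outdir / "concordance.tsv")
    write_report(ev.mendelian, outdir / "mendel.tsv")


def write_pool_reports(pe: PoolEvaluation, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report(pe.results, outdir / "pool.tsv")
    bins_flat = []
    for rep, summaries in enumerate(pe.maf_bins, start=1):
        for s in summaries:
            rec = {"replicate": rep}
            rec.update(s.to_record())
            bins_flat.append(rec)
    write_report(bins_flat, outdir / "maf_bins.tsv")
    summary = {
        "n_control_sites": len(pe.controls),
        "n_positive_control_snps": len(pe.positives),
        "r2_predicted_observed": [round(x, 4) for x in pe.r2_predicted_observed],
        "r2_between_replicates": (
            None if pe.r2_between_replicates is None else round(pe.r2_between_replicates, 4)
        ),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
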