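"""Pooled (non-barcoded) sample analysis: minor-allele detection and scoring.

Six samples pooled equimolar dilute each heterozygous allele to an
expected 1/12 of the reads at its site, so pooled variant detection works
on composite non-reference allele fractions rather than per-sample
genotypes. This module predicts composite fractions from member
genotypes, detects pooled variants under a fraction-plus-count rule
(default: >= 1% of the site's depth and a minimum absolute count swept
over {5, 10, 20}), and scores sensitivity / false-discovery rate against
positive-control sites.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .concordance_eval import PositiveControlSite, pearson_r2
from .genotype_caller import site_nonref_frequency
from .io_formats import SiteAlleleCounts, TargetPanel
from .util import fmt_pct

__all__ = [
    "PoolSpec",
    "PoolCallerConfig",
    "PoolSiteCall",
    "PoolDetectionResult",
    "MafBinSummary",
    "predict_pool_frequency",
    "predict_pool_frequencies",
    "call_pool_variants",
    "sensitivity_fdr",
    "sensitivity_fdr_from_counts",
    "predicted_vs_observed",
    "maf_bin_summary",
]

logger = logging.getLogger(__name__)

Site = tuple[str, int]
AllelePair = tuple[str, str]

#: bin edges centred on the three smallest equimolar 6-member dosage
#: fractions (1/12, 2/12, 3/12), plus the remainder of (0, 0.5]
DEFAULT_MAF_BIN_EDGES = (0.0, 1.5 / 12, 2.5 / 12, 3.5 / 12, 0.5)


@dataclass(frozen=True)
class PoolSpec:
    """Membership and mixing weights of one pooled library."""

    member_ids: tuple[str, ...]
    weights: Optional[tuple[float, ...]] = None  # default equimolar

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("pool needs at least one member")
        object.__setattr__(self, "member_ids", tuple(self.member_ids))
        if self.weights is None:
            w = (1.0 / len(self.member_ids),) * len(self.member_ids)
            object.__setattr__(self, "weights", w)
        else:
            w = tuple(float(x) for x in self.weights)
            if len(w) != len(self.member_ids):
                raise ValueError("one weight per member required")
            if any(x <= 0 for x in w):
                raise ValueError("weights must be positive")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1")
            object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class PoolCallerConfig:
    min_nonref_fraction: float = 0.01
    min_nonref_count: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.min_nonref_fraction < 1.0):
            raise ValueError("min_nonref_fraction must lie in (0, 1)")
        if self.min_nonref_count < 1:
            raise ValueError("min_nonref_count must be >= 1")


@dataclass(frozen=True)
class PoolSiteCall:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    nonref_count: int
    depth: int
    nonref_fraction: float
    detected: bool

    @property
    def site(self) -> Site:
        return (self.chrom, self.pos)


@dataclass
class PoolDetectionResult:
    """Sensitivity/FDR of pooled detection at one minimum-count threshold."""

    pool_id: str
    min_nonref_count: int
    n_positive_controls: int
    n_positive_detected: int
    n_total_detected: int
    sensitivity: float  # percent
    fdr: Optional[float]  # percent; None when nothing was detected

    def to_record(self) -> dict:
        return {
            "pool_id": self.pool_id,
            "min_nonref_count": self.min_nonref_count,
            "n_positive_controls": self.n_positive_controls,
            "n_positive_detected": self.n_positive_detected,
            "n_total_detected": self.n_total_detected,
            "sensitivity_pct": fmt_pct(self.sensitivity),
            "fdr_pct": fmt_pct(self.fdr),
        }


def nonref_dosage(genotype: AllelePair, ref_base: str) -> int:
    """Number of non-reference alleles (0, 1 or 2) in a genotype."""
    return sum(1 for a in genotype if a != ref_base)


def predict_pool_frequency(
    genotypes: Mapping[str, AllelePair], ref_base: str, spec: PoolSpec
) -> float:
    """Expected composite non-reference fraction at one site.

    Returns sum_m weight_m * dosage_m / 2 over pool members; linear in the
    weights and bounded in [0, 1]. Every member must have a genotype —
    sites with a missing member are excluded upstream.
    """
    missing = [m for m in spec.member_ids if m not in genotypes]
    if missing:
        raise KeyError(f"missing member genotypes at site: {missing}")
    return sum(
        w * nonref_dosage(genotypes[m], ref_base) / 2.0
        for m, w in zip(spec.member_ids, spec.weights)
    )


def predict_pool_frequencies(
    controls: Sequence[PositiveControlSite], spec: PoolSpec
) -> dict[Site, float]:
    """Composite fraction per control site, skipping (and logging) sites
    where any pool member lacks a genotype."""
    out: dict[Site, float] = {}
    for ctrl in controls:
        try:
            out[ctrl.site] = predict_pool_frequency(ctrl.genotypes, ctrl.ref_base, spec)
        except KeyError:
            logger.info(
                "site %s:%d excluded from prediction: member genotype missing",
                ctrl.chrom, ctrl.pos,
            )
    return out


def call_pool_variants(
    pileup: Iterable[SiteAlleleCounts],
    panel: TargetPanel | None,
    cfg: PoolCallerConfig = PoolCallerConfig(),
) -> list[PoolSiteCall]:
    """Evaluate the pooled detection rule at every analyzable site.

    A site is detected iff its top non-reference count is at least
    ``min_nonref_count`` and at least ``min_nonref_fraction`` of the
    site's depth (the fraction rule is per-site, not panel-wide).
    The returned calls carry observed fractions for *all* sites, detected
    or not, so predicted-versus-observed comparisons are unrestricted.
    """
    out: list[PoolSiteCall] = []
    for counts in pileup:
        if panel is not None and not panel.contains_analyzable(counts.chrom, counts.pos):
            continue
        depth = counts.depth
        if depth == 0:
            continue
        alt, frac = site_nonref_frequency(counts)
        n_alt = counts.counts[alt]
        detected = n_alt >= cfg.min_nonref_count and frac >= cfg.min_nonref_fraction
        out.append(
            PoolSiteCall(counts.chrom, counts.pos, counts.ref_base, alt, n_alt, depth, frac, detected)
        )
    return out


def sensitivity_fdr(
    detected_sites: Iterable[Site],
    positive_controls: Iterable[Site],
    pool_id: str = "",
    min_nonref_count: int = 0,
) -> PoolDetectionResult:
    """Score a detected site set against the positive-control sites.

    sensitivity = 100 * detected positives / positives;
    FDR = 100 * (detections that are not positives) / detections.
    """
    detected = set(detected_sites)
    positives = set(positive_controls)
    if not positives:
        raise ValueError("positive-control set is empty")
    n_pos_detected = len(detected & positives)
    n_total = len(detected)
    return PoolDetectionResult(
        pool_id=pool_id,
        min_nonref_count=min_nonref_count,
        n_positive_controls=len(positives),
        n_positive_detected=n_pos_detected,
        n_total_detected=n_total,
        sensitivity=100.0 * n_pos_detected / len(positives),
        fdr=(100.0 * (n_total - n_pos_detected) / n_total) if n_total else None,
    )


def sensitivity_fdr_from_counts(
    n_positive_controls: int,
    n_positive_detected: int,
    n_total_detected: int,
    pool_id: str = "",
    min_nonref_count: int = 0,
) -> PoolDetectionResult:
    """Score from summary counts alone by materialising index site sets.

    Useful when only a published count table is available: synthetic sites
    realising the three counts are built and pushed through
    :func:`sensitivity_fdr`, so the percentage arithmetic is the same code
    path as the site-level route.
    """
    if not (0 <= n_positive_detected <= min(n_positive_controls, n_total_detected)):
        raise ValueError("inconsistent detection counts")
    positives = {("ctrl", i) for i in range(n_positive_controls)}
    detected = {("ctrl", i) for i in range(n_positive_detected)} | {
        ("other", i) for i in range(n_total_detected - n_positive_detected)
    }
    return sensitivity_fdr(detected, positives, pool_id, min_nonref_count)


def predicted_vs_observed(
    predictions: Mapping[Site, float], observations: Mapping[Site, float]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Paired predicted/observed fractions over shared sites, plus their r^2."""
    shared = sorted(set(predictions) & set(observations))
    if len(shared) < 2:
        raise ValueError("need at least two shared sites")
    pred = np.array([predictions[s] for s in shared])
    obs = np.array([observations[s] for s in shared])
    return pred, obs, pearson_r2(pred, obs)


@dataclass
class MafBinSummary:
    """Paired five-number-style summary of predicted vs observed fractions in one MAF bin."""

    bin_low: float
    bin_high: float
    n_sites: int
    predicted_median: Optional[float]
    predicted_q1: Optional[float]
    predicted_q3: Optional[float]
    observed_median: Optional[float]
    observed_q1: Optional[float]
    observed_q3: Optional[float]

    def to_record(self) -> dict:
        def f(x):
            return "NA" if x is None else f"{x:.4f}"

        return {
            "bin_low": f"{self.bin_low:.4f}",
            "bin_high": f"{self.bin_high:.4f}",
            "n_sites": self.n_sites,
            "predicted_median": f(self.predicted_median),
            "predicted_q1": f(self.predicted_q1),
            "predicted_q3": f(self.predicted_q3),
            "observed_median": f(self.observed_median),
            "observed_q1": f(self.observed_q1),
            "observed_q3": f(self.observed_q3),
        }


def maf_bin_summary(
    predictions: Mapping[Site, float],
    observations: Mapping[Site, float],
    bin_edges: Sequence[float] = DEFAULT_MAF_BIN_EDGES,
) -> list[MafBinSummary]:
    """Bin shared sites by predicted MAF and summarise both distributions per bin.

    Bins are half-open (low, high]; a site falls in the bin containing its
    predicted fraction. Empty bins are summarised as empty, not an error.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing with >= 2 values")
    shared = sorted(set(predictions) & set(observations))
    out: list[MafBinSummary] = []
    for low, high in zip(edges, edges[1:]):
        pred = [predictions[s] for s in shared if low < predictions[s] <= high]
        obs = [observations[s] for s in shared if low < predictions[s] <= high]
        if pred:
            pq1, pmed, pq3 = np.percentile(pred, [25, 50, 75])
            oq1, omed, oq3 = np.percentile(obs, [25, 50, 75])
            out.append(
                MafBinSummary(low, high, len(pred), float(pmed), float(pq1), float(pq3),
                              float(omed), float(oq1), float(oq3))
            )
        else:
            out.append(MafBinSummary(low, high, 0, None, None, None, None, None, None))
    return out
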