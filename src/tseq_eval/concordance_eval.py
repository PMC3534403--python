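"""Concordance against reference genotypes, Mendelian checks, and replicate correlation.

Concordance is computed over *detected* calls only; the false-negative
rate is the fraction of reference-genotyped sites with no detected call.
Strata ("homozygous"/"heterozygous") are by the reference genotype's
zygosity. A call is concordant iff its implied allele pair (class +
reference base + alternate base) equals the reference allele pair.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .genotype_caller import GenotypeCall
from .io_formats import ReferenceGenotype, TargetPanel, Trio
from .util import fmt_pct

__all__ = [
    "ConcordanceReport",
    "MendelianResult",
    "PositiveControlSite",
    "concordance_summary",
    "mendelian_consistent",
    "mendelian_check",
    "pearson_r2",
    "infer_positive_controls",
]

logger = logging.getLogger(__name__)

Site = tuple[str, int]
AllelePair = tuple[str, str]


@dataclass
class ConcordanceReport:
    """One sample's detection / concordance summary versus a reference genotype set."""

    sample_id: str
    n_reference_sites: int
    n_not_detected: int
    fn_rate: float  # percent
    detection_rate: float  # percent of reference sites with a detected call
    concordance_overall: Optional[float]
    concordance_hom: Optional[float]
    concordance_het: Optional[float]

    def to_record(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_reference_sites": self.n_reference_sites,
            "n_not_detected": self.n_not_detected,
            "fn_rate_pct": fmt_pct(self.fn_rate),
            "detection_rate_pct": fmt_pct(self.detection_rate),
            "concordance_overall_pct": fmt_pct(self.concordance_overall),
            "concordance_hom_pct": fmt_pct(self.concordance_hom),
            "concordance_het_pct": fmt_pct(self.concordance_het),
        }


@dataclass
class MendelianResult:
    trio: Trio
    n_sites_tested: int
    errors: list[tuple[Site, AllelePair, AllelePair, AllelePair]] = field(
        default_factory=list
    )

    @property
    def n_errors(self) -> int:
        return len(self.errors)

    def to_record(self) -> dict:
        return {
            "family_id": self.trio.family_id,
            "father_id": self.trio.father_id,
            "mother_id": self.trio.mother_id,
            "child_id": self.trio.child_id,
            "n_sites_tested": self.n_sites_tested,
            "n_errors": self.n_errors,
        }


def false_negative_rate(n_reference_sites: int, n_not_detected: int) -> float:
    """FN rate in percent: 100 * not-detected / reference-genotyped sites."""
    if n_reference_sites <= 0:
        raise ValueError("n_reference_sites must be positive")
    if not (0 <= n_not_detected <= n_reference_sites):
        raise ValueError("n_not_detected outside [0, n_reference_sites]")
    return 100.0 * n_not_detected / n_reference_sites


def concordance_summary(
    calls: Sequence[GenotypeCall],
    refs: Sequence[ReferenceGenotype],
    panel: TargetPanel | None = None,
) -> ConcordanceReport:
    """Summarise one sample's calls against its reference genotypes.

    ``refs`` must belong to a single sample; sites with a missing reference
    genotype are excluded from the denominator. When a panel is given,
    reference sites outside analyzable target bases are excluded too.
    """
    sample_ids = {r.sample_id for r in refs}
    if len(sample_ids) > 1:
        raise ValueError(f"refs span multiple samples: {sorted(sample_ids)}")
    sample_id = next(iter(sample_ids)) if sample_ids else ""
    usable = [r for r in refs if not r.is_missing]
    if panel is not None:
        usable = [r for r in usable if panel.contains_analyzable(r.chrom, r.pos)]
    n_ref = len(usable)
    if n_ref == 0:
        raise ValueError("no non-missing reference sites to evaluate")

    detected_by_site: dict[Site, GenotypeCall] = {
        c.site: c for c in calls if c.detected
    }
    n_detected = 0
    match_all = total_all = 0
    match_hom = total_hom = 0
    match_het = total_het = 0
    for ref in usable:
        call = detected_by_site.get((ref.chrom, ref.pos))
        if call is None:
            continue
        n_detected += 1
        concordant = call.alleles == ref.alleles
        total_all += 1
        match_all += concordant
        if ref.is_het:
            total_het += 1
            match_het += concordant
        else:
            total_hom += 1
            match_hom += concordant

    def pct(num: int, den: int) -> Optional[float]:
        return 100.0 * num / den if den else None

    return ConcordanceReport(
        sample_id=sample_id,
        n_reference_sites=n_ref,
        n_not_detected=n_ref - n_detected,
        fn_rate=false_negative_rate(n_ref, n_ref - n_detected),
        detection_rate=100.0 * n_detected / n_ref,
        concordance_overall=pct(match_all, total_all),
        concordance_hom=pct(match_hom, total_hom),
        concordance_het=pct(match_het, total_het),
    )


def mendelian_consistent(
    father: AllelePair, mother: AllelePair, child: AllelePair
) -> bool:
    """True iff the child pair can be formed by one allele from each parent."""
    a, b = child
    return (a in father and b in mother) or (b in father and a in mother)


def mendelian_check(
    child_calls: Sequence[GenotypeCall],
    father_calls: Sequence[GenotypeCall],
    mother_calls: Sequence[GenotypeCall],
    trio: Trio,
) -> MendelianResult:
    """Check Mendelian transmission at every site detected in all three members."""

    def detected_map(calls: Sequence[GenotypeCall]) -> dict[Site, AllelePair]:
        return {c.site: c.alleles for c in calls if c.detected and c.alleles}

    child = detected_map(child_calls)
    father = detected_map(father_calls)
    mother = detected_map(mother_calls)
    shared = sorted(set(child) & set(father) & set(mother))
    errors = [
        (site, father[site], mother[site], child[site])
        for site in shared
        if not mendelian_consistent(father[site], mother[site], child[site])
    ]
    return MendelianResult(trio, n_sites_tested=len(shared), errors=errors)


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Square of the sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


@dataclass(frozen=True)
class PositiveControlSite:
    """A site whose genotypes are established from individually sequenced samples."""

    chrom: str
    pos: int
    ref_base: str
    genotypes: Mapping[str, AllelePair]  # sample -> consensus allele pair

    @property
    def site(self) -> Site:
        return (self.chrom, self.pos)


def infer_positive_controls(
    call_sets: Mapping[str, Sequence[Sequence[GenotypeCall]]] | Mapping[str, Sequence[GenotypeCall]],
    trios: Sequence[Trio] = (),
    min_samples: int = 2,
) -> list[PositiveControlSite]:
    """Cross-validate per-sample calls into a positive-control genotype set.

    ``call_sets`` maps each sample id to one call list or to several
    replicate call lists. A site qualifies iff (a) it carries a detected,
    replicate-consistent genotype in at least ``min_samples`` samples, and
    (b) for every trio whose three members all have a genotype there, the
    transmission is Mendelian-consistent. Replicate conflicts exclude the
    site outright (logged), mirroring the "validated across multiple
    samples" notion of a positive control.
    """
    if len(call_sets) < 2:
        raise ValueError("need call sets from at least two samples")

    def as_replicates(value) -> list[Sequence[GenotypeCall]]:
        if value and isinstance(value[0], GenotypeCall):
            return [value]
        return list(value)

    per_sample: dict[str, dict[Site, AllelePair]] = {}
    ref_base: dict[Site, str] = {}
    conflicted: set[Site] = set()
    for sample, value in call_sets.items():
        merged: dict[Site, AllelePair] = {}
        for replicate in as_replicates(value):
            for call in replicate:
                if not call.detected or call.alleles is None:
                    continue
                ref_base.setdefault(call.site, call.ref_base)
                prior = merged.get(call.site)
                if prior is not None and prior != call.alleles:
                    conflicted.add(call.site)
                    logger.info(
                        "site %s:%d excluded: replicate genotype conflict in %s (%s vs %s)",
                        call.chrom, call.pos, sample, prior, call.alleles,
                    )
                else:
                    merged[call.site] = call.alleles
        per_sample[sample] = merged

    all_sites = sorted({s for m in per_sample.values() for s in m} - conflicted)
    controls: list[PositiveControlSite] = []
    for site in all_sites:
        genotypes = {
            sample: m[site] for sample, m in per_sample.items() if site in m
        }
        if len(genotypes) < min_samples:
            continue
        consistent = True
        for trio in trios:
            gts = [genotypes.get(m) for m in trio.members]
            if all(g is not None for g in gts):
                father, mother, child = gts
                if not mendelian_consistent(father, mother, child):
                    consistent = False
                    logger.info(
                        "site %s:%d excluded: Mendelian violation in family %s",
                        site[0], site[1], trio.family_id or trio.child_id,
                    )
                    break
        if not consistent:
            continue
        controls.append(
            PositiveControlSite(site[0], site[1], ref_base[site], genotypes)
        )
    return controls
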