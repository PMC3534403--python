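"""Threshold-based genotype calling from per-site allele counts.

The evidence model is the post-filter pileup: at each site the four
A/C/G/T counts and the reference base. Classification uses non-reference
allele-frequency bands (default: het within [10%, 90%), hom-alt at
>= 90%, hom-ref below 10%) plus depth gates, and a separate "detected"
flag requiring a minimum read support per allele (default 5 reads per
allele, hence >= 10 reads for a detected het).

Boundary convention: a non-reference frequency of exactly the hom cutoff
is homozygous ("equal to or greater than 90%"); exactly the minimum
allele frequency is heterozygous.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass
from typing import Optional

from .io_formats import BASES, SiteAlleleCounts, TargetPanel

__all__ = [
    "CallerConfig",
    "GenotypeCall",
    "site_nonref_frequency",
    "call_site",
    "call_sample",
]

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
NO_CALL = "no_call"


@dataclass(frozen=True)
class CallerConfig:
    min_allele_freq: float = 0.10
    hom_freq: float = 0.90
    min_coverage: int = 5
    max_coverage: int = 15_000
    min_reads_per_allele: int = 5
    min_het_total: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.min_allele_freq < self.hom_freq <= 1.0):
            raise ValueError("require 0 < min_allele_freq < hom_freq <= 1")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.max_coverage <= self.min_coverage:
            raise ValueError("max_coverage must exceed min_coverage")


@dataclass(frozen=True)
class GenotypeCall:
    chrom: str
    pos: int
    ref_base: str
    klass: str  # hom_ref | het | hom_alt | no_call
    alt_base: Optional[str]
    nonref_freq: float
    depth: int
    detected: bool
    multiallelic: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.nonref_freq <= 1.0):
            raise ValueError("nonref_freq outside [0, 1]")
        if self.detected and self.klass == NO_CALL:
            raise ValueError("a no_call cannot be detected")

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def alleles(self) -> Optional[tuple[str, str]]:
        """Implied unordered allele pair, or None for a no-call."""
        if self.klass == HOM_REF:
            return (self.ref_base, self.ref_base)
        if self.klass == HOM_ALT:
            return (self.alt_base, self.alt_base)
        if self.klass == HET:
            return tuple(sorted((self.ref_base, self.alt_base)))
        return None


def site_nonref_frequency(counts: SiteAlleleCounts) -> tuple[str, float]:
    """Top non-reference base and its frequency among all observations.

    Ties between non-reference bases break by fixed base order A<C<G<T.
    """
    depth = counts.depth
    if depth == 0:
        raise ValueError(f"{counts.chrom}:{counts.pos}: zero depth")
    alt = max(
        (b for b in BASES if b != counts.ref_base),
        key=lambda b: (counts.counts[b], -BASES.index(b)),
    )
    return alt, counts.counts[alt] / depth


def call_site(counts: SiteAlleleCounts, cfg: CallerConfig = CallerConfig()) -> GenotypeCall:
    """Classify one site and decide its detection status.

    Depth outside [min_coverage, max_coverage] is a no-call. Otherwise the
    non-reference frequency band decides the class, and detection requires
    min_reads_per_allele support for every allele of the implied genotype
    (plus min_het_total total depth for a het).
    """
    depth = counts.depth
    if depth == 0:
        return GenotypeCall(counts.chrom, counts.pos, counts.ref_base, NO_CALL, None, 0.0, 0, False)
    alt, freq = site_nonref_frequency(counts)
    nonref_counts = sorted(
        (counts.counts[b] for b in BASES if b != counts.ref_base), reverse=True
    )
    multi = len(nonref_counts) > 1 and nonref_counts[1] >= cfg.min_reads_per_allele
    if depth < cfg.min_coverage or depth > cfg.max_coverage:
        return GenotypeCall(
            counts.chrom, counts.pos, counts.ref_base, NO_CALL, alt, freq, depth, False, multi
        )
    ref_n = counts.ref_count
    alt_n = counts.counts[alt]
    if freq < cfg.min_allele_freq:
        klass = HOM_REF
        detected = ref_n >= cfg.min_reads_per_allele
    elif freq >= cfg.hom_freq:
        klass = HOM_ALT
        detected = alt_n >= cfg.min_reads_per_allele
    else:
        klass = HET
        detected = (
            ref_n >= cfg.min_reads_per_allele
            and alt_n >= cfg.min_reads_per_allele
            and depth >= cfg.min_het_total
        )
    return GenotypeCall(
        counts.chrom, counts.pos, counts.ref_base, klass, alt, freq, depth, detected, multi
    )


def call_sample(
    pileup: Iterable[SiteAlleleCounts],
    panel: TargetPanel,
    cfg: CallerConfig = CallerConfig(),
) -> list[GenotypeCall]:
    """Call every analyzable panel site present in the pileup.

    Sites outside the primer-excluded amplicon interiors are skipped:
    variant analysis is restricted to analyzable target bases.
    """
    # pre-index analyzable intervals per chromosome for O(log n) membership
    import bisect

    intervals: dict[str, tuple[list[int], list[int]]] = {}
    for chrom in panel.chroms():
        ivals = panel.analyzable_intervals(chrom)
        intervals[chrom] = ([iv[0] for iv in ivals], [iv[1] for iv in ivals])

    def analyzable(chrom: str, pos: int) -> bool:
        if chrom not in intervals:
            return False
        starts, ends = intervals[chrom]
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and pos < ends[i]

    return [
        call_site(site, cfg)
        for site in pileup
        if analyzable(site.chrom, site.pos)
    ]
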