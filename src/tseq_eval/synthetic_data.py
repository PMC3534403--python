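"""Synthetic amplicon-resequencing data with the statistical structure the
analysis assumes: a panel of non-overlapping amplicons with primer
footprints, trio genotypes drawn under Hardy-Weinberg with Mendelian
transmission, per-amplicon log-normal depth variation, binomial
(multinomial) allele sampling with a uniform substitution-error model,
and equimolar pooling of member samples.

Everything is driven by one :class:`SimConfig`; identical configs
(including the seed) produce identical output. Named random substreams
keyed on (seed, purpose, sample) keep per-sample draws independent of
simulation order.
"""

from __future__ import annotations

import zlib
from collections.abc import Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import BASES, Amplicon, ReferenceGenotype, SiteAlleleCounts, TargetPanel, Trio
from .pool_analysis import PoolSpec, nonref_dosage

__all__ = [
    "SimConfig",
    "VariantSite",
    "TruthSet",
    "default_trios",
    "make_panel",
    "simulate_trio_genotypes",
    "make_truth",
    "simulate_sample_pileup",
    "simulate_pool_pileup",
]

Site = tuple[str, int]
AllelePair = tuple[str, str]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study design.

    Defaults emulate the benchmark design this package evaluates: a
    384-amplicon exon panel (300-600 bp amplicons, 20 bp primers at each
    end), 333 genotyped SNP sites across two HapMap-style trios, gDNA-scale
    mean depth (~2000x), ~0.5% substitution error, 66% of mapped reads
    on-target and 50 bp reads.
    """

    seed: int = 0
    n_amplicons: int = 384
    amplicon_len_range: tuple[int, int] = (300, 600)
    primer_len: int = 20
    inter_amplicon_gap: tuple[int, int] = (50, 200)
    n_variant_sites: int = 333
    maf_values: Optional[tuple[float, ...]] = None  # default: uniform on maf_range
    maf_range: tuple[float, float] = (0.10, 0.50)
    mean_depth: float = 2000.0
    #: log-scale sd of per-amplicon depth; calibrated so default uniformity
    #: at 0.2x mean lands near 85-86% (frozen constant)
    depth_dispersion: float = 1.02
    per_base_error: float = 0.005
    off_target_read_fraction: float = 0.34
    mapped_read_fraction: float = 0.33
    read_len: int = 50
    #: "stratified" permutes a systematic quantile lattice of the log-normal
    #: (variance-reduced: the realised dispersion matches the calibration);
    #: "iid" draws independently
    depth_sampling: str = "stratified"
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        lo, hi = self.amplicon_len_range
        if not (0 < lo <= hi):
            raise ValueError("bad amplicon_len_range")
        if 2 * self.primer_len >= lo:
            raise ValueError("primer footprints must leave analyzable interior")
        for frac in (self.per_base_error, self.off_target_read_fraction,
                     self.mapped_read_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.depth_sampling not in ("stratified", "iid"):
            raise ValueError("depth_sampling must be 'stratified' or 'iid'")
        if self.maf_values is not None:
            object.__setattr__(self, "maf_values", tuple(float(m) for m in self.maf_values))


def _rng(cfg: SimConfig, label: str, *extra: int) -> np.random.Generator:
    """Deterministic named substream: (seed, crc32(label), extras)."""
    key = (zlib.crc32(label.encode()),) + tuple(int(x) & 0xFFFFFFFF for x in extra)
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def default_trios() -> list[Trio]:
    """The two-trio, six-sample HapMap-style study design."""
    return [
        Trio("NA12003", "NA12004", "NA10838", family_id="1420"),
        Trio("NA11829", "NA11830", "NA10856", family_id="1350"),
    ]


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------


def make_panel(cfg: SimConfig) -> TargetPanel:
    """Non-overlapping amplicons on one synthetic chromosome.

    Lengths uniform over ``amplicon_len_range``; fixed primer footprints of
    ``primer_len`` bases at each end; random inter-amplicon gaps.
    """
    rng = _rng(cfg, "panel")
    lo, hi = cfg.amplicon_len_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_amplicons)
    glo, ghi = cfg.inter_amplicon_gap
    gaps = rng.integers(glo, ghi + 1, size=cfg.n_amplicons)
    amplicons: list[Amplicon] = []
    cursor = 1000
    for i in range(cfg.n_amplicons):
        start = cursor
        end = start + int(lengths[i])
        amplicons.append(
            Amplicon(f"AMP_{i + 1:04d}", cfg.chrom, start, end,
                     cfg.primer_len, cfg.primer_len)
        )
        cursor = end + int(gaps[i])
    return TargetPanel(amplicons, genome_label="synthetic")


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    maf: float

    @property
    def site(self) -> Site:
        return (self.chrom, self.pos)


@dataclass
class TruthSet:
    """Simulation ground truth: variant sites and every sample's genotype."""

    sites: list[VariantSite]
    genotypes: dict[str, dict[Site, AllelePair]]
    trios: list[Trio] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes)

    def reference_genotypes(self, samples: Sequence[str] | None = None) -> list[ReferenceGenotype]:
        """Expose the truth as a HapMap-style reference genotype list."""
        out: list[ReferenceGenotype] = []
        for sample in samples or self.samples:
            per_site = self.genotypes[sample]
            for v in self.sites:
                out.append(ReferenceGenotype(sample, v.chrom, v.pos, per_site[v.site]))
        return out

    def pooled_fractions(self, spec: PoolSpec) -> dict[Site, float]:
        """True composite non-reference fraction at every site for one pool."""
        out: dict[Site, float] = {}
        for v in self.sites:
            out[v.site] = sum(
                w * nonref_dosage(self.genotypes[m][v.site], v.ref_base) / 2.0
                for m, w in zip(spec.member_ids, spec.weights)
            )
        return out


def simulate_trio_genotypes(
    sites: Sequence[VariantSite], rng: np.random.Generator
) -> tuple[AllelePair, ...]:
    """Draw (father, mother, child) genotypes at each site.

    Parents are independent Hardy-Weinberg draws at the site's minor-allele
    frequency; the child receives one uniformly chosen allele from each
    parent, so Mendelian consistency holds by construction.

    Returns a flat tuple-per-site of three allele pairs.
    """
    out = []
    for v in sites:
        parent_alleles = rng.random(4) < v.maf  # father a1,a2, mother a1,a2
        father = tuple(v.alt_base if x else v.ref_base for x in parent_alleles[:2])
        mother = tuple(v.alt_base if x else v.ref_base for x in parent_alleles[2:])
        child = (father[rng.integers(2)], mother[rng.integers(2)])
        out.append((tuple(sorted(father)), tuple(sorted(mother)), tuple(sorted(child))))
    return tuple(out)


def make_truth(panel: TargetPanel, cfg: SimConfig, trios: Sequence[Trio] | None = None) -> TruthSet:
    """Place variant sites on analyzable panel bases and genotype every trio."""
    trios = list(trios) if trios is not None else default_trios()
    rng = _rng(cfg, "truth")
    positions = np.concatenate(
        [np.arange(a.analyzable_start, a.analyzable_end) for a in panel.amplicons]
    )
    if cfg.n_variant_sites > positions.size:
        raise ValueError("more variant sites requested than analyzable bases")
    chosen = np.sort(rng.choice(positions, size=cfg.n_variant_sites, replace=False))
    sites: list[VariantSite] = []
    for i, pos in enumerate(chosen):
        ref = BASES[rng.integers(4)]
        alt = [b for b in BASES if b != ref][rng.integers(3)]
        if cfg.maf_values is not None:
            maf = cfg.maf_values[i % len(cfg.maf_values)]
        else:
            maf = float(rng.uniform(*cfg.maf_range))
        sites.append(VariantSite(cfg.chrom, int(pos), ref, alt, maf))

    genotypes: dict[str, dict[Site, AllelePair]] = {}
    for trio in trios:
        drawn = simulate_trio_genotypes(sites, rng)
        for member, idx in zip(trio.members, range(3)):
            genotypes[member] = {
                v.site: drawn[j][idx] for j, v in enumerate(sites)
            }
    return TruthSet(sites=sites, genotypes=genotypes, trios=trios)


# ---------------------------------------------------------------------------
# depth and read models
# ---------------------------------------------------------------------------


def _amplicon_depths(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-amplicon mean depths: log-normal multipliers around mean_depth."""
    sigma = cfg.depth_dispersion
    if cfg.depth_sampling == "stratified":
        z = norm.ppf((np.arange(n) + 0.5) / n)
        mult = np.exp(sigma * z - sigma**2 / 2)
        rng.shuffle(mult)
    else:
        mult = np.exp(sigma * rng.standard_normal(n) - sigma**2 / 2)
    return np.rint(cfg.mean_depth * mult).astype(np.int64).clip(min=0)


def _site_base_probs(ref: str, alt: str, true_fraction: float, error: float) -> np.ndarray:
    """ACGT observation probabilities for a site with true alt fraction f.

    Each read carries the true allele and substitutes, with probability
    ``error``, to one of the other three bases uniformly; so every
    non-template base collects error/3 and, at a pure hom-ref site, the
    expected total non-reference fraction equals ``error``.
    """
    f, e = true_fraction, error
    p = np.full(4, e / 3.0)
    p[BASES.index(alt)] = f * (1 - e) + (1 - f) * e / 3.0
    p[BASES.index(ref)] = (1 - f) * (1 - e) + f * e / 3.0
    return p


def _pileup_from_fractions(
    truth: TruthSet,
    fractions: dict[Site, float],
    site_depths: dict[Site, int],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[SiteAlleleCounts]:
    out: list[SiteAlleleCounts] = []
    for v in truth.sites:
        depth = site_depths[v.site]
        if depth <= 0:
            counts = dict.fromkeys(BASES, 0)
        else:
            p = _site_base_probs(v.ref_base, v.alt_base, fractions[v.site], cfg.per_base_error)
            draw = rng.multinomial(depth, p)
            counts = dict(zip(BASES, (int(x) for x in draw)))
        out.append(SiteAlleleCounts(v.chrom, v.pos, v.ref_base, counts))
    return out


def _site_depth_map(panel: TargetPanel, depths: np.ndarray, truth: TruthSet) -> dict[Site, int]:
    starts = np.array([a.start for a in panel.amplicons])
    ends = np.array([a.end for a in panel.amplicons])
    out: dict[Site, int] = {}
    for v in truth.sites:
        idx = int(np.searchsorted(starts, v.pos, side="right")) - 1
        if idx < 0 or v.pos >= ends[idx]:
            raise ValueError(f"truth site {v.site} outside the panel")
        out[v.site] = int(depths[idx])
    return out


def _tiling_reads(panel: TargetPanel, depths: np.ndarray, cfg: SimConfig) -> pd.DataFrame:
    """Read placements realising each amplicon's depth exactly.

    Each amplicon is tiled by read_len chunks (last chunk truncated), each
    chunk emitted once per depth layer, so per-base depth over the amplicon
    equals its drawn depth. Off-target mapped reads are placed on a decoy
    contig at the configured fraction of mapped reads, and unmapped reads
    pad the total so the mapped fraction matches the config.
    """
    starts_list, ends_list = [], []
    for a, d in zip(panel.amplicons, depths):
        if d <= 0:
            continue
        cs = np.arange(a.start, a.end, cfg.read_len, dtype=np.int64)
        ce = np.minimum(cs + cfg.read_len, a.end)
        starts_list.append(np.repeat(cs, d))
        ends_list.append(np.repeat(ce, d))
    if starts_list:
        on_starts = np.concatenate(starts_list)
        on_ends = np.concatenate(ends_list)
    else:
        on_starts = on_ends = np.zeros(0, dtype=np.int64)
    n_on = on_starts.size
    otf = cfg.off_target_read_fraction
    n_off = int(round(n_on * otf / (1 - otf))) if otf < 1 else 0
    off_starts = (np.arange(n_off, dtype=np.int64) * cfg.read_len) % 10_000_000
    mf = cfg.mapped_read_fraction
    n_mapped = n_on + n_off
    n_unmapped = int(round(n_mapped * (1 - mf) / mf)) if mf > 0 else 0
    chrom = np.concatenate([
        np.full(n_on, cfg.chrom, dtype=object),
        np.full(n_off, "chrDecoy", dtype=object),
        np.full(n_unmapped, "*", dtype=object),
    ])
    start = np.concatenate([on_starts, off_starts, np.zeros(n_unmapped, dtype=np.int64)])
    end = np.concatenate([on_ends, off_starts + cfg.read_len, np.zeros(n_unmapped, dtype=np.int64)])
    mapped = np.concatenate([
        np.ones(n_mapped, dtype=bool), np.zeros(n_unmapped, dtype=bool)
    ])
    return pd.DataFrame({"chrom": chrom, "start": start, "end": end, "mapped": mapped})


# ---------------------------------------------------------------------------
# per-sample and pooled pileups
# ---------------------------------------------------------------------------


def simulate_sample_pileup(
    truth: TruthSet,
    panel: TargetPanel,
    cfg: SimConfig,
    sample_id: str,
    replicate: int = 0,
) -> tuple[list[SiteAlleleCounts], pd.DataFrame]:
    """One sample's site allele counts and read placements.

    Per-amplicon depth is log-normal around ``mean_depth`` (constant across
    the amplicon's bases); at each truth site the four base counts are a
    multinomial draw at the genotype's allele fraction (dosage/2) under the
    substitution-error model.
    """
    if sample_id not in truth.genotypes:
        raise KeyError(f"unknown sample {sample_id!r}")
    rng = _rng(cfg, "sample", zlib.crc32(sample_id.encode()), replicate)
    depths = _amplicon_depths(cfg, len(panel.amplicons), rng)
    site_depths = _site_depth_map(panel, depths, truth)
    fractions = {
        v.site: nonref_dosage(truth.genotypes[sample_id][v.site], v.ref_base) / 2.0
        for v in truth.sites
    }
    pileup = _pileup_from_fractions(truth, fractions, site_depths, cfg, rng)
    reads = _tiling_reads(panel, depths, cfg)
    return pileup, reads


def simulate_pool_pileup(
    truth: TruthSet,
    spec: PoolSpec,
    panel: TargetPanel,
    cfg: SimConfig,
    replicate: int = 0,
) -> list[SiteAlleleCounts]:
    """One pooled library's site allele counts.

    The per-site success probability is the dosage-weighted composite
    fraction of the pool members, adjusted by the same substitution-error
    model; depth follows the per-amplicon log-normal model. Distinct
    ``replicate`` values give independent technical replicates.
    """
    missing = [m for m in spec.member_ids if m not in truth.genotypes]
    if missing:
        raise KeyError(f"pool members absent from truth: {missing}")
    rng = _rng(cfg, "pool", zlib.crc32("|".join(spec.member_ids).encode()), replicate)
    depths = _amplicon_depths(cfg, len(panel.amplicons), rng)
    site_depths = _site_depth_map(panel, depths, truth)
    fractions = truth.pooled_fractions(spec)
    return _pileup_from_fractions(truth, fractions, site_depths, cfg, rng)
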