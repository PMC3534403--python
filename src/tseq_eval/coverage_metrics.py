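"""Enrichment and coverage-breadth metrics over an amplicon panel.

Implements the standard targeted-resequencing QC battery: mapped/on-target
specificity, average depth of coverage (ADoC) over analyzable target
bases, breadth-at-depth fractions C1/C20/C30/C50/C100, and coverage
uniformity as the fraction of target bases at >= 0.2x the mean depth.

Two conventions, both configurable:

* on-target membership uses the *full* amplicon span (primer footprints
  included) — enrichment reads genuinely cover primers;
* depth and breadth metrics use the *primer-excluded* interior only,
  because variant analysis is impossible under a primer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .io_formats import TargetPanel
from .util import fmt_pct, round_half_up

__all__ = [
    "ReadPlacement",
    "DepthProfile",
    "CoverageReport",
    "reads_to_frame",
    "depth_profile",
    "on_target_stats",
    "coverage_fraction",
    "uniformity_0_2x",
    "summarize_coverage",
]


class ReadPlacement(NamedTuple):
    """A mapped (or unmapped) read's genomic footprint."""

    chrom: str
    start: int
    end: int
    mapped: bool = True


READ_COLUMNS = ["chrom", "start", "end", "mapped"]


def reads_to_frame(reads) -> pd.DataFrame:
    """Normalise a read stream (iterable of ReadPlacement or DataFrame) to a frame."""
    if isinstance(reads, pd.DataFrame):
        missing = [c for c in READ_COLUMNS if c not in reads.columns]
        if missing:
            raise ValueError(f"read frame lacks columns {missing}")
        return reads
    rows = list(reads)
    if not rows:
        return pd.DataFrame(columns=READ_COLUMNS)
    return pd.DataFrame(rows, columns=READ_COLUMNS)


@dataclass
class DepthProfile:
    """Per-amplicon arrays of per-base depth over analyzable target bases."""

    depths: dict[str, np.ndarray]  # amplicon id -> int array

    def __post_init__(self) -> None:
        for amp_id, arr in self.depths.items():
            arr = np.asarray(arr)
            if arr.size and arr.min() < 0:
                raise ValueError(f"amplicon {amp_id}: negative depth")
            self.depths[amp_id] = arr

    @property
    def n_bases(self) -> int:
        return int(sum(arr.size for arr in self.depths.values()))

    def concatenated(self) -> np.ndarray:
        if not self.depths:
            return np.zeros(0, dtype=int)
        return np.concatenate([np.asarray(v) for v in self.depths.values()])

    @property
    def mean_depth(self) -> float:
        flat = self.concatenated()
        if flat.size == 0:
            raise ValueError("no target bases in profile")
        return float(flat.mean())


@dataclass
class CoverageReport:
    """Per-sample enrichment summary (one row of the coverage report table)."""

    sample_id: str
    reads_total: int
    mapped_pct: Optional[float]
    on_target_pct: Optional[float]
    adoc: Optional[float]
    c1: Optional[float]
    c20: Optional[float]
    c30: Optional[float]
    c50: Optional[float]
    c100: Optional[float]
    uniformity_0_2x: Optional[float]

    def __post_init__(self) -> None:
        cks = [self.c1, self.c20, self.c30, self.c50, self.c100]
        present = [c for c in cks if c is not None]
        if any(not (0.0 <= c <= 100.0) for c in present):
            raise ValueError("coverage fractions must lie in [0, 100]")
        if len(present) == len(cks) and any(
            a < b - 1e-9 for a, b in zip(cks, cks[1:])
        ):
            raise ValueError("coverage fractions must be non-increasing in depth")

    def to_record(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "reads_total": self.reads_total,
            "mapped_pct": fmt_pct(self.mapped_pct),
            "on_target_pct": fmt_pct(self.on_target_pct),
            "adoc": "NA" if self.adoc is None else f"{round_half_up(self.adoc, 1):.1f}",
            "c1": fmt_pct(self.c1),
            "c20": fmt_pct(self.c20),
            "c30": fmt_pct(self.c30),
            "c50": fmt_pct(self.c50),
            "c100": fmt_pct(self.c100),
            "uniformity_0_2x": fmt_pct(self.uniformity_0_2x),
        }


# ---------------------------------------------------------------------------
# depth accumulation
# ---------------------------------------------------------------------------


def depth_profile(reads, panel: TargetPanel) -> DepthProfile:
    """Per-base depth over analyzable target bases from mapped read placements.

    Each analyzable base's depth is the number of mapped reads overlapping
    it; read order is irrelevant. Reads on chromosomes absent from the
    panel contribute nothing (they are off-target, not an error).
    """
    frame = reads_to_frame(reads)
    mapped = frame[frame["mapped"].astype(bool)] if len(frame) else frame
    depths: dict[str, np.ndarray] = {}
    for chrom in panel.chroms():
        amps = [a for a in panel.amplicons if a.chrom == chrom]
        lo = min(a.start for a in amps)
        hi = max(a.end for a in amps)
        diff = np.zeros(hi - lo + 1, dtype=np.int64)
        sub = mapped[mapped["chrom"] == chrom] if len(mapped) else mapped
        if len(sub):
            starts = np.clip(sub["start"].to_numpy(np.int64), lo, hi) - lo
            ends = np.clip(sub["end"].to_numpy(np.int64), lo, hi) - lo
            keep = ends > starts
            np.add.at(diff, starts[keep], 1)
            np.add.at(diff, ends[keep], -1)
        cov = np.cumsum(diff)[:-1] if diff.size > 1 else np.zeros(0, dtype=np.int64)
        for a in amps:
            depths[a.id] = cov[a.analyzable_start - lo : a.analyzable_end - lo].copy()
    return DepthProfile(depths)


def _merge_intervals(ivals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not ivals:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for lo, hi in ivals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    arr = np.asarray(merged, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def on_target_stats(reads, panel: TargetPanel) -> tuple[int, int, int]:
    """(reads_total, mapped_count, on_target_count) over a read stream.

    A mapped read is on-target iff it overlaps at least one base of any
    amplicon, primer footprints included.
    """
    frame = reads_to_frame(reads)
    reads_total = int(len(frame))
    if reads_total == 0:
        return 0, 0, 0
    mapped_mask = frame["mapped"].astype(bool).to_numpy()
    mapped_count = int(mapped_mask.sum())
    on_target = 0
    sub = frame[mapped_mask]
    for chrom, grp in sub.groupby("chrom", observed=True, sort=False):
        starts, ends = _merge_intervals(panel.span_intervals(str(chrom)))
        if starts.size == 0:
            continue
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        idx = np.searchsorted(starts, e, side="left") - 1
        ok = (idx >= 0) & (np.where(idx >= 0, ends[np.clip(idx, 0, None)], 0) > s)
        on_target += int(ok.sum())
    return reads_total, mapped_count, on_target


# ---------------------------------------------------------------------------
# breadth and uniformity
# ---------------------------------------------------------------------------


def coverage_fraction(profile: DepthProfile, k: int) -> float:
    """Percentage of analyzable target bases covered at depth >= k."""
    if k < 1:
        raise ValueError("depth threshold k must be >= 1")
    flat = profile.concatenated()
    if flat.size == 0:
        raise ValueError("no target bases in profile")
    return float(100.0 * np.count_nonzero(flat >= k) / flat.size)


def uniformity_0_2x(profile: DepthProfile) -> float:
    """Percentage of target bases with depth >= 0.2 x mean depth.

    Scale-invariant by construction: the cutoff moves with the mean.
    """
    flat = profile.concatenated()
    if flat.size == 0:
        raise ValueError("no target bases in profile")
    mean = flat.mean()
    if mean <= 0:
        raise ValueError("mean depth is zero; uniformity undefined")
    return float(100.0 * np.count_nonzero(flat >= 0.2 * mean) / flat.size)


def summarize_coverage(
    reads, panel: TargetPanel, sample_id: str = ""
) -> CoverageReport:
    """Assemble the full per-sample coverage report from read placements."""
    frame = reads_to_frame(reads)
    reads_total, mapped, on_target = on_target_stats(frame, panel)
    if reads_total == 0:
        return CoverageReport(
            sample_id, 0, None, None, None, None, None, None, None, None, None
        )
    mapped_pct = 100.0 * mapped / reads_total
    on_target_pct = 100.0 * on_target / mapped if mapped else None
    profile = depth_profile(frame, panel)
    flat = profile.concatenated()
    if flat.size == 0:
        raise ValueError("panel has no analyzable bases")
    adoc = float(flat.mean())
    cks = {k: coverage_fraction(profile, k) for k in (1, 20, 30, 50, 100)}
    unif = uniformity_0_2x(profile) if adoc > 0 else None
    return CoverageReport(
        sample_id,
        reads_total,
        mapped_pct,
        on_target_pct,
        adoc,
        cks[1],
        cks[20],
        cks[30],
        cks[50],
        cks[100],
        unif,
    )
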