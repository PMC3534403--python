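"""Published benchmark count tables used as worked-example inputs.

These are the per-library summary *counts* reported by the six-sample
HapMap-trio amplicon-resequencing benchmark this package models: the
number of reference-genotyped SNPs and of undetected SNPs per library,
the positive-control/detection counts of the pooled libraries at each
minimum-count threshold, and the sequencing-capacity inputs. They are
inputs, not results: every derived percentage (false-negative rate,
sensitivity, FDR, samples-per-unit chain) is recomputed from them at run
time by the corresponding module.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = [
    "FnRateRow",
    "PoolCountRow",
    "FN_RATE_ROWS",
    "POOL_COUNT_ROWS",
    "CAPACITY_INPUTS",
]


class FnRateRow(NamedTuple):
    sample_id: str
    library_id: str
    n_reference_sites: int
    n_not_detected: int
    printed_fn_rate_pct: float


#: per-library detection counts and the printed FN-rate cell (percent)
FN_RATE_ROWS: tuple[FnRateRow, ...] = (
    FnRateRow("NA12003", "759L", 268, 0, 0.0),
    FnRateRow("NA12003", "765L", 268, 0, 0.0),
    FnRateRow("NA12003", "770L_BC1", 268, 2, 0.7),
    FnRateRow("NA12003", "792L_BC1", 268, 5, 1.9),
    FnRateRow("NA12004", "760L", 138, 0, 0.0),
    FnRateRow("NA12004", "766L", 138, 1, 0.7),
    FnRateRow("NA12004", "770L_BC2", 138, 3, 2.2),
    FnRateRow("NA12004", "792L_BC2", 138, 3, 2.2),
    FnRateRow("NA10838", "761L", 270, 2, 0.7),
    FnRateRow("NA10838", "770L_BC3", 270, 3, 1.1),
    FnRateRow("NA10838", "792L_BC3", 270, 2, 0.7),
    FnRateRow("NA11829", "762L", 274, 2, 0.7),
    FnRateRow("NA11829", "770L_BC4", 274, 43, 15.7),
    FnRateRow("NA11829", "792L_BC4", 274, 55, 20.1),
    FnRateRow("NA11830", "763L", 272, 0, 0.0),
    FnRateRow("NA11830", "792L_BC5", 272, 9, 3.3),
    FnRateRow("NA10856", "764L", 273, 1, 0.4),
    FnRateRow("NA10856", "770L_BC6", 273, 3, 1.1),
    FnRateRow("NA10856", "792L_BC6", 273, 4, 1.5),
)


class PoolCountRow(NamedTuple):
    min_nonref_count: int
    library_id: str
    n_positive_controls: int
    n_positive_detected: int
    n_total_detected: int
    printed_sensitivity_pct: float
    printed_fdr_pct: float


#: pooled-library detection counts per minimum non-reference count threshold
POOL_COUNT_ROWS: tuple[PoolCountRow, ...] = (
    PoolCountRow(5, "768_1L", 244, 226, 376, 92.6, 39.9),
    PoolCountRow(5, "768_2L", 244, 230, 371, 94.3, 38.0),
    PoolCountRow(10, "768_1L", 244, 212, 277, 86.9, 23.5),
    PoolCountRow(10, "768_2L", 244, 212, 267, 86.9, 20.6),
    PoolCountRow(20, "768_1L", 244, 193, 214, 79.1, 9.8),
    PoolCountRow(20, "768_2L", 244, 198, 221, 81.1, 10.4),
)


#: capacity-planning inputs of the benchmark: panel footprint, coverage
#: goal, and on-target bases available per octet (7,221,473 on-target
#: reads of 50 bp; the published constant is used as printed)
CAPACITY_INPUTS = {
    "target_bases": 172_805,
    "coverage_goal": 100,
    "available_bases_per_octet": 361_073_648,
    "units_per_flowcell": 8,
    "flowcells_per_run": 2,
}
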