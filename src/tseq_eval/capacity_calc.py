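"""Sequencing-capacity and multiplex planning arithmetic.

Given a target footprint and a coverage goal, how many samples fit in one
multiplexing unit (e.g. a SOLiD octet), one flow cell, and one run?
The chain is exact integer arithmetic: required bases per sample =
target_bases x coverage goal; samples per unit = floor(available
on-target bases per unit / required); flow cell and run totals multiply
by the number of units (default 8 wells per flow cell, 2 flow cells per
run).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CapacityPlan",
    "required_bases",
    "samples_per_unit",
    "build_plan",
    "DEFAULT_TARGET_BASES",
]

#: default panel footprint (bases); the study panel's summed amplicon length
DEFAULT_TARGET_BASES = 172_805


@dataclass(frozen=True)
class CapacityPlan:
    target_bases: int
    mean_coverage_goal: int
    required_bases_per_sample: int
    available_on_target_bases_per_unit: int
    samples_per_unit: int
    units_per_flowcell: int
    flowcells_per_run: int
    samples_per_flowcell: int
    samples_per_run: int

    def to_record(self) -> dict:
        return {
            "target_bases": self.target_bases,
            "mean_coverage_goal": self.mean_coverage_goal,
            "required_bases_per_sample": self.required_bases_per_sample,
            "available_on_target_bases_per_unit": self.available_on_target_bases_per_unit,
            "samples_per_unit": self.samples_per_unit,
            "units_per_flowcell": self.units_per_flowcell,
            "flowcells_per_run": self.flowcells_per_run,
            "samples_per_flowcell": self.samples_per_flowcell,
            "samples_per_run": self.samples_per_run,
        }


def required_bases(target_bases: int, coverage_goal: int) -> int:
    """Bases of on-target sequence needed for one sample: exact product."""
    if target_bases <= 0 or coverage_goal <= 0:
        raise ValueError("target_bases and coverage_goal must be positive")
    return int(target_bases) * int(coverage_goal)


def samples_per_unit(available_bases: int, required: int) -> int:
    """Whole samples fitting in one multiplexing unit (floor division)."""
    if required <= 0:
        raise ValueError("required bases per sample must be positive")
    if available_bases < 0:
        raise ValueError("available bases cannot be negative")
    return int(available_bases) // int(required)


def build_plan(
    target_bases: int = DEFAULT_TARGET_BASES,
    coverage_goal: int = 100,
    available_bases: int = 361_073_648,
    units_per_flowcell: int = 8,
    flowcells_per_run: int = 2,
) -> CapacityPlan:
    """Assemble the full multiplexing plan from the capacity chain."""
    if units_per_flowcell <= 0 or flowcells_per_run <= 0:
        raise ValueError("unit counts must be positive")
    req = required_bases(target_bases, coverage_goal)
    per_unit = samples_per_unit(available_bases, req)
    per_flowcell = per_unit * units_per_flowcell
    return CapacityPlan(
        target_bases=int(target_bases),
        mean_coverage_goal=int(coverage_goal),
        required_bases_per_sample=req,
        available_on_target_bases_per_unit=int(available_bases),
        samples_per_unit=per_unit,
        units_per_flowcell=int(units_per_flowcell),
        flowcells_per_run=int(flowcells_per_run),
        samples_per_flowcell=per_flowcell,
        samples_per_run=per_flowcell * int(flowcells_per_run),
    )
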