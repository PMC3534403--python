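"""Readers and writers for the external formats the pipeline touches.

Covers the amplicon target panel (BED / GFF), per-site allele counts
(samtools text pileup or a simple TSV dialect), HapMap-style genotype
tables, PED pedigrees, and the TSV/JSON report serialisation.

All internal coordinates are 0-based half-open; conversion from the
1-based inclusive conventions of GFF, pileup and genotype tables happens
only here, at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

__all__ = [
    "ParseError",
    "PanelValidationError",
    "Amplicon",
    "TargetPanel",
    "SiteAlleleCounts",
    "ReferenceGenotype",
    "Trio",
    "read_target_panel",
    "write_target_panel",
    "read_pileup",
    "parse_pileup_bases",
    "write_pileup",
    "read_genotype_table",
    "write_genotype_table",
    "read_pedigree",
    "write_pedigree",
    "write_report",
]

BASES = ("A", "C", "G", "T")
MISSING_GENOTYPE_TOKEN = "NN"


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""

    def __init__(self, message: str, path: object = None, lineno: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
        if lineno is not None:
            loc = f"{loc}:{lineno}" if loc else f"line {lineno}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.lineno = lineno


class PanelValidationError(ValueError):
    """Panel content violates a structural invariant (duplicate ids, ...)."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Amplicon:
    """One PCR amplicon of the target panel.

    ``start``/``end`` are 0-based half-open genomic coordinates of the full
    amplicon span including the primer footprints; the primer lengths at
    either end delimit the analyzable interior where variant analysis is
    allowed (primer-derived bases reflect primer sequence, not template).
    """

    id: str
    chrom: str
    start: int
    end: int
    fwd_primer_len: int = 0
    rev_primer_len: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PanelValidationError(
                f"amplicon {self.id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.fwd_primer_len < 0 or self.rev_primer_len < 0:
            raise PanelValidationError(f"amplicon {self.id}: negative primer length")
        if self.fwd_primer_len + self.rev_primer_len >= self.end - self.start:
            raise PanelValidationError(
                f"amplicon {self.id}: primer footprints cover the whole amplicon"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def analyzable_start(self) -> int:
        return self.start + self.fwd_primer_len

    @property
    def analyzable_end(self) -> int:
        return self.end - self.rev_primer_len

    @property
    def analyzable_length(self) -> int:
        return self.analyzable_end - self.analyzable_start


@dataclass
class TargetPanel:
    """The amplicon panel defining on-target membership and the coverage denominator."""

    amplicons: list[Amplicon]
    genome_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for amp in self.amplicons:
            if amp.id in seen:
                raise PanelValidationError(f"duplicate amplicon id {amp.id!r}")
            seen.add(amp.id)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    @property
    def total_analyzable_bases(self) -> int:
        return sum(a.analyzable_length for a in self.amplicons)

    @property
    def total_span_bases(self) -> int:
        return sum(a.length for a in self.amplicons)

    def chroms(self) -> list[str]:
        out: list[str] = []
        for a in self.amplicons:
            if a.chrom not in out:
                out.append(a.chrom)
        return out

    def analyzable_intervals(self, chrom: str) -> list[tuple[int, int]]:
        ivals = [
            (a.analyzable_start, a.analyzable_end)
            for a in self.amplicons
            if a.chrom == chrom
        ]
        return sorted(ivals)

    def span_intervals(self, chrom: str) -> list[tuple[int, int]]:
        ivals = [(a.start, a.end) for a in self.amplicons if a.chrom == chrom]
        return sorted(ivals)

    def contains_analyzable(self, chrom: str, pos: int) -> bool:
        """True iff (chrom, pos) lies in the primer-excluded interior of an amplicon."""
        for lo, hi in self.analyzable_intervals(chrom):
            if lo <= pos < hi:
                return True
            if lo > pos:
                break
        return False


@dataclass(frozen=True)
class SiteAlleleCounts:
    """Per-position A/C/G/T observation counts — the caller's sole evidence."""

    chrom: str
    pos: int  # 0-based
    ref_base: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.ref_base not in BASES:
            raise ValueError(f"ref_base must be one of {BASES}, got {self.ref_base!r}")
        counts = {b: int(self.counts.get(b, 0)) for b in BASES}
        if any(v < 0 for v in counts.values()):
            raise ValueError("negative allele count")
        object.__setattr__(self, "counts", counts)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def ref_count(self) -> int:
        return self.counts[self.ref_base]


@dataclass(frozen=True)
class ReferenceGenotype:
    """One sample's genotype at one site in a reference (e.g. HapMap) table.

    ``alleles`` is an unordered base pair stored sorted, or None for an
    explicitly missing genotype.
    """

    sample_id: str
    chrom: str
    pos: int  # 0-based
    alleles: Optional[tuple[str, str]]
    rsid: str = ""

    def __post_init__(self) -> None:
        if self.alleles is not None:
            a, b = self.alleles
            if a not in BASES or b not in BASES:
                raise ValueError(f"invalid alleles {self.alleles!r}")
            object.__setattr__(self, "alleles", tuple(sorted((a, b))))

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]


@dataclass(frozen=True)
class Trio:
    father_id: str
    mother_id: str
    child_id: str
    family_id: str = ""

    def __post_init__(self) -> None:
        if len({self.father_id, self.mother_id, self.child_id}) != 3:
            raise ValueError("trio members must be three distinct individuals")

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.father_id, self.mother_id, self.child_id)


# ---------------------------------------------------------------------------
# target panel I/O
# ---------------------------------------------------------------------------


def _infer_panel_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return "bed"
    if suffix in (".gff", ".gff3", ".gtf"):
        return "gff"
    raise ValueError(f"cannot infer panel format from {path.name!r}; pass format=")


def read_target_panel(path: str | Path, format: str | None = None) -> TargetPanel:
    """Read an amplicon panel from BED (0-based half-open) or GFF (1-based inclusive).

    BED columns: chrom, start, end, name, [fwd_primer_len, rev_primer_len].
    GFF: standard 9 columns; the amplicon id is taken from the ``ID`` (or
    ``Name``) attribute and primer lengths from ``fwd_primer_len`` /
    ``rev_primer_len`` attributes when present.
    """
    path = Path(path)
    fmt = (format or _infer_panel_format(path)).lower()
    if fmt not in ("bed", "gff"):
        raise ValueError(f"unknown panel format {format!r}")
    amplicons: list[Amplicon] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if fmt == "bed":
                    amplicons.append(_parse_bed_fields(fields))
                else:
                    amp = _parse_gff_fields(fields)
                    if amp is not None:
                        amplicons.append(amp)
            except PanelValidationError:
                raise
            except ParseError as exc:
                raise ParseError(str(exc.args[0]).split(": ", 1)[-1], path, lineno) from None
            except (ValueError, IndexError) as exc:
                raise ParseError(f"malformed {fmt.upper()} line: {exc}", path, lineno) from None
    return TargetPanel(amplicons, genome_label=path.stem)


def _parse_bed_fields(fields: Sequence[str]) -> Amplicon:
    if len(fields) < 4:
        raise ParseError("expected at least 4 BED columns (chrom, start, end, name)")
    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    fwd = int(fields[4]) if len(fields) > 4 else 0
    rev = int(fields[5]) if len(fields) > 5 else 0
    return Amplicon(name, chrom, start, end, fwd, rev)


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:  # GFF3: key=value
            key, _, value = chunk.partition("=")
        else:  # GFF2/GTF: key "value"
            key, _, value = chunk.partition(" ")
        out[key.strip()] = value.strip().strip('"')
    return out


def _parse_gff_fields(fields: Sequence[str]) -> Amplicon | None:
    if len(fields) < 9:
        raise ParseError("expected 9 GFF columns")
    chrom = fields[0]
    start1, end1 = int(fields[3]), int(fields[4])
    attrs = _parse_gff_attributes(fields[8])
    amp_id = attrs.get("ID") or attrs.get("Name") or attrs.get("amplicon_id")
    if amp_id is None:
        raise ParseError("GFF record lacks an ID/Name attribute for the amplicon id")
    fwd = int(attrs.get("fwd_primer_len", 0))
    rev = int(attrs.get("rev_primer_len", 0))
    # GFF is 1-based inclusive: [start1, end1] -> 0-based half-open [start1-1, end1)
    return Amplicon(amp_id, chrom, start1 - 1, end1, fwd, rev)


def write_target_panel(panel: TargetPanel, path: str | Path, format: str = "bed") -> None:
    fmt = format.lower()
    with open(path, "w") as fh:
        for amp in panel.amplicons:
            if fmt == "bed":
                fh.write(
                    f"{amp.chrom}\t{amp.start}\t{amp.end}\t{amp.id}"
                    f"\t{amp.fwd_primer_len}\t{amp.rev_primer_len}\n"
                )
            elif fmt == "gff":
                attrs = (
                    f"ID={amp.id};fwd_primer_len={amp.fwd_primer_len}"
                    f";rev_primer_len={amp.rev_primer_len}"
                )
                fh.write(
                    f"{amp.chrom}\tpanel\tamplicon\t{amp.start + 1}\t{amp.end}"
                    f"\t.\t+\t.\t{attrs}\n"
                )
            else:
                raise ValueError(f"unknown panel format {format!r}")


# ---------------------------------------------------------------------------
# pileup I/O
# ---------------------------------------------------------------------------

_PILEUP_SKIP = frozenset("><")


def parse_pileup_bases(bases: str, ref_base: str) -> dict[str, int]:
    """Tally the bases column of a samtools text pileup into A/C/G/T counts.

    ``.``/``,`` count toward the reference base; read-start (``^`` plus its
    mapping-quality character), read-end (``$``), indel (``+N<seq>`` /
    ``-N<seq>``) and deletion-placeholder (``*``) markers are stripped;
    ``N``/``n`` observations and reference-skip marks are ignored.
    """
    ref = ref_base.upper()
    counts = dict.fromkeys(BASES, 0)
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c in ".,":
            counts[ref] += 1
            i += 1
        elif c in "^":
            i += 2  # '^' is followed by a mapping-quality character
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ParseError(f"indel marker {c!r} without length at column {i}")
            i = j + int(bases[i + 1 : j])
        elif c == "*":
            i += 1
        elif c.upper() in BASES:
            counts[c.upper()] += 1
            i += 1
        elif c.upper() == "N" or c in _PILEUP_SKIP:
            i += 1
        else:
            raise ParseError(f"unknown pileup base symbol {c!r} at column {i}")
    return counts


def read_pileup(
    path: str | Path, dialect: str = "samtools-pileup"
) -> Iterator[SiteAlleleCounts]:
    """Stream per-site allele counts from a pileup-like text file.

    Dialects:

    * ``samtools-pileup`` — chrom, 1-based pos, ref base, depth, bases,
      [qualities]; counts are tallied from the bases column. A depth field
      inconsistent with the tallied bases triggers a warning and the tally
      wins.
    * ``simple-tsv`` — header ``chrom  pos  ref  A  C  G  T`` with 0-based
      positions and explicit counts.
    """
    path = Path(path)
    if dialect in ("samtools-pileup", "samtools", "pileup"):
        yield from _read_samtools_pileup(path)
    elif dialect in ("simple-tsv", "simple", "tsv"):
        yield from _read_simple_tsv(path)
    else:
        raise ValueError(f"unknown pileup dialect {dialect!r}")


def _read_samtools_pileup(path: Path) -> Iterator[SiteAlleleCounts]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError("expected >=5 pileup columns", path, lineno)
            chrom, pos1, ref = fields[0], int(fields[1]), fields[2].upper()
            try:
                counts = parse_pileup_bases(fields[4], ref)
            except ParseError as exc:
                raise ParseError(str(exc.args[0]), path, lineno) from None
            declared = int(fields[3])
            tallied = sum(counts.values())
            if declared != tallied:
                warnings.warn(
                    f"{path}:{lineno}: declared depth {declared} != tallied {tallied}; "
                    "using the tally",
                    stacklevel=2,
                )
            yield SiteAlleleCounts(chrom, pos1 - 1, ref, counts)


def _read_simple_tsv(path: Path) -> Iterator[SiteAlleleCounts]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["chrom", "pos", "ref", "A", "C", "G", "T"]
        if [h.strip() for h in header[:7]] != expected:
            raise ParseError(f"expected header {expected}", path, 1)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError("expected 7 columns", path, lineno)
            counts = {b: int(v) for b, v in zip(BASES, fields[3:7])}
            yield SiteAlleleCounts(fields[0], int(fields[1]), fields[2].upper(), counts)


def write_pileup(sites: Iterable[SiteAlleleCounts], path: str | Path) -> None:
    """Write sites in the simple-tsv dialect (0-based, explicit counts)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\tA\tC\tG\tT\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref_base}\t"
                + "\t".join(str(s.counts[b]) for b in BASES)
                + "\n"
            )


# ---------------------------------------------------------------------------
# genotype table I/O
# ---------------------------------------------------------------------------


def read_genotype_table(path: str | Path) -> list[ReferenceGenotype]:
    """Read a HapMap-style genotype table.

    Tab-separated; header ``rsid  chrom  pos  <sample1>  <sample2> ...``
    with 1-based positions. Genotype cells are two-letter allele pairs from
    ACGT or the missing token ``NN``.
    """
    path = Path(path)
    out: list[ReferenceGenotype] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 4:
            raise ParseError("expected >=4 columns (rsid, chrom, pos, samples...)", path, 1)
        samples = header[3:]
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"expected {len(header)} columns, got {len(fields)}", path, lineno
                )
            rsid, chrom, pos0 = fields[0], fields[1], int(fields[2]) - 1
            for sample, cell in zip(samples, fields[3:]):
                cell = cell.strip().upper()
                if cell == MISSING_GENOTYPE_TOKEN:
                    alleles = None
                elif len(cell) == 2 and cell[0] in BASES and cell[1] in BASES:
                    alleles = (cell[0], cell[1])
                else:
                    raise ParseError(f"bad genotype cell {cell!r}", path, lineno)
                out.append(ReferenceGenotype(sample, chrom, pos0, alleles, rsid))
    return out


def write_genotype_table(
    genotypes: Sequence[ReferenceGenotype], path: str | Path
) -> None:
    """Write genotypes in the dialect read_genotype_table expects (1-based pos)."""
    samples: list[str] = []
    sites: list[tuple[str, int, str]] = []
    cells: dict[tuple[str, int], dict[str, str]] = {}
    for g in genotypes:
        if g.sample_id not in samples:
            samples.append(g.sample_id)
        key = (g.chrom, g.pos)
        if key not in cells:
            cells[key] = {}
            sites.append((g.chrom, g.pos, g.rsid))
        cells[key][g.sample_id] = (
            MISSING_GENOTYPE_TOKEN if g.alleles is None else "".join(g.alleles)
        )
    sites.sort(key=lambda s: (s[0], s[1]))
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\t" + "\t".join(samples) + "\n")
        for chrom, pos, rsid in sites:
            row = cells[(chrom, pos)]
            fh.write(
                f"{rsid or '.'}\t{chrom}\t{pos + 1}\t"
                + "\t".join(row.get(s, MISSING_GENOTYPE_TOKEN) for s in samples)
                + "\n"
            )


# ---------------------------------------------------------------------------
# pedigree I/O
# ---------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> list[Trio]:
    """Read PED-style trios: one Trio per child row with both parents non-founder.

    Columns: family, individual, father, mother (extra columns ignored);
    ``0`` marks a founder parent. A child naming a parent absent from the
    file is a validation error.
    """
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    individuals: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError("expected >=4 PED columns", path, lineno)
            rows.append((lineno, fields))
            individuals.add(fields[1])
    trios: list[Trio] = []
    for lineno, fields in rows:
        family, child, father, mother = fields[:4]
        if father == "0" or mother == "0":
            continue
        for parent in (father, mother):
            if parent not in individuals:
                raise ParseError(
                    f"child {child} cites unknown parent {parent}", path, lineno
                )
        trios.append(Trio(father, mother, child, family))
    return trios


def write_pedigree(trios: Sequence[Trio], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trios:
            fam = t.family_id or "FAM"
            fh.write(f"{fam}\t{t.father_id}\t0\t0\t1\t0\n")
            fh.write(f"{fam}\t{t.mother_id}\t0\t0\t2\t0\n")
            fh.write(f"{fam}\t{t.child_id}\t{t.father_id}\t{t.mother_id}\t0\t0\n")


# ---------------------------------------------------------------------------
# report serialisation
# ---------------------------------------------------------------------------


def _records_of(report) -> list[dict]:
    if isinstance(report, (list, tuple)):
        return [rec for item in report for rec in _records_of(item)]
    if hasattr(report, "to_record"):
        return [report.to_record()]
    if dataclasses.is_dataclass(report):
        return [dataclasses.asdict(report)]
    if isinstance(report, dict):
        return [report]
    raise TypeError(f"cannot serialise report of type {type(report).__name__}")


def write_report(report, path: str | Path, format: str = "tsv") -> None:
    """Serialise one report (or a homogeneous list) to TSV or JSON.

    Column order follows the report type's field order; repeated writes of
    the same report are byte-identical. Percentage fields are already
    formatted to one decimal by the report's ``to_record``.
    """
    records = _records_of(report)
    fmt = format.lower()
    if fmt == "tsv":
        if not records:
            Path(path).write_text("")
            return
        cols = list(records[0].keys())
        lines = ["\t".join(cols)]
        for rec in records:
            lines.append("\t".join(str(rec.get(c, "NA")) for c in cols))
        Path(path).write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        Path(path).write_text(json.dumps(records, indent=2, sort_keys=False) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
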