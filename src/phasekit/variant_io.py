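"""Readers and writers for the formats the toolkit touches.

VCF (via pysam), the haplotag read table (TSV), Nanopolish-style
per-read methylation calls (TSV) and BED regions, plus the domain
records the rest of the package operates on.

Coordinate conventions: ``VariantRecord.pos`` is 1-based (VCF
convention); read spans, methylation sites and regions are 0-based
half-open. Conversion happens only at intersection points, never
inside the algorithms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: INFO key carrying the names of reads supporting an SV call. The SV
#: caller dialect is configurable; RNAMES is the common long-read default.
DEFAULT_RNAMES_KEY = "RNAMES"

SV_TYPES = ("DEL", "INS", "DUP", "INV", "BND")


class VcfParseError(ValueError):
    """Raised when a VCF row cannot be interpreted."""


class TableParseError(ValueError):
    """Raised when a TSV row cannot be interpreted."""


@dataclass
class VariantRecord:
    """One VCF row after multiallelic splitting (single ALT).

    ``gt`` holds the two allele indices restricted to {0 (REF), 1 (this
    ALT)}; ``phased`` mirrors the ``|`` separator and implies ``ps`` is
    set. SV annotations are populated from INFO when present.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    id: str | None = None
    qual: float | None = None
    filter: frozenset[str] = frozenset()
    gt: tuple[int, int] = (0, 1)
    phased: bool = False
    ps: int | None = None
    sv_type: str | None = None  # DEL/INS/DUP/INV/BND or None
    sv_len: int | None = None
    supporting_reads: tuple[str, ...] = ()
    conflict: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if any(a not in (0, 1) for a in self.gt):
            raise ValueError(f"allele indices must be 0/1, got {self.gt}")
        if self.phased and self.ps is None:
            raise ValueError("phased record requires a PS identifier")
        if self.sv_type is not None and self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")

    @property
    def is_sv(self) -> bool:
        return self.sv_type is not None

    @property
    def is_het(self) -> bool:
        return self.gt[0] != self.gt[1]

    def replace(self, **changes) -> "VariantRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class HaplotagRecord:
    """One haplotagged read: the HP/PS information a haplotagger
    writes into alignment tags, carried as a table row."""

    read_name: str
    chrom: str
    start: int  # 0-based half-open span
    end: int
    hp: int  # 1 or 2
    ps: int

    def __post_init__(self) -> None:
        if self.hp not in (1, 2):
            raise ValueError(f"hp must be 1 or 2, got {self.hp}")
        if not self.start < self.end:
            raise ValueError(f"empty read span [{self.start}, {self.end})")


@dataclass
class MethylationCall:
    """One per-read methylation observation over a CpG group.

    ``llr`` is the log-likelihood ratio of methylated vs unmethylated
    (positive = methylated). ``hp``/``ps`` start as ``"."`` and are
    filled in by the methylation phaser; they are either both set or
    both ``"."``.
    """

    read_name: str
    chrom: str
    start: int  # 0-based
    end: int
    llr: float
    num_motifs: int = 1
    hp: int | str = "."
    ps: int | str = "."

    def __post_init__(self) -> None:
        if self.num_motifs < 1:
            raise ValueError("num_motifs must be >= 1")
        if (self.hp == ".") != (self.ps == "."):
            raise ValueError("hp and ps must be set together or both '.'")


@dataclass(frozen=True)
class Region:
    """A named BED interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty region [{self.start}, {self.end})")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _split_alt_gt(raw_gt: Sequence[int | None], alt_index: int) -> tuple[int, int] | None:
    """Map a raw GT onto {0,1} for a single ALT (1-based alt_index).

    Alleles equal to this ALT become 1; everything else (REF or another
    ALT) becomes 0. Missing alleles make the genotype unusable.
    """
    if len(raw_gt) != 2:
        raise VcfParseError(f"non-diploid genotype {raw_gt}; only diploid GTs are supported")
    if any(a is None for a in raw_gt):
        return None
    return tuple(1 if a == alt_index else 0 for a in raw_gt)  # type: ignore[return-value]


def read_vcf(path: str | Path, rnames_key: str = DEFAULT_RNAMES_KEY) -> list[VariantRecord]:
    """Read a (possibly bgzipped) single-sample VCF into VariantRecords.

    Multiallelic rows are split into one record per ALT. Phased GTs
    (``a|b``) set the phased flag and pull PS from FORMAT; records with
    a missing GT are skipped with a warning.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for n, rec in enumerate(vcf, start=1):
            try:
                records.extend(_convert_pysam_record(rec, rnames_key))
            except VcfParseError:
                raise
            except Exception as exc:  # pragma: no cover - htslib edge cases
                raise VcfParseError(f"cannot parse VCF record {n} at {rec.chrom}:{rec.pos}: {exc}") from exc
    return records


def _convert_pysam_record(rec, rnames_key: str) -> list[VariantRecord]:
    if not rec.samples:
        raise VcfParseError(f"record at {rec.chrom}:{rec.pos} has no sample column")
    sample = rec.samples[0]
    raw_gt = sample.get("GT")
    if raw_gt is None or all(a is None for a in raw_gt):
        warnings.warn(f"missing GT at {rec.chrom}:{rec.pos}; record skipped")
        return []

    ps = sample.get("PS")
    phased = bool(sample.phased)
    info = dict(rec.info)
    sv_type = info.get("SVTYPE")
    if isinstance(sv_type, tuple):
        sv_type = sv_type[0]
    sv_len = info.get("SVLEN")
    if isinstance(sv_len, tuple):
        sv_len = sv_len[0]
    raw_names = info.get(rnames_key, ())
    if isinstance(raw_names, str):
        raw_names = raw_names.split(",")
    supporting = tuple(dict.fromkeys(raw_names))
    conflict = info.get("CONFLICT")

    filters = frozenset(rec.filter.keys())
    out: list[VariantRecord] = []
    alts = rec.alts or ()
    for alt_index, alt in enumerate(alts, start=1):
        gt = _split_alt_gt(raw_gt, alt_index)
        if gt is None:
            warnings.warn(f"half-missing GT at {rec.chrom}:{rec.pos}; record skipped")
            continue
        out.append(
            VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                id=rec.id,
                ref=rec.ref,
                alt=alt,
                # htslib stores QUAL as float32; undo the precision loss
                qual=round(rec.qual, 4) if rec.qual is not None else None,
                filter=filters,
                gt=gt,
                phased=phased,
                ps=int(ps) if (phased and ps is not None) else None,
                sv_type=sv_type,
                sv_len=int(sv_len) if sv_len is not None else None,
                supporting_reads=supporting,
                conflict=int(conflict) if conflict is not None else None,
            )
        )
    return out


def _build_header(
    records: Sequence[VariantRecord], sample: str, rnames_key: str
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=phasekit_lowqual,Description="QUAL below the automatic bimodal threshold">')
    header.add_line('##FILTER=<ID=trio_discordant,Description="Phase disagrees with the parental majority of its block">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Structural variant length">')
    header.add_line(f'##INFO=<ID={rnames_key},Number=.,Type=String,Description="Names of reads supporting the SV">')
    header.add_line('##INFO=<ID=CONFLICT,Number=1,Type=Integer,Description="Supporting reads in conflict with the assigned haplotype/phase set">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set identifier">')
    for fset in (r.filter for r in records):
        for f in fset:
            if f not in ("PASS", ".") and f not in header.filters:
                header.add_line(f'##FILTER=<ID={f},Description="{f}">')
    seen: dict[str, None] = {}
    for rec in records:
        seen.setdefault(rec.chrom, None)
    for chrom in seen:
        header.contigs.add(chrom)
    header.add_sample(sample)
    return header


def write_phased_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample: str = "SAMPLE",
    rnames_key: str = DEFAULT_RNAMES_KEY,
) -> None:
    """Write records as a VCF 4.2 with FORMAT/PS and INFO/CONFLICT.

    Input must be sorted by (chrom, pos) with each contig contiguous;
    phased genotypes come out as ``a|b`` with their PS, unphased as
    ``a/b`` without one.
    """
    _check_sorted(records)
    header = _build_header(records, sample, rnames_key)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
                id=rec.id,
                qual=rec.qual,
            )
            for f in sorted(rec.filter):
                row.filter.add(f)
            if rec.sv_type is not None:
                row.info["SVTYPE"] = rec.sv_type
            if rec.sv_len is not None:
                row.info["SVLEN"] = rec.sv_len
            if rec.supporting_reads:
                row.info[rnames_key] = rec.supporting_reads
            if rec.conflict is not None:
                row.info["CONFLICT"] = rec.conflict
            row.samples[sample]["GT"] = rec.gt
            row.samples[sample].phased = rec.phased
            if rec.phased and rec.ps is not None:
                row.samples[sample]["PS"] = rec.ps
            out.write(row)


def _check_sorted(records: Sequence[VariantRecord]) -> None:
    seen_chroms: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = 0
    for rec in records:
        if rec.chrom != prev_chrom:
            if rec.chrom in seen_chroms:
                raise ValueError(f"records not sorted: contig {rec.chrom} appears twice")
            seen_chroms.add(rec.chrom)
            prev_chrom = rec.chrom
            prev_pos = 0
        if rec.pos < prev_pos:
            raise ValueError(f"records not sorted at {rec.chrom}:{rec.pos}")
        prev_pos = rec.pos


def parse_supporting_reads(record: VariantRecord) -> tuple[str, ...]:
    """Supporting-read names of an SV record, deduplicated in order."""
    return tuple(dict.fromkeys(record.supporting_reads))


# ---------------------------------------------------------------------------
# Haplotag table
# ---------------------------------------------------------------------------

HAPLOTAG_COLUMNS = ("read_name", "chrom", "start", "end", "hp", "ps")


def read_haplotag_table(path: str | Path) -> list[HaplotagRecord]:
    """Read the 6-column haplotag TSV (read_name chrom start end hp ps).

    ``#`` lines are comments. A read may carry only one tag per contig;
    hp outside {1,2} is rejected.
    """
    records: list[HaplotagRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(HAPLOTAG_COLUMNS):
                raise TableParseError(
                    f"{path}:{lineno}: expected {len(HAPLOTAG_COLUMNS)} columns, got {len(parts)}"
                )
            name, chrom, start, end, hp, ps = parts
            try:
                rec = HaplotagRecord(name, chrom, int(start), int(end), int(hp), int(ps))
            except ValueError as exc:
                raise TableParseError(f"{path}:{lineno}: {exc}") from exc
            key = (name, chrom)
            if key in seen:
                raise TableParseError(f"{path}:{lineno}: duplicate tag for read {name!r} on {chrom}")
            seen.add(key)
            records.append(rec)
    return records


def write_haplotag_table(records: Iterable[HaplotagRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(HAPLOTAG_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.read_name}\t{r.chrom}\t{r.start}\t{r.end}\t{r.hp}\t{r.ps}\n")


def tag_mapping(records: Iterable[HaplotagRecord]) -> dict[str, HaplotagRecord]:
    """Index tags by read name (single-contig convenience view)."""
    return {r.read_name: r for r in records}


# ---------------------------------------------------------------------------
# Methylation table
# ---------------------------------------------------------------------------

#: Nanopolish-style column names; remap via the ``columns`` argument.
METH_COLUMNS = {
    "chrom": "chromosome",
    "start": "start",
    "end": "end",
    "read_name": "read_name",
    "llr": "log_lik_ratio",
    "num_motifs": "num_motifs",
}


def read_methylation_tsv(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[MethylationCall]:
    """Read per-read methylation calls (tab-separated, with header).

    Uses the Nanopolish column layout by default; pass ``columns`` to
    remap logical field -> file column. HP/PS are read back when the
    file carries them (a previously phased table), else set to ``"."``.
    """
    colmap = dict(METH_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", comment=None)
    for logical, col in colmap.items():
        if col not in df.columns:
            raise TableParseError(f"{path}: missing required column {col!r} (for {logical})")
    has_phase = "hp" in df.columns and "ps" in df.columns
    calls: list[MethylationCall] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        hp: int | str = "."
        ps: int | str = "."
        if has_phase and str(d["hp"]) != ".":
            hp, ps = int(d["hp"]), int(d["ps"])
        calls.append(
            MethylationCall(
                read_name=str(d[colmap["read_name"]]),
                chrom=str(d[colmap["chrom"]]),
                start=int(d[colmap["start"]]),
                end=int(d[colmap["end"]]),
                llr=float(d[colmap["llr"]]),
                num_motifs=int(d[colmap["num_motifs"]]),
                hp=hp,
                ps=ps,
            )
        )
    return calls


def write_methylation_tsv(calls: Iterable[MethylationCall], path: str | Path) -> None:
    """Write calls in the default column layout plus hp/ps columns."""
    rows = [
        {
            "chromosome": c.chrom,
            "start": c.start,
            "end": c.end,
            "read_name": c.read_name,
            "log_lik_ratio": c.llr,
            "num_motifs": c.num_motifs,
            "hp": c.hp,
            "ps": c.ps,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["chromosome", "start", "end", "read_name",
                                "log_lik_ratio", "num_motifs", "hp", "ps"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Region]:
    """Read BED3+name regions (0-based half-open, as BED is)."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = parts[3] if len(parts) > 3 else "."
            regions.append(Region(parts[0], int(parts[1]), int(parts[2]), name))
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
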