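"""Phase structural variants from their haplotagged supporting reads.

An SV caller reports, for each call, the names of the reads that
support the alternative allele. When those reads have been
haplotagged (HP/PS) from the phased SNV scaffold, the SV itself can be
placed on a haplotype: the supporting reads should all come from the
same haplotype of the same phase set. Reads that disagree — the
minority haplotype within the dominant phase set, or a different
phase set altogether — are *conflicts*. The SV is phased only when
the number of conflicts is within a user threshold (0 by default, the
conservative setting: a single conflicting read blocks phasing), and
every SV record receives an INFO/CONFLICT count whether or not it was
phased.

When a callset carries no read names, an optional overlap fallback
treats every tagged read whose span contains the SV breakpoint(s) as
supporting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .variant_io import HaplotagRecord, VariantRecord

#: SV types whose second breakpoint is a real local coordinate
_SPAN_TYPES = ("DEL", "INV", "DUP")


@dataclass(frozen=True)
class SVPhasingParams:
    """Knobs of the SV phasing decision.

    conflict_threshold
        Maximum number of conflicting supporting reads tolerated
        before an SV is left unphased (0 = any conflict blocks).
    min_tagged_reads
        Minimum haplotagged supporting reads required to phase.
    het_only
        Phase only heterozygous SVs (homozygous records pass through
        with their CONFLICT annotation only).
    """

    conflict_threshold: int = 0
    min_tagged_reads: int = 1
    het_only: bool = True

    def __post_init__(self) -> None:
        if self.conflict_threshold < 0:
            raise ValueError("conflict_threshold must be >= 0")
        if self.min_tagged_reads < 1:
            raise ValueError("min_tagged_reads must be >= 1")


@dataclass(frozen=True)
class SVPhasingEvidence:
    """Tagged-read tally for one SV."""

    chrom: str
    pos: int
    sv_type: str | None
    tagged_reads: int
    hp1_count: int
    hp2_count: int
    other_ps_count: int
    dominant_ps: int | None
    conflict_count: int

    def __post_init__(self) -> None:
        if self.tagged_reads != self.hp1_count + self.hp2_count + self.other_ps_count:
            raise ValueError("tagged_reads must equal hp1 + hp2 + other-PS counts")
        if self.conflict_count != min(self.hp1_count, self.hp2_count) + self.other_ps_count:
            raise ValueError("conflict_count inconsistent with counts")


def build_tag_interval_index(
    tags: Iterable[HaplotagRecord],
) -> dict[str, IntervalTree]:
    """Per-contig interval tree over read spans, for the overlap fallback."""
    trees: dict[str, IntervalTree] = {}
    for tag in tags:
        trees.setdefault(tag.chrom, IntervalTree()).addi(tag.start, tag.end, tag)
    return trees


def _fallback_supporting(
    sv: VariantRecord, index: Mapping[str, IntervalTree]
) -> tuple[str, ...]:
    """Tagged reads whose span contains the SV breakpoint(s)."""
    tree = index.get(sv.chrom)
    if tree is None:
        return ()
    start0 = sv.pos - 1
    hits = {iv.data.read_name: iv.data for iv in tree[start0]}
    if sv.sv_type in _SPAN_TYPES and sv.sv_len is not None:
        end0 = start0 + abs(sv.sv_len)
        end_hits = {iv.data.read_name for iv in tree[end0]}
        hits = {n: t for n, t in hits.items() if n in end_hits}
    return tuple(sorted(hits))


def collect_sv_evidence(
    sv: VariantRecord,
    tags: Mapping[str, HaplotagRecord],
    fallback_index: Mapping[str, IntervalTree] | None = None,
) -> SVPhasingEvidence:
    """Tally the haplotags of an SV's supporting reads.

    Untagged supporting reads are ignored. The dominant phase set is
    the one tagging the most supporting reads (ties go to the smaller
    identifier); reads tagged with any other phase set count as
    conflicts, as does the minority haplotype within the dominant set.
    """
    supporting = tuple(dict.fromkeys(sv.supporting_reads))
    if not supporting and fallback_index is not None:
        supporting = _fallback_supporting(sv, fallback_index)

    tagged = [tags[name] for name in supporting if name in tags]
    if not tagged:
        return SVPhasingEvidence(
            chrom=sv.chrom, pos=sv.pos, sv_type=sv.sv_type,
            tagged_reads=0, hp1_count=0, hp2_count=0, other_ps_count=0,
            dominant_ps=None, conflict_count=0,
        )
    ps_counts = Counter(t.ps for t in tagged)
    dominant = max(ps_counts, key=lambda ps: (ps_counts[ps], -ps))
    hp1 = sum(1 for t in tagged if t.ps == dominant and t.hp == 1)
    hp2 = sum(1 for t in tagged if t.ps == dominant and t.hp == 2)
    other = len(tagged) - hp1 - hp2
    return SVPhasingEvidence(
        chrom=sv.chrom, pos=sv.pos, sv_type=sv.sv_type,
        tagged_reads=len(tagged), hp1_count=hp1, hp2_count=hp2,
        other_ps_count=other, dominant_ps=dominant,
        conflict_count=min(hp1, hp2) + other,
    )


def decide_phase(
    evidence: SVPhasingEvidence,
    sv: VariantRecord,
    params: SVPhasingParams = SVPhasingParams(),
) -> VariantRecord:
    """Phase one SV from its evidence, or annotate why not.

    INFO/CONFLICT is always set. The SV is phased iff it is
    heterozygous (when ``het_only``), has at least ``min_tagged_reads``
    tagged supporting reads, at most ``conflict_threshold`` conflicts,
    and a strict haplotype majority. The ALT allele is placed on the
    majority haplotype: majority HP1 gives GT ``1|0``, HP2 ``0|1``.
    """
    rec = sv.replace(conflict=evidence.conflict_count)
    if params.het_only and not sv.is_het:
        return rec
    if evidence.tagged_reads < params.min_tagged_reads:
        return rec
    if evidence.conflict_count > params.conflict_threshold:
        return rec
    if evidence.hp1_count == evidence.hp2_count:
        return rec
    majority_hp = 1 if evidence.hp1_count > evidence.hp2_count else 2
    gt = (1, 0) if majority_hp == 1 else (0, 1)
    return rec.replace(gt=gt, phased=True, ps=evidence.dominant_ps)


@dataclass
class SVPhasingSummary:
    """Per-type and overall phased percentages among heterozygous SVs."""

    per_type: dict[str, dict[str, float]] = field(default_factory=dict)
    n_het: int = 0
    n_het_phased: int = 0

    @property
    def phased_pct(self) -> float:
        return 100.0 * self.n_het_phased / self.n_het if self.n_het else 0.0

    def as_dict(self) -> dict:
        return {
            "overall": {"n_het": self.n_het, "n_het_phased": self.n_het_phased,
                        "phased_pct": self.phased_pct},
            "per_type": self.per_type,
        }


def phase_sv_set(
    svs: Sequence[VariantRecord],
    tags: Mapping[str, HaplotagRecord],
    params: SVPhasingParams = SVPhasingParams(),
    fallback_index: Mapping[str, IntervalTree] | None = None,
) -> tuple[list[VariantRecord], SVPhasingSummary]:
    """Phase a whole SV callset and summarize phased rates per SV type."""
    out: list[VariantRecord] = []
    het: Counter = Counter()
    phased: Counter = Counter()
    for sv in svs:
        evidence = collect_sv_evidence(sv, tags, fallback_index)
        rec = decide_phase(evidence, sv, params)
        out.append(rec)
        key = sv.sv_type or "non-SV"
        if sv.is_het:
            het[key] += 1
            if rec.phased:
                phased[key] += 1
    summary = SVPhasingSummary(
        per_type={
            t: {
                "n_het": het[t],
                "n_het_phased": phased[t],
                "phased_pct": 100.0 * phased[t] / het[t] if het[t] else 0.0,
            }
            for t in sorted(het)
        },
        n_het=sum(het.values()),
        n_het_phased=sum(phased.values()),
    )
    return out, summary
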