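"""Phasing evaluation: switch error, Hamming error, block N50, phased
fraction and per-region reporting.

Truth and prediction are compared at their shared phased heterozygous
sites, within the *prediction's* phase blocks; sites unphased in
either callset contribute to neither metric.

Switch error counts changes of truth/prediction agreement between
adjacent sites in a block — a single mis-joined junction costs one
switch no matter how long its tail. Hamming error is the per-block
edit distance under the best global flip: ``min(#disagree, #agree)``
summed over blocks. Both are the standard definitions phasing
evaluators report. Block N50 measures phase-block lengths from the
first to the last variant of the block.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .variant_io import Region, VariantRecord

BlockId = int | str | tuple


@dataclass(frozen=True)
class PhaseComparison:
    """Truth-vs-prediction phasing metrics."""

    n_common_het: int
    n_adjacent_pairs: int
    switch_errors: int
    switch_rate: float
    hamming_errors: int
    hamming_rate: float
    per_block: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        if self.switch_errors > self.n_adjacent_pairs:
            raise ValueError("more switch errors than adjacent pairs")
        if self.hamming_errors > self.n_common_het:
            raise ValueError("more Hamming errors than common sites")


def _check_aligned(
    truth: Mapping[BlockId, Sequence[int]], pred: Mapping[BlockId, Sequence[int]]
) -> None:
    if set(truth) != set(pred):
        missing = set(truth) ^ set(pred)
        raise ValueError(f"truth/prediction block sets differ: {sorted(map(str, missing))}")
    for block in truth:
        if len(truth[block]) != len(pred[block]):
            raise ValueError(
                f"block {block!r}: site counts differ "
                f"({len(truth[block])} truth vs {len(pred[block])} prediction)"
            )


def switch_error(
    truth: Mapping[BlockId, Sequence[int]],
    pred: Mapping[BlockId, Sequence[int]],
) -> tuple[int, float]:
    """Count agreement flips between adjacent sites, per block.

    Inputs map block id -> haplotype-1 allele index per shared phased
    het site, in genomic order; the two maps must be aligned on the
    same blocks and site counts. Blocks of one site have no pairs.
    """
    _check_aligned(truth, pred)
    count = 0
    pairs = 0
    for block in truth:
        agree = [int(t == p) for t, p in zip(truth[block], pred[block])]
        pairs += max(len(agree) - 1, 0)
        count += sum(1 for a, b in zip(agree, agree[1:]) if a != b)
    return count, count / pairs if pairs else 0.0


def hamming_error(
    truth: Mapping[BlockId, Sequence[int]],
    pred: Mapping[BlockId, Sequence[int]],
) -> tuple[int, float]:
    """Per-block minimum of disagreements over the two global flips."""
    _check_aligned(truth, pred)
    count = 0
    n_sites = 0
    for block in truth:
        disagree = sum(1 for t, p in zip(truth[block], pred[block]) if t != p)
        n = len(truth[block])
        n_sites += n
        count += min(disagree, n - disagree)
    return count, count / n_sites if n_sites else 0.0


def compare_phasing(
    truth: Sequence[VariantRecord],
    pred: Sequence[VariantRecord],
) -> PhaseComparison:
    """Full comparison of two phased callsets.

    Sites are matched by (chrom, pos, ref, alt); only sites phased and
    heterozygous in both are compared, grouped by the prediction's PS.
    """
    truth_by_site = {
        (r.chrom, r.pos, r.ref, r.alt): r for r in truth if r.phased and r.is_het
    }
    truth_blocks: dict[BlockId, list[int]] = defaultdict(list)
    pred_blocks: dict[BlockId, list[int]] = defaultdict(list)
    for rec in pred:
        if not (rec.phased and rec.is_het):
            continue
        t = truth_by_site.get((rec.chrom, rec.pos, rec.ref, rec.alt))
        if t is None:
            continue
        block = (rec.chrom, rec.ps)
        truth_blocks[block].append(t.gt[0])
        pred_blocks[block].append(rec.gt[0])

    s_count, s_rate = switch_error(truth_blocks, pred_blocks)
    h_count, h_rate = hamming_error(truth_blocks, pred_blocks)
    per_block = {}
    for block in truth_blocks:
        sc, _ = switch_error({block: truth_blocks[block]}, {block: pred_blocks[block]})
        hc, _ = hamming_error({block: truth_blocks[block]}, {block: pred_blocks[block]})
        per_block[block] = {
            "n_sites": len(truth_blocks[block]),
            "switch_errors": sc,
            "hamming_errors": hc,
        }
    n_common = sum(len(v) for v in truth_blocks.values())
    return PhaseComparison(
        n_common_het=n_common,
        n_adjacent_pairs=sum(max(len(v) - 1, 0) for v in truth_blocks.values()),
        switch_errors=s_count,
        switch_rate=s_rate,
        hamming_errors=h_count,
        hamming_rate=h_rate,
        per_block=per_block,
    )


def phase_blocks(records: Sequence[VariantRecord]) -> list[tuple[str, int, int]]:
    """(chrom, first_pos, last_pos) span of every phase block (1-based)."""
    spans: dict[tuple[str, int], list[int]] = defaultdict(list)
    for rec in records:
        if rec.phased and rec.ps is not None:
            spans[(rec.chrom, rec.ps)].append(rec.pos)
    return [(chrom, min(pos), max(pos)) for (chrom, _), pos in sorted(spans.items())]


def block_n50(blocks: Sequence[tuple[str, int, int]]) -> int:
    """N50 of block lengths (first-to-last variant, inclusive)."""
    lengths = sorted((last - first + 1 for _, first, last in blocks), reverse=True)
    if not lengths:
        return 0
    if any(l < 1 for l in lengths):
        raise ValueError("block with last_pos < first_pos")
    half = sum(lengths) / 2.0
    cum = 0
    for length in lengths:
        cum += length
        if cum >= half:
            return length
    return lengths[-1]  # pragma: no cover


def phased_fraction(records: Sequence[VariantRecord]) -> float:
    """Phased heterozygous sites over all heterozygous sites."""
    n_het = sum(1 for r in records if r.is_het)
    if n_het == 0:
        return 0.0
    return sum(1 for r in records if r.is_het and r.phased) / n_het


REGION_REPORT_COLUMNS = [
    "region", "chrom", "start", "end",
    "n_snv_indel", "n_sv", "n_het", "n_het_phased", "n_phase_blocks",
]


def region_report(
    records: Sequence[VariantRecord],
    blocks: Sequence[tuple[str, int, int]],
    regions: Sequence[Region],
) -> pd.DataFrame:
    """Per-region variant and phase-block counts (e.g. medical genes).

    Variants intersect by position (SVs by their start breakpoint);
    blocks by span overlap, so a block crossing two regions counts in
    both.
    """
    rows = []
    for region in regions:
        in_region = [
            r for r in records
            if r.chrom == region.chrom and region.start <= r.pos - 1 < region.end
        ]
        n_blocks = sum(
            1 for chrom, first, last in blocks
            if chrom == region.chrom and first - 1 < region.end and region.start < last
        )
        rows.append(
            {
                "region": region.name,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "n_snv_indel": sum(1 for r in in_region if not r.is_sv),
                "n_sv": sum(1 for r in in_region if r.is_sv),
                "n_het": sum(1 for r in in_region if r.is_het),
                "n_het_phased": sum(1 for r in in_region if r.is_het and r.phased),
                "n_phase_blocks": n_blocks,
            }
        )
    return pd.DataFrame(rows, columns=REGION_REPORT_COLUMNS)
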