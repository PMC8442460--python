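"""Deterministic diploid toy-data generators.

Everything the toolkit consumes — a phased truth callset, haplotagged
reads, SV calls with supporting-read names, per-read methylation
calls, and parental genotypes — can be generated on one linear toy
contig (``chrT``) from a seed. No reference sequence is needed: the
algorithms operate on positions, tags and genotypes only. Every
generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import (
    HaplotagRecord,
    MethylationCall,
    VariantRecord,
)

CHROM = "chrT"
_BASES = np.array(list("ACGT"))
_SV_CYCLE = ("DEL", "INS", "DUP", "INV", "BND")

#: columns of the per-read truth frame returned by simulate_haplotagged_reads
READ_COLUMNS = ["read_name", "chrom", "start", "end", "true_hp", "tagged", "hp", "ps"]


def simulate_truth(
    n_blocks: int,
    sites_per_block: int,
    block_gap_bp: int = 10_000,
    seed: int = 0,
    chrom: str = CHROM,
) -> list[VariantRecord]:
    """Phased heterozygous truth sites in ``n_blocks`` phase blocks.

    Sites sit at strictly increasing positions (100–1000 bp apart
    within a block, ``block_gap_bp`` between blocks); the haplotype-1
    allele is uniform per site and PS is the block's first position.
    """
    if n_blocks < 1 or sites_per_block < 1 or block_gap_bp < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    pos = 1000
    for _ in range(n_blocks):
        block_positions = []
        for _ in range(sites_per_block):
            pos += int(rng.integers(100, 1000))
            block_positions.append(pos)
        ps = block_positions[0]
        for p in block_positions:
            h1 = int(rng.integers(0, 2))
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=p,
                    ref=str(ref),
                    alt=str(alt),
                    qual=float(np.round(rng.uniform(20, 60), 2)),
                    filter=frozenset({"PASS"}),
                    gt=(h1, 1 - h1),
                    phased=True,
                    ps=ps,
                )
            )
        pos += block_gap_bp
    return records


def _block_spans(truth: Sequence[VariantRecord]) -> list[tuple[int, int, int]]:
    """(ps, start0, end0) half-open span of each block."""
    spans: dict[int, list[int]] = {}
    for rec in truth:
        spans.setdefault(rec.ps, []).append(rec.pos)  # type: ignore[arg-type]
    return [(ps, min(p) - 1, max(p)) for ps, p in sorted(spans.items())]


def simulate_haplotagged_reads(
    truth: Sequence[VariantRecord],
    n_reads: int,
    read_len_bp: int = 8000,
    tag_error_rate: float = 0.0,
    untagged_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[HaplotagRecord], pd.DataFrame]:
    """Reads with true haplotypes and their (possibly erroneous) tags.

    Each read gets a uniform true haplotype; its emitted HP is flipped
    with ``tag_error_rate`` and the read is left out of the tag table
    with ``untagged_rate`` (or when its midpoint falls outside every
    block span). Returns the tag table and the full per-read truth
    frame (columns :data:`READ_COLUMNS`; ``hp``/``ps`` hold the
    emitted tag, 0 when untagged).
    """
    if not truth:
        raise ValueError("truth callset is empty")
    rng = np.random.default_rng(seed)
    chrom = truth[0].chrom
    contig_len = max(r.pos for r in truth) + 1000
    if read_len_bp > contig_len:
        raise ValueError(f"read_len_bp {read_len_bp} exceeds contig length {contig_len}")
    spans = _block_spans(truth)

    rows = []
    tags: list[HaplotagRecord] = []
    for i in range(n_reads):
        start = int(rng.integers(0, contig_len - read_len_bp + 1))
        end = start + read_len_bp
        mid = start + read_len_bp // 2
        true_hp = int(rng.integers(1, 3))
        ps = next((p for p, s, e in spans if s <= mid < e), None)
        tagged = ps is not None and rng.random() >= untagged_rate
        emitted = true_hp
        if rng.random() < tag_error_rate:
            emitted = 3 - true_hp
        name = f"read{i:06d}"
        if tagged:
            tags.append(HaplotagRecord(name, chrom, start, end, emitted, ps))
        rows.append(
            {
                "read_name": name, "chrom": chrom, "start": start, "end": end,
                "true_hp": true_hp, "tagged": bool(tagged),
                "hp": emitted if tagged else 0, "ps": ps if tagged else 0,
            }
        )
    return tags, pd.DataFrame(rows, columns=READ_COLUMNS)


def simulate_svs(
    truth: Sequence[VariantRecord],
    reads: pd.DataFrame,
    n_sv: int,
    het_fraction: float = 1.0,
    n_conflict_reads: int = 0,
    n_support_reads: int = 5,
    seed: int = 0,
) -> tuple[list[VariantRecord], list[dict]]:
    """SV calls whose supporting reads realize a known conflict count.

    Each heterozygous SV sits inside one block on one true haplotype;
    its supporting reads are ``n_support_reads`` reads tagged with
    that (PS, HP) cell plus exactly ``n_conflict_reads`` from the
    opposite cell. Homozygous SVs draw supporting reads from both
    haplotypes. SV types cycle through DEL/INS/DUP/INV/BND. Returns
    the records (position-sorted) and the per-SV truth
    (``{"hp": ..., "ps": ..., "het": ...}``, aligned by index).
    """
    if not 0.0 <= het_fraction <= 1.0:
        raise ValueError("het_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    spans = _block_spans(truth)
    tagged = reads[reads.tagged]
    cells: dict[tuple[int, int], list[str]] = {
        (int(ps), int(hp)): list(group.read_name)
        for (ps, hp), group in tagged.groupby(["ps", "hp"])
    }

    drafts: list[tuple[VariantRecord, dict]] = []
    used_pos: set[int] = set()
    for i in range(n_sv):
        sv_type = _SV_CYCLE[i % len(_SV_CYCLE)]
        het = bool(rng.random() < het_fraction)
        ps, s0, e0 = spans[int(rng.integers(0, len(spans)))]
        hp = int(rng.integers(1, 3))
        if het:
            need = {(ps, hp): n_support_reads, (ps, 3 - hp): n_conflict_reads}
        else:
            half = max(n_support_reads // 2, 1)
            need = {(ps, 1): half, (ps, 2): half}
        support: list[str] = []
        for cell, k in need.items():
            pool = cells.get(cell, [])
            if len(pool) < k:
                raise ValueError(
                    f"not enough tagged reads in cell {cell}: need {k}, have {len(pool)}"
                )
            support.extend(rng.choice(pool, size=k, replace=False))
        while True:
            pos = int(rng.integers(s0 + 1, e0 + 1))
            if pos not in used_pos:
                used_pos.add(pos)
                break
        length = int(rng.integers(50, 500))
        sv_len = {"DEL": -length, "BND": None}.get(sv_type, length)
        rec = VariantRecord(
            chrom=truth[0].chrom,
            pos=pos,
            ref="N",
            alt=f"<{sv_type}>",
            qual=float(np.round(rng.uniform(10, 50), 2)),
            filter=frozenset({"PASS"}),
            gt=(0, 1) if het else (1, 1),
            phased=False,
            sv_type=sv_type,
            sv_len=sv_len,
            supporting_reads=tuple(support),
        )
        drafts.append((rec, {"hp": hp if het else None, "ps": ps, "het": het}))
    drafts.sort(key=lambda d: d[0].pos)
    return [d[0] for d in drafts], [d[1] for d in drafts]


def simulate_methylation(
    reads: pd.DataFrame,
    n_sites: int,
    p_meth_h1: float,
    p_meth_h2: float,
    llr_magnitude: float = 4.0,
    seed: int = 0,
) -> list[MethylationCall]:
    """Per-read methylation calls with haplotype-specific rates.

    CpG sites are spread uniformly over the read-covered range; every
    read covering a site yields one call, methylated with its *true*
    haplotype's probability, with llr = ±``llr_magnitude``.
    """
    for p in (p_meth_h1, p_meth_h2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("methylation probabilities must be in [0, 1]")
    if n_sites == 0 or reads.empty:
        return []
    rng = np.random.default_rng(seed)
    lo, hi = int(reads.start.min()), int(reads.end.max())
    sites = sorted(int(s) for s in rng.choice(np.arange(lo, hi), size=n_sites, replace=False))
    p_by_hp = {1: p_meth_h1, 2: p_meth_h2}
    calls: list[MethylationCall] = []
    for row in reads.itertuples(index=False):
        for site in sites:
            if row.start <= site < row.end:
                methylated = rng.random() < p_by_hp[row.true_hp]
                calls.append(
                    MethylationCall(
                        read_name=row.read_name,
                        chrom=row.chrom,
                        start=site,
                        end=site + 1,
                        llr=llr_magnitude if methylated else -llr_magnitude,
                        num_motifs=1,
                    )
                )
    return calls


def simulate_trio(
    truth: Sequence[VariantRecord],
    informative_fraction: float = 0.8,
    discordance_rate: float = 0.02,
    flip_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[list[VariantRecord], list[VariantRecord], dict[int, bool]]:
    """Parental genotypes that confirm (and sometimes flip) the truth.

    Per block, decide with ``flip_fraction`` whether haplotype 1 is
    maternal (flipped) instead of paternal. Per site, with
    ``informative_fraction`` make the parents opposite homozygotes
    matching that orientation — inverted with ``discordance_rate`` —
    else both parents are uninformative hets. Returns father and
    mother callsets plus the per-block flipped truth.
    """
    rng = np.random.default_rng(seed)
    block_flipped: dict[int, bool] = {}
    father: list[VariantRecord] = []
    mother: list[VariantRecord] = []
    for rec in truth:
        assert rec.ps is not None
        if rec.ps not in block_flipped:
            block_flipped[rec.ps] = bool(rng.random() < flip_fraction)
        flipped = block_flipped[rec.ps]
        h1, h2 = rec.gt
        if rng.random() < informative_fraction:
            # paternal allele = h1 unless the block is flipped
            pat, mat = (h2, h1) if flipped else (h1, h2)
            if rng.random() < discordance_rate:
                pat, mat = mat, pat
            f_gt, m_gt = (pat, pat), (mat, mat)
        else:
            f_gt = m_gt = (0, 1)
        common = dict(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alt,
                      filter=frozenset({"PASS"}))
        father.append(VariantRecord(gt=f_gt, **common))
        mother.append(VariantRecord(gt=m_gt, **common))
    return father, mother, block_flipped
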