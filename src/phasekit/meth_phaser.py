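"""Haplotype-resolve per-read methylation calls via read haplotags.

Methylation callers report one log-likelihood ratio per read per CpG
group; they know nothing about haplotypes. Joining each call to the
HP/PS tag of its read turns the table into haplotype-resolved
methylation: calls from untagged reads keep ``"."`` in both fields and
are never dropped. Aggregation to per-site, per-haplotype methylation
frequencies uses a symmetric LLR confidence cutoff (default 2.0, the
callers' conventional threshold): llr >= cutoff counts methylated,
llr <= -cutoff unmethylated, and calls in between are ambiguous and
excluded from the frequency.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace
from typing import Mapping, Sequence

import pandas as pd

from .variant_io import HaplotagRecord, MethylationCall

DEFAULT_LLR_CUTOFF = 2.0

FREQUENCY_COLUMNS = ["chrom", "start", "hp", "n_reads", "n_methylated", "frequency"]


def phase_methylation(
    calls: Sequence[MethylationCall],
    tags: Mapping[str, HaplotagRecord],
) -> list[MethylationCall]:
    """Attach HP/PS to every methylation call from its read's tag.

    Order and count are preserved; calls from reads without a tag get
    ``"."`` in both fields.
    """
    out: list[MethylationCall] = []
    for call in calls:
        tag = tags.get(call.read_name)
        if tag is None:
            out.append(replace(call, hp=".", ps="."))
        else:
            out.append(replace(call, hp=tag.hp, ps=tag.ps))
    return out


def haplotype_methylation_frequency(
    phased_calls: Sequence[MethylationCall],
    llr_cutoff: float = DEFAULT_LLR_CUTOFF,
) -> tuple[pd.DataFrame, int]:
    """Aggregate phased calls to per-site, per-haplotype frequencies.

    Returns the frequency table (one row per (site, haplotype) group
    with at least one confident call; ``hp`` is ``1``, ``2`` or ``"."``
    for the unphased group) and the number of ambiguous calls
    (|llr| < cutoff) excluded from it. Group read counts plus the
    ambiguous count add back up to the input size.
    """
    if llr_cutoff < 0:
        raise ValueError("llr_cutoff must be non-negative")
    meth: dict[tuple, int] = defaultdict(int)
    unmeth: dict[tuple, int] = defaultdict(int)
    n_ambiguous = 0
    for call in phased_calls:
        key = (call.chrom, call.start, str(call.hp))
        if call.llr >= llr_cutoff:
            meth[key] += 1
        elif call.llr <= -llr_cutoff:
            unmeth[key] += 1
        else:
            n_ambiguous += 1
    rows = []
    for key in sorted(set(meth) | set(unmeth)):
        n_m, n_u = meth[key], unmeth[key]
        rows.append(
            {
                "chrom": key[0],
                "start": key[1],
                "hp": key[2],
                "n_reads": n_m + n_u,
                "n_methylated": n_m,
                "frequency": n_m / (n_m + n_u),
            }
        )
    return pd.DataFrame(rows, columns=FREQUENCY_COLUMNS), n_ambiguous
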