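"""Reference haplotagger: assign reads an HP/PS from phased het SNVs.

Each read's base calls at phased heterozygous sites are summarized as
:class:`ReadAlleleObservation` rows. At every covered site the
observed allele votes for haplotype 1 (it matches the first phased
allele) or haplotype 2 (the second). Votes are restricted to the phase
set covering the most sites on the read, and the read is tagged with
the majority haplotype of that phase set. Exact ties — between phase
sets (resolved toward the smaller PS identifier) never, between
haplotypes always — leave the read untagged.

This is the documented contract of read haplotagging; probabilistic
weighting by base quality and realignment are deliberately out of
scope.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .variant_io import HaplotagRecord, VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAlleleObservation:
    """One read's allele at one variant site (0-based position)."""

    read_name: str
    pos: int  # 0-based
    allele: int | None  # 0=REF, 1=ALT, None=uncalled

    def __post_init__(self) -> None:
        if self.allele is not None and self.allele not in (0, 1):
            raise ValueError(f"allele must be 0, 1 or None, got {self.allele}")


def tag_read(
    observations: Sequence[ReadAlleleObservation],
    phased_hets: Sequence[VariantRecord],
) -> HaplotagRecord | None:
    """Tag one read from its allele observations at phased het sites.

    Returns ``None`` (untagged) when no informative vote exists or the
    haplotype vote within the dominant phase set is an exact tie.
    """
    if not observations:
        return None
    by_pos = {rec.pos - 1: rec for rec in phased_hets if rec.phased and rec.is_het}

    # (ps -> haplotype votes), covered-site counts per ps
    votes: dict[int, Counter] = defaultdict(Counter)
    covered: Counter = Counter()
    name = observations[0].read_name
    for obs in observations:
        if obs.read_name != name:
            raise ValueError("tag_read expects observations from a single read")
        rec = by_pos.get(obs.pos)
        if rec is None:
            logger.debug("observation at %d matches no phased het; ignored", obs.pos)
            continue
        if obs.allele is None:
            continue
        assert rec.ps is not None
        covered[rec.ps] += 1
        if obs.allele == rec.gt[0]:
            votes[rec.ps][1] += 1
        elif obs.allele == rec.gt[1]:
            votes[rec.ps][2] += 1

    if not covered:
        return None
    # dominant phase set: most covered sites, ties -> smaller identifier
    best = max(covered, key=lambda ps: (covered[ps], -ps))
    tally = votes[best]
    if tally[1] == tally[2]:
        return None
    hp = 1 if tally[1] > tally[2] else 2
    positions = [obs.pos for obs in observations]
    chrom = phased_hets[0].chrom if phased_hets else "."
    return HaplotagRecord(
        read_name=name,
        chrom=chrom,
        start=min(positions),
        end=max(positions) + 1,
        hp=hp,
        ps=best,
    )


def tag_reads(
    observations: Iterable[ReadAlleleObservation],
    phased_hets: Sequence[VariantRecord],
) -> list[HaplotagRecord]:
    """Group observations by read and tag each; untagged reads drop out."""
    grouped: dict[str, list[ReadAlleleObservation]] = defaultdict(list)
    for obs in observations:
        grouped[obs.read_name].append(obs)
    tags = (tag_read(obs_list, phased_hets) for obs_list in grouped.values())
    return [t for t in tags if t is not None]


OBS_COLUMNS = ("read_name", "chrom", "pos", "allele")


def read_observation_tsv(path) -> list[ReadAlleleObservation]:
    """Read the 4-column observation TSV (read_name chrom pos allele).

    ``pos`` is 0-based; allele ``.`` means uncalled. ``#`` lines are
    comments.
    """
    out: list[ReadAlleleObservation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(OBS_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(OBS_COLUMNS)} columns")
            name, _chrom, pos, allele = parts
            out.append(
                ReadAlleleObservation(
                    name, int(pos), None if allele == "." else int(allele)
                )
            )
    return out


def partition_reads(
    tags: Iterable[HaplotagRecord],
) -> dict[tuple[int, int], set[str]]:
    """Partition tagged reads into (phase set, haplotype) cells."""
    cells: dict[tuple[int, int], set[str]] = defaultdict(set)
    for tag in tags:
        cells[(tag.ps, tag.hp)].add(tag.read_name)
    return dict(cells)
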