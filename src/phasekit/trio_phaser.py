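"""Confirm and orient child phase blocks with parental genotypes.

Read-backed phasing fixes the relative configuration of heterozygous
variants within a block, but not which haplotype came from which
parent, and a block may still be globally flipped relative to the
truth. Parental genotypes settle both: at an *informative* site each
child allele is transmissible by exactly one parent, so the site votes
on whether haplotype 1 of the block is paternal or maternal. A block
is *confirmed* when it has enough informative sites (default 10) and
the minority vote fraction is within the tolerance (default 5%,
inclusive); a confirmed block voting for the non-reference parent
orientation is flipped so that haplotype 1 is consistently the
``orient_h1`` parent (paternal by default).

Sites where a child allele cannot have been transmitted by either
parent are Mendelian conflicts — genotyping errors, not phase errors —
and never count toward confirmation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .variant_io import VariantRecord

TRIO_DISCORDANT_FILTER = "trio_discordant"

Genotype = tuple[int, int]


class Vote(Enum):
    H1_PATERNAL = "H1_PATERNAL"
    H1_MATERNAL = "H1_MATERNAL"
    UNINFORMATIVE = "UNINFORMATIVE"
    MENDELIAN_CONFLICT = "MENDELIAN_CONFLICT"


@dataclass(frozen=True)
class TrioParams:
    """Confirmation thresholds and orientation convention."""

    tolerance: float = 0.05
    min_snps: int = 10
    orient_h1: str = "paternal"
    merge_confirmed: bool = False
    flip: bool = True  # re-orient confirmed blocks (False: label only)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tolerance <= 1.0:
            raise ValueError("tolerance must be in [0, 1]")
        if self.min_snps < 1:
            raise ValueError("min_snps must be positive")
        if self.orient_h1 not in ("paternal", "maternal"):
            raise ValueError("orient_h1 must be 'paternal' or 'maternal'")


@dataclass(frozen=True)
class BlockParentalAssignment:
    """Vote tally and confirmation decision for one phase block."""

    ps: int
    n_informative: int
    votes_h1_paternal: int
    votes_h1_maternal: int
    n_mendelian_conflicts: int
    discordance: float
    confirmed: bool
    flipped: bool

    def __post_init__(self) -> None:
        if self.n_informative != self.votes_h1_paternal + self.votes_h1_maternal:
            raise ValueError("n_informative must equal the vote total")


def classify_informative_site(
    child: VariantRecord,
    father_gt: Genotype | None,
    mother_gt: Genotype | None,
) -> Vote:
    """Vote of one phased child het on its block's parental orientation.

    An allele is assignable iff exactly one parent carries it; the site
    is informative iff both child alleles are assignable, necessarily
    to different parents (the parents are opposite homozygotes). An
    allele carried by neither parent is a Mendelian conflict.
    """
    if not (child.phased and child.is_het):
        raise ValueError("classify_informative_site requires a phased heterozygous child record")
    if father_gt is None or mother_gt is None:
        return Vote.UNINFORMATIVE

    def transmitters(allele: int) -> list[str]:
        out = []
        if allele in father_gt:
            out.append("father")
        if allele in mother_gt:
            out.append("mother")
        return out

    h1_allele, h2_allele = child.gt
    t1, t2 = transmitters(h1_allele), transmitters(h2_allele)
    if not t1 or not t2:
        return Vote.MENDELIAN_CONFLICT
    if len(t1) == 1 and len(t2) == 1 and t1 != t2:
        return Vote.H1_PATERNAL if t1 == ["father"] else Vote.H1_MATERNAL
    return Vote.UNINFORMATIVE


def evaluate_block(
    votes: Sequence[Vote],
    params: TrioParams = TrioParams(),
    ps: int = 0,
) -> BlockParentalAssignment:
    """Tally one block's votes into a confirmation decision.

    Confirmed iff informative votes >= ``min_snps`` and the minority
    fraction <= ``tolerance`` (inclusive). ``flipped`` is true when the
    majority assigns haplotype 1 to the non-``orient_h1`` parent.
    """
    n_pat = sum(1 for v in votes if v is Vote.H1_PATERNAL)
    n_mat = sum(1 for v in votes if v is Vote.H1_MATERNAL)
    n_mendel = sum(1 for v in votes if v is Vote.MENDELIAN_CONFLICT)
    n_informative = n_pat + n_mat
    minority = min(n_pat, n_mat)
    discordance = minority / n_informative if n_informative else 0.0
    confirmed = n_informative >= params.min_snps and discordance <= params.tolerance
    majority_parent = "paternal" if n_pat >= n_mat else "maternal"
    flipped = confirmed and majority_parent != params.orient_h1
    return BlockParentalAssignment(
        ps=ps,
        n_informative=n_informative,
        votes_h1_paternal=n_pat,
        votes_h1_maternal=n_mat,
        n_mendelian_conflicts=n_mendel,
        discordance=discordance,
        confirmed=confirmed,
        flipped=flipped,
    )


def genotype_map(records: Sequence[VariantRecord]) -> dict[tuple[str, int], Genotype]:
    """Index parental genotypes by (chrom, 1-based pos)."""
    return {(r.chrom, r.pos): r.gt for r in records}


def apply_trio_phasing(
    child: Sequence[VariantRecord],
    father: Mapping[tuple[str, int], Genotype],
    mother: Mapping[tuple[str, int], Genotype],
    params: TrioParams = TrioParams(),
) -> tuple[list[VariantRecord], list[BlockParentalAssignment]]:
    """Confirm, orient and annotate a child callset against its parents.

    For every confirmed block whose majority vote points away from the
    ``orient_h1`` parent, all phased genotypes in the block are flipped
    (``a|b`` -> ``b|a``, unless ``params.flip`` is off). Sites voting
    with the minority get the ``trio_discordant`` FILTER flag.
    Unconfirmed blocks pass through unchanged but are reported. With
    ``merge_confirmed``, confirmed blocks on one chromosome share the
    smallest confirmed PS of that chromosome.
    """
    votes_by_ps: dict[int, list[Vote]] = defaultdict(list)
    site_votes: dict[int, Vote] = {}
    child_blocks: dict[int, None] = {}
    for idx, rec in enumerate(child):
        if not (rec.phased and rec.is_het):
            continue
        assert rec.ps is not None
        child_blocks.setdefault(rec.ps, None)
        key = (rec.chrom, rec.pos)
        vote = classify_informative_site(rec, father.get(key), mother.get(key))
        votes_by_ps[rec.ps].append(vote)
        site_votes[idx] = vote

    assignments = {
        ps: evaluate_block(votes_by_ps.get(ps, []), params, ps=ps)
        for ps in child_blocks
    }

    # merged PS per chromosome = smallest confirmed PS on that chromosome
    merged_ps: dict[str, int] = {}
    if params.merge_confirmed:
        for rec in child:
            if rec.phased and rec.ps in assignments and assignments[rec.ps].confirmed:
                cur = merged_ps.get(rec.chrom)
                merged_ps[rec.chrom] = rec.ps if cur is None else min(cur, rec.ps)

    out: list[VariantRecord] = []
    for idx, rec in enumerate(child):
        if not (rec.phased and rec.ps in assignments):
            out.append(rec)
            continue
        a = assignments[rec.ps]
        if not a.confirmed:
            out.append(rec)
            continue
        new = rec
        if a.flipped and params.flip:
            new = new.replace(gt=(new.gt[1], new.gt[0]))
        vote = site_votes.get(idx)
        if vote in (Vote.H1_PATERNAL, Vote.H1_MATERNAL):
            majority = Vote.H1_MATERNAL if a.votes_h1_maternal > a.votes_h1_paternal else Vote.H1_PATERNAL
            if vote is not majority:
                new = new.replace(filter=new.filter | {TRIO_DISCORDANT_FILTER})
        if params.merge_confirmed and rec.chrom in merged_ps:
            new = new.replace(ps=merged_ps[rec.chrom])
        out.append(new)
    return out, [assignments[ps] for ps in child_blocks]
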