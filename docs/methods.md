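# Methods

This note documents the models and procedures implemented in
`phasekit`, the parameters that matter, the numerical choices made
where the design was open, and what the synthetic data generator does
and does not emulate.

## Scope and assumptions

`phasekit` assumes a diploid genome throughout: genotypes are pairs of
allele indices restricted to {0 = REF, 1 = ALT} after splitting
multiallelic VCF rows per ALT, and non-diploid GTs are rejected. It
consumes the outputs of upstream tools — a phased small-variant VCF, a
haplotag table equivalent to the HP/PS tags a haplotagger writes into a
BAM, SV calls annotated with supporting-read names, per-read
methylation calls — and never parses alignments itself. Internal
coordinates are 0-based half-open for intervals (reads, regions,
methylation sites) while `VariantRecord.pos` keeps the 1-based VCF
convention; conversion happens only at comparison boundaries.

## Automatic QUAL threshold (snv_filter)

Long-read small-variant callers produce a QUAL distribution with two
bell-shaped components. The filter estimates the separating threshold
nonparametrically rather than by a parametric mixture fit: a histogram
over [min, max] (default 200 bins) is smoothed with a centered moving
average (default width 9 bins), local maxima are found with a minimum
peak distance of one smoothing window, the two highest maxima are taken
as the modes (ties broken toward the most separated pair), and the
threshold is placed at the density minimum strictly between them.

Two numerical choices matter:

- **Sub-bin valley refinement.** The raw argmin bin quantizes the
  threshold to the bin width, and in a flat valley Poisson noise moves
  the argmin by a bin or two. The final threshold is therefore the
  vertex of a quadratic fit to the smoothed density over ± one
  smoothing window around the minimum bin (falling back to the bin
  midpoint if the fit is not convex or its vertex escapes the window).
  With n = 10⁵ and well-separated modes this recovers the true density
  minimum to ~0.1 QUAL units, well under one bin width.
- **Valley-depth guard.** The valley must be below 90% of the lower
  mode's density; otherwise the distribution is declared unimodal and
  no filtering is applied. Fewer than 100 QUAL values are never called
  bimodal. Both rules prevent spurious thresholds on noisy unimodal
  callsets.

Filtering keeps records with `qual ≥ threshold` (ties kept, so the
decision is stable under exact ties). The default is *soft* mode —
failing records are tagged `phasekit_lowqual` in FILTER and retained
for audit; *hard* mode removes them, which is what a downstream phasing
stage should consume.

For mixtures whose two components share a standard deviation (equal
weights), the density minimum coincides with the point where the two
component densities cross, which is the Bayes boundary; with unequal
SDs the two differ slightly and the estimator targets the observable
quantity, the mixture's valley. The recovery experiments therefore
draw a shared SD per mixture and verify against a brute-force 10⁻³-grid
crossing oracle; an unequal-SD case (N(5, 2²) + N(20, 3²)) is checked
at a looser ±0.5 tolerance.

A single joint threshold is used for SNVs and indels together.

## Read haplotagging (haplotag)

The reference haplotagger implements the documented contract of
haplotag assignment: each observed allele at a covered phased het votes
HP1 if it matches the first phased allele, HP2 if the second; votes are
restricted to the phase set covering the most sites on the read (ties
toward the smaller PS identifier, for determinism); the read takes the
majority haplotype, and an exact tie leaves it untagged. No base-quality
weighting or realignment is attempted — reproducing an external
haplotagger's likelihood model is out of scope.

## SV phasing (sv_phaser)

For one SV, its (deduplicated) supporting reads are looked up in the
haplotag table; untagged reads are ignored. The dominant phase set is
the PS tagging the most supporting reads (ties to the smaller
identifier). With `h1`/`h2` the haplotype counts within the dominant PS
and `o` the reads tagged elsewhere,

    CONFLICT = min(h1, h2) + o.

Counting other-PS reads as conflicts (rather than dropping them) is the
conservative reading of "disagreement while identifying the PS value",
and it reproduces the default behaviour that a single discordant read
blocks phasing. The SV is phased iff it is heterozygous (`het_only`,
default on — homozygous records pass through with only the CONFLICT
annotation), `tagged_reads ≥ min_tagged_reads` (default 1),
`CONFLICT ≤ conflict_threshold` (default 0), and `h1 ≠ h2` (an exact
haplotype tie never phases, whatever the threshold). The ALT allele is
placed on the majority haplotype (majority HP1 ⇒ `1|0`), since
supporting reads carry the ALT by construction of SV callers. Raising
the threshold can only add phased SVs, so the phased fraction is
non-decreasing in the threshold — the mechanism behind trading a small
conflict allowance for a higher phasing rate.

When a callset carries no read names, an optional overlap fallback
treats as supporting every tagged read whose span contains the SV start
breakpoint — and, for DEL/INV/DUP, the end breakpoint too; breakends
(BND) use only the local breakpoint and each BND record is phased
independently. Containment of the breakpoints is the minimal
unambiguous criterion; it is off by default because named supporting
reads are strictly more specific.

## Methylation phasing (meth_phaser)

Each methylation call is joined to its read's tag; calls from untagged
reads keep `"."` in HP and PS and are never dropped, so the output is a
superset annotation of the input (same order, same count). Frequencies
are aggregated per (site, haplotype) with a symmetric log-likelihood
ratio cutoff (default 2.0, the methylation callers' conventional
confidence threshold): llr ≥ cutoff counts methylated, ≤ −cutoff
unmethylated, in between is ambiguous and excluded, and the count of
excluded calls is reported so the accounting closes. Calls spanning
multiple CpG motifs contribute once, matching the grouped output of the
callers. Unphased calls form a third, explicitly labelled group.

## Trio confirmation (trio_phaser)

At a phased child het, an allele is *assignable* iff exactly one parent
carries it; the site is *informative* iff both alleles are assignable
(necessarily to different parents — the parents are opposite
homozygotes), and it votes for the parent transmitting the haplotype-1
allele. An allele carried by neither parent is a Mendelian conflict:
evidence of a genotyping error, not a phase error, so such sites are
tallied per block but never count toward confirmation. Sites with a
heterozygous or missing parent are uninformative.

A block is confirmed iff it has ≥ `min_snps` informative votes (default
10) and minority fraction ≤ `tolerance` (default 0.05, inclusive — "5%"
naturally includes the boundary, and the inclusive rule makes the 1-in-20
case exactly confirmable). Confirmed blocks are re-oriented so that
haplotype 1 is the `orient_h1` parent (paternal by default): a block
whose majority votes maternal has every phased GT swapped (`a|b → b|a`),
an involution. `flip=False` reports the decision without rewriting
genotypes, for workflows that only want the high-confidence label.
Minority-vote sites are flagged `trio_discordant` in FILTER.
`merge_confirmed` optionally gives all confirmed blocks of a chromosome
the smallest confirmed PS, since their mutual orientation is then known.

## Phasing metrics (metrics)

Truth and prediction are matched on (chrom, pos, ref, alt) and compared
at sites phased and heterozygous in both, within the prediction's
blocks. Switch errors count changes in the truth/prediction agreement
sequence between adjacent sites (flip-invariant; a mis-joined junction
costs one switch). Hamming errors are per-block `min(#disagree,
#agree)` — the edit distance under the best global flip, hence also
flip-invariant and at most half the block size. These are the standard
definitions reported by phasing evaluators; note that informal prose
sometimes swaps the two labels. Block length is measured first to last
variant (the convention of the usual stats tools), and N50 is the
largest length L such that blocks ≥ L cover half the total. Region
reports intersect variants by position (SVs by start breakpoint) and
blocks by span overlap, so a block crossing two regions counts in both.

## Synthetic data (simulate)

One linear toy contig (`chrT`) carries everything; since no algorithm
here reads sequence, no reference FASTA is needed. Defaults were chosen
to resemble a long-read dataset at desk scale: phase blocks of 20 het
sites spaced 100–1000 bp, 10 kb between blocks, 8 kb reads (so roughly
half the reads can be midpoint-assigned to a block), uniform true
haplotypes per read. The generators are pure functions of their
parameters and one seeded stream each, so identical inputs give
byte-identical files.

The SV generator realizes conflict counts *by construction*: a het SV's
supporting reads are `n_support_reads` (default 5) reads from its true
(PS, HP) cell plus exactly `n_conflict_reads` from the opposite cell,
which makes the expected CONFLICT value exact when tag errors are off
and lets the conflict-threshold mechanics be tested sharply (0 injected
conflicts ⇒ 100% phased at threshold 0; 2 injected ⇒ 0% below
threshold 2, 100% at 2 and above). The trio generator plants a known
flip decision per block and inverts individual votes at the simulated
discordance rate (2% by default, comfortably under the 5% tolerance);
the methylation generator uses haplotype probabilities 0.9/0.1 at the
imprinting fixture with llr magnitudes above the confidence cutoff.

What the simulator does **not** emulate: sequencing error profiles,
alignment artifacts around SVs (the dominant cause of real-world SV
phasing conflicts), coverage variation, reference bias, CpG clustering,
or multi-chromosome genomes. Passing tests therefore demonstrate the
correctness of the decision rules and accounting, not the error rates
to expect on real data.

## Problem sizes

The test suite and acceptance script run at deliberately small scale —
10–20 blocks, a few thousand reads, 100–200 SVs, 10⁵-value QUAL
mixtures, 50-block trios — sizes at which every property checked is
already sharply decided, and a full run completes in seconds on one
core.

## Known limitations

- Single-sample, single-trio; no pedigrees or population phasing.
- BND mates are phased independently; no joint constraint across a
  translocation's two records.
- One QUAL threshold per callset (no separate SNV/indel thresholds).
- The haplotag table is the exchange format; an alignment-tag adapter
  would be a thin addition but the core never reads BAM.
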