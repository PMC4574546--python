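# Methods

## Scope and data model

The package models one TRA/TRD-like locus as a `GermlineSet`: name-indexed
V/D/J/C records in coding orientation, each with optional recombination
signals (heptamer + 12/23-nt spacer + nonamer) and, for V genes, the
germline CDR3 length in amino acids. The 5'→3' genomic order of D and J
genes is derived from coordinates and drives both junction parsing (D
chains must respect it) and simulation (D genes are sampled without
replacement in that order). Coordinates are 0-based half-open internally;
reports use 1-based inclusive only at the presentation layer.

## Alignment and identity

All pairwise alignment uses one global scheme — match +1, mismatch −1, gap
open −4, gap extend −1 — through Biopython's `PairwiseAligner`, taking the
first reported optimum for determinism. Percent identity excludes columns
inside terminal-gap runs, so a truncated gene compared against a complete
one is scored only over the shared span. Because co-optimal alignments can
differ in gap placement depending on argument order, `pairwise_identity`
orders its arguments canonically before aligning; identity is therefore
exactly symmetric. The internal progressive MSA (average-linkage guide
tree on 100−identity, profile–profile Gotoh alignment with the same
scoring) is a convenience for unaligned input; pre-aligned FASTA bypasses
it. It is adequate for closely related V sets, not a general-purpose
aligner.

## IMGT-style numbering

V numbering is transferred from a labelled reference by global alignment
rather than re-implementing full IMGT gap placement: matched columns
inherit the reference label, insertions get sub-numbered labels
(`60.1`, …), deletions drop labels. Within each region the reference
labels fill the IMGT span end-in (first half from the region start, second
half from the region end), which matches the loop-top gapping convention
for CDRs and is an approximation for unusual frameworks. Queries under
30 % amino-acid identity to the reference are refused as unalignable.
Conserved anchors checked: 1st-CYS 23, CONSERVED-TRP 41, hydrophobic 89
(AVILMFWY), 2nd-CYS 104.

## Functionality classification

Pseudogene: frameshift (coding length not a codon multiple), in-frame
stop, missing CYS-23/CYS-104, altered J-gene F/W-G-X-G motif, or a broken
splice donor when intron context is supplied. ORF: coding intact but the
recombination signal exceeds the mismatch tolerance (defaults: 1 heptamer,
2 nonamer mismatches against consensus CACAGTG / ACAAAAACC) or a
non-anchor conserved residue deviates. Truncated records are
`undetermined`. Consensus, tolerances and spacer defaults (V 23, D 12/23,
J 12 nt) are configurable because signal conservation, not exact sequence,
is the biologically stable property. The verdict is order-independent: all
rules are evaluated and every fired rule is reported.

## Subgroups, alleles, phylogeny

Subgroups are single-linkage components of the >75 %-identity graph.
Single linkage is deliberate: in expanded subgroups some member pairs fall
below the threshold while chains of intermediates hold the group together,
and the package's monophyly check on an NJ tree is the instrument for
confirming such groups rather than resolving the conflict by fiat — when
the identity partition and the tree disagree, both are reported. Alleles
use ≥98 % within a subgroup; allele components provably refine subgroup
components. p-distances use strict complete deletion (any column with a
gap or ambiguity in any sequence is removed). Neighbor joining is the
canonical Q-criterion agglomeration with negative branch lengths clamped
to zero and ties broken on the lexicographically smallest pair of
representative leaf names, making the topology deterministic; on additive
matrices it recovers the generating topology exactly (property-tested).

## Junction decomposition

V assignment precedes J, which precedes D; ambiguous boundary nucleotides
go to germline V/J rather than to N or D (greedy longest V prefix, then
longest J suffix). This mirrors the convention of treating the V and J
flanks as fixed context and concentrates all inference in the core. D
detection requires ≥5 consecutive matching nucleotides (configurable);
optionally a stretch extends across an isolated substitution when ≥2
matching nucleotides flank it on each side, reproducing how substituted
D regions are still recognisable. Chain selection maximises matched
nucleotides minus one per substitution, subject to non-overlap and genomic
order, with deterministic ties (fewer segments, then 5'-most placement) —
the published material gives no tie rule, so determinism was the design
goal, and tie events are flagged on the record. P nucleotides are not
modelled separately from N. Productivity = junction length ≡ 0 (mod 3) and
a stop-free translation.

Known estimator bias: when the first non-germline nucleotide after a
boundary happens to match the next germline base (probability ≈ 1/4 per
boundary), the greedy rule over-assigns germline and under-estimates the
trim. Tests therefore assert exact trim recovery on the informative subset
and exact full recovery only for noise-free clones.

## Repertoire statistics

D usage counts clones containing ≥1 stretch of a D (not stretch
multiplicity) over the denominator of clones with any recognisable D;
V and J usage use all clones. This split-denominator convention matches
how such panels are reported (e.g. "25/50" for D usage in a 56-clone set
of which 50 show a D, "38/56" for J usage) and is stated in output
headers. CDR3 length is junction nt / 3 on productive clones. Text
reports round half-up to 2 decimals; JSON is unrounded.

## Simulator and what it does (not) show

`simulate_germline` grows each subgroup from a shared random root:
subgroup ancestors at 0.35 per-site divergence, members at 0.10, alleles
at 0.01 — values that place subgroup identities around the 75 % rule's
working range and allele identities near 99 %. D genes default to the
seven observed lengths 9, 11, 11, 12, 13, 13, 15 nt; J genes are built
with an intact F/W-G-X-G motif after a 15–21-nt 5' window (one J is made a
motif-disrupted pseudogene, as in the locus that motivated the design).
The J-window range is chosen so that, with the default trimming and
N-insertion means, productive CDR3 lengths centre in the high-teens of
amino acids as observed for V-delta loops.

`simulate_rearrangement` draws the D count from (0.11, 0.23, 0.37, 0.27,
0.02) — the observed 6/13/21/15/1 split of a 56-clone panel — trims each
joined end geometrically (3'V mean 4.09 nt, 5'J mean 2.12 nt, D ends mean
1.0 nt), inserts Poisson(3) N runs of uniform composition, and optionally
resamples until productive (≤1,000 attempts). The 3'V trim may exceed the
CDR3 window (observed trims reach 13 nt against 12-nt windows), so the V
contribution floors at zero while the raw draw is recorded; the draw is
capped at 25 nt only to bound pathological tails, a cap that changes the
mean by <0.02 nt. J and D trims are capped at their windows. The D-end
trim mean and the Poisson N-length law are modelling stand-ins — no
published distribution exists for them — and are labelled as such.

The simulator emulates substitution-style divergence, trimming, N
insertion and productivity selection. It does not model somatic
hypermutation, P nucleotides as a distinct class, indel divergence within
subgroups, tissue-specific gene preferences, sequencing error, or thymic
selection. Passing tests therefore demonstrate correctness of the rules
and estimators under these generative assumptions, not performance on
archival cDNA with those extra effects.

## Problem sizes and determinism

The validation experiments use 10,000 fuzzed junctions for the partition
identity, 1,000 noise-free clones for exact recovery, 5,000 clones for
parameter recovery (3 standard errors around the configured means; 99 %
binomial/multinomial bands for usage and D-count frequencies), 100 random
6–10-taxon additive matrices for NJ consistency, and 20–40 germline seeds
for subgroup recovery — sizes chosen so the whole suite and the
acceptance script each run in minutes on one CPU while keeping the
statistical bands tight. Parameter-recovery runs disable the productivity
filter: conditioning on in-frame junctions selects on junction length and
would bias realized trim means relative to the configured generative
means, which are the quantity under test. All randomness flows from
explicit integer seeds; identical seeds give byte-identical simulator
output.

## Reproducing the published repertoire statistics

The decompose+summarize pipeline reproduces published junction statistics
(mean V-delta CDR3, trim means, J usage, D-less clone count) when run on
the archived cDNA clone sets; those sequences are not redistributable
here, so the corresponding end-to-end check expects user-supplied
downloads at `data/trd_clones.fa` / `data/tra_clones.fa` (TRA accessions
LN846380–LN846426 in ENA; TRD clone series Z12/AJ29/AJ00 in IMGT/LIGM-DB)
plus a matching germline set, and fails with an explanatory message when
they are absent. The acceptance script instead reports the analogous
quantities computed on the simulated study-condition repertoire, where
the generative parameters are the published observations.
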