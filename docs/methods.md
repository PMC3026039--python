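# Methods

## The model

An LTR-retrotransposon (LTRr) family is represented by a consensus sequence
segmented into LTR5′, internal region and LTR3′ (`FamilyModel`). The two
LTRs are identical at generation time, as they are in a fresh insertion;
total lengths default to 5–8 kb with LTRs of 200–400 bp. A genomic copy is
one of:

* **proviral complete** — the full consensus, possibly substituted;
* **proviral fragmented** — additionally carrying indels ≥ 10 bp;
* **solo-LTR** — a single LTR left by intra-element recombination;
* **gap-masked** — a provirus whose internal region is partly or fully
  replaced by a track of undetermined bases (N), modelling unsequenced
  assembly gaps. Copies with a fully masked internal region cannot be
  classified and are the source of "unknown"-condition calls.

Every copy is flanked by a 4–6 bp target-site duplication copied verbatim on
both sides. Divergence from the consensus is the age proxy throughout and is
always computed with *pairwise deletion*: mismatches divided by the number
of alignment columns in which both rows carry a determined base (gap and N
columns excluded from numerator and denominator); fewer than 50 comparable
columns returns "not determined".

## Synthetic-data generator

Substitutions are uniform over non-deleted sites and uniform over the three
alternative bases (a Jukes–Cantor-like single-parameter model); the realized
substitution count is exactly `round(d · L)`, so the planted divergence is
the target divergence up to rounding. Indels are applied after substitutions
at stated consensus offsets and never overlap.

Sampled complements default to the census composition: 41 % solo-LTRs, 19 %
complete / 23 % fragmented / 13 % partly-gap-masked proviruses, 4 % fully
masked; divergence is exponential with mean 1.3 %, truncated at 10 % (this
places ≈54 % of copies at ≤1 % divergence); indel events are deletions with
probability 2/3; sizes are drawn from the classes 10–100 / 100–1000 /
1000–1800 bp with weights 47/30/23 (deletions) and 38/37/25 (insertions),
log-uniform within a class. The upper bound of the ">1 kb" class is set to
1.8 kb so that any single indel remains bridgeable by the 2-kb chaining gap
of the search stage; fragment counts per copy are 1–4 with probabilities
0.35/0.25/0.25/0.15, giving a 60:40 moderately:highly-fragmented split.
Indels are confined to the internal region with a 60 bp margin and 50 bp
spacing, and deletions keep an 800 bp visible internal core (total deletion
of the internal region is solo-LTR formation, a separate category).

Insertion sites are sampled per compartment with rates proportional to
`multiplier × compartment length` (defaults PH 8, DIH 6, CIH 5, EU 1 —
chosen to reproduce the qualitative heterochromatin enrichment, not any
published per-compartment magnitude), with a 200 bp minimum separation and
2 kb arm-edge margins. Blueprints tile each arm with PH at the proximal end,
a small intercalary block and euchromatin; genes (1–4 exons, 2–8 kb) are
laid on a jittered grid at ≈60/Mb in euchromatin and ≈13/Mb in
heterochromatin. Compartment boundaries, genes and exons are lifted through
the insertions so that an insertion falling inside a feature stretches it —
the ground-truth manifest addresses the emitted genome exactly.

Determinism: one master seed; plans, per-arm backgrounds, genes and each
fragment derive their own `SeedSequence` streams, so identical inputs give
byte-identical outputs and arms are regenerable independently.

What the generator does **not** emulate: population polymorphism (every
copy has occupancy 1), nested insertions, and mosaic recombinant copies
(used only as a hand-built test fixture). Background sequence is i.i.d. at a
set GC content — there are no host repeat families, so the measured false
positive rate on synthetic genomes is a best case relative to a real
assembly.

## Homology search

A BLASTN-like seed-and-extend stage. The genome is indexed by exact 11-mers
(windows containing N are never indexed; arms are joined with N spacers so
no window spans two arms). Each family consensus, forward and
reverse-complemented, is looked up and every seed is extended with an
anchored, adaptive-band, x-drop Gotoh DP (match +1, mismatch −2, a gap of
length g costs 5 + 2g, X-drop 20; columns involving N score 0). Alignments
scoring ≥ 30 are kept. Seeds falling inside an already-aligned region of
the same family and strand are skipped.

Because N columns score 0 — flat rather than negative — an extension crosses
an equal-length N track; a provirus whose internal region is masked by Ns
therefore emerges as a single alignment spanning both LTRs, which is what
lets the condition rules see the mask.

Local alignments are chained into candidate copies when genome and
consensus gaps are each ≤ 2 kb and the link is a plain indel: at least one
of the two axis gaps must be ≤ 300 bp (a link gapped far on both axes would
imply a simultaneous large deletion *and* insertion at one point — in
practice the signature of two distinct nearby copies being fused). A
genome-contiguous link may jump *backwards* on the consensus by up to 1 kb:
the signature of a tandem duplication. Per-alignment identity is computed
from an edlib alignment of the matched segments, excluding N columns.

With X-drop 20, an extension stops at any indel ≥ 8 bp (cost ≥ 21), so
chained alignment boundaries mark the indels; the x-drop score of the best
seeded alignment equals the exhaustive Smith–Waterman score whenever the
optimal alignment contains an exact 11-mer and no internal score dip > 20 —
the property the oracle tests exercise on short mutated pairs.

## Copy annotation

The copy sequence (reverse-complemented for minus-strand candidates) is
aligned end-to-end against the consensus span its chain covers. The global
alignment is *stitched* from the chained local alignments used as anchors:

* anchor interiors that are equal-length and substitution-dominated
  (mismatch rate ≤ 0.15) are paired column-by-column. A unit-cost DP is
  avoided here because its cost ties can rewrite adjacent mismatch pairs as
  gap pairs, which pairwise deletion would then drop — deflating the
  divergence of old copies by up to ~0.6 percentage points;
* other anchor interiors use edlib's global alignment;
* junction windows between anchors, padded with 64 bp of anchor context on
  each side, use an affine-gap global aligner (open −10.1, extend −0.1,
  match +1, mismatch −2). The affine penalty keeps a long indel in a single
  gap run — a unit-cost DP is placement-ambiguous there — so planted indel
  sizes are recovered exactly and offsets to within a few bp.

**Family rules.** A candidate is accepted if it shows (1) ≥ 400 contiguous
aligned bp of the internal region at ≥ 90 % identity (windows of 400
non-gap, non-N internal columns spanning < 800 raw columns), or (2) ≥ 90 %
identity over at least half of either LTR. The "pol and/or gag region" is
operationalized as the whole internal segment, a conservative superset.
Overlapping accepted candidates (> 50 % of the shorter) compete; the one
maximizing identity × aligned length wins, ties broken lexicographically by
family name. Every scanned candidate ends in exactly one of
{annotated, rejected-by-family-rules, rejected-overlap}.

**Reliability.** The stitched alignment's score (match +1, mismatch −2, gap
run cost 6 + 0.2·len, N columns 0) is divided by the perfect score over its
scorable (non-gap, non-N) columns; a ratio < 0.4 marks the alignment
unreliable — SV, divergence, fragmentation and the partial flag become
undetermined, but the copy stays in the census. Mosaic copies (interleaved
segments of two families) score far below the floor; copies dominated by
clean sequence or by N (which is excluded from the denominator) stay above
it.

**Condition.** Proviral iff ≥ 30 internal-region columns carry determined
bases on both rows; solo-LTR iff identity is exclusively to an LTR; unknown
when ≥ 50 % of the internal columns the alignment reaches are N, or, for an
LTR-only hit, when an N track both covers ≥ 50 % of the adjacent
internal-length genomic window and begins within 100 bp of the junction.

**Structural variation.** Maximal gap runs ≥ 10 bp in the copy row are
deletions; in the consensus row, insertions. Every run is left-normalized
(slid to its leftmost score-equivalent placement, the VCF convention); an
insertion whose content then matches consensus within ±500 bp at ≥ 90 %
identity is a duplication — normalization is what lands a tandem-dup run on
the repeat boundary so this test can fire. Consensus sequence missing at a
copy end counts as a terminal deletion only when the genomic flank is
determined (non-N); otherwise the missing span is attributed to an
unsequenced gap. Events overlapping an LTR carry a (5′)/(3′) flag.
Fragmentation: 0 indels and no N → complete; 0 indels with N → unknown;
1–2 → moderately fragmented; ≥ 3 → highly fragmented. "Partial" means
summed deletions strictly exceed 3 % of the consensus length; solo-LTRs are
partial by construction.

**TSD.** The longest exact 4–6 bp word ending at the 5′ junction and
beginning at the 3′ junction; undetermined when a contig edge truncates a
flank. Alignment-boundary slop of a few bp can hide a real TSD, so detection
is best-effort on diverged copies.

## Genomic context

Compartment maps are ordered labeled intervals per arm. PE is derived by
walking euchromatic bp from the PH edge (on the side with more euchromatin)
toward the telomere, skipping non-euchromatic blocks, until the PE size is
accumulated (3 Mb for the real genome; scaled runs use a proportional
value); remaining euchromatin is NPE. Arms without a PH anchor become
all-NPE with a warning; arms with less euchromatin than the PE size become
all-PE. Copy membership in any region uses the interval midpoint (keeping
counts additive); bp tallies use overlap truncation.

Clusters are single-linkage components under an edge-to-edge gap ≤ 10 kb,
inclusive at exactly 10 kb (a start-to-start variant is available as a
switch, since the published "within 10 kb of each other" is ambiguous).
Gene association: a copy inside transcription borders is exonic if it
overlaps any exon, else intronic (proximity 0); outside, it associates with
a gene within 1 kb of either end — 5′ upstream of the transcription start,
3′ downstream of the end, strand-aware. The published table legend states
the opposite 5′/3′ word order; it is treated as an erratum and the
conventional strand-aware reading is used. A copy may associate with
several genes; copy-level summaries deduplicate.

Windowed densities tile non-overlapping windows from the arm start
(insertion counts by midpoint; %-bp with straddling copies split
proportionally; the final short window normalized by its true length).
Breakpoint neighborhoods report %-bp TE density inside a rearrangement, on
the proximal and distal outside segments, in each 50-kb flank pair and in a
1-Mb window centered on the proximal breakpoint.

## Statistics

Region goodness-of-fit χ² uses expected counts proportional to region
length in bp, df = 1; 2×2 tables use Pearson χ² without continuity
correction, df = 1. Both conventions are fixed by recomputation: the
published X-overrepresentation (36.39), short-arm (5.08), PE-enrichment
(87.13) and proviral:solo PH-vs-NPE (18.66) statistics are all recovered
from the packaged per-region tables only under exactly these choices
(Yates correction or gene-count weighting break them). The
heterochromatin-vs-NPE divergence comparison is a pooled-variance Student t
on the five per-arm heterochromatin means against the five per-arm NPE
means, which reproduces the published t = 5.91, p = 0.0004; copy-level and
Welch variants are available. Divergence histograms use 0.5
percentage-point bins over 0–10 % by default (the bin width is a
parameter), with headline shares of copies at ≤ 1 % and ≥ 5 % divergence.

The packaged AgamP3 census tables (`ltrscape/data/agamp3_*.tsv`) are inputs,
not results: every statistic above is recomputed from their counts and
sizes at call time.

## Numerical and I/O conventions

Coordinates are 0-based half-open internally; every emitted table is
1-based inclusive, except BED (0-based half-open per that standard).
Divergence is printed at one decimal of a percent and SV strings in the
supplementary dialect (`del120(5′), ins45`; `No`; `ND`); re-importing a
table therefore quantizes divergence to 0.1 pp, which can move copies
across the 1 %/5 % class boundaries — round-trip checks compare at that
precision. Supplementary-style tables import from TSV or XLSX. Emitted
TSV/BED/GFF3 carry `#` provenance headers (tool version, configuration
hash, seed); the configuration hash excludes the output directory, so runs
into different directories remain byte-identical.

## Validation scope and problem sizes

All accuracy claims are measured on synthetic genomes against the
generator's manifest, at these default sizes: the benchmark genome is two
1.1-Mb arms with 400 planted copies from 10 families (chosen so that the
scored categories — ≥ 100 proviral copies at ≤ 5 % divergence, ≥ 50
indel-free copies ≥ 1 kb — are populated with comfortable margin);
negative controls scan six 300-kb TE-free random genomes; the
breakpoint-uniformity simulation places 500 copies on a 10-Mb arm; the
aligner-vs-exhaustive-DP oracle runs on mutated pairs ≤ 200 bp whose
optimal alignments contain an exact 11-mer and indels ≤ 5 bp. On these
conditions the pipeline reaches 100 % detection recall and precision
(copies ≥ 500 bp, divergence ≤ 5 %), 100 % condition accuracy, ≥ 99 %
fragmentation accuracy and indel recovery (±2 bp size, ±5 bp offset), and a
divergence-estimator bias below 0.01 pp. Passing these tests shows the
implementation is internally consistent with its own generative model; it
does not bound performance on real assemblies, where segmental duplication,
nested repeats, mosaic copies and non-uniform base composition add failure
modes the generator deliberately omits.

## Known limitations

* Family assignment treats the entire internal region as pol/gag; a
  per-gene segmentation table would tighten rule 1.
* Chaining resolution: two same-family copies closer than ~300 bp on both
  axes of the link geometry could still fuse; indels > 1.8 kb split a copy
  into two candidates.
* TSD detection requires exact junction placement and is unreliable above
  ~5 % divergence.
* The unreliable-alignment floor (0.4) separates clean from mosaic copies
  by a wide margin on synthetic data but is not calibrated on real mosaic
  elements.
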