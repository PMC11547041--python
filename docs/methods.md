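# Methods

`famevol` re-implements, as a tested and reusable pipeline, the computational
core of a genome-wide gene-family evolution survey for a plant two-domain
family (an N-terminal DPBB domain followed by a C-terminal CBM63 domain, with
subfamilies EXPA, EXPB, EXLA and EXLB — the expansin architecture). This note
records the models, conventions and numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Identification cascade

Candidate proteins pass three gates, mirroring a BLASTP → HMMER-style survey:

1. **Homology gate.** Best local alignment (Smith–Waterman, BLOSUM62, gap
   open 11, extend 1; a gap of length L costs `open + L·ext`) against labeled
   reference proteins must exceed coverage > 0.30 **and** identity > 0.30
   (both strict, coverage query-relative) and pass a permutation e-value
   < 1e-3.
2. **Domain confirmation.** Both domains must be detected by ungapped PSSM
   window scan at e-value < 1e-5, with the DPBB hit N-terminal to the CBM63
   hit. PSSMs are natural-log odds over a uniform background with a
   background-proportional pseudocount (default 1.0), built from seed
   alignments; columns with > 50 % gaps are dropped.
3. **Longest isoform.** One protein per gene: the longest isoform, ties
   broken by the lexicographically smallest transcript id.

Subfamily labels come from the nearest labeled reference by global-alignment
score; the diagnostic motifs (HDF in EXPA/EXPB vs TDF in EXLA/EXLB; an
N-terminal CDRC only in EXLA) act as an independent consistency check — a
disagreement flags the member `motif-discordant` but keeps the
reference-based label, the role a secondary domain-database confirmation
plays in survey practice. The GACG–CGAC spacing (canonically ~30 residues)
is reported per member, not filtered on.

### Empirical e-values

E-values are empirical permutation tails, not Karlin–Altschul statistics:

    e-value = D · (1 + #{shuffled score ≥ observed}) / (n_shuffles + 1)

with Fisher–Yates residue shuffles (composition-preserving null) and D the
database size. This has no fitted parameters and is exactly reproducible
under a seed, at a cost: the smallest representable e-value is
`D/(n_shuffles+1)`. The thresholds therefore dictate the null sizes — the
homology gate (strict < 1e-3, per-pair D = 1) uses 1 000 shuffles and the
domain scan (strict < 1e-5) uses 100 001, the attainable minima. The scan
null is the max window score per shuffled protein; a branch-and-bound bound
(suffix sums of per-column maxima) prunes the window loop, and the loop
exits early once a hit provably cannot reach its threshold. Windows with
non-positive log-odds score are never candidates (they do not beat the
background model), so domain-free proteins skip the null loop entirely.

## Gene structure

Gene models are parsed from GFF3 (internally 0-based half-open; I/O is
exactly 1-based inclusive). Gene length is defined as the chosen
transcript's genomic span, so gene length = total exon length + total intron
length by construction; this makes the gene-length ~ exon/intron-length
correlation analysis self-consistent. Correlations are Pearson r with the
exact two-sided t-transform p-value; no multiple-testing correction is
applied. Molecular weight is the sum of average residue masses plus one
water (18.0153 Da). Isoelectric point is the bisection root of the
Henderson–Hasselbalch net charge over pH ∈ [0, 14] using the EMBOSS pKa set
(N-term 8.6, C-term 3.6, D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8,
R 12.5), iterated to |Q| < 1e-4; published pI tools use other optimized pKa
sets, so absolute values are tool-specific while orderings are robust.

## Intron-in-domain patterns

A domain at protein residues [s, e] occupies spliced-CDS nucleotides
[3(s−1)+1, 3e]. The junction after spliced position p (an intron between
CDS nucleotides p and p+1) is inside the domain iff `3(s−1)+1 ≤ p < 3e`:
an intron interrupting the domain's first codon counts, one immediately
after the last codon does not, and phase-splitting junctions need no special
casing. Only CDS junctions count. The pattern is the ordered pair
(introns in DPBB, introns in CBM63); (2,0), (1,0), (3,0) and (3,1) carry the
conventional names Patterns I, II, III and V. No fixed count pairs exist in
the literature for the remaining named patterns, so other pairs are labeled
canonically `P(d,c)` and receive unused roman numerals by dataset rank only
inside a census.

## Duplication mechanisms

Tandem clusters are maximal runs of family genes on one chromosome with at
most one intervening protein-coding gene (rank gap ≤ 2), requiring ≥ 2
members. Large-scale duplication follows the neighborhood recipe: the 20
protein-coding genes up- and downstream of each family gene (41-gene
window, truncated at chromosome ends); reciprocal-best local-alignment
anchors (identity ≥ 0.5, coverage ≥ 0.5, a shared-4-mer prefilter skips
hopeless pairs) between two windows are chained into collinear blocks —
longest strictly-monotone subsequence, both orientations, consecutive-anchor
rank gaps ≤ 25 on both sides, ≥ 5 anchors per block, each anchor in at most
one block. The block-size and gap defaults (5, 25) mirror the documented
defaults of the standard collinearity tool; chain score is the unit-weighted
anchor count so the chaining is exactly oracle-checkable. Within-species
blocks whose two regions share genes are rejected (overlapping windows
otherwise produce mirror-symmetric artifact chains), discoveries of one
physical block from both directions are collapsed, and window-truncated
fragments that are strict sub-blocks of a larger block are pruned.
Mechanism classes: tandem, wgd_segmental, both, dispersed; "both" is a real
class because tandem and collinear evidence are tallied independently.
Counts normalize to the diploid level as `count · 2 / ploidy`.

## Ka/Ks (NG86)

Protein pairs are globally aligned and back-translated to codon alignments
(gaps in whole-codon triplets). Sites follow the Nei–Gojobori counting
definition: per codon position, the fraction of non-stop single-nucleotide
changes that are synonymous; S sums the three fractions, N = 3 − S. Sites
are averaged between the two sequences over gap-free codon columns (≥ 30
required). Differences average over all mutational pathways that avoid stop
codons; a codon pair with no legal pathway is flagged and skipped.
Proportions are Jukes–Cantor corrected, `d = −(3/4)·ln(1 − 4p/3)`, undefined
at p ≥ 3/4 ("saturated"). Pairs with Ks > 2.0 are discarded before
classification (ratio > 1 positive, < 1 purifying, = 1 within 1e-12
neutral). NG86 with JC correction is used rather than a model-averaged
multi-method suite because it is closed-form, canonical and exactly testable
against codon-enumeration oracles. The default pair set is within-species
member pairs sharing a tandem cluster or collinear block (an explicit,
documented reading of "paralogous gene pairs"); all-pairs mode is available.

## Phylogeny concordance

The family tree is Saitou–Nei neighbor joining (Q-criterion; ties broken by
the smallest taxon-index pair; negative branch estimates clamped to zero
with a warning; the unrooted tree is written rooted at the midpoint of the
final join, which leaves all leaf-to-leaf path lengths unchanged) on
p-distances with pairwise gap deletion (pairs under 50 comparable columns
are flagged) from the progressive MSA. The MSA uses a 3-mer cosine-distance
NJ guide tree and affine profile–profile alignment with mean-of-pairs
BLOSUM62 column scores — deliberately simple, since the claim exercised here
is subfamily clustering, not branch support. A subfamily is *concordant*
when some edge bipartition of the unrooted tree separates exactly its
members (clan test); singletons are excluded from the denominator.
Bootstrap support is out of scope; the concordance fraction replaces it.

## Expression

FPKM = reads · 1e9 / (library size · transcript length). Categories:
expressed (FPKM ≥ 1, boundary inclusive), weak (0 < FPKM < 1), silent
(FPKM = 0). "Preferentially expressed" has no published threshold; the
default flag marks genes at ≥ 10× the within-species median FPKM of
expressed members (τ configurable).

## Synthetic data: what it emulates, and what it does not

The generator plants a complete, machine-readable ground truth. The domain
"blueprint" — consensus sequences for DPBB (100 aa, GACG and CGAC motifs 30
residues apart, an HDF/TDF diagnostic slot) and CBM63 (80 aa), subfamily
variants (domain interiors diverge ~6 % between subfamilies, reflecting
strong domain conservation; flanking regions are subfamily-specific) — is a
fixed world shared across species and seeds, playing the role of Pfam models
and curated references. Members add ~5 % divergence in domains and ~10 % in
flanks; decoys carry exactly one domain; background genes carry neither.
CDS are back-translated with uniform synonymous codon choice; introns
(60–500 bp, GT..AG) are inserted at junction offsets sampled inside/outside
the domain CDS windows (12-nt margins from domain edges) to realize each
planted (DPBB, CBM63) pattern under the module's own counting rule. Half the
family genes sit on the minus strand. Tandem arrays are mutated *copies* of
a base member (3 % per-site) so array pairs have well-defined Ka/Ks;
placement keeps all other family genes ≥ 2 intervening genes apart, making
the planted arrays exactly the realized tandem clusters. Segmental events
copy a ≥ 10-gene window (per-site substitution probability, stop-creating
changes reverted, motif codons frozen, splice ends kept) onto another
chromosome. Expression categories follow planted proportions (largest-
remainder rounding); expressed FPKM is log-uniform on [1, 300), weak uniform
on (0, 1), silent exactly 0. All randomness flows from one seed through
named substreams (per chromosome, gene, purpose), so identical specs give
byte-identical files.

Not emulated: realistic intergenic composition, transposable elements,
UTRs, alternative splicing beyond one optional shorter second isoform
(present only to exercise longest-isoform selection), pseudogenes, and
real sequence evolution along a species tree. Passing the benchmark
therefore shows the pipeline's logic is correct against planted truth at
realistic signal strengths; it does not certify performance on real genomes
with fragmented assemblies or misannotation.

## Problem sizes and determinism

The test suite and the acceptance script run the study at desk scale, the
package's own benchmark sizes: identification on bundles of 3 species with
~13 members, 50 background genes and 4 decoys per species; duplication
recovery on single-species genomes with one 3-gene tandem array and one
10-gene duplicated block; Ka/Ks calibration with 50 replicate simulated
pairs of 300 codons per ω ∈ {0.2, 0.5, 1, 2}; NJ checks on 20 random
additive 8-taxon matrices. Every stage is seeded; a pipeline re-run with the
same config and seed reproduces byte-identical reports (the run manifest
hashes the configuration minus the output directory).

## Known limitations

* The permutation e-value floor ties thresholds to null sizes; pushing the
  domain threshold below 1e-5 would require proportionally more shuffles.
* The collinearity chain score is anchor count, not e-value-weighted; a
  weighted-score hook exists but is not the default.
* EXPA vs EXPB have no separating motif; their separation rests entirely on
  reference proximity, as it rests on phylogenetic clustering in survey
  practice.
* NG86 assumes uniform substitution (no transition/transversion bias);
  the codon-pair simulator matches this assumption, which is why the ω = 1
  calibration is clean. Real data with strong κ would bias NG86 in the
  usual, well-documented ways.
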