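# famevol

Gene-family evolution analysis for two-domain plant families — built around
the expansin architecture (an N-terminal **DPBB** domain followed by a
C-terminal **CBM63** domain, subfamilies EXPA / EXPB / EXLA / EXLB) but
driven entirely by configurable references, seed alignments and thresholds.

Given per-species protein FASTA, CDS FASTA and GFF3 annotation, `famevol`
runs the full survey a molecular-evolution study performs on such a family:

* **Identification cascade** — homology gate against labeled references
  (local alignment, coverage > 30 %, identity > 30 %, permutation e-value
  < 1e-3), dual-domain confirmation by PSSM scan (e-value < 1e-5, DPBB
  before CBM63), longest-isoform selection, and subfamily assignment by
  nearest reference with diagnostic-motif consistency checks (HDF vs TDF,
  N-terminal CDRC).
* **Domain-architecture census** per species (both / DPBB-only /
  CBM63-only / neither).
* **Gene structure** — exon/intron lengths and counts, protein length
  bins, molecular weight, isoelectric point, and gene-length vs
  exon/intron-length correlations.
* **Intron-in-domain patterns** — exact projection of protein-domain
  coordinates through the CDS onto the genome; the (DPBB, CBM63) intron
  count pair per gene, with the conventional Pattern I/II/III/V names for
  (2,0)/(1,0)/(3,0)/(3,1) and a pattern census.
* **Duplication mechanisms** — tandem clusters (≤ 1 intervening gene),
  ±20-gene neighborhoods, reciprocal-best anchor chaining into collinear
  blocks (≥ 5 anchors, rank gaps ≤ 25, both orientations), mechanism
  classification (tandem / wgd_segmental / both / dispersed) and
  ploidy-normalized counts.
* **Selection** — Nei–Gojobori (NG86) Ka/Ks with Jukes–Cantor correction
  on codon alignments back-translated from protein alignments, the Ks > 2
  saturation filter, and selection classes.
* **Phylogeny concordance** — progressive MSA, p-distances, neighbor
  joining, and an unrooted clan test per subfamily.
* **Expression** — FPKM categorization (expressed ≥ 1 / weak / silent),
  census, and a preferential-expression flag.

A first-class synthetic-genome module (`famevol.syndata`) generates
multi-species genomes with planted members, decoys, tandem arrays,
duplicated collinear blocks, intron patterns and expression categories —
with machine-readable truth tables, so every stage is testable end to end
without downloads. See `docs/methods.md` for models and conventions.

## Worked example

Generate a one-species synthetic study and run the full pipeline:

```
$ famevol simulate --out demo --seed 4 --species 1 --members 6 --background 25
wrote bundle to demo (1 species, 12 planted members); config: demo/config.yaml
$ famevol run --config demo/config.yaml
12 family members; reports in demo/results
```

(The 6 requested members grow to 12 planted genes: one 3-gene tandem array
and a 10-gene duplicated block that copies family genes add the rest.)

`demo/results/members.tsv` lists each identified member with its chosen
transcript, subfamily, domain coordinates and motif checks:

```
gene_id    species  transcript    subfamily  protein_length  dpbb_start  dpbb_end  cbm63_start  cbm63_end  motif_discordant  gacg_cgac_spacing
sp1_g0000  sp1      sp1_g0000.t1  EXPA       216             20          119       128          207        0                 30
sp1_g0001  sp1      sp1_g0001.t1  EXPB       245             26          125       134          213        0                 30
sp1_g0002  sp1      sp1_g0002.t1  EXLA       277             26          125       134          213        0                 30
```

Every member carries both domains in the right order (DPBB before CBM63)
and the canonical ~30-residue GACG–CGAC spacing. The pattern census
(`pattern_census.tsv`) mirrors the planted intron architecture — here
Pattern I, two introns in the DPBB domain, dominates at 58.33 % — and
`kaks.tsv` holds the NG86 estimates for paralogous pairs from the tandem
array and the duplicated block:

```
gene_a     gene_b     ka       ks       ratio    n_sites  s_sites  selection  discarded  reason
sp1_g0001  sp1_g0036  0.03299  0.02786  1.18395  588.75   146.25   positive   0
sp1_g0003  sp1_g0040  0.03303  0.04168  0.79258  557.00   148.00   negative   0
```

Ka and Ks are substitutions per nonsynonymous / synonymous site; the
ratio diagnoses selection (here the duplicate pairs scatter around 1, as
expected for copies diverging without selective constraint in the
simulator). `tree.nwk` and `concordance.tsv` report the NJ tree and
whether each subfamily forms a clan; `expression_census.tsv` gives the
three-way expression split; `summary.tsv` aggregates per-subfamily totals,
per-lineage means and diploid-normalized counts; `manifest.json` records
the seed and configuration hash — re-running the same config and seed
reproduces every report byte for byte.

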