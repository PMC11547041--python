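"""Synthetic multi-species genomes with planted, machine-readable ground truth.

The generator emulates the input side of a plant two-domain gene-family study:
each species gets chromosomes populated with background protein-coding genes,
planted family members carrying an N-terminal DPBB-like domain and a
C-terminal CBM63-like domain, single-domain decoys, tandem arrays obeying the
<=1-intervening-gene rule, and duplicated collinear gene blocks.  Every
planted structure is recorded in TruthTables so each pipeline stage can be
scored against ground truth.

The synthetic domain "blueprint" (domain consensus sequences, subfamily
variants, diagnostic motifs) is a fixed world shared by all species and seeds,
playing the role that Pfam models and curated reference proteins play for real
data:

* DPBB consensus contains a GACG motif and a CGAC motif ~30 residues apart;
* EXPA/EXPB carry an HDF tripeptide in the DPBB, EXLA/EXLB carry TDF;
* EXLA additionally carries an N-terminal CDRC motif;
* domain interiors are strongly conserved across subfamilies (as protein
  domains are), while the N-terminal, linker and C-terminal flanks are
  subfamily-specific.

All randomness flows from one top-level seed through named substreams (one per
chromosome / gene / purpose), so identical specs give byte-identical files and
partial regeneration is stable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .seqalign import AA20, write_fasta

SUBFAMILIES = ("EXPA", "EXPB", "EXLA", "EXLB")
EXPRESSION_CATEGORIES = ("expressed", "weak", "silent")
# study-wide expression category proportions (expressed / weak / silent)
DEFAULT_EXPRESSION_PROPORTIONS = (0.3913, 0.1917, 0.4170)

DPBB_LEN = 100
CBM63_LEN = 80
_NFIX = 10       # fixed N-terminal stub (holds the EXLA CDRC motif)
_LINKER = 8
_MIN_CORE = _NFIX + DPBB_LEN + _LINKER + CBM63_LEN  # 198

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_STANDARD_TABLE.stop_codons))
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def substream(seed: int, *names) -> np.random.Generator:
    """Named RNG substream derived from the top-level seed."""
    key = [int(seed) & 0x7FFFFFFF]
    key += [zlib.crc32(str(n).encode()) & 0x7FFFFFFF for n in names]
    return np.random.default_rng(key)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float,
                    frozen: set[int] = frozenset()) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in frozen:
            continue
        if rng.random() < rate:
            out[i] = AA20[int(rng.integers(0, 20))]
    return "".join(out)


# ---------------------------------------------------------------------------
# the fixed synthetic-world blueprint
# ---------------------------------------------------------------------------

_GACG_AT = 20     # DPBB columns 20..23 hold GACG
_CGAC_AT = 54     # ~30 residues later: CGAC
_DIAG_AT = 75     # HDF / TDF tripeptide slot
_DPBB_FROZEN = set(range(_GACG_AT, _GACG_AT + 4)) | set(range(_CGAC_AT, _CGAC_AT + 4)) \
    | set(range(_DIAG_AT, _DIAG_AT + 3))


def _build_blueprint():
    rng = np.random.default_rng(970031)
    dpbb = list(_random_protein(rng, DPBB_LEN))
    dpbb[_GACG_AT:_GACG_AT + 4] = "GACG"
    dpbb[_CGAC_AT:_CGAC_AT + 4] = "CGAC"
    dpbb[_DIAG_AT:_DIAG_AT + 3] = "HDF"
    dpbb = "".join(dpbb)
    cbm63 = _random_protein(rng, CBM63_LEN)
    sub = {}
    for name in SUBFAMILIES:
        srng = substream(970031, "subfamily", name)
        d = list(_mutate_protein(srng, dpbb, 0.06, frozen=_DPBB_FROZEN))
        d[_DIAG_AT:_DIAG_AT + 3] = "HDF" if name in ("EXPA", "EXPB") else "TDF"
        c = _mutate_protein(srng, cbm63, 0.06)
        nterm = list(_random_protein(srng, _NFIX))
        if name == "EXLA":
            nterm[2:6] = "CDRC"
        npad = _random_protein(srng, 20)     # drawn from per member as needed
        linker = _random_protein(srng, _LINKER)
        cterm = _random_protein(srng, 40)
        sub[name] = {
            "dpbb": "".join(d),
            "cbm63": c,
            "nterm": "".join(nterm),
            "npad": npad,
            "linker": linker,
            "cterm": cterm,
        }
    return {"dpbb": dpbb, "cbm63": cbm63, "subfamilies": sub}


BLUEPRINT = _build_blueprint()


def reference_proteins(n_per_subfamily: int = 2) -> list[tuple[str, str]]:
    """Labeled reference proteins (headers carry ``subfamily=``), near-consensus."""
    records = []
    for name in SUBFAMILIES:
        for i in range(n_per_subfamily):
            rng = substream(970031, "reference", name, i)
            seq, _, _ = _assemble_member(rng, name, 232, mut_domain=0.03, mut_flank=0.05)
            records.append((f"{name}_ref{i + 1} subfamily={name}", seq))
    return records


def seed_alignments() -> dict[str, list[tuple[str, str]]]:
    """Ungapped seed alignments for the two domain PSSMs (10 rows each)."""
    out = {}
    for dom, cons, frozen in (("DPBB", BLUEPRINT["dpbb"], _DPBB_FROZEN),
                              ("CBM63", BLUEPRINT["cbm63"], set())):
        rows = []
        for i in range(10):
            rng = substream(970031, "seedaln", dom, i)
            s = _mutate_protein(rng, cons, 0.08, frozen=frozen)
            if dom == "DPBB" and i % 2 == 1:
                s = s[:_DIAG_AT] + "TDF" + s[_DIAG_AT + 3:]
            rows.append((f"{dom}_seed{i + 1}", s))
        out[dom] = rows
    return out


def _assemble_member(rng, subfamily: str, protein_length: int,
                     mut_domain: float = 0.05, mut_flank: float = 0.10):
    """Build one member protein; returns (protein, dpbb_span, cbm63_span) 1-based."""
    if not (200 <= protein_length <= 300):
        raise ValueError("protein_length must be in [200, 300]")
    parts = BLUEPRINT["subfamilies"][subfamily]
    extra = protein_length - _MIN_CORE  # >= 2
    npad_len = min(15, extra // 2)
    ctail_len = extra - npad_len
    frozen_n = {2, 3, 4, 5} if subfamily == "EXLA" else set()
    nterm = _mutate_protein(rng, parts["nterm"], mut_flank, frozen=frozen_n)
    npad = _mutate_protein(rng, (parts["npad"] * 2)[:npad_len], mut_flank)
    dpbb = _mutate_protein(rng, parts["dpbb"], mut_domain, frozen=_DPBB_FROZEN)
    linker = _mutate_protein(rng, parts["linker"], mut_flank)
    cbm63 = _mutate_protein(rng, parts["cbm63"], mut_domain)
    ctail = _mutate_protein(rng, (parts["cterm"] * 8)[:ctail_len], mut_flank)
    protein = nterm + npad + dpbb + linker + cbm63 + ctail
    d0 = _NFIX + npad_len
    dpbb_span = (d0 + 1, d0 + DPBB_LEN)
    c0 = d0 + DPBB_LEN + _LINKER
    cbm63_span = (c0 + 1, c0 + CBM63_LEN)
    assert len(protein) == protein_length
    return protein, dpbb_span, cbm63_span


# ---------------------------------------------------------------------------
# spec dataclasses
# ---------------------------------------------------------------------------

@dataclass
class PlantedMember:
    subfamily: str
    intron_pattern: tuple[int, int] = (2, 0)
    protein_length: int = 235
    expression_category: str = "expressed"

    def __post_init__(self):
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"unknown subfamily {self.subfamily}")
        d, c = self.intron_pattern
        if d < 0 or c < 0:
            raise ValueError("intron counts must be non-negative")
        if not (200 <= self.protein_length <= 300):
            raise ValueError("protein_length must be in [200, 300]")
        if self.expression_category not in EXPRESSION_CATEGORIES:
            raise ValueError(f"unknown expression category {self.expression_category}")


@dataclass
class TandemPlan:
    chromosome: int           # 0-based chromosome index
    array_size: int
    n_intervening: int

    def __post_init__(self):
        if self.array_size < 2:
            raise ValueError("tandem array_size must be >= 2")
        if self.n_intervening not in (0, 1):
            raise ValueError("n_intervening must be 0 or 1")


@dataclass
class SegmentalPlan:
    m: int                    # genes in the duplicated window
    source_chromosome: int
    target_chromosome: int
    subst_prob: float

    def __post_init__(self):
        if self.m < 10:
            raise ValueError("segmental window must span >= 10 genes")
        if not (0 <= self.subst_prob < 0.5):
            raise ValueError("subst_prob must be in [0, 0.5)")


@dataclass
class GenomeSpec:
    species_id: str
    n_chromosomes: int = 2
    n_background_genes: int = 50
    family_plan: list[PlantedMember] = field(default_factory=list)
    tandem_plan: list[TandemPlan] = field(default_factory=list)
    segmental_plan: list[SegmentalPlan] = field(default_factory=list)
    decoy_plan: tuple[int, int] = (0, 0)  # (n DPBB-only, n CBM63-only)
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1:
            raise ValueError("need >= 1 chromosome")
        if self.n_background_genes < 0:
            raise ValueError("negative background gene count")
        for t in self.tandem_plan:
            if not (0 <= t.chromosome < self.n_chromosomes):
                raise ValueError(f"tandem plan chromosome {t.chromosome} out of range")
        for s in self.segmental_plan:
            for c in (s.source_chromosome, s.target_chromosome):
                if not (0 <= c < self.n_chromosomes):
                    raise ValueError(f"segmental plan chromosome {c} out of range")


@dataclass
class TruthTables:
    members: dict[str, str]                      # gene_id -> subfamily
    tandem_clusters: list[list[str]]
    collinear_blocks: list[list[tuple[str, str]]]
    intron_patterns: dict[str, tuple[int, int]]
    expression: dict[str, tuple[float, str]]     # gene_id -> (fpkm, category)

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        with open(outdir / "members.tsv", "w") as fh:
            fh.write("gene_id\tsubfamily\n")
            for g, s in sorted(self.members.items()):
                fh.write(f"{g}\t{s}\n")
        with open(outdir / "tandem.tsv", "w") as fh:
            fh.write("cluster_id\tmembers\n")
            for i, cl in enumerate(self.tandem_clusters):
                fh.write(f"tandem{i + 1}\t{','.join(cl)}\n")
        with open(outdir / "collinear.tsv", "w") as fh:
            fh.write("block_id\tanchors\n")
            for i, bl in enumerate(self.collinear_blocks):
                fh.write(f"block{i + 1}\t{';'.join(f'{a},{b}' for a, b in bl)}\n")
        with open(outdir / "patterns.tsv", "w") as fh:
            fh.write("gene_id\tn_introns_dpbb\tn_introns_cbm63\n")
            for g, (d, c) in sorted(self.intron_patterns.items()):
                fh.write(f"{g}\t{d}\t{c}\n")
        with open(outdir / "expression.tsv", "w") as fh:
            fh.write("gene_id\tfpkm\tcategory\n")
            for g, (f, c) in sorted(self.expression.items()):
                fh.write(f"{g}\t{f:.4f}\t{c}\n")


# ---------------------------------------------------------------------------
# gene realization
# ---------------------------------------------------------------------------

def backtranslate_protein(rng: np.random.Generator, protein: str) -> str:
    """CDS for a protein: uniform choice among synonymous codons + stop codon."""
    codons = []
    for aa in protein:
        options = AA_TO_CODONS[aa]
        codons.append(options[int(rng.integers(0, len(options)))])
    codons.append(STOP_CODONS[int(rng.integers(0, len(STOP_CODONS)))])
    return "".join(codons)


def _domain_cds_window(span: tuple[int, int]) -> tuple[int, int]:
    """Junction-offset window [lo, hi) realizing 'inside the domain' counting."""
    s, e = span
    return 3 * (s - 1) + 1, 3 * e


_JUNCTION_MARGIN = 12  # nt kept clear of domain boundaries when planting introns


def _choose_junctions(rng, protein_len: int, dpbb_span, cbm63_span,
                      pattern: tuple[int, int], n_extra: int) -> list[int]:
    cds_len = 3 * protein_len + 3
    d_lo, d_hi = _domain_cds_window(dpbb_span)
    c_lo, c_hi = _domain_cds_window(cbm63_span)
    chosen: list[int] = []

    def pick(lo, hi, n):
        pool = [p for p in range(lo, hi)
                if all(abs(p - q) >= 6 for q in chosen)]
        if len(pool) < n:
            raise ValueError("infeasible intron pattern: domain window too small")
        for idx in sorted(rng.choice(len(pool), size=n, replace=False)):
            p = pool[int(idx)]
            if any(abs(p - q) < 6 for q in chosen):
                continue
            chosen.append(p)

    d, c = pattern
    pick(d_lo + _JUNCTION_MARGIN, d_hi - _JUNCTION_MARGIN, d)
    pick(c_lo + _JUNCTION_MARGIN, c_hi - _JUNCTION_MARGIN, c)
    if n_extra:
        outside = [p for p in range(7, cds_len - 6)
                   if not (d_lo - _JUNCTION_MARGIN <= p < d_hi + _JUNCTION_MARGIN)
                   and not (c_lo - _JUNCTION_MARGIN <= p < c_hi + _JUNCTION_MARGIN)
                   and all(abs(p - q) >= 6 for q in chosen)]
        for idx in sorted(rng.choice(len(outside), size=min(n_extra, len(outside)),
                                     replace=False)):
            p = outside[int(idx)]
            if any(abs(p - q) < 6 for q in chosen):
                continue
            chosen.append(p)
    return sorted(chosen)


def _random_intron(rng) -> str:
    length = int(rng.integers(60, 501))
    inner = "".join("ACGT"[i] for i in rng.integers(0, 4, length - 4))
    return "GT" + inner + "AG"


@dataclass
class TranscriptRecord:
    transcript_id: str
    exons: list[tuple[int, int]]      # genomic, 0-based half-open, sorted
    cds: list[tuple[int, int]]        # == exons here (no UTRs)
    protein: str
    cds_seq: str                      # spliced CDS (5'->3')


@dataclass
class GeneRecord:
    gene_id: str
    species_id: str
    kind: str                 # member / background / decoy_dpbb / decoy_cbm63
    subfamily: str | None
    strand: str
    gene_seq: str             # genomic sequence of the gene on the + strand
    transcripts: list[TranscriptRecord]
    dpbb_span: tuple[int, int] | None = None
    cbm63_span: tuple[int, int] | None = None
    intron_pattern: tuple[int, int] | None = None
    junctions: list[int] = field(default_factory=list)
    chromosome: str = ""
    start: int = 0            # genomic, 0-based; filled at assembly time


def _build_gene(gene_id: str, species_id: str, kind: str, rng,
                protein: str, strand: str, junctions: list[int],
                subfamily=None, dpbb_span=None, cbm63_span=None,
                pattern=None, cds_seq: str | None = None,
                introns: list[str] | None = None,
                second_isoform: bool = False) -> GeneRecord:
    """Realize a gene from its protein, junction offsets and strand."""
    cds = cds_seq if cds_seq is not None else backtranslate_protein(rng, protein)
    Lc = len(cds)
    if introns is None:
        introns = [_random_intron(rng) for _ in junctions]
    cuts = [0] + list(junctions) + [Lc]
    pieces = [cds[cuts[i]:cuts[i + 1]] for i in range(len(cuts) - 1)]
    local_exons = []
    seq_parts = []
    pos = 0
    for i, piece in enumerate(pieces):
        seq_parts.append(piece)
        local_exons.append((pos, pos + len(piece)))
        pos += len(piece)
        if i < len(introns):
            seq_parts.append(introns[i])
            pos += len(introns[i])
    gene_seq = "".join(seq_parts)
    glen = len(gene_seq)

    def to_genomic(local):
        if strand == "+":
            return sorted(local)
        return sorted((glen - b, glen - a) for a, b in local)

    transcripts = [TranscriptRecord(
        transcript_id=f"{gene_id}.t1",
        exons=to_genomic(local_exons),
        cds=to_genomic(local_exons),
        protein=protein,
        cds_seq=cds,
    )]
    if second_isoform:
        # a shorter isoform: the first ~60% of codons (tests isoform selection)
        K = max(30, (len(protein) * 3) // 5)
        sub_len = 3 * K
        sub_local = []
        spliced = 0  # truncate in spliced-CDS space, not gene-local space
        for a, b in local_exons:
            if spliced >= sub_len:
                break
            take = min(b - a, sub_len - spliced)
            sub_local.append((a, a + take))
            spliced += take
        transcripts.append(TranscriptRecord(
            transcript_id=f"{gene_id}.t2",
            exons=to_genomic(sub_local),
            cds=to_genomic(sub_local),
            protein=protein[:K],
            cds_seq=cds[:sub_len],
        ))
    gene_seq_out = gene_seq if strand == "+" else revcomp(gene_seq)
    return GeneRecord(
        gene_id=gene_id, species_id=species_id, kind=kind, subfamily=subfamily,
        strand=strand, gene_seq=gene_seq_out, transcripts=transcripts,
        dpbb_span=dpbb_span, cbm63_span=cbm63_span, intron_pattern=pattern,
        junctions=list(junctions),
    )


def _make_member_gene(spec: GenomeSpec, idx: int, planted: PlantedMember,
                      kind: str = "member") -> GeneRecord:
    gene_id = f"{spec.species_id}_g{idx:04d}"
    rng = substream(spec.seed, "gene", gene_id)
    protein, dspan, cspan = _assemble_member(rng, planted.subfamily,
                                             planted.protein_length)
    n_extra = min(2, int(rng.poisson(0.7)))
    junctions = _choose_junctions(rng, len(protein), dspan, cspan,
                                  planted.intron_pattern, n_extra)
    strand = "+" if idx % 2 == 0 else "-"
    return _build_gene(gene_id, spec.species_id, kind, rng, protein, strand,
                       junctions, subfamily=planted.subfamily, dpbb_span=dspan,
                       cbm63_span=cspan, pattern=planted.intron_pattern,
                       second_isoform=(idx % 5 == 0))


def _make_background_gene(spec: GenomeSpec, idx: int) -> GeneRecord:
    gene_id = f"{spec.species_id}_g{idx:04d}"
    rng = substream(spec.seed, "gene", gene_id)
    protein = _random_protein(rng, int(rng.integers(150, 351)))
    n_introns = int(rng.integers(0, 4))
    cds_len = 3 * len(protein) + 3
    junctions = sorted(
        int(p) for p in rng.choice(np.arange(7, cds_len - 6), size=n_introns,
                                   replace=False)
    ) if n_introns else []
    # enforce >= 6 nt separation
    filtered = []
    for p in junctions:
        if all(abs(p - q) >= 6 for q in filtered):
            filtered.append(p)
    strand = "+" if rng.random() < 0.5 else "-"
    return _build_gene(gene_id, spec.species_id, "background", rng, protein,
                       strand, filtered)


def _make_decoy_gene(spec: GenomeSpec, idx: int, which: str) -> GeneRecord:
    gene_id = f"{spec.species_id}_g{idx:04d}"
    rng = substream(spec.seed, "gene", gene_id)
    if which == "decoy_dpbb":
        domain = _mutate_protein(rng, BLUEPRINT["dpbb"], 0.05, frozen=_DPBB_FROZEN)
    else:
        domain = _mutate_protein(rng, BLUEPRINT["cbm63"], 0.05)
    head = _random_protein(rng, int(rng.integers(15, 40)))
    tail = _random_protein(rng, int(rng.integers(40, 90)))
    protein = head + domain + tail
    strand = "+" if rng.random() < 0.5 else "-"
    span = (len(head) + 1, len(head) + len(domain))
    return _build_gene(
        gene_id, spec.species_id, which, rng, protein, strand, [],
        dpbb_span=span if which == "decoy_dpbb" else None,
        cbm63_span=span if which == "decoy_cbm63" else None,
    )


def _copy_gene(spec: GenomeSpec, idx: int, source: GeneRecord,
               subst_prob: float) -> GeneRecord:
    """Segmental-duplication copy: per-site substitutions on CDS and introns.

    Codons that would gain an internal stop revert; intron GT..AG ends and the
    terminal stop codon are kept intact, so the copy stays a valid gene with
    the same exon-intron architecture.
    """
    gene_id = f"{spec.species_id}_g{idx:04d}"
    rng = substream(spec.seed, "gene", gene_id)
    src_t = source.transcripts[0]
    cds = list(src_t.cds_seq)
    n_codons = len(cds) // 3
    frozen: set[int] = set()  # protein positions whose codons stay untouched
    if source.kind == "member" and source.dpbb_span is not None:
        d0 = source.dpbb_span[0] - 1
        for off in (_GACG_AT, _CGAC_AT):
            frozen.update(range(d0 + off, d0 + off + 4))
        frozen.update(range(d0 + _DIAG_AT, d0 + _DIAG_AT + 3))
        if source.subfamily == "EXLA":
            frozen.update(range(2, 6))
    for ci in range(n_codons - 1):  # skip the stop codon
        if ci in frozen:
            continue
        codon = cds[3 * ci:3 * ci + 3]
        new = [("ACGT"[int(rng.integers(0, 4))] if rng.random() < subst_prob else b)
               for b in codon]
        if "".join(new) not in STOP_CODONS:
            cds[3 * ci:3 * ci + 3] = new
    cds = "".join(cds)
    protein = "".join(CODON_TO_AA[cds[i:i + 3]] for i in range(0, len(cds) - 3, 3))
    # mutate intron interiors, keep splice ends
    src_introns = _extract_introns(source)
    introns = []
    for intr in src_introns:
        inner = [("ACGT"[int(rng.integers(0, 4))] if rng.random() < subst_prob else b)
                 for b in intr[2:-2]]
        introns.append("GT" + "".join(inner) + "AG")
    return _build_gene(
        gene_id, spec.species_id,
        "member" if source.kind == "member" else source.kind + "_copy",
        rng, protein, source.strand, source.junctions,
        subfamily=source.subfamily, dpbb_span=source.dpbb_span,
        cbm63_span=source.cbm63_span, pattern=source.intron_pattern,
        cds_seq=cds, introns=introns,
    )


def _extract_introns(gene: GeneRecord) -> list[str]:
    """Intron sequences of transcript 1 in 5'->3' transcript order."""
    seq = gene.gene_seq if gene.strand == "+" else revcomp(gene.gene_seq)
    t = gene.transcripts[0]
    glen = len(seq)
    if gene.strand == "+":
        local = t.exons
    else:
        local = sorted((glen - b, glen - a) for a, b in t.exons)
    introns = []
    for (a1, b1), (a2, b2) in zip(local, local[1:]):
        introns.append(seq[b1:a2])
    return introns


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _largest_remainder_counts(n: int, proportions) -> list[int]:
    props = [float(p) for p in proportions]
    if any(p < 0 for p in props):
        raise ValueError("proportions must be non-negative")
    if abs(sum(props) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    raw = [p * n for p in props]
    counts = [int(np.floor(r)) for r in raw]
    remainders = [r - c for r, c in zip(raw, counts)]
    short = n - sum(counts)
    for i in sorted(range(len(props)), key=lambda i: (-remainders[i], i))[:short]:
        counts[i] += 1
    return counts


def _draw_fpkm(rng: np.random.Generator, category: str) -> float:
    if category == "expressed":
        return float(np.exp(rng.uniform(0.0, np.log(300.0))))
    if category == "weak":
        return float(rng.uniform(0.01, 0.99))
    return 0.0


def make_expression(members: list[str], proportions=DEFAULT_EXPRESSION_PROPORTIONS,
                    seed: int = 0) -> pd.DataFrame:
    """FPKM table for a gene list with planted category proportions.

    Category counts come from largest-remainder rounding of the proportions;
    genes are assigned in seeded shuffled order.  Expressed genes draw FPKM
    log-uniformly from [1, 300), weak ones uniformly from (0, 1), silent genes
    get exactly 0.
    """
    counts = _largest_remainder_counts(len(members), proportions)
    rng = substream(seed, "expression")
    order = list(members)
    rng.shuffle(order)
    assigned: dict[str, tuple[float, str]] = {}
    i = 0
    for category, k in zip(EXPRESSION_CATEGORIES, counts):
        for g in order[i:i + k]:
            assigned[g] = (round(_draw_fpkm(rng, category), 4), category)
        i += k
    return pd.DataFrame(
        [(g, assigned[g][0], assigned[g][1]) for g in members],
        columns=["gene_id", "fpkm", "category"],
    )


# ---------------------------------------------------------------------------
# codon-pair simulator
# ---------------------------------------------------------------------------

def _codon_neighbors(codon: str):
    for pos in range(3):
        for base in "ACGT":
            if base != codon[pos]:
                yield codon[:pos] + base + codon[pos + 1:]


def simulate_codon_pair(n_codons: int, branch_length: float, omega: float,
                        seed: int = 0) -> tuple[str, str]:
    """Two stop-free CDS diverged under a codon process with dN/dS = omega.

    Starting from a random sense-codon ancestor, each lineage evolves for
    branch_length/2 time units under a continuous-time process where each
    nucleotide position mutates to each alternative at rate 1/3, changes
    creating stops are forbidden, and nonsynonymous changes are accepted at
    ``omega`` times the synonymous rate.  branch_length = 0 returns two
    identical sequences.
    """
    if n_codons < 30:
        raise ValueError("n_codons must be >= 30")
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    rng = substream(seed, "codonpair", n_codons, omega)
    sense = sorted(CODON_TO_AA)
    ancestor = [sense[int(rng.integers(0, len(sense)))] for _ in range(n_codons)]
    scale = min(1.0, omega) / omega  # keep acceptance probabilities <= 1
    t_branch = branch_length / 2.0

    def evolve(codons):
        out = []
        for codon in codons:
            t = 0.0
            c = codon
            while True:
                moves = []
                rates = []
                for nb in _codon_neighbors(c):
                    if nb in STOP_CODONS:
                        continue
                    syn = CODON_TO_AA[nb] == CODON_TO_AA[c]
                    rate = (1.0 / 3.0) * (scale if syn else scale * omega)
                    moves.append(nb)
                    rates.append(rate)
                total = sum(rates)
                t += rng.exponential(1.0 / total)
                if t >= t_branch:
                    break
                u = rng.uniform(0, total)
                acc = 0.0
                for nb, r in zip(moves, rates):
                    acc += r
                    if u < acc:
                        c = nb
                        break
            out.append(c)
        return "".join(out)

    if branch_length == 0:
        s = "".join(ancestor)
        return s, s
    return evolve(ancestor), evolve(ancestor)


# ---------------------------------------------------------------------------
# genome assembly and file output
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    spec: GenomeSpec
    genes: list[GeneRecord]            # all genes with chromosome+start filled
    chromosomes: dict[str, str]
    truth: TruthTables
    paths: dict[str, Path]


def _serialize_gff3(genes: list[GeneRecord], species_id: str) -> str:
    lines = ["##gff-version 3"]
    ordered = sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id))
    for g in ordered:
        glen = len(g.gene_seq)
        gstart, gend = g.start + 1, g.start + glen
        lines.append("\t".join([
            g.chromosome, "famevol", "gene", str(gstart), str(gend), ".",
            g.strand, ".", f"ID={g.gene_id};Name={g.gene_id}",
        ]))
        for t in g.transcripts:
            t_lo = g.start + min(a for a, _ in t.exons) + 1
            t_hi = g.start + max(b for _, b in t.exons)
            lines.append("\t".join([
                g.chromosome, "famevol", "mRNA", str(t_lo), str(t_hi), ".",
                g.strand, ".", f"ID={t.transcript_id};Parent={g.gene_id}",
            ]))
            for i, (a, b) in enumerate(t.exons):
                lines.append("\t".join([
                    g.chromosome, "famevol", "exon",
                    str(g.start + a + 1), str(g.start + b), ".", g.strand, ".",
                    f"ID={t.transcript_id}.exon{i + 1};Parent={t.transcript_id}",
                ]))
            # CDS phases accumulate in transcript (5'->3') order
            cds_order = t.cds if g.strand == "+" else list(reversed(t.cds))
            cum = 0
            phased = []
            for (a, b) in cds_order:
                phase = (3 - cum % 3) % 3
                phased.append((a, b, phase))
                cum += b - a
            for i, (a, b, phase) in enumerate(sorted(phased)):
                lines.append("\t".join([
                    g.chromosome, "famevol", "CDS",
                    str(g.start + a + 1), str(g.start + b), ".", g.strand,
                    str(phase),
                    f"ID={t.transcript_id}.cds;Parent={t.transcript_id}",
                ]))
    return "\n".join(lines) + "\n"


def make_genome(spec: GenomeSpec, outdir) -> SyntheticGenome:
    """Realize a GenomeSpec: FASTA + GFF3 + CDS + proteins + truth tables.

    Deterministic: identical spec and seed give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = spec.species_id
    idx = 0
    members: list[GeneRecord] = []
    truth_members: dict[str, str] = {}
    truth_patterns: dict[str, tuple[int, int]] = {}
    tandem_clusters: list[list[str]] = []
    collinear_blocks: list[list[tuple[str, str]]] = []

    plain_members = []
    for planted in spec.family_plan:
        g = _make_member_gene(spec, idx, planted)
        idx += 1
        plain_members.append(g)
        truth_members[g.gene_id] = planted.subfamily
        truth_patterns[g.gene_id] = planted.intron_pattern
    members.extend(plain_members)

    background: list[GeneRecord] = []
    for _ in range(spec.n_background_genes):
        background.append(_make_background_gene(spec, idx))
        idx += 1

    decoys: list[GeneRecord] = []
    for _ in range(spec.decoy_plan[0]):
        decoys.append(_make_decoy_gene(spec, idx, "decoy_dpbb"))
        idx += 1
    for _ in range(spec.decoy_plan[1]):
        decoys.append(_make_decoy_gene(spec, idx, "decoy_cbm63"))
        idx += 1

    # spacer pool: background + decoys keep family genes apart (the tandem
    # rule is a statement about realized gene ranks, so the generator controls
    # adjacency explicitly — planted arrays are the only family genes within
    # <= 1 intervening gene of each other)
    extra_idx = [idx]

    def fresh_background() -> GeneRecord:
        g = _make_background_gene(spec, extra_idx[0])
        extra_idx[0] += 1
        return g

    spacer_pool = list(background) + list(decoys)
    substream(spec.seed, "spacer-order").shuffle(spacer_pool)
    spacer_iter = iter(spacer_pool)

    def next_spacer() -> GeneRecord:
        try:
            return next(spacer_iter)
        except StopIteration:
            return fresh_background()

    # tandem arrays: mutated copies of one base member (real duplicates, so
    # downstream Ka/Ks on array pairs is well defined)
    tandem_blocks: list[tuple[int, list[GeneRecord]]] = []
    for t_i, tp in enumerate(spec.tandem_plan):
        rng = substream(spec.seed, "tandem", t_i)
        subfamily = SUBFAMILIES[int(rng.integers(0, 4))]
        planted = PlantedMember(subfamily=subfamily,
                                intron_pattern=(int(rng.integers(1, 4)), 0),
                                protein_length=int(rng.integers(220, 260)))
        base = _make_member_gene(spec, extra_idx[0], planted)
        extra_idx[0] += 1
        block = [base]
        cluster_ids = [base.gene_id]
        for _ in range(tp.array_size - 1):
            for _ in range(tp.n_intervening):
                block.append(next_spacer())
            cp = _copy_gene(spec, extra_idx[0], base, 0.03)
            extra_idx[0] += 1
            block.append(cp)
            cluster_ids.append(cp.gene_id)
        for gid in cluster_ids:
            truth_members[gid] = subfamily
            truth_patterns[gid] = planted.intron_pattern
        # two background genes on each flank insulate the array
        block = [next_spacer(), next_spacer()] + block + [next_spacer(),
                                                          next_spacer()]
        tandem_blocks.append((tp.chromosome, block))
        tandem_clusters.append(cluster_ids)
        members.extend(b for b in block if b.kind == "member")

    # distribute plain members over chromosomes with >= 3 spacers between
    # family genes (2 intervening genes break the tandem rule)
    chrom_genes: list[list[GeneRecord]] = [[] for _ in range(spec.n_chromosomes)]
    for i, m in enumerate(plain_members):
        ci = i % spec.n_chromosomes
        chrom_genes[ci].extend([next_spacer(), next_spacer(), next_spacer(), m])
    leftovers = list(spacer_iter)
    for i, g in enumerate(leftovers):
        chrom_genes[i % spec.n_chromosomes].append(g)
    spacer_iter = iter(())
    for chrom_i, block in tandem_blocks:
        # insert tandem arrays midway, never splitting the array
        at = len(chrom_genes[chrom_i]) // 2
        chrom_genes[chrom_i] = (chrom_genes[chrom_i][:at] + block
                                + chrom_genes[chrom_i][at:])

    in_tandem_truth = {g for cl in tandem_clusters for g in cl}

    # segmental duplications: copy a window from the source chromosome's list
    for s_i, sp_plan in enumerate(spec.segmental_plan):
        src_list = chrom_genes[sp_plan.source_chromosome]
        if len(src_list) < sp_plan.m:
            raise ValueError(
                f"infeasible segmental plan {s_i}: source chromosome has "
                f"{len(src_list)} genes < window of {sp_plan.m}")
        rng = substream(spec.seed, "segmental", s_i)
        starts = [
            w for w in range(0, len(src_list) - sp_plan.m + 1)
            if any(g.kind == "member" for g in src_list[w:w + sp_plan.m])
            and not any(g.gene_id in in_tandem_truth
                        for g in src_list[w:w + sp_plan.m])
        ]
        if not starts:
            raise ValueError(
                f"infeasible segmental plan {s_i}: no window of {sp_plan.m} genes "
                f"on chromosome {sp_plan.source_chromosome} contains a family gene")
        w0 = starts[int(rng.integers(0, len(starts)))]
        window = src_list[w0:w0 + sp_plan.m]
        copies = []
        anchors = []
        for src in window:
            cp = _copy_gene(spec, extra_idx[0], src, sp_plan.subst_prob)
            extra_idx[0] += 1
            copies.append(cp)
            anchors.append((src.gene_id, cp.gene_id))
            if cp.kind == "member":
                truth_members[cp.gene_id] = cp.subfamily
                truth_patterns[cp.gene_id] = cp.intron_pattern
                members.append(cp)
        # buffer genes keep copied members clear of pre-existing family genes
        chrom_genes[sp_plan.target_chromosome].extend(
            [fresh_background(), fresh_background()] + copies)
        collinear_blocks.append(anchors)

    # realize chromosome sequences
    chromosomes: dict[str, str] = {}
    all_genes: list[GeneRecord] = []
    for ci in range(spec.n_chromosomes):
        cname = f"{sp}_chr{ci + 1}"
        crng = substream(spec.seed, "chromosome", cname)
        parts = []
        pos = 0
        spacer = "".join("ACGT"[i] for i in crng.integers(0, 4, 400))
        parts.append(spacer)
        pos += len(spacer)
        for g in chrom_genes[ci]:
            g.chromosome = cname
            g.start = pos
            parts.append(g.gene_seq)
            pos += len(g.gene_seq)
            spacer_len = int(crng.integers(200, 1501))
            spacer = "".join("ACGT"[i] for i in crng.integers(0, 4, spacer_len))
            parts.append(spacer)
            pos += spacer_len
        chromosomes[cname] = "".join(parts)
        all_genes.extend(chrom_genes[ci])

    # expression truth: planted categories for plain members, drawn for derived
    expr_rng = substream(spec.seed, "expression-fill")
    truth_expression: dict[str, tuple[float, str]] = {}
    planted_cat = {g.gene_id: pm.expression_category
                   for g, pm in zip(plain_members, spec.family_plan)}
    cum = np.cumsum(DEFAULT_EXPRESSION_PROPORTIONS)
    for g in members:
        cat = planted_cat.get(g.gene_id)
        if cat is None:
            u = expr_rng.random()
            cat = EXPRESSION_CATEGORIES[int(np.searchsorted(cum, u))]
        truth_expression[g.gene_id] = (round(_draw_fpkm(expr_rng, cat), 4), cat)

    truth = TruthTables(
        members=truth_members,
        tandem_clusters=tandem_clusters,
        collinear_blocks=collinear_blocks,
        intron_patterns=truth_patterns,
        expression=truth_expression,
    )

    paths = {
        "genome": outdir / f"{sp}.genome.fasta",
        "gff3": outdir / f"{sp}.gff3",
        "cds": outdir / f"{sp}.cds.fasta",
        "protein": outdir / f"{sp}.protein.fasta",
        "expression": outdir / f"{sp}.expression.tsv",
    }
    write_fasta(sorted(chromosomes.items()), paths["genome"])
    with open(paths["gff3"], "w") as fh:
        fh.write(_serialize_gff3(all_genes, sp))
    cds_records = []
    protein_records = []
    for g in sorted(all_genes, key=lambda g: g.gene_id):
        for t in g.transcripts:
            cds_records.append((f"{t.transcript_id} gene={g.gene_id}", t.cds_seq))
            protein_records.append((f"{t.transcript_id} gene={g.gene_id}", t.protein))
    write_fasta(cds_records, paths["cds"])
    write_fasta(protein_records, paths["protein"])
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for gid, (fpkm, _) in sorted(truth_expression.items()):
            fh.write(f"{gid}\t{fpkm:.4f}\n")
    truth.write(outdir)
    return SyntheticGenome(spec=spec, genes=all_genes, chromosomes=chromosomes,
                           truth=truth, paths=paths)


def default_genome_spec(species_id: str, seed: int, n_members: int = 13,
                        n_background: int = 50, n_decoys: tuple[int, int] = (2, 2),
                        with_tandem: bool = True,
                        with_segmental: bool = True) -> GenomeSpec:
    """A study-sized per-species spec: members over all four subfamilies with
    the common intron patterns, one tandem array and one duplicated block."""
    rng = substream(seed, "spec", species_id)
    patterns = [(2, 0), (2, 0), (1, 0), (3, 0), (3, 1)]  # common patterns mix
    plan = []
    cats = list(EXPRESSION_CATEGORIES)
    for i in range(n_members):
        plan.append(PlantedMember(
            subfamily=SUBFAMILIES[i % 4],
            intron_pattern=patterns[i % len(patterns)],
            protein_length=int(rng.integers(215, 281)),
            expression_category=cats[i % 3],
        ))
    return GenomeSpec(
        species_id=species_id,
        n_chromosomes=2,
        n_background_genes=n_background,
        family_plan=plan,
        tandem_plan=[TandemPlan(chromosome=0, array_size=3, n_intervening=1)]
        if with_tandem else [],
        segmental_plan=[SegmentalPlan(m=10, source_chromosome=1,
                                      target_chromosome=0, subst_prob=0.05)]
        if with_segmental else [],
        decoy_plan=n_decoys,
        seed=seed,
    )
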