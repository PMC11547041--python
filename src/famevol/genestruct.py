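"""Gene models and the descriptive sequence-characteristics layer.

Parses GFF3 annotation into validated gene models (internally 0-based
half-open; GFF3 I/O converts exactly to/from 1-based inclusive) and computes
per-gene structure statistics — gene length, total exon/intron length and
counts, protein length, molecular weight and isoelectric point — plus the
gene-length vs exon/intron-length correlation analysis and protein-length
binning used in family surveys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "Transcript", "GeneModel", "StructureStats", "CorrelationResult",
    "parse_gff3", "write_gff3", "structure_stats", "molecular_weight",
    "isoelectric_point", "correlate", "length_bins",
]


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]                 # 0-based half-open, sorted
    cds: list[tuple[int, int, int]]              # (start, end, phase)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)


@dataclass
class GeneModel:
    gene_id: str
    species_id: str
    chromosome: str
    strand: str
    span: tuple[int, int]
    transcripts: list[Transcript] = field(default_factory=list)

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


def _validate_model(model: GeneModel) -> str | None:
    """Return a rejection reason, or None if the model is valid."""
    for t in model.transcripts:
        exons = t.exons
        if exons != sorted(exons):
            return f"{t.transcript_id}: exons not sorted"
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                return f"{t.transcript_id}: overlapping exons"
        for s, e in exons:
            if e <= s:
                return f"{t.transcript_id}: empty exon"
        cds_iv = [(s, e) for s, e, _ in t.cds]
        for cs, ce in cds_iv:
            if not any(es <= cs and ce <= ee for es, ee in exons):
                return f"{t.transcript_id}: CDS outside exons"
        if t.cds_length % 3 != 0:
            return f"{t.transcript_id}: CDS length not divisible by 3"
    return None


def parse_gff3(path, species_id: str | None = None) -> list[GeneModel]:
    """Parse a GFF3 file into validated gene models.

    Genes violating the model invariants (unsorted/overlapping exons, CDS
    outside exons, CDS length not divisible by 3) are skipped with a warning;
    orphan features likewise.  Exon and CDS lines are sorted on load.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    models = []
    sp = species_id if species_id is not None else ""
    for gene in db.features_of_type("gene"):
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted((f.start - 1, f.end)
                           for f in db.children(mrna, featuretype="exon"))
            cds = sorted(
                (f.start - 1, f.end, 0 if f.frame == "." else int(f.frame))
                for f in db.children(mrna, featuretype="CDS"))
            transcripts.append(Transcript(
                transcript_id=mrna.id, exons=exons, cds=cds))
        transcripts.sort(key=lambda t: t.transcript_id)
        model = GeneModel(
            gene_id=gene.id,
            species_id=sp,
            chromosome=gene.seqid,
            strand=gene.strand,
            span=(gene.start - 1, gene.end),
            transcripts=transcripts,
        )
        if not transcripts:
            warnings.warn(f"gene {gene.id} has no transcripts; skipped")
            continue
        reason = _validate_model(model)
        if reason is not None:
            warnings.warn(f"gene {gene.id} skipped: {reason}")
            continue
        models.append(model)
    return models


def write_gff3(models: list[GeneModel]) -> str:
    """Serialize gene models as normalized, sorted GFF3 (phases recomputed)."""
    lines = ["##gff-version 3"]
    for g in sorted(models, key=lambda m: (m.chromosome, m.span[0], m.gene_id)):
        lines.append("\t".join([
            g.chromosome, "famevol", "gene", str(g.span[0] + 1), str(g.span[1]),
            ".", g.strand, ".", f"ID={g.gene_id};Name={g.gene_id}",
        ]))
        for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
            lo = min(s for s, _ in t.exons) + 1
            hi = max(e for _, e in t.exons)
            lines.append("\t".join([
                g.chromosome, "famevol", "mRNA", str(lo), str(hi), ".",
                g.strand, ".", f"ID={t.transcript_id};Parent={g.gene_id}",
            ]))
            for i, (s, e) in enumerate(t.exons):
                lines.append("\t".join([
                    g.chromosome, "famevol", "exon", str(s + 1), str(e), ".",
                    g.strand, ".",
                    f"ID={t.transcript_id}.exon{i + 1};Parent={t.transcript_id}",
                ]))
            cds_iv = [(s, e) for s, e, _ in t.cds]
            ordered = cds_iv if g.strand == "+" else list(reversed(cds_iv))
            cum = 0
            phased = []
            for s, e in ordered:
                phased.append((s, e, (3 - cum % 3) % 3))
                cum += e - s
            for s, e, phase in sorted(phased):
                lines.append("\t".join([
                    g.chromosome, "famevol", "CDS", str(s + 1), str(e), ".",
                    g.strand, str(phase),
                    f"ID={t.transcript_id}.cds;Parent={t.transcript_id}",
                ]))
    return "\n".join(lines) + "\n"


@dataclass
class StructureStats:
    gene_id: str
    gene_length: int
    exon_total: int
    exon_count: int
    intron_total: int
    intron_count: int
    protein_length: int | None = None
    molecular_weight: float | None = None
    isoelectric_point: float | None = None


def structure_stats(model: GeneModel, transcript_id: str,
                    protein: str | None = None) -> StructureStats:
    """Descriptive stats for one gene's chosen transcript.

    Gene length is the transcript's genomic span, so it always equals
    exon_total + intron_total; a single-exon transcript has intron totals of
    zero.  Strand- and translation-invariant by construction.
    """
    t = model.transcript(transcript_id)
    lo = min(s for s, _ in t.exons)
    hi = max(e for _, e in t.exons)
    exon_total = sum(e - s for s, e in t.exons)
    gene_length = hi - lo
    stats = StructureStats(
        gene_id=model.gene_id,
        gene_length=gene_length,
        exon_total=exon_total,
        exon_count=len(t.exons),
        intron_total=gene_length - exon_total,
        intron_count=len(t.exons) - 1,
    )
    if protein is not None:
        stats.protein_length = len(protein)
        stats.molecular_weight = molecular_weight(protein)
        stats.isoelectric_point = isoelectric_point(protein)
    return stats


# average residue masses (Da); a free protein adds one water
_WATER = 18.0153
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}


def molecular_weight(protein: str) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water."""
    if not protein:
        raise ValueError("empty protein")
    try:
        return sum(_RESIDUE_MASS[a] for a in protein) + _WATER
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc


# EMBOSS pKa set; positive groups gain charge below their pKa
_PKA_POSITIVE = {"Nterm": 8.6, "H": 6.5, "K": 10.8, "R": 12.5}
_PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def net_charge(protein: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (termini included)."""
    counts = {a: protein.count(a) for a in "HKRDECY"}
    q = 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE["Nterm"]))
    for a in "HKR":
        q += counts[a] / (1.0 + 10 ** (ph - _PKA_POSITIVE[a]))
    q -= 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE["Cterm"] - ph))
    for a in "DECY":
        q -= counts[a] / (1.0 + 10 ** (_PKA_NEGATIVE[a] - ph))
    return q


def isoelectric_point(protein: str) -> float:
    """pH at which the net charge is zero (bisection on [0, 14]).

    Iterates until |Q| < 1e-4 or the bracketing window collapses (below
    1e-10 pH units, far inside any reporting precision).  A peptide with no
    ionizable side chains still has termini, so a result is always defined.
    """
    if not protein:
        raise ValueError("empty protein")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2
        q = net_charge(protein, mid)
        if abs(q) < 1e-4 or (hi - lo) < 1e-10:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    pearson_r: float
    r_squared: float
    p_value: float
    n: int


def correlate(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    r, p = _scipy_stats.pearsonr(x, y)
    return CorrelationResult(x_name=x_name, y_name=y_name, pearson_r=float(r),
                             r_squared=float(r) ** 2, p_value=float(p),
                             n=int(x.size))


def length_bins(values, bins: list[tuple[float, float]]):
    """Fraction of values in each closed interval [lo, hi].

    Returns a list of (lo, hi, fraction); empty input gives an empty list.
    """
    values = list(values)
    out = []
    if not values:
        return out
    n = len(values)
    for lo, hi in bins:
        k = sum(1 for v in values if lo <= v <= hi)
        out.append((lo, hi, k / n))
    return out
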