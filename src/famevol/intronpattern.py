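"""Intron-in-domain patterns via protein -> CDS -> genome coordinate projection.

A domain detected on the protein occupies a spliced-CDS interval; the introns
that interrupt it are the exon-exon junctions whose spliced-CDS offset falls
inside that interval.  The ordered pair (introns in DPBB, introns in CBM63)
is the gene's intron-distribution pattern; the common patterns carry the
conventional names Pattern I = (2,0), II = (1,0), III = (3,0), V = (3,1),
and every other pair is labeled canonically "P(d,c)" (with a dataset-rank
roman-numeral alias assigned per census, since no fixed pairs exist for the
remaining named patterns).

Counting convention: the junction after spliced-CDS position p (1-based) is
inside a domain spanning residues [s, e] iff 3(s-1)+1 <= p < 3e.  An intron
interrupting the domain's first codon counts as inside; one immediately after
the last codon does not; codon-splitting junctions need no special casing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genestruct import GeneModel, Transcript
from .seqalign import DomainHit

__all__ = [
    "PatternCall", "spliced_to_genomic", "domain_cds_span", "cds_junctions",
    "introns_in_domain", "classify_pattern", "call_pattern", "pattern_census",
]

_CANONICAL = {(2, 0): "Pattern I", (1, 0): "Pattern II",
              (3, 0): "Pattern III", (3, 1): "Pattern V"}


@dataclass
class PatternCall:
    gene_id: str
    n_introns_dpbb: int
    n_introns_cbm63: int
    label: str


def _cds_pieces_in_transcript_order(transcript: Transcript, strand: str):
    pieces = [(s, e) for s, e, _ in transcript.cds]
    return pieces if strand == "+" else list(reversed(pieces))


def spliced_to_genomic(transcript: Transcript, strand: str,
                       cds_position: int) -> int:
    """Genomic coordinate (0-based) of a 1-based spliced-CDS nucleotide.

    Walks the CDS pieces in transcript order; on the minus strand coordinates
    run downward within each piece.
    """
    total = transcript.cds_length
    if not (1 <= cds_position <= total):
        raise ValueError(f"CDS position {cds_position} out of range 1..{total}")
    remaining = cds_position - 1
    for s, e in _cds_pieces_in_transcript_order(transcript, strand):
        length = e - s
        if remaining < length:
            return s + remaining if strand == "+" else (e - 1) - remaining
        remaining -= length
    raise AssertionError("unreachable")


def domain_cds_span(domain: DomainHit, protein_length: int) -> tuple[int, int]:
    """Spliced-CDS interval [3(start-1)+1, 3*end] of a protein-domain hit."""
    if domain.end > protein_length:
        raise ValueError("domain extends beyond protein")
    return 3 * (domain.start - 1) + 1, 3 * domain.end


def cds_junctions(transcript: Transcript, strand: str) -> list[int]:
    """Spliced-CDS offsets p such that an intron lies after position p."""
    pieces = _cds_pieces_in_transcript_order(transcript, strand)
    out = []
    cum = 0
    for s, e in pieces[:-1]:
        cum += e - s
        out.append(cum)
    return out


def introns_in_domain(transcript: Transcript, strand: str, domain: DomainHit,
                      protein_length: int) -> int:
    """Number of CDS junctions inside the domain's spliced-CDS interval."""
    lo, hi = domain_cds_span(domain, protein_length)
    return sum(1 for p in cds_junctions(transcript, strand) if lo <= p < hi)


def classify_pattern(n_dpbb: int, n_cbm63: int) -> str:
    if n_dpbb < 0 or n_cbm63 < 0:
        raise ValueError("negative intron count")
    return _CANONICAL.get((n_dpbb, n_cbm63), f"P({n_dpbb},{n_cbm63})")


def call_pattern(model: GeneModel, transcript_id: str, dpbb: DomainHit,
                 cbm63: DomainHit, protein_length: int) -> PatternCall:
    t = model.transcript(transcript_id)
    nd = introns_in_domain(t, model.strand, dpbb, protein_length)
    nc = introns_in_domain(t, model.strand, cbm63, protein_length)
    total_introns = len(t.cds) - 1
    assert nd + nc <= total_introns
    return PatternCall(gene_id=model.gene_id, n_introns_dpbb=nd,
                       n_introns_cbm63=nc, label=classify_pattern(nd, nc))


def _roman(n: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
                "XI", "XII", "XIII", "XIV", "XV"]
    return numerals[n - 1] if n <= len(numerals) else str(n)


def pattern_census(calls: list[PatternCall],
                   groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Pattern frequency table with percentages and dataset-rank aliases.

    Canonical labels (Patterns I/II/III/V) keep their names; other observed
    pairs get the unused roman numerals in descending-frequency order, so a
    top-6 census can always be reported.  With ``groups`` (gene_id -> group)
    an extra ``group`` column stratifies the counts; percentages are always
    global and sum to 100.
    """
    if not calls:
        return pd.DataFrame(columns=["label", "alias", "count", "pct"])
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.label] = counts.get(c.label, 0) + 1
    order = sorted(counts, key=lambda lab: (-counts[lab], lab))
    used = {"Pattern I", "Pattern II", "Pattern III", "Pattern V"}
    used_numbers = {1, 2, 3, 5}
    alias = {}
    next_free = (n for n in range(1, 100) if n not in used_numbers)
    for lab in order:
        alias[lab] = lab if lab in used else f"Pattern {_roman(next(next_free))}"
    n = len(calls)
    df = pd.DataFrame({
        "label": order,
        "alias": [alias[lab] for lab in order],
        "count": [counts[lab] for lab in order],
        "pct": [round(100.0 * counts[lab] / n, 2) for lab in order],
    })
    if groups is not None:
        rows = []
        for c in calls:
            rows.append((groups.get(c.gene_id, "unassigned"), c.label))
        g = pd.DataFrame(rows, columns=["group", "label"])
        per_group = (g.value_counts().rename("count").reset_index()
                     .sort_values(["group", "count", "label"],
                                  ascending=[True, False, True])
                     .reset_index(drop=True))
        df = df.merge(per_group, on="label", how="right", suffixes=("_total", ""))
    return df
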