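"""Coordinate projection and intron-in-domain pattern classification.

The load-bearing check is oracle equivalence: ``introns_in_domain`` must
agree with a brute-force oracle that maps every domain nucleotide to the
genome and counts junctions strictly between consecutive domain nucleotides,
on randomized gene models including minus-strand and codon-splitting introns.
"""

import numpy as np
import pytest

from famevol import intronpattern, syndata
from famevol.genestruct import GeneModel, Transcript
from famevol.intronpattern import (PatternCall, classify_pattern,
                                   domain_cds_span, introns_in_domain,
                                   pattern_census, spliced_to_genomic)
from famevol.seqalign import DomainHit


def _transcript(cds_pieces):
    return Transcript("t1", [(s, e) for s, e in cds_pieces],
                      [(s, e, 0) for s, e in cds_pieces])


def test_spliced_to_genomic_examples():
    single = _transcript([(100, 400)])
    assert spliced_to_genomic(single, "+", 1) == 100
    assert spliced_to_genomic(single, "-", 1) == 399
    two = _transcript([(0, 9), (19, 31)])
    assert spliced_to_genomic(two, "+", 10) == 19
    with pytest.raises(ValueError):
        spliced_to_genomic(single, "+", 0)
    with pytest.raises(ValueError):
        spliced_to_genomic(single, "+", 301)


def test_domain_cds_span_formula():
    hit = DomainHit("p", "DPBB", 1, 10, 0, 0)
    assert domain_cds_span(hit, 100) == (1, 30)
    assert domain_cds_span(DomainHit("p", "DPBB", 11, 11, 0, 0), 100) == (31, 33)
    with pytest.raises(ValueError):
        domain_cds_span(DomainHit("p", "DPBB", 90, 120, 0, 0), 100)


def test_single_exon_transcript_has_no_domain_introns():
    t = _transcript([(0, 300)])
    hit = DomainHit("p", "DPBB", 5, 50, 0, 0)
    assert introns_in_domain(t, "+", hit, 100) == 0


def test_classify_pattern_table():
    assert classify_pattern(2, 0) == "Pattern I"
    assert classify_pattern(1, 0) == "Pattern II"
    assert classify_pattern(3, 0) == "Pattern III"
    assert classify_pattern(3, 1) == "Pattern V"
    assert classify_pattern(0, 0) == "P(0,0)"
    assert classify_pattern(4, 2) == "P(4,2)"
    with pytest.raises(ValueError):
        classify_pattern(-1, 0)


def test_boundary_convention():
    """An intron in the first codon is inside; right after the last is not."""
    protein_len = 60
    # domain residues 11..20 -> CDS span [31, 60]
    hit = DomainHit("p", "D", 11, 20, 0, 0)
    for junction, inside in ((30, False),  # between codon 10 and 11
                             (31, True),   # splits the first domain codon
                             (59, True),   # splits the last domain codon
                             (60, False)):  # immediately after the last codon
        t = _transcript([(0, junction), (1000, 1000 + 3 * protein_len - junction)])
        assert introns_in_domain(t, "+", hit, protein_len) == int(inside), junction


@pytest.mark.parametrize("seed", range(8))
def test_introns_in_domain_matches_per_nucleotide_oracle(seed):
    """200+ randomized gene models, both strands, codon-splitting introns."""
    rng = np.random.default_rng(seed)
    for _ in range(25):
        protein_len = int(rng.integers(40, 120))
        cds_len = 3 * protein_len
        n_introns = int(rng.integers(0, 6))
        junctions = sorted(set(
            int(j) for j in rng.integers(1, cds_len, size=n_introns)))
        strand = "+" if rng.random() < 0.5 else "-"
        cuts = [0] + junctions + [cds_len]
        pieces = []
        pos = int(rng.integers(0, 1000))
        for a, b in zip(cuts, cuts[1:]):
            pieces.append((pos, pos + (b - a)))
            pos += (b - a) + int(rng.integers(60, 300))
        if strand == "-":
            total = pieces[-1][1] + 50
            pieces = sorted((total - e, total - s) for s, e in pieces)
        t = _transcript(pieces)
        s = int(rng.integers(1, protein_len - 5))
        e = int(rng.integers(s, protein_len))
        hit = DomainHit("p", "D", s, e, 0, 0)
        got = introns_in_domain(t, strand, hit, protein_len)
        # independent oracle: map every domain nucleotide to the genome and
        # count non-contiguous steps between consecutive domain nucleotides
        lo, hi = 3 * (s - 1) + 1, 3 * e
        coords = [spliced_to_genomic(t, strand, p) for p in range(lo, hi + 1)]
        step = 1 if strand == "+" else -1
        breaks = sum(1 for a, b in zip(coords, coords[1:]) if b != a + step)
        assert got == breaks


def test_mirrored_genome_gives_identical_patterns(small_genome, tmp_path):
    """Reverse-complementing every chromosome must not change any call."""
    from famevol import genestruct

    spec = small_genome.spec
    models = {m.gene_id: m
              for m in genestruct.parse_gff3(small_genome.paths["gff3"])}
    mirrored = {}
    chrom_len = {name: len(seq) for name, seq in small_genome.chromosomes.items()}
    for gid, m in models.items():
        L = chrom_len[m.chromosome]
        flip = lambda iv: (L - iv[1], L - iv[0])
        new_transcripts = [
            Transcript(t.transcript_id,
                       sorted(flip((s, e)) for s, e in t.exons),
                       [(a, b, 0) for a, b in
                        sorted(flip((s, e)) for s, e, _ in t.cds)])
            for t in m.transcripts
        ]
        mirrored[gid] = GeneModel(
            gene_id=m.gene_id, species_id=m.species_id,
            chromosome=m.chromosome,
            strand="-" if m.strand == "+" else "+",
            span=(L - m.span[1], L - m.span[0]), transcripts=new_transcripts)
    for g in small_genome.genes:
        if g.kind != "member":
            continue
        L = len(g.transcripts[0].protein)
        dpbb = DomainHit(g.gene_id, "DPBB", *g.dpbb_span, 0, 0)
        cbm = DomainHit(g.gene_id, "CBM63", *g.cbm63_span, 0, 0)
        for model_set in (models, mirrored):
            m = model_set[g.gene_id]
            t = m.transcript(g.gene_id + ".t1")
            nd = introns_in_domain(t, m.strand, dpbb, L)
            nc = introns_in_domain(t, m.strand, cbm, L)
            assert (nd, nc) == small_genome.truth.intron_patterns[g.gene_id]


def test_pattern_census_counts_and_aliases():
    calls = ([PatternCall(f"a{i}", 2, 0, "Pattern I") for i in range(5)]
             + [PatternCall(f"b{i}", 1, 0, "Pattern II") for i in range(5)])
    df = pattern_census(calls)
    assert df["pct"].tolist() == [50.0, 50.0]
    assert df["count"].sum() == len(calls)
    assert pattern_census([]).empty
    # non-canonical pairs get the unused numerals by rank
    calls2 = ([PatternCall(f"c{i}", 0, 0, classify_pattern(0, 0))
               for i in range(4)]
              + [PatternCall(f"d{i}", 4, 0, classify_pattern(4, 0))
                 for i in range(2)])
    df2 = pattern_census(calls2)
    assert df2.loc[df2["label"] == "P(0,0)", "alias"].item() == "Pattern IV"
    assert df2.loc[df2["label"] == "P(4,0)", "alias"].item() == "Pattern VI"


def test_pattern_census_top6_study_arithmetic():
    """Six common patterns covering 2409 of 2461 genes -> 97.89%."""
    pcts = [47.26, 18.89, 11.82, 8.09, 6.30, 5.53]
    pairs = [(2, 0), (1, 0), (3, 0), (0, 0), (3, 1), (4, 0)]
    n_total = 2461
    calls = []
    i = 0
    for pct, (d, c) in zip(pcts, pairs):
        for _ in range(round(pct / 100 * n_total)):
            calls.append(PatternCall(f"g{i}", d, c, classify_pattern(d, c)))
            i += 1
    rare = [(5, 0), (6, 1), (2, 1), (7, 2)]
    while len(calls) < n_total:
        d, c = rare[i % len(rare)]
        calls.append(PatternCall(f"g{i}", d, c, classify_pattern(d, c)))
        i += 1
    df = pattern_census(calls)
    top6 = df.nlargest(6, "count")["pct"].sum()
    assert top6 == pytest.approx(97.89, abs=0.02)
    assert df["count"].sum() == n_total
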