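"""Synthetic-genome generator: determinism, planted structures, simulators."""

import numpy as np
import pytest

from famevol import genestruct, intronpattern, seqalign, syndata
from famevol.seqalign import DomainHit
from famevol.syndata import (GenomeSpec, PlantedMember, SegmentalPlan,
                             TandemPlan, make_expression, make_genome,
                             simulate_codon_pair)


def test_empty_family_plan_gives_empty_truth(tmp_path):
    spec = GenomeSpec(species_id="e", n_chromosomes=1, n_background_genes=5,
                      seed=3)
    g = make_genome(spec, tmp_path)
    assert g.truth.members == {}
    assert len(g.genes) == 5


def test_same_spec_same_seed_identical_bytes(tmp_path):
    spec = syndata.default_genome_spec("d", seed=5, n_members=6,
                                       n_background=20)
    g1 = make_genome(spec, tmp_path / "a")
    g2 = make_genome(spec, tmp_path / "b")
    for key in g1.paths:
        assert g1.paths[key].read_bytes() == g2.paths[key].read_bytes()
    for name in ("members.tsv", "tandem.tsv", "collinear.tsv", "patterns.tsv",
                 "expression.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()


def test_spec_validation_rejects_infeasible_plans():
    with pytest.raises(ValueError, match="array_size"):
        TandemPlan(chromosome=0, array_size=1, n_intervening=0)
    with pytest.raises(ValueError, match="n_intervening"):
        TandemPlan(chromosome=0, array_size=2, n_intervening=2)
    with pytest.raises(ValueError, match=">= 10"):
        SegmentalPlan(m=5, source_chromosome=0, target_chromosome=1,
                      subst_prob=0.05)
    with pytest.raises(ValueError, match="out of range"):
        GenomeSpec(species_id="x", n_chromosomes=1,
                   tandem_plan=[TandemPlan(chromosome=3, array_size=2,
                                           n_intervening=0)])
    with pytest.raises(ValueError, match="protein_length"):
        PlantedMember(subfamily="EXPA", protein_length=150)


def test_segmental_plan_needs_a_family_gene_on_source(tmp_path):
    spec = GenomeSpec(species_id="x", n_chromosomes=2, n_background_genes=30,
                      segmental_plan=[SegmentalPlan(
                          m=10, source_chromosome=0, target_chromosome=1,
                          subst_prob=0.05)], seed=1)
    with pytest.raises(ValueError, match="family gene"):
        make_genome(spec, tmp_path)
    spec_short = GenomeSpec(species_id="y", n_chromosomes=2,
                            n_background_genes=6,
                            segmental_plan=[SegmentalPlan(
                                m=10, source_chromosome=0, target_chromosome=1,
                                subst_prob=0.05)], seed=1)
    with pytest.raises(ValueError, match="< window"):
        make_genome(spec_short, tmp_path / "short")


def test_planted_members_have_diagnostic_motifs(small_genome):
    by_gene = {}
    for header, seq in seqalign.read_fasta(small_genome.paths["protein"]):
        tid = header.split()[0]
        if tid.endswith(".t1"):
            by_gene[header.split("gene=")[1]] = seq
    for gid, sub in small_genome.truth.members.items():
        prot = by_gene[gid]
        assert "GACG" in prot and "CGAC" in prot
        if sub in ("EXPA", "EXPB"):
            assert "HDF" in prot
        else:
            assert "TDF" in prot
        assert ("CDRC" in prot[:40]) == (sub == "EXLA")


def test_half_of_planted_members_on_minus_strand(small_genome):
    planted = [g for g in small_genome.genes
               if g.kind == "member" and g.gene_id in
               {gid for cl in [list(small_genome.truth.members)] for gid in cl}]
    strands = [g.strand for g in small_genome.genes if g.kind == "member"]
    assert 0.25 <= strands.count("-") / len(strands) <= 0.75


def test_proteins_translate_from_cds_without_internal_stops(small_genome):
    cds = dict((h.split()[0], s)
               for h, s in seqalign.read_fasta(small_genome.paths["cds"]))
    prots = dict((h.split()[0], s)
                 for h, s in seqalign.read_fasta(small_genome.paths["protein"]))
    for tid, c in cds.items():
        body = c[:-3] if c[-3:] in syndata.STOP_CODONS else c
        aa = "".join(syndata.CODON_TO_AA[body[i:i + 3]]
                     for i in range(0, len(body), 3))
        assert aa == prots[tid]


def test_gff3_roundtrip_reconstructs_planted_models(small_genome):
    models = {m.gene_id: m
              for m in genestruct.parse_gff3(small_genome.paths["gff3"])}
    for g in small_genome.genes:
        m = models[g.gene_id]
        assert m.strand == g.strand
        for t in g.transcripts:
            parsed = m.transcript(t.transcript_id)
            expected = [(g.start + a, g.start + b) for a, b in t.exons]
            assert parsed.exons == expected
            assert [(s, e) for s, e, _ in parsed.cds] == expected


def test_planted_pattern_classified_by_projection(tmp_path):
    """A planted (2,0) member is classified (2,0) from its own coordinates."""
    spec = GenomeSpec(species_id="p", n_chromosomes=1, n_background_genes=4,
                      family_plan=[PlantedMember("EXPA", (2, 0), 240),
                                   PlantedMember("EXLB", (3, 1), 260)],
                      seed=17)
    g = make_genome(spec, tmp_path)
    models = {m.gene_id: m for m in genestruct.parse_gff3(g.paths["gff3"])}
    for gr in g.genes:
        if gr.kind != "member":
            continue
        model = models[gr.gene_id]
        t = model.transcript(gr.gene_id + ".t1")
        dpbb = DomainHit(gr.gene_id, "DPBB", *gr.dpbb_span, 0.0, 0.0)
        cbm = DomainHit(gr.gene_id, "CBM63", *gr.cbm63_span, 0.0, 0.0)
        L = len(gr.transcripts[0].protein)
        nd = intronpattern.introns_in_domain(t, model.strand, dpbb, L)
        nc = intronpattern.introns_in_domain(t, model.strand, cbm, L)
        assert (nd, nc) == g.truth.intron_patterns[gr.gene_id]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def test_expression_degenerate_and_boundary_proportions():
    genes = [f"g{i}" for i in range(10)]
    silent = make_expression(genes, (0, 0, 1), seed=1)
    assert (silent["fpkm"] == 0).all()
    expressed = make_expression(genes, (1, 0, 0), seed=1)
    assert (expressed["fpkm"] >= 1).all()
    assert make_expression([], (0.5, 0.25, 0.25), seed=1).empty


def test_expression_study_census_counts():
    # 506 genes at the study proportions split 198 / 97 / 211
    genes = [f"g{i}" for i in range(506)]
    df = make_expression(genes, (0.3913, 0.1917, 0.4170), seed=0)
    counts = df["category"].value_counts()
    assert counts["expressed"] == 198
    assert counts["weak"] == 97
    assert counts["silent"] == 211


def test_expression_rejects_bad_proportions():
    with pytest.raises(ValueError):
        make_expression(["g1"], (0.5, 0.2, 0.2))
    with pytest.raises(ValueError):
        make_expression(["g1"], (-0.1, 0.6, 0.5))


def test_expression_category_consistent_with_value(small_genome):
    for gid, (fpkm, cat) in small_genome.truth.expression.items():
        if cat == "expressed":
            assert fpkm >= 1
        elif cat == "weak":
            assert 0 < fpkm < 1
        else:
            assert fpkm == 0


# ---------------------------------------------------------------------------
# codon-pair simulator
# ---------------------------------------------------------------------------

def test_codon_pair_zero_divergence_and_determinism():
    a, b = simulate_codon_pair(40, 0.0, 1.0, seed=3)
    assert a == b and len(a) == 120
    a1, b1 = simulate_codon_pair(40, 0.5, 1.0, seed=9)
    a2, b2 = simulate_codon_pair(40, 0.5, 1.0, seed=9)
    assert (a1, b1) == (a2, b2)
    a3, _ = simulate_codon_pair(40, 0.5, 1.0, seed=10)
    assert a3 != a1


def test_codon_pair_validation_and_stop_freedom():
    with pytest.raises(ValueError):
        simulate_codon_pair(10, 0.5, 1.0)
    with pytest.raises(ValueError):
        simulate_codon_pair(40, 0.5, -1.0)
    with pytest.raises(ValueError):
        simulate_codon_pair(40, -0.5, 1.0)
    a, b = simulate_codon_pair(60, 1.0, 2.0, seed=4)
    for seq in (a, b):
        for i in range(0, len(seq), 3):
            assert seq[i:i + 3] not in syndata.STOP_CODONS


def test_largest_remainder_is_exact_partition():
    rng = np.random.default_rng(0)
    for _ in range(20):
        raw = rng.random(3)
        props = raw / raw.sum()
        n = int(rng.integers(1, 500))
        counts = syndata._largest_remainder_counts(n, props)
        assert sum(counts) == n
        assert all(abs(c - p * n) <= 1 for c, p in zip(counts, props))
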