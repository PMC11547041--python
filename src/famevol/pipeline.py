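"""End-to-end orchestration over one or many species.

``run_all`` drives the full analysis on annotated proteomes: identification
cascade and subfamily assignment, domain-architecture census, gene-structure
statistics and correlations, intron-in-domain pattern census, tandem and
collinear duplication scan with mechanism classification, NG86 Ka/Ks over
paralogous pairs, the family NJ tree with subfamily-concordance statistics,
and expression categorization — emitting one TSV per stage plus a JSON run
manifest.  Identical config + seed reproduce byte-identical outputs.

``make_bundle`` materializes a ready-to-run multi-species synthetic study
(genomes, annotation, references, domain seed alignments, config file and
truth tables) for tests and demonstrations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (dupscan, exprcat, family_id, genestruct, intronpattern, kaksng,
               phyloconcord, seqalign, syndata)

__all__ = ["SpeciesInput", "RunConfig", "load_config", "run_all",
           "summarize_counts", "make_bundle"]


@dataclass
class SpeciesInput:
    species_id: str
    protein_fasta: str
    gff3: str
    cds_fasta: str
    expression_tsv: str | None = None
    lineage: str = "unassigned"
    ploidy: int = 2


@dataclass
class Thresholds:
    min_coverage: float = 0.30
    min_identity: float = 0.30
    homology_evalue: float = 1e-3
    domain_evalue: float = 1e-5
    tandem_max_intervening: int = 1
    window_genes: int = 20
    min_block: int = 5
    max_rank_gap: int = 25
    anchor_identity: float = 0.5
    anchor_coverage: float = 0.5
    ks_max: float = 2.0
    fpkm_expressed: float = 1.0
    preferential_tau: float = 10.0


@dataclass
class RunConfig:
    species: list[SpeciesInput]
    reference_fasta: str
    seed_alignment_dpbb: str
    seed_alignment_cbm63: str
    outdir: str
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        paths = [self.reference_fasta, self.seed_alignment_dpbb,
                 self.seed_alignment_cbm63]
        for s in self.species:
            paths += [s.protein_fasta, s.gff3, s.cds_fasta]
            if s.expression_tsv:
                paths.append(s.expression_tsv)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input missing: {p}")

    def to_dict(self) -> dict:
        return {
            "species": [vars(s) for s in self.species],
            "reference_fasta": self.reference_fasta,
            "seed_alignment_dpbb": self.seed_alignment_dpbb,
            "seed_alignment_cbm63": self.seed_alignment_cbm63,
            "outdir": self.outdir,
            "seed": self.seed,
            "thresholds": vars(self.thresholds),
        }


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    thresholds = Thresholds(**raw.get("thresholds", {}))
    species = [SpeciesInput(**s) for s in raw["species"]]
    return RunConfig(species=species, reference_fasta=raw["reference_fasta"],
                     seed_alignment_dpbb=raw["seed_alignment_dpbb"],
                     seed_alignment_cbm63=raw["seed_alignment_cbm63"],
                     outdir=raw.get("outdir", "famevol_out"),
                     seed=int(raw.get("seed", 0)), thresholds=thresholds)


def _load_pssms(config: RunConfig) -> dict[str, seqalign.PSSM]:
    pssms = {}
    for name, path in (("DPBB", config.seed_alignment_dpbb),
                       ("CBM63", config.seed_alignment_cbm63)):
        rows = [seq for _, seq in seqalign.read_fasta(path)]
        pssms[name] = seqalign.build_pssm(rows, pseudocount=1.0, domain_name=name)
    return pssms


def summarize_counts(members, lineage_map: dict[str, str]):
    """Per-lineage mean member counts, per-subfamily totals and the grand total.

    ``members`` is any iterable of objects with ``species_id``/``subfamily``
    attributes, or (species_id, subfamily) tuples.  Lineage means are over
    species possessing at least one member; species absent from the lineage
    map fall into an "unassigned" bucket (with a warning upstream).
    """
    per_species: dict[str, int] = {}
    per_subfamily: dict[str, int] = {}
    for m in members:
        sp, sub = (m if isinstance(m, tuple) else (m.species_id, m.subfamily))
        per_species[sp] = per_species.get(sp, 0) + 1
        per_subfamily[sub] = per_subfamily.get(sub, 0) + 1
    per_lineage: dict[str, list[int]] = {}
    for sp, n in per_species.items():
        per_lineage.setdefault(lineage_map.get(sp, "unassigned"), []).append(n)
    lineage_means = {lin: sum(v) / len(v) for lin, v in sorted(per_lineage.items())}
    return {
        "per_species": dict(sorted(per_species.items())),
        "per_lineage_mean": lineage_means,
        "per_subfamily": dict(sorted(per_subfamily.items())),
        "grand_total": sum(per_subfamily.values()),
    }


def _strip_stop(cds: str) -> str:
    return cds[:-3] if cds[-3:].upper() in kaksng.STOP_CODONS else cds


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the result bundle and writes the report TSVs."""
    config.validate()
    th = config.thresholds
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    references = family_id.parse_reference_fasta(config.reference_fasta)
    pssms = _load_pssms(config)

    members: list[family_id.FamilyMember] = []
    rejections: dict[str, dict[str, str]] = {}
    censuses = []
    models_by_species: dict[str, dict[str, genestruct.GeneModel]] = {}
    proteins_by_gene: dict[str, str] = {}
    cds_by_transcript: dict[str, str] = {}
    members_by_species: dict[str, list[str]] = {}

    for sp in config.species:
        records = seqalign.read_fasta(sp.protein_fasta)
        sp_members, sp_rej = family_id.identify_family(
            records, references, pssms, species_id=sp.species_id,
            min_coverage=th.min_coverage, min_identity=th.min_identity,
            homology_evalue=th.homology_evalue, domain_evalue=th.domain_evalue,
            seed=config.seed)
        members.extend(sp_members)
        rejections[sp.species_id] = sp_rej
        members_by_species[sp.species_id] = [m.gene_id for m in sp_members]
        genes = family_id.group_transcripts_by_gene(records)
        member_ids = {m.gene_id for m in sp_members}
        # architecture census: cascade members are known dual-domain; the rest
        # of the proteome is scanned directly
        n_both = n_d = n_c = n_none = 0
        for gid in sorted(genes):
            if gid in member_ids:
                n_both += 1
                continue
            tid = family_id.select_isoform(genes[gid])
            prot = genes[gid][tid]
            present = {}
            for name in ("DPBB", "CBM63"):
                if len(prot) * 2 < pssms[name].length:
                    present[name] = False
                    continue
                present[name] = bool(seqalign.scan_pssm(
                    prot, pssms[name], evalue_threshold=th.domain_evalue,
                    seed=family_id._subseed(config.seed, "census", name, gid),
                    protein_id=gid))
            if present["DPBB"] and present["CBM63"]:
                n_both += 1
            elif present["DPBB"]:
                n_d += 1
            elif present["CBM63"]:
                n_c += 1
            else:
                n_none += 1
        censuses.append(family_id.ArchitectureCensus(
            species_id=sp.species_id, n_both=n_both, n_dpbb_only=n_d,
            n_cbm63_only=n_c, n_neither=n_none))
        models = genestruct.parse_gff3(sp.gff3, species_id=sp.species_id)
        models_by_species[sp.species_id] = {m.gene_id: m for m in models}
        for gid, isoforms in genes.items():
            tid = family_id.select_isoform(isoforms)
            proteins_by_gene[gid] = isoforms[tid]
        for header, seq in seqalign.read_fasta(sp.cds_fasta):
            cds_by_transcript[header.split()[0]] = seq

    # --- gene structure + correlations -------------------------------------
    structure_rows = []
    for m in members:
        model = models_by_species[m.species_id].get(m.gene_id)
        if model is None:
            continue
        prot = proteins_by_gene[m.gene_id]
        st = genestruct.structure_stats(model, m.chosen_transcript_id, prot)
        structure_rows.append((m, st))
    correlations = []
    if len(structure_rows) >= 3:
        gene_lengths = [st.gene_length for _, st in structure_rows]
        for name, values in (
                ("exon_length", [st.exon_total for _, st in structure_rows]),
                ("intron_length", [st.intron_total for _, st in structure_rows])):
            try:
                correlations.append(genestruct.correlate(
                    values, gene_lengths, x_name=name, y_name="gene_length"))
            except ValueError:
                pass

    # --- intron patterns ----------------------------------------------------
    calls = []
    for m in members:
        model = models_by_species[m.species_id].get(m.gene_id)
        if model is None:
            continue
        calls.append(intronpattern.call_pattern(
            model, m.chosen_transcript_id, m.dpbb, m.cbm63, m.protein_length))
    census_df = intronpattern.pattern_census(calls)

    # --- duplication scan ---------------------------------------------------
    ranks_by_species = {
        sp: dupscan.gene_ranks(list(models.values()))
        for sp, models in models_by_species.items()
    }
    clusters = []
    for sp in sorted(members_by_species):
        clusters.extend(dupscan.tandem_clusters(
            [g for g in members_by_species[sp]
             if g in ranks_by_species[sp]], ranks_by_species[sp]))
    blocks = dupscan.collinear_scan(
        members_by_species, ranks_by_species, proteins_by_gene,
        k=th.window_genes, min_block=th.min_block,
        max_rank_gap=th.max_rank_gap, min_identity=th.anchor_identity,
        min_coverage=th.anchor_coverage)
    mechanisms = dupscan.classify_mechanism(
        [m.gene_id for m in members], clusters, blocks)

    # --- Ka/Ks over paralogous pairs ---------------------------------------
    cds_by_gene = {}
    for m in members:
        cds = cds_by_transcript.get(m.chosen_transcript_id)
        if cds is not None:
            cds_by_gene[m.gene_id] = _strip_stop(cds)
    pair_set = set()
    for c in clusters:
        for i, ga in enumerate(c.members):
            for gb in c.members[i + 1:]:
                pair_set.add((min(ga, gb), max(ga, gb)))
    species_of = {m.gene_id: m.species_id for m in members}
    for b in blocks:
        family_anchor_pairs = [
            (ga, gb) for ga, gb in b.anchors
            if ga in species_of and gb in species_of
            and species_of[ga] == species_of[gb]]
        for ga, gb in family_anchor_pairs:
            pair_set.add((min(ga, gb), max(ga, gb)))
    pairs = []
    for ga, gb in sorted(pair_set):
        if ga not in cds_by_gene or gb not in cds_by_gene:
            continue
        aln = seqalign.global_align(proteins_by_gene[ga], proteins_by_gene[gb],
                                    query_id=ga, target_id=gb)
        codon_aln = kaksng.backtranslate(aln.aligned_query, aln.aligned_target,
                                         cds_by_gene[ga], cds_by_gene[gb],
                                         id_a=ga, id_b=gb)
        pairs.append(kaksng.kaks_pair(codon_aln))
    pairs = kaksng.filter_and_classify(pairs, ks_max=th.ks_max)

    # --- phylogeny + concordance -------------------------------------------
    newick = None
    concordance = None
    if len(members) >= 3:
        ids = [m.gene_id for m in members]
        msa = seqalign.progressive_msa([proteins_by_gene[g] for g in ids])
        dm = phyloconcord.pdistance_matrix(msa, ids=ids)
        newick = phyloconcord.neighbor_joining(dm)
        concordance = phyloconcord.subfamily_concordance(
            newick, {m.gene_id: m.subfamily for m in members})

    # --- expression ---------------------------------------------------------
    expression_records = []
    for sp in config.species:
        if not sp.expression_tsv:
            continue
        table = exprcat.load_expression_table(sp.expression_tsv)
        sp_records = exprcat.make_records(
            {g: table[g] for g in members_by_species[sp.species_id]
             if g in table})
        exprcat.preferential_flags(sp_records, tau=th.preferential_tau)
        expression_records.extend(sp_records)
    expr_census = exprcat.category_census(expression_records)

    summary = summarize_counts(
        members, {sp.species_id: sp.lineage for sp in config.species})
    ploidy_norm = {
        sp.species_id: dupscan.normalize_ploidy(
            summary["per_species"].get(sp.species_id, 0), sp.ploidy)
        for sp in config.species
    }

    results = {
        "members": members,
        "rejections": rejections,
        "censuses": censuses,
        "structure": structure_rows,
        "correlations": correlations,
        "pattern_calls": calls,
        "pattern_census": census_df,
        "tandem_clusters": clusters,
        "collinear_blocks": blocks,
        "mechanisms": mechanisms,
        "kaks_pairs": pairs,
        "newick": newick,
        "concordance": concordance,
        "expression": expression_records,
        "expression_census": expr_census,
        "summary": summary,
        "ploidy_normalized": ploidy_norm,
    }
    _write_reports(config, results, outdir)
    return results


def _write_reports(config: RunConfig, r: dict, outdir: Path) -> None:
    with open(outdir / "members.tsv", "w") as fh:
        fh.write("gene_id\tspecies\ttranscript\tsubfamily\tprotein_length\t"
                 "dpbb_start\tdpbb_end\tcbm63_start\tcbm63_end\t"
                 "motif_discordant\tgacg_cgac_spacing\n")
        for m in sorted(r["members"], key=lambda m: m.gene_id):
            fh.write(f"{m.gene_id}\t{m.species_id}\t{m.chosen_transcript_id}\t"
                     f"{m.subfamily}\t{m.protein_length}\t{m.dpbb.start}\t"
                     f"{m.dpbb.end}\t{m.cbm63.start}\t{m.cbm63.end}\t"
                     f"{int(m.motif_discordant)}\t{m.gacg_cgac_spacing}\n")
    with open(outdir / "census.tsv", "w") as fh:
        fh.write("species\tn_both\tn_dpbb_only\tn_cbm63_only\tn_neither\n")
        for c in r["censuses"]:
            fh.write(f"{c.species_id}\t{c.n_both}\t{c.n_dpbb_only}\t"
                     f"{c.n_cbm63_only}\t{c.n_neither}\n")
    with open(outdir / "structure.tsv", "w") as fh:
        fh.write("gene_id\tsubfamily\tgene_length\texon_total\texon_count\t"
                 "intron_total\tintron_count\tprotein_length\t"
                 "molecular_weight\tisoelectric_point\n")
        for m, st in sorted(r["structure"], key=lambda x: x[1].gene_id):
            fh.write(f"{st.gene_id}\t{m.subfamily}\t{st.gene_length}\t"
                     f"{st.exon_total}\t{st.exon_count}\t{st.intron_total}\t"
                     f"{st.intron_count}\t{st.protein_length}\t"
                     f"{st.molecular_weight:.2f}\t{st.isoelectric_point:.3f}\n")
    with open(outdir / "correlations.tsv", "w") as fh:
        fh.write("x\ty\tpearson_r\tr_squared\tp_value\tn\n")
        for c in r["correlations"]:
            fh.write(f"{c.x_name}\t{c.y_name}\t{c.pearson_r:.4f}\t"
                     f"{c.r_squared:.4f}\t{c.p_value:.3e}\t{c.n}\n")
    with open(outdir / "patterns.tsv", "w") as fh:
        fh.write("gene_id\tn_introns_dpbb\tn_introns_cbm63\tlabel\n")
        for c in sorted(r["pattern_calls"], key=lambda c: c.gene_id):
            fh.write(f"{c.gene_id}\t{c.n_introns_dpbb}\t{c.n_introns_cbm63}\t"
                     f"{c.label}\n")
    r["pattern_census"].to_csv(outdir / "pattern_census.tsv", sep="\t",
                               index=False)
    with open(outdir / "tandem.tsv", "w") as fh:
        fh.write("cluster_id\tchromosome\tmembers\n")
        for i, c in enumerate(r["tandem_clusters"]):
            fh.write(f"tandem{i + 1}\t{c.chromosome}\t{','.join(c.members)}\n")
    with open(outdir / "collinear.tsv", "w") as fh:
        fh.write("block_id\tspecies_a\tspecies_b\torientation\tn_anchors\t"
                 "anchors\n")
        for i, b in enumerate(r["collinear_blocks"]):
            fh.write(f"block{i + 1}\t{b.species_a}\t{b.species_b}\t"
                     f"{b.orientation}\t{len(b.anchors)}\t"
                     f"{';'.join(f'{a},{c}' for a, c in b.anchors)}\n")
    with open(outdir / "mechanism.tsv", "w") as fh:
        fh.write("gene_id\tin_tandem\tin_collinear\tmechanism\n")
        for m in sorted(r["mechanisms"], key=lambda m: m.gene_id):
            fh.write(f"{m.gene_id}\t{int(m.in_tandem)}\t{int(m.in_collinear)}\t"
                     f"{m.mechanism}\n")
    with open(outdir / "kaks.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tka\tks\tratio\tn_sites\ts_sites\t"
                 "selection\tdiscarded\treason\n")
        for p in r["kaks_pairs"]:
            fmt = lambda v: "NA" if v is None else f"{v:.5f}"
            fh.write(f"{p.gene_id_a}\t{p.gene_id_b}\t{fmt(p.ka)}\t{fmt(p.ks)}\t"
                     f"{fmt(p.ratio)}\t{p.n_sites:.2f}\t{p.s_sites:.2f}\t"
                     f"{p.selection}\t{int(p.discarded)}\t{p.reason}\n")
    if r["newick"] is not None:
        (outdir / "tree.nwk").write_text(r["newick"] + "\n")
    with open(outdir / "concordance.tsv", "w") as fh:
        fh.write("subfamily\tmonophyletic\n")
        if r["concordance"] is not None:
            for sub, flag in sorted(r["concordance"].monophyletic.items()):
                fh.write(f"{sub}\t{int(flag)}\n")
            fh.write(f"#fraction\t{r['concordance'].fraction_monophyletic:.4f}\n")
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("gene_id\tfpkm\tcategory\tpreferential\n")
        for rec in sorted(r["expression"], key=lambda x: x.gene_id):
            fh.write(f"{rec.gene_id}\t{rec.fpkm:.4f}\t{rec.category}\t"
                     f"{int(rec.preferential)}\n")
    r["expression_census"].to_csv(outdir / "expression_census.tsv", sep="\t",
                                  index=False)
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for sub, n in r["summary"]["per_subfamily"].items():
            fh.write(f"subfamily_total_{sub}\t{n}\n")
        for lin, mean in r["summary"]["per_lineage_mean"].items():
            fh.write(f"lineage_mean_{lin}\t{mean:.4f}\n")
        for sp, v in sorted(r["ploidy_normalized"].items()):
            fh.write(f"diploid_normalized_{sp}\t{v:.2f}\n")
        fh.write(f"grand_total\t{r['summary']['grand_total']}\n")
    from . import __version__

    hashed = config.to_dict()
    hashed.pop("outdir", None)  # the output location is not part of the run
    manifest = {
        "famevol_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(hashed, sort_keys=True).encode()).hexdigest(),
        "n_members": len(r["members"]),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def make_bundle(outdir, seed: int, n_species: int = 3, n_members: int = 13,
                n_background: int = 50, n_decoys: tuple[int, int] = (2, 2),
                with_tandem: bool = True, with_segmental: bool = True,
                ) -> tuple[RunConfig, dict[str, syndata.TruthTables]]:
    """Materialize a ready-to-run synthetic multi-species study.

    Writes per-species genome/annotation/CDS/protein/expression files, the
    labeled reference FASTA, the two domain seed alignments and a config.yaml;
    returns the loaded RunConfig plus per-species truth tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqalign.write_fasta(syndata.reference_proteins(),
                         outdir / "references.fasta")
    for dom, rows in syndata.seed_alignments().items():
        seqalign.write_fasta(rows, outdir / f"seed_{dom.lower()}.fasta")
    species_entries = []
    truths = {}
    lineages = ["chlorophytes", "mosses", "eudicots", "monocots", "ferns"]
    for i in range(n_species):
        sp_id = f"sp{i + 1}"
        spec = syndata.default_genome_spec(
            sp_id, seed=(seed * 1009 + i) & 0x7FFFFFFF, n_members=n_members,
            n_background=n_background, n_decoys=n_decoys,
            with_tandem=with_tandem, with_segmental=with_segmental)
        genome = syndata.make_genome(spec, outdir / sp_id)
        truths[sp_id] = genome.truth
        species_entries.append({
            "species_id": sp_id,
            "protein_fasta": str(genome.paths["protein"]),
            "gff3": str(genome.paths["gff3"]),
            "cds_fasta": str(genome.paths["cds"]),
            "expression_tsv": str(genome.paths["expression"]),
            "lineage": lineages[i % len(lineages)],
            "ploidy": 2,
        })
    config = {
        "species": species_entries,
        "reference_fasta": str(outdir / "references.fasta"),
        "seed_alignment_dpbb": str(outdir / "seed_dpbb.fasta"),
        "seed_alignment_cbm63": str(outdir / "seed_cbm63.fasta"),
        "outdir": str(outdir / "results"),
        "seed": seed,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return load_config(outdir / "config.yaml"), truths
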