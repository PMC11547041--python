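"""Two-domain family identification cascade and subfamily assignment.

The cascade mirrors a standard genome-wide gene-family survey: (1) a homology
gate against labeled reference proteins (local alignment, coverage > 30%,
identity > 30%, permutation e-value < 1e-3); (2) domain confirmation — both
the N-terminal DPBB and the C-terminal CBM63 domain must be detected by PSSM
scan at e-value < 1e-5, in that order on the protein; (3) longest-isoform
selection per gene; (4) subfamily assignment by nearest labeled reference,
cross-checked against diagnostic motifs (HDF for EXPA/EXPB vs TDF for
EXLA/EXLB; an N-terminal CDRC only in EXLA) — motif-discordant members keep
the reference-based label but are flagged.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field

from . import seqalign
from .seqalign import DomainHit, PSSM

__all__ = [
    "FamilyMember", "ArchitectureCensus", "Reference",
    "find_candidates", "detect_both_domains", "select_isoform",
    "assign_subfamily", "architecture_census", "identify_family",
    "parse_reference_fasta", "group_transcripts_by_gene",
]

CASCADE_STAGES = ("homology", "both_domains", "domain_order",
                  "longest_isoform", "subfamily")


def _subseed(seed: int, *names) -> int:
    x = seed & 0x7FFFFFFF
    for n in names:
        x = zlib.crc32(f"{x}:{n}".encode()) & 0x7FFFFFFF
    return x


@dataclass
class Reference:
    ref_id: str
    subfamily: str
    sequence: str


def parse_reference_fasta(path) -> list[Reference]:
    """Read labeled references; headers carry ``subfamily=XXXX``."""
    refs = []
    for header, seq in seqalign.read_fasta(path):
        m = re.search(r"subfamily=(\S+)", header)
        if not m:
            raise ValueError(f"reference header lacks subfamily=: {header!r}")
        refs.append(Reference(ref_id=header.split()[0], subfamily=m.group(1),
                              sequence=seq))
    return refs


@dataclass
class FamilyMember:
    gene_id: str
    species_id: str
    chosen_transcript_id: str
    protein_length: int
    dpbb: DomainHit
    cbm63: DomainHit
    subfamily: str
    filters_passed: list[str] = field(default_factory=lambda: list(CASCADE_STAGES))
    motif_discordant: bool = False
    gacg_cgac_spacing: int | None = None

    def __post_init__(self):
        if not self.dpbb.start < self.cbm63.start:
            raise ValueError("DPBB must precede CBM63 on the protein")


@dataclass
class ArchitectureCensus:
    species_id: str
    n_both: int
    n_dpbb_only: int
    n_cbm63_only: int
    n_neither: int

    @property
    def total(self) -> int:
        return self.n_both + self.n_dpbb_only + self.n_cbm63_only + self.n_neither


def find_candidates(proteome: list[tuple[str, str]],
                    queries: list[tuple[str, str]],
                    min_coverage: float = 0.30, min_identity: float = 0.30,
                    max_evalue: float = 1e-3, n_shuffles: int = 1000,
                    seed: int = 0) -> list[str]:
    """Homology gate: proteins with some query passing all three thresholds.

    Coverage and identity are strict `>` (query-relative coverage); the
    e-value is the strict `<` permutation tail of the best-passing query's
    local score against the single target (D = 1).  Note the e-value floor is
    1/(n_shuffles+1), so n_shuffles must exceed 1/max_evalue.
    """
    if not proteome or not queries:
        raise ValueError("proteome and queries must be non-empty")
    out = []
    for target_id, target in proteome:
        best = None
        for query_id, query in queries:
            aln = seqalign.local_align(query, target, query_id=query_id,
                                       target_id=target_id)
            if aln.identity > min_identity and aln.coverage > min_coverage:
                if best is None or aln.score > best[1]:
                    best = (query, aln.score)
        if best is None:
            continue
        query, score = best
        ev = seqalign.empirical_evalue(
            score, query, [target], n_shuffles=n_shuffles,
            seed=_subseed(seed, "homology", target_id),
            stop_threshold=max_evalue)
        if ev < max_evalue:
            out.append(target_id)
    return out


def detect_both_domains(candidates: list[tuple[str, str]],
                        pssms: dict[str, PSSM], max_evalue: float = 1e-5,
                        n_shuffles: int = 100001, seed: int = 0,
                        ) -> tuple[dict[str, tuple[DomainHit, DomainHit]],
                                   dict[str, str]]:
    """Keep candidates with significant DPBB *and* CBM63 hits, DPBB first.

    Returns (accepted: id -> (dpbb, cbm63), rejected: id -> reason); the best
    (lowest e-value, then highest score) hit per domain is retained.
    """
    accepted = {}
    rejected = {}
    for pid, seq in candidates:
        hits = {}
        for name in ("DPBB", "CBM63"):
            found = seqalign.scan_pssm(
                seq, pssms[name], evalue_threshold=max_evalue,
                n_shuffles=n_shuffles,
                seed=_subseed(seed, "scan", name, pid), protein_id=pid)
            if found:
                hits[name] = min(found, key=lambda h: (h.evalue, -h.score))
        if "DPBB" not in hits and "CBM63" not in hits:
            rejected[pid] = "no domain"
        elif "DPBB" not in hits:
            rejected[pid] = "missing DPBB"
        elif "CBM63" not in hits:
            rejected[pid] = "missing CBM63"
        elif not hits["DPBB"].start < hits["CBM63"].start:
            rejected[pid] = "domain order"
        else:
            accepted[pid] = (hits["DPBB"], hits["CBM63"])
    return accepted, rejected


def select_isoform(proteins_by_transcript: dict[str, str]) -> str:
    """Longest-protein isoform; ties break to the lexicographically smallest id."""
    if not proteins_by_transcript:
        raise ValueError("gene has no transcripts")
    return min(proteins_by_transcript,
               key=lambda tid: (-len(proteins_by_transcript[tid]), tid))


def _motif_consistent(protein: str, subfamily: str) -> bool:
    has_hdf = "HDF" in protein
    has_tdf = "TDF" in protein
    has_cdrc = "CDRC" in protein[:40]
    if subfamily in ("EXPA", "EXPB"):
        return has_hdf and not has_cdrc
    if subfamily == "EXLA":
        return has_tdf and has_cdrc
    if subfamily == "EXLB":
        return has_tdf and not has_cdrc
    return False


def _gacg_cgac_spacing(protein: str) -> int | None:
    """Residues between the end of the first GACG and the next CGAC motif."""
    g = protein.find("GACG")
    if g < 0:
        return None
    c = protein.find("CGAC", g + 4)
    if c < 0:
        return None
    return c - (g + 4)


def assign_subfamily(protein: str, references: list[Reference],
                     ) -> tuple[str, bool]:
    """Nearest labeled reference by global-alignment score decides the label.

    Returns (subfamily, motif_discordant): the diagnostic-motif evidence
    (HDF/TDF, N-terminal CDRC) must agree with the label, else the member is
    flagged discordant but keeps the reference-based subfamily.
    """
    if not references:
        raise ValueError("empty reference set")
    best = None
    for ref in references:
        score = seqalign.global_align(protein, ref.sequence).score
        if best is None or score > best[1]:
            best = (ref.subfamily, score)
    subfamily = best[0]
    return subfamily, not _motif_consistent(protein, subfamily)


def group_transcripts_by_gene(protein_records: list[tuple[str, str]],
                              ) -> dict[str, dict[str, str]]:
    """Map gene_id -> {transcript_id: protein} from ``tid gene=gid`` headers."""
    genes: dict[str, dict[str, str]] = {}
    for header, seq in protein_records:
        tid = header.split()[0]
        m = re.search(r"gene=(\S+)", header)
        gid = m.group(1) if m else tid.rsplit(".", 1)[0]
        genes.setdefault(gid, {})[tid] = seq
    return genes


def architecture_census(proteome: list[tuple[str, str]], pssms: dict[str, PSSM],
                        max_evalue: float = 1e-5, n_shuffles: int = 100001,
                        seed: int = 0, species_id: str = "") -> ArchitectureCensus:
    """Tally domain architectures (both / DPBB-only / CBM63-only / neither)."""
    n_both = n_d = n_c = n_none = 0
    for pid, seq in proteome:
        present = {}
        for name in ("DPBB", "CBM63"):
            if len(seq) * 2 < pssms[name].length:
                present[name] = False
                continue
            found = seqalign.scan_pssm(
                seq, pssms[name], evalue_threshold=max_evalue,
                n_shuffles=n_shuffles,
                seed=_subseed(seed, "census", name, pid), protein_id=pid)
            present[name] = bool(found)
        if present["DPBB"] and present["CBM63"]:
            n_both += 1
        elif present["DPBB"]:
            n_d += 1
        elif present["CBM63"]:
            n_c += 1
        else:
            n_none += 1
    return ArchitectureCensus(species_id=species_id, n_both=n_both,
                              n_dpbb_only=n_d, n_cbm63_only=n_c,
                              n_neither=n_none)


def identify_family(protein_records: list[tuple[str, str]],
                    references: list[Reference], pssms: dict[str, PSSM],
                    species_id: str = "", min_coverage: float = 0.30,
                    min_identity: float = 0.30, homology_evalue: float = 1e-3,
                    domain_evalue: float = 1e-5, seed: int = 0,
                    ) -> tuple[list[FamilyMember], dict[str, str]]:
    """Run the full cascade on one species' protein records.

    ``protein_records`` are (header, sequence) with ``gene=`` tags linking
    isoforms.  The longest isoform per gene is chosen first (the survey works
    per gene), then the cascade gates that protein.  Returns the accepted
    members plus a rejection log of gene_id -> failing stage.
    """
    genes = group_transcripts_by_gene(protein_records)
    rejections: dict[str, str] = {}
    chosen: list[tuple[str, str, str]] = []  # (gene, transcript, protein)
    for gid in sorted(genes):
        tid = select_isoform(genes[gid])
        chosen.append((gid, tid, genes[gid][tid]))
    queries = [(r.ref_id, r.sequence) for r in references]
    candidates = set(find_candidates(
        [(gid, prot) for gid, _, prot in chosen], queries,
        min_coverage=min_coverage, min_identity=min_identity,
        max_evalue=homology_evalue,
        n_shuffles=max(1000, int(1.0 / homology_evalue)), seed=seed))
    for gid, _, _ in chosen:
        if gid not in candidates:
            rejections[gid] = "homology"
    surviving = [(gid, tid, prot) for gid, tid, prot in chosen
                 if gid in candidates]
    accepted, rejected = detect_both_domains(
        [(gid, prot) for gid, _, prot in surviving], pssms,
        max_evalue=domain_evalue, seed=seed)
    rejections.update(rejected)
    members = []
    for gid, tid, prot in surviving:
        if gid not in accepted:
            continue
        dpbb, cbm63 = accepted[gid]
        subfamily, discordant = assign_subfamily(prot, references)
        members.append(FamilyMember(
            gene_id=gid, species_id=species_id, chosen_transcript_id=tid,
            protein_length=len(prot), dpbb=dpbb, cbm63=cbm63,
            subfamily=subfamily, motif_discordant=discordant,
            gacg_cgac_spacing=_gacg_cgac_spacing(prot)))
    return members, rejections
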