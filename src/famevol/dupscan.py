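"""Tandem and WGD/segmental duplication detection.

Tandem clusters are maximal runs of family genes on one chromosome separated
by at most one intervening protein-coding gene.  Large-scale duplications are
found the window way: the 20 protein-coding genes up- and downstream of each
family gene form a 41-gene neighborhood; reciprocal-best homology anchors
between two neighborhoods are chained into collinear blocks (longest
strictly-monotone subsequence with a rank-gap cap, both orientations, >= 5
anchors — mirroring the common collinearity-tool defaults).  Each member is
then classified tandem / wgd_segmental / both / dispersed, and per-species
counts can be normalized to the diploid level.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import seqalign
from .genestruct import GeneModel

__all__ = [
    "TandemCluster", "CollinearBlock", "MechanismCall",
    "gene_ranks", "tandem_clusters", "neighborhood", "find_anchors",
    "chain_collinear", "classify_mechanism", "normalize_ploidy",
    "collinear_scan",
]


@dataclass
class TandemCluster:
    chromosome: str
    members: list[str]

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("tandem cluster needs >= 2 members")


@dataclass
class CollinearBlock:
    species_a: str
    species_b: str
    anchors: list[tuple[str, str]]
    orientation: str  # same | inverted
    score: float


@dataclass
class MechanismCall:
    gene_id: str
    in_tandem: bool
    in_collinear: bool

    @property
    def mechanism(self) -> str:
        if self.in_tandem and self.in_collinear:
            return "both"
        if self.in_tandem:
            return "tandem"
        if self.in_collinear:
            return "wgd_segmental"
        return "dispersed"


def gene_ranks(models: list[GeneModel]) -> dict[str, tuple[str, int]]:
    """Rank protein-coding genes 0..n-1 per chromosome by start coordinate."""
    seen = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        if m.gene_id in seen:
            raise ValueError(f"duplicate gene_id {m.gene_id}")
        seen.add(m.gene_id)
        by_chrom.setdefault(m.chromosome, []).append(m)
    ranks = {}
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: (g.span[0], g.gene_id))
        for i, g in enumerate(genes):
            ranks[g.gene_id] = (chrom, i)
    return ranks


def tandem_clusters(family_genes: list[str],
                    ranks: dict[str, tuple[str, int]]) -> list[TandemCluster]:
    """Maximal chains of family genes with <= 1 intervening gene (rank gap <= 2)."""
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in family_genes:
        chrom, r = ranks[g]
        by_chrom.setdefault(chrom, []).append((r, g))
    clusters = []
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom])
        chain = [entries[0]]
        for prev, cur in zip(entries, entries[1:]):
            if cur[0] - prev[0] <= 2:
                chain.append(cur)
            else:
                if len(chain) >= 2:
                    clusters.append(TandemCluster(chrom, [g for _, g in chain]))
                chain = [cur]
        if len(chain) >= 2:
            clusters.append(TandemCluster(chrom, [g for _, g in chain]))
    return clusters


def neighborhood(gene: str, ranks: dict[str, tuple[str, int]],
                 k: int = 20) -> list[str]:
    """Up to k genes either side of the focal gene (rank order, ends truncated)."""
    chrom, r = ranks[gene]
    by_rank = {rank: g for g, (c, rank) in ranks.items() if c == chrom}
    lo = max(0, r - k)
    hi = min(max(by_rank) + 1, r + k + 1)
    return [by_rank[i] for i in range(lo, hi)]


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def find_anchors(window_a: list[str], window_b: list[str],
                 proteins: dict[str, str], min_identity: float = 0.5,
                 min_coverage: float = 0.5) -> list[tuple[str, str]]:
    """Reciprocal-best local-alignment anchor pairs between two gene windows.

    Self-pairs are dropped.  A shared-4-mer prefilter skips hopeless pairs
    before alignment (copies at the divergences that matter here share most
    4-mers; unrelated proteins share almost none).
    """
    kmers = {g: _kmer_set(proteins[g]) for g in set(window_a) | set(window_b)}
    scores: dict[tuple[str, str], float] = {}
    for ga in window_a:
        for gb in window_b:
            if ga == gb:
                continue
            ka, kb = kmers[ga], kmers[gb]
            denom = min(len(ka), len(kb)) or 1
            if len(ka & kb) / denom < 0.2:
                continue
            aln = seqalign.local_align(proteins[ga], proteins[gb],
                                       query_id=ga, target_id=gb)
            if aln.identity >= min_identity and aln.coverage >= min_coverage:
                scores[(ga, gb)] = aln.score
    if not scores:
        return []
    best_b: dict[str, tuple[float, str]] = {}
    best_a: dict[str, tuple[float, str]] = {}
    for (ga, gb), s in sorted(scores.items()):
        if ga not in best_b or s > best_b[ga][0]:
            best_b[ga] = (s, gb)
        if gb not in best_a or s > best_a[gb][0]:
            best_a[gb] = (s, ga)
    anchors = []
    for ga, (s, gb) in sorted(best_b.items()):
        if best_a[gb][1] == ga:
            anchors.append((ga, gb))
    return anchors


def _best_chain(points: list[tuple[int, int, int]], direction: int,
                max_gap: int) -> list[int]:
    """Longest chain (indices) with a-ranks strictly increasing and b-ranks
    strictly increasing (direction=+1) or decreasing (-1); gaps <= max_gap."""
    pts = sorted(range(len(points)), key=lambda i: (points[i][0],
                                                    direction * points[i][1]))
    best_len = [1] * len(pts)
    prev = [-1] * len(pts)
    for ii, i in enumerate(pts):
        ra, rb, _ = points[i]
        for jj in range(ii):
            j = pts[jj]
            qa, qb, _ = points[j]
            if qa < ra and (ra - qa) <= max_gap:
                db = (rb - qb) * direction
                if 0 < db <= max_gap:
                    if best_len[jj] + 1 > best_len[ii]:
                        best_len[ii] = best_len[jj] + 1
                        prev[ii] = jj
    end = max(range(len(pts)), key=lambda ii: (best_len[ii], -pts[ii]))
    chain = []
    ii = end
    while ii != -1:
        chain.append(pts[ii])
        ii = prev[ii]
    return list(reversed(chain))


def chain_collinear(anchors: list[tuple[str, str]],
                    ranks_a: dict[str, tuple[str, int]],
                    ranks_b: dict[str, tuple[str, int]],
                    min_block: int = 5, max_rank_gap: int = 25,
                    species_a: str = "", species_b: str = "",
                    ) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks (score = anchor count).

    Iteratively extracts the longest strictly-monotone chain (both
    orientations searched; consecutive-anchor rank gaps capped on both sides);
    each anchor joins at most one block; chains shorter than ``min_block`` are
    discarded.
    """
    pool = [(ranks_a[ga][1], ranks_b[gb][1], i)
            for i, (ga, gb) in enumerate(anchors)]
    blocks = []
    while pool:
        candidates = []
        for direction, name in ((1, "same"), (-1, "inverted")):
            chain = _best_chain(pool, direction, max_rank_gap)
            candidates.append((len(chain), name == "same", name, chain))
        n, _, orientation, chain = max(candidates)
        if n < min_block:
            break
        idxs = [pool[c][2] for c in chain]
        blocks.append(CollinearBlock(
            species_a=species_a, species_b=species_b,
            anchors=[anchors[i] for i in idxs],
            orientation=orientation, score=float(n)))
        used = {pool[c][2] for c in chain}
        pool = [p for p in pool if p[2] not in used]
    return blocks


def classify_mechanism(member_ids: list[str], clusters: list[TandemCluster],
                       blocks: list[CollinearBlock]) -> list[MechanismCall]:
    in_tandem = {g for c in clusters for g in c.members}
    in_coll = {g for b in blocks for pair in b.anchors for g in pair}
    return [MechanismCall(g, g in in_tandem, g in in_coll)
            for g in member_ids]


def normalize_ploidy(count: int, ploidy: int) -> float:
    """Scale a gene count to the diploid level (count * 2 / ploidy)."""
    if ploidy < 2 or ploidy % 2 != 0:
        raise ValueError("ploidy must be an even integer >= 2")
    return count * 2 / ploidy


def collinear_scan(members_by_species: dict[str, list[str]],
                   ranks_by_species: dict[str, dict[str, tuple[str, int]]],
                   proteins: dict[str, str], k: int = 20,
                   min_block: int = 5, max_rank_gap: int = 25,
                   min_identity: float = 0.5, min_coverage: float = 0.5,
                   ) -> list[CollinearBlock]:
    """Window-based collinearity over all (within- and cross-species) member pairs.

    For every pair of family genes whose proteins pass a quick 4-mer
    similarity check, the two 41-gene neighborhoods are anchored and chained;
    duplicate blocks discovered from overlapping windows are deduplicated by
    their anchor sets.
    """
    species = sorted(members_by_species)
    seen: set[frozenset] = set()
    blocks: list[CollinearBlock] = []
    for si in species:
        for sj in species:
            if sj < si:
                continue
            for ga in members_by_species[si]:
                for gb in members_by_species[sj]:
                    if si == sj and gb <= ga:
                        continue
                    ka, kb = _kmer_set(proteins[ga]), _kmer_set(proteins[gb])
                    denom = min(len(ka), len(kb)) or 1
                    if len(ka & kb) / denom < 0.2:
                        continue
                    wa = neighborhood(ga, ranks_by_species[si], k)
                    wb = neighborhood(gb, ranks_by_species[sj], k)
                    anchors = find_anchors(wa, wb, proteins, min_identity,
                                           min_coverage)
                    found = chain_collinear(anchors, ranks_by_species[si],
                                            ranks_by_species[sj], min_block,
                                            max_rank_gap, si, sj)
                    for b in found:
                        # the two regions of a within-species block must be
                        # disjoint (overlapping windows otherwise produce
                        # mirror-symmetric artifact chains)
                        side_a = {a for a, _ in b.anchors}
                        side_b = {c for _, c in b.anchors}
                        if si == sj and side_a & side_b:
                            continue
                        # orientation-free key: (a,b) and (b,a) discoveries
                        # of the same physical block collapse together
                        key = frozenset(frozenset(p) for p in b.anchors)
                        if key not in seen:
                            seen.add(key)
                            blocks.append(b)
    # window truncation can rediscover a block as a fragment of a larger
    # one; keep only blocks that are not sub-blocks of another
    keyed = [(frozenset(frozenset(p) for p in b.anchors), b) for b in blocks]
    keyed.sort(key=lambda kb: -len(kb[0]))
    kept: list[tuple[frozenset, CollinearBlock]] = []
    for key, b in keyed:
        if not any(key < other for other, _ in kept):
            kept.append((key, b))
    return [b for _, b in kept]
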