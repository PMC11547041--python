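"""Duplication scan: tandem rule, windows, anchor chaining, mechanisms."""

import itertools

import numpy as np
import pytest

from famevol import dupscan, genestruct, syndata
from famevol.dupscan import (chain_collinear, classify_mechanism, find_anchors,
                             gene_ranks, neighborhood, normalize_ploidy,
                             tandem_clusters)
from famevol.genestruct import GeneModel, Transcript


def _models(starts, chrom="chr1"):
    out = []
    for i, s in enumerate(starts):
        out.append(GeneModel(
            gene_id=f"g{i}", species_id="s", chromosome=chrom,
            strand="+", span=(s, s + 10),
            transcripts=[Transcript("t", [(s, s + 9)], [(s, s + 9, 0)])]))
    return out


def test_gene_ranks_by_start_with_id_tiebreak():
    ranks = gene_ranks(_models([10, 5, 20]))
    assert ranks == {"g0": ("chr1", 1), "g1": ("chr1", 0), "g2": ("chr1", 2)}
    two = _models([10, 5]) + _models([3], chrom="chr2")
    two[2].gene_id = "h0"
    ranks2 = gene_ranks(two)
    assert ranks2["h0"] == ("chr2", 0)
    dup = _models([1, 2])
    dup[1].gene_id = "g0"
    with pytest.raises(ValueError, match="duplicate"):
        gene_ranks(dup)


def _rank_map(rank_list, chrom="chr1"):
    return {f"g{r}": (chrom, r) for r in rank_list}


def test_tandem_rule_examples():
    full = {f"g{r}": ("chr1", r) for r in range(30)}
    assert [c.members for c in tandem_clusters(["g10", "g11"], full)] == \
        [["g10", "g11"]]
    assert [c.members for c in tandem_clusters(["g10", "g12"], full)] == \
        [["g10", "g12"]]  # one intervening gene still clusters
    assert tandem_clusters(["g10", "g13"], full) == []  # two intervening: no
    assert [c.members for c in tandem_clusters(["g10", "g12", "g14", "g20"],
                                               full)] == [["g10", "g12", "g14"]]


def _brute_force_clusters(ranks):
    """Maximal runs of family ranks with successive gaps <= 2, size >= 2."""
    ranks = sorted(ranks)
    runs, cur = [], [ranks[0]]
    for r in ranks[1:]:
        if r - cur[-1] <= 2:
            cur.append(r)
        else:
            runs.append(cur)
            cur = [r]
    runs.append(cur)
    return [run for run in runs if len(run) >= 2]


def test_tandem_matches_brute_force_over_all_subsets():
    full = {f"g{r}": ("chr1", r) for r in range(30)}
    rng = np.random.default_rng(0)
    all_subsets = []
    for size in range(1, 9):
        for _ in range(40):
            all_subsets.append(sorted(
                int(x) for x in rng.choice(30, size=size, replace=False)))
    for subset in all_subsets:
        got = [[int(g[1:]) for g in c.members]
               for c in tandem_clusters([f"g{r}" for r in subset], full)]
        assert got == _brute_force_clusters(subset), subset


def test_neighborhood_windows():
    full = {f"g{r}": ("chr1", r) for r in range(100)}
    w = neighborhood("g25", full, k=20)
    assert len(w) == 41 and w[0] == "g5" and w[-1] == "g45"
    w_edge = neighborhood("g3", full, k=20)
    assert len(w_edge) == 24 and w_edge[0] == "g0"
    lonely = {"solo": ("chrX", 0)}
    assert neighborhood("solo", lonely) == ["solo"]


def test_chain_collinear_perfect_and_inverted():
    anchors = [(f"a{i}", f"b{i}") for i in range(10)]
    ra = {f"a{i}": ("c1", i) for i in range(10)}
    rb = {f"b{i}": ("c2", i) for i in range(10)}
    (block,) = chain_collinear(anchors, ra, rb)
    assert len(block.anchors) == 10 and block.orientation == "same"
    rb_rev = {f"b{i}": ("c2", 9 - i) for i in range(10)}
    (inv,) = chain_collinear(anchors, ra, rb_rev)
    assert len(inv.anchors) == 10 and inv.orientation == "inverted"
    # strict monotonicity holds on every output
    for b in (block, inv):
        ras = [ra[x][1] for x, _ in b.anchors]
        assert ras == sorted(ras) and len(set(ras)) == len(ras)


def _oracle_best_chain(points, max_gap):
    """Exhaustive longest monotone chain over <= 12 anchors."""
    best = 0
    n = len(points)
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            pts = sorted(combo, key=lambda i: points[i][0])
            for direction in (1, -1):
                ok = True
                for i, j in zip(pts, pts[1:]):
                    da = points[j][0] - points[i][0]
                    db = (points[j][1] - points[i][1]) * direction
                    if not (0 < da <= max_gap and 0 < db <= max_gap):
                        ok = False
                        break
                if ok:
                    best = max(best, size)
    return best


@pytest.mark.parametrize("seed", range(6))
def test_chain_collinear_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 12))
    pts = [(int(rng.integers(0, 30)), int(rng.integers(0, 30)))
           for _ in range(n)]
    # unique a-ranks and b-ranks (anchors come from reciprocal-best pairs)
    pts = list({p[0]: p for p in {p[1]: p for p in pts}.values()}.values())
    anchors = [(f"a{i}", f"b{i}") for i in range(len(pts))]
    ra = {f"a{i}": ("c", p[0]) for i, p in enumerate(pts)}
    rb = {f"b{i}": ("c", p[1]) for i, p in enumerate(pts)}
    blocks = chain_collinear(anchors, ra, rb, min_block=2, max_rank_gap=25)
    want = _oracle_best_chain(pts, 25)
    got = max((len(b.anchors) for b in blocks), default=max(
        1 if pts else 0, 0))
    if want >= 2:
        assert got == want
    else:
        assert blocks == []


def test_find_anchors_on_planted_segmental_block(small_genome):
    models = genestruct.parse_gff3(small_genome.paths["gff3"])
    ranks = gene_ranks(models)
    proteins = {g.gene_id: g.transcripts[0].protein for g in small_genome.genes}
    (block_truth,) = small_genome.truth.collinear_blocks
    src, dst = block_truth[len(block_truth) // 2]
    wa = neighborhood(src, ranks)
    wb = neighborhood(dst, ranks)
    anchors = find_anchors(wa, wb, proteins)
    truth_pairs = set(block_truth)
    assert len(set(anchors) & truth_pairs) >= len(block_truth) - 2
    blocks = chain_collinear(anchors, ranks, ranks)
    assert blocks and len(blocks[0].anchors) >= 5


def test_find_anchors_unrelated_windows_empty():
    rng = np.random.default_rng(77)
    for trial in range(20):
        prots = {f"x{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
                 for i in range(12)}
        wa = [f"x{i}" for i in range(6)]
        wb = [f"x{i}" for i in range(6, 12)]
        assert find_anchors(wa, wb, prots) == []


def test_classify_mechanism_and_ploidy():
    clusters = [dupscan.TandemCluster("c1", ["g1", "g2"])]
    blocks = [dupscan.CollinearBlock("s", "s", [("g2", "g3")], "same", 5.0)]
    calls = {c.gene_id: c.mechanism
             for c in classify_mechanism(["g1", "g2", "g3", "g4"],
                                         clusters, blocks)}
    assert calls == {"g1": "tandem", "g2": "both", "g3": "wgd_segmental",
                     "g4": "dispersed"}
    assert normalize_ploidy(150, 6) == 50
    assert normalize_ploidy(94, 2) == 94
    assert normalize_ploidy(100, 4) == 50
    with pytest.raises(ValueError):
        normalize_ploidy(10, 3)
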