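"""Alignment machinery: DP vs enumeration oracles, e-values, PSSM scanning."""

import itertools

import numpy as np
import pytest

from famevol import seqalign, syndata
from famevol.seqalign import (build_pssm, empirical_evalue, global_align,
                              local_align, local_score, progressive_msa,
                              scan_pssm)

# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle (independent of the DP implementations)
# ---------------------------------------------------------------------------

def _enumerate_global(a, b, score_fn, gap_open, gap_ext):
    """Max score over every global alignment, scoring gap runs affinely."""
    best = [-1e18]

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], _score_cols(cols, score_fn, gap_open, gap_ext))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


def _score_cols(cols, score_fn, gap_open, gap_ext):
    total = 0.0
    run = None  # which side is gapped
    for x, y in cols:
        if x == "-" or y == "-":
            side = "x" if x == "-" else "y"
            if run != side:
                total -= gap_open
            total -= gap_ext
            run = side
        else:
            total += score_fn(x, y)
            run = None
    return total


def _enumerate_local(a, b, score_fn, gap_open, gap_ext):
    best = 0.0
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            best = max(best, _enumerate_global(a[i1:i2], b[j1:j2], score_fn,
                                               gap_open, gap_ext))
    return best


def _b62(x, y):
    from Bio.Align import substitution_matrices

    return float(substitution_matrices.load("BLOSUM62")[x, y])


@pytest.mark.parametrize("seed", range(6))
def test_global_score_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    alphabet = "ACDE"  # reduced alphabet keeps enumeration tractable
    a = "".join(rng.choice(list(alphabet), rng.integers(1, 6)))
    b = "".join(rng.choice(list(alphabet), rng.integers(1, 6)))
    got = global_align(a, b, gap_open=4, gap_extend=1).score
    want = _enumerate_global(a, b, _b62, 4, 1)
    assert got == pytest.approx(want)


@pytest.mark.parametrize("seed", range(4))
def test_local_score_matches_enumeration(seed):
    rng = np.random.default_rng(100 + seed)
    alphabet = "ACDE"
    a = "".join(rng.choice(list(alphabet), rng.integers(1, 6)))
    b = "".join(rng.choice(list(alphabet), rng.integers(1, 6)))
    got = local_align(a, b, gap_open=4, gap_extend=1).score
    want = _enumerate_local(a, b, _b62, 4, 1)
    assert got == pytest.approx(want)


def test_sw_kernel_matches_biopython_scores():
    rng = np.random.default_rng(7)
    for _ in range(10):
        a = "".join(rng.choice(list(seqalign.AA20), 40))
        b = "".join(rng.choice(list(seqalign.AA20), 55))
        assert local_score(a, b) == local_align(a, b).score


def test_identity_and_coverage_definitions():
    a = global_align("MKVLA", "MKVLA")
    assert a.identity == 1.0 and a.coverage == 1.0
    # 100-residue query fully matched inside a longer target (local)
    rng = np.random.default_rng(1)
    q = "".join(rng.choice(list(seqalign.AA20), 100))
    t = "WWWWW" + q + "WWWWW"
    loc = local_align(q, t)
    assert loc.identity == 1.0
    assert loc.coverage == 1.0
    # de-gapping recovers the aligned slice of the inputs
    assert loc.aligned_query.replace("-", "") in q
    assert loc.aligned_target.replace("-", "") in t


def test_local_score_floor_and_symmetric_identity():
    rng = np.random.default_rng(3)
    for _ in range(5):
        a = "".join(rng.choice(list(seqalign.AA20), 30))
        b = "".join(rng.choice(list(seqalign.AA20), 30))
        ab = local_align(a, b)
        ba = local_align(b, a)
        assert ab.score >= 0
        assert 0 <= ab.identity <= 1 and 0 <= ab.coverage <= 1
        assert ab.identity == pytest.approx(ba.identity)


def test_alignment_input_validation():
    with pytest.raises(ValueError):
        global_align("", "MKV")
    with pytest.raises(ValueError, match="J"):
        global_align("MJV", "MKV")


# ---------------------------------------------------------------------------
# empirical e-values
# ---------------------------------------------------------------------------

def test_evalue_closed_forms():
    rng = np.random.default_rng(0)
    q = "".join(rng.choice(list(seqalign.AA20), 40))
    t = "".join(rng.choice(list(seqalign.AA20), 40))
    # observed far above anything a shuffle can reach -> 1/(n+1)
    assert empirical_evalue(1e6, q, [t], n_shuffles=999, seed=1) == \
        pytest.approx(1 / 1000)
    # observed below every shuffled score -> e-value = D
    assert empirical_evalue(-1, q, [t, t, t], n_shuffles=99, seed=1) == \
        pytest.approx(3.0)


def test_evalue_monotone_in_score_and_deterministic():
    rng = np.random.default_rng(5)
    q = "".join(rng.choice(list(seqalign.AA20), 35))
    t = "".join(rng.choice(list(seqalign.AA20), 50))
    scores = [20, 40, 60, 90]
    evs = [empirical_evalue(s, q, [t], n_shuffles=199, seed=9) for s in scores]
    assert all(e1 >= e2 for e1, e2 in zip(evs, evs[1:]))
    again = [empirical_evalue(s, q, [t], n_shuffles=199, seed=9) for s in scores]
    assert evs == again


def test_evalue_rejects_bad_inputs():
    with pytest.raises(ValueError):
        empirical_evalue(10, "MKVL", [], n_shuffles=999)
    with pytest.raises(ValueError):
        empirical_evalue(10, "MKVL", ["MKVL"], n_shuffles=9)


# ---------------------------------------------------------------------------
# PSSM build + scan
# ---------------------------------------------------------------------------

def test_pssm_hand_computed_two_columns():
    rows = ["AC", "AC", "AC", "AD", "AC"]
    p = build_pssm(rows, pseudocount=1.0)
    # col 0: all A: p(A) = (5 + 0.05) / 6
    assert p.log_odds[0, 0] == pytest.approx(np.log((5.05 / 6) / 0.05))
    # col 1: 4 C, 1 D
    c_idx = seqalign.ALPHABET.index("C")
    d_idx = seqalign.ALPHABET.index("D")
    assert p.log_odds[1, c_idx] == pytest.approx(np.log((4.05 / 6) / 0.05))
    assert p.log_odds[1, d_idx] == pytest.approx(np.log((1.05 / 6) / 0.05))


def test_pssm_background_expected_score_nonpositive():
    rng = np.random.default_rng(2)
    rows = ["".join(rng.choice(list(seqalign.AA20), 30)) for _ in range(8)]
    p = build_pssm(rows, pseudocount=1.0)
    expected = (np.exp(0) * 0.05 * p.log_odds).sum(axis=1)  # bg-weighted mean
    assert (expected <= 1e-9).all()


def test_pssm_consensus_is_columnwise_max_and_gap_drop():
    rows = ["ACDEF"] * 6
    p = build_pssm(rows, pseudocount=0.5)
    for j, res in enumerate("ACDEF"):
        assert np.argmax(p.log_odds[j]) == seqalign.ALPHABET.index(res)
    rows_gap = ["A-CDE"] * 4 + ["AFCDE"] * 2  # col 1 is 67% gaps -> dropped
    p2 = build_pssm(rows_gap, pseudocount=0.5)
    assert p2.length == 4


def test_pssm_scores_shrink_with_large_pseudocount():
    rng = np.random.default_rng(3)
    rows = ["".join(rng.choice(list(seqalign.AA20), 20)) for _ in range(8)]
    sharp = build_pssm(rows, pseudocount=0.1)
    flat = build_pssm(rows, pseudocount=1e6)
    assert np.abs(flat.log_odds).max() < 1e-3
    assert np.abs(sharp.log_odds).max() > 1.0


def test_pssm_rejects_ragged_and_small():
    with pytest.raises(ValueError):
        build_pssm(["AC", "ACD", "AC", "AC", "AC"])
    with pytest.raises(ValueError):
        build_pssm(["AC"] * 4)


def test_scan_finds_planted_domain_at_planted_coordinates(pssms):
    rng = np.random.default_rng(11)
    prot, dspan, cspan = syndata._assemble_member(rng, "EXPA", 240)
    hits = scan_pssm(prot, pssms["DPBB"], seed=4, protein_id="m")
    assert len(hits) == 1
    assert abs(hits[0].start - dspan[0]) <= 2
    assert abs(hits[0].end - dspan[1]) <= 2
    assert hits[0].evalue < 1e-5
    chits = scan_pssm(prot, pssms["CBM63"], seed=4)
    assert len(chits) == 1 and abs(chits[0].start - cspan[0]) <= 2


def test_scan_reversed_protein_has_no_hits(pssms):
    # negative control: reversed members and decoys never reach 1e-5
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        prot, _, _ = syndata._assemble_member(rng, "EXPB", 235)
        assert scan_pssm(prot[::-1], pssms["DPBB"], seed=seed) == []


def test_scan_two_separated_motifs_give_two_hits(pssms):
    rng = np.random.default_rng(21)
    dom = syndata.BLUEPRINT["cbm63"]
    filler = "".join(rng.choice(list(seqalign.AA20), 40))
    prot = filler + dom + filler + dom + filler
    hits = scan_pssm(prot, pssms["CBM63"], seed=2)
    assert len(hits) == 2
    assert hits[0].end < hits[1].start


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def test_msa_identical_sequences_have_no_gaps():
    msa = progressive_msa(["MKVLAWYH"] * 5)
    assert msa == ["MKVLAWYH"] * 5


def test_msa_two_sequences_reduce_to_global():
    a, b = "MKVLAWY", "MKVAWY"
    aln = global_align(a, b)
    assert progressive_msa([a, b]) == [aln.aligned_query, aln.aligned_target]


def test_msa_degapping_recovers_inputs_and_width():
    rng = np.random.default_rng(8)
    base = "".join(rng.choice(list(seqalign.AA20), 60))
    seqs = []
    for i in range(6):
        s = list(base)
        for _ in range(rng.integers(0, 6)):
            s[int(rng.integers(0, len(s)))] = seqalign.AA20[
                int(rng.integers(0, 20))]
        if i % 2:
            del s[10:10 + int(rng.integers(0, 4))]
        seqs.append("".join(s))
    msa = progressive_msa(seqs)
    assert len({len(r) for r in msa}) == 1
    assert len(msa[0]) >= max(len(s) for s in seqs)
    for row, s in zip(msa, seqs):
        assert row.replace("-", "") == s


def test_msa_planted_motif_columns_agree():
    # members across subfamilies share the GACG motif; after alignment the
    # motif residues should overwhelmingly land in shared columns
    seqs = []
    for i, sub in enumerate(syndata.SUBFAMILIES * 2):
        rng = np.random.default_rng(300 + i)
        prot, dspan, _ = syndata._assemble_member(rng, sub, 225 + 5 * i)
        seqs.append((prot, prot.index("GACG")))
    msa = progressive_msa([s for s, _ in seqs])
    cols = []
    for row, (orig, motif_at) in zip(msa, seqs):
        residue_idx = -1
        for col, ch in enumerate(row):
            if ch != "-":
                residue_idx += 1
                if residue_idx == motif_at:
                    cols.append(col)
                    break
    most_common = max(cols, key=cols.count)
    assert cols.count(most_common) / len(cols) >= 0.9
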