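"""Alignment and domain-scanning machinery for the identification cascade.

This module supplies the homology-search layer of the pipeline: affine-gap
pairwise alignment (Needleman-Wunsch / Smith-Waterman via Biopython's
``PairwiseAligner``), composition-preserving permutation e-values, PSSM
construction from seed alignments and ungapped window scanning for the DPBB
and CBM63 domains, and a simple guide-tree progressive multiple aligner.

E-values here are empirical permutation tails rather than Karlin-Altschul
statistics: the observed score is ranked against best scores of
composition-preserving shuffles of the query, giving

    e-value = D * (1 + exceedances) / (n_shuffles + 1)

with D the database size.  The smallest attainable value is D/(n_shuffles+1),
so thresholds dictate the number of shuffles (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import _kernels

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "X"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def validate_protein(seq: str, name: str = "sequence") -> str:
    """Reject empty sequences and characters outside the 20+X alphabet."""
    if not seq:
        raise ValueError(f"{name} is empty")
    for ch in seq:
        if ch not in _AA_INDEX:
            raise ValueError(f"{name} contains non-alphabet character {ch!r}")
    return seq


def encode_protein(seq: str) -> np.ndarray:
    """Int-code a protein over the 20+X alphabet (X = 20)."""
    return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int32, count=len(seq))


def _int_submatrix(matrix) -> np.ndarray:
    """(21, 21) int64 substitution matrix over ALPHABET order."""
    out = np.zeros((21, 21), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = int(matrix[a, b])
    return out


_B62_INT = _int_submatrix(_BLOSUM62)


@dataclass
class PairAlignment:
    """A scored pairwise alignment with identity and coverage.

    ``aligned_query``/``aligned_target`` are equal-length gapped strings.  For
    local alignments they span the aligned segment only; ``query_start`` /
    ``target_start`` give the 0-based offsets of that segment so de-gapping
    recovers the corresponding slice of the input exactly.
    """

    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: float
    query_length: int
    query_start: int = 0
    target_start: int = 0
    identity: float = field(init=False)
    coverage: float = field(init=False)

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_target):
            raise ValueError("aligned strings differ in length")
        self.identity = self._identity()
        self.coverage = self._coverage()

    def _identity(self) -> float:
        both = ident = 0
        for a, b in zip(self.aligned_query, self.aligned_target):
            if a != "-" and b != "-":
                both += 1
                if a == b:
                    ident += 1
        return ident / both if both else 0.0

    def _coverage(self) -> float:
        aligned = sum(
            1
            for a, b in zip(self.aligned_query, self.aligned_target)
            if a != "-" and b != "-"
        )
        return aligned / self.query_length


def _make_aligner(matrix, gap_open: float, gap_extend: float, mode: str):
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix
    # a gap of length L costs gap_open + gap_extend * L
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


def _align(a, b, matrix, gap_open, gap_extend, mode, query_id, target_id):
    validate_protein(a, "query")
    validate_protein(b, "target")
    aligner = _make_aligner(matrix, gap_open, gap_extend, mode)
    try:
        aln = aligner.align(a, b)[0]
    except IndexError:
        # local mode with no positive-scoring segment: the empty alignment
        return PairAlignment(query_id=query_id, target_id=target_id,
                             aligned_query="", aligned_target="", score=0.0,
                             query_length=len(a))
    qa, ta = str(aln[0]), str(aln[1])
    q_start = int(aln.aligned[0][0][0]) if mode == "local" and len(aln.aligned[0]) else 0
    t_start = int(aln.aligned[1][0][0]) if mode == "local" and len(aln.aligned[1]) else 0
    return PairAlignment(
        query_id=query_id,
        target_id=target_id,
        aligned_query=qa,
        aligned_target=ta,
        score=float(aln.score),
        query_length=len(a),
        query_start=q_start,
        target_start=t_start,
    )


def global_align(a: str, b: str, matrix=None, gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND, query_id: str = "query",
                 target_id: str = "target") -> PairAlignment:
    """Optimal global (Needleman-Wunsch) affine-gap alignment."""
    return _align(a, b, matrix if matrix is not None else _BLOSUM62,
                  gap_open, gap_extend, "global", query_id, target_id)


def local_align(a: str, b: str, matrix=None, gap_open: float = DEFAULT_GAP_OPEN,
                gap_extend: float = DEFAULT_GAP_EXTEND, query_id: str = "query",
                target_id: str = "target") -> PairAlignment:
    """Best local (Smith-Waterman) affine-gap alignment; score >= 0 always."""
    return _align(a, b, matrix if matrix is not None else _BLOSUM62,
                  gap_open, gap_extend, "local", query_id, target_id)


def local_score(a: str, b: str, gap_open: float = DEFAULT_GAP_OPEN,
                gap_extend: float = DEFAULT_GAP_EXTEND) -> int:
    """Smith-Waterman BLOSUM62 score via the integer kernel (no traceback)."""
    return int(
        _kernels.sw_score(
            encode_protein(validate_protein(a)),
            encode_protein(validate_protein(b)),
            _B62_INT, int(gap_open), int(gap_extend),
        )
    )


def empirical_evalue(observed_score: float, query: str, database: list[str],
                     n_shuffles: int = 999, seed: int = 0,
                     gap_open: float = DEFAULT_GAP_OPEN,
                     gap_extend: float = DEFAULT_GAP_EXTEND,
                     stop_threshold: float | None = None) -> float:
    """Permutation e-value of a local-alignment score against a database.

    Shuffles the query ``n_shuffles`` times (Fisher-Yates, composition
    preserved); each shuffle's best BLOSUM62 local score over the database is
    one null draw.  When ``stop_threshold`` is given the loop stops as soon as
    the e-value provably cannot fall below it (the returned value is then an
    upper-bound-consistent count, still >= the threshold).
    """
    if not database:
        raise ValueError("empty database")
    if n_shuffles < 99:
        raise ValueError("n_shuffles must be >= 99")
    q = encode_protein(validate_protein(query, "query"))
    encoded = [encode_protein(validate_protein(t, "target")) for t in database]
    flat = np.concatenate(encoded) if encoded else np.empty(0, dtype=np.int32)
    offsets = np.zeros(len(encoded) + 1, dtype=np.int64)
    for i, e in enumerate(encoded):
        offsets[i + 1] = offsets[i] + len(e)
    D = len(database)
    if stop_threshold is None:
        k_stop = n_shuffles + 1
    else:
        # smallest k with D*(1+k)/(n+1) >= stop_threshold
        k_stop = max(1, int(np.ceil(stop_threshold * (n_shuffles + 1) / D - 1)))
    k, done = _kernels.local_null_exceedances(
        q, flat, offsets, _B62_INT, int(gap_open), int(gap_extend),
        n_shuffles, seed & 0x7FFFFFFF, int(np.floor(observed_score)), k_stop,
    )
    n_eff = n_shuffles if done == n_shuffles else done
    # partial runs can only occur past the stop threshold; report consistently
    return D * (1 + k) / (n_eff + 1)


@dataclass
class PSSM:
    """Log-odds position-specific scoring matrix for one domain."""

    domain_name: str
    log_odds: np.ndarray  # (length, 20) natural-log odds
    background: np.ndarray  # (20,) background frequencies

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def int_matrix(self) -> np.ndarray:
        """(length, 21) centi-nat integer matrix; X scores the column minimum."""
        scaled = np.rint(self.log_odds * 100).astype(np.int64)
        out = np.empty((self.length, 21), dtype=np.int64)
        out[:, :20] = scaled
        out[:, 20] = scaled.min(axis=1)
        return out


@dataclass
class DomainHit:
    """One detected domain occurrence on a protein (1-based inclusive span)."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    score: float
    evalue: float

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid domain hit span")


def build_pssm(seed_alignment: list[str], pseudocount: float = 1.0,
               domain_name: str = "domain",
               background: np.ndarray | None = None) -> PSSM:
    """Log-odds PSSM from a gapped seed alignment.

    Columns with more than 50% gaps are dropped; per-column frequencies get a
    background-proportional pseudocount.  With a uniform background the
    background-weighted expected column score is -KL(bg || column) <= 0.
    """
    if len(seed_alignment) < 5:
        raise ValueError("seed alignment needs >= 5 sequences")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    ncol = len(seed_alignment[0])
    for s in seed_alignment:
        if len(s) != ncol:
            raise ValueError("ragged seed alignment")
    bg = (np.full(20, 0.05) if background is None
          else np.asarray(background, dtype=float))
    nseq = len(seed_alignment)
    cols = []
    for j in range(ncol):
        residues = [s[j] for s in seed_alignment if s[j] != "-"]
        if len(residues) * 2 < nseq:  # > 50% gaps
            continue
        counts = np.zeros(20)
        for r in residues:
            if r == "X":
                continue
            counts[_AA_INDEX[r]] += 1
        total = counts.sum()
        probs = (counts + pseudocount * bg) / (total + pseudocount)
        cols.append(np.log(probs / bg))
    return PSSM(domain_name=domain_name, log_odds=np.array(cols), background=bg)


def scan_pssm(protein: str, pssm: PSSM, evalue_threshold: float = 1e-5,
              n_shuffles: int = 100001, seed: int = 0,
              protein_id: str = "protein") -> list[DomainHit]:
    """Best non-overlapping ungapped-window domain hits below the e-value threshold.

    The PSSM window (length L) slides over every offset; candidate hits are the
    greedy non-overlapping windows with positive log-odds score (a window that
    does not beat the background model cannot be significant).  Each candidate
    is then ranked against max-window scores of ``n_shuffles`` shuffles of the
    protein; hits with e-value < ``evalue_threshold`` are returned sorted by
    start.  Sequences with no positive window skip the null loop entirely.
    """
    validate_protein(protein, "protein")
    L = pssm.length
    if len(protein) * 2 < L:
        raise ValueError("protein shorter than half the PSSM length")
    if len(protein) < L:
        return []
    x = encode_protein(protein)
    P = pssm.int_matrix()
    scores = _kernels.window_scores(x, P)
    order = np.argsort(scores)[::-1]
    candidates: list[tuple[int, int]] = []  # (offset, score)
    taken = np.zeros(len(scores), dtype=bool)
    for o in order:
        if scores[o] <= 0:
            break
        if taken[max(0, o - L + 1):o + L].any():
            continue
        candidates.append((int(o), int(scores[o])))
        taken[o] = True
    if not candidates:
        return []
    # the formula's floor: below it nothing can pass
    if 1.0 / (n_shuffles + 1) >= evalue_threshold:
        return []
    obs_sorted = np.array(sorted(s for _, s in candidates), dtype=np.int64)
    k_stop = max(1, int(np.ceil(evalue_threshold * (n_shuffles + 1) - 1)))
    counts, done = _kernels.scan_null_exceedances(
        x, P, n_shuffles, seed & 0x7FFFFFFF, obs_sorted, k_stop)
    evalue_by_score = {
        int(s): (1 + int(k)) / (done + 1) for s, k in zip(obs_sorted, counts)
    }
    hits = []
    for o, s in candidates:
        ev = evalue_by_score[s]
        if done == n_shuffles and ev < evalue_threshold:
            hits.append(DomainHit(protein_id=protein_id, domain_name=pssm.domain_name,
                                  start=o + 1, end=o + L, score=s / 100.0, evalue=ev))
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def _kmer_cosine_distances(sequences: list[str], k: int = 3) -> np.ndarray:
    """1 - cosine similarity of k-mer count vectors (guide-tree distances)."""
    vecs = []
    for s in sequences:
        counts: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
        vecs.append(counts)
    n = len(sequences)
    D = np.zeros((n, n))
    norms = [np.sqrt(sum(v * v for v in c.values())) or 1.0 for c in vecs]
    for i in range(n):
        for j in range(i + 1, n):
            dot = sum(v * vecs[j].get(kk, 0) for kk, v in vecs[i].items())
            D[i, j] = D[j, i] = 1.0 - dot / (norms[i] * norms[j])
    return D


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(ncol, 20) residue frequencies per column, gaps excluded."""
    ncol = len(rows[0])
    F = np.zeros((ncol, 20))
    for r in rows:
        for j, ch in enumerate(r):
            if ch != "-" and ch != "X":
                F[j, _AA_INDEX[ch]] += 1
    sums = F.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return F / sums

_B62_FLOAT = _B62_INT[:20, :20].astype(float)


def _merge_profiles(rows_a: list[str], rows_b: list[str],
                    gap_open: float, gap_extend: float) -> list[str]:
    """Profile-profile global alignment; returns the merged gapped rows."""
    FA = _profile_freqs(rows_a)
    FB = _profile_freqs(rows_b)
    S = FA @ _B62_FLOAT @ FB.T
    M, X, Y = _kernels.affine_dp_matrix(S, gap_open, gap_extend)
    n, m = S.shape
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    ops = []  # 0 diag, 1 consume a, 2 consume b
    go, ge = gap_open, gap_extend
    while i > 0 or j > 0:
        if i == 0:
            ops.append(2)
            j -= 1
            continue
        if j == 0:
            ops.append(1)
            i -= 1
            continue
        if state == 0:
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            ops.append(0)
            i -= 1
            j -= 1
        elif state == 1:
            cands = [M[i - 1, j] - go - ge, X[i - 1, j] - ge, Y[i - 1, j] - go - ge]
            state = int(np.argmax(cands))
            ops.append(1)
            i -= 1
        else:
            cands = [M[i, j - 1] - go - ge, Y[i, j - 1] - ge, X[i, j - 1] - go - ge]
            state = [0, 2, 1][int(np.argmax(cands))]
            ops.append(2)
            j -= 1
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == 0 or op == 1:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[ia])
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r].append("-")
        if op == 0 or op == 2:
            for r, row in enumerate(rows_b):
                out_b[r].append(row[ib])
            ib += 1
        else:
            for r in range(len(rows_b)):
                out_b[r].append("-")
    return ["".join(r) for r in out_a] + ["".join(r) for r in out_b]


def progressive_msa(sequences: list[str], gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND) -> list[str]:
    """Guide-tree progressive multiple alignment.

    Guide tree: neighbor joining on 3-mer cosine distances; profiles are merged
    bottom-up with affine profile-profile alignment (mean-of-pairs BLOSUM62
    column scores).  De-gapping row i recovers ``sequences[i]`` exactly.
    """
    for s in sequences:
        validate_protein(s, "sequence")
    if len(sequences) == 0:
        raise ValueError("no sequences")
    if len(sequences) == 1:
        return [sequences[0]]
    if len(sequences) == 2:
        aln = global_align(sequences[0], sequences[1],
                           gap_open=gap_open, gap_extend=gap_extend)
        return [aln.aligned_query, aln.aligned_target]
    from .phyloconcord import nj_join_order

    D = _kmer_cosine_distances(sequences)
    joins = nj_join_order(D)
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [s]) for i, s in enumerate(sequences)
    }
    for left, right, new in joins:
        ids_a, rows_a = profiles.pop(left)
        ids_b, rows_b = profiles.pop(right)
        merged = _merge_profiles(rows_a, rows_b, gap_open, gap_extend)
        profiles[new] = (ids_a + ids_b, merged)
    (ids, rows), = profiles.values()
    out = [""] * len(sequences)
    for idx, row in zip(ids, rows):
        out[idx] = row
    return out


def write_fasta(records: list[tuple[str, str]], path, width: int = 60) -> None:
    """Write (id, sequence) records as 60-column wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA as (full header, sequence) pairs."""
    from Bio import SeqIO

    return [(r.description, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
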