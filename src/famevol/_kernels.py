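"""Numba kernels for the permutation-null loops.

Empirical e-values at the cascade's thresholds require 1e3-1e5 shuffled-score
draws per evaluated hit; these loops are the only hot spots in the package and
are kept in a single module so the pure-Python modules stay readable.

The in-kernel RNG is xorshift64 with a Lemire-style bounded draw (the 2**-32
range bias is irrelevant for a permutation null); it exists so that a shuffle
costs ~1 ns/swap instead of the ~10 ns of np.random inside numba, and so the
null streams are deterministic for a given integer seed on every platform.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "sw_score",
    "local_null_exceedances",
    "window_scores",
    "scan_null_exceedances",
    "affine_dp_matrix",
]

_U64 = np.uint64


@njit(cache=True)
def _next_bounded(state, bound):  # pragma: no cover - trivial, exercised via callers
    """Advance xorshift64 ``state``; return (new_state, uniform int in [0, bound))."""
    state ^= state << _U64(13)
    state ^= state >> _U64(7)
    state ^= state << _U64(17)
    j = ((state >> _U64(32)) * _U64(bound)) >> _U64(32)
    return state, np.int64(j)


@njit(cache=True)
def _shuffle(x, state):
    """In-place Fisher-Yates; returns the advanced RNG state."""
    for i in range(x.shape[0] - 1, 0, -1):
        state, j = _next_bounded(state, i + 1)
        t = x[i]
        x[i] = x[j]
        x[j] = t
    return state


@njit(cache=True)
def sw_score(a, b, S, gap_open, gap_ext):
    """Smith-Waterman best local score, affine gaps costing open+ext*len.

    ``a``/``b`` are int codes indexing the integer substitution matrix ``S``.
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = np.int64(-(10 ** 9))
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, NEG, dtype=np.int64)
    best = np.int64(0)
    for i in range(1, n + 1):
        diag = np.int64(0)
        F = NEG
        prevH = np.int64(0)
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = E[j] - gap_ext
            h_open = H[j] - gap_open - gap_ext
            if h_open > e:
                e = h_open
            E[j] = e
            f = F - gap_ext
            p_open = prevH - gap_open - gap_ext
            if p_open > f:
                f = p_open
            F = f
            h = diag + S[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            prevH = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def local_null_exceedances(query, targets_flat, target_offsets, S, gap_open,
                           gap_ext, n_shuffles, seed, obs, k_stop):
    """Count shuffled-query best-local-scores >= obs against a database.

    ``targets_flat``/``target_offsets`` encode a ragged list of int-coded
    target sequences.  Per shuffle the best score over the whole database is
    one null draw.  Stops early once ``k_stop`` exceedances are seen (the
    caller knows when the e-value can no longer pass its threshold); returns
    (exceedances, shuffles_done).
    """
    qq = query.copy()
    state = _U64(seed) * _U64(6364136223846793005) + _U64(1442695040888963407)
    k = 0
    done = 0
    n_targets = target_offsets.shape[0] - 1
    for s in range(n_shuffles):
        state = _shuffle(qq, state)
        best = np.int64(-1)
        for t in range(n_targets):
            sc = sw_score(qq, targets_flat[target_offsets[t]:target_offsets[t + 1]],
                          S, gap_open, gap_ext)
            if sc > best:
                best = sc
        done += 1
        if best >= obs:
            k += 1
            if k >= k_stop:
                break
    return k, done


@njit(cache=True)
def window_scores(x, P):
    """Score of the ungapped PSSM window at every offset; P is (L, n_alpha) int."""
    L = P.shape[0]
    W = x.shape[0] - L + 1
    out = np.empty(W, dtype=np.int64)
    for o in range(W):
        acc = np.int64(0)
        for j in range(L):
            acc += P[j, x[o + j]]
        out[o] = acc
    return out


@njit(cache=True)
def scan_null_exceedances(x, P, n_shuffles, seed, obs_sorted, k_stop):
    """Permutation null for the PSSM window scan.

    One null draw per shuffle = the max window score of the shuffled sequence.
    ``obs_sorted`` holds the observed candidate-hit scores sorted ascending;
    exceedance counters are kept per candidate.  A suffix-max bound prunes the
    column loop (a window is abandoned once even consensus residues at every
    remaining column cannot reach the smallest observed score), and the whole
    loop stops early once the *best* candidate has ``k_stop`` exceedances.
    Returns (per-candidate exceedance counts, shuffles_done).
    """
    L = P.shape[0]
    n = x.shape[0]
    W = n - L + 1
    n_obs = obs_sorted.shape[0]
    maxcol = np.empty(L, dtype=np.int64)
    for j in range(L):
        m = P[j, 0]
        for r in range(1, P.shape[1]):
            if P[j, r] > m:
                m = P[j, r]
        maxcol[j] = m
    suf = np.zeros(L + 1, dtype=np.int64)
    for j in range(L - 1, -1, -1):
        suf[j] = suf[j + 1] + maxcol[j]
    lowest = obs_sorted[0]
    counts = np.zeros(n_obs, dtype=np.int64)
    xx = x.copy()
    state = _U64(seed) * _U64(6364136223846793005) + _U64(1442695040888963407)
    done = 0
    for s in range(n_shuffles):
        state = _shuffle(xx, state)
        best = np.int64(-(10 ** 18))
        for o in range(W):
            acc = np.int64(0)
            pruned = False
            for j in range(L):
                acc += P[j, xx[o + j]]
                if acc + suf[j + 1] < lowest:
                    pruned = True
                    break
            if not pruned and acc > best:
                best = acc
        done += 1
        if best >= lowest:
            for c in range(n_obs):
                if best >= obs_sorted[c]:
                    counts[c] += 1
            if counts[n_obs - 1] >= k_stop:
                break
    return counts, done


@njit(cache=True)
def affine_dp_matrix(S, gap_open, gap_ext):
    """Global affine-gap DP over a precomputed column-pair score matrix.

    ``S`` is the (n, m) float score of aligning row-item i with col-item j
    (used for profile-profile alignment, where items are MSA columns).  A gap
    of length L costs gap_open + gap_ext * L.  Returns the three state
    matrices (M = match, X = gap consuming rows, Y = gap consuming cols); the
    caller does the exact traceback by walking the states.
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # consume row item, gap in cols
    Y = np.full((n + 1, m + 1), NEG)  # consume col item, gap in rows
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_ext * i
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_ext * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            x1 = M[i - 1, j] - gap_open - gap_ext
            x2 = X[i - 1, j] - gap_ext
            x3 = Y[i - 1, j] - gap_open - gap_ext
            v = x1 if x1 > x2 else x2
            X[i, j] = v if v > x3 else x3
            y1 = M[i, j - 1] - gap_open - gap_ext
            y2 = Y[i, j - 1] - gap_ext
            y3 = X[i, j - 1] - gap_open - gap_ext
            v = y1 if y1 > y2 else y2
            Y[i, j] = v if v > y3 else y3
            best_prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
            M[i, j] = best_prev + S[i - 1, j - 1]
    return M, X, Y
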