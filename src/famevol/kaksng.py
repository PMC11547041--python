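"""Nei-Gojobori (NG86) Ka/Ks estimation with Jukes-Cantor correction.

For each codon, every single-nucleotide change is classified synonymous or
nonsynonymous under the standard genetic code; changes creating stop codons
are excluded.  Synonymous site counts are the per-position synonymous
fractions summed over the codon (N = 3 - S); differences between two codons
are averaged over all mutational pathways that avoid stop codons.  Proportions
pS = Sd/S and pN = Nd/N are corrected for multiple hits with the Jukes-Cantor
transform d = -(3/4) ln(1 - 4p/3), undefined (saturated) at p >= 3/4.
Pairs with Ks > 2 are conventionally discarded as saturated before selection
classification (Ka/Ks > 1 positive, < 1 purifying, = 1 neutral).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment", "ParalogPair", "backtranslate", "ng86_sites",
    "ng86_differences", "kaks_pair", "filter_and_classify", "jukes_cantor",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
SENSE_CODONS = tuple(sorted(_AA))


@dataclass
class CodonAlignment:
    id_a: str
    id_b: str
    codons_a: str  # gapped CDS, gaps in whole-codon triplets
    codons_b: str

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon alignment rows differ in length")
        if len(self.codons_a) % 3 != 0:
            raise ValueError("codon alignment length not divisible by 3")


@dataclass
class ParalogPair:
    gene_id_a: str
    gene_id_b: str
    ka: float | None
    ks: float | None
    ratio: float | None
    n_sites: float
    s_sites: float
    n_codons: int
    selection: str = "undefined"   # positive | negative | neutral | undefined
    discarded: bool = False
    reason: str = ""


def backtranslate(aligned_a: str, aligned_b: str, cds_a: str, cds_b: str,
                  id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Thread CDS onto a protein alignment: residue -> codon, gap -> ``---``."""
    rows = []
    for name, prot, cds in ((id_a, aligned_a, cds_a), (id_b, aligned_b, cds_b)):
        ungapped = prot.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{name}: CDS length {len(cds)} != 3 x protein length "
                f"{len(ungapped)}")
        for i in range(0, len(cds), 3):
            codon = cds[i:i + 3]
            if codon in STOP_CODONS:
                raise ValueError(f"{name}: internal stop codon at {i + 1}")
            if codon not in _AA:
                raise ValueError(f"{name}: invalid codon {codon!r} at {i + 1}")
        out = []
        pos = 0
        for ch in prot:
            if ch == "-":
                out.append("---")
            else:
                out.append(cds[pos:pos + 3])
                pos += 3
        rows.append("".join(out))
    return CodonAlignment(id_a=id_a, id_b=id_b, codons_a=rows[0],
                          codons_b=rows[1])


def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one sense codon.

    Per position, the fraction of non-stop single-nucleotide changes that are
    synonymous; S sums the three fractions and N = 3 - S.
    """
    if codon in STOP_CODONS or codon not in _AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if _AA[alt] == _AA[codon]:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def ng86_differences(codon_a: str, codon_b: str,
                     ) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are excluded.  Returns None when no legal pathway
    exists.
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or c not in _AA:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    legal = 0
    for order in permutations(diff_pos):
        cur = codon_a
        path_syn = 0
        path_nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _AA[nxt] == _AA[cur]:
                path_syn += 1
            else:
                path_nonsyn += 1
            cur = nxt
        if ok:
            legal += 1
            syn_total += path_syn
            nonsyn_total += path_nonsyn
    if legal == 0:
        return None
    return syn_total / legal, nonsyn_total / legal


def jukes_cantor(p: float) -> float | None:
    """JC multiple-hit correction; undefined (None) at p >= 3/4."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks_pair(alignment: CodonAlignment, min_codons: int = 30) -> ParalogPair:
    """NG86 Ka, Ks and their ratio for one codon alignment.

    Sites are averaged between the two sequences over the gap-free codon
    columns; differences are pathway-averaged per codon pair.  The ratio is
    undefined when Ks = 0 or either rate is saturated.
    """
    a, b = alignment.codons_a, alignment.codons_b
    S = N = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    flagged_paths = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        n_codons += 1
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        d = ng86_differences(ca, cb)
        if d is None:
            flagged_paths += 1
            continue
        Sd += d[0]
        Nd += d[1]
    if n_codons < min_codons:
        return ParalogPair(alignment.id_a, alignment.id_b, None, None, None,
                           N, S, n_codons, discarded=True,
                           reason=f"only {n_codons} comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(pS)
    ka = jukes_cantor(pN)
    pair = ParalogPair(alignment.id_a, alignment.id_b, ka, ks,
                       None, N, S, n_codons)
    if flagged_paths:
        pair.reason = f"{flagged_paths} codon pairs without stop-free pathway"
    if ka is None or ks is None:
        pair.discarded = True
        pair.reason = "saturated"
        return pair
    if ks > 0:
        pair.ratio = ka / ks
    return pair


def filter_and_classify(pairs: list[ParalogPair],
                        ks_max: float = 2.0) -> list[ParalogPair]:
    """Apply the Ks saturation filter and classify selection on the survivors.

    Pairs with Ks > ks_max are discarded (kept in the list, marked).  For the
    rest: ratio > 1 positive, < 1 negative, = 1 (within 1e-12) neutral;
    undefined ratios stay undefined.
    """
    out = []
    for p in pairs:
        if not p.discarded and p.ks is not None and p.ks > ks_max:
            p.discarded = True
            p.reason = f"Ks > {ks_max}"
        if not p.discarded and p.ratio is not None:
            if abs(p.ratio - 1.0) <= 1e-12:
                p.selection = "neutral"
            elif p.ratio > 1.0:
                p.selection = "positive"
            else:
                p.selection = "negative"
        out.append(p)
    return out
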