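"""Independent brute-force oracles used to cross-check the package.

These deliberately share no code with the implementation: the motif
oracle works from a residue -> chemistry-label map and Counter
arithmetic, and the Fisher oracle enumerates the hypergeometric
distribution with exact integer binomials (math.comb).
"""

from __future__ import annotations

import math
from collections import Counter

from cmakit.motifs import MotifClass

_LABEL = {}
for _aa in "ACDEFGHIKLMNPQRSTVWY":
    if _aa in "FILV":
        _LABEL[_aa] = "hydro"
    elif _aa in "KR":
        _LABEL[_aa] = "pos"
    elif _aa in "DE":
        _LABEL[_aa] = "neg"
    elif _aa in "STY":
        _LABEL[_aa] = "phospho"
    else:
        _LABEL[_aa] = "other"


def motif_oracle(pent: str) -> frozenset[MotifClass]:
    """Rule-table evaluation of one pentapeptide, written independently."""
    found = set()
    for anchor, body in ((pent[0], pent[1:]), (pent[4], pent[:4])):
        c = Counter(_LABEL[aa] for aa in body)
        core = (1 <= c["hydro"] <= 2) and (1 <= c["pos"] <= 2)
        canon_body = core and c["neg"] == 1 and c["hydro"] + c["pos"] + c["neg"] == 4
        if anchor == "Q":
            if canon_body:
                found.add(MotifClass.CANONICAL)
            if (
                core
                and c["neg"] == 0
                and c["phospho"] == 1
                and c["hydro"] + c["pos"] + c["phospho"] == 4
            ):
                found.add(MotifClass.PHOSPHO_GENERATED)
        elif anchor == "K":
            if canon_body:
                found.add(MotifClass.ACETYL_GENERATED)
    return frozenset(found)


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p by full hypergeometric enumeration.

    Sums the probabilities of every table with the observed margins
    whose probability does not exceed the observed table's (with a
    tiny relative guard for float ties).
    """
    n = a + b + c + d
    K = a + c
    m = a + b
    denom = math.comb(n, m)

    def pmf(x: int) -> float:
        return math.comb(K, x) * math.comb(n - K, m - x) / denom

    p_obs = pmf(a)
    lo, hi = max(0, m + K - n), min(m, K)
    total = sum(p for x in range(lo, hi + 1) if (p := pmf(x)) <= p_obs * (1 + 1e-12))
    return min(total, 1.0)


def canonical_tables(max_margin: int = 30) -> set[tuple[int, int, int, int]]:
    """One representative per symmetry orbit of all 2×2 tables whose
    row and column margins are all ≤ max_margin.

    Two-sided Fisher p is invariant under row swap, column swap and
    transposition, so checking one representative per orbit covers
    every table (the symmetries themselves are asserted separately).
    """
    reps: set[tuple[int, int, int, int]] = set()
    for r1 in range(max_margin + 1):
        for r2 in range(max_margin + 1):
            for a in range(r1 + 1):
                for c in range(r2 + 1):
                    b, d = r1 - a, r2 - c
                    if a + c > max_margin or b + d > max_margin:
                        continue
                    orbit = [
                        (a, b, c, d), (c, d, a, b), (b, a, d, c), (d, c, b, a),
                        (a, c, b, d), (b, d, a, c), (c, a, d, b), (d, b, c, a),
                    ]
                    reps.add(min(orbit))
    reps.discard((0, 0, 0, 0))
    return reps
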