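"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive and written from the definitions,
sharing no code with the package.
"""

from __future__ import annotations

import math
from itertools import product


# ---------------------------------------------------------------- trimming

def _edit_dp(a: str, b: str) -> list[list[int]]:
    """Full unit-cost edit-distance table D[i][j] = ed(a[:i], b[:j])."""
    la, lb = len(a), len(b)
    D = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        D[i][0] = i
    for j in range(lb + 1):
        D[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else 1
            D[i][j] = min(D[i - 1][j - 1] + cost, D[i - 1][j] + 1,
                          D[i][j - 1] + 1)
    return D


def oracle_trim(read: str, adapter: str, min_overlap: int,
                rate: float) -> tuple[int, int] | None:
    """Score every placement; return (start, errors) of the best, or None.

    Placements: full adapter starting at p with a free right end, or an
    adapter prefix of length >= min_overlap flush with the read's 3' end.
    Admissible when errors <= floor(rate * aligned adapter length).  Best =
    max (aligned length - errors), ties by fewer errors, then smaller p.
    """
    A = len(adapter)
    candidates = []  # (score, -errors, -p)
    for p in range(len(read)):
        suffix = read[p:]
        D = _edit_dp(adapter, suffix)
        e_full = min(D[A])
        if e_full <= math.floor(rate * A):
            candidates.append((A - e_full, -e_full, -p))
        for ell in range(min_overlap, A + 1):
            e = D[ell][len(suffix)]
            if e <= math.floor(rate * ell):
                candidates.append((ell - e, -e, -p))
    if not candidates:
        return None
    score, neg_e, neg_p = max(candidates)
    return -neg_p, -neg_e


# ---------------------------------------------------------------- MEMs

def oracle_find_mems(read: str, ref: str, min_len: int) -> list[tuple[int, int]]:
    """Enumerate every read interval and test the MEM definition directly."""
    read = read.upper().replace("U", "T")
    ref = ref.upper().replace("U", "T")
    n = len(read)
    out = []
    for p in range(n):
        for L in range(min_len, n - p + 1):
            if read[p:p + L] not in ref:
                continue
            left_ok = p == 0 or read[p - 1:p + L] not in ref
            right_ok = p + L == n or read[p:p + L + 1] not in ref
            if left_ok and right_ok:
                out.append((p, L))
    return sorted(out)


# ---------------------------------------------------------------- Fisher

def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Point-probability two-sided Fisher p by exact integer enumeration.

    All tables share the margins (a+b, c+d, a+c); the p-value sums the
    hypergeometric probabilities of tables no more probable than the
    observed one.  Weights are exact integers, so no tolerance is needed.
    """
    r1, r2, m = a + b, c + d, a + c

    def weight(k: int) -> int:
        if k < 0 or k > r1 or m - k < 0 or m - k > r2:
            return 0
        return math.comb(r1, k) * math.comb(r2, m - k)

    w_obs = weight(a)
    total = math.comb(r1 + r2, m)
    num = sum(w for k in range(m + 1) if (w := weight(k)) <= w_obs)
    return num / total


# ---------------------------------------------------------------- motifs

_ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "T", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "W": "AT", "S": "CG",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def oracle_motif_match(motif: str, seq: str) -> bool:
    """Expand the motif to all concrete words; substring-test each one."""
    seq = seq.upper().replace("U", "T")
    words = ["".join(w) for w in product(*(_ORACLE_IUPAC[c] for c in motif))]
    return any(w in seq for w in words)


TWOFOLD = "RYKMWS"
THREEFOLD = "BDHV"


def motif_space_size_closed_form(k: int, x: int, y: int, n: int) -> int:
    """Count of the k-x-y-n space by multinomial summation over class counts."""
    total = 0
    for i in range(min(x, k) + 1):
        for j in range(min(y, k - i) + 1):
            for m in range(min(n, k - i - j) + 1):
                plain = k - i - j - m
                ways = (math.factorial(k)
                        // (math.factorial(i) * math.factorial(j)
                            * math.factorial(m) * math.factorial(plain)))
                total += ways * (6 ** i) * (4 ** j) * (4 ** plain)
    return total
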