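"""Discriminative IUPAC motif discovery between an IP set and a background.

Motif spaces are parameterized as k-x-y-n: motifs of length k over the
15-letter IUPAC alphabet with at most x twofold-degenerate characters
({R,Y,K,M,W,S}), at most y threefold-degenerate characters ({B,D,H,V}) and at
most n Ns.  Each motif is scored on a 2x2 contingency table of per-sequence
containment (IP with/without vs background with/without) by a two-sided
Fisher exact test, Bonferroni-corrected by the size of the scanned space.

A complementary text-model score is provided: an order-(k-1) Markov
background model with add-one smoothing gives each sequence an exact
probability of containing the motif (dynamic program over positions and
model context), and the observed number of containing IP sequences is
referred to the upper tail of the resulting Poisson-binomial distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TWOFOLD = "RYKMWS"
THREEFOLD = "BDHV"
PLAIN = "ACGU"

#: Full 15-letter motif alphabet in lexicographic order (U is the RNA base;
#: matching treats U and T as the same symbol).
ALPHABET15 = tuple(sorted(PLAIN + TWOFOLD + THREEFOLD + "N"))

# IUPAC base sets over the DNA alphabet (internal canonical form)
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "K": frozenset("GT"),
    "M": frozenset("AC"), "W": frozenset("AT"), "S": frozenset("CG"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_CLASS = {c: "two" for c in TWOFOLD}
_CLASS.update({c: "three" for c in THREEFOLD})
_CLASS["N"] = "n"


def _canon(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MotifSpaceForm:
    """A k-x-y-n motif space: length and per-degeneracy-class caps."""

    k: int
    x: int  # max characters from {R,Y,K,M,W,S}
    y: int  # max characters from {B,D,H,V}
    n: int  # max Ns

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for v, name in ((self.x, "x"), (self.y, "y"), (self.n, "n")):
            if not (0 <= v <= self.k):
                raise ValueError(f"{name} must be in 0..k")

    @classmethod
    def parse(cls, text: str) -> "MotifSpaceForm":
        """Parse '3-2-2-0' style form strings."""
        parts = [int(t) for t in text.replace("–", "-").split("-")]
        if len(parts) != 4:
            raise ValueError(f"form must be k-x-y-n, got {text!r}")
        return cls(*parts)

    def __str__(self) -> str:
        return f"{self.k}-{self.x}-{self.y}-{self.n}"

    def admits(self, pattern: str) -> bool:
        if len(pattern) != self.k or any(c not in IUPAC_SETS or c == "T"
                                         for c in pattern):
            return False
        n2 = sum(c in TWOFOLD for c in pattern)
        n3 = sum(c in THREEFOLD for c in pattern)
        nn = pattern.count("N")
        return n2 <= self.x and n3 <= self.y and nn <= self.n


def enumerate_motif_space(form: MotifSpaceForm) -> Iterator[str]:
    """Yield every motif of the space exactly once, in lexicographic order."""

    def rec(prefix: list[str], pos: int, x: int, y: int, n: int) -> Iterator[str]:
        if pos == form.k:
            yield "".join(prefix)
            return
        for ch in ALPHABET15:
            cls = _CLASS.get(ch)
            if cls == "two":
                if x == 0:
                    continue
                nx, ny, nn = x - 1, y, n
            elif cls == "three":
                if y == 0:
                    continue
                nx, ny, nn = x, y - 1, n
            elif cls == "n":
                if n == 0:
                    continue
                nx, ny, nn = x, y, n - 1
            else:
                nx, ny, nn = x, y, n
            prefix.append(ch)
            yield from rec(prefix, pos + 1, nx, ny, nn)
            prefix.pop()

    yield from rec([], 0, form.x, form.y, form.n)


def motif_matches_sequence(motif: str, seq: str) -> bool:
    """Per-sequence containment: does any window of ``seq`` fit ``motif``?

    Each motif character's IUPAC base set must contain the sequence base at
    that offset; N matches any base.  U and T are interchangeable on both
    sides.  A motif longer than the sequence matches nothing.
    """
    sets = [IUPAC_SETS[c] for c in motif.upper()]
    s = _canon(seq)
    k = len(sets)
    if k > len(s):
        return False
    for i in range(len(s) - k + 1):
        if all(s[i + j] in sets[j] for j in range(k)):
            return True
    return False


def expand_motif(motif: str) -> list[str]:
    """All concrete DNA k-mers matched by the motif (lexicographic)."""
    sets = [sorted(IUPAC_SETS[c]) for c in motif.upper()]
    return ["".join(t) for t in itertools.product(*sets)]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of sequences with/without a motif in IP and background sets."""

    a: int  # IP containing
    b: int  # IP not containing
    c: int  # background containing
    d: int  # background not containing

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


def build_contingency(
    motif: str, ip_seqs: Sequence[str], bg_seqs: Sequence[str]
) -> ContingencyTable:
    a = sum(motif_matches_sequence(motif, s) for s in ip_seqs)
    c = sum(motif_matches_sequence(motif, s) for s in bg_seqs)
    return ContingencyTable(a=a, b=len(ip_seqs) - a, c=c, d=len(bg_seqs) - c)


def fisher_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (point-probability method).

    The p-value is the sum of hypergeometric probabilities, over all tables
    with the observed margins, that do not exceed the observed table's
    probability (within a small relative tolerance).
    """
    p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    ).pvalue
    return float(min(1.0, p))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: min(1, p * m) for m tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return min(1.0, p * m)


@dataclass(frozen=True)
class BackgroundModel:
    """Order-o Markov chain over ACGT estimated from background (o+1)-mers.

    ``initial[w]`` is the probability that a sequence starts with the o-mer w;
    ``transitions[ctx]`` is the conditional distribution of the next base
    given the previous o bases, in ACGT order.  Both use add-one smoothing.
    """

    order: int
    initial: dict[str, float]
    transitions: dict[str, np.ndarray]

    def next_prob(self, context: str, base: str) -> float:
        return float(self.transitions[context]["ACGT".index(base)])


def estimate_background_model(
    bg_seqs: Sequence[str], k: int, order: int | None = None
) -> BackgroundModel:
    """Estimate an order-(k-1) background text model from pooled k-mers.

    ``order`` may be lowered (down to 0); transition counts then pool
    (order+1)-mers.  Add-one smoothing keeps every conditional distribution
    proper even for unseen contexts.
    """
    if not bg_seqs:
        raise ValueError("background set is empty")
    o = k - 1 if order is None else order
    if o < 0:
        raise ValueError("model order must be >= 0")
    seqs = [_canon(s) for s in bg_seqs]
    trans_counts: dict[str, np.ndarray] = {}
    for ctx in ("".join(t) for t in itertools.product("ACGT", repeat=o)):
        trans_counts[ctx] = np.zeros(4)
    for s in seqs:
        for i in range(len(s) - o):
            ctx, nxt = s[i : i + o], s[i + o]
            if ctx in trans_counts and nxt in "ACGT":
                trans_counts[ctx]["ACGT".index(nxt)] += 1
    transitions = {
        ctx: (c + 1.0) / (c.sum() + 4.0) for ctx, c in trans_counts.items()
    }
    init_counts = {w: 0 for w in transitions}
    for s in seqs:
        for i in range(len(s) - o + 1):
            w = s[i : i + o]
            if w in init_counts:
                init_counts[w] += 1
    total = sum(init_counts.values())
    denom = total + len(init_counts)
    initial = {w: (c + 1.0) / denom for w, c in init_counts.items()}
    return BackgroundModel(order=o, initial=initial, transitions=transitions)


def occurrence_probability(
    motif: str, length: int, model: BackgroundModel
) -> float:
    """Exact P(a model-generated sequence of ``length`` contains ``motif``).

    Dynamic program over positions: states are the last
    ``max(order, k-1)`` generated bases restricted to occurrence-free paths;
    a path dies when the window it completes lies in the motif's concrete
    k-mer set.  Returns 1 - P(no occurrence).
    """
    k = len(motif)
    if length < k:
        return 0.0
    hits = frozenset(expand_motif(motif))
    o = model.order
    s = max(o, k - 1)

    # distribution of the next base given a generated prefix
    def next_dist(prefix: str) -> dict[str, float]:
        t = len(prefix)
        if t >= o:
            ctx = prefix[t - o :] if o > 0 else ""
            probs = model.transitions[ctx]
            return {b: float(probs[i]) for i, b in enumerate("ACGT")}
        # marginal/conditional of the smoothed initial o-mer distribution
        num = {b: 0.0 for b in "ACGT"}
        den = 0.0
        for w, p in model.initial.items():
            if w.startswith(prefix):
                num[w[t]] += p
                den += p
        return {b: (v / den if den > 0 else 0.25) for b, v in num.items()}

    # alive[state-string] = P(prefix ends with state, no occurrence yet)
    alive: dict[str, float] = {"": 1.0}
    for t in range(length):
        nxt: dict[str, float] = {}
        for state, prob in alive.items():
            for b, pb in next_dist(state).items():
                if pb == 0.0:
                    continue
                ext = state + b
                if t + 1 >= k and ext[-k:] in hits:
                    continue  # occurrence: path leaves the "alive" set
                nxt_state = ext[-s:] if s > 0 else ""
                nxt[nxt_state] = nxt.get(nxt_state, 0.0) + prob * pb
        alive = nxt
    p_none = sum(alive.values())
    return float(min(1.0, max(0.0, 1.0 - p_none)))


def _poisson_binomial_upper_tail(qs: Sequence[float], a: int) -> float:
    """P(X >= a) for X a sum of independent Bernoulli(q_i), by convolution."""
    pmf = np.array([1.0])
    for q in qs:
        pmf = np.convolve(pmf, [1.0 - q, q])
    tail = pmf[a:].sum() if a <= len(pmf) - 1 else 0.0
    return float(min(1.0, max(0.0, tail)))


def model_pvalue(
    motif: str, ip_seqs: Sequence[str], model: BackgroundModel
) -> float:
    """Background-model p-value for the observed per-sequence occurrence count.

    Each IP sequence i of length L_i contributes an exact occurrence
    probability q_i under the model; the observed number of containing IP
    sequences is referred to the Poisson-binomial upper tail P(X >= a).
    """
    a = sum(motif_matches_sequence(motif, s) for s in ip_seqs)
    if a == 0:
        return 1.0
    lengths = [len(s) for s in ip_seqs]
    q_by_len = {L: occurrence_probability(motif, L, model)
                for L in sorted(set(lengths))}
    # group identical lengths: the pmf of m iid Bernoulli(q) is binomial
    pmf = np.array([1.0])
    for L, q in q_by_len.items():
        m = lengths.count(L)
        pmf = np.convolve(pmf, stats.binom.pmf(np.arange(m + 1), m, q))
    tail = pmf[a:].sum()
    return float(min(1.0, max(0.0, tail)))


def _presence_bitsets(seqs: Sequence[str], k: int) -> dict[str, int]:
    """k-mer -> bitmask of sequences containing it (bit i = seqs[i])."""
    out: dict[str, int] = {}
    for i, s in enumerate(seqs):
        sc = _canon(s)
        bit = 1 << i
        for j in range(len(sc) - k + 1):
            w = sc[j : j + k]
            out[w] = out.get(w, 0) | bit
    return out


def rank_motifs(
    form: MotifSpaceForm,
    ip_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    model_p_top: int | None = 50,
    model_order: int | None = None,
) -> pd.DataFrame:
    """Score every motif in the space against IP vs background sequence sets.

    Returns a DataFrame (motif, a, b, c, d, fisher_p, bonferroni_p, model_p)
    sorted by ascending Fisher p, ties by ascending pattern.  The Bonferroni
    multiplier is the size of the scanned space.  The text-model p-value is
    computed for the ``model_p_top`` best motifs (all of them when None).

    Each motif's containment counts are obtained by uniting precomputed
    per-sequence k-mer presence sets over the motif's concrete expansions;
    Fisher p-values are cached on (a, c) since the margins are fixed.
    """
    if not ip_seqs:
        raise ValueError("IP sequence set is empty")
    if not bg_seqs:
        raise ValueError("background sequence set is empty")
    ip_bits = _presence_bitsets(ip_seqs, form.k)
    bg_bits = _presence_bitsets(bg_seqs, form.k)
    n_ip, n_bg = len(ip_seqs), len(bg_seqs)

    fisher_cache: dict[tuple[int, int], float] = {}

    rows = []
    space_size = 0
    for motif in enumerate_motif_space(form):
        space_size += 1
        a_mask = 0
        c_mask = 0
        for w in expand_motif(motif):
            a_mask |= ip_bits.get(w, 0)
            c_mask |= bg_bits.get(w, 0)
        a = a_mask.bit_count()
        c = c_mask.bit_count()
        key = (a, c)
        p = fisher_cache.get(key)
        if p is None:
            p = fisher_two_sided(
                ContingencyTable(a=a, b=n_ip - a, c=c, d=n_bg - c)
            )
            fisher_cache[key] = p
        rows.append((motif, a, n_ip - a, c, n_bg - c, p))
    df = pd.DataFrame(
        rows, columns=["motif", "a", "b", "c", "d", "fisher_p"]
    )
    df["bonferroni_p"] = np.minimum(1.0, df["fisher_p"] * space_size)
    df = df.sort_values(["fisher_p", "motif"], kind="mergesort").reset_index(
        drop=True
    )
    df["model_p"] = np.nan
    n_model = len(df) if model_p_top is None else min(model_p_top, len(df))
    if n_model > 0:
        model = estimate_background_model(bg_seqs, form.k, order=model_order)
        df.loc[: n_model - 1, "model_p"] = [
            model_pvalue(df.loc[i, "motif"], ip_seqs, model)
            for i in range(n_model)
        ]
    return df


def write_motif_report(
    df: pd.DataFrame, path, top: int | None = None
) -> None:
    """TSV motif report; ``top`` limits rows (supplementary top-50 style)."""
    out = df if top is None else df.head(top)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
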