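"""Read-to-reference assignment via maximal exact matches (MEMs).

A MEM of length L with a reference s starts at position p of a read r iff the
substring ``r[p:p+L]`` occurs somewhere in s, and this stops being true when
the match is extended by one character to the left of p or to the right of
p+L-1.  A read is assigned to a reference when its qualifying MEMs (length >=
``min_mem_len``) jointly cover at least ``min_coverage`` bp of the read; among
eligible references the one with the most covered basepairs wins, with rare
residual ties broken by lexicographically smallest name (and flagged).

Occurrence is *exists-in-reference*: one read interval is one MEM no matter
how many places it occurs in s.  Reads and references are compared in a
common DNA alphabet (U -> T), forward strand only: the library protocol is
stranded, and reverse-complement spike sequences are explicit catalog entries
rather than handled by rc-matching.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .refcat import ReferenceCatalog


@dataclass(frozen=True)
class MatchParams:
    min_mem_len: int = 7
    min_coverage: int = 17

    def __post_init__(self) -> None:
        if self.min_mem_len < 1:
            raise ValueError("min_mem_len must be >= 1")
        if self.min_coverage < self.min_mem_len:
            raise ValueError("min_coverage must be >= min_mem_len")


@dataclass(frozen=True)
class MEM:
    """Half-open read interval [start, start+length) of a maximal exact match."""

    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.length < 1:
            raise ValueError("invalid MEM interval")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class Assignment:
    read_id: str
    assigned_ref: str | None
    covered_bp: int
    tie_flag: bool = False


def _canon(seq: str) -> str:
    return seq.upper().replace("U", "T")


def find_mems(read: str, ref: str, min_len: int) -> list[MEM]:
    """All MEMs of ``read`` against ``ref`` with length >= ``min_len``.

    Uses the longest-match function ell(p) = max L such that read[p:p+L]
    occurs in ref.  The interval (p, ell(p)) is right-maximal by construction
    and left-maximal iff p == 0 or ell(p-1) <= ell(p) (the left extension has
    length ell(p)+1 and occurs iff ell(p-1) >= ell(p)+1).  ell decreases by at
    most 1 per step, so extension work is amortized linear in practice.
    """
    read = _canon(read)
    ref = _canon(ref)
    n = len(read)
    mems = []
    prev_ell = 0
    for p in range(n):
        ell = max(prev_ell - 1, 0)
        while p + ell < n and read[p : p + ell + 1] in ref:
            ell += 1
        if ell >= min_len and (p == 0 or prev_ell <= ell):
            mems.append(MEM(start=p, length=ell))
        prev_ell = ell
    return mems


def read_coverage(mems: Iterable[MEM]) -> int:
    """Number of read positions covered by the union of the MEM intervals."""
    ivals = sorted((m.start, m.end) for m in mems)
    covered = 0
    cur_start = cur_end = None
    for s, e in ivals:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


class CatalogIndex:
    """q-gram index over a catalog for candidate-reference lookup.

    Any MEM of length >= q shares its first q-gram with the reference, so the
    references reachable from a read's q-grams are exactly those that can hold
    a qualifying MEM; assignment against candidates equals assignment against
    the full catalog.
    """

    def __init__(self, catalog: ReferenceCatalog, q: int):
        self.catalog = catalog
        self.q = q
        self._dna = [e.dna for e in catalog]
        self._names = catalog.names()
        index: dict[str, set[int]] = defaultdict(set)
        for i, seq in enumerate(self._dna):
            for j in range(len(seq) - q + 1):
                index[seq[j : j + q]].add(i)
        self._index = dict(index)

    def candidates(self, read: str) -> list[int]:
        read = _canon(read)
        hits: set[int] = set()
        for j in range(len(read) - self.q + 1):
            hits.update(self._index.get(read[j : j + self.q], ()))
        return sorted(hits)


def assign_read(
    read: str,
    catalog: ReferenceCatalog,
    params: MatchParams = MatchParams(),
    read_id: str | None = None,
    index: CatalogIndex | None = None,
) -> Assignment:
    """Assign one candidate-class trimmed read to a catalog entry (or not).

    The result is invariant under catalog permutation: eligibility and
    coverage are per-entry, and ties go to the lexicographically smallest
    entry name.
    """
    if index is not None:
        cand = index.candidates(read)
        names = index._names
        seqs = index._dna
    else:
        cand = range(len(catalog))
        names = catalog.names()
        seqs = [e.dna for e in catalog]
    read_c = _canon(read)
    best_cov = 0
    best_names: list[str] = []
    for i in cand:
        cov = read_coverage(find_mems(read_c, seqs[i], params.min_mem_len))
        if cov < params.min_coverage:
            continue
        if cov > best_cov:
            best_cov = cov
            best_names = [names[i]]
        elif cov == best_cov:
            best_names.append(names[i])
    rid = read_id if read_id is not None else read
    if not best_names:
        return Assignment(read_id=rid, assigned_ref=None, covered_bp=0)
    return Assignment(
        read_id=rid,
        assigned_ref=min(best_names),
        covered_bp=best_cov,
        tie_flag=len(best_names) > 1,
    )


def count_reads(
    assignments: Iterable[Assignment],
    catalog: ReferenceCatalog,
    sample: str,
) -> pd.Series:
    """Tally assigned reads per reference for one sample.

    Unassigned reads are excluded; spike-assigned reads are tallied under
    their spike entry.  The returned Series is a CountMatrix column.
    """
    tally = Counter(
        a.assigned_ref for a in assignments if a.assigned_ref is not None
    )
    col = pd.Series(
        [tally.get(name, 0) for name in catalog.names()],
        index=catalog.names(),
        name=sample,
        dtype=int,
    )
    return col


def count_unique_reads(
    seq_counts: Mapping[str, int],
    catalog: ReferenceCatalog,
    params: MatchParams = MatchParams(),
    sample: str = "sample",
    index: CatalogIndex | None = None,
    cache: dict[str, Assignment] | None = None,
) -> tuple[pd.Series, list[Assignment]]:
    """Assign deduplicated read sequences and expand to a count column.

    ``seq_counts`` maps a trimmed candidate sequence to its read multiplicity
    (as produced by :func:`mirmeth.readprep.trim_fastq`).  ``cache`` may be
    shared across samples: assignment depends only on the sequence.
    """
    if index is None:
        index = CatalogIndex(catalog, params.min_mem_len)
    tally: Counter = Counter()
    log: list[Assignment] = []
    for seq, mult in seq_counts.items():
        if cache is not None and seq in cache:
            a = cache[seq]
        else:
            a = assign_read(seq, catalog, params, index=index)
            if cache is not None:
                cache[seq] = a
        log.append(a)
        if a.assigned_ref is not None:
            tally[a.assigned_ref] += mult
    col = pd.Series(
        [tally.get(name, 0) for name in catalog.names()],
        index=catalog.names(),
        name=sample,
        dtype=int,
    )
    return col, log


def count_matrix(columns: Sequence[pd.Series]) -> pd.DataFrame:
    """Stack per-sample columns into a references x samples count table."""
    return pd.concat(columns, axis=1)
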