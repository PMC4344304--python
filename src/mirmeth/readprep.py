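"""3' adapter removal and read-length classification for small-RNA reads.

Mature miRNAs (16-28 bp of interest) are shorter than the 50-bp reads, so a
typical read runs through the insert into the 3' sequencing adapter.  The
adapter is located by an error-tolerant scan and removed; reads are then
classified by trimmed length into ``too_short`` (< min_len, discarded),
``candidate`` (min_len..max_len, passed to matching) and ``too_long``.

Placement semantics (matching the behaviour of cutadapt-style 3' trimming):
a candidate placement at read position p is either

* the **full adapter** aligned starting at p with a free right end
  (unit-cost edit distance, budget ``floor(max_error_rate * |adapter|)``), or
* a **prefix** of the adapter of length ``l >= min_overlap`` aligned flush
  with the read's 3' end (budget ``floor(max_error_rate * l)``).

Among admissible placements the one maximizing the aligned adapter length
minus errors (the match count) wins; ties are broken by fewer errors, then by
leftmost start.  If none is admissible the read is returned untrimmed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from numba import njit

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

READ_CLASSES = ("too_short", "candidate", "too_long")

# base -> code; N (and anything else) -> 4, which matches no adapter base
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class TrimParams:
    """Adapter search and length-filter settings."""

    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 4
    max_error_rate: float = 0.20
    min_len: int = 16
    max_len: int = 28

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_error_rate < 1.0):
            raise ValueError("max_error_rate must be in [0, 1)")
        if not (1 <= self.min_overlap <= len(self.adapter)):
            raise ValueError("min_overlap must be in 1..len(adapter)")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if set(self.adapter.upper()) - set("ACGT"):
            raise ValueError("adapter must be plain DNA")


@dataclass(frozen=True)
class TrimResult:
    trimmed_seq: str
    adapter_found: bool
    adapter_start: int | None
    n_errors: int
    read_class: str


@njit(cache=True)
def _scan_adapter(read, adapter, min_overlap, rate):  # pragma: no cover - jit
    """Return (start, errors) of the best admissible placement, or (-1, -1).

    Dynamic program per start p: D[i][j] = edit distance between adapter[:i]
    and read[p:p+j].  A placement's score is its aligned adapter length minus
    its errors (a match count); the scan keeps the placement with the highest
    score, breaking ties by fewer errors, then by smaller p.  Row minima of
    the DP are non-decreasing in i, so a start is abandoned once the row
    minimum exceeds the largest budget.
    """
    L = read.shape[0]
    A = adapter.shape[0]
    bfull = int(rate * A)  # floored error budget for the full adapter
    width = A + bfull  # alignments consuming more read than this exceed bfull
    prev = np.empty(width + 1, dtype=np.int64)
    cur = np.empty(width + 1, dtype=np.int64)
    best_p = -1
    best_e = -1
    best_score = -1
    for p in range(L):
        m = L - p
        maxj = m if m < width else width
        flush_possible = m <= width
        for j in range(maxj + 1):
            prev[j] = j
        for i in range(1, A + 1):
            ai = adapter[i - 1]
            cur[0] = i
            rmin = i
            for j in range(1, maxj + 1):
                cost = 0 if read[p + j - 1] == ai else 1
                d = prev[j - 1] + cost
                if prev[j] + 1 < d:
                    d = prev[j] + 1
                if cur[j - 1] + 1 < d:
                    d = cur[j - 1] + 1
                cur[j] = d
                if d < rmin:
                    rmin = d
            if flush_possible and i >= min_overlap:
                # adapter prefix of length i against the whole read suffix
                e = cur[m]
                if e <= int(rate * i):
                    score = i - e
                    if score > best_score or (score == best_score and
                                              e < best_e):
                        best_score, best_e, best_p = score, e, p
            if i == A:
                # full adapter, free right end
                e = cur[0]
                for j in range(1, maxj + 1):
                    if cur[j] < e:
                        e = cur[j]
                if e <= bfull:
                    score = A - e
                    if score > best_score or (score == best_score and
                                              e < best_e):
                        best_score, best_e, best_p = score, e, p
            if rmin > bfull:
                break
            tmp = prev
            prev = cur
            cur = tmp
    return best_p, best_e


def classify_length(length: int, params: TrimParams) -> str:
    if length < params.min_len:
        return "too_short"
    if length <= params.max_len:
        return "candidate"
    return "too_long"


def classify_read(trim: TrimResult, params: TrimParams) -> str:
    """Length class of a trim result (recomputed from the trimmed sequence)."""
    return classify_length(len(trim.trimmed_seq), params)


def trim_adapter(read_seq: str, params: TrimParams = TrimParams()) -> TrimResult:
    """Locate and remove the 3' adapter from one read.

    Always returns a result; when no placement is admissible the read is
    returned untrimmed with ``adapter_found=False``.
    """
    if not read_seq:
        raise ValueError("empty read")
    read = _encode(read_seq)
    adapter = _encode(params.adapter)
    p, e = _scan_adapter(
        read, adapter, params.min_overlap, params.max_error_rate
    )
    if p < 0:
        trimmed = read_seq
        found = False
        start: int | None = None
        nerr = 0
    else:
        trimmed = read_seq[:p]
        found = True
        start = int(p)
        nerr = int(e)
    return TrimResult(
        trimmed_seq=trimmed,
        adapter_found=found,
        adapter_start=start,
        n_errors=nerr,
        read_class=classify_length(len(trimmed), params),
    )


@dataclass
class TrimReport:
    """Per-sample trimming tallies."""

    total: int = 0
    adapter_found: int = 0
    too_short: int = 0
    candidate: int = 0
    too_long: int = 0

    def to_row(self) -> dict[str, int]:
        return {
            "total": self.total,
            "adapter_found": self.adapter_found,
            "too_short": self.too_short,
            "candidate": self.candidate,
            "too_long": self.too_long,
        }


def trim_fastq(
    in_path: str | Path,
    out_path: str | Path | None,
    params: TrimParams = TrimParams(),
) -> tuple[TrimReport, Counter]:
    """Trim every read of a FASTQ file.

    Candidate-class reads (with their quality strings sliced to the trimmed
    length) are written to ``out_path`` when given; too-short and too-long
    reads are discarded from the output but tallied in the report.  Also
    returns a Counter of candidate trimmed sequences, the deduplicated input
    to read assignment.
    """
    report = TrimReport()
    counts: Counter = Counter()
    out = open(out_path, "w") if out_path is not None else None
    try:
        with open(in_path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                report.total += 1
                res = trim_adapter(seq.upper(), params)
                if res.adapter_found:
                    report.adapter_found += 1
                if res.read_class == "too_short":
                    report.too_short += 1
                elif res.read_class == "too_long":
                    report.too_long += 1
                else:
                    report.candidate += 1
                    counts[res.trimmed_seq] += 1
                    if out is not None:
                        n = len(res.trimmed_seq)
                        out.write(f"@{title}\n{res.trimmed_seq}\n+\n{qual[:n]}\n")
    finally:
        if out is not None:
            out.close()
    return report, counts
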