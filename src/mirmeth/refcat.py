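"""Mature-miRNA reference catalog: parsing, duplicate collapsing, spike-ins.

The reference set for read assignment is a mature-miRNA FASTA (miRBase
mature-sequence dialect) stored in the RNA alphabet {A,C,G,U}.  Entries with
exactly the same sequence are collapsed into one, and the knockdown siRNA /
scrambled-control sequences ("spikes") are appended so that their reads are
identified during matching and excluded from miRNA totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

#: Knockdown siRNA and scrambled-control sequences added to the reference set,
#: as printed in the experimental protocol (verbatim, mixed DNA/RNA letters in
#: the source; normalized to RNA here by ``add_spikes``).
SPIKE_SEQUENCES: dict[str, str] = {
    "SR312322A": "gcagcugaaauauccuaaacuaatt",
    "SR312322A_rc": "uuaguuuaggauauuucagcugc",
    "SR312322B": "agacagaacuuagagacaucccagt",
    "SR312322B_rc": "acugggaugucucuaaguucugucu",
    "SR312322C": "agcgugugacaaagccuaaccuact",
    "SR312322C_rc": "aguagguuaggcuuugucacacgcu",
    "Scrambled": "cguuaaucgcguauaauacgcguat",
    "Scrambled_rc": "auacgcguauuauacgcgauuaacg",
}


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; the message names the offending line."""


def _normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class ReferenceEntry:
    """One catalog entry (possibly the merge of several identical records)."""

    name: str
    sequence: str  # RNA alphabet, uppercase
    member_names: frozenset[str] = field(default=None)  # type: ignore[assignment]
    is_spike: bool = False

    def __post_init__(self) -> None:
        if self.member_names is None:
            object.__setattr__(self, "member_names", frozenset({self.name}))
        if not self.sequence:
            raise ValueError(f"entry {self.name!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"entry {self.name!r}: non-RNA characters {sorted(bad)}"
            )
        if self.name not in self.member_names:
            raise ValueError(f"entry {self.name!r}: name missing from member_names")

    @property
    def dna(self) -> str:
        """Sequence in the DNA alphabet (U->T), the alphabet reads live in."""
        return self.sequence.replace("U", "T")


@dataclass(frozen=True)
class ReferenceCatalog:
    """Ordered collection of reference entries with unique names."""

    entries: tuple[ReferenceEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate entry names in catalog")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ReferenceEntry]:
        return iter(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def get(self, name: str) -> ReferenceEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def non_spike_names(self) -> list[str]:
        return [e.name for e in self.entries if not e.is_spike]

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as TSV: name, sequence, member_names (comma-joined), is_spike."""
        with open(path, "w") as fh:
            fh.write("name\tsequence\tmember_names\tis_spike\n")
            for e in self.entries:
                members = ",".join(sorted(e.member_names))
                fh.write(f"{e.name}\t{e.sequence}\t{members}\t{int(e.is_spike)}\n")

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.name}\n{e.sequence}\n")


def _validate_fasta_layout(path: str | Path) -> None:
    """Light structural validation so errors can name a line number.

    Bio.SeqIO silently drops leading junk and accepts empty records; the file
    layout is checked here first.
    """
    seen_header = False
    seq_len = 0
    header_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if seen_header and seq_len == 0:
                    raise FastaParseError(
                        f"{path}: record starting at line {header_line} has an "
                        "empty sequence"
                    )
                seen_header = True
                seq_len = 0
                header_line = lineno
            else:
                if not seen_header:
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before any "
                        "'>' header"
                    )
                seq_len += len(line)
        if seen_header and seq_len == 0:
            raise FastaParseError(
                f"{path}: record starting at line {header_line} has an empty "
                "sequence"
            )


def parse_mature_fasta(path: str | Path) -> ReferenceCatalog:
    """Read a mature-miRNA FASTA into a catalog.

    Sequences are uppercased and T is normalized to U; wrapped records are
    supported; record order is preserved.  The entry name is the first word of
    the header (miRBase headers carry accession and species after it).
    """
    _validate_fasta_layout(path)
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entries.append(
            ReferenceEntry(name=rec.id, sequence=_normalize_rna(str(rec.seq)))
        )
    return ReferenceCatalog(entries=tuple(entries))


def collapse_identical(catalog: ReferenceCatalog) -> ReferenceCatalog:
    """Merge entries with exactly the same sequence into a single one.

    The surviving entry keeps the position of the first occurrence, its
    ``member_names`` is the union of the merged entries' members, and its name
    is the lexicographically smallest member name.  Idempotent.
    """
    by_seq: dict[str, list[ReferenceEntry]] = {}
    order: list[str] = []
    for e in catalog:
        if e.sequence not in by_seq:
            by_seq[e.sequence] = []
            order.append(e.sequence)
        by_seq[e.sequence].append(e)
    merged = []
    for seq in order:
        group = by_seq[seq]
        members = frozenset().union(*(e.member_names for e in group))
        merged.append(
            ReferenceEntry(
                name=min(members),
                sequence=seq,
                member_names=members,
                is_spike=any(e.is_spike for e in group),
            )
        )
    return ReferenceCatalog(entries=tuple(merged))


def add_spikes(
    catalog: ReferenceCatalog,
    spikes: Mapping[str, str] | None = None,
) -> ReferenceCatalog:
    """Append spike-in entries (``is_spike=True``) and re-collapse.

    ``spikes`` maps name -> sequence (any case, T or U); defaults to the eight
    protocol sequences in :data:`SPIKE_SEQUENCES`.  Spike names must be absent
    from the catalog.
    """
    if spikes is None:
        spikes = SPIKE_SEQUENCES
    existing = set()
    for e in catalog:
        existing.add(e.name)
        existing.update(e.member_names)
    clashes = sorted(existing & set(spikes))
    if clashes:
        raise ValueError(f"spike names already present in catalog: {clashes}")
    spike_entries = tuple(
        ReferenceEntry(name=name, sequence=_normalize_rna(seq), is_spike=True)
        for name, seq in spikes.items()
    )
    return collapse_identical(
        ReferenceCatalog(entries=catalog.entries + spike_entries)
    )


def build_catalog(
    fasta_path: str | Path,
    spikes: Mapping[str, str] | None = None,
    with_spikes: bool = True,
) -> ReferenceCatalog:
    """parse -> collapse -> add_spikes, the standard preparation chain."""
    cat = collapse_identical(parse_mature_fasta(fasta_path))
    if with_spikes:
        cat = add_spikes(cat, spikes)
    return cat
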