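"""Ground-truthed synthetic data with the structure the analysis assumes.

No raw sequencing data accompanies the study design this pipeline targets, so
the generator emulates it: a catalog of random 19-27 nt mature references, a
methylated subset carrying a planted methyltransferase-consensus motif, and
adapter-bearing 50-bp FASTQ reads per sample with substitution errors.  The
expression model is deliberately simple and fully parameterized:

* per-reference abundance ~ log-normal (median 100, sigma 1.5 on the log);
* knockdown multiplies methylated references by ``kd_down_fold``;
* anti-m6A IP multiplies methylated references by ``ip_enrichment_fold``;
* IgG control and scrambled samples see plain abundances;
* reads are multinomial draws of ``reads_per_sample`` over those weights,
  each emitted as reference DNA + substitution errors + adapter + random pad
  to 50 bp, with a small fraction of adapter-free random 50-mers.

Everything is driven by one seed; per-sample substreams are derived from it
deterministically, so identical configurations reproduce byte-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .readprep import DEFAULT_ADAPTER
from .refcat import ReferenceCatalog, ReferenceEntry

CONDITIONS = ("scr", "kd", "m6A", "IgG")

_BASES_RNA = np.array(list("ACGU"))
_BASES_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """All distributional knobs of the generator (one seed, no globals)."""

    seed: int
    n_refs: int = 300
    ref_len_range: tuple[int, int] = (19, 27)
    methylated_fraction: float = 0.25
    planted_motif: str = "GGACU"  # an RRACH instance
    motif_plant_rate: float = 0.6  # fraction of methylated refs carrying it
    ip_enrichment_fold: float = 8.0
    kd_down_fold: float = 0.4
    abundance_mean_log: float = math.log(100.0)
    abundance_sd_log: float = 1.5
    reads_per_sample: int = 50_000
    error_rate: float = 0.005
    no_adapter_rate: float = 0.02
    n_replicates: int = 3
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50

    def __post_init__(self) -> None:
        for rate, name in (
            (self.methylated_fraction, "methylated_fraction"),
            (self.motif_plant_rate, "motif_plant_rate"),
            (self.error_rate, "error_rate"),
            (self.no_adapter_rate, "no_adapter_rate"),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ip_enrichment_fold <= 0 or self.kd_down_fold <= 0:
            raise ValueError("fold parameters must be positive")
        lo, hi = self.ref_len_range
        if not (len(self.planted_motif) <= lo <= hi):
            raise ValueError("ref_len_range must be increasing and hold the motif")

    def rng(self, *subkeys: int) -> np.random.Generator:
        """Deterministic substream keyed on (seed, *subkeys)."""
        return np.random.default_rng([self.seed, *subkeys])


@dataclass
class SyntheticTruth:
    """Planted ground truth: abundances, methylated flags, motif positions."""

    table: pd.DataFrame  # index: ref name; abundance, methylated, motif_pos

    @property
    def methylated_names(self) -> list[str]:
        return list(self.table.index[self.table["methylated"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="name")


def default_design(n_replicates: int = 3) -> pd.DataFrame:
    """Sample sheet: 3 kd/scr pairs and 3 m6A/IgG pairs by default."""
    rows = [
        {"sample": f"{cond}_{rep}", "condition": cond, "replicate": rep}
        for cond in CONDITIONS
        for rep in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES_RNA, size=length))


def generate_catalog(
    config: SimulationConfig,
) -> tuple[ReferenceCatalog, SyntheticTruth]:
    """Random distinct references with a planted methylated subset.

    The planted motif is inserted at a random valid offset into
    ``motif_plant_rate`` of the methylated references (overwriting the bases
    there); other references may still contain motif-like windows by chance,
    as real backgrounds do.
    """
    rng = config.rng(0)
    lo, hi = config.ref_len_range
    seqs: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(seqs) < config.n_refs:
        attempts += 1
        if attempts > 100 * config.n_refs:
            raise RuntimeError("could not generate distinct sequences")
        s = _random_rna(rng, int(rng.integers(lo, hi + 1)))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    n_meth = round(config.methylated_fraction * config.n_refs)
    meth_idx = set(rng.choice(config.n_refs, size=n_meth, replace=False).tolist())
    planted = set(
        rng.choice(sorted(meth_idx),
                   size=round(config.motif_plant_rate * n_meth),
                   replace=False).tolist()
    ) if n_meth else set()
    motif = config.planted_motif.upper()
    names = [f"syn-mir-{i:04d}" for i in range(config.n_refs)]
    rows = []
    entries = []
    final_seen: set[str] = set()
    for i, (name, s) in enumerate(zip(names, seqs)):
        pos = -1
        if i in planted:
            pos = int(rng.integers(0, len(s) - len(motif) + 1))
            s = s[:pos] + motif + s[pos + len(motif):]
        if s in final_seen:
            raise RuntimeError("sequence collision after motif planting")
        final_seen.add(s)
        entries.append(ReferenceEntry(name=name, sequence=s))
        rows.append({"name": name, "methylated": i in meth_idx, "motif_pos": pos})
    abund = rng.lognormal(
        mean=config.abundance_mean_log,
        sigma=config.abundance_sd_log,
        size=config.n_refs,
    )
    truth = pd.DataFrame(rows).set_index("name")
    truth.insert(0, "abundance", abund)
    truth.insert(1, "length", [len(e.sequence) for e in entries])
    return ReferenceCatalog(entries=tuple(entries)), SyntheticTruth(table=truth)


def simulate_counts(
    truth: SyntheticTruth,
    design: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Expected (unnormalized) sampling weights per reference and sample."""
    required = {"sample", "condition"}
    if not required <= set(design.columns):
        raise ValueError("design needs 'sample' and 'condition' columns")
    unknown = set(design["condition"]) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions in design: {sorted(unknown)}")
    base = truth.table["abundance"].to_numpy()
    meth = truth.table["methylated"].to_numpy()
    cols = {}
    for _, row in design.iterrows():
        w = base.copy()
        if row["condition"] == "kd":
            w = np.where(meth, w * config.kd_down_fold, w)
        elif row["condition"] == "m6A":
            w = np.where(meth, w * config.ip_enrichment_fold, w)
        cols[row["sample"]] = w
    return pd.DataFrame(cols, index=truth.table.index)


def simulate_reads(
    weights: pd.Series,
    catalog: ReferenceCatalog,
    config: SimulationConfig,
    out_path: str | Path,
    sample_key: int,
) -> int:
    """Write one sample's FASTQ of ``reads_per_sample`` 50-bp reads.

    ``sample_key`` selects the deterministic substream for this sample.
    Returns the number of reads written.
    """
    w = weights.to_numpy(dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    rng = config.rng(1, sample_key)
    total = config.reads_per_sample
    n_junk = rng.binomial(total, config.no_adapter_rate)
    counts = rng.multinomial(total - n_junk, w / w.sum())
    ref_dna = [e.dna for e in catalog]
    L = config.read_length
    adapter = config.adapter
    reads: list[str] = []
    for i, c in enumerate(counts):
        if c == 0:
            continue
        seq = ref_dna[i]
        m = len(seq)
        base_codes = np.array([_BASES_DNA.tolist().index(b) for b in seq])
        err = rng.random((c, m)) < config.error_rate
        shifts = rng.integers(1, 4, size=(c, m))
        codes = np.where(err, (base_codes[None, :] + shifts) % 4,
                         base_codes[None, :])
        pad_len = L - m - len(adapter)
        pads = rng.integers(0, 4, size=(c, pad_len)) if pad_len > 0 else None
        for j in range(c):
            insert = "".join(_BASES_DNA[codes[j]])
            pad = "".join(_BASES_DNA[pads[j]]) if pads is not None else ""
            reads.append((insert + adapter + pad)[:L])
    for _ in range(n_junk):
        reads.append("".join(_BASES_DNA[rng.integers(0, 4, size=L)]))
    order = rng.permutation(len(reads))
    qual = "I" * L
    name = weights.name or "sample"
    with open(out_path, "w") as fh:
        for serial, idx in enumerate(order):
            fh.write(f"@{name}:{serial}\n{reads[idx]}\n+\n{qual}\n")
    return len(reads)


def simulate_experiment(
    config: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Full simulated experiment on disk: catalog, truth, design, FASTQs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog, truth = generate_catalog(config)
    design = default_design(config.n_replicates)
    weights = simulate_counts(truth, design, config)
    paths: dict[str, Path] = {}
    catalog.to_fasta(outdir / "catalog.fasta")
    truth.to_tsv(outdir / "truth.tsv")
    design.to_csv(outdir / "samplesheet.tsv", sep="\t", index=False)
    paths["catalog"] = outdir / "catalog.fasta"
    paths["truth"] = outdir / "truth.tsv"
    paths["samplesheet"] = outdir / "samplesheet.tsv"
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    for key, sample in enumerate(design["sample"]):
        fq = reads_dir / f"{sample}.fastq"
        simulate_reads(weights[sample], catalog, config, fq, sample_key=key)
        paths[f"fastq:{sample}"] = fq
    return paths


def simulate_motif_sets(
    n_ip: int,
    n_bg: int,
    length: int,
    motif: str,
    ip_rate: float,
    bg_rate: float,
    seed: int,
) -> tuple[list[str], list[str]]:
    """Random RNA sequence sets with a motif instance planted at given rates.

    Used to exercise motif discovery in isolation: the concrete ``motif``
    string is written over a random offset in ``ip_rate`` of the IP sequences
    and ``bg_rate`` of the background sequences (chance occurrences come on
    top, as in real data).
    """
    rng = np.random.default_rng([seed, 2])
    motif = motif.upper()

    def make(n: int, rate: float) -> list[str]:
        seqs = []
        plant = rng.random(n) < rate
        for i in range(n):
            s = _random_rna(rng, length)
            if plant[i]:
                pos = int(rng.integers(0, length - len(motif) + 1))
                s = s[:pos] + motif + s[pos + len(motif):]
            seqs.append(s)
        return seqs

    return make(n_ip, ip_rate), make(n_bg, bg_rate)
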