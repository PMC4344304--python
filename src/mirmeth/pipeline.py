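"""Stage functions behind the CLI and the analysis drivers.

Each stage is a pure function of its declared inputs and parameters: it
writes its artifacts plus a JSON manifest (parameters, input checksums,
package versions) into the output directory, and returns the main in-memory
result so tests and scripts can chain stages without re-reading files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .memmatch import CatalogIndex, MatchParams, count_matrix, count_unique_reads
from .motifdisc import MotifSpaceForm, rank_motifs, write_motif_report
from .quant import (DiffParams, RipParams, call_differential, call_methylated,
                    filter_expressed, log2_fold_changes, normalize_rpm)
from .readprep import TrimParams, trim_fastq
from .refcat import build_catalog
from .stats import pearson_r, shapiro_wilk
from .synthetic import SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    stage: str,
    params: Mapping,
    inputs: Mapping[str, str | Path],
) -> Path:
    """Machine-readable run manifest accompanying every stage."""
    import numpy
    import scipy

    manifest = {
        "stage": stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": json.loads(json.dumps(params, default=str)),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in inputs.items()
        },
        "versions": {
            "mirmeth": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path = Path(outdir) / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def _require(path: str | Path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"missing {what}: {p}")
    return p


def read_samplesheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(_require(path, "sample sheet"), sep="\t")
    need = {"sample", "condition", "replicate"}
    if not need <= set(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(need)}")
    return sheet


def condition_samples(sheet: pd.DataFrame, condition: str) -> list[str]:
    sub = sheet[sheet["condition"] == condition].sort_values("replicate")
    return list(sub["sample"])


def replicate_pairs(
    sheet: pd.DataFrame, treated: str, control: str
) -> list[tuple[str, str]]:
    """Pair treated/control samples of matching replicate index."""
    t = sheet[sheet["condition"] == treated].set_index("replicate")["sample"]
    c = sheet[sheet["condition"] == control].set_index("replicate")["sample"]
    common = sorted(set(t.index) & set(c.index))
    if not common:
        raise ValueError(f"no paired replicates for {treated} vs {control}")
    return [(t[r], c[r]) for r in common]


def run_simulate(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    t0 = time.time()
    paths = simulate_experiment(config, outdir)
    write_manifest(outdir, "simulate", asdict(config), {})
    logger.info("simulate: %d samples in %.1fs",
                sum(k.startswith("fastq:") for k in paths), time.time() - t0)
    return paths


def run_trim(
    samplesheet: str | Path,
    reads_dir: str | Path,
    outdir: str | Path,
    params: TrimParams = TrimParams(),
) -> pd.DataFrame:
    """Trim every sample's FASTQ; write trimmed FASTQs and the report TSV."""
    sheet = read_samplesheet(samplesheet)
    outdir = Path(outdir)
    (outdir / "trimmed").mkdir(parents=True, exist_ok=True)
    rows = []
    inputs = {}
    for sample in sheet["sample"]:
        fq = _require(Path(reads_dir) / f"{sample}.fastq", f"FASTQ for {sample}")
        inputs[sample] = fq
        report, _ = trim_fastq(fq, outdir / "trimmed" / f"{sample}.fastq", params)
        rows.append({"sample": sample, **report.to_row()})
        logger.info("trim %s: %d reads, %d candidates",
                    sample, report.total, report.candidate)
    table = pd.DataFrame(rows).set_index("sample")
    table.to_csv(outdir / "trim_report.tsv", sep="\t")
    write_manifest(outdir, "trim", asdict(params), inputs)
    return table


def run_count(
    samplesheet: str | Path,
    trimmed_dir: str | Path,
    catalog_fasta: str | Path,
    outdir: str | Path,
    match_params: MatchParams = MatchParams(),
    trim_params: TrimParams = TrimParams(),
) -> pd.DataFrame:
    """Assign trimmed reads per sample and write the count matrix TSV.

    Trimmed FASTQs are deduplicated to unique sequences before assignment;
    the assignment cache is shared across samples (assignment is a function
    of the sequence alone).
    """
    from collections import Counter

    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    sheet = read_samplesheet(samplesheet)
    catalog = build_catalog(_require(catalog_fasta, "reference catalog"))
    index = CatalogIndex(catalog, match_params.min_mem_len)
    cache: dict = {}
    cols = []
    inputs = {"catalog": Path(catalog_fasta)}
    for sample in sheet["sample"]:
        fq = _require(Path(trimmed_dir) / f"{sample}.fastq",
                      f"trimmed FASTQ for {sample}")
        inputs[sample] = fq
        counter: Counter = Counter()
        with open(fq) as fh:
            for _title, seq, _q in FastqGeneralIterator(fh):
                counter[seq.upper()] += 1
        col, _log = count_unique_reads(
            counter, catalog, match_params, sample=sample, index=index,
            cache=cache,
        )
        logger.info("count %s: %d assigned of %d candidate reads",
                    sample, int(col.sum()), sum(counter.values()))
        cols.append(col)
    counts = count_matrix(cols)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="reference")
    catalog.to_tsv(outdir / "catalog.tsv")
    write_manifest(outdir, "count", asdict(match_params), inputs)
    return counts


def _load_counts(outdir: str | Path) -> tuple[pd.DataFrame, list[str]]:
    counts = pd.read_csv(_require(Path(outdir) / "counts.tsv", "count matrix"),
                         sep="\t", index_col="reference")
    cat = pd.read_csv(_require(Path(outdir) / "catalog.tsv", "catalog table"),
                      sep="\t")
    spikes = list(cat.loc[cat["is_spike"] == 1, "name"])
    return counts, spikes


def run_quantify(
    counts_dir: str | Path,
    samplesheet: str | Path,
    outdir: str | Path,
    min_rpm: float = 15.0,
) -> pd.DataFrame:
    """RPM-normalize the count matrix and write the expressed list."""
    counts, spikes = _load_counts(counts_dir)
    sheet = read_samplesheet(samplesheet)
    rpm = normalize_rpm(counts, spikes)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rpm.to_csv(outdir / "rpm.tsv", sep="\t", index_label="reference")
    scr = condition_samples(sheet, "scr")
    mirna_rpm = rpm.drop(index=[s for s in spikes if s in rpm.index])
    expressed = filter_expressed(mirna_rpm, scr, min_rpm)
    pd.Series(expressed, name="reference").to_csv(
        outdir / "expressed.tsv", sep="\t", index=False
    )
    write_manifest(outdir, "quantify", {"min_rpm": min_rpm},
                   {"counts": Path(counts_dir) / "counts.tsv"})
    return rpm


def run_diff(
    quant_dir: str | Path,
    samplesheet: str | Path,
    outdir: str | Path,
    params: DiffParams = DiffParams(),
) -> pd.DataFrame:
    """Knockdown-vs-scrambled differential table (S2 style)."""
    rpm = pd.read_csv(_require(Path(quant_dir) / "rpm.tsv", "RPM matrix"),
                      sep="\t", index_col="reference")
    sheet = read_samplesheet(samplesheet)
    pairs = replicate_pairs(sheet, "kd", "scr")
    diff = call_differential(rpm, pairs, params)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    diff.to_csv(outdir / "differential.tsv", sep="\t", index_label="reference")
    write_manifest(outdir, "diff", asdict(params),
                   {"rpm": Path(quant_dir) / "rpm.tsv"})
    return diff


def run_rip(
    quant_dir: str | Path,
    samplesheet: str | Path,
    outdir: str | Path,
    params: RipParams = RipParams(),
) -> pd.DataFrame:
    """m6A-IP vs IgG enrichment table (Table-1 / S3 style)."""
    rpm = pd.read_csv(_require(Path(quant_dir) / "rpm.tsv", "RPM matrix"),
                      sep="\t", index_col="reference")
    sheet = read_samplesheet(samplesheet)
    ip = rpm[condition_samples(sheet, "m6A")]
    ctrl = rpm[condition_samples(sheet, "IgG")]
    enr = call_methylated(ip, ctrl, params)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index_label="reference")
    write_manifest(outdir, "rip", asdict(params),
                   {"rpm": Path(quant_dir) / "rpm.tsv"})
    return enr


def run_motifs(
    ip_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    forms: Sequence[str | MotifSpaceForm],
    outdir: str | Path,
    model_p_top: int | None = 50,
) -> dict[str, pd.DataFrame]:
    """Scan one or more motif spaces; write full and top-50 reports per form."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = {}
    for form in forms:
        f = form if isinstance(form, MotifSpaceForm) else MotifSpaceForm.parse(form)
        df = rank_motifs(f, list(ip_seqs), list(bg_seqs), model_p_top=model_p_top)
        write_motif_report(df, outdir / f"motifs_{f}.tsv")
        write_motif_report(df, outdir / f"motifs_{f}_top50.tsv", top=50)
        logger.info("motifs %s: %d motifs, best %s (fisher_p=%.3g)",
                    f, len(df), df.iloc[0]["motif"], df.iloc[0]["fisher_p"])
        results[str(f)] = df
    write_manifest(outdir, "motifs",
                   {"forms": [str(f) for f in forms],
                    "n_ip": len(ip_seqs), "n_bg": len(bg_seqs),
                    "model_p_top": model_p_top}, {})
    return results


def motif_input_sets(
    counts_dir: str | Path, rip_dir: str | Path
) -> tuple[list[str], list[str]]:
    """IP/background sequence sets from the methylation calls.

    IP = called-methylated references; background = all other non-spike
    references of the catalog.
    """
    cat = pd.read_csv(_require(Path(counts_dir) / "catalog.tsv", "catalog table"),
                      sep="\t")
    enr = pd.read_csv(
        _require(Path(rip_dir) / "enrichment.tsv", "enrichment table"),
        sep="\t", index_col="reference",
    )
    meth = set(enr.index[enr["methylated"]])
    mirna = cat[cat["is_spike"] == 0]
    ip = [r.sequence for r in mirna.itertuples() if r.name in meth]
    bg = [r.sequence for r in mirna.itertuples() if r.name not in meth]
    return ip, bg


def run_correlate(
    rip_dir: str | Path,
    diff_dir: str | Path,
    outdir: str | Path,
    plot: bool = False,
) -> dict:
    """Scatter table, Pearson correlation with regression line, normality test."""
    enr = pd.read_csv(_require(Path(rip_dir) / "enrichment.tsv",
                               "enrichment table"),
                      sep="\t", index_col="reference")
    diff = pd.read_csv(_require(Path(diff_dir) / "differential.tsv",
                                "differential table"),
                       sep="\t", index_col="reference")
    meth = enr[enr["methylated"]]
    scatter = log2_fold_changes(meth, diff)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scatter.to_csv(outdir / "scatter.tsv", sep="\t", index_label="reference")
    result: dict = {"n": int(len(scatter))}
    if len(scatter) >= 3:
        corr = pearson_r(scatter["log2_enrichment"], scatter["log2_kd_fc"])
        sw = shapiro_wilk(scatter["log2_kd_fc"])
        down = float((scatter["log2_kd_fc"] < 0).mean())
        result.update(
            r=corr.r, slope=corr.slope, intercept=corr.intercept,
            shapiro_W=sw.W, shapiro_p=sw.pvalue, fraction_down=down,
        )
        if plot:
            _plot_scatter(scatter, corr, outdir / "scatter.png")
    with open(outdir / "correlation.json", "w") as fh:
        json.dump(result, fh, indent=2)
    write_manifest(outdir, "correlate", {},
                   {"enrichment": Path(rip_dir) / "enrichment.tsv",
                    "differential": Path(diff_dir) / "differential.tsv"})
    return result


def _plot_scatter(scatter: pd.DataFrame, corr, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    x = scatter["log2_enrichment"]
    ax.scatter(x, scatter["log2_kd_fc"], s=12, alpha=0.6)
    xs = pd.Series([x.min(), x.max()])
    ax.plot(xs, corr.slope * xs + corr.intercept, "r:", lw=1.5)
    ax.set_xlabel("log2 fold enrichment (m6A-IP / IgG)")
    ax.set_ylabel("log2 fold change after knockdown")
    ax.set_title(f"r = {corr.r:.3f} (n = {corr.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_all(
    config: SimulationConfig,
    outdir: str | Path,
    forms: Sequence[str] = ("3-2-2-0",),
    trim_params: TrimParams = TrimParams(),
    match_params: MatchParams = MatchParams(),
    diff_params: DiffParams = DiffParams(),
    rip_params: RipParams = RipParams(),
    plot: bool = False,
) -> dict:
    """Simulate, then run every analysis stage into one output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_simulate(config, outdir / "sim")
    sheet = outdir / "sim" / "samplesheet.tsv"
    run_trim(sheet, outdir / "sim" / "reads", outdir, trim_params)
    counts = run_count(sheet, outdir / "trimmed", outdir / "sim" / "catalog.fasta",
                       outdir, match_params, trim_params)
    run_quantify(outdir, sheet, outdir, min_rpm=diff_params.min_rpm)
    diff = run_diff(outdir, sheet, outdir, diff_params)
    enr = run_rip(outdir, sheet, outdir, rip_params)
    ip, bg = motif_input_sets(outdir, outdir)
    motifs = run_motifs(ip, bg, forms, outdir) if ip else {}
    corr = run_correlate(outdir, outdir, outdir, plot=plot)
    return {
        "counts": counts, "differential": diff, "enrichment": enr,
        "motifs": motifs, "correlation": corr, "outdir": outdir,
    }
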