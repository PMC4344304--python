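# mirmeth

Analysis pipeline for studying N6-adenosine methylation (m6A) in mature
microRNAs from small-RNA sequencing: quantification of miRNAs in
knockdown/control and anti-m6A-IP/IgG-IP experiments, threshold-based calling
of deregulated and methylated miRNAs, and discovery of IUPAC consensus motifs
that discriminate immunoprecipitated from remaining miRNAs.

It is written for bioinformaticians re-running or stress-testing this style
of RIP-seq analysis. Because no raw sequencing data is publicly available
for the original experiment, the package ships a first-class synthetic-data
generator with planted ground truth (expression levels, a methylated subset,
a planted methyltransferase-consensus motif), against which the whole
pipeline's operating characteristics are measured.

## Method

**Read preparation.** Mature miRNAs (16–28 bp of interest) are shorter than
the 50-bp reads, so each read runs through the insert into the 3′ adapter
(5′-TGGAATTCTCGGGTGCCAAGG-3′). The adapter is located by an error-tolerant
scan (unit-cost edit distance, error budget ⌊0.2 · aligned adapter length⌋,
minimum 4 bp overlap at the 3′ end) and removed; trimmed reads of 16–28 bp
are candidate miRNA reads.

**Assignment by maximal exact matches (MEMs).** A MEM of length *L* with
reference *s* starts at position *p* of read *r* iff *r*[*p*:*p*+*L*] occurs
in *s* and neither one-character extension still occurs. A read is assigned
to the reference whose MEMs of length ≥ 7 cover the most read positions,
requiring ≥ 17 covered bp; the reference catalog is duplicate-collapsed and
augmented with the knockdown siRNA/scrambled spike sequences so their reads
are identified and excluded from miRNA totals.

**Quantification and calls.** Counts are normalized to reads per million
mapped miRNA reads (RPM). A miRNA is *expressed* at ≥ 15 RPM in all control
samples; *down* after knockdown when expressed in all controls and the mean
per-pair fold change is < 0.5 (up: > 2, with a secondary 1.5-fold
threshold); *methylated* when ≥ 100 RPM in all anti-m6A IP replicates with
mean (IP+1)/(IgG+1) enrichment ≥ 2.

**Motif discovery.** All IUPAC consensus motifs of form *k-x-y-n* (length
*k*, ≤ *x* characters from {R,Y,K,M,W,S}, ≤ *y* from {B,D,H,V}, ≤ *n* Ns)
are enumerated — 2464, 37248 and 571904 motifs for the forms 3-2-2-0,
4-2-2-1 and 5-3-2-1 — and each motif's per-sequence containment counts in
the IP and background sets form a 2×2 table tested with the two-sided Fisher
exact test, Bonferroni-corrected by the space size. A complementary
text-model score refers the observed count to the Poisson-binomial tail of
exact per-sequence occurrence probabilities under an order-(k−1) Markov
background model.

## Worked example

The numbered scripts under `analysis/` replay the full study design on
synthetic data (12 samples × 50,000 reads, seed 7); intermediates stage
under `scratch/analysis/` and tables land in `results/analysis/`:

```sh
python analysis/01_simulate.py
python analysis/02_trim.py
python analysis/03_count.py
python analysis/04_quantify.py
python analysis/05_motifs.py
python analysis/06_correlate.py
```

`04_quantify.py` prints

```
expressed (>=15 RPM in all scr): 293
down at 2-fold: 56; up at 2-fold: 7
methylated calls: 71 (sensitivity 0.947, FDR 0.000)
```

i.e. of 300 simulated references (75 truly methylated), 71 are called
methylated — 94.7% of the planted set with no false calls. The knockdown
responses follow: the 56 down-calls are dominated by methylated references
(the simulator reduces them to 0.4×). `05_motifs.py` then recovers the
planted site from sequence alone:

```
form 3-2-2-0: top motif GAC (a=49/71, fisher_p=4.11e-10, bonferroni_p=1.01e-06) matches the planted site
form 4-2-2-1: top motif GACU (a=45/71, fisher_p=2.54e-20, bonferroni_p=9.45e-16) matches the planted site
```

— the best-ranked motifs are the core of the planted GGACU instance, still
significant after Bonferroni correction over the full motif space. Finally
`06_correlate.py` reports

```
n = 71 methylated references
Pearson r = -0.213 (regression slope -0.525)
Shapiro-Wilk p = 4.47e-10 (fold changes non-normal)
fraction downregulated after knockdown: 0.986
```

98.6% of called-methylated references shift down after knockdown, while the
*magnitude* of IP enrichment carries little information about the magnitude
of the response (weak correlation) — both derive from the same binary
methylated state in this model.

The same stages are available as subcommands of the `mirmeth` CLI
(`mirmeth all --seed 7 --out out/`, or `simulate`/`trim`/`count`/
`quantify`/`diff`/`rip`/`motifs`/`correlate` individually, each writing a
JSON manifest with parameters, input checksums and versions).

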