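# Methods

This note documents the models, parameters and numerical choices behind
`mirmeth`, and what the synthetic-data experiments do and do not establish.

## Study design

The pipeline targets two paired small-RNA-seq designs over HEK293-like
cells: (i) knockdown of the m6A demethylase FTO versus scrambled-siRNA
controls in three cell lines (3 kd/scr pairs), and (ii) RNA
immunoprecipitation of the small-RNA fraction with an anti-m6A antibody
versus an IgG isotype control in three replicates (3 m6A/IgG pairs).
Reads are quantified against the mature-miRNA catalog; methylation is
inferred from IP enrichment, and methyltransferase-consensus motifs
(RRACH and relatives) are sought in the enriched set.

## Reference catalog

Mature sequences are stored in the RNA alphabet; entries with exactly the
same sequence are collapsed into one (the surviving entry keeps the first
occurrence's position, the union of member names, and the
lexicographically smallest member name — the naming rule is our choice, as
is retaining full membership in outputs). The knockdown siRNA and
scrambled sequences (eight entries, including the printed
reverse-complement forms) are appended as spikes: their reads are thereby
identified during matching and excluded from the miRNA normalization
total. Matching operates in a canonical DNA alphabet (U→T) because reads
are DNA; catalogs and reports stay in RNA.

## Adapter trimming

Candidate placements of the 21-nt 3′ adapter in a read are (a) the full
adapter starting at any position with a free right end, and (b) an adapter
prefix of length ℓ ≥ 4 flush with the read's 3′ end. A placement is
admissible when its unit-cost edit distance e (substitutions, insertions,
deletions) satisfies e ≤ ⌊0.2 · aligned adapter length⌋ — the budget is
floored, so the full adapter tolerates 4 edits. Among admissible
placements the winner maximizes (aligned adapter length − e), i.e. the
match count, with ties broken by fewer errors, then by leftmost start.
A pure leftmost-first rule is not usable with an edit-distance model: the
placement 4 positions left of an exact adapter occurrence is always
admissible via leading insertions, so leftmost-first would trim 4 insert
bases from essentially every read; the match-count criterion is also what
established trimming tools optimize. The scan is an exact banded dynamic
program (numba-compiled); a brute-force enumerator over all placements
serves as the test oracle. Trimmed reads are classified by length:
< 16 bp discarded, 16–28 bp candidates, longer reads (including untrimmed
50-mers) excluded from miRNA counting.

## MEM assignment

For each (read, reference) pair, all maximal exact matches of length ≥ 7
are found via the longest-match function ℓ(p) (the longest prefix of
read[p:] occurring in the reference): the interval (p, ℓ(p)) is a MEM iff
ℓ(p) ≥ 7 and ℓ(p−1) ≤ ℓ(p). Occurrence is exists-in-reference: one read
interval is one MEM regardless of how many places it occurs. "Most
matching basepairs" is interpreted as the size of the union of qualifying
MEM intervals on the read, the same quantity as the ≥ 17 bp eligibility
coverage. Residual ties go to the lexicographically smallest reference
name and are flagged; the rule is order-free, so assignment is invariant
under catalog permutation. A 7-gram index prunes candidate references
(any qualifying MEM shares its first 7-gram), and identical read
sequences are assigned once and expanded by multiplicity. 16-bp reads
are retained as candidates per the stated window although they can never
reach 17 covered bp; they are reported unassigned. Comparison is
forward-strand only — the library protocol is stranded, and
reverse-complement spike entries are explicit catalog entries.

## Quantification and calls

RPM normalization divides each count column by its per-sample sum over
non-spike references (×10⁶); spike rows are scaled by the same
denominator but excluded from it, and an all-zero sample yields an
all-zero column with a warning. Thresholds follow the stated wording
literally: "at least" bounds are inclusive (≥ 15 RPM, ≥ 100 RPM, ≥ 2-fold
enrichment), fold-change cuts are strict (mean fc < 0.5 for down, > 2 for
up, secondary 1.5-fold threshold reported alongside). Fold changes are
means of per-pair ratios, reported with their SD, rather than ratios of
means — with three replicate pairs either convention is defensible; this
one also yields the SD column of the output tables. The knockdown ratio
uses a 1.0-RPM pseudocount only when the control is zero; the RIP
enrichment always uses (IP+1)/(IgG+1), since IgG columns are legitimately
near zero for well-enriched species. The 100-RPM RIP cutoff is applied to
all three IP replicates, mirroring the explicit all-three phrasing of the
15-RPM rule. All pseudocounts and thresholds are dataclass parameters.

## Motif discovery

The k-x-y-n motif space is enumerated recursively in lexicographic order
over the 15-letter IUPAC alphabet with per-class caps. Direct enumeration
gives 2464 (3-2-2-0), 37248 (4-2-2-1) and 571904 (5-3-2-1) motifs, each
exactly 2 below the counts reported for the original software; the source
of those two extra motifs is unidentified (the difference, ≤ 0.09%, does
not affect any ranking) and the definitional counts are what this package
reports. Counting is per-sequence containment, not occurrence
multiplicity. Each motif's 2×2 table (IP with/without vs background
with/without) is tested with the two-sided Fisher exact test
(point-probability method, via scipy — itself checked in the tests
against an exact integer hypergeometric enumeration), and
Bonferroni-corrected by the size of the scanned space. For speed, each
sequence's k-mer presence set is precomputed as a bitset; a motif's count
is the popcount of the union over its concrete expansions, and Fisher
p-values are cached on (a, c) since margins are fixed within a scan.

The original analysis also scored motifs with a compound-distribution
text-model statistic from a dedicated motif-discovery suite. That
machinery is not reimplemented; in its place is a defined surrogate with
the same inputs and interpretation: an order-(k−1) Markov model with
add-one smoothing is estimated from the pooled background k-mers, each IP
sequence's probability qᵢ of containing the motif is computed exactly by
dynamic programming over positions and model context, and the observed
number of containing sequences is referred to the upper tail of the
Poisson-binomial distribution of the qᵢ (grouped by sequence length and
convolved). Ranking is by the Fisher p-value; the surrogate is reported
for the top 50 motifs of a scan by default (configurable up to the whole
space — it is exact but pure-Python, minutes at k = 5).

Under a null with identical IP and background composition, the *minimum
raw* Fisher p across ~2.5k correlated motifs is routinely below 0.05
(order 10⁻⁴ in simulation); the meaningful null statement, which the
tests assert, is that no motif stays significant after Bonferroni
correction.

## Downstream statistics

Pearson's product-moment correlation with its least-squares line
summarizes log2 IP enrichment against log2 knockdown fold change over the
methylated set; normality of the fold changes is tested with
Shapiro-Wilk (Royston's algorithm, delegated to scipy, n restricted to
3–5000). References with non-positive means are excluded from the log2
table and logged. The published values of these statistics depend on the
unreleased sequencing data; on synthetic data they are demonstrated
qualitatively (direction and significance), never asserted numerically.

## Synthetic data

The generator emulates the study conditions: 300 references of 19–27 nt
(all distinct), log-normal abundances (median 100, σ_log 1.5), a 25%
methylated subset, a concrete RRACH instance (GGACU) overwritten at a
random offset in 60% of methylated references, knockdown factor 0.4 and
IP enrichment factor 8 applied multiplicatively to methylated references,
50,000 reads per sample drawn multinomially, reads built as reference DNA
with iid substitution errors at 0.005/base plus adapter plus random pad
to 50 bp, and 2% adapter-free random reads. One seed drives everything;
per-sample substreams derive from it deterministically, so equal
configurations give byte-identical FASTQs.

What the generator does **not** emulate: isomiRs and templated/untemplated
tailing, indel sequencing errors, realistic quality strings, ligation
bias, partial methylation of a species, antibody cross-reactivity, or
siRNA spike reads. Passing recovery tests therefore shows the pipeline's
logic is sound under its own model assumptions — not that the thresholds
are optimal for real libraries.

Note one interaction the model exposes: because RPM renormalizes within
each sample, enriching 25% of the mass 8-fold in the IP sample deflates
everything else, so the realized mean enrichment of methylated references
is ≈ 3 rather than 8, and unmethylated ones sit near 0.36. The ≥ 2-fold
cutoff still separates the groups cleanly; sensitivity losses come from
the 100-RPM floor on low-abundance species.

## Problem sizes and runtimes

The shipped analysis and the end-to-end tests use the full simulated
design (12 samples × 50,000 reads, 300 references): simulation through
correlation runs in ~25 s on one CPU, with motif scans at form 3-2-2-0 in
~2 s and 4-2-2-1 in ~40 s. Property tests compare against brute-force
oracles on 1,000 random read/reference pairs (MEMs), 10,000 motif/sequence
pairs, and 200 random contingency tables; motif-recovery calibration uses
20 seeded runs of 200 IP vs 2,000 background sequences.

## Known limitations

* The MEM tie rule, collapsed-entry naming, pseudocount placement and
  mean-of-ratios convention are reasonable but not uniquely determined
  choices; all are parameterized.
* The text-model p-value is a surrogate with the same interface as the
  original compound-distribution statistic, not a reimplementation of it;
  only Fisher results should be compared across implementations.
* Reads are matched forward-strand only and without indel tolerance in
  the assignment step (MEM coverage absorbs substitutions by splitting,
  at a 2-bp cost per substitution).
* Published per-miRNA tables (expressed counts, deregulation counts,
  fold-enrichment lists) are not reproducible without the original raw
  data and are out of scope.
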