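# Methods

`evmir` analyses small-RNA sequencing of three extracellular-vesicle (EV)
subtypes — two immunoaffinity-captured exosome populations (A33-Exos,
EpCAM-Exos) and shed microvesicles (sMVs) — against their parental cell line
(CL), and ships a synthetic-study generator so every stage is testable end to
end without external data.

## Read quality control (`evmir.qc`)

Raw reads are truncated at the leftmost admissible occurrence of the 3'
sequencing adapter (`TGGAATTCTCGGGTGCCAAGG`): a window of length
`L = min(len(adapter), bases remaining)` matches when `L >= 6` and it carries
at most `L // 10` mismatches. Reads beginning with the 5' adapter, or empty
after trimming, are insert-less ligation products. The surviving insert is a
*clean read* when, checked in this order, it (1) contains no `N`, (2) has at
most 6 bases below Phred 13 and at most 4 below Phred 10, and (3) is 18-30 nt
long. Each raw read lands in exactly one QC bucket; `QCStats.check()` enforces
the partition.

## Quantification (`evmir.quantify`)

Assignment is 5'-anchored with a 3' isomiR tolerance of ±2 nt: a clean read
matches a mature arm when it equals the arm exactly, equals the arm shortened
by 1-2 nt at the 3' end, or extends the arm by 1-2 nt. A read matching `k`
arms contributes `1/k` to each, conserving library totals. Unmatched reads are
screened against contaminant references (exact substring, in the fixed order
rRNA, tRNA, snRNA, snoRNA, srpRNA) and otherwise counted unannotated.

TPM uses the library's miRNA-assigned reads as denominator —
`TPM = count / miRNA_reads * 1e6` — so each column sums to one million over
arms. Detection requires TPM strictly greater than 5 in at least one library;
denominators are not recomputed after filtering.

## Enrichment classification (`evmir.enrichment`)

For each detected arm, `log2(TPM_EV / TPM_CL)` is computed per EV library; a
pseudocount of 0.01 is added to both operands only when one is zero (both-zero
ratios are 0). An arm is *enriched* in an EV when the ratio is >= 1.0 (i.e. at
least two-fold). The three membership flags place every arm in one of seven
Venn categories or `not_enriched`.

Significance between two libraries uses the Audic-Claverie posterior-
predictive test: given `x` counts in a library of `n1` reads, the count in a
library of `n2` reads follows a negative binomial with `x + 1` successes and
success probability `n1 / (n1 + n2)`; tails are evaluated through
`scipy.stats.nbinom` (regularised incomplete beta), and the two-sided p-value
is `min(1, 2 * min(lower, upper))`. P-values are reported alongside the
fold-change classification; membership is fold-change-based unless a
significance floor is requested (`require_p`).

The tails satisfy the exact identity
`P(Y' >= y | x; n1, n2) = P(X' <= x | y - 1; n2, n1)`, which the test suite
verifies against a direct-summation oracle. (The naive symmetric form without
the `y - 1` shift is *not* an identity; a counterexample is `x = 0, y = 1,
n1 = n2`, where the two sides are 1/2 and 1/4.)

## Genomic context (`evmir.clusters`)

Precursors on one chromosome are chained into polycistronic clusters when the
intervening distance (`next.start - running_max_end - 1`, strand-agnostic) is
at most 10 kb; chains of two or more are emitted. A start-to-start distance
mode is also available. Cluster over-representation in a detected precursor
set is scored with a one-sided Fisher exact test and Benjamini-Hochberg
q-values; family representation is tallied from the reference family table.

## Strand analysis (`evmir.strands`)

Star (passenger-strand) identity is fixed reference annotation. Per precursor
and library, the star arm is *dominant* when its TPM strictly exceeds the
mature arm's (ties dominate neither). A *dominance switch* for an EV library
is a precursor whose star arm dominates in that EV while the mature arm
dominates in CL.

## qRT-PCR concordance (`evmir.qpcr`)

Relative expression uses
`ddCt = (Ct_target,EV - Ct_ref,EV) - (Ct_target,CL - Ct_ref,CL)`, with the
reference Ct per sample being the mean over the normaliser assays (U6-snRNA
and MaMMU6 by default) or, in `global_mean` mode, over all measured targets.
Assays with any required Ct above 35 cycles are excluded. `-ddCt`
approximates the sequencing log2 fold change; concordance is the fraction of
shared targets whose signs agree. The synthetic Ct generator links expression
by `Ct = 36 - log2(TPM) + noise`, clipped at 40 cycles, with constant-Ct
controls, so noiseless tables reproduce sequencing fold changes exactly.

## Synthetic data (`evmir.simulate`)

The generator builds a reference whose arm sequences (20-23 nt) are mutually
prefix-free and adapter-trim-safe, making the ±2 nt assignment policy
unambiguous by construction. Hairpins are `5p-arm + 15 nt loop + 3p-arm` and
are placed with exact intervening gaps so configured cluster layouts are
recovered coordinate-exactly. Per-arm abundances follow a log-normal baseline
(sigma 1.5); enrichment scenarios multiply assigned arms by `2^effect_log2`
in the member EV libraries and renormalise. Reads are truncated inserts
(0/1/2 nt removed with probability 0.8/0.15/0.05) plus adapter, padded to
50 nt, with iid per-base substitution errors (0.5%), 5% contaminant reads,
and deliberate QC-violating reads (0.5% with an `N`, 1% with seven
quality-12 bases inside the insert). All randomness derives from one seed via
named `numpy` generator streams; identical configurations are byte-identical.

## Packaged fixtures (`evmir.fixtures`)

Two printed study tables ship with the package: the per-library read-count
summary (raw/clean/annotated counts with printed percentages) and the 63-row
enriched-miRNA table (per-library TPMs, printed log2 ratios, Venn group and
star flags). `evmir.pipeline.fixture_check()` recomputes every printed
quantity from the raw fixture numbers. Because printed TPMs carry two
decimals, a recomputed log2 ratio can differ from the printed one by up to
`(0.005/num + 0.005/den) / ln 2`; the check therefore uses the stated band
(0.02, or 0.01 when both TPMs >= 50) widened to that exact rounding envelope
where the envelope is larger, which only matters for two sub-1-TPM cells.

## Verification

The test suite pairs each component with an independent oracle: direct
term-by-term summation for Audic-Claverie tails, union-find transitive
closure for cluster chaining, and a conditional-binomial envelope (source
probability x truncation/error retention, renormalised over arms) for TPM
recovery on full-scale synthetic studies. `scripts/acceptance.py --seed N
--out report.json` reproduces the headline quantities.
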