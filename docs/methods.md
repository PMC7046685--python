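# Methods

This note records the models, conventions and numerical choices behind
rohscan, in the order data flows through the pipeline.

## Genotype representation and I/O

Genotypes are `int8` codes — 0 hom-A, 1 het, 2 hom-B, −1 missing — in a
samples × variants matrix with pandas frames for sample metadata (id, breed,
group) and the variant map (chrom, id, bp, alleles). All downstream
computations are invariant to which physical allele is "A"; the coding is
per-variant bookkeeping only.

PLINK text (PED/MAP) and binary (BED/BIM/FAM, SNP-major, magic `6C 1B`,
mode `01`, 2-bit little-endian packing, four samples per byte) are the
interchange formats. The text reader assigns allele A as the first allele
observed in file order. Consequence: a panel whose first non-missing call
at some variant is hom-B comes back from a PED round trip with that
variant's homozygote codes swapped. `GenotypeMatrix.canonical_codes()`
normalizes orientation for comparisons; hom/het/missing status — the only
thing ROH analysis consumes — is always preserved exactly, and binary round
trips are bit-exact because the BIM file stores both alleles.

## Quality control

Filter order is fixed: (1) drop non-autosomal variants (autosomes 1..29 by
default, configurable); (2) drop samples with missing fraction > 0.10;
(3) drop variants by call rate, then MAF, then HWE, each statistic
recomputed on the surviving samples. Boundary semantics follow the
"excluded at ≤" reading: retention requires CR > 0.90 and MAF > 0.05, and
HWE removal triggers at p ≤ 0.001. These choices change counts for
boundary cases (a variant at CR exactly 0.90 is removed) and are therefore
stated prominently here.

The HWE test is the exact conditional test (no mid-p): given the allele
counts, every possible heterozygote count is assigned its probability and
the p-value sums all outcomes no more likely than the observed one.
Probabilities are computed in log space via `gammaln` and normalized, with
an `lru_cache` on (n, rare-allele count, observed het) because small
cohorts generate few distinct tables; a chi-square variant is available via
`hwe_method="chisq"`. HWE is tested within breed by default (a variant
fails if it fails in any breed) because pooling differentiated breeds
produces Wahlund-effect rejections at perfectly well-behaved markers; a
pooled mode is available.

## ROH detection

**Sliding-window scan.** A window of `window_snp` SNPs (default 50) slides
one SNP at a time along each chromosome of each sample. A window is
homozygous iff it contains ≤ 1 heterozygous and ≤ 5 missing calls. Each
SNP's hit fraction is (homozygous windows overlapping it) / (windows
overlapping it); near chromosome ends the denominator shrinks, and a
chromosome shorter than the window is scanned with a single truncated
window. SNPs with hit fraction ≥ 0.05 are run-eligible; maximal stretches
of eligible SNPs are split where adjacent SNPs are > 1000 kb apart, then
filtered by ≥ 100 SNPs, ≥ 1000 kb, and density ≤ 50 kb/SNP (density applied
to the emitted stretch, length/SNP count). Coordinates are 1-based
inclusive bp of the first/last SNP; length = (end − start + 1)/1000 kb.
The implementation is pure cumulative-sum algebra (interior SNPs via a
shifted difference, chromosome-end SNPs via explicit gathers) and is tested
for exact segment-set equality against `brute_force_runs`, a deliberately
naive loop-based re-derivation of the same definition.

**Consecutive-runs scan.** The window-free detector reads each chromosome
SNP by SNP, accumulating a candidate run while the *run-level* budgets hold
(≤ 1 het, ≤ 5 missing, gaps ≤ 1000 kb). When a het/missing call would
exceed its budget the candidate closes at the previous SNP and scanning
restarts *after* the violating call; a gap violation closes the candidate
and restarts *at* the current SNP (the call itself is unobjectionable).
Runs may begin or end on a tolerated het/missing call. The two detectors
deliberately differ — per-window versus per-run allowances — mirroring the
two tool families in common use; on clean input (no het/missing/gaps) they
emit identical segments, which is a test.

## Inbreeding coefficients

`L_AUTO` is the summed per-chromosome SNP-map span (last − first SNP bp) of
the post-QC map — removed variants no longer define coverage; chromosomes
with < 2 SNPs carry no span and are warned about. `F_ROH(t)` sums segment
lengths ≥ t kb (inclusive threshold: the detector's 1000 kb minimum makes
the "> 1 Mb" tier exactly the full segment set, and a segment of exactly
8000.0 kb counts as "> 8 Mb"; the inclusive/strict distinction is
measure-zero for continuous positions but is fixed here for
reproducibility).

`F_HOM = (O − E)/(N − E)` with per-locus expected homozygosity
`1 − 2pq·T/(T−1)`, where p is the cohort (or per-breed, via `by_breed`)
allele frequency and T the cohort's non-missing allele count at the locus.
The `T/(T−1)` factor unbiases the plug-in heterozygosity estimate — the
standard method-of-moments form — so a cohort drawn exactly at HWE averages
F_HOM ≈ 0; `unbiased=False` yields the plain `1 − 2pq` expectation.
Frequencies estimated from the pooled cohort inflate F_HOM when breeds are
differentiated (Wahlund effect); the per-breed mode is the right choice for
within-breed inbreeding questions.

Spearman correlations are mid-rank Pearson correlations (scipy's
implementation); zero-variance input is an error, not NaN.

## Summaries

Length classes are half-open in Mb — [1,2), [2,4), [4,8), [8,16), [16,∞) —
so a 2.0 Mb run falls in 2–4 and no run is double-counted; the cumulative
">1" and ">8" tiers are unions of the five. Per-breed MN_ROH means include
zero-ROH animals as zeros; SDs are sample SDs (n−1). Chromosome coverage
follows the two-step rule: total ROH Mb on the chromosome ÷ animals with
≥ 1 ROH *on that chromosome* (a genome-wide-denominator mode exists for
sensitivity), then ÷ chromosome length. Chromosome lengths default to the
SNP-map span but a user-supplied assembly-length table is accepted.

## Islands and tests

Support curves count, per SNP, group members with a ROH spanning it;
frequency divides by the full group size. Islands are maximal runs of
SNPs at frequency ≥ the floor; `merge_gap_bp` (default 0, i.e. no merging)
optionally fuses runs across short gaps, a configurable because any
island-boundary rule beyond "consecutive SNPs above threshold" is a
convention. Ranking is by peak frequency with a positional tie-break.
Note that raising the floor is monotone for total island *extent* but not
for island *count* — a dip can split one island into two.

Per-breed frequencies at consensus regions count any-bp overlap by default;
a "span" mode requires a single ROH to cover the whole region (for narrow
regions the two nearly coincide). Flanks extend ± 2 Mb, clamped at bp 1.
Annotation intervals are 1-based inclusive (a `bed_convention` flag shifts
0-based half-open input); an annotation overlapping several islands of a
group counts once, deduplicated by name, since the totals count
annotations, not overlap events.

The two-proportion test is the pooled-variance two-sided z test
(≡ 1-df chi-square without continuity correction; a Yates-corrected variant
is exposed because spreadsheet tools differ and neither variant is claimed
to match any particular one). The Monte-Carlo companion redraws both
counts binomially under the pooled proportion (default 5000 replicates,
seeded) and reports the add-one-smoothed exceedance fraction of
|p̂1 − p̂2|; it converges to the continuous p on non-extreme tables. The
K-proportion test is the chi-square homogeneity test on the 2 × K table
(K−1 df) with expected counts reported and a small-cell warning; at K = 2
it reproduces the z test's p exactly.

## PCA structuring

Animals are coded 0/1 at consensus regions (any-overlap carrier status;
a length-weighted coding was considered and rejected as the default because
carrier status is what the island frequency itself measures). Regions are
filtered at carrier frequency ≥ 12.5% and capped at the 170 most frequent.
PCA is the SVD of the column-centered incidence matrix — equivalent in
eigenstructure to an eigen-analysis of the samples' cross-product
relationship matrix; allele-frequency-weighted genomic relationship
variants do not apply to 0/1 incidences. Column scaling is "center" by
default with a "correlation" option. Component signs are fixed by making
each component's largest-|loading| positive, so outputs are reproducible
across runs and sample orders (degenerate trailing eigen-subspaces remain
basis-arbitrary, as in any PCA). Contributions are 100·loading² per
component; the Kaiser rule retains eigenvalues strictly above the mean
eigenvalue (the "> 1" rule under correlation scaling). Region ranking for
scale-down weights each region's contribution by the component's
explained-variance share across the retained components.

## Synthetic panels

The generator plants autozygosity directly instead of simulating pedigrees
or coalescence: every downstream statistic depends only on tract length,
placement and sharing structure, and direct planting yields exact truth.
Per animal, tract counts per length class are Poisson with configurable
rates, lengths uniform within class bounds (the open-ended class is drawn
on 16–32 Mb), and placements uniform without within-animal overlap via
rejection sampling (longest tract first, 1000 retries, then an error —
demands near chromosome capacity are a configuration mistake, not
something to silently accommodate). Island carriers are an exact-count
random subset, `round(fraction × group size)`, so the planted carrier
fraction is the realised fraction rather than a binomial draw whose
shortfall would confound recovery tests. Inside tracts the genotype is
homozygous for an allele drawn by its frequency, with heterozygote "errors"
at rate 0.001 and uniform missingness at 0.01 (≈ the 99% genotyping rates
typical of array data). Baseline genotypes are exact HWE draws within
breed, with breed allele frequencies from a Beta(2,2) prior.

Default SNP spacing is ~6 kb (jitter ± 2 kb), emulating a high-density
bovine array, on which the canonical thresholds are mutually consistent:
1 Mb of map carries ~170 SNPs, comfortably above the 100-SNP minimum. At
the ~50 kb spacing of low-density arrays the same thresholds would make
every 1–8 Mb tract undetectable (1 Mb ≈ 20 SNPs), which is a property of
the parameter set, not of this implementation.

The `emulate_study_profile` cohort is a scaled study stand-in: seven
breeds of 13–18 animals whose per-class tract rates make expected ROH
counts span ~25 (dairy-like) to ~64 (draft-like) per animal with one
long-ROH-enriched dwarf breed (> 8 Mb classes ≈ 70% of planted length),
group-specific planted islands, and eight 150 Mb autosomes (~1.2 Gb,
200k SNPs) rather than a full ~2.5 Gb genome — chosen to keep repeated
end-to-end simulation cheap while preserving every structural contrast the
analyses measure. Genome-fraction statistics (MGP_ROH, F_ROH) are
correspondingly larger than they would be on a full-length genome at equal
tract counts; orderings and class shares are unaffected.

**What passing tests show, and what they do not.** The generator reproduces
breed-structured allele frequencies, length-classed autozygosity, genotype
errors and missingness, and shared islands. It does not model linkage
disequilibrium, mutation/recombination processes, ascertainment bias of
array design, or identical-by-state runs that mimic autozygosity — so
recovery results bound detector performance under clean planted truth, not
under every property of real array data.

## Numerical conventions

Lengths are kb throughout (Mb = kb/1000); positions are 1-based inclusive
bp. Detector output is sorted by (sample, chrom, start) with a stable
sort; all stochastic components take explicit seeds and one
`numpy.random.Generator` drives each simulation in a fixed draw order, so
identical configurations produce byte-identical serialized output.
Window-fraction thresholds are compared as floating-point `num/den ≥ t`,
computed identically in the fast detector and the brute-force oracle.
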