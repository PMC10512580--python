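# Methods

## Model and scope

`pqtlmr` implements two-sample summary-data Mendelian randomization with
proteins as exposures and a binary disease as outcome. The exposure
effect scale is SD units of circulating protein; the outcome scale is
log odds. The usual instrumental-variable assumptions apply (relevance,
independence, exclusion restriction); restricting instruments to
cis-pQTLs — variants within ±1 Mb of the encoding gene's transcription
start site — is the design's main defence of the exclusion restriction,
since cis variants act on the protein through the gene itself far more
plausibly than trans variants do.

## Instrument selection

Five sequential criteria, all configurable (`InstrumentConfig`):

| step | rule | default | why |
|---|---|---|---|
| significance | P < threshold (strict) | 5×10⁻⁸ | genome-wide significance |
| MHC | drop chr6:26,000,000–34,000,000, endpoints inclusive | fixed region | extreme LD/gene density breaks instrument assumptions |
| cis | same chromosome, \|pos − TSS\| ≤ window (inclusive) | 1 Mb | field convention for cis action |
| clumping | greedy by ascending P; accept iff r² < threshold with every accepted SNP within the window; ties broken by (chrom, pos, id) | r² 0.001, 10 Mb | one instrument per LD clump |
| strength | F > 10 (strict) | 10 | weak-instrument bias |

PVE defaults to the SE-based approximation β²/(β² + n·se²) because
allele frequency is sometimes missing in source files; an eaf-based
variant 2·maf(1−maf)·β² (standardized trait) is available via
`snp_strength(..., method="eaf")`. F = PVE·(n−2)/(1−PVE), so F ≈ z² for
small PVE; both options for the F definition are thereby exposed.
Significance, MHC, cis and strength are set-intersection filters and
commute; clumping is order-sensitive and always runs after them (on the
supplied per-region LD matrix — the package never computes LD from
genotypes).

## Harmonization

Outcome records are aligned to the exposure's effect allele: swapped
labels flip the beta sign and complement the allele frequency;
irreconcilable allele sets are dropped. Palindromic SNPs (A/T, C/G)
cannot be resolved from labels, so they are kept only when both allele
frequencies are on the same side of 0.5 and outside 0.5 ± window
(default 0.08, the convention of the standard two-sample MR tooling);
palindromic SNPs with a missing frequency are dropped. Harmonization is
idempotent, and flipping every outcome record's labels and sign leaves
all downstream estimates unchanged (property-tested).

## Estimation

The Wald-ratio SE is first order (se_out/|β_exp|), the default of the
standard MR packages; with F > 10 instruments the exposure-noise
correction is negligible, but a second-order SE is available
(`second_order=True`). IVW is fixed-effect — heterogeneity in this
design is typically absent with one-to-few cis instruments — with a
multiplicative random-effects inflation √(max(1, Q/(k−1))) behind a
flag. MR-Egger orients SNPs to positive exposure effects, fits WLS with
weights 1/se_out², and reports t-based inference (k−2 df). 95% CIs use
z = 1.959964; all p-values are two-sided normal unless stated, floored
at the smallest positive double so they stay in (0, 1].

The Bonferroni denominator is the number of proteins *attempted* (not
protein×outcome pairs, and not successful fits), at family α = 0.05;
the comparison is strict. Replication requires P < 0.05 with a
direction consistent with discovery, under either the same-variant
strategy (re-using discovery SNPs) or the significant-variant strategy
(instruments re-selected in the replication pQTL data); the pipeline
records both and counts a protein replicated if either succeeds.

## Direction guards

Steiger: per-SNP r² on each side is z²/(z²+n), summed over instruments;
for the binary outcome the same observed-scale approximation is used
(no liability-scale correction — the data generator provides no
liability parameters, and the comparison only needs a common scale).
The Fisher-z statistic (atanh r_exp − atanh r_out)/√(1/(n_exp−3) +
1/(n_out−3)) gives a two-sided p; a tie in r² is conservatively *not*
the correct direction.

Bidirectional MR re-runs the instrument pipeline on the disease GWAS
(cis filter disabled — disease instruments are genome-wide) and
estimates disease → protein. In the pipeline, disease instruments are
drawn from outside the protein's cis region: a shared cis causal
variant makes the reverse test significant in both directions by
construction, so including it would flag every true target. IVW p is
primary and Egger p is reported alongside (configurable); a protein
with reverse p < 0.05 is excluded from the tier report but remains in
the MR results table with its flag.

## Colocalization

Wakefield log-ABF per SNP: ½(log(1−r) + r·z²) with r = W/(V+W), V = se²,
W the squared effect prior SD — 0.15·sdY for the quantitative trait
(sdY = 1 by default, since pQTL betas are in SD units; no sdY estimation
in this version) and 0.2 for the binary trait, the standard defaults.
Hypothesis weights are assembled in log space with log-sum-exp; the H3
term exp(S1+S2) − exp(S12) uses a stable log-difference floored at −∞
(exactly −∞ for single-SNP regions, where two distinct causal variants
are impossible). Priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵. Colocalization is
declared at PPH4 ≥ 0.8; the threshold comparison is inclusive, matching
the stated decision rule (an exact-boundary region is treated as
colocalized). A brute-force enumeration over all single-causal-variant
configurations serves as an independent oracle in the tests and the
acceptance script; on small regions the two agree to 10⁻⁹.

## Tier classification

With flags (replicated, colocalized, drug-linked): tier 1 = colocalized
∧ replicated; tier 2 = drug-linked ∧ replicated (and not tier 1);
tier 3 = exactly one flag; tier 4 = otherwise. "Exactly one flag" is
the reading of the tier-3 rule that uniquely reproduces all thirteen
published example assignments; a protein that colocalizes and is
drug-linked but fails replication is therefore tier 4. PPI edges use
STRING semantics: integer scores 0–1000 are rescaled to [0, 1],
self-loops dropped, duplicates keep the maximum score, and the 0.4
threshold is inclusive. Phenotype scanning is a local-table lookup
(snp, trait, p) — no live web services, for reproducibility — with
hits at P < 5×10⁻⁸ and a pleiotropy flag when the trait is a declared
risk factor for the indication.

## Synthetic data

Summary statistics are simulated directly from the multivariate-normal
approximation β̂ ~ MVN(R·γ, se²·R) with AR(1) LD (r_ij = ρ^|i−j|,
positive definite for ρ < 1); no individual genotypes are generated.
SEs are 1/√n (standardized quantitative scale) and 1/√(n·φ(1−φ))
(log-OR scale, case fraction φ — a constant-information approximation
that ignores per-SNP allele-frequency dependence of the SE).

Defaults (one choice, stated once): m = 100 SNPs spaced 2 kb, ρ = 0.5,
pQTL GWAS n = 10,000, disease GWAS n = 100,000 with φ = 0.5, per-allele
cis effect b = 0.3 SD (PVE ≈ 9%, F ≈ 900 — a strong cis-pQTL), causal
effect θ = 0.2 log-OR per SD, MAF uniform on (0.05, 0.5). The
replication copy redraws all noise independently with n = 35,559
(sized after a large replication pQTL study) and outcome n = 100,000.
Proteome bundles assign causal proteins |θ| ~ U(0.15, 0.35) with random
sign; non-causal proteins keep their cis-pQTL with θ = 0.

Scenarios: `shared_causal` (outcome effects θ·γ), `exposure_only`
(θ = 0), `null`, `distinct_causal` (separate disease variant, per-allele
log-OR d = 0.3), and `reverse_causation`, in which the apparent cis
signal is really a disease variant (effect d = 0.3) propagated to the
protein with reverse_theta = 0.3 — chosen so that the induced pQTL is
genome-wide significant (z ≈ 9 at n = 10,000), Steiger prefers the
outcome side (reverse_theta² < φ(1−φ)), and the genome-wide disease
instrument panel (20 LD-free loci, per-allele effects U(0.05, 0.15))
gives the bidirectional test high power. An
`exposure_causal_indices` override places several independent exposure
causal SNPs for estimator calibration; the default remains one causal
cis variant per protein, which is also what the single-causal-variant
colocalization model assumes.

What the generator does **not** emulate: realistic human LD panels
(block structure, long-range LD), allele-frequency-dependent SEs,
sample overlap between exposure and outcome GWAS, population
stratification, horizontal pleiotropy of cis instruments, and
liability-scale effects. Calibrations passing on this generator
therefore establish internal statistical correctness of the estimators
and decision rules under their own assumptions — not robustness to
those real-data complications.

## Numerical choices

Degenerate inputs are explicit errors: zero exposure beta in a Wald
ratio, k below the estimator minimum, non-positive SEs or priors,
ρ ≥ 1, LD dimension mismatches. Clumping ties break deterministically
by (chrom, pos, id). P-values are clamped to ≥ 5×10⁻³²⁴. Posterior
normalization is exact to 10⁻⁹ by construction (tested by fuzzing). All
simulation randomness flows through `numpy.random.default_rng` seeds;
pipeline runs are byte-identical under a fixed seed, and the run
manifest records the seed, config hash and package version needed to
reproduce any output file.

## Problem sizes used in validation

The test suite and acceptance script use: 1,000 random instrument sets
for the IVW oracle check; 300 fuzzed regions for normalization and 200
small regions for the enumeration oracle; 200 replicates each for the
colocalization (n = 100k/100k), reverse-detection and Steiger
calibrations; 2,000 replicates for type-I error and 3×500 for parameter
recovery (n_outcome = 100k); and a 50-protein bundle (one planted
causal protein) for the end-to-end run. These sizes give Monte-Carlo
error comfortably inside each acceptance band.

## Known limitations

Single-causal-variant colocalization only (no SuSiE-style multi-signal
analysis, no conditional analysis or credible sets); no weighted-median
or mode-based MR estimators; no MR-PRESSO; no liability-scale
conversion; no VCF/dbSNP/liftover support in the I/O layer (delimited
text with configurable column maps only); the CLI exposes `simulate`,
`discover`, `report` and `all`, with validation and tiering folded into
`discover` since they operate on the same in-memory results.
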