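# Methods

## Model and estimator

`crossfdr` works entirely on two aligned vectors of per-SNP p-values.
For a SNP with p-values (p_i, p_j) in the primary and conditional trait,
the conditional FDR is the posterior null probability given that both
observed p-values are at least as extreme:

    cFDR(p_i | p_j) = Pr(H0_i | P_i <= p_i, P_j <= p_j).

We estimate it with the empirical-CDF plug-in, with the null fraction pi0
fixed at 1 (conservative, and free of density estimation):

    cFDR_hat[k] = p_i[k] * #{m : p_j[m] <= p_j[k]}
                          / #{m : p_i[m] <= p_i[k] and p_j[m] <= p_j[k]}.

The numerator p_i[k] * (conditional stratum size) is the expected number of
null SNPs at or beyond p_i[k] inside the stratum under a uniform null; the
denominator is the number observed there. Thresholds are inclusive and
each SNP counts itself, so the denominator is >= 1 and the estimate is
well defined for every SNP; estimates are capped at 1. Ties share counts
exactly (no random tie-breaking). The conjunctional FDR is the
elementwise maximum of the two reciprocal conditional FDRs — a
conservative bound on the FDR of claiming association with both traits.

Because the count ratio is >= 1, cFDR_hat >= p_primary and hence
ccFDR >= max(p_a, p_b). This is worth internalizing: no SNP can attain
ccFDR below its worse single-trait p-value, which caps the attainable
sensitivity of any recovery experiment (see "Calibration and power").

### Counting

Production counting is O(n log n): SNPs are swept in order of the
conditional p-value and a Fenwick tree over primary-p ranks answers the
joint dominance counts; ties on the conditional axis are inserted as a
block before any member is queried. A naive O(n^2) counter
(`empirical_cfdr_bruteforce`) is retained and the two are asserted equal —
exactly, not approximately — on randomized instances in the tests.

### Monotone cleanup

The raw plug-in estimator need not be monotone in p_primary at fixed
conditioning. We post-process with the quadrant running maximum

    out[k] = max{ cfdr[m] : p_primary[m] <= p_primary[k], p_cond[m] <= p_cond[k] },

which only increases values (stays conservative) and makes the surface
non-decreasing in both arguments. Exact evaluation is quadratic and used
for n <= 10,000; above that the axes are quantile-binned into a 512x512
grid, per-cell maxima are accumulated cumulatively along both axes, and
each SNP looks up its cell. The grid lookup includes same-cell neighbours
with slightly larger p, i.e. it can only round *up* (by at most the
within-cell spread, ~0.2% of the data per axis); on planted-signal runs
grid and exact calls differ negligibly.

### Genomic control

Inflation is estimated per trait by median chi-square:
lambda = median(chi2_1_isf(p)) / 0.454936, where 0.454936 is the exact
chi2(1 df) median. Correction maps p to the upper-tail probability of
chi2(p)/lambda; lambda is clamped at 1 so correction never sharpens
p-values. The correction is applied to each trait's vector before cFDR
estimation. The placement (per trait, before estimation) and the
median-chi-square estimator are package choices; intercept-based
alternatives (e.g. LD-score style) need more inputs than two p-value
columns.

The locus caller's dual per-trait filter (p < 1e-5 in both traits) is
applied to the corrected p-values when genomic control ran — correction
precedes everything downstream, and since corrected p >= raw p this is the
conservative reading.

## Pipeline defaults

| parameter | default | meaning |
|---|---|---|
| `ccfdr_max` | 0.01 | conjunctional FDR calling threshold |
| `p_max` | 1e-5 | suggestive-significance filter, each trait |
| `maf_min` | 0.01 | QC: minimum minor allele frequency |
| `hwe_min` | 1e-6 | QC: minimum Hardy-Weinberg p |
| `call_rate_min` | 0.95 | QC: minimum genotyping call rate |
| stratum cutoffs | 1, 0.1, 0.01, 0.001 | conditional p-value strata for Q-Q/fold curves |
| enrichment grid | 101 points on [0, min(10, max)] | nominal -log10 p axis |
| monotone grid | 512 x 512 | quantile bins for the running-max cleanup |

QC fields absent from a summary-statistics file pass their filter: public
GWAS releases routinely apply these cuts upstream at genotype level and
omit the columns. Zero p-values are clamped to 0.1x the smallest positive
p in the table so -log10 transforms stay finite. Only p-values are used —
no signed effects — so no strand or effect-allele harmonization is
performed, and none is needed.

"Locus" is SNP-level throughout: each passing SNP is reported, with no LD
clumping by default (a greedy best-ccFDR-within-window convenience,
`clump_loci`, is available but off). Duplicated rsIDs are collapsed by
arithmetic-mean p at ingest and by arithmetic-mean ccFDR after calling;
duplicates that disagree on chromosome (ingest) or position (calling) are
treated as data conflicts, not averaged.

Gene annotation is interval-based from a user-supplied BED (0-based
half-open, converted on read) or GFF3 (`gene` features, `Name=` symbol)
file; distance to an interval is max(start - pos, pos - end, 0), SNPs
inside a gene get all containing genes, and exact distance ties return all
tied genes. Web annotation services are deliberately not queried — they
are not reproducible inputs. The packaged 49-locus table's gene column is
treated as published data, not as a target the distance rule must
reproduce: its assignments come from a curated database lookup whose exact
rule is not algorithmically specified.

## The synthetic generator

`simulate_pair` draws each SNP's class from a four-groups multinomial
(null/null, A-only, B-only, shared) and, given the class, independent
z-scores z ~ N(0, 1 + sigma2 * 1[non-null]) per trait, converted to
two-sided p-values. Defaults are a realistic desk-scale polygenic
scenario: 100,000 SNPs, pi_null = 0.95, pi_a_only = pi_b_only = 0.02,
pi_shared = 0.01, sigma2 = 25 (non-null |z| ~ 5 on average, i.e. loci
spanning the suggestive-to-genome-wide range). Optional multiplicative
inflation of z^2 emulates confounding for the genomic-control recovery
tests, and `dup_fraction` plants duplicate rsIDs (second copy: an
independent draw from the same class) to exercise deduplication. SNPs sit
at unit spacing on one synthetic chromosome — coordinates exist for the
locus logic, not for realism.

What the generator does *not* model: linkage disequilibrium (SNPs are
independent by design), realistic allele frequencies, ancestry
structure, or sample overlap between cohorts (shared controls would
correlate the traits' test statistics and inflate cross-trait enrichment).
Passing tests therefore demonstrate the statistics are computed correctly
and calibrated under independence — not that real GWAS pairs meet those
assumptions.

A subtlety that matters for testing: with pi_shared = 0 the four classes
are mutually exclusive, so the two traits' signal indicators are
*negatively* dependent (a SNP carrying A-signal cannot carry B-signal).
Conditioning on trait B then selects against trait-A signal and fold
enrichment drops below 1 — real anti-enrichment, faithfully reported by
the curves. Genuine independence requires factorized fractions
(pi_shared = pa * pb), which is what the independence property tests use;
the pi_shared = 0 regime is tested for the depletion it actually implies.

## Calibration and power

Under a global null (pi_null = 1) the pipeline calls essentially nothing:
the dual p < 1e-5 filter alone has expected 100,000 * (1e-5)^2 = 1e-5
qualifying SNPs. With the default planted-sharing conditions, calls at
ccFDR < 0.05 are > 90% truly shared, but sensitivity plateaus around
0.36-0.38: since ccFDR >= max(p_a, p_b), a shared SNP is callable at 0.05
only if p < 0.05 in both traits, an event of probability
(2*Phi_bar(1.96/sqrt(26)))^2 ≈ 0.49 under sigma2 = 25 — and the
conservative count ratio (~7x on p for well-conditioned SNPs) lowers the
practical ceiling further. Sensitivity rises monotonically with effect
variance, as the tests assert over sigma2 in {9, 16, 25}.

Small enrichment strata are noisy: under the null the 0.001-cutoff stratum
holds ~100 of 100,000 SNPs, so its fold values at t ~ 2 carry O(1) Poisson
error. Calibration checks on mean fold weight strata by size, and
envelope checks require a populated tail (>= 500 exceedances) on both the
baseline and the stratum being compared.

## Numerical choices

- p-values are validated into (0, 1]; tail conversions go through
  `scipy.stats` survival functions and are floored at 1e-300.
- Empirical Q-Q quantiles use r/(n+1), keeping -log10 finite at both ends.
- Fold-enrichment curves are trimmed where the baseline tail holds fewer
  than 10 SNPs.
- Chromosome ordering is numeric-aware (1..22 before non-numeric labels).
- All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bit-identical tables.

## Known limitations

- pi0 = 1 makes cFDR conservative; no local-FDR or covariate-weighted
  variants are provided.
- No LD pruning or weighting: in real data, clustered SNPs are correlated
  and the 49-SNP fixture is one such cluster — SNP-level calls should not
  be read as independent discoveries.
- The fold-enrichment display is tabular first; plotting is a thin
  optional matplotlib layer over the tables.
- No genetic-correlation estimator (e.g. LD-score regression) is included;
  enrichment curves are the only cross-trait summary.
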