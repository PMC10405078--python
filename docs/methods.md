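# Methods

`methmediate` implements a two-stage epigenetic mediation analysis for
case/control studies with matched SNP genotypes and DNA-methylation
beta-values: genotype quality control and association screening, DMP-targeted
methQTL mapping, and a four-condition causal inference test (CIT) whose
composite p-value follows the intersection–union principle. This note records
the statistical model behind each stage, the tunable parameters and their
defaults, what the synthetic-study generator does and does not emulate, and
the numerical and design choices a maintainer would want spelled out.

## Data model

Three aligned objects: a genotype matrix `G` (samples × SNPs, additive
dosages 0/1/2 counting alt alleles, NaN missing), a methylation matrix `M`
(samples × probes, beta-values in [0, 1], NaN missing), and a binary
phenotype `Y` (1 = case). Coordinates are 1-based; SNP–CpG distance is
`|pos_snp − pos_probe|` on a shared chromosome. All statistics use pairwise
complete cases. Sample alignment restricts all three objects to the common
id set in the genotype file's order, so alignment is idempotent and
insensitive to the other files' row order.

## Genotype QC

Three per-SNP filters, failure strictly below threshold (equality passes):

| filter | statistic | default threshold |
|---|---|---|
| call rate | fraction of non-missing genotypes, all samples | ≥ 0.98 |
| MAF | min(f, 1−f), f = alt-allele fraction among called | ≥ 0.05 |
| HWE | exact conditional test, **controls only** | p ≥ 1 × 10⁻⁴ |

HWE deviation is assessed in the unaffected arm because deviation there flags
genotyping artefacts without discarding true case-enriched associations. The
exact test conditions on the observed allele counts and sums the
probabilities of all heterozygote configurations no more probable than the
observed one (no mid-p). Probabilities are built from the neighbour-ratio
recurrence in log space and normalised with log-sum-exp; ties are resolved
with a relative tolerance of 1e-10. The full per-(n, minor-allele-count)
distribution is cached, making repeated scalar calls O(1). A 1-df chi-square
alternative (`hwe_test="chisq"`) exists because the original array-QC
software may have used either; exact is the default at n = 44 controls,
where the asymptotic test is unreliable.

## Case/control association

Default test: the classic allelic chi-square — a 1-df Pearson test without
continuity correction on the 2×2 allele-count table (alt/ref × case/control).
The odds ratio gets a Haldane–Anscombe 0.5 correction only when a cell is
zero, purely for reportability. An additive logistic alternative
(likelihood-ratio test of the dosage term, log-odds per alt allele) is
selectable and shares its solver with the CIT. Selection defaults to raw
p < 0.05; an FDR < 0.05 mode exists because either convention is defensible
for a screening stage feeding a downstream corrected analysis.

Benjamini–Hochberg adjustment is shared package-wide:
`q_(i) = min_{j≥i} p_(j)·m/j` capped at 1, with missing p-values propagated
as missing and excluded from `m`.

## methQTL mapping

Each candidate SNP × DMP-probe pair is fitted by ordinary least squares of
the probe's beta-value on dosage with intercept (the linear additive model
standard in QTL mapping); t = slope/SE with n−2 df. Regression is on the
beta scale by default — effect sizes then read directly as Δbeta per
allele — with a logit2 M-value option for variance stabilisation. BH runs
**once across the full tested Cartesian product**; pairs with constant
dosage or fewer than 3 complete cases are untestable and excluded from the
correction denominator. Pairs are labelled *cis* when on the same chromosome
strictly within 500 kb, otherwise *trans* (distance undefined across
chromosomes). No covariates by default: the intended study design (single
sex, narrow age band, one array batch) removes the usual ones; a covariate
hook exists. The mapping loop is vectorised per probe across SNPs with
mask-weighted sums; a test pins its equality to the scalar reference fit.

## Causal inference test

For a triple (G, M, Y), mediation is declared only when all four conditions
reject at α (default 0.05):

1. **G–Y**: logistic LRT of dosage (1 df).
2. **M–Y | G**: logistic LRT of M in `Y ~ G + M` vs `Y ~ G`.
3. **G–M | Y**: partial F-test of dosage in the linear model `M ~ Y + G`.
4. **G ⫫ Y | M**: equivalence-type permutation test, below.

The composite p is the maximum of the four (intersection–union test): it
rejects only if every component rejects, hence is conservative — observed
type-I rates under non-mediation topologies sit well below nominal. The
attenuation pair (G coefficient in `Y ~ G` vs `Y ~ G + M`, same model scale)
is reported with every result; mediation shrinks it.

### Condition (iv) construction

A conditional-independence condition cannot be certified by an ordinary
significance test — failing to reject is not evidence of independence — so
condition (iv) is an equivalence test whose null hypothesis is "G retains a
direct effect on Y as large as its observed marginal effect". Construction:

* Observed statistic `S_obs`: partial F for G in the linear outcome model
  `Y ~ M + G`.
* Surrogates: regress G on M, keep the fitted values, permute the residuals
  (`G* = fit + permuted resid`), preserving the G–M association while
  severing any direct G→Y path.
* Effect transfer: the estimated marginal slope `b̂` of Y on G moves onto
  the surrogate, `Y* = Y − b̂·G + b̂·G*`, so each replicate realises the
  putative direct effect through a variable that is conditionally
  independent of the original G.
* `p₄ = (1 + #{S* ≤ S_obs}) / (B + 1)` with B permutations (default 1000,
  add-one smoothing keeps p > 0).

Under pure mediation `S_obs` is central while every `S*` carries the
transferred effect, so p₄ is small; under a genuine direct path `S_obs` and
`S*` are exchangeable to first order and p₄ is roughly uniform, which keeps
the composite conservative. The statistic is computed on the
linear-probability scale for either outcome-model setting, because the
effect-transfer construction needs an additive outcome; the partial F is a
monotone measure of the residual G–Y association that the condition is
about. A naive permutation scheme without the transfer makes p₄ uniform
under mediation (surrogates then have exactly the observed statistic's null
distribution) and was rejected on that calibration ground.

Logistic fitting is a step-halving Newton iteration with a separation guard
(linear predictor capped at ±30). Under quasi-separation the achieved
log-likelihood is a lower bound of the supremum, so the LRT p-value reported
by the CIT components is a conservative upper bound rather than a missing
value; the association module's user-facing test instead flags separation
with a missing p and a warning. The batched variant fits all permutation
designs simultaneously. `statsmodels` is used as an independent oracle in
the test suite, never in the computation path.

Each tested pair draws its permutations from a stream derived from
(seed, pair index), so results are reproducible and independent of how many
pairs are tested.

## Region annotation

Probes map to eight mutually exclusive array categories (TSS1500, TSS200,
5′UTR, 1stExon, Body, ExonBnd, 3′UTR, IGR). Multi-annotation probes reduce
by a promoter-first priority (TSS200 > TSS1500 > 5′UTR > 1stExon > ExonBnd >
Body > 3′UTR, else IGR). Subset-vs-background comparison reports per-category
fraction ratios with a two-sided exact binomial p — exact because methQTL
CpG sets are tiny (single digits); the p-value layer is an extension beyond
a purely descriptive comparison and is labelled as such in the output.

## Synthetic studies

The generator emits complete studies with known causal truth under four
per-triad topologies: **mediation** (G→M→Y), **consequential** (G→Y→M, the
reactive-methylation model), **independent** (M←G→Y with no M→Y path) and
**null**. Mechanics:

* Genotypes: two independent allele draws at the configured MAF — HWE holds
  by construction. MAF uniform in (0.10, 0.50) by default, so the panel
  passes default QC (≥ 99% of SNPs, verified by test).
* Methylation: per-probe baseline uniform in (0.25, 0.75), plus centred
  genotype contributions `a·(G − Ḡ)` (centring keeps probe means at
  baseline so extreme baselines do not saturate the beta range), plus a
  `d·Y` shift for reactive probes, plus Gaussian noise (sd 0.02), clipped
  to [0.01, 0.99]. Gaussian-with-clipping was chosen over a logit-normal
  because the analysis operates on the beta scale; noise sd 0.02 makes
  Δbeta effects on the 0.06–0.24 scale comfortably detectable at n = 88.
* Phenotype: per-sample log-odds = intercept + sum of triad contributions
  (`b·(M − M̄)` for mediation, `c·(G − Ḡ)` for direct paths); Bernoulli
  outcomes drawn over a population pool, then exactly 44 cases and 44
  controls sampled from the realised arms (rejection sampling), matching a
  fixed-arm design rather than prevalence sampling.
* Several triads may share one mediator probe (`M = baseline + Σ aᵢGᵢ + ε`),
  and the SNPs of a shared probe can form an LD block (each haplotype copies
  a shared allele with probability τ; pairwise dosage correlation ≈ τ²,
  HWE preserved). This mirrors the empirical structure of methQTL hits —
  clusters of correlated tag SNPs around few CpGs — and it matters
  statistically: five *independent* strong mediation triads acting on one
  88-sample outcome dilute each other's marginal effects below any
  recoverable level, whereas tag-SNP clusters on shared mediators keep
  per-SNP effects detectable.
* The consequential model retains an optional G→M path so that
  methQTL-significant pairs still arise under a non-mediation topology —
  necessary to demonstrate that the CIT, not methQTL alone, separates the
  models.

Reference effect sizes (`default_effects`): standard mediation a = 0.05
beta/allele with b = 60 log-odds per beta-unit (≈ 2 log-odds per mediator
SD — strong but within what a detectable methylation mediator implies at
n = 88); the "strong" set used for planted-truth recovery puts five tag
SNPs (MAF 0.30–0.50, τ = 0.65) on one mediator CpG with a = 0.11
(|Δbeta| ≈ 0.22) and b = 50, ascertained from a low-prevalence pool
(risk intercept −1.5, pool factor 8). Non-mediation triads use a = 0.08
with modest direct effects (c = 0.3) and, for reactive probes, a case shift
d = 0.08.

**What the generator does not emulate:** genome-wide LD structure beyond
planted blocks, batch and cell-composition effects in blood methylation,
probe-specific measurement error, covariate structure (age, sex, ancestry),
and genotype error processes that real HWE filters exist to catch. Passing
the planted-truth suite therefore demonstrates that the pipeline's logic and
calibration are correct under its stated model, not that real cohorts of
this size yield comparable operating characteristics.

## Numerical and degenerate-input conventions

* Constant dosage: association/CIT conditions return p = 1 (nothing to
  test); methQTL marks the pair untestable (missing p, excluded from BH).
* Constant methylation: condition (ii) and (iv) return p = 1; attenuation
  is a no-op (adjusted = unadjusted).
* Perfect fits (zero residual) underflow to p = 0 rather than erroring.
* Missing composite components make the composite missing and the verdict
  `not_mediation`.
* Monomorphic-in-both-arms chi-square: statistic 0, p 1, OR missing.
* All randomness flows from explicit seeds through `numpy.random.Generator`;
  pipeline outputs are byte-identical across reruns with equal config.

## Problem sizes in the validation suite

The statistical suites run at desk scale chosen to give tight Monte-Carlo
error while staying fast: exhaustive HWE oracle comparison over all triples
with total ≤ 200; methQTL null calibration at 23 probes × 500 SNPs × 200
replicates; CIT level at 500 replicates (two non-mediation topologies,
1000 permutations each); CIT power and attenuation at 300–400 replicates;
end-to-end planted-truth recovery over studies of 44 SNPs × 29 probes with
24 planted triads. `scripts/acceptance.py` recomputes the same quantities
from scratch at comparable sizes.

## Known limitations

* The CIT addresses forward mediation only; reverse mediation (Y→M tested
  as mediator of something else), multi-mediator models and
  instrumental-variable estimators are out of scope.
* Condition (iv)'s equivalence bound is the estimated marginal effect; with
  a very weak marginal G–Y signal the test has little power to support
  independence (appropriately — condition (i) fails there too).
* The linear-probability scale of the condition (iv) statistic is a
  pragmatic choice; a fully logistic effect-transfer would require
  parametric simulation of Y and was not adopted.
* No population-structure correction, imputation, LD pruning, or
  permutation-based QTL significance; single-cohort, single-batch designs
  are assumed.
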