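# Methods

`poegwas` implements a parent-of-origin aware GWAS pipeline for
quantitative traits on pedigreed cohorts, exercised end-to-end on
synthetic cohorts with known truth. This note documents the statistical
model, the generator, the numerical choices, and what the validation
studies do and do not establish.

## Association model

Within each family cluster the standardized trait is modelled as

    y ~ N(alpha + beta * g,  sigma^2 * V),   V = theta * K + (1 - theta) * I

where `g` is the expected allele count under the genetic model being
tested and `K = 2 * Phi` is the scaled pedigree kinship matrix (recursive
tabular computation; founders unrelated and non-inbred). Four models are
fit per variant:

* **additive** — `g` = paternal + maternal dosage (0..2);
* **recessive** — `g` = product of the haplotype dosages (the minor-hom
  indicator for hard calls), fit only when at least one minor-allele
  homozygote is observed;
* **paternal / maternal** — `g` = that haplotype's dosage alone (0..1).

`(alpha, beta, sigma^2)` are maximum-likelihood estimates obtained by
whitening each cluster in the eigenbasis of its `K` block, pooling, and
solving least squares (`sigma^2` uses divisor `n`, not `n - p`). The test
is the Wald chi-squared `(beta/se)^2` against chi-squared(1); all
P-values are two-sided. The paternal-versus-maternal contrast is a Wald
test of `b_p - b_m = 0` in the joint model with both haplotype dosages as
covariates (a joint fit, not a difference of marginal fits, so the null
distribution is exact), flagged untestable when the parental dosages are
collinear (r^2 > 0.999).

**The kinship variance share theta.** The covariance
proportional-to-kinship model (`theta = 1`) is exact only for a fully
heritable trait. Real traits carry a non-genetic variance share, and
using `K` alone overstates within-family correlation, which we measured
to inflate the parental and contrast tests (type-I ~0.07–0.08 at nominal
0.05 on a trio cohort with background heritability 0.8). The engine
therefore estimates `theta` once per trait by profile maximum likelihood
under the intercept-only model — a scalar optimization made cheap by the
per-cluster eigendecomposition — and uses `V(theta)` for every variant.
`theta = 1` remains the default when no estimate is requested. After this
change all three tests are calibrated (type-I 0.04–0.06 over 2,000 null
replicates).

**Clusters.** Exact GLS on a whole cohort is O(n^3); samples are split
into pedigree-connected clusters (connected components; components above
the size cap, default 2,000, are bisected by Kernighan–Lin with cut edges
logged) and the likelihood factorizes over clusters. Kinship is stored
block-diagonally by component, so unrelated cohorts cost O(n). Samples
missing a dosage are dropped per variant (complete case), never
mean-imputed.

## Phenotype standardization

Raw measurements are processed within strata (trait x sex x measurement
source; measured and self-reported values are corrected separately):
least-squares residualization on year of birth, then a rank-based inverse
normal transform with the Blom offset 3/8. Rank inverse-normal was chosen
over z-scoring because z-scores do not make an arbitrary distribution
normal; the year correction is linear (a nonparametric correction would
also be defensible; the simulated secular trends are linear). Strata
under 10 samples are excluded with a warning. Effects are reported in
s.d. units and converted to physical units by `effect * trait_sd` with
half-up rounding to one decimal; default trait s.d. are 6.6 cm (adult
height) and 2.5 cm (birth length).

## Calibration, thresholds, signals

**LD score regression.** Per model, chi-squared statistics are regressed
(unweighted least squares) on in-cohort LD scores (sum of r^2 over a
window, default 1 Mb, self included, computed from unordered additive
dosages; zero-variance variants excluded from both sides). The intercept
is the correction factor: `chi2 / cf` with P recomputed from the
chi-squared(1) tail — the classic genomic-control form. Intercepts below
1 are clamped to 1 unless deflation is explicitly allowed. An optional
`max_chi2` cut excludes large-effect outliers from the regression, needed
on small variant panels where single loci dominate; on such panels LD
partners of causal variants also leak true signal into the intercept
(mildly conservative), which a genome-scale panel's slope would absorb.
Whether corrected P should come from deflated chi-squared or inflated
standard errors is a free choice; the deflated-chi-squared route is
implemented.

**Class-specific Bonferroni.** The family-wise alpha = 0.05 is allocated
equally across variant impact classes (high / moderate / low) and
Bonferroni-corrected within class: `t_c = (alpha / n_classes) / N_c`.
Equal allocation reproduces, from the genome-wide class counts 9,989 /
170,692 / 31,421,778, the familiar thresholds 1.7e-6 / 9.8e-8 / 5.3e-10
at two significant figures; other allocations are supported through an
explicit weight map. Significance is strict (`P < t`), and unannotated
variants default to the most stringent class. Whether a significant
parent-of-origin signal's *opposite* parental allele also has an effect
is tested at 0.05 / (number of parent-of-origin signals).

**Conditional analysis.** Each region (±2 Mb around a genome-wide
significant lead) is scanned iteratively: the lead's dosage enters the
GLS as a covariate, all info > 0.9 variants in the region are retested,
any variant still genome-wide significant is appended to the conditioning
set, and the loop repeats until none remains. Conditioning covariates
are the additive dosages for the additive and recessive models; for the
parental models *both* haplotype dosages of each conditioning variant are
included — an additive covariate averages the haplotypes and leaves a
parental residue, while a single haplotype leaves the other's, and either
leak manufactures spurious "independent" signals. Ties on P break toward
the smaller genomic position.

**Classification.** Signals are classified against a reported-variant
catalogue (same model, ±500 kb): *novel* if no reported correlate reaches
r^2 >= 0.10 and conditioning on the nearby reported variants leaves the
signal genome-wide significant; *refinement* if a moderate correlate
exists (0.10 < r^2 < 0.80), the signal associates more strongly than
every reported correlate and absorbs them (their adjusted P >= 1e-3)
while they cannot fully account for it (its adjusted P < 1e-3);
*reported* otherwise. "More strongly" has no printed threshold in the
procedures this follows; it is implemented as a lower P than every
reported correlate. A catalogue variant absent from the genotypes makes
LD unknowable and forces a conservative *reported* call with a review
note.

**Variance explained.** One representative variant per independent
signal contributes the variance of its regressor: `2f(1-f)a^2`
(additive), `f_h(1-f_h)a_r^2` (recessive, `f_h` the minor-homozygote
frequency), and `f(1-f)(a_p^2 + a_m^2)` for parent-of-origin signals,
where a parental term enters only if that model's P < 1e-2 (otherwise it
is zeroed). The parental form is the variance of two independent
Bernoulli(f) haplotype regressors; the recessive and parent-of-origin
formulas are reconstructed from that regressor-variance logic.

## Imprinting diagnostics

Parental origin is deduced from trios by Mendelian logic (forced whenever
the child or at least one parent is homozygous; the triple heterozygote
is ambiguous and excluded; inconsistencies are flagged). The
non-transmitted-allele test runs four *separate* simple linear
regressions of the child's standardized trait on transmitted-paternal,
transmitted-maternal, non-transmitted-paternal and non-transmitted-
maternal allele counts over genotyped trios: genomic imprinting loads
only on the transmitted allele of the imprinted parent, while a
parental-genotype (e.g. in-utero) effect also appears on the
non-transmitted allele. Under the generator's per-allele
maternal-genotype parametrization the non-transmitted maternal slope
equals the per-allele effect (the mother's two alleles contribute
independently). Fewer than 30 informative trios flags low power but
still returns results. Ordered-genotype summaries report mean trait per
pat|mat genotype with 95% CI `mean ± 1.96 * se * sqrt(cf)`; the square
root on the correction factor is the adopted reading (the unrooted
variant is available via `sqrt_cf=False`), and the variant must have
imputation info > 0.8.

## Polygenic scores

Scoring is a plain weighted sum of effect-allele dosages (ref-allele
weights flip the dosage; mismatched alleles are skipped and counted;
missing dosages contribute the cohort mean). LD-aware re-weighting of
external summary statistics is out of scope — the weight table is an
input. Explained variance is the squared Pearson correlation from a
simple linear regression.

## Synthetic cohorts

The generator emulates the features the pipeline depends on, not human
demography:

* **Pedigrees** — founders with alternating sexes; each later generation
  pairs the previous one's males and females at random (avoiding full-sib
  matings when possible), a `mating_rate` fraction of possible couples
  mate, and family sizes are 1 + Poisson. Helper constructors give
  founder-only and independent-trio designs.
* **Haplotypes** — blockwise ancestor copying: variants in a block share
  an allele frequency (uniform on the MAF range) and each founder
  haplotype copies a latent block ancestor per site with mutation
  probability `mu`, giving within-block `r^2 = (1 - mu)^4` (so
  `target_r2` is exact in expectation and block size 1 gives independent
  variants). Mixed block-size patterns are supported to give LD scores a
  spread. Meiosis applies one uniform-position crossover per parent, and
  the child's paternal haplotype is the father's gamete, so parental
  origin is known exactly. Imputation info defaults to 1.0.
* **Phenotypes** — sum of causal effects (additive, recessive,
  paternal-only, maternal-only, opposing `a_p`/`a_m`, and an optional
  maternal-genotype effect applied per allele of the mother's genotype,
  with founders receiving its expectation to avoid a mean shift), a
  polygenic background transmitted as per-founder Gaussian half-values
  (inducing exactly the `h2 * K` covariance the engine must absorb), and
  Gaussian noise completing unit variance. The background defaults to
  `h2 = 0.8`, the commonly estimated narrow-sense heritability of adult
  height. Standardized values are mapped to cm through per-sex means
  (178.8 / 165.6 cm for the height analogue), the trait s.d., an optional
  secular year-of-birth trend, and a measured / self-reported source
  label, so the standardization module has real work to do. A second
  trait (birth-length analogue, s.d. 2.5 cm) shares the causal variants
  with effects scaled by a single factor.

Everything is driven by `numpy.random.default_rng(seed)`; a fixed seed
reproduces the cohort bit for bit.

**What the generator does not emulate:** population history and realistic
LD decay, imputation error beyond a scalar info attenuation, assortative
mating, X-linked inheritance, genotyping error, or ascertainment. Passing
tests therefore demonstrate the statistical machinery is correct under
its stated model, not that real-cohort complications are handled.

## Validation studies

The cohort behind the motivating scan is proprietary, so
`poegwas.validation` checks the pipeline by property at stated problem
sizes (chosen as the smallest at which each property is statistically
sharp): GLS equals the explicit-inverse formula to 1e-10 on <=50-sample
fixtures; type-I error of the additive, paternal and contrast tests is
0.04–0.06 over 2,000 null replicates on 400 trio families; a pure
paternal-imprinting effect is recovered within 2 s.e. on 10,000 trios
with null non-transmitted alleles; the opposing-effect condition
(a_p = −0.12, a_m = +0.056, f = 0.05, n = 90,000 unrelated samples)
yields a genome-wide significant paternal test but a non-genome-wide
additive test; the LDSC intercept recovers 1 under the null and a known
inflation factor after scaling, within 3 s.e.; the conditional scan
recovers two uncorrelated causals as two signals and collapses a causal
plus r^2 = 0.9 proxy to one in >= 95% of 200 replicates (phenotypes
redrawn every replicate, genotypes every 10); and recursive kinship
matches a 100,000-drop gene-dropping Monte Carlo within 3 s.e.
`scripts/acceptance.py` reruns these studies from scratch and writes the
measured numbers.

## Numerical choices and edge cases

* PSD jitter 1e-8 on near-singular kinship blocks; eigenvalues floored at
  the same jitter.
* Zero-variance dosages, monomorphic variants, and recessive tests with
  no observed minor homozygote are returned as untestable rows with a
  note, not errors; monomorphic *causal* variants in the generator are an
  error.
* Dosages are alt-allele oriented as stored; the generator draws alt
  frequencies <= 0.5, and the recessive testability check orients to the
  minor allele by empirical frequency.
* `sd_to_units` computes in decimal arithmetic so that half-up rounding
  is exact (0.86 x 2.5 = 2.15 -> 2.2 despite binary floats).
* BED intervals are 0-based half-open throughout; VCF positions are
  1-based and converted once at the boundary. The VCF phase convention is
  paternal-first on write and by declaration on read; trio deduction can
  override it.

## Known limitations

Cluster-splitting ignores kinship across cut edges (cuts are logged for
audit). The LDSC intercept is noisy on small variant panels and absorbs
some true polygenic signal there. `theta` is estimated once per trait,
not jointly per variant. The classification rules depend on the analysis
cohort's LD, so a catalogue variant's correlation is judged in-sample.
The generator's LD is blockwise-exchangeable rather than distance-
decaying, which makes LD-window choices less informative than they would
be on real data.
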