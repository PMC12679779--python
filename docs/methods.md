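# Methods

## Setting and model

The package targets the standard evaluation design for genomic selection
in a self-pollinated crop: a panel of inbred lines genotyped on a SNP
array and phenotyped in randomized complete blocks, repeated over years,
under two water regimes (rainfed WS, irrigated WW). Analyses run per trait
and regime; the combined regime (CWR) is the per-line mean of the WS and
WW line means, each regime weighted equally.

Plot-level data follow the linear mixed model

    y_ikj = mu + g_i + y_k + (gy)_ik + b_j(k) + e_ikj

with all non-intercept terms independent Gaussians: genotype
`g ~ N(0, sigma2_g)`, year `y ~ N(0, sigma2_y)`, genotype-by-year
`gy ~ N(0, sigma2_gy)`, block-within-year `b ~ N(0, sigma2_b)` and residual
`e ~ N(0, sigma2_e)`. Broad-sense heritability on an entry-mean basis is
`H2 = sigma2_g / (sigma2_g + sigma2_gy/e + sigma2_e/(r e))` for `e` years
and `r` blocks per year.

### REML implementation

Variance components are estimated by direct maximisation of the restricted
log-likelihood over the component vector (L-BFGS-B with box constraints
`[0, 50]` on a response rescaled to unit variance; the upper bound is far
above any plausible ratio). The objective builds the full n-by-n
covariance from the design-matrix outer products and uses one Cholesky per
evaluation; a 1e-10 diagonal jitter keeps the factorisation defined when
components hit zero, and estimates below 1e-8 (on the unit-variance scale)
are truncated to exactly zero. A method-of-moments (expected mean squares)
fit on balanced data provides warm starts and serves in the tests as an
independent estimator that REML must agree with whenever all moment
estimates are interior. Single-year data degrade gracefully: sigma2_y and
sigma2_gy are dropped from the model, returned as zero with a warning flag.

CWR heritability is estimated by the same model on regime-averaged plot
data (each genotype-year-block cell averaged over WS and WW). This is an
approximation — how genotype-by-year variance should be partitioned for a
pooled regime is not identified by the design — and is flagged as such.

GV/PV/EV for the variability table are mapped as GV = sigma2_g, PV = the
H2 denominator and EV = sigma2_e, which makes H2 = GV/PV an identity of
the table. Coefficients of variation are 100 sqrt(GV)/mean etc.

## Marker QC

Order is fixed: heterozygous-call masking, then the missingness filter
(strictly "more than" 30 %), then the MAF filter (>= 5 % kept, computed on
non-missing calls), then kNN imputation. Masked heterozygotes therefore
count toward missingness — a deliberate, order-sensitive choice asserted
by a fixture in the tests. Masking calls (rather than dropping every
column containing a heterozygote) is the default because column dropping
would remove far more markers than array attrition rates suggest; a
`het_mode="drop"` switch provides the stricter reading.

Imputation delegates to a k-nearest-neighbour imputer with nan-Euclidean
distance between lines over mutually observed markers (scaled by the
number of shared markers) and uniform weights over the K = 5 neighbours;
imputed values are rounded to the nearest homozygous dosage. Markers with
at most K observed donors fall back to the marker mode, logged. Observed
cells are never altered.

## Prediction models

All marker models fit on column-centred dosages. RKHS additionally
standardizes columns to unit variance (dropping monomorphic columns); the
tree learners see raw {0, 2} dosages (scale-invariant) and the SVR
standardizes inputs inside its pipeline.

**RR-BLUP.** `y = 1 mu + Z u + e`, `u ~ N(0, I sigma2_u)`. The restricted
likelihood is profiled over `delta = sigma2_e / sigma2_u` on the eigenbasis
of A'KA, where K = ZZ' and A is an orthonormal basis of the intercept's
complement (a Householder contrast — building the basis explicitly avoids
the degenerate-eigenspace pitfalls of projecting K and discarding one
eigenvector). The profile is maximised by bounded scalar search on
log-delta; the lower bound floors delta at 1e-6 times the top eigenvalue,
below which the profile is flat to rounding and the covariance numerically
singular. Effects follow from the mixed-model equations
`u = Z'(ZZ' + lambda I)^-1 (y - mu)`. The same routine fits any
line-by-line covariance (GBLUP, RKHS kernels); RR-BLUP/GBLUP equivalence
and the dual/primal ridge identity are enforced at 1e-8 in the tests.

**Bayesian alphabet.** Five single-site Gibbs samplers share one code
path: BRR (one common marker variance), Bayes A (per-marker
scaled-inverse-chi-square variances), Bayes B (spike at zero with
probability pi, t slab via per-marker variances), Bayes C (spike plus
common-variance Gaussian slab by default; `slab="t"` gives the
scaled-t-slab reading of that model, since published descriptions differ —
both are provided rather than adjudicated) and the Bayesian LASSO
(double-exponential prior through the normal scale mixture, with inverse-
Gaussian tau updates and a Gamma hyperprior on lambda^2). Hyperpriors use
conventional whole-genome-regression defaults: df = 5 scaled-inverse-
chi-square priors with scales set from the phenotypic variance assuming
R2 = 0.5 of it is genetic (the slab scale divided by 1 - pi0 for the
mixtures), and a weak Beta prior (count 10, mean 0.5) on pi, sampled
unless fixed. Chains default to 30,000 iterations with 10,000 burn-in;
tests and the desk-scale analyses run shorter chains because their checks
are oracle equivalences (e.g. the BRR posterior mean must match RR-BLUP
when variances are fixed), not chain-length benchmarks. Fixed seeds make
runs bit-reproducible; non-finite draws abort with the iteration index.

**RKHS.** `d2_ij = ||x_i - x_j||^2` on the standardized matrix,
`K = exp(-d2 / (2 h2))`. The bandwidth grid is interpreted on the squared
scale: candidate `h2 = factor x median(d2)` for factors {0.5, 1, 2, 4} —
the published grid mixes a bandwidth with a squared distance, and scaling
median(d2) directly is the reading that keeps the kernel argument
dimensionless. The factor is chosen by inner cross-validation (pooled
predictive correlation) on the training fold only; for a fixed kernel the
fit is the closed-form kernel-space ridge via the same spectral REML as
GBLUP, the BLUP equivalent of sampling this model.

**Machine learning.** Random forest, RBF-kernel SVR and gradient-boosted
trees are delegated to scikit-learn and xgboost and tuned by minimum RMSE
in inner CV strictly within the training partition. The forest's default
search space is depth {40, 60, 80, 100}, feature subsampling {p/3, sqrt(p)}
("auto" for regression is read as p/3) and {200, 300, 500, 1000} trees.
The SVR defaults to C = 1 with gamma = 1/(p var(X)) on standardized inputs
(no established wheat-GS convention exists for these; they are exposed for
overriding). XGBoost uses squared-error loss with lambda = 1, gamma = 0
regularisation and a compact depth/learning-rate/trees grid. Zero-variance
responses yield a constant predictor with a warning.

## Evaluation harness

KFCV is repeated random subsampling: each of `n_iterations` (default 150)
draws holds out 20 % of lines, the model refits on the rest and the
Pearson correlation and RMSE of the held-out predictions are recorded;
the reported r_MP is the mean over iterations (SD alongside). A strict
disjoint k-fold mode exists behind a flag. LOOCV pools the n out-of-fold
predictions and reports their single correlation (a per-fold correlation
is undefined at n = 1). Cross-condition runs train on all lines in one
regime and correlate predictions against the other regime's line means.

`r_MG = r_MP / sqrt(H2)` uses the regime's own H2 within-regime and the
**test** regime's H2 for cross-condition runs — the convention that
produces accuracies above 1 when pooled-regime training meets a
low-heritability test regime; such values are flagged, not clipped. Fold
splits and model seeds derive from one master seed through a hash-based
stream, so every run is reproducible in isolation. Constant predictions
make the correlation undefined; affected iterations are skipped and
counted (detected with a relative tolerance, since identical floats can
carry a ~1e-17 summation-rounding standard deviation). Report tables
average trait values rounded to two decimals, mirroring printed-table
arithmetic, with full-precision means alongside.

No tuning step ever sees validation phenotypes: models receive only the
training partition, and a leakage canary test (a marker column equal to
the phenotype on validation rows only) asserts that accuracy does not
inflate.

## Synthetic data: what it emulates and what it does not

`simdata` generates inbred-line dosages with per-marker allele frequencies
uniform on the configured MAF range, missing calls and residual
heterozygotes at their configured rates, and optional AR(1) block LD via a
latent Gaussian copula (off by default; imputation accuracy is only
meaningful with some LD). Phenotypes are built from the same mixed model
the analysis fits, with sigma2_g fixed at 1, sigma2_y / sigma2_gy /
sigma2_b set as ratios of it, and sigma2_e obtained by inverting the H2
formula — so the true components reproduce the target H2 exactly, and a
target exceeding the cap imposed by the genotype-by-year ratio is rejected.
Default ratios (year 1.0, genotype-by-year 0.25, block 0.25 relative to
genetic variance) reflect the year-dominated environmental variation of
rainfed Mediterranean trials. Genetic values are rescaled to have
population variance exactly sigma2_g, so recovery tests target the
realized, not just expected, architecture.

The two regimes draw per-marker effect pairs with correlation
`regime_cor` (default 0.84, the observed cross-regime consistency of
kernel weight). Note the consequence: `regime_cor` is a **genetic**
correlation, and observed line-mean correlations are attenuated by the
entry-mean heritability (approximately rho x H2 when both regimes share
one H2) — the tests assert 0.84 on true breeding values and the attenuated
value on line means. Effect families mirror the model priors (Gaussian,
scaled-t with 5 df, exact point-mass mixture with floor(pi x p) zeros,
Laplace), each standardized so the expected genetic variance is 1 before
rescaling.

Not emulated: population structure and families (the real germplasm mixes
cultivars with F6–F10 selections), dominance and epistasis, spatial field
trends, genotype-by-regime interaction beyond the effect correlation, and
trait-trait pleiotropy (multi-trait tables are built from independent
draws over shared genotypes). Phenotypes are unbounded Gaussians, so a
low-heritability trait with a realistic mean can produce negative plot
values; nothing downstream assumes positivity. Passing tests therefore
demonstrate correctness of the machinery under the stated generative
model, not performance claims about any particular field dataset.

## Desk-scale study conditions

The analysis scripts and the acceptance script run the pipeline at
150 lines x 1,000–2,000 markers, KFCV at 15–50 iterations, Bayesian chains
at a few hundred to 3,000 iterations, and tuned-model grids reduced to one
or two candidates; these sizes are the package's chosen desk-scale
conditions and are stated in each script. With 1,000 *independent* markers
the effective dimensionality far exceeds what array data in strong LD
presents, which depresses predictive ability for a fully polygenic trait;
the oligogenic settings (point-mass mixture, 5 % causal) used for the
kernel-weight- and protein-like traits restore an effective dimensionality
comparable to real panels and reproduce the magnitude and ordering of
accuracies seen in practice: LOOCV within a few hundredths of KFCV,
cross-regime ability tracking the genetic correlation, and CWR-trained
models exceeding r_MG = 1 on single-regime tests.

## Numerical choices

- REML optimizer tolerance is the L-BFGS-B default on a unit-variance
  response; H2 is invariant to response rescaling by construction.
- Spectral REML floors the variance-ratio search (see above) and treats a
  response with variance below 1e-14 (relative) as constant.
- kNN-imputed dosages round at 1.0 to the nearest of {0, 2}.
- Marker alignment at prediction is by marker ID: a consistent permutation
  is accepted and reordered, any set difference raises an error listing
  the offending IDs; nothing is silently reindexed.
- Mixture-model spike/slab log-odds are clamped at |35| before the
  logistic to avoid overflow; effects at markers with zero variance in the
  training fold are fixed at zero.

## Known limitations

- The Gibbs samplers are single-site and pure Python/NumPy: correct and
  reproducible, but not tuned for the 20,000-marker, 30,000-iteration
  scale of production runs.
- CWR variance components inherit the averaging approximation above.
- GCV/PCV-style coefficients assume strictly positive trait means.
- The REML mixed model assumes one observation per genotype-block cell
  and does not model spatial row/column trends.
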