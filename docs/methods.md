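# Methods

`patternherit` estimates the narrow-sense heritability of three
continuous colour-pattern traits measured from standardized dorsal
photographs ("swatches") of juvenile lizards raised in a split-clutch
thermal-treatment breeding design. This note documents the models, the
numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Colour-pattern metrics

A swatch is a rectangular 8-bit RGB crop of the dorsal surface with
image columns aligned to the longitudinal (head-to-tail) body axis.
After optional white balancing (per-channel linear scaling against a
white standard, rounded half-up), three response variables are
computed:

**Brightness.** The mean over pixels of
`(R/255 + G/255 + B/255)/3`, a dimensionless value in [0, 1]. It uses
all pixels of the swatch and is invariant to any spatial rearrangement.

**Colour classes.** Pixels are assigned to one of *k* colour classes
by k-means on their RGB triples (scikit-learn, 10 restarts, seeded;
best within-cluster sum of squares kept). Classes are relabelled in
decreasing centroid brightness, so label 1 is always the brightest
class and results do not depend on k-means' arbitrary cluster
numbering. *k* is either fixed for all images (typically 3 or 4) or
supplied per image from a manual-assessment table (2–5); the package
computes Pearson/Spearman concordance between the two schemes.

**Elongation.** Adjacent sampled-pixel pairs are tallied along both
axes at a configurable grid stride (default 1, i.e. every pixel): `N_LR`
transverse (left/right) pairs of which `T_LR` have differing class
labels, and `N_UD` longitudinal (up/down) pairs of which `T_UD`
differ. The literature defines the construct — elongation is high when
longitudinal transitions are rare relative to transverse ones, i.e.
when blotches fuse into lengthwise stripes — but no closed formula is
standard, so this package defines

    E = [(T_LR + 1) / (N_LR + 2)] / [(T_UD + 1) / (N_UD + 2)],

the add-one smoothed ratio of transverse to longitudinal transition
densities. The smoothing makes E finite for uniform maps, strictly
monotone in each tally, and exactly reciprocal under transposition
(`E(map) * E(mapᵀ) = 1`). The raw per-direction densities are emitted
alongside so any alternative definition can be derived downstream.
Values above 1 indicate lengthwise striping.

**Contrast.** The brightness of the brightest class centroid minus
that of the darkest, in [0, 1]. Centroid brightness (not per-pixel
extremes) is used, so contrast reflects the segmented pattern rather
than noise pixels.

## The animal model

Each metric is analysed separately with an identical mixed model

    y = Xβ + Z_a u_a + Z_dam u_dam + Z_pc u_pc + Z_oc u_oc + e,

where `u_a ~ N(0, A σ²_A)` are additive genetic values with A the
pedigree-derived additive relationship matrix, and dam identity,
parental cage and offspring cage are iid random intercepts. Fixed
effects are sampling year, age at photograph (days, uncentred), sex,
offspring and parental basking treatment, and the
sex × offspring × parental interaction with all lower-order terms —
ten coefficients including the intercept, with reference levels the
earliest year, female, and long-bask. Records with any missing
covariate are excluded (complete-case) with a logged count.
Narrow-sense heritability is the per-draw ratio

    h² = σ²_A / (σ²_A + σ²_dam + σ²_pcage + σ²_ocage + σ²_R).

**Pedigree algebra.** A is built by the tabular method over a
topologically sorted pedigree (unknown parents are founders; the
diagonal is 1 + F). A⁻¹ is assembled directly from pedigree structure
via the parent–offspring contribution rules with inbreeding, where the
Mendelian-sampling variance is `1 − 0.25(1+F_s) − 0.25(1+F_d)` for two
known parents (analogously for one or none); inbreeding coefficients
come from memoised recursive kinship. Cycles are reported with the
individuals involved.

**Gibbs sampler.** Each sweep draws (i) all location effects — β and
the four random-effect vectors — jointly from their Gaussian full
conditional via the mixed-model equations (one Cholesky factorisation
per sweep; A⁻¹ enters the animal block; β carries a near-flat Gaussian
prior, implemented as a 10⁻¹⁰ ridge on its block, i.e. prior variance
10¹⁰ × σ²_R), and
(ii) each variance from its scaled inverse-chi-square full
conditional: with prior scale V and degrees of freedom ν, a term with
q levels and scaled sum of squares SS updates as
`σ² = (νV + SS) / χ²(ν + q)` (the animal SS is `u_aᵀ A⁻¹ u_a`, the
residual SS is `eᵀe` with q = n). Default prior V = 1, ν = 0.002 per
component — very weak. A variance draw that underflows is floored at
`max(var(y)·10⁻¹², tiny)` and counted; a non-finite draw aborts with
its iteration index. Joint location sampling was chosen over
single-site updates for mixing; the stationary distribution is the
same either way.

**MCMC schedule.** The default mirrors the study protocol: 1,500,000
iterations, thinning 1,000, burn-in 1,000 (retained draws =
⌊(n_iter − burnin)/thin⌋). The burn-in is small relative to the chain
and is kept verbatim as the default; both are configurable, and all
bundled tests and the acceptance report use short profiles
(1,200–50,000 iterations) chosen so the whole suite runs on a single
CPU in minutes. The problem sizes used by the shipped benchmark are a
study-shaped design of ≈180 phenotyped offspring (≈390 location
effects) and a balanced half-sib validation design of 400 offspring
(40 sires × 2 dams × 5 offspring; ≈700 location effects).

**Posterior summaries.** Point estimates are posterior modes from a
Gaussian-kernel density estimate with the classic Silverman
rule-of-thumb bandwidth `0.9·min(sd, IQR/1.34)·n^(−1/5)` evaluated on
a 512-point grid (this is R's `bw.nrd0`, the convention behind the
usual reporting of animal-model posterior modes; scipy's built-in
"silverman" rule differs). Intervals are 95% highest-posterior-density
intervals — the narrowest window containing ⌈0.95 n⌉ sorted draws;
HPD was chosen over equal-tailed to match the reference convention for
skewed variance posteriors. `pMCMC = 2·min(#>0, #<0)/n`, floored at
1/n. Convergence diagnostics are the lag-1 autocorrelation of the
thinned chain and the Geweke z-score comparing the first 10% and last
50% of the chain, with segment variances from spectral density at
zero estimated by an AIC-selected Yule-Walker AR fit.

**REML cross-check.** An independent maximiser of the restricted
log-likelihood over the same five components (dense algebra,
L-BFGS-B on log-variances, asymptotic standard errors from the
numerical Hessian) validates the sampler: on balanced half-sib data
with all components equal to 1, Gibbs posterior means agree with REML
within three standard errors of the comparison, where the comparison
SE combines the chain's batch-means Monte-Carlo error with the REML
estimate's own asymptotic SE (the latter dominates; a chain-only SE
would shrink indefinitely with chain length while the posterior-mean
vs REML difference is a fixed finite-sample quantity).

## Synthetic data generator

The generator emulates the study conditions so that every stage is
testable without the deposited photographs:

* **Breeding design.** Adults are housed in cages of three females and
  one male; two seasons (years 2015/2016); dams breed in a season with
  probability 0.58 producing one clutch of 2–5 eggs (uniform); a
  fraction (default 0.15) of clutches are wild-conceived and receive a
  unique dummy founder sire (assuming full sibship within the clutch);
  6% of cages have their sire replaced between seasons, mirroring the
  study's re-pairing/paternity uncertainty. Offspring are split within
  clutch across the two basking treatments (split-clutch), sexed
  50/50 independently (constant incubation temperature de-confounds
  sex and temperature in the study system), aged uniform-integer on
  6–62 days at photography, and housed in offspring cages of 3–6
  within season × treatment. The paper reports neither clutch sizes
  nor breeding rates, so those defaults were chosen once to land on
  the printed totals: the defaults give ≈150–195 offspring from ≈33–39
  dams in 30 parental and ≈40 offspring cages.
* **Trait architecture.** Phenotypes are simulated from exactly the
  fitted model: gene dropping realises additive values down the
  pedigree (founders N(0, σ²_A); descendants parental mean plus a
  Mendelian deviation of variance `(σ²_A/2)(1 − (F_s + F_d)/2)`), so
  replicate covariances converge to A σ²_A without building dense A;
  dam/cage effects and residuals are iid normal. The study-like truth
  sets h² near the reported modes (0.16/0.18/0.23), intercepts and
  year/age coefficients near the reported coefficients, and total
  variances at realistic trait scales.
* **Swatch rendering.** An anisotropic Gaussian random field (white
  noise under a separable Gaussian filter with periodic boundaries;
  longitudinal/transverse correlation lengths in ratio `anisotropy`,
  geometric mean 4 px) is thresholded at equal-share quantiles into
  2–5 classes; class greys are evenly spaced so the pixel-mean
  brightness and the brightest-minus-darkest gap hit their targets
  exactly, then iid channel noise is added and clipped. Measured
  contrast tracks the class gap to ±0.02 and measured elongation
  tracks anisotropy nearly 1:1, so appearance targets double as ground
  truth for the metric stage.

What the generator does **not** emulate: real skin texture, shedding
cycles, chromatic (non-grey) variation, exposure/focus failures or any
photographic artefact beyond additive noise, temperature-dependent sex
determination, or sperm storage as an explicit paternity process.
Passing tests therefore demonstrate correctness of the estimation
machinery under the assumed model, not robustness to real-image
segmentation ambiguity or pedigree errors.

## Benchmark design and expectations

With ≈180 offspring the h² posterior is wide — in the bundled runs the
95% HPD intervals span several-fold ranges such as 0.06–0.41. Point
recovery at that size is noisy, and the meaningful guarantees are
interval coverage and null-case behaviour. The posterior mode in particular is bistable at
this sample size: depending on the data realisation and how long the
σ²_A chain lingers near zero, the kernel-density mode either sits at
the near-zero spike induced by the weak inverse-chi-square prior or
at an interior value near the truth. The posterior mean is the more
stable point summary and is reported alongside the mode in the
recovery output. The shipped benchmark checks that the 95% HPD
interval covers a true h² of 0.2 in at least 4 of 5 seeded replicates
and that the mean posterior mode under a true h² of 0 stays below 0.1.
The `recover` CLI subcommand exposes the full grid
(h² ∈ {0, 0.2, 0.5}, 20 replicates) for users with more time.

The recovery benchmark fits the *latent* simulated phenotypes. The
end-to-end `all` run instead measures traits from the rendered images,
so its heritabilities are attenuated by rendering and segmentation
noise — strongly for elongation (whose latent value passes through
the correlation structure of a random field), mildly for brightness
and contrast (which map almost losslessly onto image appearance).
This mirrors real studies: measurement error in the phenotype biases
h² toward zero, it does not inflate it.

## Known limitations

* The elongation statistic is this package's definition; published
  values computed with other adjacency-analysis software are on a
  different scale and should only be compared after rank
  transformation.
* The Gibbs sampler uses dense Cholesky factorisations sized by the
  number of location effects; it is comfortable to a few thousand
  individuals but not designed for large national pedigrees.
* The REML cross-check is dense in n and intended for n ≲ 2,000.
* Credible intervals are HPD; equal-tailed intervals from the same
  chains will differ for skewed posteriors.
* With the near-improper variance prior (ν = 0.002), chains for weakly
  identified components spend time near zero; the underflow floor
  guards the arithmetic but very small true variances are reported as
  such rather than exactly zero.
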