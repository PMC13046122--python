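# Methods

## The generative model and what the simulator emulates

`synthetic_trials` draws plot-level phenotypes from the additive model

    y_ijkl = μ(regime) + env_j + rep_k(j) + block_l(kj) + g_i + (ge)_ij + ε_ijkl

with independent Gaussian effects, except for the genotype effects, which
are drawn once per genotype with a Kronecker-structured covariance: a
trait × trait correlation matrix times a 2×2 regime block with cross-regime
correlation ρ (default 0.4).  Genotype and GxE effects are drawn once and
reused across replicates, so replicate-level data carry the correct
entry-mean covariance.

The default soybean screening configuration has 150 accessions, two water
regimes (WS, WW) each observed in two year-environments, three replicates
laid out as a rotated cyclic partition into 10 incomplete blocks of 15
(statistical balance, not field-plan optimality, is the goal), and nine
traits (D50F, D95M, FB, PH, NPP, NSPP, LS, HSW, GY).  Per trait and regime
the generator is parameterized by a (mean, residual CV%, H²%) triple typical
of tropical soybean screens — e.g. grain yield 859.49 kg/ha (CV 21.5%,
H² 43%) under stress vs 2324.26 kg/ha (CV 30.7%, H² 21.6%) well-watered, a
63% stress reduction.  Components are back-solved from the triple: σ²ε from
the CV, σ²ge = σ²ε/2 (a typical MET ratio), σ²g from the entry-mean
heritability identity; replicate and block variances are set to 0.1·σ²ε and
the environment (year) variance to 0.25·σ²ε — nuisance scales that affect
BLUE precision but not the targeted H².  The trait × trait genotype-effect
correlations encode the familiar structure of such panels: phenology traits
cluster (D50F–D95M 0.61), maturity trades off against seed weight and yield
(D95M–HSW −0.38, D95M–GY −0.28), canopy traits co-vary (PH–FB 0.5), yield
correlates with its components (GY–HSW 0.25, GY–NPP 0.21).  Lodging score is
truncated to its 1–5 scale after the Gaussian draw.

What the simulator does **not** emulate: spatial field trends, non-Gaussian
residuals, missing plots, genotype-specific stress sensitivity of variance
(only the mean shifts between regimes), and year × management interactions
beyond a single environment main effect + GxE term.  Passing tests therefore
demonstrate that the estimators and indices are computed correctly and
recover known parameters under the stated model — not that any particular
real accession ranking would be reproduced.  Quantities that depend on the
original unpublished plot data (specific heritability values, specific
selected accessions, specific correlations) are checked structurally, not
numerically.

## REML and the balanced-ANOVA oracle

Variance components come from EM-REML on Henderson's mixed-model equations
with all design terms random.  Defaults: relative convergence tolerance
1e-8, at most 500 iterations, negative solutions truncated to zero.  The
iteration is initialized at the balanced expected-mean-squares
(method-of-moments) solution; on balanced block-free data that solution *is*
the REML optimum whenever it is interior, so the EM start is exact there and
merely verified by the iteration, while on lattice data (incomplete blocks
non-orthogonal to genotypes) EM does the real work from a close start.  A
property test drives EM from a deliberately neutral equal-split start on
random balanced designs and confirms convergence to the ANOVA estimator to
1e-6 relative; a second oracle cross-checks against lme4's REML on a small
balanced layout.  Noise-free data (residual mean square numerically zero)
short-circuits to the exact ANOVA decomposition, because with σ²ε = 0 the EM
step is degenerate.  With a single environment the GxE component is not
estimable and is reported as zero with a warning.

Heritability uses the entry-mean formula with nEnv = environments within the
regime (2) and nRep = replicates (3); the CV is the residual CV of the
combined within-regime model.  The ANOVA table uses sequential sums of
squares (Env, Rep(Env), Gen, Env×Gen, Residual; incomplete-block variation
stays in the residual stratum) with expected-mean-squares denominators:
genotype over GxE, GxE over residual, environment over Rep(Env).

BLUEs are generalized-least-squares genotype means: genotype fixed (cell
means), nuisance terms random at their estimated components, one mixed-model
solve.  Their accuracy is bounded by √H² — the recovery test asserts the
correlation with true effects equals √H² within sampling error, which is the
correct attainable value (at H² = 0.67, ≈ 0.82).

## Index and rank-sum conventions

TOL and SSI are ranked ascending (small yield penalty ⇒ rank 1); all other
columns (Ys, Yp, STI, GMP, MP, HM, YSI, YI) descending.  Ties take average
ranks.  STI and GMP use their standard Fernandez forms, STI = YsYp/ȳp² and
GMP = √(YsYp).  SDR is the sample standard deviation (n−1) of a genotype's
ranks.  Selection size is round-half-up of g × intensity (150 × 0.20 = 30
exactly).  RS ties are broken by smaller rank mean, then label order, to
keep selections deterministic.

## MGIDI numerical choices

- Rescaling is the exact two-point linear map; both senses place the
  desirable end at 100, so the ideotype is the all-100 row.  Constant trait
  columns are rejected (the map is undefined).
- Factor extraction is the eigendecomposition of the trait correlation
  matrix; retention is strictly eigenvalue > 1 (boundary excluded); if
  nothing qualifies, one factor is kept with a warning.  Initial loadings
  are eigenvectors scaled by √eigenvalue, then varimax-rotated (the
  customary rotation for this index; MGIDI distances are invariant to any
  orthogonal rotation of the score space, which the tests exploit by
  checking distances against an unrotated transcription).
- The ideotype is standardized with the genotype column means/SDs — it is a
  reference point, not data, and does not perturb the factor model.
- R⁻¹ in the score equation gets a 1e-8 ridge only when the correlation
  matrix is near-singular (condition number > 1e8), so well-conditioned
  problems are solved exactly.
- Selection differentials are reported raw (SD% of the trait mean) and,
  when heritabilities are supplied, heritability-weighted (SD%·H²) — the
  raw differential is what the selection set achieves on adjusted means;
  the weighted one approximates expected genetic gain.
- A genotype exactly at the ideotype has distance 0 and undefined
  contribution shares; it is reported with a uniform ω row and a warning.

## Biplot and comparisons

The genotype × index biplot is the SVD of the column-standardized index
table (each index centered and scaled to unit SD), with axis variance =
squared singular value / total and symmetric scaling (both sides carry
√singular-value).  Standardization, rather than centering alone, keeps
dimensionless indices (SSI, YSI) commensurate with kg/ha ones.  Under the
symmetric scaling, angle cosines only approximate correlations; rescaling
the index coordinates by another √singular-value restores the column metric,
which is what the angle test does.  Venn regions are exact-membership counts
over all 2^k − 1 subsets, verified against brute-force enumeration.

## Problem sizes and runtime

Default analyses use the full 150-genotype, 16,200-record configuration;
parameter-recovery tests use 300 genotypes × 2 environments × 3 reps
(block-free, balanced), and oracle equivalence tests use ≤ 20 genotypes.
One full pipeline run (18 REML fits plus all downstream stages) takes on the
order of a minute on a laptop core; the mixed-model equations (~500–900
unknowns) are solved by dense Cholesky each EM sweep.

## Known limitations

- EM-REML is linearly convergent; components whose true value is near zero
  can converge slowly (the 500-iteration cap then triggers a warning).
  The EMS initialization makes this rare in practice.
- The EMS oracle applies only to balanced block-free layouts; with
  incomplete blocks REML and Henderson-III differ by design.
- Unbalanced data are accepted (the MME solve does not require balance) but
  the sequential ANOVA is order-dependent there and warns implicitly through
  its construction; severe unbalance is untested territory.
- The LS truncation slightly biases that trait's realized variance
  components relative to their nominal values; recovery tests use unbounded
  traits.
- The pipeline's yield-index stage requires both WS and WW regimes and
  positive yields; genotypes with non-positive fitted yields are excluded
  from the index table with a warning.
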