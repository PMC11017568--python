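# Methods

This note documents the statistical models implemented in echoscale, the
defaults and numerical choices behind them, what the synthetic generators
do and do not emulate, and the known limitations.

## Data model

Analyses operate on an `AlignedDataset`: a rooted phylogeny with branch
lengths whose tip set exactly matches a species-by-trait table.  The four
continuous traits — body mass (g), peak frequency (kHz), bandwidth (kHz),
call duration (ms) — are stored as log10 values; the raw inputs are kept
alongside for reporting.  Harmonization intersects species (matching is
case-sensitive after reconciling the space/underscore conventions of trait
tables and Newick), drops rows with missing or non-positive required
traits, prunes the tree, and emits a per-species report (kept/dropped with
reason) so the accounting `kept + dropped = input rows` always holds.

Emission type (nasal vs oral laryngeal call emission) can be given
explicitly or derived from taxonomic family: six families are classified
nasal (Hipposideridae, Megadermatidae, Nycteridae, Phyllostomidae,
Rhinolophidae, Rhinopomatidae) and twelve oral (Cistugidae,
Craseonycteridae, Emballonuridae, Furipteridae, Miniopteridae, Molossidae,
Mormoopidae, Mystacinidae, Myzopodidae, Natalidae, Noctilionidae,
Thyropteridae).  Any other family — including the non-laryngeal
Pteropodidae — is reported as *unclassified*, never silently defaulted; an
explicit `emission` column in the input takes precedence, which is also the
supported route for families outside these two lists (e.g.
Vespertilionidae, which carries an explicit value in any table this
package generates).

Ultrametricity is checked (warning above a relative tip-depth spread of
1e-6) but not required; zero-length terminal branches are allowed with a
warning since they remove a tip's independent variance.  Polytomies are
accepted and resolved to arbitrary zero-length bifurcations for contrast
computation, which leaves every Brownian-motion likelihood unchanged.

## PGLS with Pagel's λ

The regression residual covariance is σ²·C_λ with C[i,j] the shared
root-path length of tips i and j, and C_λ = λ·C off-diagonally with the
diagonal kept.  λ = 0 is an ordinary regression (exactly so on ultrametric
trees, where the diagonal is constant); λ = 1 is pure Brownian residual
structure.

Estimation details:

* **GLS core.**  Closed-form β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y via Cholesky solves;
  σ² profiled out (ML: RSS/n; REML: RSS/(n−p)).  The REML log-likelihood
  includes the log|XᵀV⁻¹X| − log|XᵀX| adjustment, making it invariant to
  the choice of design-matrix basis spanning the same column space.
* **λ profile.**  Coarse 0.05 grid over [0, 1] followed by bounded Brent
  refinement (tolerance 1e-6) around the best grid point, with both
  endpoints always candidates.  On ultrametric trees diag(C) = T·1, so
  C_λ = λC + (1−λ)T·I shares C's eigenvectors; after one rotation each
  profile point costs O(np²).  Non-ultrametric trees use the generic
  Cholesky path; both paths are tested equal.
* **Reported estimates** come from the REML-profiled fit; **model
  comparison** (AIC, LR tests, R²_lik) uses ML refits with λ re-profiled
  per model, because REML likelihoods are not comparable across
  fixed-effect structures.  AIC counts k = coefficients + λ + σ²; ties
  (ΔAIC < 1e-8) prefer fewer parameters.
* **Factors** use treatment coding with the alphabetically first level as
  reference ("nasal" before "oral"), reported explicitly.
* **Type-III tests** remove one term at a time with all others retained
  and compare ML fits by likelihood ratio against χ²(df = columns
  removed).  R²_lik = 1 − exp(−2(logL − logL₀)/n) against the
  intercept-only ML fit, clipped at zero.
* **Slope CIs** are Wald intervals β̂ ± z·SE from the REML fit; p-values
  are reported unadjusted across responses.

## Multivariate Brownian motion and the correlation posterior

Σ = α²·diag(ζ)·R·diag(ζ) with α² > 0, ζ > 0 constrained to mean 1 for
identifiability, and R a correlation matrix.  The likelihood is evaluated
through phylogenetically independent contrasts: each of the n−1 contrasts
is a zero-mean d-variate normal with covariance v_k·Σ, which integrates
the root state out (restricted likelihood) and — after caching the d×d
contrast scatter matrix — makes one likelihood evaluation O(d³) regardless
of tree size.  The dense C⊗Σ Kronecker evaluation is kept as a test
oracle and agrees to 1e-8 on all small trees tested.

Priors: α² log-uniform on [r̂/1000, r̂·1000] with r̂ the mean univariate
REML rate across traits (weakly informative, data-scaled); ζ/d symmetric
Dirichlet(1); R ~ LKJ(η), default η = 1 (uniform over valid correlation
matrices, so every pairwise correlation has a symmetric marginal centred
at zero — the scaled Beta(η+(d−2)/2, η+(d−2)/2) on (−1,1), which gives
the exact prior density at zero used by the Savage-Dickey ratio).

Sampler: one random move per generation — log-scale random walk on α²
(with the multiplicative Hastings correction), a two-coordinate mass
shift on the rate simplex, or a single-pair random walk on R rejecting
non-positive-definite proposals.  Proposal windows adapt toward 20–40%
acceptance during burnin only and are frozen afterwards, so the retained
chain is a valid fixed-kernel MCMC sample.  Default run settings are
5,000,000 generations, sampling every 1000, burnin 100,000 generations
(4900 retained samples); burnin is specified in generations so that
arithmetic is exact.  Everything is reproducible from a single integer
seed.

Summaries per trait pair: Gaussian-kernel posterior density (Silverman
bandwidth, boundary reflection at ±1), its highest-density mode, the
central 95% credible range, and the Savage-Dickey Bayes factor
BF = prior density at 0 / posterior density at 0 — reported in the
direction of evidence *against* zero correlation and labelled as such.
When the posterior density at zero underflows, the BF is reported as a
lower bound with a flag.

## Ancestral states

ML reconstruction under univariate BM by Gaussian belief propagation: an
upward pass contracts each subtree into a (mean, variance) message, a
downward pass combines each node's subtree message with the information
from the rest of the tree.  The root estimate equals the phylogenetically
weighted mean (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x; node variances are message-precision
inverses scaled by the contrast-REML rate σ̂².  Estimates are linear in
the data and match a dense joint-GLS solve to 1e-8 (and phytools'
reference implementation in a cross-check test).  Reconstruction is ML,
not Bayesian, matching its exploratory trait-mapping role; rendering of
gradient-painted trees is out of scope.

## Synthetic generators and what passing tests mean

The generators produce: Yule (pure-birth) trees with exactly n tips,
optionally rescaled to unit height; multivariate BM trait values with any
PSD Σ; and regression datasets whose predictor evolves by BM, whose
residuals are drawn from σ²·C_λ, and whose binary covariate is assigned
to the two clades flanking the root — deliberately clade-structured,
because emission type in real bats is phylogenetically clustered and this
is precisely the confounding a PGLS must handle.

Default study-shaped conditions (chosen once): 314 tips, unit-height
tree, log-mass BM rate 0.35 (tip spread ≈ 0.6 on the log10-gram scale,
matching the range of bats from ~3 g to ~150 g), residual σ² = 0.03
(slope standard errors ≈ 0.03), slopes −0.29 (peak frequency), −0.18
(bandwidth), +0.18 (duration), residual λ = 0.9, nasal/oral intercepts
2.09/1.94 (peak), equal (bandwidth) and 0.31/0.55 (duration).

What the generators do **not** emulate: real trait marginal distributions
beyond log-scale normality, intra-family covariance structure of emission
type (the synthetic covariate is a clean root split, the harshest
confounding case), extinction, measurement error, or missing data beyond
what harmonization tests construct.  Passing parameter-recovery tests
therefore demonstrates correctness of the estimators under their assumed
model, not robustness to violations of it.

Note on the clade-assigned covariate: because a root-split offset is
confounded with Brownian drift, its effective information content grows
slowly with n; power experiments in the test suite use offsets of ~3
standard errors for this reason, while calibration (null-effect) checks
use the defaults.

## Problem sizes and tolerances used in validation

Recovery experiments run at 300 tips × 100 replicates (slope), 500
replicates (CI coverage, nominal 0.95 ± 0.03), 200 replicates (type-III
size at α = 0.05 ± 0.03); correlation recovery at 100 tips with 200k
generations (mode within ±0.15 of −0.5, BF > 10) and 50 null replicates
at 40k generations (median BF < 3).  The LKJ marginal at zero is checked
against 10⁶ onion-method draws (2%), Savage-Dickey against a conjugate
normal closed form (10%), and all likelihoods against independent dense
oracles (1e-8–1e-10).  These sizes were chosen so the statistical
tolerances above are comfortably tighter than the corresponding Monte
Carlo noise.

## Known limitations

* Only Pagel's λ residual structure (no OU/ACDC alternatives).
* The Bayesian model handles continuous traits only; categorical
  predictors cannot enter the correlated-evolution analysis.
* No reversible-jump model search and no marginal-likelihood estimation
  beyond Savage-Dickey.
* No trait imputation: species missing a required trait are dropped and
  reported.
* The single-pair random-walk move on R is simple and adequate at d = 4
  but would mix slowly for much larger trait sets.
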