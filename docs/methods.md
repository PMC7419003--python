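# Methods

## Model

For subject i = 1..m with n_i repeated measures, the package models a
nonnegative response Y_ij through two layers of multiplicative random
effects and a log-linear regression:

* subject level: U_i i.i.d. Tweedie Tw_r(1, σ²), r ≥ 2, so E U_i = 1,
  var U_i = σ²;
* observation level: U_ij | U_i = u_i ~ Tw_t(u_i, ν² u_i^{1−t}), t ≥ 2, so
  E(U_ij | u_i) = u_i and var(U_ij | u_i) = ν² u_i at t = 2; ν² = 0 collapses
  U_ij ≡ U_i (the "one-level" structure);
* response: Y_ij | U ~ Tw_q(u_ij μ_ij, γ² u_ij^{1−q}) with
  μ_ij = exp(x_ij' β); q = 1 is the (quasi-)Poisson count case, and
  q ∈ {0, 2, 3} gives normal, gamma and inverse-Gaussian variance functions.

The scientific target is the conditional quantile model

    Q_τ(Y_ij | U) = U_ij exp(x_ij' β_τ),

estimated for each τ separately with the random effects replaced by their
best linear unbiased predictors (BLUPs) from the mean model.  Because
quantiles are equivariant to multiplication by a positive factor, the mean
model and every quantile model can share one set of random effects; the
package exploits this to avoid integrating the effects out.

## Orthodox BLUPs and dispersion estimation

With w_ij = 1/(γ² + ν² μ_ij^{2−q}), the moment-based (orthodox) BLUPs are

    Û_i  = (1 + σ² Σ_j w_ij μ_ij^{1−q} y_ij) / (1 + σ² Σ_j w_ij μ_ij^{2−q}),
    Û_ij = γ² w_ij Û_i + ν² w_ij μ_ij^{1−q} y_ij,

with mean squared prediction distances

    c_i  = σ² / (1 + σ² Σ_j w_ij μ_ij^{2−q}),
    c_ij = γ² w_ij (ν² + γ² c_i w_ij).

These are exact moment formulas, not likelihood approximations; the test
suite verifies on simulated data that E(Û_i − U_i)² = c_i and
E(Û_ij − U_ij)² = c_ij hold to Monte-Carlo accuracy.

The dispersion parameters are estimated by bias-adjusted Pearson moments:

    σ̂² = m⁻¹ Σ_i [(Û_i − 1)² + c_i],
    ν̂² = N⁻¹ Σ_ij [(Û_ij − Û_i)² + c_ij + c_i − 2 γ² c_i w_ij],
    γ̂² = N⁻¹ Σ_ij [(y_ij − Û_ij μ_ij)² / μ_ij^q + c_ij μ_ij^{2−q}].

All three are exactly unbiased under the model when evaluated at the true
parameters — this follows from the BLUP orthogonality cov(Û − U, Y) = 0 and
cov(Û − U, U) = −c, and is confirmed empirically in the tests.  Two details
are deliberate design choices:

* the γ̂² residual divides by the variance function μ^q (a Pearson
  statistic) and uses the observation-level predictor Û_ij with c_ij.  The
  variant built on the subject-level Û_i with c_i (available as
  `gamma2_mode="subject"`) estimates γ² + ν² μ^{2−q} — the reciprocal mean
  weight — rather than γ² itself, and is kept only for sensitivity
  analysis; with ν² = 0 the two coincide.
* moment estimators can go negative in small samples; σ̂² and ν̂² are
  floored at 0, and γ̂² at 1e−10.

Fixing any dispersion (e.g. γ² = 1 for a strict Poisson model) is supported
through `fix_sigma2` / `fix_nu2` / `fix_gamma2`.

## Mean-model fitting

β solves the plug-in estimating equation
Σ_ij x_ij μ^{1−q} (y − Û_ij μ)/γ² = 0 via Newton–Raphson with the
model-based sensitivity matrix S(β) (three terms: the quasi-GLM information
plus two corrections for the feedback of y on the BLUPs).  Each outer
iteration takes one Newton step, refreshes μ, the weights and BLUPs at the
new β, then refreshes the dispersions — in that order.  Iteration stops when
the maximum relative parameter change falls below `tol` (default 1e−8,
denominator |θ| + 1e−4), with `max_iter` 1000.

Initial values: β⁰ from an independence quasi-GLM (IRLS with variance μ^q),
γ²⁰ = Pearson statistic / df from that fit, σ²⁰ = ν²⁰ = 0.1.

Convergence caveats observed in simulation at m = 59: γ² and ν² trade off
along a flat ridge, so convergence is linear and occasionally slow
(hundreds of iterations), and a small fraction of samples drifts to the
degenerate boundary fixed point γ² = 0 (where Û_ij interpolates y exactly).
Replicates that fail to converge within the iteration budget are excluded
from simulation summaries and counted.

Standard errors for β̂ use the sandwich S⁻¹ V S⁻¹ with V the empirical
covariance of per-subject scores, inflated by the usual small-sample factor
m/(m − p).

## Quantile estimating equations

For residuals ε_ij = y_ij − U_ij μ_ijτ the raw estimating function weights
check-score signs ψ_τ(s) = τ − I(s < 0) by a working covariance:

    Ψ(β_τ) = Σ_i X_i' Δ_i Γ_i Σ_i(ρ)⁻¹ ψ_τ(ε_i),

with Δ_i = diag(Û_ij μ_ijτ), Γ_i a density weight (identity by default),
and Σ_i(ρ) = τ(1−τ) C_i(ρ) where C_i is a stationary Toeplitz correlation
matrix with lag parameters ρ_ℓ estimated from standardized residual signs
(clamped to ±0.95; the Toeplitz matrix is shrunk ρ ← 0.9ρ until its
smallest eigenvalue exceeds 1e−8).  The sign series is centered at its
overall mean before the lag products are formed: at the solution the signs
have mean zero and centering changes nothing, but during iteration the raw
moment would read a displaced β_τ's squared sign-mean as correlation, and
the resulting near-equicorrelation Σ⁻¹ supports a spurious stable root of
the weighted score with the fitted surface far above the data — the
centered (ordinary sample-autocorrelation) form removes that attractor.  ψ_τ is discontinuous, so the indicator
is smoothed with a normal CDF on the log scale (induced smoothing):

    ψ̃_τ components: τ − 1 + Φ(b_ij / r_ij),
    b_ij = log(y_ij / (Û_ij μ_ijτ)),  r_ij = sqrt(x_ij' Ω x_ij),

where Ω is a covariance-scale matrix for β_τ, so the smoothing bandwidth
shrinks at the estimator's own 1/√m rate.  The square root in r_ij makes
b/r a standardized argument (a flag restores the raw quadratic form for
sensitivity analysis).  Zero counts are the b → −∞ limit: the score
component is exactly τ − 1 and the density weight φ(b/r)/r is 0 — no
continuity correction is needed.

The Newton direction uses the Jacobian −Σ X'ΔΓΣ⁻¹Λ̃X with
Λ̃ = diag(φ(b/r)/r), which is the derivative of the smoothed score holding
Δ fixed (a Gauss–Newton convention; the omitted ∂Δ/∂β term is
score-weighted and vanishes at the solution).

Γ modes: `identity` (default — the density matrix treated as scalar) and
`difference-quotient`, which estimates f_ij(0) by
2 h_n / (exp(x'β̂_{τ+h}) − exp(x'β̂_{τ−h})) from two auxiliary fits, floored
at 1e−8, with h_n = m^{−1/3} by default, computed once (not re-estimated
per iteration).  For a scalar Γ the weight cancels from the sandwich, so
identity mode loses nothing asymptotically.

## Solver

`fit_quantile` alternates:

1. re-estimate ρ̂ from current residual signs and rebuild Σ_i;
2. solve the smoothed score equation in β_τ to convergence by damped
   Newton at fixed (ρ, Ω): ridge-regularized −J (the density matrix Λ̃ can
   be nearly rank-deficient when few records sit near their quantile), a
   step cap of 2 per coordinate (log scale), and step-halving on a
   scale-standardized score norm — standardized by the mean of the Δ
   diagonal, because the raw norm can be driven to zero trivially by
   μ_τ → 0;
3. check the relative change in β_τ.

The smoothing bandwidth matrix is held at its initial value Ω⁰ — the
mean-fit sandwich covariance, an O(1/m) matrix on the right scale — and the
quantile covariance Ω̃ = (−J)⁻¹ cov(Ψ̃) (−J)⁻¹ is computed once at the
solution.  Iterating Ω jointly with β_τ to a fixed point is unstable for
τ ≠ 0.5: growing Ω inflates the bandwidth, the Jacobian decays like 1/r
while the score covariance does not, and the map diverges (a symmetric
collapse attractor exists on the other side).  A damped fixed-point
iteration, where it converges, reproduces the one-step value.

Discrete responses make the ρ̂ ↔ β_τ alternation prone to tight limit
cycles: each iterate is an exact root at its own ρ̂, and the sign vector
flips between two patterns.  A drift-free cycle with relative amplitude
below 0.03 — far below the estimator's sampling noise — is accepted at its
mean after at least 50 outer iterations; anything larger is reported as
non-convergence.

cov(Ψ̃) is the empirical outer-product term plus a BLUP-uncertainty term
O Γ Σ⁻¹ Λ̃ C_i Λ̃ Σ⁻¹ Γ O propagating the prediction error of the plugged-in
effects; C_i = diag(c_ij) in the two-level model and C_i = c_i 11' (the full
matrix — one shared subject-level error) in the one-level model.

## Conditional vs unconditional standard errors

Ω̃ is a *conditional* covariance: it treats the mean-model parameters and
the BLUP prediction-error magnitudes as known, propagating only the
first-order effect-prediction term.  In simulation at m = 59 it understates
the replicate-to-replicate standard deviation of β̃_τ severely, because the
refitted mean model (β̂, σ̂², ν̂², and through them every Û_ij) varies between
samples.  The *unconditional* standard deviations are estimated by the
cluster bootstrap (`bootstrap_se`): subjects resampled with replacement,
the whole mean + quantile pipeline rerun per replicate (warm-started at the
original-data fit), SD over converged replicates, deterministic given a
seed.  Bootstrap SEs are the package's recommended basis for confidence
intervals on β_τ; the simulation study uses them wherever coverage of
quantile coefficients is evaluated, and reports asymptotic SEs (flagged in
the `SE_source` column) where the bootstrap is disabled for speed.

## Synthetic data and the pseudo-population study

The generator mimics the epilepsy seizure panel: per-subject Base =
log(quarter of a negative-binomial baseline count, moments matched to the
real data, mean ≈ 31 and variance ≈ 720, floored at 1 count), treatment
Bernoulli(0.5), Age = log of an integer uniform on [18, 42], Visit on the
centred linear codes (−0.3, −0.1, 0.1, 0.3), and the Base×Trt interaction.
Random effects are gamma (r = t = 2): U_i with mean 1 and variance σ², and
U_ij | u_i with mean u_i and variance ν² u_i.  The response is Poisson with
conditional mean u_ij exp(x'β); generation fixes γ² = 1 (the natural
Poisson dispersion) while estimation leaves γ² free.  Default true values:
β = (−1.30, 0.88, −0.88, 0.50, −0.23, 0.34), σ² = 0.24, ν² = 0.44.

The study generates one cohort of 10000 subjects (4 visits each) as a
pseudo-population, fits both dispersion structures on the full cohort for
reference values, then draws replicates of 59 subjects *without
replacement*, refits everything from the estimator's own initial values,
and summarizes per parameter, per τ, per structure: Bias (against the
pseudo-population fit — the generating truth is logged alongside), ESD
(mean of the per-replicate SEs, bootstrap or asymptotic as configured),
MC_SD (the replicate SD of the estimates) and CP (95% interval coverage of
the reference value).  Prediction-interval coverage for U_1 and U_11 uses
Û ± 1.96 √c with the corresponding mean squared distances; these intervals
are normal approximations to a skewed (gamma) prediction-error
distribution and are exact in neither shape nor — once the dispersions are
estimated at m = 59 — in scale, so their empirical coverage runs below
nominal for U_11.

What the generator does not emulate: dropout and missed visits (all
panels are balanced), covariate measurement error, time-varying treatment,
and any misspecification of the Tweedie layers — passing tests quantify
the method's behaviour *under the model*, plus the one deliberate
misspecification exercise of forcing ν² = 0 on two-level data.

## Numerical choices

* Linear predictors are clipped at ±30 before exponentiation.
* Relative convergence uses denominator |θ| + 1e−4 throughout.
* Quantile solves use `tol` 1e−8 (library default) and 1e−6 inside the
  simulation study; study replicate fits cap mean-model iterations at 1000.
* The reduced study defaults (the `reproduce-table2` command) use 100
  replicates without bootstrap; the acceptance pipeline uses 300 replicates
  with a 25-draw bootstrap at τ = 0.5 — sizes chosen so the whole study
  completes on a single CPU at desk scale.
* All randomness flows through `numpy.random.default_rng` seeds recorded in
  every artifact; replicate and bootstrap streams are derived sub-seeds.

## Known limitations

* Only gamma random effects (r = t = 2) are generated; the estimating
  equations themselves never need the Tweedie density constants, so other
  shapes affect only the simulator.
* Response generation supports q ∈ {0, 1}; fitting supports the variance
  functions q ∈ {0, 1, 2, 3}.
* The asymptotic Ω̃ is anti-conservative at small m (see above); use the
  bootstrap for inference.
* The γ² = 0 boundary is a genuine degenerate fixed point of the
  dispersion iteration; rare small-sample fits end there and are flagged
  by their convergence status rather than repaired.
* Quantile estimates at extreme τ on small counts are sensitive to the
  smoothing bandwidth convention (sqrt vs literal quadratic form); both are
  implemented, and the package makes no claim that its convention matches
  any particular historical analysis beyond the central quantiles.
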