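# Methods

## Model and hypotheses

The package works with the one-way fixed-effects ANCOVA model

    Y_ij = mu_i + X_ij' beta + eps_ij,    eps_ij ~ N(0, sigma^2) i.i.d.,

for groups i = 1..G (G >= 2), subjects j = 1..N_i, and P >= 1 covariates
with common slopes beta. Treatment effects are hypotheses C mu = 0 for a
c x G contrast C of full row rank with zero row sums (1 <= c <= G - 1).
Because the rows of C sum to zero, C mu = C mu* where mu* are the
adjusted means (expected responses at the grand covariate mean), so the
same contrast tests either parameterization.

Multi-factor designs are not given special bookkeeping: G can be read as
the number of combined factor-level cells, with the factorial structure
encoded through mu and C by the user.

## Estimation and the Wald test

Slopes are estimated by pooled within-group least squares,
beta_hat = S_XX^{-1} S_XY, where S_XX and S_XY accumulate
within-group-centred cross products; intercepts are
mu_hat_i = Ybar_i - Xbar_i' beta_hat, and SSE = S_YY - S_XY' S_XX^{-1} S_XY
with sigma2_hat = SSE / nu, nu = N_T - G - P. The covariance of mu_hat is
sigma^2 V with V = D + Xbar' S_XX^{-1} Xbar, D = Diag(1/N_i); the
adjusted means carry the analogous V* with Xbar centred at the grand
covariate mean. The Wald statistic is

    W = (C mu_hat)' (C V C')^{-1} (C mu_hat) / (c sigma2_hat),

and is identical when computed from (mu_hat*, V*) — the fit exposes both
forms and the tests assert their agreement. Under H0, W ~ F(c, nu).

The divisor is c, the contrast row count. For the omnibus contrast
c = G - 1, and only the divisor c is consistent with the null F(c, nu)
law for general contrasts, so the package uses c throughout.

Numerics: all matrix inverses are solve-based (no explicit inversion);
an S_XX condition number above 1e10 triggers a warning, and exact
singularity raises. Group labels are mapped to 1..G in first-appearance
order and recorded on the fit.

## Power functions

Fixed covariates: W ~ F(c, nu, Lambda) with
Lambda = (C mu)' (C V C')^{-1} (C mu) / sigma^2, and power
Psi(Lambda) = P{F(c, nu, Lambda) > F_{c,nu,alpha}}.

Random multinormal covariates X_ij ~ N_P(theta, Sigma): the
noncentrality becomes Lambda = Gamma * B with Gamma = N_T gamma^2,

    gamma^2 = (C mu)' (C Q C')^{-1} (C mu) / sigma^2,
    Q = Diag(1/q_i),  q_i = N_i / N_T,

and B ~ Beta((nu+1)/2, P/2). Neither theta nor Sigma enters — a fact the
Monte-Carlo suite verifies empirically. The exact power is

    Psi_E = E_B[ Psi(Gamma * B) ],

and for the omnibus contrast gamma^2 reduces to the weighted intercept
variance delta^2 = sum_i q_i (mu_i - mu~)^2 / sigma^2 (the f^2 analogue).
The general-contrast and omnibus paths share one implementation; the
delta^2 helper is a convenience wrapper, not a second engine.

Comparison methods:

* approximate (Cohen-style): Psi_A = Psi(N_T gamma^2) on (c, nu) degrees
  of freedom. Since 0 < B < 1, Psi_A >= Psi_E always, with strict
  inequality away from power saturation.
* ANOVA reference: Psi_O on (G-1, N_T-G) degrees of freedom with
  noncentrality (1 - rho^2) N_T delta^2, where rho is the multiple
  correlation between the response and the covariate combination;
  delta^2 stays defined against the ANCOVA error variance sigma^2 so a
  single effect specification serves all three methods.

### Quadrature

Psi_E is an expectation against a Beta density whose exponent at B -> 1
is b - 1 = P/2 - 1; for P = 1 the density is unbounded there. The
integral is therefore evaluated in quantile space,

    Psi_E = ∫_0^1 Psi(Gamma * Q_B(u)) du,

with Gauss–Legendre nodes on (0, 1), which absorbs the singularity into
the (smooth) quantile map. Default 128 nodes; the node count is doubled
until the estimate changes by less than 1e-6 (absolute), and a failure
to converge by 4096 nodes raises. Critical values come from the central
F inverse survival function and noncentral-F tails from scipy's ncf —
no series expansions are hand-rolled. Tables report powers rounded to 4
decimals; full precision is kept internally.

One table cell sits on a rounding knife-edge: the converged value for
the (N_T = 63, P = 1, delta^2 = 0.1684) cell is 0.811559, which rounds
to 0.8116 rather than the tabulated 0.8115; tests therefore assert
agreement to within one unit in the fourth decimal for that cell.

## Sample-size search

Given allocation ratios r_i (r_1 = 1), the solver scans N_1 upward in
steps of 1 from the smallest feasible design (all N_i >= 2, positive
error degrees of freedom), with N_i = ceil(N_1 r_i) — rounding up
guarantees the realized allocation never undershoots the nominal one —
and returns the first design whose power (exact, approximate, or ANOVA)
reaches the target. A linear scan rather than bisection is a deliberate
choice: power is empirically monotone in N_1 but ratio rounding can
create locally flat steps, and the scan is cheap at realistic sizes.
Every returned solution satisfies the minimality property (one fewer
subject per ratio unit misses the target), which the tests re-verify
independently. A configurable cap (default N_T = 1e6) turns the
divergent null-effect case into a clean error. The N_i >= 2 feasibility
floor is an implementation choice.

## Monte-Carlo validation

The simulation engine draws covariates from a configurable family,
generates responses from the model, fits the ANCOVA, and rejects when W
exceeds the central-F critical value. Defaults mirror the validation
protocol the analytic results are checked against: covariates i.i.d.
N_P(0, I_P), equal slopes beta* solved from the target correlation via

    beta*^2 (1' Sigma 1) / (beta*^2 (1' Sigma 1) + sigma^2) = rho^2,

10,000 replicates per design cell, and rejection fractions compared with
Psi_E / Psi_A / Psi_O (the result object reports analytic - empirical
errors and the binomial Monte-Carlo standard error).

Non-normal covariate families (exponential, gamma, Laplace, lognormal,
uniform, discrete uniform) are supported for robustness checks. Each is
linearly standardized to zero mean and unit variance using its analytic
moments before slopes are applied, so a given slope implies the same rho
across families. Default shape parameters (exponential scale 1, gamma
shape 2, lognormal sigma 1, uniform(0,1), discrete uniform on {1..5})
are explicit and configurable. Reproducibility uses one master seed with
counter-based per-replicate child streams (numpy SeedSequence spawn
keys), so each replicate is independent of execution order; replicates
with singular S_XX are redrawn from fresh streams and counted, and more
than 1% regeneration aborts the run.

What the simulations do and do not show: the generator draws exactly
from the model the power theory assumes (i.i.d. covariates, normal
homoscedastic errors, common slopes). Agreement between empirical and
analytic power therefore validates the distribution theory and the
implementation, not the model's fit to any real dataset — real studies
with slope heterogeneity, non-normal or dependent errors, or measurement
error in covariates are outside what these tests can certify. Variance
heterogeneity across groups is explicitly unsupported.

## Problem sizes in the test suite

Unit tests use replicate counts of 300–3,000; the acceptance-level
simulations (null size and the strongest-covariate power cell) use
10,000 replicates, matching the validation protocol. The
quadrature-vs-Monte-Carlo oracle uses 10^6 Beta draws per checked tuple,
at which the Monte-Carlo standard error is comfortably below the 3e-4
comparison tolerance.

## Known limitations

* Variance-heterogeneous ANCOVA, slope-by-treatment interaction tests,
  missing data, and robust/sandwich variants are out of scope.
* The approximate and ANOVA engines are included for comparison and
  planning continuity, not because they are recommended; the exact
  mixture method dominates them in accuracy.
* Power saturates numerically at 1 for large designs; strict
  exact-vs-approximate orderings are asserted only away from saturation.
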