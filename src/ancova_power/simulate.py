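"""Monte-Carlo engine for validating the analytic power formulas.

Datasets are generated from the ANCOVA model with covariates drawn from
a configurable family (multinormal plus several non-normal options), the
Wald test is applied to each replicate, and the rejection fraction is
compared against the exact, approximate and ANOVA power values for the
same design.

Non-normal covariate families are linearly standardized to zero mean and
unit variance (using their analytic moments) before the slopes are
applied, so a given slope vector implies the same response-covariate
correlation rho across families:

    rho^2 = beta' Sigma beta / (beta' Sigma beta + sigma^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import ContrastMatrix, DesignSpec, EffectSpec, effect_size_delta2
from .power import anova_power, approx_power, exact_power
from .wald import AncovaDataset, fit_ancova, wald_test

__all__ = [
    "CovariateModel",
    "SimulationSpec",
    "SimulationResult",
    "solve_equal_slope",
    "generate_dataset",
    "empirical_power",
]

FAMILIES = (
    "multinormal",
    "exponential",
    "gamma",
    "laplace",
    "lognormal",
    "uniform",
    "discrete_uniform",
)


@dataclass(frozen=True)
class CovariateModel:
    """Distribution from which the N_T x P covariate scores are drawn.

    ``theta``/``Sigma`` apply to the multinormal family; the other
    families draw each covariate i.i.d. with per-family parameters from
    ``family_params`` and, when ``standardize`` is set (the default for
    non-normal families), are shifted and scaled to zero mean and unit
    variance using the family's analytic moments.

    Default shape parameters: exponential scale 1; gamma shape 2, scale 1;
    laplace scale 1; lognormal sigma 1; uniform on (0, 1); discrete
    uniform on {1, ..., 5}.
    """

    family: str = "multinormal"
    P: int = 1
    theta: np.ndarray | None = None
    Sigma: np.ndarray | None = None
    family_params: dict = field(default_factory=dict)
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown covariate family {self.family!r}")
        if self.family == "multinormal":
            theta = (np.zeros(self.P) if self.theta is None
                     else np.asarray(self.theta, dtype=float))
            Sigma = (np.eye(self.P) if self.Sigma is None
                     else np.asarray(self.Sigma, dtype=float))
            if theta.shape != (self.P,):
                raise ValueError(f"theta must have length P={self.P}")
            if Sigma.shape != (self.P, self.P):
                raise ValueError(f"Sigma must be {self.P} x {self.P}")
            if not np.allclose(Sigma, Sigma.T):
                raise ValueError("Sigma must be symmetric")
            if np.any(np.linalg.eigvalsh(Sigma) <= 0):
                raise ValueError("Sigma must be positive definite")
            object.__setattr__(self, "theta", theta)
            object.__setattr__(self, "Sigma", Sigma)

    @property
    def effective_Sigma(self) -> np.ndarray:
        """Covariance of the scores actually fed into the model."""
        if self.family == "multinormal":
            return self.Sigma
        if self.standardize:
            return np.eye(self.P)
        m, v = self._moments()
        return v * np.eye(self.P)

    def _moments(self) -> tuple[float, float]:
        """Analytic (mean, variance) of one unstandardized draw."""
        p = self.family_params
        if self.family == "exponential":
            scale = p.get("scale", 1.0)
            return scale, scale**2
        if self.family == "gamma":
            shape, scale = p.get("shape", 2.0), p.get("scale", 1.0)
            return shape * scale, shape * scale**2
        if self.family == "laplace":
            scale = p.get("scale", 1.0)
            return 0.0, 2.0 * scale**2
        if self.family == "lognormal":
            s = p.get("sigma", 1.0)
            return math.exp(s**2 / 2), (math.exp(s**2) - 1) * math.exp(s**2)
        if self.family == "uniform":
            lo, hi = p.get("low", 0.0), p.get("high", 1.0)
            return (lo + hi) / 2, (hi - lo) ** 2 / 12
        if self.family == "discrete_uniform":
            lo, hi = p.get("low", 1), p.get("high", 5)
            k = hi - lo + 1
            return (lo + hi) / 2, (k**2 - 1) / 12
        raise AssertionError(self.family)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw an n x P matrix of covariate scores."""
        p = self.family_params
        if self.family == "multinormal":
            return rng.multivariate_normal(self.theta, self.Sigma, size=n)
        if self.family == "exponential":
            X = rng.exponential(p.get("scale", 1.0), size=(n, self.P))
        elif self.family == "gamma":
            X = rng.gamma(p.get("shape", 2.0), p.get("scale", 1.0), size=(n, self.P))
        elif self.family == "laplace":
            X = rng.laplace(0.0, p.get("scale", 1.0), size=(n, self.P))
        elif self.family == "lognormal":
            X = rng.lognormal(0.0, p.get("sigma", 1.0), size=(n, self.P))
        elif self.family == "uniform":
            X = rng.uniform(p.get("low", 0.0), p.get("high", 1.0), size=(n, self.P))
        elif self.family == "discrete_uniform":
            X = rng.integers(p.get("low", 1), p.get("high", 5) + 1,
                             size=(n, self.P)).astype(float)
        else:
            raise AssertionError(self.family)
        if self.standardize:
            m, v = self._moments()
            X = (X - m) / math.sqrt(v)
        return X


def solve_equal_slope(
    rho: float, P: int, sigma2: float, Sigma: np.ndarray | None = None
) -> float:
    """Common slope beta* such that beta = beta* 1_P yields correlation rho.

    Solves beta' Sigma beta / (beta' Sigma beta + sigma^2) = rho^2; for
    Sigma = I_P this is beta* = sqrt(rho^2 sigma^2 / ((1 - rho^2) P)).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    if Sigma is None:
        s = float(P)
    else:
        Sigma = np.asarray(Sigma, dtype=float)
        if np.any(np.linalg.eigvalsh(Sigma) <= 0):
            raise ValueError("Sigma must be positive definite")
        s = float(np.ones(P) @ Sigma @ np.ones(P))
    return math.sqrt(rho**2 * sigma2 / ((1.0 - rho**2) * s))


def implied_rho(beta: np.ndarray, Sigma: np.ndarray, sigma2: float) -> float:
    """Correlation between the response and the covariate combination X'beta."""
    bsb = float(beta @ Sigma @ beta)
    if bsb == 0.0:
        return 0.0
    return math.sqrt(bsb / (bsb + sigma2))


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to simulate one design cell reproducibly."""

    design: DesignSpec
    mu: np.ndarray
    sigma2: float
    beta: np.ndarray
    covariates: CovariateModel
    n_reps: int = 10_000
    seed: int = 0
    contrast: ContrastMatrix | None = None

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "beta", beta)
        if self.contrast is None:
            from .design import omnibus_contrast

            object.__setattr__(self, "contrast", omnibus_contrast(self.design.G))
        if len(mu) != self.design.G:
            raise ValueError("mu must have one intercept per group")
        if len(beta) != self.design.P:
            raise ValueError("beta must have one slope per covariate")
        if self.covariates.P != self.design.P:
            raise ValueError("covariate model P disagrees with the design")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.n_reps < 100:
            raise ValueError("need at least 100 replicates")

    @classmethod
    def from_rho(
        cls,
        design: DesignSpec,
        mu,
        sigma2: float,
        rho: float,
        covariates: CovariateModel | None = None,
        n_reps: int = 10_000,
        seed: int = 0,
        contrast: ContrastMatrix | None = None,
    ) -> "SimulationSpec":
        """Equal slopes solved so the implied correlation equals ``rho``."""
        if covariates is None:
            covariates = CovariateModel(family="multinormal", P=design.P)
        bstar = solve_equal_slope(rho, design.P, sigma2, covariates.effective_Sigma)
        return cls(design=design, mu=np.asarray(mu, float), sigma2=sigma2,
                   beta=np.full(design.P, bstar), covariates=covariates,
                   n_reps=n_reps, seed=seed, contrast=contrast)

    @property
    def rho(self) -> float:
        return implied_rho(self.beta, self.covariates.effective_Sigma, self.sigma2)

    @property
    def sigma2_Y(self) -> float:
        Sigma = self.covariates.effective_Sigma
        return float(self.beta @ Sigma @ self.beta) + self.sigma2


def _rep_rng(seed: int, rep_index: int) -> np.random.Generator:
    # counter-based child streams: independent of execution order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep_index,)))


def generate_dataset(spec: SimulationSpec, rep_index: int = 0) -> AncovaDataset:
    """Draw one dataset from the ANCOVA model under ``spec``.

    Replicate streams are seeded by (seed, rep_index), so each replicate
    is reproducible in isolation.
    """
    rng = _rep_rng(spec.seed, rep_index)
    sizes = spec.design.group_sizes
    N_T = spec.design.N_T
    X = spec.covariates.draw(rng, N_T)
    group = np.repeat(np.arange(1, spec.design.G + 1), sizes)
    eps = rng.normal(0.0, math.sqrt(spec.sigma2), size=N_T)
    y = spec.mu[group - 1] + X @ spec.beta + eps
    return AncovaDataset(group=group, y=y, X=X)


@dataclass(frozen=True)
class SimulationResult:
    empirical_power: float
    mc_se: float
    n_reps: int
    analytic_powers: dict  # {"exact": ..., "approx": ..., "anova": ...}
    errors: dict  # analytic - empirical, per method
    n_regenerated: int = 0


def empirical_power(spec: SimulationSpec, alpha: float | None = None) -> SimulationResult:
    """Rejection fraction of the Wald test over ``spec.n_reps`` replicates.

    Each replicate draws covariates, errors and responses, fits the
    ANCOVA model and rejects when W exceeds the central-F critical value.
    Replicates with singular S_XX are redrawn from a fresh stream and
    counted; more than 1% regeneration aborts.  The result carries the
    three analytic power values for the same design and their errors
    (analytic minus empirical).
    """
    design = spec.design
    if alpha is None:
        alpha = design.alpha
    elif alpha != design.alpha:
        design = DesignSpec(G=design.G, P=design.P,
                            group_sizes=design.group_sizes, alpha=alpha)
    crit = stats.f.isf(alpha, spec.contrast.c, design.nu)
    rejections = 0
    regenerated = 0
    max_regen = max(1, spec.n_reps // 100)
    for rep in range(spec.n_reps):
        attempt = rep
        while True:
            data = generate_dataset(spec, attempt)
            try:
                fit = fit_ancova(data)
            except np.linalg.LinAlgError:
                regenerated += 1
                if regenerated > max_regen:
                    raise RuntimeError(
                        "more than 1% of replicates had singular S_XX"
                    )
                attempt += spec.n_reps  # fresh, never-colliding stream
                continue
            break
        result = wald_test(fit, spec.contrast)
        if result.W_star > crit:
            rejections += 1

    p_hat = rejections / spec.n_reps
    mc_se = math.sqrt(p_hat * (1.0 - p_hat) / spec.n_reps)

    weights = design.weights
    eff = EffectSpec(mu=spec.mu, sigma2=spec.sigma2, weights=weights,
                     contrast=spec.contrast)
    d2 = effect_size_delta2(spec.mu, weights, spec.sigma2)
    analytic = {
        "exact": exact_power(design, eff).power,
        "approx": approx_power(design, eff).power,
        "anova": anova_power(design.N_T, design.G, d2, spec.rho, alpha).power,
    }
    errors = {k: v - p_hat for k, v in analytic.items()}
    return SimulationResult(
        empirical_power=p_hat,
        mc_se=mc_se,
        n_reps=spec.n_reps,
        analytic_powers=analytic,
        errors=errors,
        n_regenerated=regenerated,
    )
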