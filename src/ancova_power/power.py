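"""The four power functions for treatment-effect tests in one-way ANCOVA.

* ``fixed_covariate_power`` — power of the Wald test conditional on the
  covariate values, a plain noncentral-F tail probability.
* ``exact_power`` — the unconditional (random multinormal covariates)
  power: the expectation of the fixed-covariate power over the Beta
  mixing law of the noncentrality, evaluated by deterministic quadrature.
* ``approx_power`` — the conventional Cohen-style approximation that
  plugs the full noncentrality N_T * delta^2 into a single noncentral F;
  it always over-states the exact power because the mixing variable B
  lies strictly inside (0, 1).
* ``anova_power`` — the ANOVA reference method with error variance
  inflated back to sigma_Y^2 = sigma^2 / (1 - rho^2), i.e. noncentrality
  (1 - rho^2) * N_T * delta^2 on (G-1, N_T-G) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import roots_legendre

from .design import DesignSpec, EffectSpec, effect_size_gamma2

__all__ = [
    "PowerResult",
    "fixed_covariate_power",
    "beta_mixture_expectation",
    "exact_power",
    "approx_power",
    "anova_power",
]

DEFAULT_NODES = 128
_MAX_NODES = 4096
_QUAD_TOL = 1e-6


@dataclass(frozen=True)
class PowerResult:
    """Power value with the distributional bookkeeping behind it."""

    method: str  # {"fixed", "exact", "approx", "anova"}
    power: float
    df1: int
    df2: int
    noncentrality: float  # Gamma for "exact", Lambda otherwise
    quadrature_nodes: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0:
            raise ValueError(f"power outside [0, 1]: {self.power}")
        if self.df1 < 1 or self.df2 < 1:
            raise ValueError("degrees of freedom must be at least 1")


def fixed_covariate_power(c: int, nu: int, Lambda: float, alpha: float) -> float:
    """P{ F(c, nu, Lambda) > F_{c,nu,alpha} }.

    The power of the level-alpha Wald test when the covariate values (and
    hence the noncentrality Lambda) are fixed.  Reduces to alpha at
    Lambda = 0.
    """
    if c < 1 or nu < 1:
        raise ValueError(f"invalid degrees of freedom (c={c}, nu={nu}); design too small")
    if Lambda < 0:
        raise ValueError(f"noncentrality must be nonnegative, got {Lambda}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    crit = stats.f.isf(alpha, c, nu)
    if Lambda == 0.0:
        return alpha
    return float(stats.ncf.sf(crit, c, nu, Lambda))


def _beta_quantile_nodes(a: float, b: float, nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights for E[g(B)], B ~ Beta(a, b).

    The expectation is written as an integral over the uniform quantile
    u in (0, 1) of g(Q_B(u)); mapping through the Beta quantile function
    absorbs the endpoint singularity of the density at B -> 1 that occurs
    for b = P/2 <= 1 (in particular the single-covariate case b = 1/2).
    Weights sum to one by construction.
    """
    x, w = roots_legendre(nodes)
    u = 0.5 * (x + 1.0)
    return stats.beta.ppf(u, a, b), 0.5 * w


def beta_mixture_expectation(
    c: int,
    nu: int,
    Gamma: float,
    P: int,
    alpha: float,
    nodes: int = DEFAULT_NODES,
    tol: float = _QUAD_TOL,
) -> float:
    """Exact unconditional power: E_B[ P{F(c, nu, Gamma*B) > F_{c,nu,alpha}} ].

    B ~ Beta((nu+1)/2, P/2).  Evaluated by Gauss-Legendre quadrature in
    quantile space; convergence is confirmed by node doubling until the
    change drops below ``tol`` (raises if ``_MAX_NODES`` is reached first).
    """
    value, _ = _beta_mixture(c, nu, Gamma, P, alpha, nodes, tol)
    return value


def _beta_mixture(
    c: int, nu: int, Gamma: float, P: int, alpha: float,
    nodes: int, tol: float,
) -> tuple[float, int]:
    """Node-doubled quadrature; returns (value, nodes used)."""
    if Gamma < 0:
        raise ValueError(f"Gamma must be nonnegative, got {Gamma}")
    if P < 1:
        raise ValueError(f"need at least one covariate, got P={P}")
    if nodes < 16:
        raise ValueError(f"need at least 16 quadrature nodes, got {nodes}")
    if Gamma == 0.0:
        return alpha, nodes
    crit = stats.f.isf(alpha, c, nu)
    a, b = (nu + 1) / 2.0, P / 2.0

    def estimate(n: int) -> float:
        bvals, w = _beta_quantile_nodes(a, b, n)
        return float(w @ stats.ncf.sf(crit, c, nu, Gamma * bvals))

    value = estimate(nodes)
    while True:
        nodes *= 2
        refined = estimate(nodes)
        if abs(refined - value) <= tol:
            return refined, nodes
        if nodes >= _MAX_NODES:
            raise RuntimeError(
                f"quadrature did not converge to {tol} within {_MAX_NODES} nodes"
            )
        value = refined


def exact_power(
    design: DesignSpec, effect: EffectSpec, nodes: int = DEFAULT_NODES
) -> PowerResult:
    """Exact random-covariate power of the general linear hypothesis test."""
    _check_consistent(design, effect)
    gamma2 = effect_size_gamma2(effect)
    power, used = _beta_mixture(
        c=effect.contrast.c,
        nu=design.nu,
        Gamma=design.N_T * gamma2,
        P=design.P,
        alpha=design.alpha,
        nodes=nodes,
        tol=_QUAD_TOL,
    )
    return PowerResult(
        method="exact",
        power=power,
        df1=effect.contrast.c,
        df2=design.nu,
        noncentrality=design.N_T * gamma2,
        quadrature_nodes=used,
    )


def approx_power(design: DesignSpec, effect: EffectSpec) -> PowerResult:
    """Cohen-style approximate power at Lambda_A = N_T * gamma^2.

    Treats the covariates as if they contributed their full noncentrality,
    so this bounds the exact power from above.
    """
    _check_consistent(design, effect)
    Lambda_A = design.N_T * effect_size_gamma2(effect)
    power = fixed_covariate_power(effect.contrast.c, design.nu, Lambda_A, design.alpha)
    return PowerResult(
        method="approx",
        power=power,
        df1=effect.contrast.c,
        df2=design.nu,
        noncentrality=Lambda_A,
    )


def anova_power(
    N_T: int, G: int, delta2: float, rho: float, alpha: float
) -> PowerResult:
    """ANOVA omnibus power with the covariates folded into the variance.

    delta^2 is measured against the ANCOVA error variance sigma^2; since
    ANOVA works with sigma_Y^2 = sigma^2 / (1 - rho^2), the noncentrality
    is Lambda_O = (1 - rho^2) * N_T * delta^2 on (G-1, N_T-G) degrees of
    freedom.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if delta2 < 0:
        raise ValueError(f"delta2 must be nonnegative, got {delta2}")
    df2 = N_T - G
    Lambda_O = (1.0 - rho**2) * N_T * delta2
    power = fixed_covariate_power(G - 1, df2, Lambda_O, alpha)
    return PowerResult(
        method="anova", power=power, df1=G - 1, df2=df2, noncentrality=Lambda_O
    )


def _check_consistent(design: DesignSpec, effect: EffectSpec) -> None:
    if design.G != effect.G:
        raise ValueError(
            f"design has G={design.G} groups but effect has G={effect.G}"
        )
    if not np.allclose(design.weights, effect.weights, atol=1e-12):
        raise ValueError(
            "effect weights disagree with the design's allocation N_i / N_T"
        )
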