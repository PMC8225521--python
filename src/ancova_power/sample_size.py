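"""Minimum sample sizes attaining a target power under allocation ratios.

The search scans N_1 upward in steps of one from the smallest feasible
value, applying the a-priori ratios r_i = N_i / N_1 (r_1 = 1, fractional
sizes rounded up) and evaluating the chosen power function at the
realized design.  A linear scan is used deliberately: power is
empirically monotone in N_1 but ratio rounding can produce locally flat
or jagged steps, and the magnitudes involved make the scan cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignSpec, EffectSpec
from .power import anova_power, approx_power, exact_power

__all__ = ["SampleSizeResult", "solve_sample_size"]

_METHODS = ("exact", "approx", "anova")
_DEFAULT_CAP = 10**6


@dataclass(frozen=True)
class SampleSizeResult:
    method: str
    per_group_sizes: tuple[int, ...]
    N_T: int
    achieved_power: float
    target_power: float
    alpha: float
    iterations: int

    def __post_init__(self) -> None:
        if self.achieved_power < self.target_power:
            raise ValueError("achieved power below target; search is broken")
        if self.N_T != sum(self.per_group_sizes):
            raise ValueError("N_T must equal the sum of per-group sizes")


def _sizes_from_n1(n1: int, ratios: np.ndarray) -> tuple[int, ...]:
    # ceil guarantees the realized allocation never undershoots n1 * r_i
    return tuple(int(np.ceil(n1 * r - 1e-9)) for r in ratios)


def _power_at(
    method: str,
    sizes: tuple[int, ...],
    effect: EffectSpec,
    G: int,
    P: int,
    alpha: float,
    rho: float | None,
) -> float | None:
    """Power of the realized design, or None if the design is infeasible."""
    N_T = sum(sizes)
    if any(n < 2 for n in sizes):
        return None
    weights = np.asarray(sizes, float) / N_T
    eff = EffectSpec(mu=effect.mu, sigma2=effect.sigma2, weights=weights,
                     contrast=effect.contrast)
    if method == "anova":
        if N_T - G < 1:
            return None
        from .design import effect_size_delta2

        d2 = effect_size_delta2(eff.mu, eff.weights, eff.sigma2)
        return anova_power(N_T, G, d2, rho, alpha).power
    if N_T - G - P < 1:
        return None
    design = DesignSpec(G=G, P=P, group_sizes=sizes, alpha=alpha)
    engine = exact_power if method == "exact" else approx_power
    return engine(design, eff).power


def solve_sample_size(
    method: str,
    effect: EffectSpec,
    G: int,
    P: int,
    ratios,
    alpha: float,
    target_power: float,
    rho: float | None = None,
    cap: int = _DEFAULT_CAP,
) -> SampleSizeResult:
    """Smallest N_1 (hence N_i = ceil(N_1 r_i)) reaching ``target_power``.

    ``method`` is one of ``"exact"`` (Beta-mixture power), ``"approx"``
    (Cohen-style noncentral F) or ``"anova"`` (requires ``rho``, the
    response-covariate correlation that inflates the error variance back
    to sigma_Y^2).  Raises if the target is unreachable below a total
    sample size of ``cap`` — which happens exactly when the effect is null.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    if not alpha < target_power < 1.0:
        raise ValueError(
            f"target power must lie in (alpha, 1), got {target_power}"
        )
    if (rho is None) and method == "anova":
        raise ValueError("the anova method requires rho")
    r = np.asarray(ratios, dtype=float)
    if len(r) != G or not np.isclose(r[0], 1.0) or np.any(r <= 0):
        raise ValueError("ratios must be G positive values with r_1 = 1")
    if effect.G != G:
        raise ValueError(f"effect has G={effect.G} groups, expected {G}")

    n1 = 2
    iterations = 0
    while True:
        sizes = _sizes_from_n1(n1, r)
        if sum(sizes) > cap:
            raise RuntimeError(
                f"target power {target_power} unreachable below N_T = {cap}; "
                "is the effect size zero?"
            )
        power = _power_at(method, sizes, effect, G, P, alpha, rho)
        iterations += 1
        if power is not None and power >= target_power:
            return SampleSizeResult(
                method=method,
                per_group_sizes=sizes,
                N_T=sum(sizes),
                achieved_power=power,
                target_power=target_power,
                alpha=alpha,
                iterations=iterations,
            )
        n1 += 1
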