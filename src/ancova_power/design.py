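"""Design and effect-size objects shared by every power method.

The one-way ANCOVA model is

    Y_ij = mu_i + sum_k X_kij * beta_k + eps_ij,   eps_ij ~ N(0, sigma^2),

with G >= 2 treatment groups, P >= 1 covariates and group sizes
N_1..N_G (N_T = sum N_i, error degrees of freedom nu = N_T - G - P).
Hypotheses about treatment effects are expressed as C mu = 0 for a
full-row-rank contrast matrix C whose rows sum to zero.

The scalar effect size gamma^2 = sigma_gamma^2 / sigma^2 with

    sigma_gamma^2 = (C mu)' (C Q C')^{-1} (C mu),
    Q = Diag(1/q_1, ..., 1/q_G),  q_i = N_i / N_T,

drives every power computation through the noncentrality Gamma = N_T *
gamma^2.  When covariates are treated as multinormal random variables the
realized noncentrality is Lambda = Gamma * B with B ~ Beta((nu+1)/2, P/2);
:class:`NoncentralityLaw` captures that mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContrastMatrix",
    "DesignSpec",
    "EffectSpec",
    "NoncentralityLaw",
    "omnibus_contrast",
    "effect_size_gamma2",
    "effect_size_delta2",
    "noncentrality_law",
]

_ROWSUM_TOL = 1e-10


@dataclass(frozen=True)
class ContrastMatrix:
    """A c x G contrast matrix of full row rank with zero row sums."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.atleast_2d(np.asarray(self.entries, dtype=float))
        object.__setattr__(self, "entries", entries)
        c, G = entries.shape
        if not 1 <= c <= G - 1:
            raise ValueError(
                f"contrast must have between 1 and G-1 rows, got {c} rows for G={G}"
            )
        row_sums = entries.sum(axis=1)
        if np.any(np.abs(row_sums) > _ROWSUM_TOL):
            raise ValueError(f"contrast rows must sum to zero, got row sums {row_sums}")
        if np.linalg.matrix_rank(entries) != c:
            raise ValueError("contrast rows must be linearly independent")

    @property
    def c(self) -> int:
        """Number of contrast rows (numerator degrees of freedom)."""
        return self.entries.shape[0]

    @property
    def n_groups(self) -> int:
        return self.entries.shape[1]


def omnibus_contrast(G: int) -> ContrastMatrix:
    """Contrast encoding equality of all G group effects.

    Row i compares group 1 with group i+1, giving the (G-1) x G matrix
    (1_{G-1}, -I_{G-1}).  Testing C mu = 0 with this contrast is the
    omnibus test of no treatment differences.
    """
    if G < 2:
        raise ValueError(f"omnibus contrast needs at least two groups, got G={G}")
    entries = np.hstack([np.ones((G - 1, 1)), -np.eye(G - 1)])
    return ContrastMatrix(entries)


@dataclass(frozen=True)
class DesignSpec:
    """Group/covariate structure, sample sizes and significance level."""

    G: int
    P: int
    group_sizes: tuple[int, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_sizes", tuple(int(n) for n in self.group_sizes))
        if self.G < 2:
            raise ValueError(f"need at least two groups, got G={self.G}")
        if self.P < 1:
            raise ValueError(f"need at least one covariate, got P={self.P}")
        if len(self.group_sizes) != self.G:
            raise ValueError(
                f"expected {self.G} group sizes, got {len(self.group_sizes)}"
            )
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("every group needs at least two subjects")
        if self.nu < 1:
            raise ValueError(
                f"error degrees of freedom nu = N_T - G - P = {self.nu} < 1; "
                "design too small"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def balanced(cls, G: int, P: int, n_per_group: int, alpha: float = 0.05) -> "DesignSpec":
        return cls(G=G, P=P, group_sizes=(n_per_group,) * G, alpha=alpha)

    @classmethod
    def from_ratios(
        cls, G: int, P: int, n1: int, ratios: "np.ndarray | list[float]",
        alpha: float = 0.05,
    ) -> "DesignSpec":
        """Build sizes from N_1 and ratios r_i = N_i / N_1 (r_1 = 1).

        Fractional N_1 * r_i are rounded up so realized sizes never fall
        short of the nominal allocation.
        """
        r = np.asarray(ratios, dtype=float)
        if len(r) != G or not np.isclose(r[0], 1.0):
            raise ValueError("ratios must have length G with r_1 = 1")
        if np.any(r <= 0):
            raise ValueError("ratios must be positive")
        sizes = tuple(int(np.ceil(n1 * ri - 1e-9)) for ri in r)
        return cls(G=G, P=P, group_sizes=sizes, alpha=alpha)

    @property
    def N_T(self) -> int:
        return sum(self.group_sizes)

    @property
    def nu(self) -> int:
        """Error degrees of freedom N_T - G - P."""
        return self.N_T - self.G - self.P

    @property
    def weights(self) -> np.ndarray:
        """Allocation proportions q_i = N_i / N_T."""
        sizes = np.asarray(self.group_sizes, dtype=float)
        return sizes / sizes.sum()


@dataclass(frozen=True)
class EffectSpec:
    """Group intercepts, error variance, allocation and hypothesis contrast.

    ``weights`` are the allocation proportions q_i; when a concrete design
    exists they must equal N_i / N_T, and :func:`noncentrality_law` enforces
    that.  Free-standing weights are allowed in pure planning mode.
    """

    mu: np.ndarray
    sigma2: float
    weights: np.ndarray
    contrast: ContrastMatrix = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "weights", weights)
        if self.contrast is None:
            object.__setattr__(self, "contrast", omnibus_contrast(len(mu)))
        if self.sigma2 <= 0:
            raise ValueError(f"error variance must be positive, got {self.sigma2}")
        if len(weights) != len(mu):
            raise ValueError("weights and mu must have the same length")
        if np.any(weights <= 0) or not np.isclose(weights.sum(), 1.0):
            raise ValueError("weights must be positive and sum to 1")
        if self.contrast.n_groups != len(mu):
            raise ValueError(
                f"contrast has {self.contrast.n_groups} columns but mu has "
                f"{len(mu)} entries"
            )

    @classmethod
    def balanced(
        cls, mu, sigma2: float, contrast: ContrastMatrix | None = None
    ) -> "EffectSpec":
        G = len(mu)
        return cls(mu=np.asarray(mu, float), sigma2=sigma2,
                   weights=np.full(G, 1.0 / G), contrast=contrast)

    @property
    def G(self) -> int:
        return len(self.mu)

    @property
    def gamma2(self) -> float:
        return effect_size_gamma2(self)


def effect_size_gamma2(effect: EffectSpec) -> float:
    """Standardized effect size gamma^2 = sigma_gamma^2 / sigma^2.

    sigma_gamma^2 = (C mu)' (C Q C')^{-1} (C mu) with Q = Diag(1/q_i).
    Zero exactly when the contrast annihilates the intercepts (C mu = 0).
    """
    C = effect.contrast.entries
    Cmu = C @ effect.mu
    CQC = (C / effect.weights) @ C.T  # C Diag(1/q) C'
    try:
        sigma_g2 = float(Cmu @ np.linalg.solve(CQC, Cmu))
    except np.linalg.LinAlgError as err:  # full-rank C with q > 0 cannot get here
        raise ValueError("C Q C' is singular; contrast is malformed") from err
    return max(sigma_g2, 0.0) / effect.sigma2


def effect_size_delta2(mu, weights, sigma2: float) -> float:
    """Omnibus effect size delta^2, the ANCOVA analogue of ANOVA's f^2.

    delta^2 = sum_i q_i (mu_i - mu~)^2 / sigma^2 with mu~ = sum_i q_i mu_i;
    for equal weights this is the mean squared intercept deviation over
    sigma^2.  Coincides with gamma^2 under the omnibus contrast.
    """
    if sigma2 <= 0:
        raise ValueError(f"error variance must be positive, got {sigma2}")
    mu = np.asarray(mu, dtype=float)
    q = np.asarray(weights, dtype=float)
    mu_tilde = float(q @ mu)
    return float(q @ (mu - mu_tilde) ** 2) / sigma2


@dataclass(frozen=True)
class NoncentralityLaw:
    """Distribution of the random noncentrality Lambda = Gamma * B.

    B ~ Beta(beta_a, beta_b) with beta_a = (nu+1)/2 and beta_b = P/2 arises
    from averaging the fixed-covariate noncentrality over multinormal
    covariate draws; Lambda therefore lies in [0, Gamma].
    """

    Gamma: float
    beta_a: float
    beta_b: float

    def __post_init__(self) -> None:
        if self.Gamma < 0:
            raise ValueError(f"Gamma must be nonnegative, got {self.Gamma}")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta parameters must be positive")


def noncentrality_law(design: DesignSpec, effect: EffectSpec) -> NoncentralityLaw:
    """Noncentrality mixture implied by a design and an effect.

    Weights are rederived from the design's group sizes, so the effect's
    free-standing weights must agree with N_i / N_T.
    """
    if design.G != effect.G:
        raise ValueError(
            f"design has G={design.G} groups but effect has G={effect.G}"
        )
    if not np.allclose(design.weights, effect.weights, atol=1e-12):
        raise ValueError(
            "effect weights disagree with the design's allocation N_i / N_T"
        )
    gamma2 = effect_size_gamma2(effect)
    return NoncentralityLaw(
        Gamma=design.N_T * gamma2,
        beta_a=(design.nu + 1) / 2.0,
        beta_b=design.P / 2.0,
    )
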