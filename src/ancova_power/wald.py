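"""Least-squares ANCOVA fit and the Wald test of treatment effects.

The model Y_ij = mu_i + X_ij' beta + eps_ij is fitted by pooled
within-group least squares: the common slopes are beta_hat =
S_XX^{-1} S_XY where S_XX and S_XY accumulate within-group-centred
cross-products, and the intercepts are mu_hat_i = Ybar_i - Xbar_i' beta_hat.

The Wald statistic for the hypothesis C mu = 0 is

    W = (C mu_hat)' (C V C')^{-1} (C mu_hat) / (c * sigma2_hat),

with V = D + Xbar' S_XX^{-1} Xbar, D = Diag(1/N_i); under the null
W ~ F(c, nu), nu = N_T - G - P.  The identical value is obtained from the
adjusted means mu_hat*_i (the expected responses at the grand covariate
mean) and their covariance matrix V*, because the zero-row-sum contrast
annihilates the shift between the two parameterizations.

The divisor is c, the number of contrast rows; for the omnibus test
c = G - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ContrastMatrix

__all__ = [
    "AncovaDataset",
    "AncovaFit",
    "WaldTestResult",
    "fit_ancova",
    "wald_test",
]

_COND_WARN = 1e10


@dataclass(frozen=True)
class AncovaDataset:
    """One observation per row: group label, response y, covariates X.

    Group labels may be integers or strings; they are mapped to 1..G in
    first-appearance order by :func:`fit_ancova`.
    """

    group: np.ndarray
    y: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        group = np.asarray(self.group)
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        n = len(group)
        if len(y) != n or X.shape[0] != n:
            raise ValueError("group, y and X must have the same number of rows")
        if np.isnan(y).any() or np.isnan(X).any():
            raise ValueError("missing values are not supported")
        labels, counts = np.unique(group, return_counts=True)
        if len(labels) < 2:
            raise ValueError("need at least two groups")
        if counts.min() < 2:
            raise ValueError("every group needs at least two observations")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        group_col: str = "group",
        response_col: str = "y",
        covariate_cols: "list[str] | None" = None,
    ) -> "AncovaDataset":
        if covariate_cols is None:
            covariate_cols = [c for c in df.columns if c not in (group_col, response_col)]
        if not covariate_cols:
            raise ValueError("no covariate columns found")
        return cls(
            group=df[group_col].to_numpy(),
            y=df[response_col].to_numpy(dtype=float),
            X=df[covariate_cols].to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {"group": self.group, "y": self.y}
        for k in range(self.X.shape[1]):
            data[f"x{k + 1}"] = self.X[:, k]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class AncovaFit:
    """Least-squares estimates and the covariance structure of mu_hat."""

    group_labels: np.ndarray  # original labels in first-appearance order
    group_sizes: np.ndarray
    mu_hat: np.ndarray
    beta_hat: np.ndarray
    adjusted_means: np.ndarray
    sse: float
    sigma2_hat: float
    nu: int
    S_XX: np.ndarray
    S_XY: np.ndarray
    groupwise_covariate_means: np.ndarray  # G x P
    grand_covariate_mean: np.ndarray  # P
    V: np.ndarray
    V_star: np.ndarray

    @property
    def G(self) -> int:
        return len(self.group_labels)

    @property
    def P(self) -> int:
        return len(self.beta_hat)

    @property
    def N_T(self) -> int:
        return int(self.group_sizes.sum())


@dataclass(frozen=True)
class WaldTestResult:
    W_star: float
    df1: int
    df2: int
    p_value: float
    contrast: ContrastMatrix


def fit_ancova(data: AncovaDataset) -> AncovaFit:
    """Fit the common-slopes ANCOVA model by pooled within-group least squares."""
    labels, first_idx = np.unique(data.group, return_index=True)
    labels = data.group[np.sort(first_idx)]  # first-appearance order
    G = len(labels)
    N_T, P = data.X.shape
    nu = N_T - G - P
    if nu < 1:
        raise ValueError(
            f"error degrees of freedom nu = {N_T} - {G} - {P} = {nu} < 1"
        )

    sizes = np.empty(G, dtype=int)
    ybar = np.empty(G)
    xbar = np.empty((G, P))
    S_XX = np.zeros((P, P))
    S_XY = np.zeros(P)
    syy = 0.0
    for i, lab in enumerate(labels):
        mask = data.group == lab
        sizes[i] = mask.sum()
        yi = data.y[mask]
        Xi = data.X[mask]
        ybar[i] = yi.mean()
        xbar[i] = Xi.mean(axis=0)
        Xc = Xi - xbar[i]
        yc = yi - ybar[i]
        S_XX += Xc.T @ Xc
        S_XY += Xc.T @ yc
        syy += float(yc @ yc)

    cond = np.linalg.cond(S_XX)
    if not np.isfinite(cond):
        raise np.linalg.LinAlgError("S_XX is singular: collinear covariates")
    if cond > _COND_WARN:
        warnings.warn(
            f"S_XX condition number {cond:.2e} exceeds {_COND_WARN:.0e}; "
            "covariates are nearly collinear",
            stacklevel=2,
        )
    S_XX_inv_SXY = np.linalg.solve(S_XX, S_XY)
    beta_hat = S_XX_inv_SXY
    mu_hat = ybar - xbar @ beta_hat

    grand_mean = (sizes @ xbar) / N_T
    adjusted = ybar - (xbar - grand_mean) @ beta_hat

    sse = syy - float(S_XY @ beta_hat)
    sse = max(sse, 0.0)
    sigma2_hat = sse / nu

    D = np.diag(1.0 / sizes)
    # V = D + Xbar' S_XX^{-1} Xbar with Xbar the P x G matrix of group means
    Xbar = xbar.T
    V = D + Xbar.T @ np.linalg.solve(S_XX, Xbar)
    Xc = Xbar - grand_mean[:, None]
    V_star = D + Xc.T @ np.linalg.solve(S_XX, Xc)

    return AncovaFit(
        group_labels=labels,
        group_sizes=sizes,
        mu_hat=mu_hat,
        beta_hat=beta_hat,
        adjusted_means=adjusted,
        sse=sse,
        sigma2_hat=sigma2_hat,
        nu=nu,
        S_XX=S_XX,
        S_XY=S_XY,
        groupwise_covariate_means=xbar,
        grand_covariate_mean=grand_mean,
        V=V,
        V_star=V_star,
    )


def wald_test(
    fit: AncovaFit, contrast: ContrastMatrix, use_adjusted: bool = False
) -> WaldTestResult:
    """Wald test of C mu = 0 from a fitted model.

    ``use_adjusted`` switches to the mathematically equivalent form based
    on the adjusted means and V*; the value of the statistic is identical
    for any zero-row-sum contrast.
    """
    if contrast.n_groups != fit.G:
        raise ValueError(
            f"contrast has {contrast.n_groups} columns but the fit has {fit.G} groups"
        )
    C = contrast.entries
    if use_adjusted:
        Cm, CVC = C @ fit.adjusted_means, C @ fit.V_star @ C.T
    else:
        Cm, CVC = C @ fit.mu_hat, C @ fit.V @ C.T
    try:
        quad = float(Cm @ np.linalg.solve(CVC, Cm))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "C V C' is singular: degenerate design"
        ) from err
    c = contrast.c
    if fit.sigma2_hat == 0.0:
        raise ZeroDivisionError("residual variance is zero; Wald statistic undefined")
    W = quad / (c * fit.sigma2_hat)
    p = float(stats.f.sf(W, c, fit.nu))
    return WaldTestResult(W_star=W, df1=c, df2=fit.nu, p_value=p, contrast=contrast)
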