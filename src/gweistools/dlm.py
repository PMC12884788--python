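"""Distributed-lag detection of sensitive periods for gene-environment
interactions.

For a time-varying exposure measured annually at ages 1..18, the model

    y = mu + sum_j alpha_j E_j + sum_j gamma_j I_j + beta_G G + beta_C C + eps

relates the phenotype to the whole exposure history (E_j) and to the
age-specific interaction terms I_j = E_j * G.  Both lag curves are
constrained through a natural cubic spline with three degrees of freedom
(knots equally spaced on the lag scale), so the fit is an ordinary least
squares on the cross-basis transforms and the per-age interaction effects
gamma_j are reconstructed from the spline coefficients with pointwise Wald
95% confidence intervals.  A sensitive period is a maximal run of
consecutive ages whose CI excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LagBasis",
    "DlmFit",
    "PeriodFrequency",
    "build_lag_basis",
    "fit_dlm",
    "extract_sensitive_periods",
    "period_frequency",
    "truncate_lags_for_missingness",
]


@dataclass
class LagBasis:
    """Natural cubic spline basis over an integer lag grid."""

    lags: np.ndarray  # e.g. ages 1..18
    knots: np.ndarray
    C: np.ndarray  # (n_lags, df) basis matrix

    @property
    def df(self) -> int:
        return self.C.shape[1]


def _natural_spline(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural cubic spline basis (no intercept column).

    With K knots the natural-spline space has dimension K; excluding the
    constant leaves K-1 columns: the linear term plus K-2 curvature terms
    that are linear beyond the boundary knots.
    """
    K = len(knots)
    xi_K = knots[-1]
    xi_Km1 = knots[-2]

    def d(k: int) -> np.ndarray:
        return (
            np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - xi_K, 0, None) ** 3
        ) / (xi_K - knots[k])

    d_last = d(K - 2)
    cols = [x] + [d(k) - d_last for k in range(K - 2)]
    return np.column_stack(cols)


def build_lag_basis(n_lags: int = 18, df: int = 3) -> LagBasis:
    """Natural cubic spline basis over lags 1..n_lags with ``df`` columns.

    Boundary knots sit at the first and last lag; internal knots are
    equally spaced between them.  ``df`` columns require df+1 knots.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if n_lags < df + 1:
        raise ValueError("need n_lags >= df + 1")
    lags = np.arange(1, n_lags + 1, dtype=float)
    knots = np.linspace(1.0, float(n_lags), df + 1)
    C = _natural_spline(lags, knots)
    if np.linalg.matrix_rank(C) < df:
        raise ValueError("degenerate spline basis")
    return LagBasis(lags=lags, knots=knots, C=C)


@dataclass
class DlmFit:
    """Per-age lag effects reconstructed from the cross-basis OLS fit."""

    ages: np.ndarray
    alpha: np.ndarray  # exposure lag effects
    gamma: np.ndarray  # interaction lag effects
    gamma_se: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    flagged: np.ndarray  # CI excludes zero
    beta_g: float
    n: int
    lag_range: tuple[int, int]


def fit_dlm(
    y: np.ndarray,
    trajectories: np.ndarray,
    G: np.ndarray,
    C: pd.DataFrame | None = None,
    basis: LagBasis | None = None,
    min_n_per_param: int = 10,
    lag_offset: int = 0,
) -> DlmFit:
    """Fit the distributed-lag interaction model by cross-basis OLS.

    ``trajectories`` is (n, L) with the exposure at each age; rows with any
    missing year (or missing y/G/covariate) are dropped.  ``lag_offset``
    shifts the reported ages when early lags were truncated (ages become
    offset+1 .. offset+L).
    """
    y = np.asarray(y, dtype=float)
    E = np.asarray(trajectories, dtype=float)
    g = np.asarray(G, dtype=float)
    n_all, L = E.shape
    if basis is None:
        basis = build_lag_basis(L)
    if basis.C.shape[0] != L:
        raise ValueError("basis grid does not match the number of lags")
    c_arr = C.to_numpy(dtype=float) if C is not None else np.empty((n_all, 0))
    ok = (
        np.isfinite(y)
        & np.isfinite(g)
        & np.isfinite(E).all(axis=1)
        & np.isfinite(c_arr).all(axis=1)
    )
    n = int(ok.sum())
    df = basis.df
    n_params = 1 + 2 * df + 1 + c_arr.shape[1]
    if n < min_n_per_param * n_params:
        raise ValueError(
            f"insufficient sample: n={n} < {min_n_per_param} x {n_params} parameters"
        )
    ys, Es, gs_raw = y[ok], E[ok], g[ok]
    if gs_raw.std() == 0:
        raise ValueError("monomorphic variant")
    gs = (gs_raw - gs_raw.mean()) / gs_raw.std()
    W_a = Es @ basis.C  # exposure cross-basis
    W_t = (Es * gs[:, None]) @ basis.C  # interaction cross-basis
    X = np.column_stack([np.ones(n), W_a, W_t, gs, c_arr[ok]])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("degenerate cross-basis design (collinear lag structure)")
    coef, _, _, _ = np.linalg.lstsq(X, ys, rcond=None)
    resid = ys - X @ coef
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    a_hat = coef[1 : 1 + df]
    theta = coef[1 + df : 1 + 2 * df]
    cov_theta = cov[1 + df : 1 + 2 * df, 1 + df : 1 + 2 * df]
    gamma = basis.C @ theta
    gamma_se = np.sqrt(np.einsum("ij,jk,ik->i", basis.C, cov_theta, basis.C))
    ci_lo = gamma - 1.96 * gamma_se
    ci_hi = gamma + 1.96 * gamma_se
    flagged = (ci_lo > 0) | (ci_hi < 0)
    ages = np.arange(lag_offset + 1, lag_offset + L + 1)
    return DlmFit(
        ages=ages,
        alpha=basis.C @ a_hat,
        gamma=gamma,
        gamma_se=gamma_se,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        flagged=flagged,
        beta_g=float(coef[1 + 2 * df]),
        n=n,
        lag_range=(lag_offset + 1, lag_offset + L),
    )


def extract_sensitive_periods(fit: DlmFit) -> list[tuple[int, int]]:
    """Maximal runs of consecutive flagged ages as inclusive age windows."""
    windows: list[tuple[int, int]] = []
    start = None
    for age, flag in zip(fit.ages, fit.flagged):
        if flag and start is None:
            start = age
        elif not flag and start is not None:
            windows.append((int(start), int(age - 1)))
            start = None
    if start is not None:
        windows.append((int(start), int(fit.ages[-1])))
    return windows


@dataclass
class PeriodFrequency:
    """Per-age appearance counts of sensitive periods across interactions."""

    ages: np.ndarray
    counts: np.ndarray
    n_interactions: int


def period_frequency(
    windows_per_interaction: list[list[tuple[int, int]]],
    included: list[bool] | None = None,
    n_ages: int = 18,
) -> PeriodFrequency:
    """Count, for each year of age, how many interactions' sensitive periods
    cover it.

    ``included`` excludes interactions analyzed on truncated lag ranges
    (high-missingness exposures) from the profile.
    """
    if included is None:
        included = [True] * len(windows_per_interaction)
    counts = np.zeros(n_ages, dtype=int)
    n_used = 0
    for wins, keep in zip(windows_per_interaction, included):
        if not keep:
            continue
        n_used += 1
        for lo, hi in wins:
            if not (1 <= lo <= hi <= n_ages):
                raise ValueError(f"window [{lo}, {hi}] outside 1..{n_ages}")
            counts[lo - 1 : hi] += 1
    return PeriodFrequency(
        ages=np.arange(1, n_ages + 1), counts=counts, n_interactions=n_used
    )


def truncate_lags_for_missingness(
    trajectories: np.ndarray, min_n: int = 500
) -> tuple[np.ndarray, tuple[int, int]]:
    """Drop edge lags until the complete-case sample reaches ``min_n``.

    High-missingness exposures (satellite records that begin mid-childhood)
    lose whole early or late years; interior ages are never removed.  Each
    step drops whichever edge lag carries more missing cells, preferring
    the earliest on ties.  Returns the truncated array and the retained
    1-based inclusive lag range.
    """
    E = np.asarray(trajectories, dtype=float)
    L = E.shape[1]
    lo, hi = 0, L  # python slice bounds over retained lags
    while hi - lo > 0:
        n_complete = int(np.isfinite(E[:, lo:hi]).all(axis=1).sum())
        if n_complete >= min_n:
            return E[:, lo:hi], (lo + 1, hi)
        if hi - lo == 1:
            break
        miss_first = int(np.isnan(E[:, lo]).sum())
        miss_last = int(np.isnan(E[:, hi - 1]).sum())
        if miss_first >= miss_last:
            lo += 1
        else:
            hi -= 1
    raise ValueError(f"no lag range reaches complete-case n >= {min_n}")
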