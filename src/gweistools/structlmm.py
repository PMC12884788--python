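"""Multivariate gene-environment interaction verification with a
structured linear mixed model.

The model lets a variant's effect vary across individuals according to
their environmental similarity:

    y = X b + G beta_G + G (.) beta_GxE + e + psi

with e ~ N(0, sigma2_e * E E') a shared environment random effect,
psi ~ N(0, sigma2_n * I) noise, and the interaction random effect giving
covariance sigma2_gxe * diag(G) E E' diag(G).  Exposure columns are
standardized and the environment kernel E E' is trace-normalized to n so
variance components are on comparable scales.

The overall interaction is tested by the variance-component score test for
sigma2_gxe = 0; its null distribution is a weighted sum of 1-df chi-squares
whose weights are the nonzero eigenvalues of the projected kernel.  The
p-value uses Imhof's exact characteristic-function inversion with a Liu
moment-matching fallback.

Because the environment kernel has rank k = n_exposures << n, the null
REML fit works in the thin SVD of E: every likelihood evaluation is O(n k)
instead of O(n^3).  Per-exposure Bayes factors profile a rank-one
interaction component on top of the null fit via Sherman-Morrison updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.integrate import quad

__all__ = [
    "NullLmm",
    "ScoreTestResult",
    "VerificationResult",
    "fit_null_lmm",
    "score_test_gxe",
    "bh_fdr",
    "exposure_bayes_factors",
    "verify_interactions",
    "chi2_mixture_sf",
]


# ---------------------------------------------------------------------------
# weighted chi-square mixture survival function
# ---------------------------------------------------------------------------

def _liu_sf(q: float, lambdas: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching approximation to P(sum l_i chi2_1 > q)."""
    c1 = lambdas.sum()
    c2 = (lambdas**2).sum()
    c3 = (lambdas**3).sum()
    c4 = (lambdas**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    mu_x = df + delta
    sigma_x = np.sqrt(2) * np.sqrt(df + 2 * delta)
    return float(stats.ncx2.sf(t_star * sigma_x + mu_x, df, delta))


def chi2_mixture_sf(q: float, lambdas: np.ndarray) -> tuple[float, str]:
    """Survival function of a positively weighted sum of 1-df chi-squares.

    Imhof's exact inversion of the characteristic function, with the Liu
    moment-matching approximation as a numerical fallback.  Returns
    (p, method).
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-10 * max(lam.max(), 1e-300)]
    if lam.size == 0:
        return 1.0, "degenerate"
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], df=1)), "exact-1df"

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return np.sin(theta) / (u * rho)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val, err = quad(integrand, 0.0, np.inf, limit=200)
        p = 0.5 + val / np.pi
        if np.isfinite(p) and err < 1e-4 and -1e-8 <= p <= 1 + 1e-8:
            return float(min(max(p, 1e-300), 1.0)), "imhof"
    except Exception:  # pragma: no cover - quad failures fall through
        pass
    return max(_liu_sf(q, lam), 1e-300), "liu"


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

@dataclass
class NullLmm:
    """REML fit of the no-interaction structured LMM.

    Holds the rotated sufficient statistics needed by the score test and
    the Bayes-factor computation.  ``delta`` is sigma2_e / sigma2_n.
    """

    beta: np.ndarray  # GLS fixed effects for [X, G]
    sigma2_n: float
    sigma2_e: float
    delta: float
    reml_loglik: float
    converged: bool
    n: int
    # internal state (rotated representation)
    y: np.ndarray = field(repr=False, default=None)
    Xt: np.ndarray = field(repr=False, default=None)  # [X, G]
    G: np.ndarray = field(repr=False, default=None)
    E: np.ndarray = field(repr=False, default=None)  # standardized, / sqrt(k)
    U: np.ndarray = field(repr=False, default=None)  # left singular vectors of E
    s: np.ndarray = field(repr=False, default=None)  # eigenvalues of E E'

    def _m_apply(self, A: np.ndarray) -> np.ndarray:
        """(I + delta K)^{-1} A using the thin SVD of the kernel."""
        c = self.delta * self.s / (1.0 + self.delta * self.s)
        UA = self.U.T @ A
        if A.ndim == 1:
            return A - self.U @ (c * UA)
        return A - self.U @ (c[:, None] * UA)

    def p_apply(self, A: np.ndarray) -> np.ndarray:
        """REML projection P A = V^{-1}(A) - V^{-1}X(X'V^{-1}X)^{-1}X'V^{-1}A."""
        if A.ndim == 1:
            A = A[:, None]
            squeeze = True
        else:
            squeeze = False
        MA = self._m_apply(A)
        MX = self._m_apply(self.Xt)
        xmx = self.Xt.T @ MX
        out = (MA - MX @ np.linalg.solve(xmx, self.Xt.T @ MA)) / self.sigma2_n
        return out[:, 0] if squeeze else out


def _standardize_columns(E: np.ndarray) -> np.ndarray:
    mu = E.mean(axis=0)
    sd = E.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant exposure column cannot be standardized")
    return (E - mu) / sd


def _reml_neg_loglik(
    log_delta: float,
    yty: float,
    Xty: np.ndarray,
    XtX: np.ndarray,
    Uy: np.ndarray,
    UX: np.ndarray,
    s: np.ndarray,
    n: int,
) -> tuple[float, float, np.ndarray]:
    """Negative REML log-likelihood profiled over the scale, plus the
    profiled sigma2_n and GLS beta, for one value of delta."""
    delta = np.exp(log_delta)
    c = delta * s / (1.0 + delta * s)
    xmx = XtX - UX.T @ (c[:, None] * UX)
    xmy = Xty - UX.T @ (c * Uy)
    ymy = yty - Uy @ (c * Uy)
    sign, logdet_xmx = np.linalg.slogdet(xmx)
    if sign <= 0:
        return np.inf, np.nan, np.zeros_like(Xty)
    beta = np.linalg.solve(xmx, xmy)
    ypy = ymy - xmy @ beta
    p = XtX.shape[0]
    if ypy <= 0:
        return np.inf, np.nan, beta
    sigma2 = ypy / (n - p)
    logdet_v = n * np.log(sigma2) + np.sum(np.log1p(delta * s))
    logdet_x = logdet_xmx - p * np.log(sigma2)
    nll = 0.5 * (
        logdet_v + logdet_x + (n - p) + (n - p) * np.log(2 * np.pi)
    )
    return nll, sigma2, beta


def fit_null_lmm(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    G: np.ndarray,
    E: pd.DataFrame | np.ndarray,
    max_iter: int = 200,
) -> NullLmm:
    """REML fit of y ~ N([X, G] b, sigma2_e EE' + sigma2_n I).

    Rows with any missing value (including any exposure: the multivariate
    stage requires complete exposome data) are dropped.  E is
    column-standardized and the kernel EE' trace-normalized to n.  The
    variance ratio delta = sigma2_e / sigma2_n is profiled by bounded
    scalar optimization on the log scale.
    """
    y = np.asarray(y, dtype=float)
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    Ga = np.asarray(G, dtype=float)
    Ea = E.to_numpy(dtype=float) if isinstance(E, pd.DataFrame) else np.asarray(E, dtype=float)
    if Ea.ndim == 1:
        Ea = Ea[:, None]
    ok = (
        np.isfinite(y)
        & np.isfinite(Ga)
        & np.isfinite(Xa).all(axis=1)
        & np.isfinite(Ea).all(axis=1)
    )
    y, Xa, Ga, Ea = y[ok], Xa[ok], Ga[ok], Ea[ok]
    n, k = Ea.shape
    if Ga.std() == 0:
        raise ValueError("monomorphic variant")
    Es = _standardize_columns(Ea) / np.sqrt(k)  # trace(EE') = n
    if not np.allclose(Xa[:, 0], 1.0):
        Xa = np.column_stack([np.ones(n), Xa])
    Xt = np.column_stack([Xa, (Ga - Ga.mean()) / Ga.std()])
    p = Xt.shape[1]
    if n <= p + 2:
        raise ValueError("too few complete cases for the null LMM")

    U, d, _ = np.linalg.svd(Es, full_matrices=False)
    s = d**2
    yty = float(y @ y)
    Xty = Xt.T @ y
    XtX = Xt.T @ Xt
    Uy = U.T @ y
    UX = U.T @ Xt

    def obj(log_delta: float) -> float:
        return _reml_neg_loglik(log_delta, yty, Xty, XtX, Uy, UX, s, n)[0]

    # coarse grid then local refinement; include the delta -> 0 boundary
    grid = np.linspace(-12.0, 8.0, 41)
    vals = [obj(g) for g in grid]
    i0 = int(np.argmin(vals))
    lo = grid[max(0, i0 - 1)]
    hi = grid[min(len(grid) - 1, i0 + 1)]
    res = optimize.minimize_scalar(
        obj, bounds=(lo, hi), method="bounded", options={"maxiter": max_iter}
    )
    converged = bool(res.success)
    log_delta = float(res.x) if np.isfinite(res.fun) else grid[i0]
    nll, sigma2, beta = _reml_neg_loglik(log_delta, yty, Xty, XtX, Uy, UX, s, n)
    # boundary check: pure-noise model (delta ~ 0)
    nll0, sigma2_0, beta0 = _reml_neg_loglik(-30.0, yty, Xty, XtX, Uy, UX, s, n)
    if nll0 <= nll:
        log_delta, nll, sigma2, beta = -30.0, nll0, sigma2_0, beta0
    delta = float(np.exp(log_delta))
    if delta < 1e-10:
        delta = 0.0
    return NullLmm(
        beta=beta,
        sigma2_n=float(sigma2),
        sigma2_e=float(delta * sigma2),
        delta=delta,
        reml_loglik=float(-nll),
        converged=converged,
        n=n,
        y=y,
        Xt=Xt,
        G=Xt[:, -1],
        E=Es,
        U=U,
        s=s,
    )


# ---------------------------------------------------------------------------
# score test
# ---------------------------------------------------------------------------

@dataclass
class ScoreTestResult:
    Q: float
    p: float
    method: str
    n: int


def score_test_gxe(null: NullLmm) -> ScoreTestResult:
    """Variance-component score test for sigma2_gxe = 0.

    Q = 1/2 y'P K_g P y with K_g = diag(G) EE' diag(G); under the null Q is
    distributed as the weighted chi-square mixture with weights from the
    eigenvalues of 1/2 F'PF, F = diag(G) E.
    """
    if not null.converged:
        raise ValueError("null model did not converge")
    F = null.G[:, None] * null.E  # n x k, kernel factor
    Py = null.p_apply(null.y)
    half_score = F.T @ Py
    Q = 0.5 * float(half_score @ half_score)
    PF = null.p_apply(F)
    S = 0.5 * (F.T @ PF)
    lam = np.linalg.eigvalsh(S)
    lam = lam[lam > 0]
    p, method = chi2_mixture_sf(Q, lam)
    return ScoreTestResult(Q=Q, p=p, method=method, n=null.n)


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# per-exposure Bayes factors
# ---------------------------------------------------------------------------

def _restricted_loglik_rank1(
    null: NullLmm, u: np.ndarray, tau: float
) -> float:
    """REML log-likelihood with the rank-one interaction component
    tau * u u' added to the null covariance, null variance components held
    fixed (Sherman-Morrison / determinant-lemma update)."""
    sig = null.sigma2_n

    def a_inv(A: np.ndarray) -> np.ndarray:
        return null._m_apply(A) / sig

    y, Xt = null.y, null.Xt
    n, p = Xt.shape
    Aiy = a_inv(y)
    AiX = a_inv(Xt)
    Aiu = a_inv(u)
    uAu = float(u @ Aiu)
    denom = 1.0 + tau * uAu
    uy = float(u @ Aiy)
    uX = u @ AiX
    Viy = Aiy - (tau * uy / denom) * Aiu
    ViX = AiX - (tau / denom) * np.outer(Aiu, uX)
    xvx = Xt.T @ ViX
    xvy = Xt.T @ Viy
    sign, logdet_xvx = np.linalg.slogdet(xvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xvx, xvy)
    ypy = float(y @ Viy - xvy @ beta)
    logdet_v = (
        null.n * np.log(sig)
        + np.sum(np.log1p(null.delta * null.s))
        + np.log(denom)
    )
    return -0.5 * (logdet_v + logdet_xvx + ypy + (n - p) * np.log(2 * np.pi))


def exposure_bayes_factors(null: NullLmm, exposure_names: list[str] | None = None) -> pd.DataFrame:
    """Leave-one-in log Bayes factors: evidence that each single exposure
    drives the variant's overall interaction.

    For exposure k the interaction random effect is rebuilt from column k
    alone (rank-one kernel on G*E_k, trace-normalized); its variance is
    profiled with the null components held at their REML estimates, and
    BF_k is the restricted log-likelihood gain over the no-interaction
    null.  Rank 1 = largest BF; exact ties share the minimum rank and are
    flagged; zero-BF ties are ordered by the single-exposure score
    statistic (a continuous tie-break that preserves null symmetry).
    """
    k = null.E.shape[1]
    names = exposure_names if exposure_names is not None else [f"E{j:02d}" for j in range(k)]
    if len(names) != k:
        raise ValueError("exposure_names length mismatch")
    E_std = null.E * np.sqrt(k)  # undo the kernel normalization: unit-SD columns
    Py = null.p_apply(null.y)
    log_bf = np.empty(k)
    score = np.empty(k)
    flagged = np.zeros(k, dtype=bool)
    ll_null = null.reml_loglik
    for j in range(k):
        u = null.G * E_std[:, j]
        norm = np.linalg.norm(u)
        if norm == 0:
            log_bf[j] = -np.inf
            score[j] = 0.0
            flagged[j] = True
            continue
        u_n = u * (np.sqrt(null.n) / norm)  # trace-normalized rank-1 kernel
        score[j] = 0.5 * float(u_n @ Py) ** 2

        def nll(log_tau: float, u_n: np.ndarray = u_n) -> float:
            return -_restricted_loglik_rank1(null, u_n, np.exp(log_tau))

        try:
            grid = np.linspace(-10.0, 6.0, 17)
            vals = [nll(g) for g in grid]
            i0 = int(np.argmin(vals))
            res = optimize.minimize_scalar(
                nll,
                bounds=(grid[max(0, i0 - 1)], grid[min(len(grid) - 1, i0 + 1)]),
                method="bounded",
            )
            ll_tau = -float(res.fun)
            log_bf[j] = max(ll_tau - ll_null, 0.0)
        except Exception:
            log_bf[j] = -np.inf
            flagged[j] = True
    # ranking: BF descending, continuous score as tie-break, exact ties share min rank
    order_key = np.array(
        [(-log_bf[j], -score[j]) for j in range(k)],
        dtype=[("bf", float), ("score", float)],
    )
    order = np.argsort(order_key, order=("bf", "score"), kind="mergesort")
    rank = np.empty(k, dtype=int)
    pos = 1
    for idx, j in enumerate(order):
        if idx > 0:
            prev = order[idx - 1]
            if np.isclose(log_bf[j], log_bf[prev], atol=1e-12) and np.isclose(
                score[j], score[prev], rtol=1e-10, atol=1e-300
            ):
                rank[j] = rank[prev]
                flagged[j] = flagged[prev] = True
                continue
        rank[j] = idx + 1
    return pd.DataFrame(
        {
            "EXPOSURE": names,
            "LOG_BF": log_bf,
            "SCORE": score,
            "BF_RANK": rank,
            "TIED": flagged,
        }
    )


# ---------------------------------------------------------------------------
# verification rule
# ---------------------------------------------------------------------------

@dataclass
class VerificationResult:
    """Pair-level score-test verdicts and interaction-level verification."""

    pairs: pd.DataFrame  # PAIR, SCORE_P, Q, PAIR_VERIFIED
    interactions: pd.DataFrame  # PAIR, EXPOSURE, BF_RANK, N_SIG, VERIFIED


def verify_interactions(
    univariate: pd.DataFrame,
    score_results: pd.DataFrame,
    bf_tables: dict[str, pd.DataFrame],
    fdr_level: float = 0.05,
) -> VerificationResult:
    """Apply the two-stage multivariate verification rule.

    A variant-IDP pair is verified when its score-test BH-FDR q < the FDR
    level; an individual interaction is verified when its pair is verified
    AND its exposure's Bayes-factor rank is no larger than the number of
    univariate independent interactions found for the pair (n_sig).

    ``univariate`` needs columns PAIR and EXPOSURE (one row per independent
    interaction); ``score_results`` needs PAIR and SCORE_P;
    ``bf_tables`` maps PAIR to its exposure BF table.
    """
    sc = score_results.copy().reset_index(drop=True)
    sc["Q_FDR"] = bh_fdr(sc["SCORE_P"].to_numpy())
    sc["PAIR_VERIFIED"] = sc["Q_FDR"] < fdr_level
    n_sig = univariate.groupby("PAIR").size().rename("N_SIG")
    rows = []
    for _, rec in univariate.iterrows():
        pair = rec["PAIR"]
        hit = sc[sc["PAIR"] == pair]
        if hit.empty:
            raise ValueError(f"no score-test result for pair {pair!r}")
        pair_ok = bool(hit["PAIR_VERIFIED"].iloc[0])
        bf = bf_tables.get(pair)
        if bf is None:
            raise ValueError(f"no Bayes-factor table for pair {pair!r}")
        match = bf[bf["EXPOSURE"] == rec["EXPOSURE"]]
        if match.empty:
            raise ValueError(
                f"candidate exposure {rec['EXPOSURE']!r} absent from BF table of {pair!r}"
            )
        bf_rank = int(match["BF_RANK"].iloc[0])
        ns = int(n_sig[pair])
        rows.append(
            {
                "PAIR": pair,
                "EXPOSURE": rec["EXPOSURE"],
                "SCORE_P": float(hit["SCORE_P"].iloc[0]),
                "Q_FDR": float(hit["Q_FDR"].iloc[0]),
                "BF_RANK": bf_rank,
                "N_SIG": ns,
                "VERIFIED": pair_ok and bf_rank <= ns,
            }
        )
    return VerificationResult(
        pairs=sc,
        interactions=pd.DataFrame(rows),
    )
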