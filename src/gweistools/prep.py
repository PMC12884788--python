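"""Phenotype preparation: scanner harmonization, normal-score transform,
genetic principal components, and per-category covariate assembly.

Imaging phenotypes pooled across scanners carry additive and multiplicative
batch effects.  ``combat_harmonize`` removes them with the parametric
empirical-Bayes location/scale model (per-scanner effects shrunk toward
their across-feature prior), while preserving associations with protected
biological covariates.  Harmonized phenotypes are then mapped to normal
scores so downstream linear models see well-behaved margins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DosageMatrix, IdpMatrix

__all__ = [
    "combat_harmonize",
    "inverse_normal_transform",
    "compute_genetic_pcs",
    "assemble_covariates",
    "CATEGORY_NUISANCE",
]

#: Per-category nuisance covariate added to the base design (age, sex, PCs).
CATEGORY_NUISANCE: dict[str, str | None] = {
    "GMV": "TIV",
    "SA": "total_SA",
    "CT": "mean_CT",
    "Amp": "mean_FD",
    "FC": "mean_FD",
    "ReHo": "mean_FD",
    "FA": None,
}


def _eb_fit(
    g_hat: np.ndarray, d_hat: np.ndarray, n: int, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric empirical-Bayes shrinkage of one batch's per-feature
    location (g_hat) and scale (d_hat, variances) estimates.

    Priors: gamma ~ N(g_bar, t2), delta^2 ~ InverseGamma(lam, th) with
    hyperparameters moment-matched across features; solved by the standard
    fixed-point iteration.
    """
    g_bar = g_hat.mean()
    t2 = g_hat.var(ddof=1) if g_hat.size > 1 else 1.0
    v = d_hat.mean()
    s2 = d_hat.var(ddof=1) if d_hat.size > 1 else 1.0
    lam = (2 * s2 + v**2) / s2 if s2 > 0 else 3.0
    th = (v**3 + v * s2) / s2 if s2 > 0 else v
    g_star, d_star = g_hat.copy(), d_hat.copy()
    for _ in range(200):
        g_new = (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)
        ssq = (n - 1) * d_hat + n * (g_hat - g_new) ** 2
        d_new = (th + 0.5 * ssq) / (n / 2 + lam - 1)
        if np.max(np.abs(g_new - g_star)) < tol and np.max(np.abs(d_new - d_star)) < tol:
            g_star, d_star = g_new, d_new
            break
        g_star, d_star = g_new, d_new
    return g_star, d_star


def combat_harmonize(
    idps: IdpMatrix,
    protect: pd.DataFrame | None = None,
    min_scanner_n: int = 10,
) -> IdpMatrix:
    """Remove per-scanner location/scale batch effects (parametric EB ComBat).

    Protected covariates' associations are estimated jointly with the batch
    means, removed before batch-parameter estimation, and re-added to the
    harmonized values.

    Parameters
    ----------
    idps
        Phenotype matrix with per-participant scanner labels.
    protect
        Optional covariates (e.g. age, sex, TIV) whose biological signal
        must survive harmonization.
    min_scanner_n
        Minimum participants per scanner.
    """
    y = idps.values.to_numpy(dtype=float)
    scanners = np.asarray(idps.scanners)
    batches = pd.unique(scanners)
    if len(batches) < 2:
        raise ValueError("need >= 2 scanners to harmonize")
    counts = {b: int((scanners == b).sum()) for b in batches}
    small = [b for b, c in counts.items() if c < min_scanner_n]
    if small:
        raise ValueError(
            f"scanner(s) below minimum size {min_scanner_n}: {', '.join(map(str, small))}"
        )
    n, p = y.shape
    batch_onehot = np.column_stack([(scanners == b).astype(float) for b in batches])
    if protect is not None:
        if len(protect) != n:
            raise ValueError("protect covariates must align with participants")
        xp = np.column_stack(
            [
                (protect[c] - protect[c].mean()).to_numpy(dtype=float)
                for c in protect.columns
            ]
        )
        design = np.hstack([batch_onehot, xp])
    else:
        xp = np.zeros((n, 0))
        design = batch_onehot

    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    n_b = len(batches)
    batch_means = beta[:n_b]  # per-batch, per-feature
    cov_beta = beta[n_b:]
    props = np.array([counts[b] for b in batches], dtype=float) / n
    grand_mean = props @ batch_means  # weighted across batches
    fitted_cov = xp @ cov_beta
    resid = y - design @ beta
    var_pooled = (resid**2).sum(axis=0) / n
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    stand = (y - grand_mean[None, :] - fitted_cov) / np.sqrt(var_pooled)[None, :]
    adjusted = np.empty_like(y)
    for bi, b in enumerate(batches):
        rows = scanners == b
        zb = stand[rows]
        g_hat = zb.mean(axis=0)
        d_hat = zb.var(axis=0, ddof=1)
        d_hat = np.where(d_hat <= 0, 1e-12, d_hat)
        g_star, d_star = _eb_fit(g_hat, d_hat, counts[b])
        adjusted[rows] = (zb - g_star[None, :]) / np.sqrt(d_star)[None, :]
    harmonized = (
        adjusted * np.sqrt(var_pooled)[None, :] + grand_mean[None, :] + fitted_cov
    )
    return IdpMatrix(
        pd.DataFrame(harmonized, columns=idps.values.columns, index=idps.values.index),
        categories=idps.categories,
        scanners=idps.scanners,
    )


def inverse_normal_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based normal scores with the Blom offset.

    Maps value with (tie-averaged) rank r among n non-missing observations
    to ``Phi^{-1}((r - 3/8) / (n + 1/4))``.  Missing values stay missing.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need >= 3 non-missing values")
    if np.ptp(x[ok]) == 0:
        raise ValueError("constant column: all ranks tied")
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return out


def compute_genetic_pcs(genotypes: DosageMatrix, k: int = 10) -> pd.DataFrame:
    """Principal-component scores of the column-standardized dosage matrix.

    Scores are orthonormal (unit-norm columns); sign convention: the
    largest-magnitude variant loading of each component is positive.
    Monomorphic variants are dropped before standardization.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= min(genotypes.n_participants, genotypes.n_variants) + 1:
        raise ValueError("k must be < min(participants, variants)")
    g = genotypes.dosages
    sd = g.std(axis=0)
    keep = sd > 0
    z = (g[:, keep] - g[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k]
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, columns=[f"PC{j + 1}" for j in range(k)])


def assemble_covariates(base: pd.DataFrame, idp_category: str) -> pd.DataFrame:
    """Per-category nuisance design: age, sex, 10 genetic PCs, plus the
    category's imaging covariate (TIV for GMV, total surface area for SA,
    mean cortical thickness for CT, mean framewise displacement for the
    functional categories; none for FA).
    """
    if idp_category not in CATEGORY_NUISANCE:
        raise ValueError(f"unknown IDP category {idp_category!r}")
    cols = ["age", "sex"] + [f"PC{j + 1}" for j in range(10)]
    extra = CATEGORY_NUISANCE[idp_category]
    if extra is not None:
        cols.append(extra)
    missing = [c for c in cols if c not in base.columns]
    if missing:
        raise ValueError(f"missing required covariate column(s): {', '.join(missing)}")
    design = base[cols].astype(float)
    if design.isna().any().any():
        raise ValueError("covariate matrix contains missing values")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    return design
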