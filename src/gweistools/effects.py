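"""Main-effect models, eta-squared variance decomposition, rank-sum
comparisons of variance shares, genotype-subgroup post-hoc analyses, and
interaction-density summaries.

The central contrast this module supports: a variant-exposure pair can
carry a genome-wide significant interaction while both its genetic and
environmental main effects are negligible, and the interaction's
eta-squared (share of phenotype variance) exceeds the main-effect shares.
Main effects are therefore estimated in separate models (significance of
main-effect terms inside an interaction model depends on arbitrary variable
coding):

    genetic:        y = mu + beta_G x_G + beta_C x_C + eps
    environmental:  y = mu + beta_E x_E + beta_C x_C + eps
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod

import numpy as np
import pandas as pd
from scipy import stats

from .gweis import InteractionModelFit

__all__ = [
    "VarianceShare",
    "SubgroupAnalysis",
    "GENOTYPE_BINS",
    "bonferroni_threshold",
    "main_effect_models",
    "eta_squared",
    "compare_variance_shares",
    "genotype_subgroups",
    "interaction_density",
]

#: Hard-call dosage bins (inclusive): homozygous ref, heterozygous, homozygous alt.
GENOTYPE_BINS = ((0.0, 0.2), (0.8, 1.2), (1.8, 2.0))


@dataclass
class VarianceShare:
    """Share of phenotype variance attributable to one model term.

    eta2 = Var_effect / Var_T, with Var_effect the add-last (partial)
    sum of squares of the term in the full model and Var_T the total
    (mean-centered) sum of squares.
    """

    eta2: float
    var_effect: float
    var_total: float
    kind: str

    def __post_init__(self) -> None:
        if not (0 <= self.eta2 <= 1 + 1e-12):
            raise ValueError("eta-squared must lie in [0, 1]")


@dataclass
class SubgroupAnalysis:
    """Per-genotype-bin environmental slopes with the merging bookkeeping."""

    bins: pd.DataFrame  # BIN, N, BETA, SE, P
    alpha: float
    merged: bool
    skipped: bool
    log: list[str] = field(default_factory=list)


def bonferroni_threshold(alpha: float = 0.05, *counts: int) -> float:
    """Bonferroni-corrected significance threshold alpha / prod(counts)."""
    if not counts:
        raise ValueError("need at least one test count")
    if any(c <= 0 for c in counts):
        raise ValueError("test counts must be positive")
    return alpha / prod(counts)


def _ols(y: np.ndarray, X: np.ndarray, names: list[str]) -> InteractionModelFit:
    n, p = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("rank-deficient design")
    resid = y - X @ coef
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
    t = coef / se
    pvals = np.clip(2.0 * stats.t.sf(np.abs(t), dof), np.finfo(float).tiny, 1.0)
    return InteractionModelFit(
        coef=pd.Series(coef, index=names),
        se=pd.Series(se, index=names),
        t=pd.Series(t, index=names),
        p=pd.Series(pvals, index=names),
        resid_var=sigma2,
        n=n,
    )


def _complete(*arrays: np.ndarray) -> np.ndarray:
    ok = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a.ndim == 1:
            ok &= np.isfinite(a)
        else:
            ok &= np.isfinite(a).all(axis=1)
    return ok


def _std(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("constant predictor")
    return (x - x.mean()) / sd


def main_effect_models(
    y: np.ndarray,
    g: np.ndarray,
    e: np.ndarray,
    C: pd.DataFrame | None = None,
) -> tuple[InteractionModelFit, InteractionModelFit]:
    """Separate OLS fits of the genetic and environmental main-effect models."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    c_arr = C.to_numpy(dtype=float) if C is not None else np.empty((len(y), 0))
    c_names = list(C.columns) if C is not None else []
    ok = _complete(y, g, e, c_arr)
    ys, cs = y[ok], c_arr[ok]
    n = int(ok.sum())
    if n < cs.shape[1] + 12:
        raise ValueError("too few complete cases")
    ones = np.ones(n)
    gfit = _ols(
        ys,
        np.column_stack([ones, _std(g[ok]), cs]),
        ["intercept", "g"] + c_names,
    )
    efit = _ols(
        ys,
        np.column_stack([ones, _std(e[ok]), cs]),
        ["intercept", "e"] + c_names,
    )
    return gfit, efit


def eta_squared(y: np.ndarray, X: pd.DataFrame, term: str) -> VarianceShare:
    """Add-last eta-squared of one term in the full model.

    Var_effect is the drop in residual sum of squares when ``term`` is
    added last to the model containing all other columns of ``X`` (plus an
    intercept); Var_T is the mean-centered total sum of squares of y.
    """
    if term not in X.columns:
        raise ValueError(f"term {term!r} not in the design")
    y = np.asarray(y, dtype=float)
    Xa = X.to_numpy(dtype=float)
    ok = _complete(y, Xa)
    ys, Xs = y[ok], Xa[ok]
    ss_total = float(np.sum((ys - ys.mean()) ** 2))
    if ss_total == 0:
        raise ValueError("constant response: total sum of squares is zero")
    n = len(ys)
    full = np.column_stack([np.ones(n), Xs])
    j = X.columns.get_loc(term)
    reduced = np.delete(full, j + 1, axis=1)

    def rss(M: np.ndarray) -> float:
        coef, _, _, _ = np.linalg.lstsq(M, ys, rcond=None)
        r = ys - M @ coef
        return float(r @ r)

    var_effect = max(rss(reduced) - rss(full), 0.0)
    kind = {"g": "genetic main", "e": "environmental main", "g_x_e": "interaction"}.get(
        term, term
    )
    return VarianceShare(
        eta2=min(var_effect / ss_total, 1.0),
        var_effect=var_effect,
        var_total=ss_total,
        kind=kind,
    )


def compare_variance_shares(
    a: np.ndarray | list[float], b: np.ndarray | list[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two eta-squared lists.

    Returns (Z, p).  Z > 0 when ``a`` tends larger.  Normal approximation
    with tie correction; exact enumeration when both samples have n <= 10.
    All values tied across both groups -> degenerate (Z=0, p=1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    n1, n2 = a.size, b.size
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = (w - mu) / np.sqrt(var)
    if n1 <= 10 and n2 <= 10:
        try:
            p = float(
                stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            )
        except ValueError:
            p = float(2 * stats.norm.sf(abs(z)))
    else:
        p = float(2 * stats.norm.sf(abs(z)))
    return float(z), min(p, 1.0)


def genotype_subgroups(
    y: np.ndarray,
    g: np.ndarray,
    e: np.ndarray,
    C: pd.DataFrame | None = None,
    min_n: int = 30,
) -> SubgroupAnalysis:
    """Environmental slope per hard-called genotype subgroup.

    Dosage is binned at 0-0.2 / 0.8-1.2 / 1.8-2.0 (outside -> missing
    genotype).  If the minor-allele homozygote bin has fewer than ``min_n``
    participants it is merged with the heterozygote bin.  The environmental
    model is fit per analyzed bin, with per-bin significance at
    0.05 / number of bins analyzed; if any analyzed bin still has
    n < ``min_n`` the analysis is skipped.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    log: list[str] = []
    masks = [
        (g >= lo) & (g <= hi) & np.isfinite(g) for lo, hi in GENOTYPE_BINS
    ]
    names = ["hom_ref", "het", "hom_alt"]
    n_out = int(np.isfinite(g).sum() - sum(m.sum() for m in masks))
    if n_out:
        log.append(f"{n_out} participants outside all dosage bins -> missing genotype")
    counts = [int(m.sum()) for m in masks]
    # minor-allele homozygotes: the smaller homozygote bin
    minor_idx = 0 if counts[0] < counts[2] else 2
    merged = False
    groups: list[tuple[str, np.ndarray]] = []
    if counts[minor_idx] < min_n:
        merged = True
        log.append(
            f"minor homozygote bin ({names[minor_idx]}, n={counts[minor_idx]}) "
            "merged with heterozygotes"
        )
        combined = masks[1] | masks[minor_idx]
        major_idx = 2 - minor_idx
        groups = [
            (names[major_idx], masks[major_idx]),
            (f"het+{names[minor_idx]}", combined),
        ]
    else:
        groups = list(zip(names, masks))
    groups = [(nm, m) for nm, m in groups if m.sum() > 0]
    alpha = 0.05 / len(groups)
    rows = []
    skipped = False
    for nm, m in groups:
        n_bin = int(m.sum())
        if n_bin < min_n:
            skipped = True
            log.append(f"bin {nm} has n={n_bin} < {min_n}: analysis skipped")
            continue
        cb = C.to_numpy(dtype=float)[m] if C is not None else np.empty((n_bin, 0))
        c_names = list(C.columns) if C is not None else []
        ok = _complete(y[m], e[m], cb)
        try:
            efit = _ols(
                y[m][ok],
                np.column_stack([np.ones(int(ok.sum())), _std(e[m][ok]), cb[ok]]),
                ["intercept", "e"] + c_names,
            )
        except ValueError as exc:
            skipped = True
            log.append(f"bin {nm}: {exc}")
            continue
        rows.append(
            {
                "BIN": nm,
                "N": efit.n,
                "BETA": float(efit.coef["e"]),
                "SE": float(efit.se["e"]),
                "P": float(efit.p["e"]),
            }
        )
    if skipped:
        rows = []
    return SubgroupAnalysis(
        bins=pd.DataFrame(rows, columns=["BIN", "N", "BETA", "SE", "P"]),
        alpha=alpha,
        merged=merged,
        skipped=skipped,
        log=log,
    )


def interaction_density(
    counts: dict[str, int], sizes: dict[str, int]
) -> dict[str, float]:
    """Interactions per exposure (or per IDP) in each category, to 2 decimals."""
    out = {}
    for cat, size in sizes.items():
        if size <= 0:
            raise ValueError(f"category {cat!r} has non-positive size")
        out[cat] = round(counts.get(cat, 0) / size, 2)
    return out
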