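"""Univariate genome-wide by environment interaction scan.

At each variant the additive interaction model

    y = mu + beta_G * x_G + beta_E * x_E + beta_GE * x_G x_E + beta_C x_C + eps

is fit by ordinary least squares on internally standardized genotype dosage
(x_G) and exposure (x_E), with the interaction term formed after
standardization.  The scan statistic is the two-sided t test on beta_GE.
Scan-level inflation is corrected by genomic control: lambda_GC is the
median interaction chi-square over its 1-df null expectation (0.4549), and
when lambda_GC > 1 every chi-square is deflated by it before recomputing
the p-value.

The scan is vectorized across variants via Frisch-Waugh residualization
against the variant-independent design (intercept, covariates, exposure),
which reproduces the full OLS coefficients and classical standard errors
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DosageMatrix

__all__ = [
    "InteractionModelFit",
    "ScanSummary",
    "GENOME_WIDE_P",
    "CHI2_1_NULL_MEDIAN",
    "encode_x_dosage",
    "fit_interaction_model",
    "genome_scan",
    "genomic_control_adjust",
]

#: Genome-wide significance threshold for interaction p-values.
GENOME_WIDE_P = 5e-8

#: Median of the 1-df chi-square distribution (genomic-control denominator).
CHI2_1_NULL_MEDIAN = 0.4549


@dataclass
class InteractionModelFit:
    """OLS fit of the interaction model at one variant.

    ``coef``/``se``/``t``/``p`` are indexed by term name: ``intercept``,
    ``g``, ``e``, ``g_x_e`` and the covariate columns.
    """

    coef: pd.Series
    se: pd.Series
    t: pd.Series
    p: pd.Series
    resid_var: float
    n: int

    @property
    def beta_ge(self) -> float:
        return float(self.coef["g_x_e"])

    @property
    def p_ge(self) -> float:
        return float(self.p["g_x_e"])


SCAN_COLUMNS = [
    "CHR", "POS", "ID", "A1", "A2", "A1FREQ", "N", "BETA_GxE", "SE", "T", "P", "P_GC",
]


@dataclass
class ScanSummary:
    """All per-variant interaction records for one exposure-IDP scan."""

    records: pd.DataFrame
    lambda_gc: float | None = None
    skipped: list[str] = field(default_factory=list)
    exposure: str | None = None
    idp: str | None = None

    def significant(self, threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
        col = "P_GC" if self.records["P_GC"].notna().any() else "P"
        return self.records[self.records[col] < threshold]


def encode_x_dosage(genotypes: DosageMatrix, sex: np.ndarray) -> DosageMatrix:
    """Scale male non-PAR X dosages by 2 so all dosages span [0, 2].

    Males are hemizygous outside the pseudo-autosomal regions, so their raw
    dosage lies in [0, 1]; doubling makes it comparable with the female
    0-2 coding.  Females, PAR variants, and autosomes are unchanged.
    ``sex`` codes males as 1.
    """
    if "is_par" not in genotypes.variants.columns:
        raise ValueError("variant table must carry an is_par flag for X variants")
    male = np.asarray(sex) == 1
    chrom = genotypes.variants["chrom"].astype(str).to_numpy()
    is_x = np.isin(chrom, ("X", "x", "23", "chrX"))
    non_par_x = is_x & ~genotypes.variants["is_par"].to_numpy(dtype=bool)
    dosages = genotypes.dosages.copy()
    if non_par_x.any() and male.any():
        block = dosages[np.ix_(male, non_par_x)]
        if np.nanmax(block) > 1 + 1e-9:
            raise ValueError(
                "male non-PAR X dosage > 1: data already scaled or inconsistent"
            )
        dosages[np.ix_(male, non_par_x)] = block * 2.0
    return DosageMatrix(dosages, genotypes.variants.copy(), genotypes.participants)


def _standardize(x: np.ndarray, what: str) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError(f"zero variance in {what} after complete-case restriction")
    return (x - x.mean()) / sd


def fit_interaction_model(
    y: np.ndarray,
    g: np.ndarray,
    e: np.ndarray,
    C: pd.DataFrame | np.ndarray | None = None,
) -> InteractionModelFit:
    """Fit the univariate interaction model at one variant by OLS.

    Rows with any missing value are dropped (complete-case); ``g`` and ``e``
    are standardized on the analysis rows before the product term is formed.
    Two-sided t test on every coefficient; classical (homoskedastic) SEs.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    if C is None:
        c_arr = np.empty((len(y), 0))
        c_names: list[str] = []
    elif isinstance(C, pd.DataFrame):
        c_arr = C.to_numpy(dtype=float)
        c_names = list(C.columns)
    else:
        c_arr = np.asarray(C, dtype=float)
        if c_arr.ndim == 1:
            c_arr = c_arr[:, None]
        c_names = [f"c{j}" for j in range(c_arr.shape[1])]
    ok = np.isfinite(y) & np.isfinite(g) & np.isfinite(e)
    if c_arr.shape[1]:
        ok &= np.isfinite(c_arr).all(axis=1)
    n = int(ok.sum())
    p = 4 + c_arr.shape[1]
    if n < p + 10:
        raise ValueError(f"need >= {p + 10} complete cases, got {n}")
    ys, gs, es = y[ok], _standardize(g[ok], "g"), _standardize(e[ok], "e")
    names = ["intercept", "g", "e", "g_x_e"] + c_names
    X = np.column_stack([np.ones(n), gs, es, gs * es, c_arr[ok]])
    coef, _, rank, _ = np.linalg.lstsq(X, ys, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient interaction design")
    resid = ys - X @ coef
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return InteractionModelFit(
        coef=pd.Series(coef, index=names),
        se=pd.Series(se, index=names),
        t=pd.Series(t, index=names),
        p=pd.Series(pvals, index=names),
        resid_var=sigma2,
        n=n,
    )


def genome_scan(
    genotypes: DosageMatrix,
    exposure: np.ndarray,
    idp: np.ndarray,
    C: pd.DataFrame | np.ndarray | None = None,
    maf_threshold: float = 0.05,
    adjust: bool = True,
    exposure_name: str | None = None,
    idp_name: str | None = None,
) -> ScanSummary:
    """Interaction scan of one exposure-IDP pair across all variants.

    Variants below the MAF threshold are excluded up front; monomorphic (or
    missing) variants on the analysis rows are skipped and logged rather
    than aborting the scan.  With ``adjust`` the genomic-control correction
    is applied to the finished scan.
    """
    y = np.asarray(idp, dtype=float)
    e = np.asarray(exposure, dtype=float)
    if genotypes.n_participants != len(y) or len(e) != len(y):
        raise ValueError("genotype, exposure and phenotype row counts differ")
    if C is None:
        c_arr = np.empty((len(y), 0))
    else:
        c_arr = C.to_numpy(dtype=float) if isinstance(C, pd.DataFrame) else np.asarray(C, dtype=float)
        if c_arr.ndim == 1:
            c_arr = c_arr[:, None]
    ok = np.isfinite(y) & np.isfinite(e)
    if c_arr.shape[1]:
        ok &= np.isfinite(c_arr).all(axis=1)
    n = int(ok.sum())
    ys = y[ok]
    es = _standardize(e[ok], "e")
    A = np.column_stack([np.ones(n), c_arr[ok], es])
    p_fixed = A.shape[1]
    # hat-matrix solve for the fixed block, reused for every variant
    AtA_inv_At = np.linalg.solve(A.T @ A, A.T)
    ry = ys - A @ (AtA_inv_At @ ys)

    maf = genotypes.maf()
    rows: list[dict] = []
    skipped: list[str] = []
    meta = genotypes.variants
    dof = n - (p_fixed + 2)
    for j in range(genotypes.n_variants):
        vid = str(meta["id"].iloc[j])
        if maf[j] < maf_threshold:
            skipped.append(f"{vid}: MAF {maf[j]:.4f} below threshold")
            continue
        gcol = genotypes.dosages[ok, j]
        if not np.isfinite(gcol).all():
            skipped.append(f"{vid}: missing dosage on analysis rows")
            continue
        sd = gcol.std()
        if sd == 0:
            skipped.append(f"{vid}: monomorphic on analysis rows")
            continue
        gs = (gcol - gcol.mean()) / sd
        B = np.column_stack([gs, gs * es])
        rb = B - A @ (AtA_inv_At @ B)
        btb = rb.T @ rb
        try:
            btb_inv = np.linalg.inv(btb)
        except np.linalg.LinAlgError:
            skipped.append(f"{vid}: collinear with fixed design")
            continue
        beta = btb_inv @ (rb.T @ ry)
        resid = ry - rb @ beta
        sigma2 = float(resid @ resid) / dof
        se = np.sqrt(sigma2 * np.diag(btb_inv))
        tstat = beta / se
        pval = float(np.clip(2.0 * stats.t.sf(abs(tstat[1]), dof), np.finfo(float).tiny, 1.0))
        rows.append(
            {
                "CHR": meta["chrom"].iloc[j],
                "POS": int(meta["pos"].iloc[j]),
                "ID": vid,
                "A1": meta["alt"].iloc[j],
                "A2": meta["ref"].iloc[j],
                "A1FREQ": float(np.mean(gcol) / 2.0),
                "N": n,
                "BETA_GxE": float(beta[1]),
                "SE": float(se[1]),
                "T": float(tstat[1]),
                "P": pval,
                "P_GC": np.nan,
            }
        )
    records = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    summary = ScanSummary(
        records=records, skipped=skipped, exposure=exposure_name, idp=idp_name
    )
    if adjust and len(records):
        summary = genomic_control_adjust(summary)
    return summary


def genomic_control_adjust(summary: ScanSummary) -> ScanSummary:
    """Estimate lambda_GC and deflate the scan when it exceeds 1.

    lambda_GC = median(chi2_1 statistics) / 0.4549.  When lambda_GC > 1
    every chi-square is divided by lambda_GC and the p-value recomputed from
    the 1-df chi-square tail; otherwise adjusted p equals raw p.
    """
    records = summary.records
    if records.empty:
        raise ValueError("cannot genomic-control-adjust an empty scan")
    if len(records) < 100:
        warnings.warn(
            f"lambda_GC estimated from only {len(records)} records; unreliable",
            stacklevel=2,
        )
    chi2 = stats.chi2.isf(records["P"].to_numpy(), df=1)
    lam = float(np.median(chi2) / CHI2_1_NULL_MEDIAN)
    out = records.copy()
    if lam > 1:
        out["P_GC"] = np.clip(stats.chi2.sf(chi2 / lam, df=1), np.finfo(float).tiny, 1.0)
    else:
        out["P_GC"] = out["P"]
    return ScanSummary(
        records=out,
        lambda_gc=lam,
        skipped=summary.skipped,
        exposure=summary.exposure,
        idp=summary.idp,
    )
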