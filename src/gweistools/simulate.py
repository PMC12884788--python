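"""Synthetic cohort generator with planted gene-environment interactions.

Generates cohorts with the statistical structure the analysis pipeline
assumes: biallelic dosages with tunable local LD, a block-correlated
exposome (a minority of exposures dichotomized, emulating birth-season /
only-child style binaries), 18-year exposure trajectories with
completely-at-random missingness, and imaging phenotypes carrying planted
G, E and GxE effects plus per-scanner location/scale batch effects.

Ground truth (planted effects with realized variance shares, exposure
cluster assignments, scanner parameters) is recorded before noise-free
quantities are perturbed, so recovery can be asserted exactly.

Genotypes use a latent AR(1) Gaussian per haplotype thresholded to alleles
and summed in pairs: adjacent-variant LD then decays geometrically with the
latent autocorrelation, without needing a haplotype reference panel.

Interaction effect sizes are calibrated analytically: the coefficient is
solved from the target variance share using the realized variance of the
g*e product on the simulated cohort, so the planted eta-squared is matched
without iterative tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import IDP_CATEGORIES, DosageMatrix, ExposureSet, IdpMatrix

__all__ = [
    "SimConfig",
    "PlantedEffect",
    "CohortTruth",
    "simulate_genotypes",
    "simulate_x_genotypes",
    "simulate_exposome",
    "simulate_trajectories",
    "simulate_idps",
    "simulate_cohort",
]


@dataclass
class PlantedEffect:
    """One planted variant x exposure x IDP effect.

    ``interaction_eta2`` is the target share of phenotype variance carried by
    the GxE product term (the study-scale default is ~0.005, i.e. 0.5%).
    ``sensitive_window`` restricts the interaction to the mean exposure over
    an inclusive age interval, making that window the distributed-lag ground
    truth.
    """

    variant_index: int
    exposure_index: int
    idp_index: int
    interaction_eta2: float = 0.005
    genetic_main_eta2: float = 0.0
    environmental_main_eta2: float = 0.0
    sensitive_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for name in ("interaction_eta2", "genetic_main_eta2", "environmental_main_eta2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if (
            self.interaction_eta2
            + self.genetic_main_eta2
            + self.environmental_main_eta2
        ) >= 1:
            raise ValueError("planted eta-squared values must sum to < 1")


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the cohort the pipeline is designed for: exposures in
    four correlated clusters, 18 annual exposure values per participant, and
    planted interactions around a 0.5% variance share.
    """

    n_participants: int = 2000
    n_variants: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.8
    n_exposures: int = 41
    n_clusters: int = 4
    within_cluster_rho: float = 0.5
    n_ages: int = 18
    trajectory_ar: float = 0.7
    missing_rate: float = 0.0
    n_scanners: int = 3
    scanner_shift_sd: float = 0.3
    scanner_scale_sd: float = 0.1
    n_idps: int = 21
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    binary_exposure_fraction: float = 0.2
    covariate_var: float = 0.1
    pos_step: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0.05, 0.5]")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must be in [0, 1)")
        if not (2 <= self.n_clusters <= self.n_exposures):
            raise ValueError("need 2 <= n_clusters <= n_exposures")
        if not (0 <= self.within_cluster_rho < 1):
            raise ValueError("within_cluster_rho must be in [0, 1)")
        for name in ("missing_rate", "binary_exposure_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be a proportion in [0, 1]")
        if self.n_ages < 2:
            raise ValueError("n_ages must be >= 2")
        if not (-1 <= self.trajectory_ar <= 1):
            raise ValueError("trajectory_ar must be in [-1, 1]")
        if self.scanner_shift_sd < 0 or self.scanner_scale_sd < 0:
            raise ValueError("scanner effect SDs must be >= 0")
        for eff in self.planted_effects:
            if eff.sensitive_window is not None:
                lo_a, hi_a = eff.sensitive_window
                if not (1 <= lo_a <= hi_a <= self.n_ages):
                    raise ValueError("sensitive_window must lie within [1, n_ages]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent reproducible stream per generator stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class CohortTruth:
    """Ground truth recorded by the generator before noise addition."""

    planted_effects: list[PlantedEffect]
    realized_eta2: list[dict[str, float]]
    exposure_clusters: np.ndarray | None = None
    scanner_shift: np.ndarray | None = None
    scanner_scale: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    noiseless: np.ndarray | None = None


def simulate_genotypes(config: SimConfig) -> DosageMatrix:
    """Draw biallelic dosages with geometric LD decay along the chromosome.

    Two latent AR(1) Gaussian haplotype processes are thresholded at the
    per-variant allele frequency quantile and summed, giving dosages in
    {0, 1, 2} whose adjacent-variant correlation decays with ``ld_decay``.
    """
    rng = config.rng(1)
    n, m = config.n_participants, config.n_variants
    maf = rng.uniform(*config.maf_range, size=m)
    phi = config.ld_decay
    dosage = np.zeros((n, m))
    thresh = stats.norm.isf(maf)  # allele present when latent > threshold
    for _hap in range(2):
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, m))
        scale = np.sqrt(1.0 - phi**2)
        for j in range(1, m):
            z[:, j] = phi * z[:, j - 1] + scale * innov[:, j]
        dosage += (z > thresh[None, :]).astype(float)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1) * config.pos_step,
            "id": [f"var{j:05d}" for j in range(m)],
            "ref": "A",
            "alt": "G",
            "is_par": False,
        }
    )
    return DosageMatrix(dosage, variants)


def simulate_x_genotypes(
    config: SimConfig, sex: np.ndarray, n_par: int = 0
) -> DosageMatrix:
    """X-chromosome dosages: males carry one allele (raw dosage in {0, 1})
    outside the pseudo-autosomal regions (PAR); PAR variants behave
    autosomally.  ``sex`` codes males as 1.
    """
    rng = config.rng(7)
    n, m = config.n_participants, config.n_variants
    maf = rng.uniform(*config.maf_range, size=m)
    is_par = np.zeros(m, dtype=bool)
    is_par[:n_par] = True
    male = np.asarray(sex) == 1
    dosage = np.zeros((n, m))
    for j in range(m):
        a1 = rng.random(n) < maf[j]
        a2 = rng.random(n) < maf[j]
        col = a1.astype(float) + a2
        if not is_par[j]:
            col[male] = a1[male].astype(float)  # hemizygous: one allele only
        dosage[:, j] = col
    variants = pd.DataFrame(
        {
            "chrom": "X",
            "pos": np.arange(1, m + 1) * config.pos_step,
            "id": [f"xvar{j:05d}" for j in range(m)],
            "ref": "A",
            "alt": "G",
            "is_par": is_par,
        }
    )
    return DosageMatrix(dosage, variants)


def _cluster_assignment(n_exposures: int, n_clusters: int) -> np.ndarray:
    """Contiguous, near-equal blocks of exposures per cluster."""
    sizes = np.full(n_clusters, n_exposures // n_clusters)
    sizes[: n_exposures % n_clusters] += 1
    return np.repeat(np.arange(n_clusters), sizes)


def simulate_exposome(config: SimConfig) -> ExposureSet:
    """Draw block-correlated exposures; a minority dichotomized.

    Within a cluster the latent Gaussians share a factor giving pairwise
    correlation ``within_cluster_rho``; across clusters correlation is ~0.
    True cluster labels are stored on the returned set.
    """
    rng = config.rng(2)
    n, m = config.n_participants, config.n_exposures
    labels = _cluster_assignment(m, config.n_clusters)
    rho = config.within_cluster_rho
    factors = rng.standard_normal((n, config.n_clusters))
    noise = rng.standard_normal((n, m))
    z = np.sqrt(rho) * factors[:, labels] + np.sqrt(1.0 - rho) * noise
    # Dichotomize a deterministic minority spread across clusters, emulating
    # binary questionnaire items (birth season, only-child status, ...).
    n_binary = int(round(config.binary_exposure_fraction * m))
    binary_idx = (
        np.unique(np.round(np.linspace(0, m - 1, n_binary)).astype(int))
        if n_binary
        else np.array([], dtype=int)
    )
    values = z.copy()
    for j in binary_idx:
        values[:, j] = (z[:, j] > 0).astype(float)
    names = [f"E{j:02d}" for j in range(m)]
    return ExposureSet(
        pd.DataFrame(values, columns=names), cluster_labels=labels.copy()
    )


def simulate_trajectories(config: SimConfig, exposures: ExposureSet) -> ExposureSet:
    """Attach per-age AR(1) trajectories whose mean over ages equals the
    stored time-invariant value, then inject completely-at-random
    missingness at ``missing_rate``.

    Binary exposures stay time-invariant (no trajectory).  Deviations around
    the participant's long-run value have SD equal to the cross-sectional SD:
    over an 18-year span exposures such as air pollution or night-time
    lights change within a person as much as they differ between people.
    """
    if config.n_ages < 2:
        raise ValueError("n_ages must be >= 2")
    rng = config.rng(3)
    n, n_ages = exposures.n_participants, config.n_ages
    ar = config.trajectory_ar
    trajectories: dict[str, np.ndarray] = {}
    for name in exposures.exposure_names:
        col = exposures.values[name].to_numpy()
        if np.isin(np.unique(col), [0.0, 1.0]).all():
            continue  # binary exposures have no age series
        if abs(ar) >= 1.0 - 1e-12:
            dev = np.zeros((n, n_ages))  # degenerate AR: constant series
        else:
            dev = np.empty((n, n_ages))
            dev[:, 0] = rng.standard_normal(n)
            innov = rng.standard_normal((n, n_ages))
            scale = np.sqrt(1.0 - ar**2)
            for t in range(1, n_ages):
                dev[:, t] = ar * dev[:, t - 1] + scale * innov[:, t]
            dev -= dev.mean(axis=1, keepdims=True)
            dev *= np.std(col)
        traj = col[:, None] + dev
        if config.missing_rate > 0:
            mask = rng.random(traj.shape) < config.missing_rate
            traj = traj.copy()
            traj[mask] = np.nan
        trajectories[name] = traj
    return ExposureSet(
        exposures.values.copy(),
        trajectories=trajectories,
        cluster_labels=exposures.cluster_labels,
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - np.mean(x)) / sd


def _window_exposure(
    exposures: ExposureSet, name: str, window: tuple[int, int], fallback: np.ndarray
) -> np.ndarray:
    """Mean exposure over an inclusive age window (1-based ages); falls back
    to the time-invariant value where the whole window is missing."""
    if name not in exposures.trajectories:
        return fallback
    lo, hi = window
    seg = exposures.trajectories[name][:, lo - 1 : hi]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(seg, axis=1)
    return np.where(np.isnan(mean), fallback, mean)


def simulate_idps(
    config: SimConfig,
    genotypes: DosageMatrix,
    exposures: ExposureSet,
) -> tuple[IdpMatrix, CohortTruth]:
    """Build imaging phenotypes carrying the planted effects.

    Each IDP is covariate signal + planted beta_G*g + beta_E*e + beta_GE*g*e
    (on standardized g, e) + Gaussian noise filling total variance to 1,
    then per-scanner shift/scale batch effects.  Coefficients are solved
    from the target variance shares using the realized variance of each
    term, and the realized shares are recorded in the truth object.
    """
    rng = config.rng(4)
    n = config.n_participants
    if genotypes.n_participants != n or exposures.n_participants != n:
        raise ValueError("genotypes/exposures row counts disagree with config")
    for eff in config.planted_effects:
        if not (0 <= eff.variant_index < genotypes.n_variants):
            raise ValueError("planted variant_index out of bounds")
        if not (0 <= eff.exposure_index < exposures.n_exposures):
            raise ValueError("planted exposure_index out of bounds")
        if not (0 <= eff.idp_index < config.n_idps):
            raise ValueError("planted idp_index out of bounds")

    # Covariates: age, sex, and one TIV-like nuisance per structural category.
    covariates = pd.DataFrame(
        {
            "age": rng.normal(24.0, 3.0, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "TIV": rng.normal(1500.0, 120.0, size=n),
            "total_SA": rng.normal(1800.0, 150.0, size=n),
            "mean_CT": rng.normal(2.5, 0.1, size=n),
            "mean_FD": np.abs(rng.normal(0.15, 0.05, size=n)),
        }
    )
    pcs = rng.standard_normal((n, 10))
    for k in range(10):
        covariates[f"PC{k + 1}"] = pcs[:, k]

    scanners = rng.integers(0, config.n_scanners, size=n)
    shift = rng.normal(0.0, config.scanner_shift_sd, size=config.n_scanners)
    scale = np.exp(rng.normal(0.0, config.scanner_scale_sd, size=config.n_scanners))

    n_idps = config.n_idps
    categories = np.array([IDP_CATEGORIES[j % len(IDP_CATEGORIES)] for j in range(n_idps)])
    by_idp: dict[int, list[tuple[int, PlantedEffect]]] = {}
    for i, eff in enumerate(config.planted_effects):
        by_idp.setdefault(eff.idp_index, []).append((i, eff))

    # Covariate signal: small weights on standardized age/sex/nuisance, total
    # share covariate_var of unit phenotype variance.
    cov_cols = ["age", "sex", "TIV", "mean_FD"]
    cov_std = np.column_stack([_standardize(covariates[c].to_numpy()) for c in cov_cols])
    w = np.sqrt(config.covariate_var / len(cov_cols))

    y = np.empty((n, n_idps))
    noiseless = np.empty((n, n_idps))
    realized: list[dict[str, float]] = [{} for _ in config.planted_effects]
    eps = rng.standard_normal((n, n_idps))
    for j in range(n_idps):
        signal = cov_std @ np.full(len(cov_cols), w)
        explained = config.covariate_var
        for eff_idx, eff in by_idp.get(j, []):
            g = _standardize(genotypes.column(eff.variant_index))
            e_raw = exposures.values.iloc[:, eff.exposure_index].to_numpy()
            name = exposures.exposure_names[eff.exposure_index]
            if eff.sensitive_window is not None:
                e_raw = _window_exposure(exposures, name, eff.sensitive_window, e_raw)
            e = _standardize(e_raw)
            rec: dict[str, float] = {}
            for kind, target, term in (
                ("genetic_main", eff.genetic_main_eta2, g),
                ("environmental_main", eff.environmental_main_eta2, e),
                ("interaction", eff.interaction_eta2, g * e),
            ):
                if target <= 0:
                    rec[kind] = 0.0
                    continue
                beta = np.sqrt(target) / np.std(term)
                contrib = beta * term
                signal = signal + contrib
                rec[kind] = float(np.var(contrib))
                explained += target
            realized[eff_idx] = rec
        if explained >= 1:
            raise ValueError("planted + covariate variance shares must sum to < 1")
        noise_sd = np.sqrt(1.0 - explained)
        clean = signal
        noiseless[:, j] = clean
        y[:, j] = scale[scanners] * (clean + noise_sd * eps[:, j]) + shift[scanners]

    idps = IdpMatrix(
        pd.DataFrame(y, columns=[f"IDP{j:03d}" for j in range(n_idps)]),
        categories=categories,
        scanners=np.array([f"scanner{s}" for s in scanners]),
    )
    truth = CohortTruth(
        planted_effects=list(config.planted_effects),
        realized_eta2=realized,
        exposure_clusters=exposures.cluster_labels,
        scanner_shift=shift,
        scanner_scale=scale,
        covariates=covariates,
        noiseless=noiseless,
    )
    return idps, truth


def simulate_cohort(
    config: SimConfig,
) -> tuple[DosageMatrix, ExposureSet, IdpMatrix, CohortTruth]:
    """End-to-end generator: genotypes, exposome with trajectories, IDPs, truth."""
    genotypes = simulate_genotypes(config)
    exposures = simulate_trajectories(config, simulate_exposome(config))
    idps, truth = simulate_idps(config, genotypes, exposures)
    return genotypes, exposures, idps, truth
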