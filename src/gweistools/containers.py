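"""Core in-memory containers shared across the pipeline.

The analysis operates on three participant-aligned tables: allelic dosages
with per-variant metadata, an exposure set (time-invariant values plus
per-age trajectories), and an imaging-derived phenotype (IDP) matrix with
category and scanner labels.  All are thin wrappers over numpy/pandas with
the invariants the downstream stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: IDP categories in the order used throughout (structural, diffusion, functional).
IDP_CATEGORIES = ("GMV", "CT", "SA", "FA", "Amp", "FC", "ReHo")


@dataclass
class DosageMatrix:
    """Participants x variants allelic dosages in [0, 2].

    Parameters
    ----------
    dosages
        Array of shape ``(n_participants, n_variants)``; imputed allelic
        dosage of the counted (alternate) allele, each value in ``[0, 2]``.
    variants
        Per-variant metadata with columns ``chrom, pos, id, ref, alt`` and
        optionally ``is_par`` (pseudo-autosomal flag, X chromosome only).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    participants: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (participants x variants)")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError(
                f"variant table has {len(self.variants)} rows but dosage "
                f"matrix has {self.dosages.shape[1]} columns"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
        if self.participants is None:
            self.participants = np.array(
                [f"P{i:06d}" for i in range(self.dosages.shape[0])]
            )

    @property
    def n_participants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per variant (dosage mean / 2, folded)."""
        p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def filter_maf(self, threshold: float = 0.05) -> tuple["DosageMatrix", int]:
        """Drop variants below the MAF threshold; returns (filtered, n_dropped)."""
        keep = self.maf() >= threshold
        filtered = DosageMatrix(
            self.dosages[:, keep],
            self.variants.loc[keep].reset_index(drop=True),
            self.participants,
        )
        return filtered, int((~keep).sum())

    def column(self, j: int) -> np.ndarray:
        return self.dosages[:, j]


@dataclass
class ExposureSet:
    """Participants x exposures: time-invariant values plus optional trajectories.

    ``values`` holds one number per participant per exposure (for time-varying
    exposures this is the mean over the 18 annual values).  ``trajectories``
    maps an exposure name to an ``(n_participants, n_ages)`` array with NaN
    for missing person-years.
    """

    values: pd.DataFrame
    trajectories: dict[str, np.ndarray] = field(default_factory=dict)
    cluster_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, traj in self.trajectories.items():
            if name not in self.values.columns:
                raise ValueError(f"trajectory for unknown exposure {name!r}")
            if traj.shape[0] != len(self.values):
                raise ValueError(f"trajectory for {name!r} has wrong row count")

    @property
    def n_participants(self) -> int:
        return len(self.values)

    @property
    def n_exposures(self) -> int:
        return self.values.shape[1]

    @property
    def exposure_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_ages(self) -> int:
        if not self.trajectories:
            return 0
        return next(iter(self.trajectories.values())).shape[1]

    def missing_mask(self, name: str) -> np.ndarray:
        """Boolean mask of missing person-years for one trajectory."""
        return np.isnan(self.trajectories[name])


@dataclass
class IdpMatrix:
    """Participants x imaging-derived phenotypes with category and scanner labels."""

    values: pd.DataFrame
    categories: np.ndarray  # per-IDP category label, one of IDP_CATEGORIES
    scanners: np.ndarray  # per-participant scanner label

    def __post_init__(self) -> None:
        self.categories = np.asarray(self.categories)
        self.scanners = np.asarray(self.scanners)
        if len(self.categories) != self.values.shape[1]:
            raise ValueError("one category label per IDP required")
        if len(self.scanners) != len(self.values):
            raise ValueError("one scanner label per participant required")
        unknown = set(self.categories) - set(IDP_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown IDP categories: {sorted(unknown)}")

    @property
    def n_participants(self) -> int:
        return len(self.values)

    @property
    def n_idps(self) -> int:
        return self.values.shape[1]

    def category_of(self, idp: str) -> str:
        j = self.values.columns.get_loc(idp)
        return str(self.categories[j])
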