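"""LD clumping of significant interactions, iterative conditional selection
of exposure-independent interactions, and locus merging.

Clumping is the PLINK-style greedy reduction: repeatedly take the most
significant remaining variant as a lead and absorb every variant within the
base-pair window AND in LD (r^2 above threshold) with it.  Conditional
selection prunes interactions of correlated exposures at one variant-IDP
pair by refitting the interaction model with the already-selected
interactions (and their exposure main effects) as covariates.  Lead-variant
windows are merged into loci, with the MHC and the chr8p23.1 inversion
region each collapsed to a single locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DosageMatrix
from .gweis import GENOME_WIDE_P, fit_interaction_model

__all__ = [
    "ClumpResult",
    "Locus",
    "MHC_REGION",
    "CHR8_INVERSION",
    "ld_r2",
    "ld_clump",
    "conditional_select",
    "merge_loci",
]

#: hg19 major histocompatibility complex region (1-based inclusive).
MHC_REGION = ("6", 25_119_106, 33_854_733)
#: hg19 chromosome 8p23.1 inversion region (1-based inclusive).
CHR8_INVERSION = ("8", 7_242_715, 12_483_982)


@dataclass
class ClumpResult:
    """Lead variants and the clumped-variant -> lead assignment."""

    leads: pd.DataFrame  # rows of the input records that became leads
    assignment: dict[str, str]  # member variant id -> lead variant id
    window: int
    r2_threshold: float
    p_threshold: float

    @property
    def lead_ids(self) -> list[str]:
        return list(self.leads["ID"])


@dataclass
class Locus:
    """A merged genomic interval (1-based inclusive) of lead-variant windows."""

    chrom: str
    start: int
    end: int
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("locus start must be < end")


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors (allele-flip
    invariant)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must align on the same participants")
    ok = np.isfinite(g1) & np.isfinite(g2)
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("cannot compute LD with a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _dosage_by_id(genotypes: DosageMatrix) -> dict[str, int]:
    return {str(v): j for j, v in enumerate(genotypes.variants["id"])}


def ld_clump(
    records: pd.DataFrame,
    genotypes: DosageMatrix,
    window: int = 500_000,
    r2_threshold: float = 0.1,
    p_threshold: float = GENOME_WIDE_P,
) -> ClumpResult:
    """Greedy LD clumping of significant records.

    Iteratively the minimum-p record becomes a lead (ties broken toward the
    lower genomic position) and all remaining records on the same chromosome
    within ``window`` bp AND with r^2 > ``r2_threshold`` against the lead
    are clumped into it.  ``records`` needs columns ID, CHR, POS and P (or
    P_GC, preferred when present).
    """
    pcol = "P_GC" if "P_GC" in records.columns and records["P_GC"].notna().any() else "P"
    work = records.copy().reset_index(drop=True)
    idx_of = _dosage_by_id(genotypes)
    missing = [v for v in work["ID"].astype(str) if v not in idx_of]
    if missing:
        raise ValueError(f"no genotype column for record(s): {', '.join(missing[:5])}")
    remaining = work.sort_values([pcol, "POS"], kind="mergesort").index.to_list()
    lead_rows: list[int] = []
    assignment: dict[str, str] = {}
    while remaining:
        lead = remaining.pop(0)
        lead_rows.append(lead)
        lead_id = str(work.at[lead, "ID"])
        assignment[lead_id] = lead_id
        g_lead = genotypes.dosages[:, idx_of[lead_id]]
        keep: list[int] = []
        for i in remaining:
            same_chr = str(work.at[i, "CHR"]) == str(work.at[lead, "CHR"])
            near = abs(int(work.at[i, "POS"]) - int(work.at[lead, "POS"])) <= window
            if same_chr and near:
                g_i = genotypes.dosages[:, idx_of[str(work.at[i, "ID"])]]
                if ld_r2(g_lead, g_i) > r2_threshold:
                    assignment[str(work.at[i, "ID"])] = lead_id
                    continue
            keep.append(i)
        remaining = keep
    leads = work.loc[lead_rows].reset_index(drop=True)
    return ClumpResult(
        leads=leads,
        assignment=assignment,
        window=window,
        r2_threshold=r2_threshold,
        p_threshold=p_threshold,
    )


def conditional_select(
    pair_records: pd.DataFrame,
    y: np.ndarray,
    g: np.ndarray,
    exposures: pd.DataFrame,
    C: pd.DataFrame | None = None,
    p_threshold: float = GENOME_WIDE_P,
) -> tuple[pd.DataFrame, list[str]]:
    """Iterative conditional pruning of one variant-IDP pair's interactions.

    ``pair_records`` holds one row per LD-independent significant
    interaction for the pair (columns EXPOSURE and P).  Each round the most
    significant candidate is selected, and every remaining candidate is
    refit with the selected exposures' interaction terms AND main effects
    added as covariates; candidates still below ``p_threshold`` survive to
    the next round.  Returns the selected interactions (with the round and
    the conditional p at selection) plus a log of dropped candidates.
    """
    if pair_records.empty:
        raise ValueError("need >= 1 significant interaction for the pair")
    y = np.asarray(y, dtype=float)
    gv = np.asarray(g, dtype=float)
    log: list[str] = []

    def _std(x: np.ndarray) -> np.ndarray:
        return (x - np.nanmean(x)) / np.nanstd(x)

    gs = _std(gv)
    candidates = list(
        pair_records.sort_values("P", kind="mergesort")["EXPOSURE"].astype(str)
    )
    current_p = {
        str(r["EXPOSURE"]): float(r["P"]) for _, r in pair_records.iterrows()
    }
    selected: list[dict] = []
    round_no = 0
    while candidates:
        round_no += 1
        best = min(candidates, key=lambda s: (current_p[s],))
        selected.append(
            {"EXPOSURE": best, "P_CONDITIONAL": current_p[best], "ROUND": round_no}
        )
        candidates.remove(best)
        if not candidates:
            break
        cond_cols = {}
        for rec in selected:
            s = rec["EXPOSURE"]
            es = _std(exposures[s].to_numpy(dtype=float))
            cond_cols[f"{s}_main"] = es
            cond_cols[f"{s}_x_g"] = es * gs
        cond = pd.DataFrame(cond_cols)
        Cfull = cond if C is None else pd.concat(
            [C.reset_index(drop=True), cond], axis=1
        )
        survivors = []
        for s in candidates:
            try:
                fit = fit_interaction_model(
                    y, gv, exposures[s].to_numpy(dtype=float), Cfull
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                log.append(f"{s}: dropped in round {round_no} ({exc})")
                continue
            current_p[s] = fit.p_ge
            if fit.p_ge < p_threshold:
                survivors.append(s)
            else:
                log.append(
                    f"{s}: conditional p {fit.p_ge:.3g} >= threshold in round {round_no}"
                )
        candidates = survivors
    out = pd.DataFrame(selected, columns=["EXPOSURE", "P_CONDITIONAL", "ROUND"])
    merged = pair_records.merge(out, on="EXPOSURE", how="inner")
    return merged, log


def _merge_intervals(loci: list[Locus]) -> list[Locus]:
    loci = sorted(loci, key=lambda lc: (lc.chrom, lc.start))
    out: list[Locus] = []
    for lc in loci:
        if out and out[-1].chrom == lc.chrom and lc.start <= out[-1].end:
            out[-1].end = max(out[-1].end, lc.end)
            out[-1].members.extend(lc.members)
        else:
            out.append(Locus(lc.chrom, lc.start, lc.end, list(lc.members)))
    return out


def merge_loci(
    leads: ClumpResult | pd.DataFrame,
    genotypes: DosageMatrix,
    window: int = 500_000,
    r2_threshold: float = 0.1,
    special_regions: tuple = (MHC_REGION, CHR8_INVERSION),
) -> list[Locus]:
    """Merge +/-500 kb lead-variant windows into non-overlapping loci.

    Overlapping windows merge; windows whose leads are in LD
    (r^2 > threshold, same chromosome) merge; windows touching the MHC or
    chr8p23.1 regions merge into one locus per special region.  Negative
    starts clip to 1.
    """
    table = leads.leads if isinstance(leads, ClumpResult) else leads
    idx_of = _dosage_by_id(genotypes)
    loci = [
        Locus(
            str(r["CHR"]),
            max(1, int(r["POS"]) - window),
            int(r["POS"]) + window,
            [str(r["ID"])],
        )
        for _, r in table.iterrows()
    ]
    # absorb windows touching a special high-LD region into that region
    for chrom, start, end in special_regions:
        hit = [lc for lc in loci if lc.chrom == chrom and lc.start <= end and lc.end >= start]
        if hit:
            merged = Locus(
                chrom,
                min(start, *(lc.start for lc in hit)),
                max(end, *(lc.end for lc in hit)),
                [m for lc in hit for m in lc.members],
            )
            loci = [lc for lc in loci if lc not in hit] + [merged]
    loci = _merge_intervals(loci)
    # LD-based merging between loci (leads in r^2 > threshold)
    changed = True
    while changed:
        changed = False
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                if loci[i].chrom != loci[j].chrom:
                    continue
                linked = False
                for a in loci[i].members:
                    for b in loci[j].members:
                        ga = genotypes.dosages[:, idx_of[a]]
                        gb = genotypes.dosages[:, idx_of[b]]
                        if ga.std() == 0 or gb.std() == 0:
                            continue
                        if ld_r2(ga, gb) > r2_threshold:
                            linked = True
                            break
                    if linked:
                        break
                if linked:
                    loci[i] = Locus(
                        loci[i].chrom,
                        min(loci[i].start, loci[j].start),
                        max(loci[i].end, loci[j].end),
                        loci[i].members + loci[j].members,
                    )
                    del loci[j]
                    changed = True
                    break
            if changed:
                break
        if changed:
            loci = _merge_intervals(loci)
    return sorted(loci, key=lambda lc: (lc.chrom, lc.start))
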