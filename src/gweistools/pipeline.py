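"""End-to-end orchestration: prep -> cluster -> scan -> clump/condition ->
multivariate verification -> effects -> distributed-lag sensitive periods.

Each stage consumes the previous stage's outputs and appends its counts to
a run manifest, so the funnel (candidate interactions >= LD-independent >=
conditionally independent >= verified) is auditable.  Stages degrade
gracefully: an empty scan result short-circuits the downstream stages with
a complete manifest rather than erroring.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clump as clump_mod
from . import dlm as dlm_mod
from . import io as io_mod
from .containers import DosageMatrix, ExposureSet, IdpMatrix
from .effects import eta_squared, genotype_subgroups, main_effect_models
from .exposome import cluster_exposures, spearman_matrix
from .gweis import genome_scan
from .prep import assemble_covariates, combat_harmonize, compute_genetic_pcs, inverse_normal_transform
from .simulate import SimConfig, simulate_cohort
from .structlmm import exposure_bayes_factors, fit_null_lmm, score_test_gxe, verify_interactions

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    Either ``sim`` is given (the cohort is generated) or the four input
    paths point at existing files.
    """

    outdir: str | Path
    sim: SimConfig | None = None
    genotypes_path: str | Path | None = None
    genotype_format: str | None = None
    exposures_path: str | Path | None = None
    trajectories_path: str | Path | None = None
    idps_path: str | Path | None = None
    covariates_path: str | Path | None = None
    maf_threshold: float = 0.05
    genome_wide_p: float = 5e-8
    fdr_level: float = 0.05
    clump_window: int = 500_000
    clump_r2: float = 0.1
    dlm_min_n: int = 500
    dlm_df: int = 3
    n_pcs: int = 10
    min_scanner_n: int = 10
    harmonize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "genome_wide_p", "fdr_level", "clump_r2"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.clump_window <= 0:
            raise ValueError("clump_window must be positive")


@dataclass
class RunManifest:
    """Per-stage bookkeeping for one pipeline run."""

    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    completed: bool = False

    def log_stage(self, name: str, n_in: int, n_out: int, **extra) -> None:
        self.stages.append(
            {"stage": name, "n_in": n_in, "n_out": n_out, **extra}
        )

    def counts(self) -> dict[str, int]:
        return {s["stage"]: s["n_out"] for s in self.stages}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "stages": self.stages,
                    "warnings": self.warnings,
                    "completed": self.completed,
                },
                fh,
                sort_keys=False,
            )


def _load_inputs(
    cfg: PipelineConfig, outdir: Path
) -> tuple[DosageMatrix, ExposureSet, IdpMatrix, pd.DataFrame]:
    if cfg.sim is not None:
        genotypes, exposures, idps, truth = simulate_cohort(cfg.sim)
        inputs = outdir / "inputs"
        inputs.mkdir(exist_ok=True)
        io_mod.write_dosage_table(genotypes, inputs / "dosages.tsv")
        io_mod.write_exposures(
            exposures, inputs / "exposures.tsv", inputs / "trajectories.tsv"
        )
        io_mod.write_idps(idps, inputs / "idps.tsv")
        truth.covariates.to_csv(inputs / "covariates.tsv", sep="\t", index=False)
        io_mod.write_truth(truth, inputs / "truth.yaml")
        return genotypes, exposures, idps, truth.covariates
    if not (cfg.genotypes_path and cfg.exposures_path and cfg.idps_path and cfg.covariates_path):
        raise ValueError("either sim or all input paths must be provided")
    genotypes, _ = io_mod.read_genotypes(cfg.genotypes_path, cfg.genotype_format)
    exposures = io_mod.read_exposures(cfg.exposures_path, cfg.trajectories_path)
    idps = io_mod.read_idps(cfg.idps_path)
    covariates = pd.read_csv(cfg.covariates_path, sep="\t")
    return genotypes, exposures, idps, covariates


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run all stages in order and write stage outputs under ``outdir``."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()

    genotypes, exposures, idps, covar_base = _load_inputs(cfg, outdir)

    # --- stage: prep -------------------------------------------------------
    genotypes, n_maf_dropped = genotypes.filter_maf(cfg.maf_threshold)
    n_scanners = len(pd.unique(idps.scanners))
    if cfg.harmonize and n_scanners >= 2:
        protect_cols = [c for c in ("age", "sex") if c in covar_base.columns]
        idps = combat_harmonize(
            idps,
            protect=covar_base[protect_cols] if protect_cols else None,
            min_scanner_n=cfg.min_scanner_n,
        )
    transformed = idps.values.copy()
    for col in transformed.columns:
        transformed[col] = inverse_normal_transform(transformed[col].to_numpy())
    idps = IdpMatrix(transformed, categories=idps.categories, scanners=idps.scanners)
    pcs = compute_genetic_pcs(genotypes, k=cfg.n_pcs)
    base = pd.concat(
        [covar_base.reset_index(drop=True).drop(
            columns=[c for c in covar_base.columns if c.startswith("PC")]
        ), pcs], axis=1,
    )
    io_mod.write_idps(idps, outdir / "idps_prepared.tsv")
    manifest.log_stage(
        "prep", idps.n_idps, idps.n_idps, maf_filtered=n_maf_dropped
    )

    # --- stage: cluster ----------------------------------------------------
    corr = spearman_matrix(exposures)
    clustering = cluster_exposures(corr)
    pd.DataFrame(
        {"exposure": exposures.exposure_names, "cluster": clustering.labels}
    ).to_csv(outdir / "exposure_clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"k": list(clustering.ch_by_k), "CH": list(clustering.ch_by_k.values())}
    ).to_csv(outdir / "ch_by_k.tsv", sep="\t", index=False)
    if not clustering.reliable:
        manifest.warnings.append("exposure clustering: no pronounced CH optimum")
    manifest.log_stage("cluster", exposures.n_exposures, int(clustering.k))

    # --- stage: scan -------------------------------------------------------
    scans_dir = outdir / "scans"
    scans_dir.mkdir(exist_ok=True)
    sig_rows: list[pd.DataFrame] = []
    n_tests = 0
    covars_by_cat = {
        cat: assemble_covariates(base, cat)
        for cat in pd.unique(idps.categories)
    }
    for idp_name in idps.values.columns:
        cat = idps.category_of(idp_name)
        C = covars_by_cat[cat]
        y = idps.values[idp_name].to_numpy()
        for exp_name in exposures.exposure_names:
            summary = genome_scan(
                genotypes,
                exposures.values[exp_name].to_numpy(),
                y,
                C,
                maf_threshold=cfg.maf_threshold,
                exposure_name=exp_name,
                idp_name=idp_name,
            )
            n_tests += len(summary.records)
            sig = summary.significant(cfg.genome_wide_p)
            if len(sig):
                summary.records.to_csv(
                    scans_dir / f"{exp_name}__{idp_name}.tsv", sep="\t", index=False
                )
                sig = sig.copy()
                sig["EXPOSURE"] = exp_name
                sig["IDP"] = idp_name
                sig["LAMBDA_GC"] = summary.lambda_gc
                sig_rows.append(sig)
    significant = (
        pd.concat(sig_rows, ignore_index=True)
        if sig_rows
        else pd.DataFrame(columns=["ID", "CHR", "POS", "P", "P_GC", "EXPOSURE", "IDP"])
    )
    significant.to_csv(outdir / "significant_interactions.tsv", sep="\t", index=False)
    manifest.log_stage("scan", n_tests, len(significant))
    if significant.empty:
        manifest.log_stage("clump", 0, 0)
        manifest.log_stage("condition", 0, 0)
        manifest.log_stage("verify", 0, 0)
        manifest.log_stage("effects", 0, 0)
        manifest.log_stage("dlm", 0, 0)
        manifest.completed = True
        manifest.write(outdir / "manifest.yaml")
        return manifest

    # --- stage: clump + conditional ---------------------------------------
    # LD-independent interactions per exposure-IDP scan
    ld_independent: list[pd.DataFrame] = []
    for (exp_name, idp_name), grp in significant.groupby(["EXPOSURE", "IDP"]):
        res = clump_mod.ld_clump(
            grp, genotypes, window=cfg.clump_window, r2_threshold=cfg.clump_r2,
            p_threshold=cfg.genome_wide_p,
        )
        ld_independent.append(res.leads)
    ld_ind = pd.concat(ld_independent, ignore_index=True)
    # LD-independent variant-IDP pairs: clump across exposures per IDP
    pair_rows = []
    for idp_name, grp in significant.groupby("IDP"):
        best = grp.sort_values("P", kind="mergesort").drop_duplicates("ID")
        res = clump_mod.ld_clump(
            best, genotypes, window=cfg.clump_window, r2_threshold=cfg.clump_r2,
            p_threshold=cfg.genome_wide_p,
        )
        for _, lead in res.leads.iterrows():
            pair_rows.append({"IDP": idp_name, "ID": lead["ID"],
                              "CHR": lead["CHR"], "POS": lead["POS"]})
    pairs = pd.DataFrame(pair_rows)
    pairs["PAIR"] = pairs["ID"].astype(str) + "|" + pairs["IDP"].astype(str)
    ld_ind.to_csv(outdir / "ld_independent.tsv", sep="\t", index=False)
    manifest.log_stage("clump", len(significant), len(ld_ind), n_pairs=len(pairs))

    # conditional selection within each variant-IDP pair
    idx_of = {str(v): j for j, v in enumerate(genotypes.variants["id"])}
    independent_rows = []
    cond_log: list[str] = []
    for _, pair in pairs.iterrows():
        cand = ld_ind[
            (ld_ind["ID"].astype(str) == str(pair["ID"]))
            & (ld_ind["IDP"] == pair["IDP"])
        ]
        if cand.empty:
            continue
        cat = idps.category_of(pair["IDP"])
        sel, log = clump_mod.conditional_select(
            cand[["EXPOSURE", "P"]],
            idps.values[pair["IDP"]].to_numpy(),
            genotypes.dosages[:, idx_of[str(pair["ID"])]],
            exposures.values,
            covars_by_cat[cat],
            p_threshold=cfg.genome_wide_p,
        )
        cond_log.extend(log)
        for _, r in sel.iterrows():
            independent_rows.append(
                {"PAIR": pair["PAIR"], "ID": pair["ID"], "IDP": pair["IDP"],
                 "EXPOSURE": r["EXPOSURE"], "P": r["P"],
                 "P_CONDITIONAL": r["P_CONDITIONAL"]}
            )
    independent = pd.DataFrame(independent_rows)
    independent.to_csv(outdir / "independent_interactions.tsv", sep="\t", index=False)
    manifest.warnings.extend(cond_log)
    manifest.log_stage("condition", len(ld_ind), len(independent))

    # --- stage: multivariate verification ----------------------------------
    complete_exposures = exposures.values.dropna()
    score_rows = []
    bf_tables: dict[str, pd.DataFrame] = {}
    for pair_id in independent["PAIR"].unique():
        vid, idp_name = pair_id.split("|", 1)
        cat = idps.category_of(idp_name)
        g = genotypes.dosages[:, idx_of[vid]]
        try:
            null = fit_null_lmm(
                idps.values[idp_name].to_numpy(),
                covars_by_cat[cat],
                g,
                exposures.values,
            )
            sc = score_test_gxe(null)
            bf_tables[pair_id] = exposure_bayes_factors(
                null, exposures.exposure_names
            )
            score_rows.append(
                {"PAIR": pair_id, "SCORE_P": sc.p, "Q_STAT": sc.Q, "N": sc.n}
            )
        except ValueError as exc:
            manifest.warnings.append(f"structlmm {pair_id}: {exc}")
    if score_rows:
        verification = verify_interactions(
            independent, pd.DataFrame(score_rows), bf_tables, cfg.fdr_level
        )
        verified = verification.interactions[verification.interactions["VERIFIED"]]
        verification.interactions.to_csv(
            outdir / "verification.tsv", sep="\t", index=False
        )
    else:
        verified = pd.DataFrame(columns=["PAIR", "EXPOSURE"])
    manifest.log_stage("verify", len(independent), len(verified))

    # merged loci for the verified pairs
    if len(verified):
        lead_meta = pairs[pairs["PAIR"].isin(verified["PAIR"])][["ID", "CHR", "POS"]]
        loci = clump_mod.merge_loci(
            lead_meta.drop_duplicates("ID"), genotypes,
            window=cfg.clump_window, r2_threshold=cfg.clump_r2,
        )
        io_mod.write_loci_bed(loci, outdir / "loci.bed")

    # --- stage: effects ----------------------------------------------------
    effect_rows = []
    subgroup_rows = []
    for _, rec in verified.iterrows():
        vid, idp_name = rec["PAIR"].split("|", 1)
        cat = idps.category_of(idp_name)
        C = covars_by_cat[cat]
        y = idps.values[idp_name].to_numpy()
        g = genotypes.dosages[:, idx_of[vid]]
        e = exposures.values[rec["EXPOSURE"]].to_numpy()
        gfit, efit = main_effect_models(y, g, e, C)
        gs = (g - np.nanmean(g)) / np.nanstd(g)
        es = (e - np.nanmean(e)) / np.nanstd(e)
        design = C.copy()
        design.insert(0, "g", gs)
        design.insert(1, "e", es)
        design.insert(2, "g_x_e", gs * es)
        effect_rows.append(
            {
                "PAIR_ID": rec["PAIR"],
                "EXPOSURE": rec["EXPOSURE"],
                "ETA2_GXE": eta_squared(y, design, "g_x_e").eta2,
                "ETA2_G": eta_squared(y, design.drop(columns=["e", "g_x_e"]), "g").eta2,
                "ETA2_E": eta_squared(y, design.drop(columns=["g", "g_x_e"]), "e").eta2,
                "P_G": gfit.p["g"],
                "P_E": efit.p["e"],
            }
        )
        sub = genotype_subgroups(y, g, e, C)
        for _, b in sub.bins.iterrows():
            subgroup_rows.append(
                {"PAIR_ID": rec["PAIR"], "EXPOSURE": rec["EXPOSURE"], **b.to_dict()}
            )
    pd.DataFrame(effect_rows).to_csv(outdir / "effects.tsv", sep="\t", index=False)
    pd.DataFrame(subgroup_rows).to_csv(outdir / "subgroups.tsv", sep="\t", index=False)
    manifest.log_stage("effects", len(verified), len(effect_rows))

    # --- stage: distributed-lag sensitive periods ---------------------------
    dlm_rows = []
    window_rows = []
    n_dlm = 0
    for _, rec in verified.iterrows():
        exp_name = rec["EXPOSURE"]
        if exp_name not in exposures.trajectories:
            continue
        vid, idp_name = rec["PAIR"].split("|", 1)
        traj = exposures.trajectories[exp_name]
        try:
            traj_used, (lag_lo, lag_hi) = dlm_mod.truncate_lags_for_missingness(
                traj, min_n=min(cfg.dlm_min_n, traj.shape[0] // 2)
            )
            basis = dlm_mod.build_lag_basis(lag_hi - lag_lo + 1, cfg.dlm_df)
            fit = dlm_mod.fit_dlm(
                idps.values[idp_name].to_numpy(),
                traj_used,
                genotypes.dosages[:, idx_of[vid]],
                covars_by_cat[idps.category_of(idp_name)],
                basis,
                lag_offset=lag_lo - 1,
            )
        except ValueError as exc:
            manifest.warnings.append(f"dlm {rec['PAIR']} x {exp_name}: {exc}")
            continue
        n_dlm += 1
        windows = dlm_mod.extract_sensitive_periods(fit)
        for age, gm, se, lo_ci, hi_ci, fl in zip(
            fit.ages, fit.gamma, fit.gamma_se, fit.ci_lo, fit.ci_hi, fit.flagged
        ):
            dlm_rows.append(
                {
                    "INTERACTION_ID": f"{rec['PAIR']}|{exp_name}",
                    "AGE": int(age),
                    "GAMMA": gm,
                    "SE": se,
                    "CI_LO": lo_ci,
                    "CI_HI": hi_ci,
                    "FLAGGED": bool(fl),
                }
            )
        for lo_w, hi_w in windows:
            window_rows.append(
                {
                    "INTERACTION_ID": f"{rec['PAIR']}|{exp_name}",
                    "START_AGE": lo_w,
                    "END_AGE": hi_w,
                    "FULL_LAG_RANGE": (lag_lo == 1 and lag_hi == traj.shape[1]),
                }
            )
    pd.DataFrame(dlm_rows).to_csv(outdir / "sensitive_periods.tsv", sep="\t", index=False)
    pd.DataFrame(window_rows).to_csv(outdir / "sensitive_windows.tsv", sep="\t", index=False)
    manifest.log_stage("dlm", len(verified), n_dlm)

    manifest.completed = True
    manifest.stages.append({"stage": "total_runtime_s", "n_in": 0,
                            "n_out": round(time.time() - t0, 1)})
    manifest.write(outdir / "manifest.yaml")
    return manifest
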