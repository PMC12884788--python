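"""Reading and writing the pipeline's on-disk formats.

Genotypes travel as VCF with a DS (dosage) FORMAT field or as a
PLINK-style tab-separated dosage table (variants in rows, samples in
columns).  Exposures, trajectories, IDPs and covariates are TSV with
headers; loci export as BED (0-based half-open, converted from the 1-based
inclusive coordinates used internally); ground truth serializes to YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clump import Locus
from .containers import DosageMatrix, ExposureSet, IdpMatrix
from .simulate import CohortTruth

__all__ = [
    "write_vcf_dosage",
    "write_dosage_table",
    "read_genotypes",
    "write_exposures",
    "read_exposures",
    "write_idps",
    "read_idps",
    "write_loci_bed",
    "write_truth",
]


def write_vcf_dosage(genotypes: DosageMatrix, path: str | Path) -> None:
    """Write dosages as an uncompressed VCF with a DS FORMAT field."""
    path = Path(path)
    samples = "\t".join(map(str, genotypes.participants))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated allelic dosage">\n'
        )
        if "is_par" in genotypes.variants.columns:
            fh.write('##INFO=<ID=PAR,Number=0,Type=Flag,Description="Pseudo-autosomal">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, row in genotypes.variants.iterrows():
            info = "PAR" if row.get("is_par", False) else "."
            ds = "\t".join(f"{d:.3f}" for d in genotypes.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t{info}\tDS\t{ds}\n"
            )


def write_dosage_table(genotypes: DosageMatrix, path: str | Path) -> None:
    """PLINK-style text dosage table: one variant per row, samples in columns."""
    meta = genotypes.variants
    cols = {"CHR": meta["chrom"], "POS": meta["pos"], "ID": meta["id"],
            "A1": meta["alt"], "A2": meta["ref"]}
    df = pd.concat(
        [
            pd.DataFrame(cols),
            pd.DataFrame(
                genotypes.dosages.T, columns=[str(p) for p in genotypes.participants]
            ),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def _read_vcf_dosage(path: Path) -> DosageMatrix:
    samples: list[str] = []
    dosage_rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    n_fixed = 9
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < n_fixed + 1:
                    raise ValueError(f"line {lineno}: VCF header has no samples")
                samples = fields[n_fixed:]
                header_seen = True
                continue
            if not line:
                continue
            if not header_seen:
                raise ValueError(f"line {lineno}: record before #CHROM header")
            fields = line.split("\t")
            if len(fields) != n_fixed + len(samples):
                raise ValueError(
                    f"line {lineno}: expected {n_fixed + len(samples)} fields, "
                    f"got {len(fields)} (truncated or malformed record)"
                )
            fmt = fields[8].split(":")
            if "DS" not in fmt:
                raise ValueError(f"line {lineno}: no DS field in FORMAT")
            ds_idx = fmt.index("DS")
            try:
                ds = np.array(
                    [float(f.split(":")[ds_idx]) for f in fields[n_fixed:]]
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"line {lineno}: malformed DS value ({exc})") from exc
            if np.nanmin(ds) < -1e-9 or np.nanmax(ds) > 2 + 1e-9:
                raise ValueError(f"line {lineno}: dosage outside [0, 2]")
            dosage_rows.append(ds)
            meta_rows.append(
                {
                    "chrom": fields[0].removeprefix("chr"),
                    "pos": int(fields[1]),
                    "id": fields[2],
                    "ref": fields[3],
                    "alt": fields[4],
                    "is_par": "PAR" in fields[7].split(";"),
                }
            )
    if not meta_rows:
        raise ValueError("no variant records found")
    return DosageMatrix(
        np.array(dosage_rows).T, pd.DataFrame(meta_rows), np.array(samples)
    )


def _read_dosage_table(path: Path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t")
    required = ["CHR", "POS", "ID", "A1", "A2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"dosage table missing column(s): {', '.join(missing)}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise ValueError("dosage table has no sample columns")
    dosages = df[sample_cols].to_numpy(dtype=float).T
    meta = pd.DataFrame(
        {
            "chrom": df["CHR"].astype(str),
            "pos": df["POS"].astype(int),
            "id": df["ID"].astype(str),
            "ref": df["A2"].astype(str),
            "alt": df["A1"].astype(str),
            "is_par": df.get("IS_PAR", pd.Series(False, index=df.index)).astype(bool),
        }
    )
    return DosageMatrix(dosages, meta, np.array(sample_cols))


def read_genotypes(
    path: str | Path,
    fmt: str | None = None,
    maf_threshold: float = 0.0,
) -> tuple[DosageMatrix, int]:
    """Load dosages from VCF (DS field) or a PLINK-style text dosage table.

    Variants below ``maf_threshold`` are filtered; returns (genotypes,
    n_filtered).  Malformed records raise with the offending line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf-dosage" if path.suffix.lower() == ".vcf" else "plink-text"
    if fmt == "vcf-dosage":
        geno = _read_vcf_dosage(path)
    elif fmt == "plink-text":
        geno = _read_dosage_table(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if maf_threshold > 0:
        return geno.filter_maf(maf_threshold)
    return geno, 0


def write_exposures(exposures: ExposureSet, values_path: str | Path,
                    trajectories_path: str | Path | None = None) -> None:
    """Exposure values as wide TSV; trajectories (if any) as long TSV."""
    out = exposures.values.copy()
    out.insert(0, "participant", np.arange(len(out)))
    if exposures.cluster_labels is not None:
        pd.DataFrame(
            {"exposure": exposures.exposure_names, "cluster": exposures.cluster_labels}
        ).to_csv(str(values_path) + ".clusters.tsv", sep="\t", index=False)
    out.to_csv(values_path, sep="\t", index=False)
    if trajectories_path is not None and exposures.trajectories:
        frames = []
        for name, traj in exposures.trajectories.items():
            n, L = traj.shape
            frames.append(
                pd.DataFrame(
                    {
                        "participant": np.repeat(np.arange(n), L),
                        "exposure": name,
                        "age": np.tile(np.arange(1, L + 1), n),
                        "value": traj.ravel(),
                    }
                )
            )
        pd.concat(frames).to_csv(trajectories_path, sep="\t", index=False, na_rep="NA")


def read_exposures(
    values_path: str | Path, trajectories_path: str | Path | None = None
) -> ExposureSet:
    values = pd.read_csv(values_path, sep="\t")
    values = values.drop(columns=[c for c in ("participant",) if c in values.columns])
    trajectories: dict[str, np.ndarray] = {}
    if trajectories_path is not None and Path(trajectories_path).exists():
        long = pd.read_csv(trajectories_path, sep="\t", na_values=["NA"])
        for name, grp in long.groupby("exposure"):
            wide = grp.pivot(index="participant", columns="age", values="value")
            trajectories[str(name)] = wide.sort_index().to_numpy()
    return ExposureSet(values, trajectories=trajectories)


def write_idps(idps: IdpMatrix, path: str | Path) -> None:
    out = idps.values.copy()
    out.insert(0, "participant", np.arange(len(out)))
    out.insert(1, "scanner", idps.scanners)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
    pd.DataFrame({"idp": idps.values.columns, "category": idps.categories}).to_csv(
        str(path) + ".categories.tsv", sep="\t", index=False
    )


def read_idps(path: str | Path) -> IdpMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    scanners = df["scanner"].to_numpy()
    values = df.drop(columns=["participant", "scanner"], errors="ignore")
    cat_path = Path(str(path) + ".categories.tsv")
    if cat_path.exists():
        cats = pd.read_csv(cat_path, sep="\t").set_index("idp")["category"]
        categories = cats.reindex(values.columns).to_numpy()
    else:
        categories = np.array(["GMV"] * values.shape[1])
    return IdpMatrix(values, categories=categories, scanners=scanners)


def write_loci_bed(loci: list[Locus], path: str | Path) -> None:
    """Loci as BED: 0-based half-open, converted from 1-based inclusive."""
    with open(path, "w") as fh:
        for lc in loci:
            name = ",".join(lc.members)
            fh.write(f"{lc.chrom}\t{lc.start - 1}\t{lc.end}\t{name}\n")


def write_truth(truth: CohortTruth, path: str | Path) -> None:
    doc = {
        "planted_effects": [
            {
                "variant_index": e.variant_index,
                "exposure_index": e.exposure_index,
                "idp_index": e.idp_index,
                "interaction_eta2": e.interaction_eta2,
                "genetic_main_eta2": e.genetic_main_eta2,
                "environmental_main_eta2": e.environmental_main_eta2,
                "sensitive_window": list(e.sensitive_window)
                if e.sensitive_window
                else None,
            }
            for e in truth.planted_effects
        ],
        "realized_eta2": truth.realized_eta2,
        "exposure_clusters": truth.exposure_clusters.tolist()
        if truth.exposure_clusters is not None
        else None,
        "scanner_shift": truth.scanner_shift.tolist()
        if truth.scanner_shift is not None
        else None,
        "scanner_scale": truth.scanner_scale.tolist()
        if truth.scanner_scale is not None
        else None,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
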