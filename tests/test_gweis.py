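"""Univariate interaction scan: model fit, X coding, genomic control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gweistools as gt


def _x_genotypes(dosages, is_par):
    m = dosages.shape[1]
    meta = pd.DataFrame(
        {"chrom": "X", "pos": np.arange(1, m + 1) * 1000,
         "id": [f"x{j}" for j in range(m)], "ref": "A", "alt": "G",
         "is_par": is_par}
    )
    return gt.DosageMatrix(dosages, meta)


class TestEncodeXDosage:
    def test_male_hemizygous_doubled(self):
        geno = _x_genotypes(np.array([[1.0], [0.5], [1.0]]), [False])
        out = gt.encode_x_dosage(geno, sex=np.array([1, 1, 0]))
        assert out.dosages[0, 0] == 2.0
        assert out.dosages[1, 0] == 1.0
        assert out.dosages[2, 0] == 1.0  # female unchanged

    def test_par_variant_untouched(self):
        geno = _x_genotypes(np.array([[1.0], [2.0]]), [True])
        out = gt.encode_x_dosage(geno, sex=np.array([1, 0]))
        assert out.dosages[0, 0] == 1.0

    def test_autosomes_unchanged(self, toy_genotypes):
        sex = np.tile([0, 1], 100)
        out = gt.encode_x_dosage(toy_genotypes, sex)
        assert np.array_equal(out.dosages, toy_genotypes.dosages)

    def test_inconsistent_male_dosage_rejected(self):
        geno = _x_genotypes(np.array([[1.6], [0.5]]), [False])
        with pytest.raises(ValueError, match="non-PAR"):
            gt.encode_x_dosage(geno, sex=np.array([1, 0]))


class TestFitInteractionModel:
    def test_exact_recovery_of_pure_interaction(self, rng):
        n = 300
        g = rng.binomial(2, 0.3, n).astype(float)
        e = rng.standard_normal(n)
        gs = (g - g.mean()) / g.std()
        es = (e - e.mean()) / e.std()
        fit = gt.fit_interaction_model(0.5 * gs * es, g, e)
        assert fit.beta_ge == pytest.approx(0.5, abs=1e-12)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-20)

    def test_matches_brute_force_normal_equations(self, rng):
        n = 50
        g = rng.binomial(2, 0.4, n).astype(float)
        e = rng.standard_normal(n)
        C = pd.DataFrame(rng.standard_normal((n, 1)), columns=["c0"])
        y = rng.standard_normal(n)
        fit = gt.fit_interaction_model(y, g, e, C)
        gs = (g - g.mean()) / g.std()
        es = (e - e.mean()) / e.std()
        X = np.column_stack([np.ones(n), gs, es, gs * es, C["c0"]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.abs(fit.coef.to_numpy() - beta).max() < 1e-10

    def test_type_one_error_calibrated(self, rng):
        n, reps = 500, 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        e = rng.standard_normal(n)
        rejections = 0
        Y = rng.standard_normal((n, reps))
        gs = (g - g.mean()) / g.std()
        es = (e - e.mean()) / e.std()
        X = np.column_stack([np.ones(n), gs, es, gs * es])
        coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        dof = n - 4
        sigma2 = (resid**2).sum(axis=0) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * xtx_inv[3, 3])
        t = coef[3] / se
        p = 2 * stats.t.sf(np.abs(t), dof)
        rejections = (p < 0.05).mean()
        assert abs(rejections - 0.05) < 0.01
        # spot-check the vectorized null against the model API
        fit = gt.fit_interaction_model(Y[:, 0], g, e)
        assert fit.p_ge == pytest.approx(p[0], rel=1e-9)

    def test_constant_genotype_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            gt.fit_interaction_model(
                rng.standard_normal(100), np.ones(100), rng.standard_normal(100)
            )

    def test_t_equals_beta_over_se(self, rng):
        fit = gt.fit_interaction_model(
            rng.standard_normal(200),
            rng.binomial(2, 0.3, 200).astype(float),
            rng.standard_normal(200),
        )
        assert np.allclose(np.abs(fit.t), np.abs(fit.coef / fit.se))


class TestGenomeScan:
    def test_record_bookkeeping(self, toy_genotypes, rng):
        n = toy_genotypes.n_participants
        geno = gt.DosageMatrix(
            np.column_stack([toy_genotypes.dosages, np.ones(n)]),
            pd.concat(
                [toy_genotypes.variants,
                 pd.DataFrame({"chrom": ["1"], "pos": [999_999], "id": ["mono"],
                               "ref": "A", "alt": "G", "is_par": False})],
                ignore_index=True,
            ),
        )
        summary = gt.genome_scan(
            geno, rng.standard_normal(n), rng.standard_normal(n),
            maf_threshold=0.0, adjust=False,
        )
        assert len(summary.records) + len(summary.skipped) == geno.n_variants
        assert any("mono" in s for s in summary.skipped)

    def test_maf_filter_applied(self, rng):
        n = 500
        rare = np.zeros(n)
        rare[:10] = 1.0  # MAF 0.01
        common = rng.binomial(2, 0.3, n).astype(float)
        meta = pd.DataFrame({"chrom": "1", "pos": [100, 200],
                             "id": ["rare", "common"], "ref": "A", "alt": "G",
                             "is_par": False})
        geno = gt.DosageMatrix(np.column_stack([rare, common]), meta)
        summary = gt.genome_scan(
            geno, rng.standard_normal(n), rng.standard_normal(n), adjust=False
        )
        assert list(summary.records["ID"]) == ["common"]

    def test_scan_invariant_to_exposure_units(self, toy_genotypes, rng):
        n = toy_genotypes.n_participants
        e = rng.standard_normal(n)
        y = rng.standard_normal(n)
        a = gt.genome_scan(toy_genotypes, e, y, adjust=False)
        b = gt.genome_scan(toy_genotypes, 3.7 * e + 11.0, y, adjust=False)
        assert np.allclose(a.records["P"], b.records["P"])
        assert np.allclose(a.records["BETA_GxE"], b.records["BETA_GxE"])

    def test_allele_flip_flips_interaction_sign(self, toy_genotypes, rng):
        n = toy_genotypes.n_participants
        e = rng.standard_normal(n)
        y = rng.standard_normal(n)
        flipped = gt.DosageMatrix(
            2.0 - toy_genotypes.dosages, toy_genotypes.variants
        )
        a = gt.genome_scan(toy_genotypes, e, y, adjust=False)
        b = gt.genome_scan(flipped, e, y, adjust=False)
        assert np.allclose(a.records["BETA_GxE"], -b.records["BETA_GxE"])
        assert np.allclose(np.abs(a.records["T"]), np.abs(b.records["T"]))

    def test_dimension_mismatch_rejected(self, toy_genotypes, rng):
        with pytest.raises(ValueError, match="row counts"):
            gt.genome_scan(
                toy_genotypes, rng.standard_normal(7), rng.standard_normal(7)
            )


class TestGenomicControl:
    def _summary(self, pvals):
        n = len(pvals)
        records = pd.DataFrame(
            {"CHR": "1", "POS": np.arange(n), "ID": [f"v{i}" for i in range(n)],
             "A1": "G", "A2": "A", "A1FREQ": 0.3, "N": 1000,
             "BETA_GxE": 0.0, "SE": 1.0, "T": 0.0, "P": pvals, "P_GC": np.nan}
        )
        return gt.ScanSummary(records=records)

    def test_null_median_gives_lambda_one(self):
        p_at_null_median = stats.chi2.sf(0.4549, 1)
        pvals = np.full(201, p_at_null_median)
        out = gt.genomic_control_adjust(self._summary(pvals))
        assert out.lambda_gc == pytest.approx(1.0, abs=1e-3)
        assert np.allclose(out.records["P_GC"], out.records["P"])

    def test_twofold_inflation_deflates_chi_square(self):
        # median chi2 = 0.9098 -> lambda 2; chi2 29.72 -> 14.86
        base_p = stats.chi2.sf(0.9098, 1)
        pvals = np.full(201, base_p)
        pvals[0] = stats.chi2.sf(29.72, 1)
        out = gt.genomic_control_adjust(self._summary(pvals))
        assert out.lambda_gc == pytest.approx(2.0, abs=1e-3)
        assert out.records["P_GC"].iloc[0] == pytest.approx(1.16e-4, rel=0.01)
        assert (out.records["P_GC"] >= out.records["P"] - 1e-15).all()

    def test_lambda_matches_brute_force_median(self, rng):
        chi2 = 1.8 * rng.chisquare(1, 500)
        pvals = stats.chi2.sf(chi2, 1)
        out = gt.genomic_control_adjust(self._summary(pvals))
        assert out.lambda_gc == pytest.approx(np.median(chi2) / 0.4549, rel=1e-6)

    def test_deflation_never_applied_below_one(self, rng):
        pvals = np.clip(rng.random(300) * 0.5 + 0.5, None, 1.0)  # deflated stats
        out = gt.genomic_control_adjust(self._summary(pvals))
        assert out.lambda_gc < 1
        assert np.allclose(out.records["P_GC"], out.records["P"])

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gt.genomic_control_adjust(self._summary(np.array([])))

    def test_few_records_warns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            gt.genomic_control_adjust(self._summary(np.full(50, 0.5)))

    def test_null_scan_lambda_near_one(self):
        cfg = gt.SimConfig(n_participants=1500, n_variants=4000, ld_decay=0.2, seed=77)
        geno = gt.simulate_genotypes(cfg)
        r = np.random.default_rng(7)
        summary = gt.genome_scan(
            geno, r.standard_normal(1500), r.standard_normal(1500)
        )
        assert summary.lambda_gc == pytest.approx(1.0, abs=0.05)
        assert stats.kstest(summary.records["P_GC"], "uniform").pvalue > 0.01
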