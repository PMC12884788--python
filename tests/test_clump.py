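"""LD clumping, conditional selection, and locus merging."""

import numpy as np
import pandas as pd
import pytest

import gweistools as gt
from conftest import make_ld_instance


class TestLdR2:
    def test_identical_vectors(self, rng):
        g = rng.binomial(2, 0.3, 50).astype(float)
        assert gt.ld_r2(g, g) == pytest.approx(1.0)

    def test_allele_flip_invariant(self, rng):
        g = rng.binomial(2, 0.3, 50).astype(float)
        assert gt.ld_r2(g, 2.0 - g) == pytest.approx(1.0)

    def test_matches_pearson_squared(self):
        g1 = np.array([0.0, 0, 1, 2, 2, 1])
        g2 = np.array([1.0, 0, 2, 0, 1, 1])
        brute = np.corrcoef(g1, g2)[0, 1] ** 2
        assert gt.ld_r2(g1, g2) == pytest.approx(brute, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gt.ld_r2(np.ones(10), np.arange(10.0))


def _geno_from_columns(cols, positions, chrom="1"):
    dosages = np.column_stack(cols)
    meta = pd.DataFrame(
        {"chrom": chrom, "pos": positions,
         "id": [f"v{j}" for j in range(len(cols))],
         "ref": "A", "alt": "G", "is_par": False}
    )
    return gt.DosageMatrix(dosages, meta)


class TestLdClump:
    @pytest.fixture()
    def abc(self, rng):
        """A and B in LD 50 kb apart; C independent 100 kb away; D far."""
        n = 400
        a = rng.binomial(2, 0.3, n).astype(float)
        b = np.clip(a + (rng.random(n) < 0.1) * rng.choice([-1.0, 1.0], n), 0, 2)
        c = rng.binomial(2, 0.3, n).astype(float)
        d = np.clip(a + (rng.random(n) < 0.05) * rng.choice([-1.0, 1.0], n), 0, 2)
        geno = _geno_from_columns(
            [a, b, c, d], [1_000_000, 1_050_000, 1_100_000, 1_700_000]
        )
        records = pd.DataFrame(
            {"ID": ["v0", "v1", "v2", "v3"], "CHR": "1",
             "POS": [1_000_000, 1_050_000, 1_100_000, 1_700_000],
             "P": [1e-10, 1e-9, 1e-8, 1e-9]}
        )
        return records, geno

    def test_greedy_worked_example(self, abc):
        records, geno = abc
        res = gt.ld_clump(records.iloc[:3], geno)
        assert res.lead_ids == ["v0", "v2"]
        assert res.assignment["v1"] == "v0"

    def test_outside_window_stays_lead_despite_ld(self, abc):
        records, geno = abc
        res = gt.ld_clump(records, geno)
        # v3 is in strong LD with v0 but 700 kb away: both conditions required
        assert "v3" in res.lead_ids

    def test_single_variant_is_own_lead(self, abc):
        records, geno = abc
        res = gt.ld_clump(records.iloc[[0]], geno)
        assert res.lead_ids == ["v0"]
        assert res.assignment == {"v0": "v0"}

    def test_equal_p_tie_breaks_to_lower_position(self, rng):
        n = 300
        a = rng.binomial(2, 0.3, n).astype(float)
        b = rng.binomial(2, 0.3, n).astype(float)
        geno = _geno_from_columns([a, b], [2_000_000, 1_000_000])
        records = pd.DataFrame(
            {"ID": ["v0", "v1"], "CHR": "1", "POS": [2_000_000, 1_000_000],
             "P": [1e-9, 1e-9]}
        )
        res = gt.ld_clump(records, geno)
        assert res.lead_ids[0] == "v1"

    def test_missing_genotype_column_rejected(self, abc):
        records, geno = abc
        bad = records.copy()
        bad.loc[0, "ID"] = "nonexistent"
        with pytest.raises(ValueError, match="no genotype column"):
            gt.ld_clump(bad, geno)

    def test_matches_exhaustive_greedy_oracle(self):
        """Greedy clumping equals an independent step-by-step enumeration."""
        for seed in range(25):
            records, geno = make_ld_instance(seed)
            res = gt.ld_clump(records, geno)
            # oracle: literal restatement of the printed procedure
            remaining = records.sort_values(["P", "POS"]).to_dict("records")
            idx = {v: j for j, v in enumerate(geno.variants["id"])}
            leads = []
            while remaining:
                lead = remaining.pop(0)
                leads.append(lead["ID"])
                keep = []
                for r in remaining:
                    near = abs(r["POS"] - lead["POS"]) <= 500_000
                    g1 = geno.dosages[:, idx[lead["ID"]]]
                    g2 = geno.dosages[:, idx[r["ID"]]]
                    linked = near and np.corrcoef(g1, g2)[0, 1] ** 2 > 0.1
                    if not linked:
                        keep.append(r)
                remaining = keep
            assert res.lead_ids == leads


class TestConditionalSelect:
    def test_single_candidate_returned_unchanged(self, rng):
        n = 600
        g = rng.binomial(2, 0.3, n).astype(float)
        e = rng.standard_normal(n)
        y = rng.standard_normal(n)
        recs = pd.DataFrame({"EXPOSURE": ["e0"], "P": [1e-9]})
        sel, log = gt.conditional_select(recs, y, g, pd.DataFrame({"e0": e}))
        assert list(sel["EXPOSURE"]) == ["e0"]
        assert log == []

    def test_collinear_exposures_pruned_to_true_driver(self):
        """rho=0.95 proxy exposure is removed by conditioning on the driver."""
        hits = 0
        for s in range(20):
            r = np.random.default_rng(80 + s)
            n = 5000
            g = r.binomial(2, 0.3, n).astype(float)
            gs = (g - g.mean()) / g.std()
            e1 = r.standard_normal(n)
            e2 = 0.95 * e1 + np.sqrt(1 - 0.95**2) * r.standard_normal(n)
            y = np.sqrt(0.03) * gs * (e1 - e1.mean()) / e1.std() + r.standard_normal(n)
            f1 = gt.fit_interaction_model(y, g, e1)
            f2 = gt.fit_interaction_model(y, g, e2)
            recs = pd.DataFrame({"EXPOSURE": ["e1", "e2"], "P": [f1.p_ge, f2.p_ge]})
            recs = recs[recs["P"] < 5e-8]
            sel, _ = gt.conditional_select(
                recs, y, g, pd.DataFrame({"e1": e1, "e2": e2})
            )
            hits += list(sel["EXPOSURE"]) == ["e1"]
        assert hits >= 18

    def test_independent_drivers_both_retained(self):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(300 + s)
            n = 5000
            g = r.binomial(2, 0.3, n).astype(float)
            gs = (g - g.mean()) / g.std()
            e1 = r.standard_normal(n)
            e2 = r.standard_normal(n)
            y = (
                np.sqrt(0.02) * gs * e1
                + np.sqrt(0.02) * gs * e2
                + r.standard_normal(n)
            )
            recs = pd.DataFrame(
                {"EXPOSURE": ["e1", "e2"],
                 "P": [gt.fit_interaction_model(y, g, e1).p_ge,
                       gt.fit_interaction_model(y, g, e2).p_ge]}
            )
            recs = recs[recs["P"] < 5e-8]
            if len(recs) < 2:
                continue
            sel, _ = gt.conditional_select(
                recs, y, g, pd.DataFrame({"e1": e1, "e2": e2})
            )
            hits += set(sel["EXPOSURE"]) == {"e1", "e2"}
        assert hits >= 8

    def test_empty_records_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 1"):
            gt.conditional_select(
                pd.DataFrame(columns=["EXPOSURE", "P"]),
                rng.standard_normal(50),
                rng.binomial(2, 0.3, 50).astype(float),
                pd.DataFrame({"e": rng.standard_normal(50)}),
            )


class TestMergeLoci:
    def _leads(self, rows):
        return pd.DataFrame(rows, columns=["ID", "CHR", "POS"])

    def _geno(self, ids, rng, chrom="1"):
        cols = [rng.binomial(2, 0.3, 200).astype(float) for _ in ids]
        meta = pd.DataFrame(
            {"chrom": chrom, "pos": np.arange(1, len(ids) + 1) * 10_000,
             "id": ids, "ref": "A", "alt": "G", "is_par": False}
        )
        return gt.DosageMatrix(np.column_stack(cols), meta)

    def test_mhc_window_absorbed(self, rng):
        geno = self._geno(["a"], rng, chrom="6")
        loci = gt.merge_loci(self._leads([("a", "6", 30_000_000)]), geno)
        assert len(loci) == 1
        assert loci[0].start <= 25_119_106 and loci[0].end >= 33_854_733

    def test_overlapping_windows_merge_without_ld(self, rng):
        geno = self._geno(["a", "b"], rng)
        loci = gt.merge_loci(
            self._leads([("a", "1", 10_000_000), ("b", "1", 10_400_000)]), geno
        )
        assert len(loci) == 1  # 400 kb gap < 500+500 kb windows

    def test_different_chromosomes_never_merge(self, rng):
        ga = self._geno(["a"], rng, chrom="1")
        gb = self._geno(["b"], rng, chrom="2")
        geno = gt.DosageMatrix(
            np.column_stack([ga.dosages, gb.dosages]),
            pd.concat([ga.variants, gb.variants], ignore_index=True),
        )
        loci = gt.merge_loci(
            self._leads([("a", "1", 10_000_000), ("b", "2", 10_000_000)]), geno
        )
        assert len(loci) == 2

    def test_ld_linked_distant_windows_merge(self, rng):
        shared = rng.binomial(2, 0.3, 200).astype(float)
        meta = pd.DataFrame(
            {"chrom": "1", "pos": [10_000_000, 12_000_000], "id": ["a", "b"],
             "ref": "A", "alt": "G", "is_par": False}
        )
        geno = gt.DosageMatrix(np.column_stack([shared, shared]), meta)
        loci = gt.merge_loci(
            self._leads([("a", "1", 10_000_000), ("b", "1", 12_000_000)]), geno
        )
        assert len(loci) == 1

    def test_negative_start_clipped(self, rng):
        geno = self._geno(["a"], rng)
        loci = gt.merge_loci(self._leads([("a", "1", 100_000)]), geno)
        assert loci[0].start == 1

    def test_every_lead_in_exactly_one_locus(self):
        for seed in range(5):
            records, geno = make_ld_instance(seed, n_variants=8)
            leads = records[["ID", "CHR", "POS"]]
            loci = gt.merge_loci(leads, geno)
            members = [m for lc in loci for m in lc.members]
            assert sorted(members) == sorted(leads["ID"])
            assert len(loci) <= len(leads)
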