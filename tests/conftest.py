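import numpy as np
import pandas as pd
import pytest

import gweistools as gt


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 800-participant cohort with one planted interaction."""
    cfg = gt.SimConfig(
        n_participants=800,
        n_variants=60,
        n_exposures=12,
        n_clusters=4,
        within_cluster_rho=0.6,
        missing_rate=0.05,
        n_idps=14,
        seed=3,
        planted_effects=[gt.PlantedEffect(5, 2, 1, interaction_eta2=0.05)],
    )
    return cfg, *gt.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_genotypes(rng):
    """Ten variants on one chromosome, 200 participants."""
    cfg = gt.SimConfig(n_participants=200, n_variants=10, seed=17)
    return gt.simulate_genotypes(cfg)


def make_ld_instance(seed, n_variants=None, n=80):
    """Random clumping instance (records + genotypes) for oracle checks."""
    r = np.random.default_rng(seed)
    m = int(n_variants if n_variants is not None else r.integers(2, 13))
    maf = r.uniform(0.1, 0.5, m)
    base = r.binomial(2, maf[0], n).astype(float)
    cols = []
    for j in range(m):
        fresh = r.binomial(2, maf[j], n).astype(float)
        mix = r.random()
        col = np.where(r.random(n) < mix, base, fresh)
        if col.std() == 0:
            col = fresh
        cols.append(col)
    dosages = np.column_stack(cols)
    pos = np.sort(r.integers(1, 3_000_000, m))
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "id": [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
            "is_par": False,
        }
    )
    records = pd.DataFrame(
        {
            "ID": meta["id"],
            "CHR": "1",
            "POS": pos,
            "P": 10.0 ** (-r.uniform(8, 15, m)),
        }
    )
    return records, gt.DosageMatrix(dosages, meta)
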