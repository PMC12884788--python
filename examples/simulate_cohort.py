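"""Generate a synthetic imaging-genetics cohort with a planted interaction.

Builds 2000 participants with LD-structured dosages, a block-correlated
exposome with 18-year trajectories, and imaging phenotypes carrying one
planted gene-environment interaction, then prints the realized variance
shares against their targets.
"""

import gweistools as gt

cfg = gt.SimConfig(
    n_participants=2000,
    n_variants=300,
    n_exposures=16,
    n_clusters=4,
    within_cluster_rho=0.5,
    missing_rate=0.05,
    n_idps=14,
    seed=7,
    planted_effects=[
        gt.PlantedEffect(
            variant_index=120, exposure_index=3, idp_index=2,
            interaction_eta2=0.02, genetic_main_eta2=0.001,
        )
    ],
)
genotypes, exposures, idps, truth = gt.simulate_cohort(cfg)

print(f"cohort: {genotypes.n_participants} participants, "
      f"{genotypes.n_variants} variants, {exposures.n_exposures} exposures, "
      f"{idps.n_idps} IDPs")
print(f"MAF range: {genotypes.maf().min():.3f} - {genotypes.maf().max():.3f}")
for eff, realized in zip(truth.planted_effects, truth.realized_eta2):
    print(
        f"planted effect at variant {eff.variant_index}: "
        f"target interaction eta2 {eff.interaction_eta2:.4f}, "
        f"realized {realized['interaction']:.4f}"
    )
# The realized share should sit within a few percent of the target: the
# interaction coefficient is solved analytically from the variance of the
# genotype-by-exposure product on this cohort.
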