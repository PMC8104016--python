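"""Mirror-site density control for promoter-interacting variants.

For every (promoter, variant) contact pair, promoter-distal interaction
density is profiled around the variant and around its mirror image on the
opposite side of the promoter (same distance from the probed feature).
Extra promoter-distal contacts are planted at 3x within 25 kb of each
variant, so the variant-side curve exceeds the mirror-side curve in the
first five 5-kb bins and the two converge beyond.
"""

import loopmap as lm
from loopmap.simulate import InteractionModel, PlantingModel

cfg = lm.SimConfig(seed=41, n_chroms=2, chrom_length=25_000_000, n_genes=300,
                   n_variant_probes=60, n_leads=200,
                   interactions=InteractionModel(mean_per_promoter=8.0,
                                                 mean_gp_per_variant=3.0,
                                                 replicate_drop=0.0),
                   planting=PlantingModel(pd_near_variant_fold=3.0,
                                          pd_near_variant_radius=25_000))
genome = lm.simulate_genome(cfg)
gwas = lm.simulate_gwas_ld(cfg, genome)
rep1, _ = lm.simulate_interactions(cfg, genome, variants=gwas.probed)
classified = lm.classify_interactions(rep1, genome.promoters, gwas.probed)

profile = lm.mirror_density(classified.subset("GP"), classified.subset("PD"),
                            genome.promoters, gwas.probed,
                            bin_size=5_000, max_distance=100_000)

print(f"{profile.n_pairs} promoter-variant pairs aggregated")
print("bin_start_kb  variant_side  mirror_side")
for row in profile.to_frame().head(10).itertuples(index=False):
    print(f"{row.bin_start // 1000:>12}  {row.variant_side_count:>12}  "
          f"{row.mirror_side_count:>11}")
# Bins 0-4 (0-25 kb) show the planted variant-side excess; the mirror side
# is flat at the baseline, confirming that the clustering is anchored at
# the variant and not an artifact of distance from the promoter.
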