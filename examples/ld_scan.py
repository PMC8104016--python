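"""Double-randomization scan of LD-proxy overlap with distal elements.

Proxies in LD (r2 >= 0.8) with trait-associated lead SNPs are planted inside
distal elements at a 3x excess out to 50 kb from their leads.  The scan
counts proxy SNPs falling inside distal elements per distance window and
tests each window against two matched null ensembles: random interaction
sets (length- and distance-matched) and random SNP sets (MAF- and
LD-structure-matched).  The enrichment horizon is the largest window whose
distance ring is still significant.
"""

import loopmap as lm
from loopmap.simulate import InteractionModel, PlantingModel

cfg = lm.SimConfig(seed=31, n_chroms=2, chrom_length=25_000_000, n_genes=300,
                   n_variant_probes=0, n_leads=600,
                   interactions=InteractionModel(mean_per_promoter=8.0,
                                                 replicate_drop=0.0),
                   planting=PlantingModel(proxy_de_fold=3.0,
                                          proxy_max_distance=50_000))
genome = lm.simulate_genome(cfg)
rep1, _ = lm.simulate_interactions(cfg, genome)
pd_set = lm.classify_interactions(rep1, genome.promoters).subset("PD")
gwas = lm.simulate_gwas_ld(cfg, genome, de_intervals=pd_set.distal_intervals())

rand_int = lm.matched_random_interactions(
    pd_set, genome.promoters, genome.chrom_sizes,
    lm.RandomSetSpec(n_sets=60, seed=32))
real_leads = gwas.universe[gwas.universe["rsid"].isin(gwas.leads["rsid"])]
rand_snp = lm.matched_random_snps(
    real_leads.reset_index(drop=True), gwas.universe,
    lm.MatchedSNPSpec(seed=33, ld_buddy_bins=(0, 1, 6)), 60)

scan = lm.ld_overlap_scan(
    pd_set, list(gwas.leads["rsid"]), gwas.ld_table, gwas.universe,
    windows=list(range(10_000, 250_001, 10_000)),
    rand_interaction_sets=rand_int, rand_snp_sets=rand_snp)

print("window_kb  ring_observed  ring_fold  ring_p")
for r in scan.annulus[:8]:
    print(f"{r.window // 1000:>9}  {r.observed:>13}  {r.fold:>9.2f}  {r.empirical_p:.4f}")
print(f"enrichment horizon: {scan.horizon / 1000:.0f} kb "
      f"(planted excess extends to 50 kb)")
# Rings inside the planted distance show fold near 3 and small empirical
# p-values under both randomizations; beyond 50 kb the fold returns to 1
# and the horizon stops at the planted distance.
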