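"""Peak-overlap enrichment of promoter-interacting distal elements.

Distal elements are simulated to carry regulatory peaks (H3K27ac-like) at
three times the background rate.  The test compares the observed overlap
count with segment-length and distance-from-promoter matched random
placements, reporting fold enrichment and an empirical p-value.
"""

import loopmap as lm
from loopmap.simulate import InteractionModel, PeakModel

cfg = lm.SimConfig(seed=7, n_chroms=2, chrom_length=30_000_000, n_genes=200,
                   n_variant_probes=0, n_leads=10,
                   interactions=InteractionModel(mean_per_promoter=2.5,
                                                 replicate_drop=0.0),
                   peaks=PeakModel(background_rate=0.2, de_rate=0.6))
genome = lm.simulate_genome(cfg)
rep1, _ = lm.simulate_interactions(cfg, genome)
pd_set = lm.classify_interactions(rep1, genome.promoters).subset("PD")
peaks = lm.simulate_peaks(cfg, genome, pd_set.distal_intervals())

random_sets = lm.matched_random_interactions(
    pd_set, genome.promoters, genome.chrom_sizes,
    lm.RandomSetSpec(n_sets=50, seed=8))
res = lm.feature_overlap_enrichment(pd_set, peaks, random_sets)

print(f"{res.observed:.0f} of {len(pd_set)} distal elements overlap a peak")
print(f"matched random sets: {res.null_mean:.1f} +- {res.null_sd:.1f}")
print(f"fold enrichment {res.fold:.2f}, empirical p {res.empirical_p:.4f}")
# The generative peak rates are 0.6 on distal elements vs 0.2 background,
# so the measured fold sits near 3; the empirical p is the add-one
# permutation p against the 50 matched random sets.
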