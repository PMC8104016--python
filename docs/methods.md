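# Methods

This note documents the models, conventions and design choices behind
`loopmap`, in the spirit of a methods appendix: what each statistic assumes,
which knobs matter, and what the synthetic data do and do not emulate.

## Coordinates and annotation

All intervals are 0-based half-open; BED input is native and GTF is
converted on read.  A gene carries one representative TSS (`body.start` on
the + strand, `body.end − 1` on −).  Distances from an interval anchor (a
distal element or a probe) use the interval midpoint; variants use their
single base position.  "Nearest gene" is defined on TSS distance — the
alternative (gene-body distance) changes results only for anchors inside
long gene bodies, and TSS distance is the convention under which a
gene-jump index of 1 means exactly "the nearest gene was jumped over".
Nearest-gene ties break by smaller TSS, then lexicographic gene id, making
every ranking deterministic.  The gene-jump index is the rank (from 0) of
the target gene when all genes on the chromosome are ordered by TSS
distance from the anchor; it is a bijection onto 0..n−1 for a fixed anchor.

## Interaction processing

Interactions arrive as anchor → distal-fragment calls with per-replicate
read-pair support and an interaction-call p-value from the upstream caller
(whose background model is out of scope here).  Replicate consistency keeps
a pair only when present in both replicates; supports are concatenated and
the merged p-value is the larger (less significant) of the two — a
conservative choice, since the callers' p-values are not independent and no
merge rule is canonical.  Distal fragments are compared across replicates
by exact coordinates: fragments come from one fixed restriction map, so no
fuzzy matching is needed.

Classification is by overlap with the promoter-probe track: a
promoter-anchored call whose fragment overlaps another promoter probe is
PP, otherwise PD; a variant-anchored call onto a promoter probe is GP.
Variant-anchored calls onto non-probed fragments are kept with class
`unset` and surfaced by `class_counts` — they carry no promoter assignment
and enter no downstream statistic.

The regulatory network is an undirected graph over promoters, variants and
distal elements; PP and GP edges connect probe nodes through the overlapped
promoter probe, PD edges connect a promoter to its fragment.  Edges are
unweighted (p-values are kept as attributes only).  The interaction-profile
matrix marks, per cell type, which genomic bin (distal midpoint, fixed bin
size, default 5 kb in the examples) each promoter contacts; the principal
component decomposition of that matrix is delegated to the caller.

## Matched null ensembles

*Random interaction sets.*  For every real interaction, a promoter is drawn
uniformly from the probe panel and a segment of identical length is placed
at the same absolute anchor–distal midpoint distance on a uniformly random
side.  Placements off the chromosome or inside exclusion intervals
(typically the probed regions) are rejected and fully re-drawn, rather than
wrapped or clipped, so the distance distribution is not distorted at
chromosome edges; chance collisions on the same (promoter, fragment) key
are also re-drawn.  Consequently the segment-length multiset and the
|distance| multiset of every random set equal the real set's exactly — the
null varies only genomic context.  "Genomic context control" is
operationalized as distance preservation plus exclusion of probed regions;
no GC or gene-density matching is attempted.

*Random SNP sets.*  Each real SNP is replaced by a uniform draw among
universe SNPs within an absolute MAF tolerance (default 0.05) and in the
same LD-buddy-count bin (buddies counted at the working r² threshold,
default bins {0}, {1–5}, {6–20}, {21–100}, {>100}), excluding the real set
and avoiding within-set duplicates.  The bin partition is configurable:
desk-scale simulated universes (a few thousand SNPs) leave the extreme bins
nearly empty, so the simulation-scale tests use the coarser partition
{0}, {1–5}, {≥6}; with a 1000-Genomes-scale universe the default bins are
appropriate.  Matching is enforced exactly — a SNP with no eligible partner
raises an error naming it.

Both ensembles derive per-set streams from one master seed (set index keyed
into the generator), so results are bit-reproducible and sets are
independent under parallel execution.

## Enrichment statistics

Empirical p-values use the add-one form (1 + #{null ≥ obs}) / (1 + n_sets),
never zero, and fold is observed over null mean.  Peak-overlap enrichment
counts distal elements overlapping at least one peak; it is invariant to
peak order and duplication.

The LD-proxy scan addresses the fact that an apparent excess of LD SNPs in
distal elements could come either from where the interactions sit or from
the LD structure of the SNP set.  It therefore tests the observed count of
distinct proxies (r² ≥ 0.8 with a lead, lead distance at most the window
cap) inside distal elements against *both* nulls: the same proxies versus
each random interaction set, and the proxies of each matched random SNP set
versus the real distal elements.  Both conditional p-values are reported;
the headline per-window p is the larger of the two, guarding against either
randomization alone being anti-conservative.  Under a pure-null generator
each conditional p is uniform up to the discreteness of count statistics,
and the combined p is super-uniform by construction (the maximum of two
roughly uniform variables), which the calibration tests check explicitly.

Cumulative window counts are non-decreasing by construction, which means a
bounded planted excess stays "significant" at every window beyond its true
extent.  The *enrichment horizon* is therefore defined on distance rings
(annuli between consecutive windows, each proxy counted once at its minimal
lead distance): the largest window up to which every ring remains
significant at the configured level — an isolated far ring, a level-rate
false positive among many rings, does not extend it.  Under planting to
50 kb the rings inside 50 kb are enriched and those beyond are not, so the
horizon lands at the planted distance; the cumulative results are still
reported per window.  Windows
default to 10–250 kb in 10-kb steps, and no multiplicity adjustment is
applied across windows — the horizon is descriptive.

Trait overrepresentation uses the catalog's trait fractions: for a trait
with n_t of N catalog variants and M interacting variants, expected =
(n_t/N)·M and fold = observed/expected; traits with fewer than 14 catalog
variants are dropped, and the fraction of each trait's variants recovered
is reported alongside.  Q–Q construction pairs −log10 quantiles of two
p-value lists on a common grid of min(n₁, n₂) points with linear
interpolation, reporting the fraction of points above the diagonal.  Note
that under the null that fraction follows an occupation-time (arcsine-type)
law per dataset — only its average over datasets is ½.

## Mirror-site density control

For each (promoter P, variant v) contact pair, the mirror site is the
reflection of v across P's probe midpoint — the same distance from the
probed feature, opposite side.  All PD interactions of P contribute their
distal-midpoint distances to v and to the mirror into 5-kb bins (configurable,
500 kb range by default).  Counts are raw aggregates (no per-promoter
normalization) and a PD interaction may count through several variants of
the same promoter: the object of interest is a density, not a set size.
Mirror sites falling below coordinate 0 are skipped and counted.  Feeding
the mirror as the "variant" exactly swaps the two curves (tested), and
under a side-symmetric interaction landscape the curves agree within
Poisson noise; the control is presented as a profile, not a formal test,
though the tests bound each bin with conditional binomial intervals.

## Target assignment and coexpression

LD expansion keeps table rows with r² ≥ threshold (default 0.8) and lead
distance ≤ cap, both inclusive; each lead is its own proxy at distance 0.
Distance caps are per-cell-type configuration (defaults 80/20/30 kb for the
three example profiles).  Assignment evidence classes: `GP_direct` (the
probed variant contacts the promoter), `PD_contained` (the lead lies inside
a promoter-interacting fragment) and `PD_LD` (a non-lead proxy lies inside
one, recording the proxy).  Every assignment carries the interaction
distance (variant-to-probe for GP, loop length for PD) and the gene-jump
index computed from the variant's position.  The summary reports variant
and gene counts, the fraction of single-promoter variants, the fraction of
nearest-gene assignments and the mean interaction distance.

Enhancer-sharing pairs come from any element (variant or distal fragment)
assigned to ≥ 2 genes: all unordered pairs, deduplicated across elements
with every supporting element recorded.  Elements with more than `hub_max`
genes can be excluded — one variant contacting a large gene cluster would
otherwise dominate the pair set; the cutoff is exposed as a parameter
(examples use 8) because no principled value exists.  Coexpression is a
two-sided Pearson correlation test across samples (Spearman available);
pairs with a gene missing from the matrix are excluded from denominators
and reported.  The enrichment test is a 1-df goodness-of-fit χ² of the
coexpressed count against a background proportion estimated from an
equal-sized uniform random pair set; a 2×2 contingency variant is provided
when the background sample size should enter the test.  The two forms give
different p-values for the same proportions — which one a printed p-value
came from is generally not recoverable, so both are exposed.

## Synthetic data

The generator reproduces the statistical structure the analysis relies on,
not the biology:

- **Genome** — 2 chromosomes × 20 Mb by default; genes placed without TSS
  collisions; 1-kb promoter probes centred on TSSs; a fixed restriction map
  with exponential cut spacing.  A distal element is the fragment containing
  a contact point, i.e. a size-biased draw from the map, so the map spacing
  is half the configured DE mean (default 750 bases, the short-fragment
  resolution of sequence-capture Hi-C).
- **Interactions** — per-promoter Poisson counts (default mean 4; most
  promoters contact few elements) with exponential distal offsets (default
  scale 120 kb) on a random side — the simplest model with a long-range
  (>500 kb) tail — snapped to fragments; per-replicate independent dropout
  (default 10%) gives the replicate filter work; variant probes get GP
  contacts to nearby promoters.  Planting can add PD contacts around
  variants at a configured fold within a radius.
- **GWAS/LD** — SNPs on a per-block Poisson process (default block mean
  80 kb, spacing 6 kb), MAF ~ U(0.05, 0.5), within-block pairwise r² drawn
  with 25% mass above 0.8; association p-values ≤ 10⁻⁶ as in a filtered
  catalog; traits multinomial.  Planting relocates proxies within the
  planting distance of a catalog lead into a distal element near the lead
  with probability (fold − 1) × coverage, so the proxy-in-DE rate is about
  fold × coverage inside the planted range and baseline outside.
- **Peaks** — fixed-width (1 kb) background peaks at a Poisson rate
  calibrated so a typical distal element overlaps one with the configured
  background probability; extra peaks forced onto distal elements raise
  their rate to the configured DE rate.
- **Expression** — Gaussian log-scale baseline over 131 samples (the size
  of an aortic intima-media expression panel); genes connected by sharing
  pairs load on a shared factor giving within-group pairwise correlation ≈ ρ.

Everything is deterministic under one master seed, with sub-streams per
generator.  What the simulation does **not** emulate: realistic coalescent
LD, GC/mappability structure, expression normalization artifacts,
interaction-caller biases, or dependence between interaction strength and
peak occupancy.  Passing tests therefore demonstrate correctness of the
statistics and recoverability of planted effects under the stated
generative model — not robustness to every property of real capture Hi-C
data.

## Test and experiment sizing

Oracle-equivalence tests run on ~100-seed batches of toy genomes (4–10
genes, ≤ 25 interactions) against brute-force enumeration.  Calibration
experiments use 200 null simulations with 99 random sets each, sized
(≈ 500–1500 distal elements, 100 leads, 3–7% genome coverage) so the count
statistics take enough distinct values for the rejection rate at 0.05 to be
meaningful despite the discreteness of empirical p-values; overlap-count
ties deflate rejection slightly below nominal, which the binomial
acceptance band accommodates.  Recovery experiments plant effects at fold 3
(peaks, proxies, near-variant contacts) and ρ = 0.6 (coexpression) and are
sized so the planted signal is several null standard deviations: ~500
distal elements for the peak fold, 600 leads and ~2300 elements for the
horizon scan, ~180 promoter–variant pairs for the mirror control.  One
caveat documented deliberately: planted peaks sit on real distal elements,
so distance-matched random placements overlap them slightly more often than
pure background, biasing the measured fold a few percent below the
generative ratio; at ~1% planted-peak coverage the bias is well inside the
recovery band.

## Known limitations

- The interaction caller's negative-background model is consumed, not
  implemented; p-values are taken at face value.
- Promoters are gene-level (one TSS); transcript-level promoter definitions
  and strand-aware regulatory directionality are out of scope.
- The χ² background proportion depends on the random background pair draw;
  with few tested pairs the test is anti-conservative if the background
  fraction is estimated as exactly zero (it is floored at half a count).
- eQTL p-values are inputs (only Q–Q construction is provided); GO-term
  enrichment and genotype-level analyses are out of scope.
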