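"""Synthetic data generator for the whole pipeline.

Emulates the statistical structure the analysis assumes — promoter-anchored
interactions with exponential distance decay snapped to a fixed restriction
map, LD-block-structured variant catalogs with allele frequencies, peak
tracks enriched at interacting distal elements, and expression with planted
correlation for enhancer-sharing gene pairs — so that every stage is testable
without any external download.

Design points:

* distal fragments come from a simulated restriction map with ~750-base mean
  fragment length, matching the short distal elements high-resolution capture
  Hi-C produces, so replicate coordinates agree exactly;
* distance decay is exponential (configurable scale) with a random side,
  which produces the long-range (>500 kb) tail while keeping the landscape
  side-symmetric unless extra interactions are planted;
* planted effects (peak enrichment on distal elements, LD proxies relocated
  into distal elements near their leads, extra promoter-distal interactions
  around probed variants, correlated expression for sharing pairs) are each
  controlled by one knob and default to "off", giving a pure null;
* every generator draws from a stream derived from one master seed, so the
  full dataset is reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import Gene, GeneAnnotation, GenomicInterval
from .interactions import Interaction, InteractionSet

__all__ = [
    "InteractionModel",
    "PeakModel",
    "LDModel",
    "PlantingModel",
    "ExpressionModel",
    "SimConfig",
    "SimGenome",
    "SimGwas",
    "simulate_genome",
    "simulate_interactions",
    "simulate_gwas_ld",
    "simulate_peaks",
    "simulate_expression",
    "write_inputs",
]


@dataclass
class InteractionModel:
    mean_per_promoter: float = 4.0      # most promoters contact few elements
    decay_scale: float = 120_000.0      # bases; exponential mean of offsets
    min_offset: float = 3_000.0         # bases; keeps distal ends off the probe
    side_symmetric: bool = True
    replicate_drop: float = 0.1         # per-replicate independent drop rate
    mean_support: float = 4.0           # read pairs above the minimum of 1
    mean_gp_per_variant: float = 1.5


@dataclass
class PeakModel:
    background_rate: float = 0.2  # P(a ~750 b random segment overlaps a peak)
    de_rate: float = 0.2          # P(a distal element overlaps a peak)
    width: int = 1_000


@dataclass
class LDModel:
    block_length: float = 80_000.0
    snp_spacing: float = 6_000.0  # mean within-block spacing
    p_high_r2: float = 0.25       # share of within-block pairs with r2 >= 0.8
    maf_low: float = 0.05
    maf_high: float = 0.5
    r2_buddy_threshold: float = 0.8


@dataclass
class PlantingModel:
    proxy_de_fold: float = 1.0            # in-DE rate multiplier for near proxies
    proxy_max_distance: float = 50_000.0  # planting limited to this lead distance
    pd_near_variant_fold: float = 1.0     # PD density multiplier near variants
    pd_near_variant_radius: float = 25_000.0
    coexpr_rho: float = 0.0               # planted correlation for sharing pairs


@dataclass
class ExpressionModel:
    n_samples: int = 131   # matches an aortic intima-media expression panel
    noise_sd: float = 1.0
    baseline_mean: float = 5.0  # log2 expression scale


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 20_000_000
    n_genes: int = 300
    n_promoter_probes: int | None = None  # default: every gene
    n_variant_probes: int = 50
    n_leads: int = 200
    n_traits: int = 10
    fragment_mean: float = 750.0
    probe_width: int = 1_000
    interactions: InteractionModel = field(default_factory=InteractionModel)
    peaks: PeakModel = field(default_factory=PeakModel)
    ld: LDModel = field(default_factory=LDModel)
    planting: PlantingModel = field(default_factory=PlantingModel)
    expression: ExpressionModel = field(default_factory=ExpressionModel)

    def __post_init__(self) -> None:
        for rate in (self.peaks.background_rate, self.peaks.de_rate,
                     self.interactions.replicate_drop):
            if not (0 <= rate <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.planting.proxy_de_fold < 1 or self.planting.pd_near_variant_fold < 1:
            raise ValueError("planting folds must be >= 1")
        if self.expression.n_samples < 3:
            raise ValueError("need at least 3 expression samples")


def _rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *key])


@dataclass
class SimGenome:
    genes: GeneAnnotation
    genes_df: pd.DataFrame
    promoters: pd.DataFrame       # promoter probe table
    cuts: dict                    # chrom -> sorted restriction cut positions
    chrom_sizes: dict

    def fragment_of(self, chrom: str, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Start/end of the restriction fragment containing each position."""
        cuts = self.cuts[chrom]
        i = np.clip(np.searchsorted(cuts, pos, side="right") - 1, 0, len(cuts) - 2)
        return cuts[i], cuts[i + 1]


def simulate_genome(cfg: SimConfig) -> SimGenome:
    """Genes, promoter probes and a fixed restriction map.

    TSS positions are drawn without collisions; fragment boundaries come from
    a homogeneous cut process calibrated so that contact-sampled distal
    elements average ``fragment_mean`` (~750 bases).
    """
    rng = _rng(cfg, 0)
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    min_sep = 4 * cfg.probe_width
    capacity = cfg.n_chroms * (cfg.chrom_length // min_sep)
    if cfg.n_genes > capacity:
        raise ValueError(
            f"genome too small: {cfg.n_genes} genes need more than "
            f"{capacity} separated TSS slots"
        )
    per_chrom = np.bincount(
        rng.integers(0, cfg.n_chroms, size=cfg.n_genes), minlength=cfg.n_chroms
    )
    genes, rows = [], []
    gi = 0
    margin = 200_000  # keep probes and typical offsets on-chromosome
    for ci, (chrom, size) in enumerate(chrom_sizes.items()):
        n = int(per_chrom[ci])
        slots = rng.choice(
            np.arange(margin // min_sep, (size - margin) // min_sep),
            size=n, replace=False,
        )
        tss = np.sort(slots * min_sep + rng.integers(0, min_sep // 2, size=n))
        strands = rng.choice(["+", "-"], size=n)
        lengths = rng.integers(2_000, 50_000, size=n)
        for t, s, L in zip(tss, strands, lengths):
            gid = f"G{gi:05d}"
            gi += 1
            if s == "+":
                body = GenomicInterval(chrom, int(t), int(t + L), "+")
            else:
                body = GenomicInterval(chrom, int(t - L + 1), int(t + 1), "-")
            genes.append(Gene(gid, gid, int(t), s, body))
            rows.append(
                {"gene_id": gid, "name": gid, "chrom": chrom,
                 "start": body.start, "end": body.end, "strand": s, "tss": int(t)}
            )
    genes_df = pd.DataFrame(rows)
    ann = GeneAnnotation(genes)

    n_prom = cfg.n_promoter_probes or cfg.n_genes
    chosen = genes_df.sample(n=n_prom, random_state=int(rng.integers(2**31)))
    chosen = chosen.sort_values(["chrom", "tss"])
    half = cfg.probe_width // 2
    promoters = pd.DataFrame(
        {
            "gene_id": chosen["gene_id"].to_numpy(),
            "chrom": chosen["chrom"].to_numpy(),
            "start": chosen["tss"].to_numpy() - half,
            "end": chosen["tss"].to_numpy() + half,
        }
    ).reset_index(drop=True)

    # distal elements are fragments hit by a uniformly-placed contact point,
    # i.e. a size-biased draw from the map: with exponential spacing the
    # sampled-fragment mean is twice the map mean, so the map uses half the
    # configured DE mean
    cuts = {}
    spacing = cfg.fragment_mean / 2
    for chrom, size in chrom_sizes.items():
        n_cuts = int(size / spacing * 1.3) + 10
        gaps = rng.exponential(spacing, size=n_cuts)
        pos = np.unique(np.concatenate([[0], np.cumsum(gaps), [size]]).astype(np.int64))
        cuts[chrom] = pos[pos <= size]
        if cuts[chrom][-1] != size:
            cuts[chrom] = np.append(cuts[chrom], size)
    return SimGenome(ann, genes_df, promoters, cuts, chrom_sizes)


def _draw_offsets(rng, n, model: InteractionModel):
    off = rng.exponential(model.decay_scale, size=n) + model.min_offset
    if model.side_symmetric:
        side = rng.integers(0, 2, size=n) * 2 - 1
    else:
        side = np.ones(n, dtype=int)
    return off.astype(np.int64), side


def simulate_interactions(
    cfg: SimConfig,
    genome: SimGenome,
    variants: pd.DataFrame | None = None,
    cell_type: str = "CT1",
    stream: int = 1,
) -> tuple[InteractionSet, InteractionSet]:
    """A replicate pair of raw interaction sets for one cell type.

    Per promoter, a Poisson count of distal contacts is placed by exponential
    offset with a random side and snapped to the containing restriction
    fragment.  Probed variants receive GP contacts to nearby promoter probes.
    When ``planting.pd_near_variant_fold > 1``, extra promoter-distal
    interactions are added around each variant that contacts the promoter, at
    the configured fold over the local decay density within the radius.
    Each replicate independently drops a configured fraction of the parent
    interaction list, so the replicate-consistency filter has work to do.
    """
    rng = _rng(cfg, stream)
    im = cfg.interactions
    parents: list[tuple] = []  # (anchor_id, anchor_type, chrom, fs, fe)

    prom = genome.promoters
    pm = (prom["start"].to_numpy(np.int64) + prom["end"].to_numpy(np.int64)) // 2
    pchrom = prom["chrom"].to_numpy()
    gids = prom["gene_id"].to_numpy()

    counts = rng.poisson(im.mean_per_promoter, size=len(prom))
    for j in range(len(prom)):
        n = int(counts[j])
        if n == 0:
            continue
        off, side = _draw_offsets(rng, n, im)
        mids = pm[j] + side * off
        size = genome.chrom_sizes[pchrom[j]]
        mids = mids[(mids >= 0) & (mids < size)]
        if not len(mids):
            continue
        fs, fe = genome.fragment_of(pchrom[j], mids)
        for a, b in zip(fs, fe):
            if b > a:
                parents.append((gids[j], "promoter", pchrom[j], int(a), int(b)))

    gp_pairs: list[tuple[int, str, int]] = []  # (promoter row, rsid, variant pos)
    if variants is not None and len(variants):
        prom_by_chrom = {
            c: np.flatnonzero(pchrom == c) for c in np.unique(pchrom)
        }
        for v in variants.itertuples():
            n = rng.poisson(im.mean_gp_per_variant)
            cand = prom_by_chrom.get(v.chrom)
            if n == 0 or cand is None or not len(cand):
                continue
            off, side = _draw_offsets(rng, n, im)
            targets_pos = int(v.pos) + side * off
            for tp in targets_pos:
                j = cand[np.argmin(np.abs(pm[cand] - tp))]
                parents.append(
                    (v.rsid, "variant", pchrom[j], int(prom.iloc[j]["start"]),
                     int(prom.iloc[j]["end"]))
                )
                gp_pairs.append((int(j), v.rsid, int(v.pos)))

    # planted excess of promoter-distal contacts on the variant side
    pl = cfg.planting
    if pl.pd_near_variant_fold > 1 and gp_pairs:
        r = pl.pd_near_variant_radius
        s = im.decay_scale
        for j, rsid, vpos in gp_pairs:
            dv = abs(vpos - pm[j])
            lo, hi = max(dv - r, im.min_offset), dv + r
            # baseline expected contacts in the one-sided window under the
            # exponential decay; the planted excess is (fold - 1) times that
            mass = 0.5 * (np.exp(-(lo - im.min_offset) / s) - np.exp(-(hi - im.min_offset) / s))
            n_extra = rng.poisson((pl.pd_near_variant_fold - 1) * im.mean_per_promoter * mass)
            if n_extra == 0:
                continue
            mids = vpos + rng.integers(-int(r), int(r), size=n_extra)
            mids = mids[(np.abs(mids - pm[j]) >= im.min_offset)]
            mids = mids[(mids >= 0) & (mids < genome.chrom_sizes[pchrom[j]])]
            if not len(mids):
                continue
            fs, fe = genome.fragment_of(pchrom[j], mids)
            for a, b in zip(fs, fe):
                if b > a:
                    parents.append((gids[j], "promoter", pchrom[j], int(a), int(b)))

    # deduplicate parents and attach replicate-level support and p-values
    uniq = list(dict.fromkeys(parents))
    pvals = 10.0 ** -rng.uniform(2, 8, size=len(uniq))
    sup = 1 + rng.poisson(im.mean_support, size=(len(uniq), 2))
    keep = rng.random(size=(len(uniq), 2)) >= im.replicate_drop
    reps = []
    for r in range(2):
        items = [
            Interaction(
                u[0], u[1], GenomicInterval(u[2], u[3], u[4]),
                (int(sup[i, r]),), float(pvals[i]),
            )
            for i, u in enumerate(uniq)
            if keep[i, r]
        ]
        reps.append(InteractionSet(cell_type, items, replicate_count=1))
    return reps[0], reps[1]


@dataclass
class SimGwas:
    catalog: pd.DataFrame      # rsid, trait, pvalue
    universe: pd.DataFrame     # rsid, chrom, pos, maf, n_ld_buddies
    ld_table: pd.DataFrame     # lead_rsid, proxy_rsid, r2, distance
    leads: pd.DataFrame        # rsid, chrom, pos, maf
    probed: pd.DataFrame       # variant probe table (subset of leads)


def simulate_gwas_ld(
    cfg: SimConfig,
    genome: SimGenome,
    de_intervals: Sequence[GenomicInterval] | None = None,
    stream: int = 5,
) -> SimGwas:
    """Variant catalog, SNP universe and LD table with block structure.

    SNPs are placed on a per-block Poisson process; within-block pairs draw
    their r-squared from a mixture putting ``p_high_r2`` mass at or above the
    buddy threshold.  Association p-values respect the catalog cutoff of
    1e-6.  With ``planting.proxy_de_fold > 1`` (and distal elements
    supplied), proxies within the planting distance of a catalog lead are
    relocated into a distal element near the lead at the configured excess
    over the genome-wide coverage rate.
    """
    rng = _rng(cfg, stream)
    ld = cfg.ld
    rows = []
    si = 0
    block_of = {}
    block_id = 0
    for chrom, size in genome.chrom_sizes.items():
        start = 0
        while start < size:
            blen = rng.exponential(ld.block_length)
            end = min(size, start + max(blen, 10_000))
            n = rng.poisson((end - start) / ld.snp_spacing)
            pos = np.sort(rng.integers(int(start), int(end), size=n))
            for p in pos:
                rsid = f"rs{si:06d}"
                si += 1
                rows.append(
                    {"rsid": rsid, "chrom": chrom, "pos": int(p),
                     "maf": float(rng.uniform(ld.maf_low, ld.maf_high)),
                     "block": block_id}
                )
                block_of[rsid] = block_id
            start = end
            block_id += 1
    snps = pd.DataFrame(rows)
    if len(snps) < cfg.n_leads:
        raise ValueError("SNP universe smaller than the requested lead count")

    lead_idx = rng.choice(len(snps), size=cfg.n_leads, replace=False)
    leads = snps.iloc[np.sort(lead_idx)].reset_index(drop=True)
    traits = [f"trait_{chr(ord('A') + i)}" for i in range(cfg.n_traits)]
    trait_weights = rng.dirichlet(np.ones(cfg.n_traits) * 2)
    catalog = pd.DataFrame(
        {
            "rsid": leads["rsid"],
            "trait": rng.choice(traits, size=len(leads), p=trait_weights),
            "pvalue": 10.0 ** -(6 + rng.exponential(2, size=len(leads))),
        }
    )

    # within-block pairwise r2 (undirected, stored once per pair)
    a_parts, b_parts, r2_parts = [], [], []
    rsid_arr = snps["rsid"].to_numpy()
    for _, block in snps.groupby("block"):
        ids = block.index.to_numpy()
        if len(ids) < 2:
            continue
        iu, ju = np.triu_indices(len(ids), k=1)
        high = rng.random(size=len(iu)) < ld.p_high_r2
        r2 = np.where(
            high,
            rng.uniform(ld.r2_buddy_threshold, 1.0, size=len(iu)),
            rng.uniform(0.0, ld.r2_buddy_threshold, size=len(iu)),
        )
        a_parts.append(rsid_arr[ids[iu]])
        b_parts.append(rsid_arr[ids[ju]])
        r2_parts.append(r2)
    pa = np.concatenate(a_parts) if a_parts else np.array([], dtype=object)
    pb = np.concatenate(b_parts) if b_parts else np.array([], dtype=object)
    pr2 = np.concatenate(r2_parts) if r2_parts else np.array([])

    # optional planting: relocate near proxies of catalog leads into DEs
    pl = cfg.planting
    pos_s = pd.Series(snps["pos"].to_numpy(), index=snps["rsid"])
    if pl.proxy_de_fold > 1 and de_intervals:
        chrom_s = pd.Series(snps["chrom"].to_numpy(), index=snps["rsid"])
        de_by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in de_intervals:
            de_by_chrom.setdefault(iv.chrom, []).append(iv)
        de_mid = {
            c: np.array([iv.midpoint for iv in lst]) for c, lst in de_by_chrom.items()
        }
        genome_len = sum(genome.chrom_sizes.values())
        coverage = sum(iv.length for iv in de_intervals) / genome_len
        p_move = min(1.0, (pl.proxy_de_fold - 1) * coverage)
        lead_set = set(leads["rsid"])
        high_mask = pr2 >= ld.r2_buddy_threshold
        dist0 = np.abs(pos_s[pa].to_numpy() - pos_s[pb].to_numpy())
        near_mask = high_mask & (dist0 <= pl.proxy_max_distance)
        moved: set[str] = set()
        for a, b in zip(pa[near_mask], pb[near_mask]):
            for lead, proxy in ((a, b), (b, a)):
                if lead not in lead_set or proxy in moved or proxy in lead_set:
                    continue
                if abs(pos_s[lead] - pos_s[proxy]) > pl.proxy_max_distance:
                    continue
                if rng.random() >= p_move:
                    continue
                chrom = chrom_s[lead]
                cand = de_by_chrom.get(chrom)
                if not cand:
                    continue
                near = np.flatnonzero(
                    np.abs(de_mid[chrom] - pos_s[lead]) <= pl.proxy_max_distance
                )
                if not len(near):
                    continue
                iv = cand[int(rng.choice(near))]
                pos_s[proxy] = int(rng.integers(iv.start, iv.end))
                moved.add(proxy)
        snps = snps.assign(pos=snps["rsid"].map(pos_s))

    dist = np.abs(pos_s[pa].to_numpy() - pos_s[pb].to_numpy())
    ld_table = pd.DataFrame(
        {
            "lead_rsid": np.concatenate([pa, pb]),
            "proxy_rsid": np.concatenate([pb, pa]),
            "r2": np.concatenate([pr2, pr2]),
            "distance": np.concatenate([dist, dist]),
        }
    )

    buddies = (
        ld_table.loc[ld_table["r2"] >= ld.r2_buddy_threshold, "lead_rsid"]
        .value_counts()
    )
    universe = snps[["rsid", "chrom", "pos", "maf"]].copy()
    universe["n_ld_buddies"] = universe["rsid"].map(buddies).fillna(0).astype(int)

    leads = snps.loc[snps["rsid"].isin(leads["rsid"]), ["rsid", "chrom", "pos", "maf"]]
    leads = leads.reset_index(drop=True)
    probed_idx = rng.choice(len(leads), size=min(cfg.n_variant_probes, len(leads)), replace=False)
    probed = leads.iloc[np.sort(probed_idx)].reset_index(drop=True)
    return SimGwas(catalog, universe, ld_table, leads, probed)


def simulate_peaks(
    cfg: SimConfig,
    genome: SimGenome,
    de_intervals: Sequence[GenomicInterval] = (),
    stream: int = 7,
) -> pd.DataFrame:
    """A peak track (BED-like frame) with optional enrichment on DEs.

    Background peaks form a Poisson process calibrated so a typical distal
    element overlaps one with probability ``background_rate``; when
    ``de_rate`` exceeds the background, extra peaks are forced onto distal
    elements to raise their overlap rate to ``de_rate``.
    """
    rng = _rng(cfg, stream)
    pk = cfg.peaks
    seg = cfg.fragment_mean + pk.width
    lam = -np.log(max(1e-12, 1 - pk.background_rate)) / seg
    rows = []
    for chrom, size in genome.chrom_sizes.items():
        n = rng.poisson(lam * size)
        starts = np.sort(rng.integers(0, size - pk.width, size=n))
        for s in starts:
            rows.append((chrom, int(s), int(s + pk.width)))
    q_extra = (pk.de_rate - pk.background_rate) / max(1e-12, 1 - pk.background_rate)
    if q_extra > 0:
        for iv in de_intervals:
            if rng.random() < q_extra:
                lo = max(0, iv.start - pk.width + 1)
                s = int(rng.integers(lo, iv.end))
                rows.append((iv.chrom, s, s + pk.width))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_expression(
    cfg: SimConfig,
    genome: SimGenome,
    pairs: pd.DataFrame | None = None,
    stream: int = 9,
) -> pd.DataFrame:
    """Log-scale expression matrix (genes x samples).

    Baseline values are independent Gaussians.  Genes linked by the supplied
    sharing pairs receive a shared latent factor inducing pairwise correlation
    of approximately ``planting.coexpr_rho`` within each connected group.
    """
    rho = cfg.planting.coexpr_rho
    if not (-1 < rho < 1):
        raise ValueError("coexpr_rho must lie in (-1, 1)")
    rng = _rng(cfg, stream)
    ex = cfg.expression
    gene_ids = genome.genes_df["gene_id"].tolist()
    n = len(gene_ids)
    mat = ex.baseline_mean + ex.noise_sd * rng.standard_normal((n, ex.n_samples))
    if pairs is not None and len(pairs) and rho != 0:
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(zip(pairs["gene_a"], pairs["gene_b"]))
        gi = {gid: i for i, gid in enumerate(gene_ids)}
        comps = sorted(nx.connected_components(g), key=lambda c: min(c))
        for comp in comps:
            factor = rng.standard_normal(ex.n_samples)
            # sets iterate in hash order, which varies across processes;
            # sort so the draw sequence is reproducible
            for gid in sorted(comp):
                if gid not in gi:
                    continue
                eps = rng.standard_normal(ex.n_samples)
                mat[gi[gid]] = ex.baseline_mean + ex.noise_sd * (
                    np.sqrt(rho) * factor + np.sqrt(1 - rho) * eps
                )
    return pd.DataFrame(
        mat, index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"S{j + 1:03d}" for j in range(ex.n_samples)],
    )


def write_inputs(
    outdir: str,
    genome: SimGenome,
    gwas: SimGwas | None = None,
    interaction_sets: dict | None = None,
    peaks: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    truth: dict | None = None,
) -> None:
    """Write every generated input in its standard on-disk format."""
    from .interactions import write_interactions
    from .io import write_expression

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bed = genome.genes_df[["chrom", "start", "end", "gene_id"]].copy()
    bed["score"] = 0
    bed["strand"] = genome.genes_df["strand"]
    bed.to_csv(out / "genes.bed", sep="\t", index=False, header=False)
    genome.promoters.to_csv(out / "promoter_probes.tsv", sep="\t", index=False)
    if gwas is not None:
        gwas.probed.to_csv(out / "variant_probes.tsv", sep="\t", index=False)
        gwas.catalog.to_csv(out / "trait_catalog.tsv", sep="\t", index=False)
        gwas.universe.to_csv(out / "snp_universe.tsv", sep="\t", index=False)
        gwas.ld_table.to_csv(out / "ld_table.tsv", sep="\t", index=False)
    for name, iset in (interaction_sets or {}).items():
        write_interactions(iset, out / f"interactions_{name}.tsv")
    if peaks is not None:
        peaks.to_csv(out / "peaks.bed", sep="\t", index=False, header=False)
    if expression is not None:
        write_expression(expression, out / "expression.tsv")
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
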