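import numpy as np
import pandas as pd
import pytest

from loopmap import (
    Gene,
    GeneAnnotation,
    GenomicInterval,
    Interaction,
    InteractionSet,
)


def make_gene(gene_id, chrom, tss, strand="+", length=5_000, name=None):
    if strand == "+":
        body = GenomicInterval(chrom, tss, tss + length, "+")
    else:
        body = GenomicInterval(chrom, tss - length + 1, tss + 1, "-")
    return Gene(gene_id, name or gene_id, tss, strand, body)


def make_interaction(anchor_id, chrom, start, end, anchor_type="promoter",
                     support=(3,), pvalue=0.01, iclass="unset"):
    return Interaction(anchor_id, anchor_type, GenomicInterval(chrom, start, end),
                       tuple(support), pvalue, iclass)


@pytest.fixture
def toy_annotation():
    return GeneAnnotation(
        [
            make_gene("G1", "chr1", 10_000),
            make_gene("G2", "chr1", 20_000),
            make_gene("G3", "chr1", 30_000, strand="-"),
            make_gene("G4", "chr1", 40_000),
            make_gene("G5", "chr1", 50_000),
            make_gene("GX", "chr2", 15_000),
        ]
    )


@pytest.fixture
def toy_promoters():
    return pd.DataFrame(
        {
            "gene_id": ["G1", "G2", "G3"],
            "chrom": ["chr1"] * 3,
            "start": [9_500, 19_500, 29_500],
            "end": [10_500, 20_500, 30_500],
        }
    )


@pytest.fixture
def toy_variants():
    return pd.DataFrame(
        {
            "rsid": ["rs1", "rs2"],
            "chrom": ["chr1", "chr1"],
            "pos": [60_000, 70_000],
            "maf": [0.2, 0.3],
        }
    )


def random_toy_problem(rng):
    """A random toy genome + probes + raw interactions, small enough for
    brute-force oracles."""
    n_genes = int(rng.integers(4, 10))
    chroms = ["chr1", "chr2"]
    genes, prows = [], []
    tss_used = {c: set() for c in chroms}
    for i in range(n_genes):
        c = chroms[int(rng.integers(0, 2))]
        while True:
            t = int(rng.integers(5_000, 200_000))
            if all(abs(t - u) > 2_000 for u in tss_used[c]):
                break
        tss_used[c].add(t)
        g = make_gene(f"G{i}", c, t)
        genes.append(g)
        prows.append({"gene_id": g.gene_id, "chrom": c, "start": t - 500, "end": t + 500})
    promoters = pd.DataFrame(prows)
    variants = pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(3)],
            "chrom": [chroms[int(rng.integers(0, 2))] for _ in range(3)],
            "pos": [int(rng.integers(5_000, 200_000)) for _ in range(3)],
            "maf": rng.uniform(0.05, 0.5, size=3),
        }
    )
    items = []
    n_int = int(rng.integers(5, 25))
    for _ in range(n_int):
        if rng.random() < 0.25:
            anchor = variants.iloc[int(rng.integers(0, len(variants)))]["rsid"]
            atype = "variant"
        else:
            anchor = promoters.iloc[int(rng.integers(0, len(promoters)))]["gene_id"]
            atype = "promoter"
        c = chroms[int(rng.integers(0, 2))]
        s = int(rng.integers(0, 200_000))
        e = s + int(rng.integers(200, 2_000))
        it = make_interaction(anchor, c, s, e, anchor_type=atype,
                              pvalue=float(rng.uniform(1e-6, 0.05)))
        items.append(it)
    # deduplicate keys
    seen, uniq = set(), []
    for it in items:
        if it.key not in seen:
            seen.add(it.key)
            uniq.append(it)
    return GeneAnnotation(genes), promoters, variants, InteractionSet("toy", uniq)
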