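"""LD expansion, variant-to-gene target assignment, enhancer-sharing gene
pairs and the coexpression enrichment test.

Evidence classes for an assignment:

* ``GP_direct``    the probed variant itself interacts with the promoter;
* ``PD_contained`` the lead variant lies inside a promoter-interacting
  distal fragment;
* ``PD_LD``        a proxy in LD with the lead (r-squared at or above the
  threshold, within the distance cap) lies inside such a fragment.

Boundaries are inclusive throughout: proxies at exactly the r-squared
threshold or the distance cap are kept.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneAnnotation, IntervalIndex
from .interactions import InteractionSet

__all__ = [
    "compute_r2",
    "expand_ld",
    "assign_targets",
    "sharing_pairs",
    "coexpression_test",
    "coexpr_chi2",
    "coexpr_chi2_contingency",
    "Chi2Result",
]

ASSIGNMENT_COLUMNS = [
    "rsid", "gene_id", "evidence", "proxy_rsid", "element",
    "interaction_distance", "jump_index",
]


def compute_r2(n_AB: int, n_Ab: int, n_aB: int, n_ab: int) -> float:
    """Squared haplotype correlation from the four haplotype counts.

    r2 = D^2 / (pA (1-pA) pB (1-pB)) with D = pAB - pA pB.
    """
    total = n_AB + n_Ab + n_aB + n_ab
    if total <= 0:
        raise ValueError("total haplotype count must be positive")
    p_ab = n_AB / total
    p_a = (n_AB + n_Ab) / total
    p_b = (n_AB + n_aB) / total
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        raise ValueError("r2 undefined for a monomorphic locus")
    d = p_ab - p_a * p_b
    return d * d / denom


def expand_ld(
    leads: Sequence[str],
    ld_table: pd.DataFrame,
    r2_min: float = 0.8,
    distance_cap: int | None = None,
    warn_missing: bool = True,
) -> pd.DataFrame:
    """Proxy sets per lead: rows (lead_rsid, proxy_rsid, r2, distance).

    Keeps table rows with ``r2 >= r2_min`` and ``distance <= distance_cap``
    (both inclusive) and adds every lead as its own proxy at distance 0.
    Leads absent from the table yield a lead-only proxy set with a warning.
    """
    leads = list(dict.fromkeys(leads))
    sub = ld_table[ld_table["lead_rsid"].isin(leads)]
    sub = sub[sub["r2"] >= r2_min]
    if distance_cap is not None:
        sub = sub[sub["distance"] <= distance_cap]
    missing = set(leads) - set(sub["lead_rsid"])
    if warn_missing and (absent := set(leads) - set(ld_table["lead_rsid"])):
        warnings.warn(
            f"{len(absent)} leads have no LD-table entries; "
            "their proxy sets contain only the lead itself"
        )
    self_rows = pd.DataFrame(
        {"lead_rsid": leads, "proxy_rsid": leads, "r2": 1.0, "distance": 0}
    )
    out = pd.concat([self_rows, sub[["lead_rsid", "proxy_rsid", "r2", "distance"]]])
    return out.drop_duplicates(["lead_rsid", "proxy_rsid"]).reset_index(drop=True)


def _element_id(kind: str, *parts) -> str:
    return kind + ":" + ":".join(map(str, parts))


def assign_targets(
    gp_set: InteractionSet | None,
    pd_set: InteractionSet,
    proxies: pd.DataFrame,
    snp_pos: pd.DataFrame,
    genes: GeneAnnotation,
    promoters: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Variant-to-gene assignment table with evidence classes and a summary.

    ``proxies`` is the long-form output of :func:`expand_ld` (self-pairs mark
    the leads themselves); ``snp_pos`` maps every rsid to chrom/pos.  The
    summary reports the number of assigned variants and genes, the fraction
    of variants with exactly one target promoter, the fraction of assignments
    reaching the nearest gene (jump index 0) and the mean interaction
    distance.
    """
    pos = snp_pos.set_index("rsid")
    pidx = IntervalIndex(promoters)
    prom_mid = {
        r.gene_id: (int(r.start) + int(r.end)) // 2 for r in promoters.itertuples()
    }
    rows: list[dict] = []

    def add_row(rsid, gene_id, evidence, proxy_rsid, element, var_pos, distance):
        try:
            jump = genes.gene_jump_index(var_pos, gene_id)
        except KeyError:
            jump = -1
        rows.append(
            {
                "rsid": rsid,
                "gene_id": gene_id,
                "evidence": evidence,
                "proxy_rsid": proxy_rsid,
                "element": element,
                "interaction_distance": int(distance),
                "jump_index": jump,
            }
        )

    if gp_set is not None:
        for it in gp_set:
            if it.iclass != "GP":
                continue
            v = pos.loc[it.anchor_id]
            for h in pidx.query(it.distal.chrom, it.distal.start, it.distal.end):
                gid = promoters.loc[h, "gene_id"]
                add_row(
                    it.anchor_id, gid, "GP_direct", None,
                    _element_id("variant", it.anchor_id),
                    int(v["pos"]), abs(int(v["pos"]) - prom_mid[gid]),
                )

    # group proxy table by chromosome once for fast containment scans
    prox = proxies.join(pos[["chrom", "pos"]], on="proxy_rsid", how="inner")
    is_self = prox["proxy_rsid"] == prox["lead_rsid"]
    by_chrom = {c: sub.reset_index(drop=True) for c, sub in prox.groupby("chrom")}
    for it in pd_set:
        if it.iclass != "PD":
            continue
        sub = by_chrom.get(it.distal.chrom)
        if sub is None:
            continue
        inside = sub[(sub["pos"] >= it.distal.start) & (sub["pos"] < it.distal.end)]
        if inside.empty:
            continue
        gid = it.anchor_id
        loop_len = abs(prom_mid[gid] - it.distal.midpoint)
        element = _element_id("fragment", it.distal.chrom, it.distal.start, it.distal.end)
        for r in inside.itertuples():
            if r.proxy_rsid == r.lead_rsid:
                add_row(r.lead_rsid, gid, "PD_contained", None, element, int(r.pos), loop_len)
            else:
                add_row(r.lead_rsid, gid, "PD_LD", r.proxy_rsid, element, int(r.pos), loop_len)

    table = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    table = table.drop_duplicates(["rsid", "gene_id", "evidence", "proxy_rsid", "element"])
    table = table.reset_index(drop=True)

    if len(table):
        per_variant = table.groupby("rsid")["gene_id"].nunique()
        summary = {
            "n_variants": int(table["rsid"].nunique()),
            "n_genes": int(table["gene_id"].nunique()),
            "frac_single_promoter": float((per_variant == 1).mean()),
            "frac_nearest_gene": float((table["jump_index"] == 0).mean()),
            "mean_interaction_distance": float(table["interaction_distance"].mean()),
        }
    else:
        summary = {
            "n_variants": 0, "n_genes": 0, "frac_single_promoter": float("nan"),
            "frac_nearest_gene": float("nan"), "mean_interaction_distance": float("nan"),
        }
    return table, summary


def sharing_pairs(
    assignments: pd.DataFrame, hub_max: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unordered gene pairs sharing a regulatory element.

    An element (distal fragment or variant) with ``k >= 2`` distinct target
    genes yields all ``k (k - 1) / 2`` pairs; pairs recurring across elements
    are reported once with every supporting element.  Elements with more than
    ``hub_max`` genes are excluded as hubs (second return value lists them) —
    a single variant contacting a large gene cluster would otherwise dominate
    the pair set.
    """
    pair_elements: dict[tuple, list] = {}
    hubs = []
    grouped = (
        assignments.groupby("element")["gene_id"].agg(lambda s: sorted(set(s)))
        if len(assignments)
        else pd.Series(dtype=object)
    )
    # a variant's fragment and the variant itself may both appear; group by
    # the recorded element id
    for element, gene_list in grouped.items():
        if len(gene_list) < 2:
            continue
        if hub_max is not None and len(gene_list) > hub_max:
            hubs.append({"element": element, "n_genes": len(gene_list)})
            continue
        for a, b in itertools.combinations(gene_list, 2):
            pair_elements.setdefault((a, b), []).append(element)
    pairs = pd.DataFrame(
        [
            {"gene_a": a, "gene_b": b, "elements": tuple(els), "n_elements": len(els)}
            for (a, b), els in sorted(pair_elements.items())
        ],
        columns=["gene_a", "gene_b", "elements", "n_elements"],
    )
    return pairs, pd.DataFrame(hubs, columns=["element", "n_genes"])


def coexpression_test(
    pairs: pd.DataFrame,
    expr: pd.DataFrame,
    thresholds: Sequence[float] = (1e-3, 1e-10),
    method: str = "pearson",
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Correlation test per gene pair across expression samples.

    Returns the pair table with ``corr_r``/``corr_p`` columns, the fraction
    of tested pairs below each threshold, and the pairs excluded because a
    gene is missing from the matrix (excluded pairs do not enter the
    denominators).
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation test")
    test = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows, missing = [], []
    for r in pairs.itertuples(index=False):
        if r.gene_a not in expr.index or r.gene_b not in expr.index:
            missing.append({"gene_a": r.gene_a, "gene_b": r.gene_b})
            continue
        x = expr.loc[r.gene_a].to_numpy(float)
        y = expr.loc[r.gene_b].to_numpy(float)
        res = test(x, y)
        d = r._asdict()
        d["corr_r"], d["corr_p"] = float(res.statistic), float(res.pvalue)
        rows.append(d)
    tested = pd.DataFrame(rows)
    fractions = {
        t: float((tested["corr_p"] <= t).mean()) if len(tested) else float("nan")
        for t in thresholds
    }
    return tested, fractions, pd.DataFrame(missing, columns=["gene_a", "gene_b"])


@dataclass
class Chi2Result:
    statistic: float
    pvalue: float
    expected_warning: bool = False


def coexpr_chi2(k_observed: int, n_pairs: int, background_prop: float) -> Chi2Result:
    """1-df goodness-of-fit chi-squared of the coexpressed-pair count against
    a background proportion.

    Compares (k, n-k) with expectations (n q, n (1-q)); the p-value is the
    upper tail.  A warning flag is set when an expected cell falls below 1.
    """
    if not (0 <= k_observed <= n_pairs):
        raise ValueError("need 0 <= k_observed <= n_pairs")
    if not (0 < background_prop < 1):
        raise ValueError("background_prop must be in (0, 1)")
    e1 = n_pairs * background_prop
    e0 = n_pairs * (1 - background_prop)
    stat = (k_observed - e1) ** 2 / e1 + ((n_pairs - k_observed) - e0) ** 2 / e0
    return Chi2Result(
        statistic=float(stat),
        pvalue=float(stats.chi2.sf(stat, df=1)),
        expected_warning=min(e1, e0) < 1,
    )


def coexpr_chi2_contingency(
    k_observed: int, n_pairs: int, k_background: int, n_background: int
) -> Chi2Result:
    """2x2 chi-squared variant comparing the tested pairs with an explicit
    background pair sample (continuity-corrected)."""
    table = np.array(
        [
            [k_observed, n_pairs - k_observed],
            [k_background, n_background - k_background],
        ]
    )
    stat, p, _, expected = stats.chi2_contingency(table)
    return Chi2Result(float(stat), float(p), bool((expected < 1).any()))
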