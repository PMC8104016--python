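"""Randomization-based enrichment statistics.

Implements feature-overlap fold enrichment against matched random interaction
sets, the double-randomization scan of LD-proxy overlap with distal elements
over increasing distance windows, trait overrepresentation in the interacting
variant set, and quantile-quantile construction for p-value lists.

Empirical p-values use the add-one permutation form
``(1 + #{null >= observed}) / (1 + n_sets)`` and are therefore never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval, IntervalIndex
from .interactions import InteractionSet

__all__ = [
    "EnrichmentResult",
    "DistanceWindowScan",
    "feature_overlap_enrichment",
    "ld_overlap_scan",
    "trait_fold_enrichment",
    "qq_construct",
]


@dataclass
class EnrichmentResult:
    """Observed statistic against a permutation null."""

    observed: float
    null_mean: float
    null_sd: float
    fold: float
    empirical_p: float
    n_sets: int
    degenerate_null: bool = False


def _empirical_p(observed: float, null: np.ndarray) -> float:
    return (1.0 + float(np.sum(null >= observed))) / (1.0 + len(null))


def _make_result(observed: float, null: np.ndarray) -> EnrichmentResult:
    mean = float(np.mean(null))
    degenerate = mean == 0.0
    return EnrichmentResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=float(np.std(null, ddof=1)) if len(null) > 1 else 0.0,
        fold=float(observed) / mean if not degenerate else 0.0,
        empirical_p=_empirical_p(observed, null),
        n_sets=len(null),
        degenerate_null=degenerate,
    )


def _as_intervals(obj) -> list[GenomicInterval]:
    if isinstance(obj, InteractionSet):
        return obj.distal_intervals()
    return list(obj)


def _overlap_count(intervals: Sequence[GenomicInterval], idx: IntervalIndex) -> int:
    n = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        n += int(idx.overlaps_any(chrom, starts, ends).sum())
    return n


def feature_overlap_enrichment(
    des: Iterable[GenomicInterval] | InteractionSet,
    track: pd.DataFrame,
    random_sets: Sequence,
) -> EnrichmentResult:
    """Fold enrichment of distal elements overlapping a peak track.

    ``observed`` is the number of DEs overlapping at least one peak; the null
    applies the same count to each matched random set.  Peak-track order and
    duplicated peaks do not change the result.
    """
    if not len(random_sets):
        raise ValueError("need at least one random set")
    des = _as_intervals(des)
    idx = IntervalIndex(track)
    observed = _overlap_count(des, idx)
    null = np.array([_overlap_count(_as_intervals(s), idx) for s in random_sets], dtype=float)
    res = _make_result(observed, null)
    if not des:
        res.empirical_p = 1.0
    return res


@dataclass
class WindowResult:
    """Double-randomization result at one distance window (or annulus)."""

    window: int
    observed: int
    vs_random_interactions: EnrichmentResult
    vs_random_snps: EnrichmentResult
    fold: float          # observed over the pooled null mean
    empirical_p: float   # the more conservative of the two conditional p's


@dataclass
class DistanceWindowScan:
    """Per-window results of the LD-proxy / distal-element overlap scan.

    ``cumulative`` counts proxies with lead distance at most the window cap
    (non-decreasing in window size); ``annulus`` counts each proxy once, in
    the ring between consecutive windows, and determines the enrichment
    horizon: the largest window up to which every ring stays significant at
    ``level``.
    """

    windows: list
    cumulative: list
    annulus: list
    horizon: int | None
    level: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, results in (("cumulative", self.cumulative), ("annulus", self.annulus)):
            for r in results:
                rows.append(
                    {
                        "kind": kind,
                        "window": r.window,
                        "observed": r.observed,
                        "fold": r.fold,
                        "empirical_p": r.empirical_p,
                        "p_vs_random_interactions": r.vs_random_interactions.empirical_p,
                        "p_vs_random_snps": r.vs_random_snps.empirical_p,
                    }
                )
        return pd.DataFrame(rows)


class _ProxyLookup:
    """Factorized per-lead proxy arrays for fast repeated proxy-set queries.

    SNPs are coded by their row in the universe table; proxies are
    pre-filtered to the r-squared threshold and the maximal window, with
    self-pairs excluded.
    """

    def __init__(self, ld_table: pd.DataFrame, snp_pos: pd.DataFrame,
                 r2_min: float, max_window: int):
        self.snp_pos = snp_pos.reset_index(drop=True)
        self.code = {r: i for i, r in enumerate(self.snp_pos["rsid"])}
        self.chrom = self.snp_pos["chrom"].to_numpy()
        self.pos = self.snp_pos["pos"].to_numpy(np.int64)
        sub = ld_table[
            (ld_table["r2"] >= r2_min)
            & (ld_table["distance"] <= max_window)
            & (ld_table["proxy_rsid"] != ld_table["lead_rsid"])
            & ld_table["proxy_rsid"].isin(self.code)
        ]
        codes = sub["proxy_rsid"].map(self.code).to_numpy(np.int64)
        dists = sub["distance"].to_numpy(np.int64)
        self._by_lead: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for lead, grp_idx in sub.groupby("lead_rsid").indices.items():
            self._by_lead[lead] = (codes[grp_idx], dists[grp_idx])

    def proxies(self, leads: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Unique proxy codes of ``leads`` with minimal lead distance."""
        parts = [self._by_lead[l] for l in leads if l in self._by_lead]
        if not parts:
            return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
        codes = np.concatenate([p[0] for p in parts])
        dists = np.concatenate([p[1] for p in parts])
        order = np.lexsort((dists, codes))
        codes, dists = codes[order], dists[order]
        first = np.ones(len(codes), dtype=bool)
        first[1:] = codes[1:] != codes[:-1]
        return codes[first], dists[first]

    def flags_in(self, codes: np.ndarray, idx: IntervalIndex) -> np.ndarray:
        flags = np.zeros(len(codes), dtype=bool)
        for chrom in np.unique(self.chrom[codes]):
            m = self.chrom[codes] == chrom
            flags[m] = idx.contains_points(chrom, self.pos[codes[m]])
        return flags


def ld_overlap_scan(
    des: Iterable[GenomicInterval] | InteractionSet,
    leads: Sequence[str],
    ld_table: pd.DataFrame,
    snp_pos: pd.DataFrame,
    windows: Sequence[int],
    rand_interaction_sets: Sequence,
    rand_snp_sets: Sequence[pd.DataFrame],
    r2_min: float = 0.8,
    level: float = 0.05,
) -> DistanceWindowScan:
    """Double-randomization scan of LD-proxy overlap with distal elements.

    For each distance cap ``w`` the observed statistic counts distinct proxy
    SNPs within ``w`` of a lead that fall inside a real distal element.  Two
    conditional nulls are computed: the same proxies against each matched
    random interaction set, and the proxies of each matched random SNP set
    against the real distal elements.  The headline per-window empirical p is
    the larger (more conservative) of the two; the fold divides the observed
    count by the pooled null mean.
    """
    windows = list(windows)
    if any(b <= a for a, b in zip(windows, windows[1:])) or not windows:
        raise ValueError("windows must be non-empty and strictly increasing")
    des = _as_intervals(des)
    real_idx = IntervalIndex.from_intervals(des)
    wmax = windows[-1]

    lookup = _ProxyLookup(ld_table, snp_pos, r2_min, wmax)
    codes, dist = lookup.proxies(leads)
    in_real = lookup.flags_in(codes, real_idx)

    rand_idx = [IntervalIndex.from_intervals(_as_intervals(s)) for s in rand_interaction_sets]
    in_rand = np.array([lookup.flags_in(codes, ix) for ix in rand_idx])  # sets x proxies

    # in-real-DE flag for every universe SNP, computed once
    all_codes = np.arange(len(lookup.pos))
    in_real_all = lookup.flags_in(all_codes, real_idx)
    snp_cd = [lookup.proxies(list(s["rsid"])) for s in rand_snp_sets]
    snp_dist = [d for _, d in snp_cd]
    snp_in_real = [in_real_all[c] for c, _ in snp_cd]

    def window_result(mask_fn) -> WindowResult:
        m = mask_fn(dist)
        obs = int(np.sum(in_real & m))
        null_i = in_rand[:, m].sum(axis=1).astype(float) if in_rand.size else np.zeros(len(rand_idx))
        null_ii = np.array(
            [float(np.sum(f & mask_fn(d))) for d, f in zip(snp_dist, snp_in_real)]
        )
        r_i = _make_result(obs, null_i)
        r_ii = _make_result(obs, null_ii)
        pooled = np.concatenate([null_i, null_ii])
        pooled_mean = float(np.mean(pooled)) if len(pooled) else 0.0
        return WindowResult(
            window=0,
            observed=obs,
            vs_random_interactions=r_i,
            vs_random_snps=r_ii,
            fold=obs / pooled_mean if pooled_mean else 0.0,
            empirical_p=max(r_i.empirical_p, r_ii.empirical_p),
        )

    cumulative, annulus = [], []
    prev = 0
    for w in windows:
        rc = window_result(lambda d, w=w: d <= w)
        rc.window = w
        cumulative.append(rc)
        ra = window_result(lambda d, lo=prev, hi=w: (d > lo) & (d <= hi))
        ra.window = w
        annulus.append(ra)
        prev = w

    # horizon: largest window up to which every distance ring stays
    # significant; an isolated far ring (a ~level-rate false positive among
    # many rings) does not extend it
    horizon = None
    for r in annulus:
        if r.empirical_p < level:
            horizon = r.window
        else:
            break
    return DistanceWindowScan(windows, cumulative, annulus, horizon, level)


def trait_fold_enrichment(
    interacting_variants: Sequence[str],
    catalog: pd.DataFrame,
    min_variants: int = 14,
) -> pd.DataFrame:
    """Per-trait fold enrichment of the interacting variant set.

    For a trait with ``n_t`` catalog variants out of ``N`` total, the expected
    count among the ``M`` interacting variants is ``(n_t / N) * M``; the fold
    divides the observed count by that expectation.  ``fraction_found`` is the
    share of the trait's variants recovered in the interaction set.  Traits
    with fewer than ``min_variants`` catalog variants are dropped.
    """
    if min_variants < 1:
        raise ValueError("min_variants must be >= 1")
    interacting = set(interacting_variants)
    stray = interacting - set(catalog["rsid"])
    if stray:
        raise ValueError(
            f"{len(stray)} interacting variants absent from the catalog, "
            f"e.g. {sorted(stray)[:5]}"
        )
    n_total = catalog["rsid"].nunique()
    m = len(interacting)
    rows = []
    for trait, sub in catalog.groupby("trait"):
        trait_vars = set(sub["rsid"])
        n_t = len(trait_vars)
        if n_t < min_variants:
            continue
        observed = len(trait_vars & interacting)
        expected = n_t / n_total * m
        rows.append(
            {
                "trait": trait,
                "n_trait_variants": n_t,
                "observed": observed,
                "expected": expected,
                "fold": observed / expected if expected else np.nan,
                "fraction_found": observed / n_t,
            }
        )
    return (
        pd.DataFrame(
            rows,
            columns=[
                "trait", "n_trait_variants", "observed", "expected", "fold", "fraction_found",
            ],
        )
        .sort_values("fold", ascending=False)
        .reset_index(drop=True)
    )


@dataclass
class QQResult:
    """Quantile pairs of two p-value lists on the -log10 scale."""

    control: np.ndarray
    real: np.ndarray
    fraction_above: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"control_neglog10": self.control, "real_neglog10": self.real})


def qq_construct(p_real: Sequence[float], p_control: Sequence[float]) -> QQResult:
    """Pair the -log10 quantiles of two p-value lists on a common grid.

    The grid has ``k = min(len(real), len(control))`` points; the longer list
    is linearly interpolated.  ``fraction_above`` is the share of grid points
    where the real quantile exceeds the control quantile (above the diagonal).
    """
    p_real = np.asarray(p_real, dtype=float)
    p_control = np.asarray(p_control, dtype=float)
    if not len(p_real) or not len(p_control):
        raise ValueError("both p-value lists must be non-empty")
    for name, p in (("real", p_real), ("control", p_control)):
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError(f"{name} p-values must lie in (0, 1]")
    t_real = np.sort(-np.log10(p_real))
    t_ctrl = np.sort(-np.log10(p_control))
    k = min(len(t_real), len(t_ctrl))
    qs = (np.arange(k) + 0.5) / k
    x = np.quantile(t_ctrl, qs, method="linear")
    y = np.quantile(t_real, qs, method="linear")
    return QQResult(control=x, real=y, fraction_above=float(np.mean(y > x)))
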