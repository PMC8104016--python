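"""Matched null ensembles for the permutation tests.

Two null models are provided:

* random interaction sets that preserve, for every real interaction, the
  distal segment length exactly and the anchor-to-distal midpoint distance
  exactly, while re-drawing the anchoring promoter uniformly and the side of
  the promoter at random ("segment-length and distance-from-promoter
  controlled" sets);
* random SNP sets matched to the real set on minor allele frequency (within
  an absolute tolerance) and on local LD structure (the number of LD buddies
  at the working r-squared threshold, binned).

Both use one master seed with per-set derived streams, so ensembles are
reproducible and sets are independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicInterval, IntervalIndex
from .interactions import Interaction, InteractionSet

__all__ = [
    "RandomSetSpec",
    "MatchedSNPSpec",
    "matched_random_interactions",
    "matched_random_snps",
]


@dataclass
class RandomSetSpec:
    """Controls for the matched random interaction ensemble.

    ``exclusion`` intervals (typically the probed regions) are never
    overlapped by placements; off-chromosome or excluded placements are
    rejected and re-drawn with a fresh promoter and side.
    """

    n_sets: int = 100
    seed: int = 0
    exclusion: pd.DataFrame | None = None  # chrom/start/end
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


@dataclass
class MatchedSNPSpec:
    """Controls for the matched random SNP ensemble.

    ``ld_buddy_bins`` are the left edges of the buddy-count bins; the default
    bins are {0}, {1-5}, {6-20}, {21-100}, {>100}.
    """

    maf_tolerance: float = 0.05
    ld_buddy_bins: tuple = (0, 1, 6, 21, 101)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf_tolerance < 0.5):
            raise ValueError("maf_tolerance must be in (0, 0.5)")

    def buddy_bin(self, counts: np.ndarray) -> np.ndarray:
        edges = np.asarray(self.ld_buddy_bins)
        return np.clip(np.searchsorted(edges, counts, side="right") - 1, 0, len(edges) - 1)


def _anchor_midpoints(
    real: InteractionSet, promoters: pd.DataFrame, variants: pd.DataFrame | None
) -> np.ndarray:
    prom_mid = {
        r.gene_id: (int(r.start) + int(r.end)) // 2 for r in promoters.itertuples()
    }
    var_pos = (
        {r.rsid: int(r.pos) for r in variants.itertuples()} if variants is not None else {}
    )
    mids = []
    for it in real:
        if it.anchor_type == "promoter":
            mids.append(prom_mid[it.anchor_id])
        else:
            mids.append(var_pos[it.anchor_id])
    return np.asarray(mids, dtype=np.int64)


def matched_random_interactions(
    real: InteractionSet,
    promoters: pd.DataFrame,
    chrom_sizes: dict,
    spec: RandomSetSpec,
    variants: pd.DataFrame | None = None,
) -> list[InteractionSet]:
    """Draw ``spec.n_sets`` random interaction sets matched to ``real``.

    For each real interaction a promoter is drawn uniformly from the probe
    panel and a segment of identical length is placed at the same absolute
    anchor-to-distal-midpoint distance on a uniformly random side.  Length and
    |distance| multisets of every random set therefore equal the real set's
    exactly; only the anchoring promoter and the side vary.
    """
    real_items = list(real)
    lengths = np.array([it.distal.length for it in real_items], dtype=np.int64)
    mids = _anchor_midpoints(real, promoters, variants)
    dmids = np.array([it.distal.midpoint for it in real_items], dtype=np.int64)
    dists = np.abs(dmids - mids)

    pm = ((promoters["start"].to_numpy(np.int64) + promoters["end"].to_numpy(np.int64)) // 2)
    pchrom = promoters["chrom"].to_numpy()
    psize = np.array([chrom_sizes[c] for c in pchrom], dtype=np.int64)
    excl = IntervalIndex(spec.exclusion) if spec.exclusion is not None else None

    out = []
    for k in range(spec.n_sets):
        rng = np.random.default_rng([spec.seed, k])
        n = len(real_items)
        res_prom = np.full(n, -1, dtype=np.int64)
        res_start = np.zeros(n, dtype=np.int64)
        pending = np.arange(n)
        for _ in range(spec.max_attempts):
            if not len(pending):
                break
            pi = rng.integers(0, len(pm), size=len(pending))
            side = rng.integers(0, 2, size=len(pending)) * 2 - 1
            mid = pm[pi] + side * dists[pending]
            start = mid - lengths[pending] // 2
            end = start + lengths[pending]
            ok = (start >= 0) & (end <= psize[pi])
            if excl is not None:
                for c in np.unique(pchrom[pi]):
                    m = ok & (pchrom[pi] == c)
                    if m.any():
                        ok[m] &= ~excl.overlaps_any(c, start[m], end[m])
            res_prom[pending[ok]] = pi[ok]
            res_start[pending[ok]] = start[ok]
            pending = pending[~ok]
        if len(pending):
            it = real_items[pending[0]]
            raise RuntimeError(
                f"could not place segment for interaction {it.key} after "
                f"{spec.max_attempts} attempts"
            )
        gid_arr = promoters["gene_id"].to_numpy()
        items: list[Interaction] = []
        seen: set[tuple] = set()
        for i, it in enumerate(real_items):
            pi_i, start_i = int(res_prom[i]), int(res_start[i])
            attempts = 0
            while True:
                end_i = start_i + int(lengths[i])
                full_key = (gid_arr[pi_i], pchrom[pi_i], start_i, end_i)
                if full_key not in seen:
                    break
                # chance collision on (anchor, distal): re-draw promoter and
                # side so the length and |distance| multisets stay exact
                attempts += 1
                if attempts > spec.max_attempts:
                    raise RuntimeError(
                        f"could not place unique segment for interaction {it.key}"
                    )
                pi_i = int(rng.integers(0, len(pm)))
                side_i = int(rng.integers(0, 2)) * 2 - 1
                start_i = int(pm[pi_i]) + side_i * int(dists[i]) - int(lengths[i]) // 2
                end_i = start_i + int(lengths[i])
                if not (0 <= start_i and end_i <= int(psize[pi_i])):
                    start_i = int(res_start[i])  # invalid draw: loop again
                    pi_i = int(res_prom[i])
                    continue
                if excl is not None and bool(
                    excl.overlaps_any(
                        pchrom[pi_i], np.array([start_i]), np.array([end_i])
                    )[0]
                ):
                    start_i = int(res_start[i])
                    pi_i = int(res_prom[i])
                    continue
            seen.add(full_key)
            distal = GenomicInterval(pchrom[pi_i], start_i, end_i)
            items.append(
                Interaction(
                    gid_arr[pi_i], "promoter", distal, it.support, it.pvalue, it.iclass
                )
            )
        out.append(InteractionSet(real.cell_type, items, real.replicate_count))
    return out


def matched_random_snps(
    real: pd.DataFrame,
    universe: pd.DataFrame,
    spec: MatchedSNPSpec,
    n_sets: int,
) -> list[pd.DataFrame]:
    """Draw ``n_sets`` random SNP sets matched on MAF and LD-buddy bin.

    ``real`` and ``universe`` need columns rsid, maf, n_ld_buddies (the
    universe additionally carries chrom/pos, passed through).  Each real SNP
    is replaced by a uniform draw among universe SNPs within the MAF tolerance
    and in the same buddy bin, excluding the real set itself and avoiding
    duplicates within a set.
    """
    real_rsids = set(real["rsid"])
    u_maf = universe["maf"].to_numpy()
    u_bin = spec.buddy_bin(universe["n_ld_buddies"].to_numpy())
    u_ok = ~universe["rsid"].isin(real_rsids).to_numpy()
    eligible: list[np.ndarray] = []
    for row in real.itertuples():
        rbin = spec.buddy_bin(np.array([row.n_ld_buddies]))[0]
        mask = u_ok & (np.abs(u_maf - row.maf) <= spec.maf_tolerance) & (u_bin == rbin)
        idx = np.flatnonzero(mask)
        if not len(idx):
            raise ValueError(
                f"no eligible match for SNP {row.rsid} "
                f"(maf={row.maf:.3f}, buddy bin {rbin})"
            )
        eligible.append(idx)

    out = []
    for k in range(n_sets):
        rng = np.random.default_rng([spec.seed, k])
        used: set[int] = set()
        chosen: list[int] = []
        for idx in eligible:
            pick = None
            for _ in range(1000):
                cand = int(idx[rng.integers(0, len(idx))])
                if cand not in used:
                    pick = cand
                    break
            if pick is None:
                # exhaustive fallback before giving up
                free = [i for i in idx if i not in used]
                if not free:
                    raise RuntimeError("matched SNP pool exhausted within a set")
                pick = int(free[rng.integers(0, len(free))])
            used.add(pick)
            chosen.append(pick)
        out.append(universe.iloc[chosen].reset_index(drop=True))
    return out
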