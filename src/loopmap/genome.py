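"""Coordinate conventions and annotation types shared by every analysis stage.

All coordinates are 0-based, half-open ``[start, end)``.  BED input is used
natively; GTF input is converted on read (GTF is 1-based inclusive).  Distances
between an interval anchor and a gene use the interval midpoint; variants use
their single base position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Gene",
    "PromoterProbe",
    "VariantProbe",
    "GeneAnnotation",
    "IntervalIndex",
    "overlaps",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic segment ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base (half-open)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class Gene:
    """A gene with a single representative TSS.

    The TSS sits at ``body.start`` on the + strand and at ``body.end - 1`` on
    the - strand.
    """

    gene_id: str
    name: str
    tss: int
    strand: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be +/-, got {self.strand!r}")
        expected = self.body.start if self.strand == "+" else self.body.end - 1
        if self.tss != expected:
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"{self.strand} strand body {self.body.start}-{self.body.end}"
            )


@dataclass(frozen=True)
class PromoterProbe:
    """A capture probe centred on a gene's TSS."""

    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class VariantProbe:
    """A capture probe on a trait-associated variant.

    ``traits`` holds (trait name, association p-value) pairs; catalog
    filtering upstream guarantees p <= 1e-6.
    """

    rsid: str
    chrom: str
    pos: int
    maf: float
    traits: tuple = ()

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError("maf must be in [0, 0.5]")


class NoAnnotationError(KeyError):
    """Raised when a chromosome carries no annotated genes."""


class GeneAnnotation:
    """A queryable set of genes with fast nearest-TSS lookups.

    Ties in nearest-gene queries break by smaller TSS, then lexicographic
    gene_id, so results are deterministic.
    """

    def __init__(self, genes: Iterable[Gene]):
        self._genes: dict[str, Gene] = {}
        by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g
            by_chrom.setdefault(g.body.chrom, []).append(g)
        self._by_chrom: dict[str, list[Gene]] = {}
        self._tss: dict[str, np.ndarray] = {}
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self._by_chrom[chrom] = gs
            self._tss[chrom] = np.array([g.tss for g in gs], dtype=np.int64)

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __iter__(self):
        return iter(self._genes.values())

    def __getitem__(self, gene_id: str) -> Gene:
        return self._genes[gene_id]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chrom: str) -> list[Gene]:
        return list(self._by_chrom.get(chrom, []))

    def nearest_gene(self, chrom: str, pos: int) -> tuple[Gene, int]:
        """Gene minimising ``|tss - pos|`` and that minimal distance."""
        if chrom not in self._by_chrom:
            raise NoAnnotationError(f"no annotated genes on chromosome {chrom!r}")
        gs = self._by_chrom[chrom]
        tss = self._tss[chrom]
        i = int(np.searchsorted(tss, pos))
        best: Gene | None = None
        best_key: tuple[int, int, str] | None = None
        for j in range(max(0, i - 1), min(len(gs), i + 1) + 1):
            if j >= len(gs):
                continue
            g = gs[j]
            key = (abs(g.tss - pos), g.tss, g.gene_id)
            if best_key is None or key < best_key:
                best, best_key = g, key
        # several genes may share the winning TSS; gs is (tss, gene_id)-sorted
        # so scan the equal-tss run for the lexicographically smallest id
        assert best is not None and best_key is not None
        d = best_key[0]
        for g in gs:
            if abs(g.tss - pos) == d and (g.tss, g.gene_id) < (best.tss, best.gene_id):
                best = g
        return best, d

    def gene_jump_index(self, anchor_pos: int, target: Gene | str) -> int:
        """Rank (from 0) of ``target`` when the chromosome's genes are sorted
        by distance of their TSS from ``anchor_pos``.

        0 means the interaction reaches the nearest gene; 1 means the nearest
        gene is jumped over, and so on.  Ties order as in :meth:`nearest_gene`.
        """
        if isinstance(target, str):
            target = self._genes[target]
        elif target.gene_id not in self._genes:
            raise KeyError(f"target {target.gene_id!r} not in annotation set")
        chrom = target.body.chrom
        if chrom not in self._by_chrom:
            raise NoAnnotationError(f"no annotated genes on chromosome {chrom!r}")
        ranked = sorted(
            self._by_chrom[chrom],
            key=lambda g: (abs(g.tss - anchor_pos), g.tss, g.gene_id),
        )
        return next(i for i, g in enumerate(ranked) if g.gene_id == target.gene_id)


class IntervalIndex:
    """Vectorised overlap queries against a fixed interval collection.

    Uses per-chromosome start-sorted arrays with a running maximum of ends, so
    membership queries cost one ``searchsorted`` even when intervals overlap
    each other.
    """

    def __init__(self, frame: pd.DataFrame):
        """``frame`` needs columns chrom, start, end."""
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._cummax: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        self._maxlen: dict[str, int] = {}
        if len(frame):
            for chrom, sub in frame.groupby("chrom", sort=False):
                order = np.argsort(sub["start"].to_numpy(), kind="stable")
                s = sub["start"].to_numpy(np.int64)[order]
                e = sub["end"].to_numpy(np.int64)[order]
                self._starts[chrom] = s
                self._ends[chrom] = e
                self._cummax[chrom] = np.maximum.accumulate(e)
                self._order[chrom] = sub.index.to_numpy()[order]
                self._maxlen[chrom] = int((e - s).max())

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalIndex":
        rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def __bool__(self) -> bool:
        return bool(self._starts)

    def contains_points(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean array: does some interval contain each position?"""
        pos = np.asarray(pos, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self._starts[chrom], pos, side="right")
        hit = idx > 0
        hit[hit] = self._cummax[chrom][idx[hit] - 1] > pos[hit]
        return hit

    def overlaps_any(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean array: does each query interval overlap some interval?"""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(starts.shape, dtype=bool)
        idx = np.searchsorted(self._starts[chrom], ends, side="left")
        hit = idx > 0
        hit[hit] = self._cummax[chrom][idx[hit] - 1] > starts[hit]
        return hit

    def query(self, chrom: str, start: int, end: int) -> list:
        """Original frame indices of all intervals overlapping [start, end)."""
        if chrom not in self._starts:
            return []
        s = self._starts[chrom]
        lo = int(np.searchsorted(s, start - self._maxlen[chrom], side="left"))
        hi = int(np.searchsorted(s, end, side="left"))
        out = []
        for j in range(lo, hi):
            if self._ends[chrom][j] > start:
                out.append(self._order[chrom][j])
        return out
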