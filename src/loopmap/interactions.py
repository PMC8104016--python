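"""Interaction tables: reading, replicate filtering, classification,
network construction and the cross-cell-type interaction-profile matrix.

An interaction connects an anchored capture probe (a promoter or a probed
variant) to a distal restriction fragment, with per-replicate supporting
read-pair counts and an interaction-call p-value from the upstream caller.
Classes follow the three interaction types of capture Hi-C maps:

* ``PP``  promoter anchor whose distal fragment overlaps another promoter probe
* ``PD``  promoter anchor with a non-probed distal fragment
* ``GP``  variant anchor whose distal fragment overlaps a promoter probe

Variant-anchored interactions to non-promoter fragments are retained with
class ``unset`` and surfaced through :func:`class_counts`.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genome import GenomicInterval, IntervalIndex

__all__ = [
    "Interaction",
    "InteractionSet",
    "RegNetwork",
    "read_interactions",
    "write_interactions",
    "write_bedpe",
    "replicate_consistent",
    "classify_interactions",
    "class_counts",
    "build_network",
    "profile_matrix",
]

ANCHOR_TYPES = ("promoter", "variant")
CLASSES = ("PP", "PD", "GP", "unset")


@dataclass(frozen=True)
class Interaction:
    """One called contact between an anchored probe and a distal fragment."""

    anchor_id: str
    anchor_type: str
    distal: GenomicInterval
    support: tuple
    pvalue: float
    iclass: str = "unset"

    def __post_init__(self) -> None:
        if self.anchor_type not in ANCHOR_TYPES:
            raise ValueError(f"anchor_type must be one of {ANCHOR_TYPES}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"pvalue must be in (0, 1], got {self.pvalue}")
        if any(s < 1 for s in self.support):
            raise ValueError("all support counts must be >= 1")
        if self.iclass not in CLASSES:
            raise ValueError(f"iclass must be one of {CLASSES}")

    @property
    def key(self) -> tuple:
        return (self.anchor_id, self.distal.chrom, self.distal.start, self.distal.end)


class InteractionSet:
    """An ordered, duplicate-free collection of interactions for one cell type."""

    def __init__(
        self,
        cell_type: str,
        interactions: Iterable[Interaction] = (),
        replicate_count: int = 1,
    ):
        self.cell_type = cell_type
        self.replicate_count = replicate_count
        self._items: dict[tuple, Interaction] = {}
        for it in interactions:
            if it.key in self._items:
                raise ValueError(f"duplicate interaction {it.key}")
            self._items[it.key] = it

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items.values())

    def __contains__(self, key: tuple) -> bool:
        return key in self._items

    def get(self, key: tuple) -> Interaction | None:
        return self._items.get(key)

    def subset(self, iclass: str) -> "InteractionSet":
        return InteractionSet(
            self.cell_type,
            (it for it in self if it.iclass == iclass),
            self.replicate_count,
        )

    def distal_intervals(self) -> list[GenomicInterval]:
        return [it.distal for it in self]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        nrep = max((len(it.support) for it in self), default=self.replicate_count)
        for it in self:
            row = {
                "anchor_id": it.anchor_id,
                "anchor_type": it.anchor_type,
                "chrom": it.distal.chrom,
                "distal_start": it.distal.start,
                "distal_end": it.distal.end,
            }
            for r in range(nrep):
                row[f"support_rep{r + 1}"] = it.support[r] if r < len(it.support) else 0
            row["pvalue"] = it.pvalue
            row["iclass"] = it.iclass
            rows.append(row)
        cols = ["anchor_id", "anchor_type", "chrom", "distal_start", "distal_end"]
        cols += [f"support_rep{r + 1}" for r in range(nrep)] + ["pvalue", "iclass"]
        return pd.DataFrame(rows, columns=cols)


def read_interactions(
    path: str,
    promoters: pd.DataFrame,
    variants: pd.DataFrame | None = None,
    cell_type: str = "unknown",
    replicate_count: int | None = None,
) -> InteractionSet:
    """Read an interaction TSV, resolving every anchor against the probe tables.

    Expected columns: anchor_id, anchor_type, chrom, distal_start, distal_end,
    support_rep1[, support_rep2, ...], pvalue.  Unknown anchors raise with the
    offending ids; malformed rows raise with their line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        warnings.warn(f"{path}: empty interaction file")
        return InteractionSet(cell_type, (), replicate_count or 1)
    sup_cols = sorted(c for c in df.columns if c.startswith("support_rep"))
    if replicate_count is None:
        replicate_count = len(sup_cols)
    known_prom = set(promoters["gene_id"])
    known_var = set(variants["rsid"]) if variants is not None else set()
    unknown = sorted(
        set(
            df.loc[
                ~(
                    ((df["anchor_type"] == "promoter") & df["anchor_id"].isin(known_prom))
                    | ((df["anchor_type"] == "variant") & df["anchor_id"].isin(known_var))
                ),
                "anchor_id",
            ]
        )
    )
    if unknown:
        raise ValueError(f"{path}: unknown anchor ids: {', '.join(map(str, unknown))}")
    items, bad = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            support = tuple(int(getattr(row, c)) for c in sup_cols)
            items.append(
                Interaction(
                    str(row.anchor_id),
                    str(row.anchor_type),
                    GenomicInterval(str(row.chrom), int(row.distal_start), int(row.distal_end)),
                    support,
                    float(row.pvalue),
                    getattr(row, "iclass", "unset"),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append(f"line {line_no}: {exc}")
    if bad:
        raise ValueError(f"{path}: malformed rows:\n" + "\n".join(bad))
    return InteractionSet(cell_type, items, replicate_count)


def write_interactions(iset: InteractionSet, path: str) -> None:
    iset.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bedpe(iset: InteractionSet, path: str, promoters: pd.DataFrame, variants: pd.DataFrame | None = None) -> None:
    """BEDPE export: anchor probe coordinates, distal coordinates,
    name=anchor_id, score=-log10 p."""
    prom = promoters.set_index("gene_id")
    var = variants.set_index("rsid") if variants is not None else None
    rows = []
    for it in iset:
        if it.anchor_type == "promoter":
            p = prom.loc[it.anchor_id]
            a = (p["chrom"], int(p["start"]), int(p["end"]))
        else:
            v = var.loc[it.anchor_id]
            a = (v["chrom"], int(v["pos"]), int(v["pos"]) + 1)
        rows.append(
            (*a, it.distal.chrom, it.distal.start, it.distal.end, it.anchor_id,
             round(-np.log10(it.pvalue), 4))
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def replicate_consistent(a: InteractionSet, b: InteractionSet) -> InteractionSet:
    """Keep (anchor, distal) pairs present in both replicates.

    Support counts are concatenated per replicate and the merged p-value is
    the less significant (larger) of the two, a conservative merge.
    """
    if a.cell_type != b.cell_type:
        raise ValueError(
            f"replicates have different cell types: {a.cell_type!r} vs {b.cell_type!r}"
        )
    merged = []
    for it in a:
        other = b.get(it.key)
        if other is None:
            continue
        merged.append(
            replace(
                it,
                support=it.support + other.support,
                pvalue=max(it.pvalue, other.pvalue),
            )
        )
    return InteractionSet(a.cell_type, merged, a.replicate_count + b.replicate_count)


def classify_interactions(
    iset: InteractionSet, promoters: pd.DataFrame, variants: pd.DataFrame | None = None
) -> InteractionSet:
    """Assign PP / PD / GP classes by overlap with the promoter probe track.

    Variant-anchored interactions whose distal fragment overlaps no promoter
    probe stay ``unset`` (the upstream caller targets promoters, so these are
    reported rather than classified).
    """
    pidx = IntervalIndex(promoters.rename(columns={"start": "start", "end": "end"}))
    out = []
    for it in iset:
        on_promoter = bool(
            pidx.overlaps_any(
                it.distal.chrom,
                np.array([it.distal.start]),
                np.array([it.distal.end]),
            )[0]
        )
        if it.anchor_type == "promoter":
            iclass = "PP" if on_promoter else "PD"
        else:
            iclass = "GP" if on_promoter else "unset"
        out.append(replace(it, iclass=iclass))
    return InteractionSet(iset.cell_type, out, iset.replicate_count)


def class_counts(iset: InteractionSet) -> Counter:
    """Interaction counts per class; unset counts flag unclassifiable rows."""
    return Counter(it.iclass for it in iset)


@dataclass
class RegNetwork:
    """The promoter-enhancer-variant graph with its connected components."""

    graph: nx.Graph
    components: list
    composition: pd.DataFrame  # one row per component, node-kind counts

    @property
    def giant_component(self) -> set:
        return max(self.components, key=len) if self.components else set()


def _node_id(kind: str, *parts) -> str:
    return kind + ":" + ":".join(map(str, parts))


def build_network(
    sets: Sequence[InteractionSet],
    promoters: pd.DataFrame,
    per_chrom: bool = False,
) -> RegNetwork:
    """Build the undirected regulatory network from classified interaction sets.

    Nodes are promoters (``P:``), variants (``V:``) and distal elements
    (``D:``); every interaction contributes one edge.  PP and GP edges connect
    probe nodes through the promoter probe the distal fragment overlaps.
    With ``per_chrom`` the composition table also records each component's
    chromosome.
    """
    pidx = IntervalIndex(promoters)
    g = nx.Graph()
    for iset in sets:
        for it in iset:
            dnode = _node_id("D", it.distal.chrom, it.distal.start, it.distal.end)
            if it.anchor_type == "promoter":
                anode = _node_id("P", it.anchor_id)
                g.add_node(anode, kind="promoter")
            else:
                anode = _node_id("V", it.anchor_id)
                g.add_node(anode, kind="variant")
            if it.iclass in ("PP", "GP"):
                hits = pidx.query(it.distal.chrom, it.distal.start, it.distal.end)
                for h in hits:
                    onode = _node_id("P", promoters.loc[h, "gene_id"])
                    g.add_node(onode, kind="promoter")
                    g.add_edge(anode, onode, pvalue=it.pvalue, iclass=it.iclass)
            else:
                g.add_node(dnode, kind="distal", chrom=it.distal.chrom)
                g.add_edge(anode, dnode, pvalue=it.pvalue, iclass=it.iclass)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    rows = []
    for i, comp in enumerate(comps):
        kinds = Counter(g.nodes[n]["kind"] for n in comp)
        row = {
            "component": i,
            "n_nodes": len(comp),
            "n_promoters": kinds.get("promoter", 0),
            "n_variants": kinds.get("variant", 0),
            "n_distal": kinds.get("distal", 0),
            "n_edges": g.subgraph(comp).number_of_edges(),
        }
        if per_chrom:
            chroms = {
                g.nodes[n].get("chrom") for n in comp if g.nodes[n].get("chrom")
            }
            row["chroms"] = ",".join(sorted(chroms))
        rows.append(row)
    return RegNetwork(g, comps, pd.DataFrame(rows))


def profile_matrix(
    sets: Mapping[str, InteractionSet],
    bin_size: int,
    chrom_sizes: Mapping[str, int],
    gene_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary promoter x genomic-bin matrix of PD interactions, one block of
    rows per cell type (index level ``cell_type``).

    Entry 1 iff the promoter has a PD interaction whose distal midpoint falls
    in the bin.  Feeds a principal-component decomposition downstream (the
    decomposition itself is delegated to the caller).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if len(sets) < 2:
        raise ValueError("profile matrix needs at least two cell types")
    chroms = sorted(chrom_sizes)
    offsets, total = {}, 0
    for c in chroms:
        offsets[c] = total
        total += -(-chrom_sizes[c] // bin_size)
    columns = []
    for c in chroms:
        nb = -(-chrom_sizes[c] // bin_size)
        columns += [f"{c}:{i * bin_size}" for i in range(nb)]
    promoters: set[str] = set()
    for iset in sets.values():
        promoters |= {it.anchor_id for it in iset if it.iclass == "PD"}
    if gene_subset is not None:
        promoters &= set(gene_subset)
    promoters_sorted = sorted(promoters)
    prow = {p: i for i, p in enumerate(promoters_sorted)}
    blocks = []
    index = []
    for cell_type in sorted(sets):
        mat = np.zeros((len(promoters_sorted), total), dtype=np.int8)
        for it in sets[cell_type]:
            if it.iclass != "PD" or it.anchor_id not in prow:
                continue
            col = offsets[it.distal.chrom] + it.distal.midpoint // bin_size
            mat[prow[it.anchor_id], col] = 1
        blocks.append(mat)
        index += [(cell_type, p) for p in promoters_sorted]
    data = np.vstack(blocks) if blocks else np.zeros((0, total), dtype=np.int8)
    return pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(index, names=["cell_type", "gene_id"]),
        columns=columns,
    )
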