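import numpy as np
import pandas as pd
import pytest

from loopmap import (
    InteractionSet,
    build_network,
    class_counts,
    classify_interactions,
    profile_matrix,
    read_interactions,
    replicate_consistent,
    write_interactions,
)

from conftest import make_interaction


@pytest.fixture
def raw_set(toy_promoters, toy_variants):
    items = [
        # promoter anchor onto another promoter's probe -> PP
        make_interaction("G1", "chr1", 20_000, 20_400),
        # promoter anchor onto intergenic fragment -> PD
        make_interaction("G1", "chr1", 100_000, 100_700),
        make_interaction("G2", "chr1", 150_000, 150_600),
        # variant anchor onto promoter probe -> GP
        make_interaction("rs1", "chr1", 29_600, 30_400, anchor_type="variant"),
        # variant anchor onto non-probed fragment -> unset
        make_interaction("rs2", "chr1", 180_000, 180_500, anchor_type="variant"),
    ]
    return InteractionSet("AEC", items)


def test_round_trip_preserves_fields(tmp_path, raw_set, toy_promoters, toy_variants):
    path = tmp_path / "ints.tsv"
    write_interactions(raw_set, path)
    back = read_interactions(path, toy_promoters, toy_variants, cell_type="AEC")
    assert len(back) == len(raw_set)
    for it in raw_set:
        other = back.get(it.key)
        assert other is not None
        assert other.support == it.support
        assert other.pvalue == pytest.approx(it.pvalue)
        assert other.anchor_type == it.anchor_type


def test_unknown_anchor_named_in_error(tmp_path, raw_set, toy_promoters, toy_variants):
    path = tmp_path / "ints.tsv"
    df = raw_set.to_frame()
    df.loc[0, "anchor_id"] = "GHOST"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="GHOST"):
        read_interactions(path, toy_promoters, toy_variants)


def test_empty_file_warns(tmp_path, toy_promoters, toy_variants):
    path = tmp_path / "empty.tsv"
    pd.DataFrame(columns=["anchor_id", "anchor_type", "chrom", "distal_start",
                          "distal_end", "support_rep1", "pvalue"]).to_csv(
        path, sep="\t", index=False)
    with pytest.warns(UserWarning):
        back = read_interactions(path, toy_promoters, toy_variants)
    assert len(back) == 0


class TestReplicateConsistent:
    def test_pair_in_one_replicate_only_excluded(self):
        a = InteractionSet("AEC", [make_interaction("G1", "chr1", 1_000, 1_500)])
        b = InteractionSet("AEC", [make_interaction("G1", "chr1", 2_000, 2_500)])
        assert len(replicate_consistent(a, b)) == 0

    def test_identical_replicates_identity(self, raw_set):
        merged = replicate_consistent(raw_set, raw_set)
        assert len(merged) == len(raw_set)
        assert {it.key for it in merged} == {it.key for it in raw_set}

    def test_intersection_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            keys_a = {(f"G{i}", "chr1", int(s), int(s) + 500)
                      for i, s in enumerate(rng.integers(0, 1_000_000, size=10))}
            keys_b = set(list(keys_a)[:7]) | {
                ("GX", "chr1", int(s), int(s) + 500)
                for s in rng.integers(0, 1_000_000, size=5)
            }
            mk = lambda k: make_interaction(k[0], k[1], k[2], k[3])
            a = InteractionSet("CT", map(mk, keys_a))
            b = InteractionSet("CT", map(mk, keys_b))
            merged = replicate_consistent(a, b)
            assert {it.key for it in merged} == keys_a & keys_b
            assert len(merged) <= min(len(a), len(b))

    def test_conservative_pvalue_and_support_concat(self):
        a = InteractionSet("AEC", [make_interaction("G1", "chr1", 0, 500, support=(5,), pvalue=1e-4)])
        b = InteractionSet("AEC", [make_interaction("G1", "chr1", 0, 500, support=(9,), pvalue=1e-2)])
        (m,) = replicate_consistent(a, b)
        assert m.support == (5, 9)
        assert m.pvalue == 1e-2

    def test_cell_type_mismatch(self, raw_set):
        other = InteractionSet("ASMC", list(raw_set))
        with pytest.raises(ValueError):
            replicate_consistent(raw_set, other)


def test_classification_examples(raw_set, toy_promoters, toy_variants):
    c = classify_interactions(raw_set, toy_promoters, toy_variants)
    by_key = {it.anchor_id: it.iclass for it in c}
    assert by_key["G1"] in ("PP", "PD")  # G1 appears twice; check per key below
    classes = {it.key: it.iclass for it in c}
    assert classes[("G1", "chr1", 20_000, 20_400)] == "PP"
    assert classes[("G1", "chr1", 100_000, 100_700)] == "PD"
    assert classes[("rs1", "chr1", 29_600, 30_400)] == "GP"
    assert classes[("rs2", "chr1", 180_000, 180_500)] == "unset"
    counts = class_counts(c)
    assert sum(counts.values()) == len(raw_set)  # exhaustive partition


def test_network_components_and_composition(raw_set, toy_promoters, toy_variants):
    c = classify_interactions(raw_set, toy_promoters, toy_variants)
    net = build_network([c], toy_promoters)
    # G1-probe(G2) PP edge; G1-D PD; G2-D PD; rs1-probe(G3) GP; rs2-D unset
    comp_sizes = sorted(len(cc) for cc in net.components)
    assert sum(comp_sizes) == net.graph.number_of_nodes()
    assert net.composition["n_nodes"].sum() == net.graph.number_of_nodes()
    giant = net.giant_component
    assert {"P:G1", "P:G2"} <= giant  # PP edge joins both promoters


def test_network_forest_component_count():
    # edges {P1-D1, P2-D1, P3-D2}: components {P1,P2,D1}, {P3,D2}
    promoters = pd.DataFrame(
        {"gene_id": ["P1", "P2", "P3"], "chrom": ["chr1"] * 3,
         "start": [0, 10_000, 20_000], "end": [1_000, 11_000, 21_000]}
    )
    items = [
        make_interaction("P1", "chr1", 50_000, 50_500, iclass="PD"),
        make_interaction("P2", "chr1", 50_000, 50_500, iclass="PD"),
        make_interaction("P3", "chr1", 80_000, 80_500, iclass="PD"),
    ]
    net = build_network([InteractionSet("CT", items)], promoters)
    sizes = sorted(len(c) for c in net.components)
    assert sizes == [2, 3]
    # forest: components = nodes - edges
    assert len(net.components) == net.graph.number_of_nodes() - net.graph.number_of_edges()


def test_network_matches_union_find_oracle():
    rng = np.random.default_rng(23)
    for _ in range(20):
        promoters = pd.DataFrame(
            {"gene_id": [f"P{i}" for i in range(5)], "chrom": ["chr1"] * 5,
             "start": np.arange(5) * 10_000, "end": np.arange(5) * 10_000 + 1_000}
        )
        items = {}
        for _ in range(int(rng.integers(2, 12))):
            p = f"P{int(rng.integers(0, 5))}"
            s = int(rng.integers(0, 8)) * 5_000 + 100_000
            items[(p, s)] = make_interaction(p, "chr1", s, s + 500, iclass="PD")
        net = build_network([InteractionSet("CT", items.values())], promoters)

        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            parent[find(a)] = find(b)

        for (p, s) in items:
            union(("P", p), ("D", s))
        roots = {}
        for node in list(parent):
            roots.setdefault(find(node), set()).add(node)
        assert sorted(len(c) for c in roots.values()) == sorted(
            len(c) for c in net.components
        )


def test_profile_matrix_hand_example():
    promoters = pd.DataFrame(
        {"gene_id": ["P1", "P2"], "chrom": ["chr1", "chr1"],
         "start": [0, 10_000], "end": [1_000, 11_000]}
    )
    set_a = InteractionSet("A", [make_interaction("P1", "chr1", 7_000, 8_000, iclass="PD")])
    set_b = InteractionSet(
        "B",
        [
            make_interaction("P1", "chr1", 12_000, 13_000, iclass="PD"),
            make_interaction("P2", "chr1", 1_000, 2_000, iclass="PD"),
        ],
    )
    m = profile_matrix({"A": set_a, "B": set_b}, bin_size=5_000, chrom_sizes={"chr1": 20_000})
    assert m.shape == (4, 4)
    assert m.loc[("A", "P1")].tolist() == [0, 1, 0, 0]  # midpoint 7500 -> bin 1
    assert m.loc[("B", "P1")].tolist() == [0, 0, 1, 0]  # midpoint 12500 -> bin 2
    assert m.loc[("B", "P2")].tolist() == [1, 0, 0, 0]
    assert m.loc[("A", "P2")].sum() == 0


def test_profile_matrix_validations():
    with pytest.raises(ValueError):
        profile_matrix({"A": InteractionSet("A")}, 5_000, {"chr1": 10_000})
    with pytest.raises(ValueError):
        profile_matrix({"A": InteractionSet("A"), "B": InteractionSet("B")}, 0, {"chr1": 10_000})
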