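import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loopmap import (
    GeneAnnotation,
    InteractionSet,
    assign_targets,
    coexpr_chi2,
    coexpr_chi2_contingency,
    coexpression_test,
    compute_r2,
    expand_ld,
    sharing_pairs,
)

from conftest import make_gene, make_interaction


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((50, 0, 0, 50), 1.0),
        ((25, 25, 25, 25), 0.0),
        ((40, 10, 10, 40), 0.36),  # D=0.15, denominator 0.0625
    ],
)
def test_compute_r2_hand_values(counts, expected):
    assert compute_r2(*counts) == pytest.approx(expected)


def test_compute_r2_errors():
    with pytest.raises(ValueError):
        compute_r2(0, 0, 0, 0)
    with pytest.raises(ValueError):
        compute_r2(50, 50, 0, 0)  # locus B monomorphic


class TestExpandLD:
    def _table(self):
        return pd.DataFrame(
            {
                "lead_rsid": ["L1", "L1", "L1", "L2"],
                "proxy_rsid": ["p1", "p2", "p3", "p4"],
                "r2": [0.9, 0.79, 0.85, 0.95],
                "distance": [10_000, 5_000, 80_001, 20_000],
            }
        )

    def test_threshold_and_cap_inclusive(self):
        out = expand_ld(["L1"], self._table(), r2_min=0.8, distance_cap=80_000)
        got = set(out["proxy_rsid"])
        assert got == {"L1", "p1"}  # p2 below threshold, p3 beyond cap
        out2 = expand_ld(["L1"], self._table(), r2_min=0.8, distance_cap=80_001)
        assert "p3" in set(out2["proxy_rsid"])  # cap is inclusive

    def test_lead_included_as_self_proxy(self):
        out = expand_ld(["L2"], self._table(), r2_min=0.8)
        self_row = out[out["proxy_rsid"] == "L2"].iloc[0]
        assert self_row["distance"] == 0 and self_row["r2"] == 1.0

    def test_missing_lead_warns_and_returns_self(self):
        with pytest.warns(UserWarning):
            out = expand_ld(["L9"], self._table())
        assert out["proxy_rsid"].tolist() == ["L9"]

    def test_monotone_in_threshold_and_cap(self):
        t = self._table()
        loose = set(map(tuple, expand_ld(["L1", "L2"], t, 0.7, 100_000)[["lead_rsid", "proxy_rsid"]].values))
        tight = set(map(tuple, expand_ld(["L1", "L2"], t, 0.9, 15_000)[["lead_rsid", "proxy_rsid"]].values))
        assert tight <= loose


def _toy_assignment_problem():
    genes = GeneAnnotation(
        [make_gene("GA", "chr1", 100_000), make_gene("GB", "chr1", 200_000),
         make_gene("GC", "chr1", 300_000)]
    )
    promoters = pd.DataFrame(
        {"gene_id": ["GA", "GB", "GC"], "chrom": ["chr1"] * 3,
         "start": [99_500, 199_500, 299_500], "end": [100_500, 200_500, 300_500]}
    )
    snp_pos = pd.DataFrame(
        {
            "rsid": ["L1", "L2", "L3", "p1", "p2"],
            "chrom": ["chr1"] * 5,
            "pos": [150_000, 250_200, 400_000, 155_200, 260_000],
        }
    )
    ld = pd.DataFrame(
        {
            "lead_rsid": ["L1", "L2"],
            "proxy_rsid": ["p1", "p2"],
            "r2": [0.9, 0.85],
            "distance": [5_200, 9_800],
        }
    )
    gp = InteractionSet(
        "CT",
        [make_interaction("L3", "chr1", 299_500, 300_500, anchor_type="variant", iclass="GP")],
    )
    pdset = InteractionSet(
        "CT",
        [
            # contains L1 (150,000) and p1 (155,200)
            make_interaction("GA", "chr1", 149_800, 155_400, iclass="PD"),
            # contains p2 (260,000) only
            make_interaction("GB", "chr1", 259_900, 260_400, iclass="PD"),
            make_interaction("GC", "chr1", 500_000, 500_700, iclass="PD"),
        ],
    )
    return genes, promoters, snp_pos, ld, gp, pdset


def test_assign_targets_evidence_classes():
    genes, promoters, snp_pos, ld, gp, pdset = _toy_assignment_problem()
    proxies = expand_ld(["L1", "L2", "L3"], ld, 0.8, 80_000, warn_missing=False)
    table, summary = assign_targets(gp, pdset, proxies, snp_pos, genes, promoters)
    ev = set(map(tuple, table[["rsid", "gene_id", "evidence"]].values))
    assert ("L3", "GC", "GP_direct") in ev
    assert ("L1", "GA", "PD_contained") in ev
    assert ("L1", "GA", "PD_LD") in ev  # p1 also inside the GA fragment
    assert ("L2", "GB", "PD_LD") in ev
    assert summary["n_variants"] == 3
    ld_row = table[(table["evidence"] == "PD_LD") & (table["rsid"] == "L2")].iloc[0]
    assert ld_row["proxy_rsid"] == "p2"


def test_assign_targets_matches_bruteforce_oracle():
    rng = np.random.default_rng(31)
    for _ in range(30):
        n_genes = 4
        tss = np.sort(rng.choice(np.arange(20, 200), size=n_genes, replace=False) * 1_000)
        genes = GeneAnnotation([make_gene(f"G{i}", "chr1", int(t)) for i, t in enumerate(tss)])
        promoters = pd.DataFrame(
            {"gene_id": [f"G{i}" for i in range(n_genes)], "chrom": "chr1",
             "start": tss - 500, "end": tss + 500}
        )
        snp_ids = [f"L{i}" for i in range(3)] + [f"p{i}" for i in range(2)]
        snp_pos = pd.DataFrame(
            {"rsid": snp_ids, "chrom": "chr1",
             "pos": rng.integers(10_000, 210_000, size=5)}
        )
        ld = pd.DataFrame(
            {"lead_rsid": ["L0", "L1"], "proxy_rsid": ["p0", "p1"],
             "r2": [0.9, 0.9], "distance": [1, 1]}
        )
        frags = []
        for _ in range(6):
            s = int(rng.integers(5_000, 215_000))
            frags.append((s, s + int(rng.integers(500, 6_000))))
        pdset = InteractionSet(
            "CT",
            {make_interaction(f"G{int(rng.integers(0, n_genes))}", "chr1", s, e, iclass="PD")
             for s, e in frags},
        )
        proxies = expand_ld(["L0", "L1", "L2"], ld, 0.8, None, warn_missing=False)
        table, _ = assign_targets(None, pdset, proxies, snp_pos, genes, promoters)
        got = set(map(tuple, table[["rsid", "gene_id", "evidence"]].values))
        # oracle: exhaustive scan over (variant, fragment)
        exp = set()
        pos_of = dict(zip(snp_pos["rsid"], snp_pos["pos"]))
        lead_of_proxy = {"p0": "L0", "p1": "L1"}
        for it in pdset:
            for v in ["L0", "L1", "L2"]:
                if it.distal.start <= pos_of[v] < it.distal.end:
                    exp.add((v, it.anchor_id, "PD_contained"))
            for p, lead in lead_of_proxy.items():
                if it.distal.start <= pos_of[p] < it.distal.end:
                    exp.add((lead, it.anchor_id, "PD_LD"))
        assert got == exp


class TestSharingPairs:
    def _assignments(self, rows):
        return pd.DataFrame(
            rows, columns=["rsid", "gene_id", "evidence", "proxy_rsid", "element",
                           "interaction_distance", "jump_index"]
        )

    def test_three_genes_three_pairs(self):
        a = self._assignments(
            [("r", g, "GP_direct", None, "variant:r", 1_000, 0) for g in "ABC"]
        )
        pairs, hubs = sharing_pairs(a)
        assert set(map(tuple, pairs[["gene_a", "gene_b"]].values)) == {
            ("A", "B"), ("A", "C"), ("B", "C"),
        }

    def test_single_gene_no_pairs(self):
        a = self._assignments([("r", "A", "GP_direct", None, "variant:r", 1_000, 0)])
        pairs, _ = sharing_pairs(a)
        assert len(pairs) == 0

    def test_hub_exclusion(self):
        rows = [("hub", f"G{i}", "GP_direct", None, "variant:hub", 1_000, 0)
                for i in range(10)]
        pairs_all, hubs0 = sharing_pairs(self._assignments(rows))
        assert len(pairs_all) == 45 and len(hubs0) == 0
        pairs, hubs = sharing_pairs(self._assignments(rows), hub_max=8)
        assert len(pairs) == 0
        assert hubs.iloc[0]["n_genes"] == 10

    def test_cross_element_deduplication(self):
        rows = [
            ("r1", "A", "GP_direct", None, "variant:r1", 1_000, 0),
            ("r1", "B", "GP_direct", None, "variant:r1", 1_000, 0),
            ("r2", "A", "PD_contained", None, "fragment:chr1:5:9", 1_000, 0),
            ("r2", "B", "PD_contained", None, "fragment:chr1:5:9", 1_000, 0),
        ]
        pairs, _ = sharing_pairs(self._assignments(rows))
        assert len(pairs) == 1
        assert pairs.iloc[0]["n_elements"] == 2


class TestCoexpression:
    def _expr(self, rng, n_genes=20, n_samples=50):
        return pd.DataFrame(
            rng.standard_normal((n_genes, n_samples)),
            index=[f"G{i}" for i in range(n_genes)],
        )

    def test_self_pair_perfect_correlation(self):
        rng = np.random.default_rng(0)
        expr = self._expr(rng)
        pairs = pd.DataFrame({"gene_a": ["G0"], "gene_b": ["G0"]})
        tested, fr, _ = coexpression_test(pairs, expr)
        assert tested.iloc[0]["corr_r"] == pytest.approx(1.0)
        assert tested.iloc[0]["corr_p"] < 1e-30

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        expr = self._expr(rng, n_genes=400, n_samples=40)
        pairs = pd.DataFrame(
            {"gene_a": [f"G{2 * i}" for i in range(200)],
             "gene_b": [f"G{2 * i + 1}" for i in range(200)]}
        )
        tested, fr, _ = coexpression_test(pairs, expr, thresholds=(0.05,))
        # 200 independent pairs at level 0.05: expect ~10 +- binomial CI
        assert 0.01 <= fr[0.05] <= 0.10

    def test_planted_correlation_power(self):
        rng = np.random.default_rng(2)
        n = 131
        f = rng.standard_normal((100, n))
        a = np.sqrt(0.6) * f + np.sqrt(0.4) * rng.standard_normal((100, n))
        b = np.sqrt(0.6) * f + np.sqrt(0.4) * rng.standard_normal((100, n))
        expr = pd.DataFrame(
            np.vstack([a, b]),
            index=[f"A{i}" for i in range(100)] + [f"B{i}" for i in range(100)],
        )
        pairs = pd.DataFrame({"gene_a": [f"A{i}" for i in range(100)],
                              "gene_b": [f"B{i}" for i in range(100)]})
        tested, fr, _ = coexpression_test(pairs, expr, thresholds=(1e-3,))
        assert fr[1e-3] >= 0.9

    def test_missing_genes_excluded_from_denominator(self):
        rng = np.random.default_rng(3)
        expr = self._expr(rng)
        pairs = pd.DataFrame({"gene_a": ["G0", "GHOST"], "gene_b": ["G1", "G2"]})
        tested, fr, missing = coexpression_test(pairs, expr, thresholds=(0.5,))
        assert len(tested) == 1 and len(missing) == 1

    def test_too_few_samples(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["G0"])
        with pytest.raises(ValueError):
            coexpression_test(pd.DataFrame({"gene_a": ["G0"], "gene_b": ["G0"]}), expr)


class TestChi2:
    def test_exact_background_gives_zero(self):
        res = coexpr_chi2(23, 100, 0.23)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_derived_enrichment_case(self):
        # (34 of 75 vs 23%): chi2 = 16.75^2/17.25 + 16.75^2/57.75 = 21.12
        res = coexpr_chi2(34, 75, 0.23)
        assert res.statistic == pytest.approx(21.12, abs=0.02)
        assert res.pvalue == pytest.approx(4.3e-6, rel=0.05)

    def test_symmetric_depletion_case(self):
        res = coexpr_chi2(0, 10, 0.5)
        assert res.statistic == pytest.approx(10.0)
        assert res.pvalue == pytest.approx(stats.chi2.sf(10, 1))

    def test_small_expected_flag_and_validation(self):
        assert coexpr_chi2(0, 3, 0.1).expected_warning
        with pytest.raises(ValueError):
            coexpr_chi2(5, 3, 0.2)
        with pytest.raises(ValueError):
            coexpr_chi2(1, 3, 0.0)

    def test_contingency_variant_agrees_in_direction(self):
        res = coexpr_chi2_contingency(34, 75, 23, 100)
        assert res.pvalue < 0.01
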