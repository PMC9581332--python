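import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from clonetrace.datamodel import CountMatrix, MetadataTable, ValueKind
from clonetrace.fate import (
    BiasTable,
    bias_table,
    category_summary,
    classify_lineage_bias,
    correlogram_matrix,
    heatmap_matrix,
    pairwise_abundance,
    sharing_breakdown,
    ternary_abundance,
)


def _bias_from_reads(reads: dict[str, list[float]], lineages: list[str]) -> BiasTable:
    """BiasTable built by direct division (column normalization skipped:
    all examples here assume equal sample depths)."""
    R = pd.DataFrame(reads, index=lineages).T
    R = R.loc[R.sum(axis=1) > 0]
    P = R.div(R.sum(axis=1), axis=0)
    bt = BiasTable(lineages=lineages)
    bt.R["ind1"] = R
    bt.P["ind1"] = P
    return bt


def _cm_md_levels(columns: dict[str, list[float]], variables: list[str]):
    df = pd.DataFrame(columns, index=[f"bc{i}" for i in
                                      range(len(next(iter(columns.values()))))])
    cm = CountMatrix(df.astype(float))
    md = MetadataTable.from_sample_names(list(df.columns), variables)
    return cm, md


class TestPairwiseAbundance:
    def test_axis_placement(self):
        cm, md = _cm_md_levels({"m1_cDC1": [5, 0, 2], "m1_cDC2": [0, 3, 2]},
                               ["individual", "cell_type"])
        table = pairwise_abundance(cm, md, "cell_type", "cDC1", "cDC2")
        assert len(table) == 3
        byb = table.set_index("barcode")
        assert byb.loc["bc0", "y"] == 0 and byb.loc["bc0", "x"] > 0
        assert byb.loc["bc1", "x"] == 0 and byb.loc["bc1", "y"] > 0
        assert (byb.loc["bc2", ["x", "y"]] > 0).all()

    def test_arcsin_range(self):
        cm, md = _cm_md_levels({"m1_A": [5, 0], "m1_B": [0, 3]},
                               ["individual", "cell_type"])
        table = pairwise_abundance(cm, md, "cell_type", "A", "B", transform="arcsin")
        assert ((0 <= table[["x", "y"]]) & (table[["x", "y"]] <= np.pi / 2)).all().all()

    def test_doubly_zero_excluded(self):
        cm, md = _cm_md_levels({"m1_A": [5, 0], "m1_B": [3, 0]},
                               ["individual", "cell_type"])
        table = pairwise_abundance(cm, md, "cell_type", "A", "B")
        assert table["barcode"].tolist() == ["bc0"]

    def test_unknown_level_rejected(self):
        cm, md = _cm_md_levels({"m1_A": [1.0]}, ["individual", "cell_type"])
        with pytest.raises(ValueError, match="unknown level"):
            pairwise_abundance(cm, md, "cell_type", "A", "Z")


class TestSharingBreakdown:
    def test_enumerated_thirds(self):
        table = pd.DataFrame({"barcode": list("abc"),
                              "x": [5.0, 0.0, 2.0], "y": [0.0, 3.0, 2.0]})
        b = sharing_breakdown(table, "pooled")
        for v in b.categories.values():
            assert v == pytest.approx(100 / 3)

    def test_all_shared(self):
        table = pd.DataFrame({"barcode": ["a"], "x": [1.0], "y": [1.0]})
        assert sharing_breakdown(table).categories["shared"] == pytest.approx(100.0)

    def test_per_individual_mean_and_sd(self):
        # ind1: 2 shared of 2 (100%); ind2: 0 shared of 2 (0%) -> mean 50, sd ~70.7
        table = pd.DataFrame({
            "barcode": ["a", "b", "c", "d"],
            "x": [1.0, 1.0, 1.0, 0.0],
            "y": [1.0, 1.0, 0.0, 1.0],
            "individual": ["i1", "i1", "i2", "i2"],
        })
        b = sharing_breakdown(table, "per_individual_mean")
        assert b.categories["shared"] == pytest.approx(50.0)
        assert b.sd["shared"] == pytest.approx(np.std([100.0, 0.0], ddof=1))

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({"barcode": [f"b{i}" for i in range(50)],
                              "x": rng.integers(0, 3, 50).astype(float),
                              "y": rng.integers(0, 3, 50).astype(float)})
        table = table[(table.x > 0) | (table.y > 0)]
        b = sharing_breakdown(table)
        assert sum(b.categories.values()) == pytest.approx(100.0, abs=1e-9)


class TestTernary:
    def test_center_and_vertex(self):
        # equal column depths so column normalization is a common rescale
        cm, md = _cm_md_levels({"m1_A": [10, 5, 0], "m1_B": [10, 0, 5], "m1_C": [10, 0, 5]},
                               ["individual", "cell_type"])
        t = ternary_abundance(cm, md, "cell_type", ("A", "B", "C"))
        row0 = t.set_index("barcode").loc["bc0"]
        np.testing.assert_allclose(row0[["p_A", "p_B", "p_C"]].astype(float),
                                   [1 / 3, 1 / 3, 1 / 3])
        row1 = t.set_index("barcode").loc["bc1"]
        np.testing.assert_allclose(row1[["p_A", "p_B", "p_C"]].astype(float), [1, 0, 0])

    def test_coordinates_sum_to_one(self):
        rng = np.random.default_rng(8)
        cm, md = _cm_md_levels({f"m1_{lv}": rng.integers(0, 9, 12).astype(float)
                                for lv in "ABC"}, ["individual", "cell_type"])
        t = ternary_abundance(cm, md, "cell_type", ("A", "B", "C"))
        np.testing.assert_allclose(
            t[["p_A", "p_B", "p_C"]].sum(axis=1).to_numpy(), 1.0, atol=1e-12)

    def test_requires_three_levels(self):
        cm, md = _cm_md_levels({"m1_A": [1.0]}, ["individual", "cell_type"])
        with pytest.raises(ValueError, match="three"):
            ternary_abundance(cm, md, "cell_type", ("A", "B"))


class TestClassifier:
    def test_unbalanced_clone_bi_at_zero_cdc2_at_020(self):
        """A clone with reads (20, 5000): bi-outcome at t=0 (both lineages
        present) but cDC2-only at t=0.20 since P_cDC1 = 20/5020 < 0.20."""
        bt = _bias_from_reads({"bc": [20.0, 5000.0]}, ["cDC1", "cDC2"])
        at0 = classify_lineage_bias(bt, 0.0)[0]
        assert at0.category == frozenset({"cDC1", "cDC2"})
        at20 = classify_lineage_bias(bt, 0.20)[0]
        assert at20.category == frozenset({"cDC2"})

    def test_absent_lineage_never_assigned(self):
        bt = _bias_from_reads({"bc": [0.0, 100.0]}, ["cDC1", "cDC2"])
        for t in (0.0, 0.3, 0.99):
            assert classify_lineage_bias(bt, t)[0].category == frozenset({"cDC2"})

    def test_threshold_domain(self):
        bt = _bias_from_reads({"bc": [1.0, 1.0]}, ["A", "B"])
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError, match="threshold"):
                classify_lineage_bias(bt, bad)

    def test_monotone_shrinking_categories(self):
        rng = np.random.default_rng(12)
        reads = {f"b{i}": rng.integers(0, 200, 3).astype(float).tolist()
                 for i in range(30)}
        reads = {k: v for k, v in reads.items() if sum(v) > 0}
        bt = _bias_from_reads(reads, ["A", "B", "C"])
        prev = None
        for t in (0.0, 0.1, 0.25, 0.4, 0.6):
            cats = {a.barcode_id: a.category for a in classify_lineage_bias(bt, t)}
            if prev is not None:
                for bc, cat in cats.items():
                    assert cat <= prev[bc]
            prev = cats

    def test_above_half_threshold_single_lineage(self):
        rng = np.random.default_rng(13)
        reads = {f"b{i}": (rng.random(4) * 100).tolist() for i in range(20)}
        bt = _bias_from_reads(reads, ["A", "B", "C", "D"])
        for a in classify_lineage_bias(bt, 0.51):
            assert len(a.category) <= 1

    def test_t_zero_equals_presence_absence(self):
        rng = np.random.default_rng(14)
        reads = {f"b{i}": rng.integers(0, 3, 2).astype(float).tolist() for i in range(30)}
        reads = {k: v for k, v in reads.items() if sum(v) > 0}
        bt = _bias_from_reads(reads, ["A", "B"])
        for a in classify_lineage_bias(bt, 0.0):
            present = {lv for lv, r in zip(["A", "B"], reads[a.barcode_id]) if r > 0}
            assert a.category == frozenset(present)


class TestBiasTableAndSummary:
    def test_counts_per_category(self):
        bt = _bias_from_reads({"A_only": [10, 0], "B_only": [0, 10], "both": [5, 5]},
                              ["L1", "L2"])
        asg = classify_lineage_bias(bt, 0.0)
        summary = category_summary(asg, bt).set_index("category")
        assert summary.loc["L1", "n_barcodes"] == 1
        assert summary.loc["L2", "n_barcodes"] == 1
        assert summary.loc["L1+L2", "n_barcodes"] == 1

    def test_contributions_partition_each_lineage(self):
        rng = np.random.default_rng(15)
        reads = {f"b{i}": rng.integers(0, 50, 2).astype(float).tolist() for i in range(25)}
        reads = {k: v for k, v in reads.items() if sum(v) > 0}
        bt = _bias_from_reads(reads, ["L1", "L2"])
        summary = category_summary(classify_lineage_bias(bt, 0.2), bt)
        for lv in ("L1", "L2"):
            assert summary[lv].sum() == pytest.approx(100.0, abs=1e-9)

    def test_two_identical_individuals_average_to_each(self):
        bt1 = _bias_from_reads({"a": [10, 0], "b": [3, 7]}, ["L1", "L2"])
        bt = BiasTable(lineages=["L1", "L2"])
        bt.R = {"i1": bt1.R["ind1"], "i2": bt1.R["ind1"].copy()}
        bt.P = {"i1": bt1.P["ind1"], "i2": bt1.P["ind1"].copy()}
        asg = classify_lineage_bias(bt, 0.0)
        summary = category_summary(asg, bt).set_index("category")
        single = category_summary(classify_lineage_bias(bt1, 0.0), bt1).set_index("category")
        np.testing.assert_allclose(summary[["L1", "L2"]].to_numpy(),
                                   single[["L1", "L2"]].to_numpy(), atol=1e-12)
        assert (summary["n_barcodes"] == 2 * single["n_barcodes"]).all()

    def test_bias_table_depth_correction(self):
        # the cDC1 sample is sequenced 10x deeper; column normalization must
        # cancel that before row proportions are formed
        cm, md = _cm_md_levels({"m1_cDC1": [1000.0, 9000.0], "m1_cDC2": [100.0, 900.0]},
                               ["individual", "cell_type"])
        bt = bias_table(cm, md, lineage_var="cell_type")
        P = bt.P["m1"]
        np.testing.assert_allclose(P.to_numpy(), [[0.5, 0.5], [0.5, 0.5]], atol=1e-12)


def brute_force_complete_linkage(points: np.ndarray):
    """Naive O(n^3) agglomerative complete linkage; returns the cophenetic
    distance matrix. Independent of scipy's nearest-neighbor chain."""
    n = len(points)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return coph


class TestHeatmap:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 0.0]],
                          index=["a", "b", "c"], columns=["s1", "s2"])
        res = heatmap_matrix(CountMatrix(df), transform="none")
        assert res.row_linkage[0, 2] == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = rng.integers(3, 7)
            pts = rng.random((n, 3))
            df = pd.DataFrame(pts, index=[f"b{i}" for i in range(n)],
                              columns=["s1", "s2", "s3"])
            res = heatmap_matrix(CountMatrix(df, ValueKind.TRANSFORMED),
                                 transform="none", distance="euclidean",
                                 linkage="complete")
            got = squareform(cophenet(res.row_linkage))
            expected = brute_force_complete_linkage(res.matrix.to_numpy())
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_transform_invariant_for_proportion_identical_rows(self):
        df = pd.DataFrame([[2.0, 6.0], [2.0, 6.0], [9.0, 1.0]],
                          index=["a", "b", "c"], columns=["s1", "s2"])
        res = heatmap_matrix(CountMatrix(df), transform="arcsin")
        # rows a and b have identical counts, hence identical proportions
        # and identical arcsin values -> first merge at 0
        assert res.row_linkage[0, 2] == pytest.approx(0.0)
        assert set(res.row_linkage[0, :2].astype(int)) == {0, 1}

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="at least 2"):
            heatmap_matrix(CountMatrix(df), transform="none")

    def test_input_order_invariance(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(rng.random((6, 3)), index=[f"b{i}" for i in range(6)],
                          columns=["s1", "s2", "s3"])
        res1 = heatmap_matrix(CountMatrix(df, ValueKind.TRANSFORMED), transform="none")
        shuffled = df.sample(frac=1.0, random_state=1)
        res2 = heatmap_matrix(CountMatrix(shuffled, ValueKind.TRANSFORMED), transform="none")
        assert res1.row_order == res2.row_order


class TestCorrelogram:
    def test_identical_levels_correlate_one(self):
        cm, md = _cm_md_levels({"m1_A": [5, 1, 3], "m1_B": [5, 1, 3]},
                               ["individual", "cell_type"])
        mat = correlogram_matrix(cm, md, "cell_type")
        assert mat.loc["A", "B"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(31)
        cm, md = _cm_md_levels({f"m1_{lv}": rng.integers(0, 20, 10).astype(float)
                                for lv in "ABC"}, ["individual", "cell_type"])
        mat = correlogram_matrix(cm, md, "cell_type")
        np.testing.assert_allclose(np.diag(mat), 1.0)
        pd.testing.assert_frame_equal(mat, mat.T, check_names=False)

    def test_matches_per_pair_recomputation(self):
        from scipy import stats
        rng = np.random.default_rng(32)
        raw = {f"m1_{lv}": rng.integers(0, 30, 5).astype(float) for lv in "ABC"}
        cm, md = _cm_md_levels(raw, ["individual", "cell_type"])
        mat = correlogram_matrix(cm, md, "cell_type")
        norm = {lv: raw[f"m1_{lv}"] / raw[f"m1_{lv}"].sum() for lv in "ABC"}
        for a, b in itertools.combinations("ABC", 2):
            x, y = norm[a], norm[b]
            keep = (x > 0) | (y > 0)
            expected = stats.spearmanr(x[keep], y[keep]).statistic
            assert mat.loc[a, b] == pytest.approx(expected, abs=1e-12)


@settings(max_examples=40, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 100), st.integers(0, 100), st.integers(0, 100)),
                min_size=1, max_size=15).filter(lambda rs: all(sum(r) > 0 for r in rs)),
       st.floats(min_value=0.0, max_value=0.99))
def test_classifier_category_members_meet_threshold(rows, t):
    """Every assigned lineage satisfies P >= t and P > 0."""
    reads = {f"b{i}": [float(v) for v in r] for i, r in enumerate(rows)}
    bt = _bias_from_reads(reads, ["A", "B", "C"])
    for a in classify_lineage_bias(bt, t):
        P = bt.P["ind1"].loc[a.barcode_id]
        for lv in a.category:
            assert P[lv] >= t and P[lv] > 0
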