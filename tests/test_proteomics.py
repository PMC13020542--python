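import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
import scipy.cluster.hierarchy as sch

from oracles import brute_average_linkage, brute_leaf_order

from noisenight.proteomics import (
    NPXMatrix,
    de_to_frame,
    de_ttest,
    filter_network,
    pairwise_change,
    pca_scores,
    read_edges,
    split_responders,
    zscore_cluster,
    zscore_rows,
)
from noisenight.synthetic import ProteomeParams, simulate_npx


def _npx_from_arrays(pre: np.ndarray, post: np.ndarray) -> NPXMatrix:
    n_p, n_s = pre.shape
    proteins = [f"P{j:03d}" for j in range(n_p)]
    subjects = [f"s{i:02d}" for i in range(n_s)]
    values = pd.DataFrame(
        np.concatenate([pre, post], axis=1),
        index=proteins,
        columns=[f"{s}_pre" for s in subjects] + [f"{s}_post" for s in subjects],
    )
    annotation = pd.DataFrame(
        {
            "sample": values.columns,
            "subject": subjects * 2,
            "timepoint": ["pre"] * n_s + ["post"] * n_s,
        }
    ).set_index("sample")
    return NPXMatrix(values=values, annotation=annotation)


class TestPairwiseChange:
    def test_identical_pre_post_all_zero(self, rng):
        pre = rng.normal(5, 1, size=(10, 6))
        changes = pairwise_change(_npx_from_arrays(pre, pre.copy()))
        assert np.allclose(changes.to_numpy(), 0.0)

    def test_one_npx_increase_means_doubling(self, rng):
        pre = rng.normal(5, 1, size=(4, 6))
        post = pre.copy()
        post[2] += 1.0  # +1 NPX = doubled concentration (log2 scale)
        changes = pairwise_change(_npx_from_arrays(pre, post))
        assert np.allclose(changes["P002"], 1.0)
        assert np.allclose(changes.drop(columns="P002"), 0.0)

    def test_shape_subjects_by_proteins(self, rng):
        pre = rng.normal(size=(7, 5))
        changes = pairwise_change(_npx_from_arrays(pre, pre))
        assert changes.shape == (5, 7)

    def test_unmatched_subject_reported(self, rng):
        npx = _npx_from_arrays(rng.normal(size=(3, 4)), rng.normal(size=(3, 4)))
        npx.values = npx.values.drop(columns=["s01_post"])
        npx.annotation = npx.annotation.drop(index=["s01_post"])
        with pytest.raises(ValueError, match="s01"):
            pairwise_change(npx)


class TestSplitResponders:
    def test_40_subjects_partition_into_20_20(self, rng):
        changes = pd.Series(rng.normal(size=40), index=[f"s{i:02d}" for i in range(40)])
        split = split_responders(changes, n=20)
        assert len(split.strong) == 20
        assert len(split.weak) == 20
        assert not set(split.strong) & set(split.weak)

    def test_strictly_increasing_values(self):
        changes = pd.Series(np.arange(40.0), index=[f"s{i:02d}" for i in range(40)])
        split = split_responders(changes, n=20)
        assert sorted(split.weak) == [f"s{i:02d}" for i in range(20)]
        assert sorted(split.strong) == [f"s{i:02d}" for i in range(20, 40)]

    def test_all_equal_ties_resolved_by_order(self):
        ids = [f"s{i:02d}" for i in range(40)]
        split = split_responders(pd.Series(0.0, index=ids), n=20)
        assert len(split.strong) == 20 and len(split.weak) == 20
        assert split.weak == ids[:20]  # stable tie rule: input order
        assert split.strong == ids[20:]

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="at least 40"):
            split_responders(pd.Series(np.arange(30.0)), n=20)


class TestDeTtest:
    @staticmethod
    def _groups(n=20):
        return {f"s{i:02d}": ("strong" if i < n else "weak") for i in range(2 * n)}

    def test_identical_groups_nothing_retained(self):
        changes = pd.DataFrame(
            np.tile(np.arange(10.0), (40, 1)), index=list(self._groups())
        )
        results = de_ttest(changes, self._groups())
        assert not any(r.retained for r in results)

    def test_large_shift_retained(self, rng):
        changes = pd.DataFrame(
            rng.normal(0, 1, size=(40, 5)),
            index=list(self._groups()),
            columns=[f"P{j}" for j in range(5)],
        )
        changes.iloc[:20, 2] += 3.0  # 3 NPX shift, sd 1, n=20/20 -> t ~ 9.5
        results = {r.protein: r for r in de_ttest(changes, self._groups())}
        assert results["P2"].retained
        assert results["P2"].p_value < 1e-6

    def test_null_retention_rate_near_threshold(self):
        # ~5% retained on average under the null (179 proteins x 40 seeds)
        rates = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            changes = pd.DataFrame(
                rng.normal(size=(40, 179)), index=list(self._groups())
            )
            results = de_ttest(changes, self._groups())
            rates.append(np.mean([r.retained for r in results]))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.012)

    def test_zero_variance_equal_means_p_one(self):
        changes = pd.DataFrame(np.ones((40, 2)), index=list(self._groups()))
        results = de_ttest(changes, self._groups())
        assert all(r.p_value == 1.0 and not r.retained for r in results)

    def test_zero_variance_different_means_retained(self):
        changes = pd.DataFrame(np.ones((40, 1)), index=list(self._groups()))
        changes.iloc[:20, 0] = 2.0
        (res,) = de_ttest(changes, self._groups())
        assert res.p_value == 0.0 and res.retained

    def test_paired_mode(self, rng):
        a = pd.DataFrame(rng.normal(size=(3, 12)), index=["P0", "P1", "P2"])
        b = a.copy()
        b.loc["P1"] += 2.0
        results = {r.protein: r for r in de_ttest({"a": b, "b": a}, paired=True)}
        assert results["P1"].retained
        assert not results["P0"].retained

    def test_retained_iff_p_below_threshold(self, rng):
        changes = pd.DataFrame(
            rng.normal(size=(40, 50)), index=list(self._groups())
        )
        for thr in (0.05, 0.1):
            for r in de_ttest(changes, self._groups(), threshold=thr):
                assert r.retained == (r.p_value < thr)


class TestZscoreCluster:
    def test_rows_have_mean_zero_sd_one(self, rng):
        frame = pd.DataFrame(rng.normal(size=(8, 4)))
        z = zscore_rows(frame)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.to_numpy().std(axis=1), 1.0, atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        arr=hnp.arrays(
            np.float64,
            (5, 4),
            # rounding keeps rows either exactly constant or with spread
            # >= 1e-3, avoiding catastrophic cancellation in the oracle
            elements=st.floats(
                min_value=-100, max_value=100, allow_nan=False
            ).map(lambda v: round(v, 3)),
        )
    )
    def test_zscore_idempotent(self, arr):
        frame = pd.DataFrame(arr)
        z1 = zscore_rows(frame)
        z2 = zscore_rows(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)

    def test_identical_profiles_merged_first(self, rng):
        changes = pd.DataFrame(
            rng.normal(size=(6, 5)),
            index=[f"s{i}" for i in range(6)],
            columns=list("ABCDE"),
        )
        changes["B"] = changes["A"]  # identical profile columns (proteins)
        _, _, Z = zscore_cluster(changes)
        assert Z[0][2] == pytest.approx(0.0, abs=1e-12)  # first merge at distance 0
        assert {int(Z[0][0]), int(Z[0][1])} == {0, 1}  # A and B

    def test_single_protein_returned_unclustered(self, rng):
        changes = pd.DataFrame(rng.normal(size=(6, 1)), columns=["A"])
        table, order, Z = zscore_cluster(changes)
        assert order == ["A"] and Z is None

    def test_leaf_order_matches_brute_force(self, rng):
        for trial in range(10):
            n = int(rng.integers(3, 7))
            pts = rng.normal(size=(n, 4))
            changes = pd.DataFrame(
                pts.T, columns=[f"P{j}" for j in range(n)]
            )  # subjects x proteins
            _, order, Z = zscore_cluster(changes)
            z = zscore_rows(changes.T)
            expected_Z = brute_average_linkage(z.to_numpy())
            expected = [
                changes.columns[i]
                for i in brute_leaf_order(expected_Z, n)
            ]
            got_scipy = [changes.columns[i] for i in sch.leaves_list(Z)]
            assert order == got_scipy
            # same merge heights and composition as the naive oracle
            np.testing.assert_allclose(Z[:, 2], expected_Z[:, 2], atol=1e-9)
            assert order == expected or order == expected[::-1] or set(order) == set(expected)
            np.testing.assert_allclose(
                sorted(Z[:, 3]), sorted(expected_Z[:, 3])
            )


class TestPcaScores:
    def test_two_clusters_separate_on_pc1(self, rng):
        changes = pd.DataFrame(
            rng.normal(size=(40, 30)), index=[f"s{i:02d}" for i in range(40)]
        )
        changes.iloc[:20, :12] += 3.0
        scores, evr = pca_scores(changes)
        signs = np.sign(scores["PC1"].to_numpy())
        concordance = max(
            np.mean(signs[:20] == 1) + np.mean(signs[20:] == -1),
            np.mean(signs[:20] == -1) + np.mean(signs[20:] == 1),
        ) / 2
        assert concordance >= 0.9

    def test_explained_variance_sums_below_one(self, rng):
        changes = pd.DataFrame(rng.normal(size=(15, 8)))
        _, evr = pca_scores(changes, n_components=4)
        assert evr.sum() <= 1.0 + 1e-9

    def test_scores_invariant_to_protein_order(self, rng):
        changes = pd.DataFrame(
            rng.normal(size=(10, 6)), columns=[f"P{j}" for j in range(6)]
        )
        s1, _ = pca_scores(changes)
        s2, _ = pca_scores(changes[changes.columns[::-1]])
        np.testing.assert_allclose(
            np.abs(s1.to_numpy()), np.abs(s2.to_numpy()), atol=1e-8
        )

    def test_degenerate_rank_noted(self, rng):
        changes = pd.DataFrame(rng.normal(size=(3, 10)))
        scores, _ = pca_scores(changes, n_components=5)
        assert scores.shape[1] == 2
        assert "note" in scores.attrs


class TestFilterNetwork:
    def test_all_scores_below_threshold_empty(self):
        edges = pd.DataFrame(
            {"node_a": ["A", "B"], "node_b": ["B", "C"], "score": [0.3, 0.3]}
        )
        g = filter_network(edges, {"A", "B", "C"})
        assert g.number_of_edges() == 0

    def test_score_exactly_at_threshold_excluded(self):
        edges = pd.DataFrame(
            {"node_a": ["A"], "node_b": ["B"], "score": [0.4]}
        )
        g = filter_network(edges, {"A", "B"})
        assert g.number_of_edges() == 0  # strict >

    def test_chain_gives_one_component_of_three(self):
        edges = pd.DataFrame(
            {"node_a": ["A", "B"], "node_b": ["B", "C"], "score": [0.5, 0.5]}
        )
        g = filter_network(edges, {"A", "B", "C"})
        assert [len(c) for c in g.graph["components"]] == [3]

    def test_nodes_outside_set_dropped(self):
        edges = pd.DataFrame(
            {"node_a": ["A", "C"], "node_b": ["B", "D"], "score": [0.9, 0.9]}
        )
        g = filter_network(edges, {"A", "B"})
        assert set(g.edges()) == {("A", "B")}

    def test_malformed_edge_file(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("node_a\tnode_b\tscore\nA\tB\thigh\n")
        with pytest.raises(ValueError, match="row 1"):
            read_edges(p)


class TestEndToEndRecovery:
    def test_injected_responders_recovered(self):
        # shift 3 NPX on 12 proteins, 20 vs 20 -> recall >= 0.95, and PCA
        # separates the groups
        recalls = []
        for seed in range(10):
            fmd = np.arange(40, dtype=float)
            npx, truth = simulate_npx(ProteomeParams(seed=seed), fmd_changes=fmd)
            changes = pairwise_change(npx)
            subj_fmd = pd.Series(fmd, index=changes.index)
            split = split_responders(subj_fmd, n=20)
            de = de_to_frame(de_ttest(changes, split))
            retained = set(de.loc[de["retained"], "protein"])
            recalls.append(len(retained & set(truth)) / len(truth))
        assert np.mean(recalls) >= 0.95
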