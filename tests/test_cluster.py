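"""Hierarchical clustering, subset labelling and concordance statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import sigscore as sg
from sigscore.cluster import correlation_distance

from conftest import make_compendium


def naive_average_linkage(dist):
    """O(n^3) agglomeration oracle; returns the sequence of merged leaf-sets
    with merge heights."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for i in clusters:
            for j in clusters:
                if i >= j:
                    continue
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i] | clusters[j], d))
        new_label = max(clusters) + 1
        clusters[new_label] = clusters.pop(i) | clusters.pop(j)
    return merges


def subset_templates(n_genes=40, n_per=10, noise=0.0, seed=0):
    """Four orthogonal block templates, n_per arrays each."""
    rng = np.random.default_rng(seed)
    block = n_genes // 4
    arrays, labels = [], []
    for s in range(4):
        template = np.zeros(n_genes)
        template[s * block : (s + 1) * block] = 2.0
        for a in range(n_per):
            arrays.append(template + rng.normal(0, noise, n_genes))
            labels.append(f"subset{s}")
    values = np.column_stack(arrays)
    gm = sg.GeneMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"a{j}" for j in range(len(labels))],
        ),
        id_space="probe",
    )
    return gm, pd.Series(labels, index=gm.values.columns)


class TestClusterArrays:
    def test_noiseless_templates_recovered_perfectly(self):
        gm, truth = subset_templates(noise=0.05)
        assign = sg.cluster_arrays(gm, k=4, min_cluster_size=2)
        assert adjusted_rand_score(truth, assign.labels) == 1.0

    def test_simulated_subsets_recovered(self):
        aris = []
        for seed in range(3):
            comp, samples, truth = sg.simulate_compendium(sg.CompendiumSimSpec(seed=seed))
            adj, _ = sg.combat_fit_transform(comp, samples)
            planted = truth.program_of_gene.index[truth.program_of_gene != "background"]
            gm = sg.GeneMatrix(adj.values.loc[planted], id_space="probe")
            assign = sg.cluster_arrays(gm, k=4, min_cluster_size=2)
            ok = assign.labels != sg.UNASSIGNED
            aris.append(
                adjusted_rand_score(truth.subset_of_array[ok.index[ok]], assign.labels[ok])
            )
        assert np.mean(aris) >= 0.9

    def test_merge_order_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        gm = sg.GeneMatrix(
            pd.DataFrame(
                rng.normal(size=(12, 6)),
                index=[f"g{i}" for i in range(12)],
                columns=list("abcdef"),
            ),
            id_space="probe",
        )
        assign = sg.cluster_arrays(gm, k=2, min_cluster_size=1, median_center_genes=False,
                                   cluster_genes=False)
        centered = gm.values
        dist = correlation_distance(centered).to_numpy()
        merges = naive_average_linkage(dist)
        Z = assign.array_linkage
        # reconstruct merged leaf-sets from the scipy linkage
        sets = {i: frozenset([i]) for i in range(6)}
        for row_idx, (a, b, height, _) in enumerate(Z):
            merged = sets[int(a)] | sets[int(b)]
            sets[6 + row_idx] = merged
            assert merged == merges[row_idx][0]
            assert height == pytest.approx(merges[row_idx][1], rel=1e-10)

    def test_small_clusters_become_unassigned(self):
        gm, truth = subset_templates(n_per=6, noise=0.05)
        # an outlier array unlike any template
        outlier = pd.DataFrame(
            np.linspace(-3, 3, gm.values.shape[0]), index=gm.values.index, columns=["odd"]
        )
        gm2 = sg.GeneMatrix(pd.concat([gm.values, outlier], axis=1), id_space="probe")
        assign = sg.cluster_arrays(gm2, k=5, min_cluster_size=3)
        assert assign.labels["odd"] == sg.UNASSIGNED

    def test_invariant_to_array_and_gene_order(self):
        gm, _ = subset_templates(noise=0.3, seed=2)
        assign = sg.cluster_arrays(gm, k=4, min_cluster_size=2)
        rng = np.random.default_rng(0)
        shuffled = gm.values.iloc[
            rng.permutation(gm.values.shape[0]), rng.permutation(gm.values.shape[1])
        ]
        assign2 = sg.cluster_arrays(sg.GeneMatrix(shuffled, id_space="probe"), k=4,
                                    min_cluster_size=2)
        a = assign.labels.sort_index()
        b = assign2.labels.sort_index()
        assert adjusted_rand_score(a, b) == 1.0

    def test_dendrogram_cut_consistency(self):
        gm, _ = subset_templates(noise=0.4, seed=3)
        a4 = sg.cluster_arrays(gm, k=4, min_cluster_size=1).labels
        a3 = sg.cluster_arrays(gm, k=3, min_cluster_size=1).labels
        # the k=3 partition merges exactly two of the k=4 clusters
        tab = pd.crosstab(a4, a3)
        assert ((tab > 0).sum(axis=1) == 1).all()
        assert (tab > 0).to_numpy().sum() == 4


class TestLabelClusters:
    def test_dominant_marker_wins(self):
        gm, truth = subset_templates(noise=0.05)
        assign = sg.cluster_arrays(gm, k=4, min_cluster_size=2)
        markers = {f"subset{s}": [f"g{i}" for i in range(s * 10, s * 10 + 5)] for s in range(4)}
        labelled = sg.label_clusters(assign, gm, markers)
        assert (labelled.labels == truth).all()

    def test_tie_breaks_lexicographically(self):
        values = pd.DataFrame(
            np.zeros((4, 6)), index=[f"g{i}" for i in range(4)], columns=[f"a{j}" for j in range(6)]
        )
        values.iloc[:, :] = 1.0  # all markers equal everywhere
        gm = sg.GeneMatrix(values, id_space="probe")
        assign = sg.SubsetAssignment(
            labels=pd.Series("cluster_1", index=values.columns),
            array_linkage=np.empty((0, 4)),
            gene_linkage=None,
            params={},
        )
        labelled = sg.label_clusters(assign, gm, {"beta": ["g0", "g1"], "alpha": ["g2", "g3"]})
        assert (labelled.labels == "alpha").all()

    def test_missing_markers_hard_error(self):
        gm, _ = subset_templates()
        assign = sg.cluster_arrays(gm, k=4, min_cluster_size=2)
        with pytest.raises(sg.SigscoreError, match="ghost"):
            sg.label_clusters(assign, gm, {"x": ["ghost"]})


class TestConcordance:
    def _paper_style_labels(self):
        """Contingency built from the published per-subset retention counts."""
        rows = {
            "inflammatory": [("inflammatory", 47), ("fibroproliferative", 16), ("limited", 12)],
            "fibroproliferative": [("fibroproliferative", 69), ("inflammatory", 17), ("normal_like", 13)],
            "limited": [("limited", 12), ("fibroproliferative", 6), ("normal_like", 1)],
            "normal_like": [("normal_like", 58), ("limited", 28), ("inflammatory", 18)],
        }
        orig, new = [], []
        for o, dests in rows.items():
            for d, n in dests:
                orig.extend([o] * n)
                new.extend([d] * n)
        idx = [f"a{i}" for i in range(len(orig))]
        return pd.Series(orig, index=idx), pd.Series(new, index=idx)

    def test_printed_retention_percentages(self):
        orig, new = self._paper_style_labels()
        rep = sg.concordance(orig, new)
        assert rep.per_subset.loc["inflammatory", "percent"] == 63
        assert rep.per_subset.loc["fibroproliferative", "percent"] == 70
        assert rep.per_subset.loc["limited", "percent"] == 63
        assert rep.per_subset.loc["normal_like", "percent"] == 56
        assert rep.p_value <= 0.001

    def test_identical_labelings(self):
        labels = pd.Series(
            ["x"] * 12 + ["y"] * 12 + ["z"] * 12, index=[f"a{i}" for i in range(36)]
        )
        rep = sg.concordance(labels, labels.copy())
        assert (rep.per_subset["percent"] == 100).all()
        assert rep.p_value < 1e-6

    def test_disjoint_vocabularies_error(self):
        a = pd.Series(["x"] * 4, index=list("abcd"))
        b = pd.Series(["y"] * 4, index=list("abcd"))
        with pytest.raises(sg.SigscoreError):
            sg.concordance(a, b)

    def test_contingency_margins_match_counts(self):
        orig, new = self._paper_style_labels()
        rep = sg.concordance(orig, new)
        assert rep.contingency.to_numpy().sum() == len(orig)
        pd.testing.assert_series_equal(
            rep.contingency.sum(axis=1).sort_index(),
            orig.value_counts().sort_index(),
            check_names=False,
        )


class TestTreeViewExport:
    def test_files_written_and_consistent(self, tmp_path):
        gm, _ = subset_templates(noise=0.2)
        assign = sg.cluster_arrays(gm, k=4, min_cluster_size=2)
        prefix = tmp_path / "demo"
        sg.write_treeview(gm, assign, str(prefix))
        cdt = (prefix.with_suffix(".cdt")).read_text().splitlines()
        assert len(cdt) == 2 + gm.values.shape[0]
        atr = (prefix.with_suffix(".atr")).read_text().splitlines()
        assert len(atr) == gm.values.shape[1] - 1
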