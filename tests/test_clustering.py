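import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from stimplant.io_formats import CountMatrix, StimplantError
from stimplant.clustering import (
    ClusterAssignment,
    ClusteringConfig,
    NormalizedExpression,
    bh_adjust,
    cluster_frequencies,
    compare_frequencies,
    differential_expression,
    embed_and_cluster,
    find_markers,
    normalize,
    program_score,
    subcluster,
    volcano_flag,
)


def make_expr(values, prefix="c"):
    values = np.asarray(values, dtype=float)
    return NormalizedExpression(
        cells=[f"{prefix}{i:04d}" for i in range(values.shape[0])],
        genes=[f"g{j:03d}" for j in range(values.shape[1])],
        values=values,
    )


def blob_expr(rng, sizes, shifts, n_genes=20, scale=6.0):
    """Isotropic Gaussian blobs in expression space; shifts index marker dims."""
    blocks = []
    for size, dims in zip(sizes, shifts):
        mu = np.zeros(n_genes)
        mu[list(dims)] = scale
        blocks.append(rng.normal(mu, 1.0, (size, n_genes)))
    return make_expr(np.vstack(blocks))


class TestNormalize:
    def test_single_cell_scale_factor_one(self):
        cm = CountMatrix(["gA", "gB"], ["c1"], sp.csr_matrix(np.array([[2], [0]])))
        expr = normalize(cm)
        assert expr.values[0, 0] == pytest.approx(np.log(3.0))
        assert expr.values[0, 1] == 0.0

    def test_per_cell_depth_invariance(self):
        # Scaling one cell's library leaves its normalized profile unchanged
        # as long as the median total is unchanged. (Scaling *all* counts
        # also rescales the median target, so global doubling is not an
        # invariance of median-total normalization.)
        counts = np.array(
            [[5, 5, 5, 5, 12], [5, 5, 5, 5, 8]], dtype=int
        )  # totals 10,10,10,10,20; median 10
        scaled = counts.copy()
        scaled[:, 4] *= 3  # totals 10,10,10,10,60; median still 10
        genes, cells = ["g1", "g2"], [f"c{i}" for i in range(5)]
        e1 = normalize(CountMatrix(genes, cells, sp.csr_matrix(counts)))
        e2 = normalize(CountMatrix(genes, cells, sp.csr_matrix(scaled)))
        np.testing.assert_allclose(e1.values, e2.values, rtol=1e-12)

    def test_zero_total_cell_excluded_with_warning(self):
        counts = np.array([[2, 0, 1], [1, 0, 3]])
        cm = CountMatrix(["g1", "g2"], ["c1", "c2", "c3"], sp.csr_matrix(counts))
        with pytest.warns(UserWarning, match="zero-count"):
            expr = normalize(cm)
        assert expr.cells == ["c1", "c3"]

    def test_all_zero_matrix_errors(self):
        cm = CountMatrix(["g"], ["c1", "c2"], sp.csr_matrix((1, 2), dtype=int))
        with pytest.raises(StimplantError):
            normalize(cm)


class TestEmbedAndCluster:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(0)
        expr = blob_expr(rng, [200, 200], [(0, 1, 2, 3, 4), (10, 11, 12, 13, 14)])
        cfg = ClusteringConfig(n_components=10, n_neighbors=15, seed=0)
        assignment, emb = embed_and_cluster(expr, cfg)
        assert assignment.n_clusters == 2
        labels = assignment.labels.values
        # partition matches ground truth up to label order
        assert len(set(labels[:200])) == 1
        assert len(set(labels[200:])) == 1
        assert labels[0] != labels[200]
        assert len(emb) == 400 and {"cell_id", "dim1", "dim2"} <= set(emb.columns)

    def test_determinism(self):
        rng = np.random.default_rng(1)
        expr = blob_expr(rng, [100, 100], [(0, 1), (5, 6)])
        cfg = ClusteringConfig(n_components=8, n_neighbors=10, seed=7)
        a1, e1 = embed_and_cluster(expr, cfg)
        a2, e2 = embed_and_cluster(expr, cfg)
        pd.testing.assert_series_equal(a1.labels, a2.labels)
        pd.testing.assert_frame_equal(e1, e2)

    def test_null_noise_does_not_explode(self):
        # i.i.d. noise has no real structure; modularity methods still
        # partition it, but the split should stay modest at this resolution.
        rng = np.random.default_rng(2)
        expr = make_expr(np.abs(rng.normal(0, 1, (500, 30))))
        assignment, _ = embed_and_cluster(
            expr, ClusteringConfig(n_components=15, n_neighbors=20, seed=0)
        )
        assert assignment.n_clusters <= 10

    def test_too_few_cells_errors(self):
        rng = np.random.default_rng(3)
        expr = make_expr(np.abs(rng.normal(0, 1, (10, 20))))
        with pytest.raises(StimplantError):
            embed_and_cluster(expr, ClusteringConfig(n_neighbors=20))

    def test_labels_partition_ordered_by_size(self):
        rng = np.random.default_rng(4)
        expr = blob_expr(rng, [150, 60], [(0, 1, 2), (8, 9, 10)])
        assignment, _ = embed_and_cluster(
            expr, ClusteringConfig(n_components=8, n_neighbors=10, seed=0)
        )
        sizes = assignment.labels.value_counts().sort_index()
        assert list(sizes.index) == list(range(assignment.n_clusters))
        assert list(sizes.values) == sorted(sizes.values, reverse=True)
        assert len(assignment.labels) == 210  # every cell labeled exactly once


class TestSubcluster:
    def test_planted_subblobs_recovered(self):
        # The parent assignment is an input: give subcluster a known parent
        # whose cluster 0 is a union of 3 planted sub-blobs (split on dims
        # 10..15, shared signature on dims 0..4) and check full recovery.
        rng = np.random.default_rng(5)
        sub_dims = [(10, 11), (12, 13), (14, 15)]
        blocks = []
        for dims in sub_dims:
            mu = np.zeros(24)
            mu[:5] = 6.0
            mu[list(dims)] = 6.0
            blocks.append(rng.normal(mu, 1.0, (80, 24)))
        mu_other = np.zeros(24)
        mu_other[20:] = 6.0
        blocks.append(rng.normal(mu_other, 1.0, (100, 24)))
        expr = make_expr(np.vstack(blocks))
        parent = ClusterAssignment(
            "global",
            pd.Series([0] * 240 + [1] * 100, index=pd.Index(expr.cells)),
        )
        cfg = ClusteringConfig(n_components=10, n_neighbors=12, seed=0)
        sub, _ = subcluster(expr, parent, 0, cfg)
        assert sub.n_clusters == 3
        assert set(sub.cells) == set(parent.members(0))
        assert sub.level.startswith("global/")
        # partition matches the planted sub-blobs exactly
        for start in (0, 80, 160):
            chunk = sub.labels.iloc[start : start + 80]
            assert chunk.nunique() == 1

    def test_coverage_and_determinism(self):
        rng = np.random.default_rng(6)
        expr = blob_expr(rng, [120, 80], [(0, 1, 2), (8, 9, 10)])
        cfg = ClusteringConfig(n_components=8, n_neighbors=10, seed=0)
        parent, _ = embed_and_cluster(expr, cfg)
        s1, _ = subcluster(expr, parent, 0, cfg)
        s2, _ = subcluster(expr, parent, 0, cfg)
        pd.testing.assert_series_equal(s1.labels, s2.labels)
        members = set(parent.members(0))
        assert set(s1.cells) == members
        assert members < set(expr.cells)

    def test_small_target_errors(self):
        rng = np.random.default_rng(7)
        expr = blob_expr(rng, [150, 8], [(0, 1, 2, 3, 4), (10, 11, 12, 13, 14)])
        parent = ClusterAssignment(
            "global",
            pd.Series([0] * 150 + [1] * 8, index=pd.Index(expr.cells)),
        )
        cfg = ClusteringConfig(n_components=5, n_neighbors=10, seed=0)
        with pytest.raises(StimplantError, match="subcluster"):
            subcluster(expr, parent, 1, cfg)


def planted_marker_counts(
    rng, n_cells=200, n_genes=100, n_markers=10, cluster_size=60,
    log2fc=2.0, pct=0.8,
):
    """NB counts with the first n_markers genes up in the first cells."""
    base = np.full(n_genes, 0.3)
    base[:n_markers] = 1.0
    means = np.tile(base[:, None], (1, n_cells))
    in_cluster = np.zeros(n_cells, dtype=bool)
    in_cluster[:cluster_size] = True
    for g in range(n_markers):
        on = in_cluster & (rng.uniform(size=n_cells) < pct)
        means[g, on] *= 2.0 ** log2fc
    r = 2.0
    counts = rng.poisson(rng.gamma(r, means / r))
    labels = np.where(in_cluster, 0, 1)
    cm = CountMatrix(
        [f"g{j:03d}" for j in range(n_genes)],
        [f"c{i:04d}" for i in range(n_cells)],
        sp.csr_matrix(counts),
    )
    return cm, labels


class TestFindMarkers:
    @pytest.fixture()
    def planted(self):
        rng = np.random.default_rng(11)
        cm, labels = planted_marker_counts(rng)
        expr = normalize(cm)
        assignment = ClusterAssignment(
            "global", pd.Series(labels, index=pd.Index(cm.cells, name="cell_id"))
        )
        return expr, assignment

    def test_pct_below_half_excluded(self):
        # marker expressed in only 40% of in-cluster cells, huge fold change
        counts = np.zeros((2, 20), dtype=int)
        counts[0, :4] = 50          # 4 of 10 in-cluster cells -> pct_in 0.4
        counts[1, :] = 1            # housekeeping keeps totals nonzero
        cm = CountMatrix(["marker", "hk"], [f"c{i}" for i in range(20)],
                         sp.csr_matrix(counts))
        expr = normalize(cm)
        labels = pd.Series([0] * 10 + [1] * 10, index=pd.Index(cm.cells))
        assignment = ClusterAssignment("global", labels)
        res = find_markers(expr, assignment, 0)
        assert "marker" not in set(res["gene"])
        allres = find_markers(expr, assignment, 0, return_all=True)
        row = allres[allres["gene"] == "marker"].iloc[0]
        assert row["pct_in"] == pytest.approx(0.4)
        assert row["log2fc"] > 0.25

    def test_pct_06_and_fc_above_quarter_retained(self):
        counts = np.zeros((2, 20), dtype=int)
        counts[0, :6] = 3           # 6 of 10 -> pct_in 0.6
        counts[1, :] = 2
        cm = CountMatrix(["marker", "hk"], [f"c{i}" for i in range(20)],
                         sp.csr_matrix(counts))
        expr = normalize(cm)
        assignment = ClusterAssignment(
            "global", pd.Series([0] * 10 + [1] * 10, index=pd.Index(cm.cells))
        )
        res = find_markers(expr, assignment, 0)
        row = res[res["gene"] == "marker"]
        assert len(row) == 1
        assert row.iloc[0]["pct_in"] == pytest.approx(0.6)
        assert row.iloc[0]["log2fc"] > 0.25

    def test_all_zero_gene_excluded(self, planted):
        expr, assignment = planted
        zeroed = expr.values.copy()
        zeroed[:, 50] = 0.0
        expr2 = NormalizedExpression(expr.cells, expr.genes, zeroed)
        allres = find_markers(expr2, assignment, 0, return_all=True)
        row = allres[allres["gene"] == "g050"].iloc[0]
        assert row["pct_in"] == 0.0
        assert "g050" not in set(find_markers(expr2, assignment, 0)["gene"])

    def test_small_cluster_errors(self):
        rng = np.random.default_rng(12)
        cm, _ = planted_marker_counts(rng, n_cells=30)
        expr = normalize(cm)
        labels = pd.Series([0] * 2 + [1] * 28, index=pd.Index(cm.cells))
        with pytest.raises(StimplantError):
            find_markers(expr, ClusterAssignment("global", labels), 0)

    def test_output_shrinks_with_thresholds(self, planted):
        expr, assignment = planted
        base = len(find_markers(expr, assignment, 0, min_pct=0.3, min_log2fc=0.1))
        higher_pct = len(find_markers(expr, assignment, 0, min_pct=0.6, min_log2fc=0.1))
        higher_fc = len(find_markers(expr, assignment, 0, min_pct=0.3, min_log2fc=1.0))
        assert higher_pct <= base
        assert higher_fc <= base

    def test_planted_recovery(self, planted):
        expr, assignment = planted
        res = find_markers(expr, assignment, 0)
        markers = {f"g{j:03d}" for j in range(10)}
        found = set(res["gene"])
        assert len(found & markers) >= 9
        false_pos = found - markers
        assert len(false_pos) / 90 < 0.05

    def test_p_adj_at_least_p(self, planted):
        expr, assignment = planted
        res = find_markers(expr, assignment, 0, return_all=True)
        assert (res["p_adj"] >= res["p_value"] - 1e-15).all()


class TestBHAdjust:
    def _oracle(self, p):
        """Brute-force BH: sort, scale by m/rank, enforce monotonicity."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank_from_end, i in enumerate(order[::-1]):
            rank = m - rank_from_end
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(bh_adjust(p), self._oracle(p), rtol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestVolcanoFlag:
    def test_inclusive_thresholds(self):
        assert volcano_flag(1.0, 2.0)
        assert not volcano_flag(0.999, 2.0)
        assert not volcano_flag(1.0, 1.999)
        assert volcano_flag(1.5, 3.0)


class TestDifferentialExpression:
    def _expr_and_samples(self, rng, fc=4.0, n_per=400):
        base = np.full(50, 0.8)
        means_a = np.tile(base[:, None], (1, n_per))
        means_b = means_a.copy()
        means_b[0] *= fc  # gene g000 planted up in group b
        counts = np.hstack(
            [rng.poisson(rng.gamma(2.0, m / 2.0)) for m in (means_a, means_b)]
        )
        cm = CountMatrix(
            [f"g{j:03d}" for j in range(50)],
            [f"c{i:04d}" for i in range(2 * n_per)],
            sp.csr_matrix(counts),
        )
        expr = normalize(cm)
        sample_of = pd.Series(
            ["sa1" if i % 2 else "sa2" for i in range(n_per)]
            + ["sb1" if i % 2 else "sb2" for i in range(n_per)],
            index=pd.Index(cm.cells),
        )
        return expr, sample_of

    def test_planted_fold_change_flagged(self):
        rng = np.random.default_rng(21)
        expr, sample_of = self._expr_and_samples(rng)
        res = differential_expression(expr, sample_of, ["sa1", "sa2"], ["sb1", "sb2"])
        assert res.iloc[0]["gene"] == "g000"  # sorted by log2fc desc
        assert bool(res.iloc[0]["significant"])

    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_null_groups_not_flagged(self, seed):
        rng = np.random.default_rng(seed)
        expr, sample_of = self._expr_and_samples(rng, fc=1.0, n_per=150)
        res = differential_expression(expr, sample_of, ["sa1", "sa2"], ["sb1", "sb2"])
        assert not res["significant"].any()

    def test_overlapping_samples_error(self):
        rng = np.random.default_rng(22)
        expr, sample_of = self._expr_and_samples(rng, n_per=50)
        with pytest.raises(StimplantError):
            differential_expression(expr, sample_of, ["sa1", "sb1"], ["sb1", "sb2"])


class TestClusterFrequencies:
    def _assignment(self, labels, cells=None):
        cells = cells or [f"c{i}" for i in range(len(labels))]
        return ClusterAssignment(
            "global", pd.Series(labels, index=pd.Index(cells, name="cell_id"))
        )

    def test_basic_fractions(self):
        a = self._assignment([0] * 70 + [1] * 30)
        sample_of = pd.Series("s1", index=a.labels.index)
        freqs = cluster_frequencies(a, sample_of)
        assert freqs.set_index("cluster")["frequency"].to_dict() == pytest.approx(
            {0: 0.7, 1: 0.3}
        )

    def test_absent_cluster_explicit_zero(self):
        a = self._assignment([0] * 10 + [1] * 10)
        sample_of = pd.Series(
            ["s1"] * 10 + ["s2"] * 10, index=a.labels.index
        )
        freqs = cluster_frequencies(a, sample_of)
        row = freqs[(freqs["sample_id"] == "s1") & (freqs["cluster"] == 1)]
        assert len(row) == 1 and row.iloc[0]["frequency"] == 0.0

    def test_frequencies_sum_to_one(self, small_study):
        _, pairs, _ = small_study
        truth = pd.concat([t.cells for _, t in pairs])
        a = self._assignment(
            truth["cluster"].tolist(), cells=truth["cell_id"].tolist()
        )
        sample_of = pd.Series(
            np.repeat([s.sample_id for s, _ in pairs],
                      [len(t.cells) for _, t in pairs]),
            index=truth["cell_id"],
        )
        freqs = cluster_frequencies(a, sample_of)
        sums = freqs.groupby("sample_id")["frequency"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestCompareFrequencies:
    def _freqs(self, per_sample: dict):
        rows = []
        for sid, fr in per_sample.items():
            for k, f in enumerate(fr):
                rows.append({"sample_id": sid, "level": "global", "cluster": k,
                             "n_cells": int(1000 * f), "frequency": f})
        return pd.DataFrame(rows)

    def test_planted_26_fold_flagged(self):
        rng = np.random.default_rng(40)
        per = {}
        for i in range(4):
            j = rng.normal(0, 1e-4, 2)
            per[f"skin{i}"] = [0.1 + j[0], 0.9 - j[0]]
            per[f"pcl{i}"] = [0.26 + j[1], 0.74 - j[1]]
        freqs = self._freqs(per)
        table, flagged = compare_frequencies(
            freqs, [f"skin{i}" for i in range(4)], [f"pcl{i}" for i in range(4)]
        )
        row = table[table["cluster"] == 0].iloc[0]
        assert row["fold_change"] == pytest.approx(2.6, rel=0.01)
        assert 0 in flagged

    def test_equal_means_not_flagged(self):
        per = {f"s{i}": [0.5, 0.5] for i in range(4)}
        per.update({f"p{i}": [0.5, 0.5] for i in range(4)})
        _, flagged = compare_frequencies(
            self._freqs(per), [f"s{i}" for i in range(4)],
            [f"p{i}" for i in range(4)],
        )
        assert flagged == []

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(41)
        per = {}
        for i in range(4):
            per[f"a{i}"] = [0.1 + rng.normal(0, 1e-3), 0.9 - rng.normal(0, 1e-3)]
        for i in range(4):
            per[f"b{i}"] = [0.3 + rng.normal(0, 1e-3), 0.7 - rng.normal(0, 1e-3)]
        ga = [f"a{i}" for i in range(4)]
        gb = [f"b{i}" for i in range(4)]
        _, fwd = compare_frequencies(self._freqs(per), ga, gb)
        _, rev = compare_frequencies(self._freqs(per), gb, ga)
        assert 0 in fwd and 0 not in rev
        assert 1 in rev and 1 not in fwd

    def test_too_few_samples_error(self):
        per = {"a1": [1.0], "b1": [1.0], "b2": [1.0]}
        with pytest.raises(StimplantError):
            compare_frequencies(self._freqs(per), ["a1"], ["b1", "b2"])


class TestProgramScore:
    def test_single_gene_panel(self):
        rng = np.random.default_rng(50)
        expr = make_expr(np.abs(rng.normal(0, 1, (30, 5))))
        score = program_score(expr, ["g002"])
        np.testing.assert_allclose(score.values, expr.values[:, 2])

    def test_duplicated_gene_same_as_unique(self):
        rng = np.random.default_rng(51)
        expr = make_expr(np.abs(rng.normal(0, 1, (30, 5))))
        s1 = program_score(expr, ["g001", "g003"])
        s2 = program_score(expr, ["g001", "g003", "g001"])
        np.testing.assert_allclose(s1.values, s2.values)

    def test_missing_gene_warns_all_missing_errors(self):
        rng = np.random.default_rng(52)
        expr = make_expr(np.abs(rng.normal(0, 1, (10, 3))))
        with pytest.warns(UserWarning, match="missing"):
            program_score(expr, ["g000", "nope"])
        with pytest.raises(StimplantError):
            program_score(expr, ["nope", "also_nope"])

    def test_panel_cells_score_higher(self):
        rng = np.random.default_rng(53)
        n = 200
        base = np.abs(rng.normal(1, 0.3, (2 * n, 10)))
        base[:n, :4] *= 4.0  # first n cells have the panel at 4x
        expr = make_expr(base)
        score = program_score(expr, ["g000", "g001", "g002", "g003"])
        p = stats.mannwhitneyu(score.values[:n], score.values[n:],
                               alternative="greater").pvalue
        assert p < 0.01
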