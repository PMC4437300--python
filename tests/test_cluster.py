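"""Taxonomy pipeline: uniformity filter, min-max scaling, Ward agglomeration.

The Ward implementation is checked against two independent oracles: an
exhaustive search that evaluates every candidate merge's error-sum-of-
squares increase directly from cluster members (n <= 7), and scipy's
Ward linkage (whose heights equal sqrt(2 x ESS increase)).
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage

from asicephys import cluster, synth
from asicephys.cluster import (
    UniformityFilter,
    WardClusterer,
    assign_labels,
    minmax_normalize,
    uniformity_filter,
    ward_cluster,
)


def _ess(points):
    c = points.mean(axis=0)
    return float(((points - c) ** 2).sum())


def exhaustive_ward(mat):
    """Greedy ESS-minimizing agglomeration computed from cluster members."""
    clusters = {i: [i] for i in range(len(mat))}
    merges = []
    next_id = len(mat)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            members = clusters[a] + clusters[b]
            inc = _ess(mat[members]) - _ess(mat[clusters[a]]) - _ess(mat[clusters[b]])
            if best is None or (inc, a, b) < best:
                best = (inc, a, b)
        inc, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, inc, len(clusters[next_id])))
        next_id += 1
    return np.array(merges)


def _partition_sets(labels):
    return frozenset(frozenset(np.nonzero(labels == v)[0]) for v in np.unique(labels))


class TestUniformityFilter:
    def test_bimodal_feature_retained(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.3, 36), rng.normal(5, 0.3, 36)])
        kept, report = uniformity_filter(pd.DataFrame({"f": x}))
        assert list(kept.columns) == ["f"]
        assert (report["decision"] == "retained: nonuniform").all()

    def test_uniform_feature_dropped_in_most_seeds(self):
        dropped = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            frame = pd.DataFrame({
                "u": rng.uniform(0, 1, 72),
                "keep": np.concatenate([rng.normal(0, 0.05, 36), rng.normal(1, 0.05, 36)]),
            })
            kept, _ = uniformity_filter(frame)
            if "u" not in kept.columns:
                dropped += 1
        assert dropped >= 180  # >= 90% of seeds

    def test_constant_feature_dropped(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({
            "const": np.ones(40),
            "keep": np.concatenate([rng.normal(0, 0.05, 20), rng.normal(1, 0.05, 20)]),
        })
        kept, report = uniformity_filter(frame)
        assert "const" not in kept.columns
        row = report[report["feature"] == "const"].iloc[0]
        assert row["decision"] == "dropped: degenerate range"

    def test_all_dropped_is_explicit_error(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame({"u": rng.uniform(0, 1, 500)})
        with pytest.raises(ValueError, match="manually"):
            UniformityFilter(alpha=1e-6).fit(frame)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="cells"):
            UniformityFilter().fit(pd.DataFrame({"f": np.arange(5.0)}))


class TestMinMaxNormalize:
    def test_formula(self):
        out = minmax_normalize(pd.DataFrame({"f": [2.0, 4.0, 6.0]}))
        np.testing.assert_allclose(out["f"], [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self):
        frame = pd.DataFrame({"f": [0.0, 0.25, 1.0]})
        out = minmax_normalize(minmax_normalize(frame))
        np.testing.assert_allclose(out["f"], frame["f"])

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="zero-range"):
            minmax_normalize(pd.DataFrame({"f": [1.0, 1.0]}))

    @settings(deadline=None, max_examples=30)
    @given(
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-100.0, 100.0),
    )
    def test_affine_invariance(self, scale, offset):
        col = np.array([0.3, 1.7, -2.2, 0.9, 4.1])
        a = minmax_normalize(pd.DataFrame({"f": col}))
        b = minmax_normalize(pd.DataFrame({"f": scale * col + offset}))
        np.testing.assert_allclose(a["f"], b["f"], atol=1e-9)


class TestWardCluster:
    def test_first_merge_is_nearest_pair(self):
        tree = ward_cluster(pd.DataFrame({"x": [0.0, 0.1, 1.0]}))
        assert set(tree.merges[0, :2]) == {0, 1}

    def test_duplicate_points_merge_first_at_zero_height(self):
        tree = ward_cluster(pd.DataFrame({"x": [0.5, 0.5, 0.0, 1.0]}))
        assert set(tree.merges[0, :2]) == {0, 1}
        assert tree.merges[0, 2] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_ess_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 8)
        mat = rng.uniform(size=(n, 3))
        tree = ward_cluster(pd.DataFrame(mat))
        oracle = exhaustive_ward(mat)
        np.testing.assert_allclose(tree.merges[:, 2], oracle[:, 2], rtol=1e-9, atol=1e-12)
        for k in range(1, n + 1):
            ours = _partition_sets(tree.cut(k))
            # rebuild oracle partition at k via union-find over its merges
            theirs = _partition_sets(
                cluster.Dendrogram(oracle, n).cut(k)
            )
            assert ours == theirs

    def test_heights_match_scipy_ward(self):
        rng = np.random.default_rng(3)
        mat = rng.uniform(size=(15, 4))
        tree = ward_cluster(pd.DataFrame(mat))
        z = linkage(mat, method="ward")
        # scipy heights are sqrt(2 x ESS increase)
        np.testing.assert_allclose(np.sqrt(2.0 * tree.merges[:, 2]), z[:, 2], rtol=1e-8)
        for k in (2, 3, 4):
            assert _partition_sets(tree.cut(k)) == _partition_sets(
                fcluster(z, k, criterion="maxclust")
            )

    def test_monotone_heights_on_random_data(self):
        rng = np.random.default_rng(4)
        tree = ward_cluster(pd.DataFrame(rng.uniform(size=(40, 4))))
        assert np.all(np.diff(tree.merges[:, 2]) >= -1e-12)

    def test_permutation_invariance_of_partition(self):
        rng = np.random.default_rng(5)
        mat = rng.uniform(size=(20, 3))
        perm = rng.permutation(20)
        labels_a = WardClusterer(n_clusters=3).fit_predict(pd.DataFrame(mat))
        labels_b = WardClusterer(n_clusters=3).fit_predict(pd.DataFrame(mat[perm]))
        a_sets = _partition_sets(labels_a)
        b_sets = frozenset(
            frozenset(perm[list(s)]) for s in _partition_sets(labels_b)
        )
        assert a_sets == b_sets

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ward_cluster(pd.DataFrame({"x": [0.0, np.nan, 1.0]}))


class TestAssignLabels:
    def test_k_equals_n_singletons(self):
        tree = ward_cluster(pd.DataFrame({"x": [0.0, 0.3, 0.9, 1.0]}))
        assert len(set(assign_labels(tree, 4))) == 4

    def test_k_one_single_cluster(self):
        tree = ward_cluster(pd.DataFrame({"x": [0.0, 0.3, 0.9, 1.0]}))
        assert set(assign_labels(tree, 1)) == {1}

    def test_out_of_range_k_rejected(self):
        tree = ward_cluster(pd.DataFrame({"x": [0.0, 1.0]}))
        with pytest.raises(ValueError):
            assign_labels(tree, 3)

    def test_labels_ordered_by_cluster_size(self):
        x = pd.DataFrame({"x": [0.0, 0.01, 0.02, 0.03, 1.0]})
        labels = assign_labels(ward_cluster(x), 2)
        assert list(labels) == [1, 1, 1, 1, 2]


class TestPlantedRecovery:
    def test_well_separated_delay_populations_recovered(self):
        """Two delay populations separated by ~6 pooled SDs: >= 95% label
        agreement with ground truth over 100 seeds."""
        agreements = []
        for seed in range(100):
            cfg = synth.SimConfig(seed=seed, step_duration_s=2.0)
            specs = synth.cel_cohort_specs(sem_ls=24.0, sem_es=24.0 * np.sqrt(46 / 26))
            tab = synth.gen_cohort(specs, cfg)
            norm = minmax_normalize(tab[["spike_delay_ms"]])
            labels = assign_labels(ward_cluster(norm), 2)
            truth = (tab["phenotype"] == "late_spiking").to_numpy()
            ours = labels == 1  # larger cluster: 46 late-spiking cells
            agreements.append(max(np.mean(ours == truth), np.mean(ours != truth)))
        assert np.mean(agreements) >= 0.95

    def test_well_separated_cohort_recovers_four_types(self):
        cfg = synth.SimConfig(seed=9)
        tab = synth.gen_cohort(synth.bla_cohort_specs(), cfg)
        feats = tab[list(synth.COHORT_FEATURES)]
        kept, _ = uniformity_filter(feats)
        labels = assign_labels(ward_cluster(minmax_normalize(kept)), 4)
        # cluster/type contingency: each planted type maps to one dominant cluster
        frame = pd.DataFrame({"lab": labels, "truth": tab["phenotype"]})
        purity = frame.groupby("truth")["lab"].agg(lambda s: s.value_counts().iloc[0] / len(s))
        assert (purity >= 0.9).all()
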