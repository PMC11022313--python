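import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import habcircuit as hc
from habcircuit.clustering import (AmbiguousLabelingError, CorrelationKMeans,
                                   cluster_traces, correlation_distance,
                                   label_clusters, select_k, split_regions)


class TestSplitRegions:
    def test_labels_given(self):
        meta = pd.DataFrame({"cell_id": list("abc"),
                             "region": ["dorsal", "ventral", "dorsal"]})
        d, v = split_regions(meta)
        assert d.tolist() == [True, False, True]
        assert v.tolist() == [False, True, False]

    def test_z_threshold_convention(self):
        meta = pd.DataFrame({"cell_id": ["a", "b"], "region": [None, None],
                             "z": [10.0, 50.0]})
        d, v = split_regions(meta, z_threshold=30.0)
        assert d.tolist() == [True, False]       # smaller z = dorsal
        d2, v2 = split_regions(meta, z_threshold=30.0, dorsal_smaller_z=False)
        assert d2.tolist() == [False, True]

    def test_missing_region_and_position_reported(self):
        meta = pd.DataFrame({"cell_id": ["a"], "region": [None]})
        with pytest.raises(ValueError, match="missing both"):
            split_regions(meta)

    def test_synthetic_experiment_counts_preserved(self):
        tm = hc.simulate_habenula(seed=0, noise_sd=0.0)
        d, v = split_regions(tm.cell_meta)
        assert d.sum() == 1747 and v.sum() == 1227
        assert not np.any(d & v) and np.all(d | v)


class TestCorrelationDistance:
    def test_identical_and_anticorrelated(self):
        a = np.array([1.0, 2.0, 3.0, 1.0])
        assert correlation_distance(a, a) == pytest.approx(0.0, abs=1e-14)
        assert correlation_distance(a, -a) == pytest.approx(2.0, abs=1e-14)

    def test_hand_computed_value(self):
        # x=[1,2,3], y=[1,2,4]: r = 1/sqrt(28/27) => d = 1 - sqrt(27/28)
        d = correlation_distance([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert d == pytest.approx(1.0 - np.sqrt(27.0 / 28.0), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_invariant_to_positive_affine_rescaling(self, a, b):
        x = np.array([0.3, -1.2, 2.0, 0.7, -0.5])
        y = np.array([1.0, 0.2, -0.4, 1.5, 0.3])
        d0 = correlation_distance(x, y)
        d1 = correlation_distance(a * x + b, y)
        assert d1 == pytest.approx(d0, abs=1e-10)


class TestCorrelationKMeans:
    def test_two_separated_subtypes_perfect_partition(self, protocol, kernels):
        tm = hc.simulate_habenula({"D-ON-Tonic": 20, "D-OFF-Phasic": 20},
                                  noise_sd=0.05, seed=1)
        est = cluster_traces(tm.values, 2, seed=0)
        ari = adjusted_rand_score(tm.cell_meta["true_subtype"], est.labels_)
        assert ari == 1.0

    def test_k1_centroid_is_standardised_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 30))
        est = cluster_traces(X, 1, seed=0)
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        m = Z.mean(0)
        expect = (m - m.mean()) / m.std()
        assert np.allclose(est.cluster_centers_[0], expect)
        assert set(est.labels_) == {0}

    def test_affine_rescaling_of_traces_does_not_change_assignment(self):
        tm = hc.simulate_habenula({"D-ON-Tonic": 15, "D-OFF-Tonic": 15},
                                  noise_sd=0.1, seed=2)
        base = cluster_traces(tm.values, 2, seed=3).labels_
        rng = np.random.default_rng(4)
        gains = rng.uniform(0.5, 3.0, (tm.n_cells, 1))
        offs = rng.normal(0, 2.0, (tm.n_cells, 1))
        scaled = cluster_traces(gains * tm.values + offs, 2, seed=3).labels_
        assert np.array_equal(base, scaled)

    def test_permuting_cells_permutes_labels(self):
        tm = hc.simulate_habenula({"D-ON-Tonic": 12, "D-OFF-Phasic": 14},
                                  noise_sd=0.1, seed=5)
        ids = tm.cell_meta["cell_id"].tolist()
        est = cluster_traces(tm.values, 2, seed=1, cell_ids=ids)
        perm = np.random.default_rng(6).permutation(tm.n_cells)
        est_p = cluster_traces(tm.values[perm], 2, seed=1,
                               cell_ids=[ids[i] for i in perm])
        assert np.array_equal(est.labels_[perm], est_p.labels_)

    def test_sklearn_euclidean_on_standardised_agrees_on_separated_data(self):
        """Independent cross-check: on well-separated data, sklearn KMeans on
        standardised traces finds the same partition."""
        from sklearn.cluster import KMeans

        from habcircuit.clustering import standardize_traces
        tm = hc.simulate_habenula({"D-ON-Tonic": 20, "D-OFF-Tonic": 20,
                                   "D-OFF-Phasic": 20}, noise_sd=0.1, seed=7)
        ours = cluster_traces(tm.values, 3, seed=0).labels_
        ref = KMeans(3, n_init=10, random_state=0).fit(
            standardize_traces(tm.values)).labels_
        assert adjusted_rand_score(ours, ref) == 1.0

    def test_more_clusters_than_cells_rejected(self):
        with pytest.raises(ValueError):
            cluster_traces(np.random.default_rng(0).normal(size=(2, 10)), 3)


class TestSelectK:
    def test_silhouette_peaks_at_three_for_three_kernels(self):
        tm = hc.simulate_habenula({"D-ON-Tonic": 50, "D-OFF-Tonic": 50,
                                   "D-OFF-Phasic": 50}, noise_sd=0.2, seed=8)
        diag = select_k(tm.values, range(2, 6), seed=0, n_restarts=5)
        sil = {k: v["silhouette"] for k, v in diag.items()}
        assert max(sil, key=sil.get) == 3
        assert set(diag) == {2, 3, 4, 5}
        assert all(v["inertia"] >= 0 for v in diag.values())

    def test_identical_traces_flagged_degenerate(self):
        X = np.tile(np.sin(np.arange(30.0)), (8, 1))
        diag = select_k(X, [2, 3], seed=0, n_restarts=2)
        assert all(v["degenerate"] for v in diag.values())
        assert all(np.isnan(v["silhouette"]) for v in diag.values())


class TestLabelClusters:
    def test_noise_free_kernels_labelled_correctly(self, protocol, kernels):
        for region, names in (("dorsal", hc.naming.DORSAL_SUBTYPES),
                              ("ventral", hc.naming.VENTRAL_SUBTYPES)):
            C = np.vstack([kernels[n] for n in names])
            lab = label_clusters(C, protocol, region)
            assert [lab[i] for i in range(3)] == list(names)

    def test_constant_centroid_flagged_ambiguous(self, protocol, kernels):
        C = np.vstack([np.zeros(protocol.n_samples),
                       kernels["D-OFF-Tonic"], kernels["D-OFF-Phasic"]])
        with pytest.raises(AmbiguousLabelingError):
            label_clusters(C, protocol, "dorsal")

    def test_labelling_stable_under_10pct_noise_across_20_seeds(self, protocol, kernels):
        names = list(hc.naming.DORSAL_SUBTYPES)
        C0 = np.vstack([kernels[n] for n in names])
        amp = np.abs(C0).max()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            C = C0 + rng.normal(0, 0.1 * amp, C0.shape)
            lab = label_clusters(C, protocol, "dorsal")
            assert [lab[i] for i in range(3)] == names

    def test_all_six_names_covered_across_regions(self, protocol, kernels):
        got = set()
        for region, names in (("dorsal", hc.naming.DORSAL_SUBTYPES),
                              ("ventral", hc.naming.VENTRAL_SUBTYPES)):
            C = np.vstack([kernels[n] for n in names])
            got |= set(label_clusters(C, protocol, region).values())
        assert got == set(hc.SUBTYPES)
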