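"""Functional subtyping of habenula cells.

Cells are split into dorsal/ventral by anatomical position, then clustered
per region with k-means under correlation distance (1 - Pearson r), the
configuration that recovers the classic tonic/phasic, ON/OFF phenotypes.
The optimal k is a human judgement supported by per-k diagnostics (the
experiment settled on k = 3 per region); ``label_clusters`` formalises the
mapping from the three centroid shapes to the ON-Tonic / OFF-Tonic /
OFF-Phasic names via stimulus-locked indices.

Correlation-distance k-means is implemented as Lloyd iteration on
standardised traces: for unit-variance, zero-mean vectors u, v the squared
Euclidean distance is 2 n (1 - r), so minimising correlation distance is
Lloyd's update with centroids re-standardised after each mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .naming import SUBTYPES
from .protocol import LightProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_distance", "standardize_traces", "CorrelationKMeans",
    "cluster_traces", "split_regions", "select_k", "label_clusters",
    "AmbiguousLabelingError", "SubtypeLabeling",
]


class AmbiguousLabelingError(RuntimeError):
    """Centroid indices tie within tolerance; no silent label choice is made."""


def standardize_traces(X: np.ndarray) -> np.ndarray:
    """Row-wise (x - mean) / population sd.  Errors on zero-variance rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd.ravel() == 0)
        raise ValueError(f"zero-variance trace(s) at rows {bad.tolist()[:10]}")
    return (X - mu) / sd


def correlation_distance(a, b) -> float:
    """1 - Pearson correlation; in [0, 2]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("traces must have equal length")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation distance undefined for zero-variance trace")
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return 1.0 - r


def correlation_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise (n, n) correlation distances (rows standardised internally)."""
    Z = standardize_traces(X)
    n_t = Z.shape[1]
    D = 1.0 - (Z @ Z.T) / n_t
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


class CorrelationKMeans(ClusterMixin, BaseEstimator):
    """K-means under correlation distance (Lloyd with re-standardised means).

    Initialisation is k-means++-style under correlation distance, with
    ``n_restarts`` seeded restarts; the best run by total within-cluster
    distance is kept.  When ``cell_ids`` are passed to :meth:`fit`, the
    seeded choices are keyed to the sorted cell-id order, so permuting the
    input rows permutes ``labels_`` identically.

    Attributes
    ----------
    labels_ : (n,) cluster index per cell, dense 0..k-1.
    cluster_centers_ : (k, T) standardised centroid traces.
    inertia_ : total within-cluster correlation distance.
    """

    distance = "correlation"

    def __init__(self, n_clusters: int = 3, n_restarts: int = 10,
                 max_iter: int = 300, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None, cell_ids=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = int(self.n_clusters)
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if X.shape[0] < k:
            raise ValueError("need at least n_clusters cells")

        if cell_ids is not None:
            order = np.argsort(np.asarray(cell_ids, dtype=object), kind="stable")
        else:
            order = np.arange(X.shape[0])
        Z = standardize_traces(X[order])
        n, n_t = Z.shape

        best = None
        rng = np.random.default_rng(self.random_state)
        for _ in range(max(1, int(self.n_restarts))):
            labels, centers, inertia = self._lloyd(Z, k, rng)
            if best is None or inertia < best[2]:
                best = (labels, centers, inertia)

        labels = np.empty(n, dtype=int)
        labels[order] = best[0]
        self.labels_ = labels
        self.cluster_centers_ = best[1]
        self.inertia_ = float(best[2])
        self.n_features_in_ = n_t
        return self

    def _dist_to_centers(self, Z, C):
        # rows of Z and C standardised: d = 1 - (z . c)/T
        return 1.0 - (Z @ C.T) / Z.shape[1]

    def _lloyd(self, Z, k, rng):
        n = Z.shape[0]
        # k-means++ seeding under correlation distance
        idx = [int(rng.integers(n))]
        while len(idx) < k:
            D = self._dist_to_centers(Z, Z[idx]).min(axis=1)
            D = np.clip(D, 0.0, None)
            p = D ** 2
            tot = p.sum()
            if tot <= 0:
                cand = int(rng.integers(n))
            else:
                cand = int(rng.choice(n, p=p / tot))
            idx.append(cand)
        C = Z[idx].copy()

        labels = np.full(n, -1)
        for _ in range(int(self.max_iter)):
            D = self._dist_to_centers(Z, C)
            new_labels = D.argmin(axis=1)
            for j in range(k):
                members = new_labels == j
                if not np.any(members):
                    # re-seed an empty cluster from the farthest point
                    far = int(D.min(axis=1).argmax())
                    logger.debug("re-seeding empty cluster %d from point %d", j, far)
                    C[j] = Z[far]
                    new_labels[far] = j
                    members = new_labels == j
                m = Z[members].mean(axis=0)
                sd = m.std()
                C[j] = (m - m.mean()) / sd if sd > 0 else m - m.mean()
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        inertia = float(self._dist_to_centers(Z, C)[np.arange(n), labels].sum())
        return labels, C, inertia

    def predict(self, X):
        Z = standardize_traces(np.atleast_2d(np.asarray(X, dtype=float)))
        return self._dist_to_centers(Z, self.cluster_centers_).argmin(axis=1)


def cluster_traces(traces, k: int, seed: int = 0, n_restarts: int = 10,
                   cell_ids=None) -> CorrelationKMeans:
    """Functional wrapper over :class:`CorrelationKMeans` (fitted estimator)."""
    est = CorrelationKMeans(n_clusters=k, n_restarts=n_restarts, random_state=seed)
    return est.fit(traces, cell_ids=cell_ids)


def split_regions(cell_meta: pd.DataFrame, z_threshold: float | None = None,
                  dorsal_smaller_z: bool = True):
    """Partition habenula cells into dorsal and ventral index masks.

    Uses the ``region`` column when present; otherwise a ``z`` position and a
    configured threshold (by convention smaller z = dorsal, configurable).
    """
    n = len(cell_meta)
    region = cell_meta["region"] if "region" in cell_meta else pd.Series([None] * n)
    has_region = region.isin(["dorsal", "ventral"]).to_numpy()
    dorsal = np.zeros(n, dtype=bool)
    ventral = np.zeros(n, dtype=bool)
    dorsal[has_region] = (region[has_region] == "dorsal").to_numpy()
    ventral[has_region] = (region[has_region] == "ventral").to_numpy()

    rest = ~has_region
    if np.any(rest):
        if "z" not in cell_meta or z_threshold is None:
            bad = cell_meta.index[rest].tolist()
            raise ValueError("cells missing both region label and z position "
                             f"(rows {bad[:10]}{'...' if len(bad) > 10 else ''})")
        z = cell_meta.loc[rest, "z"].to_numpy(dtype=float)
        if np.any(~np.isfinite(z)):
            bad = cell_meta.index[rest][~np.isfinite(z)].tolist()
            raise ValueError(f"cells with non-finite z position: rows {bad[:10]}")
        is_dorsal = z < z_threshold if dorsal_smaller_z else z >= z_threshold
        dorsal[np.flatnonzero(rest)] = is_dorsal
        ventral[np.flatnonzero(rest)] = ~is_dorsal
    return dorsal, ventral


def select_k(traces, k_range=range(2, 11), seed: int = 0,
             n_restarts: int = 10, cell_ids=None) -> dict:
    """Per-k diagnostics (within-cluster distance sum, mean silhouette).

    Supports the judgement of the optimal k; does not commit to one.  When
    traces are (near-)identical the diagnostics are flagged degenerate and
    the silhouette is NaN.
    """
    X = np.atleast_2d(np.asarray(traces, dtype=float))
    D = correlation_distance_matrix(X)
    degenerate = bool(np.all(D < 1e-12))
    out = {}
    for k in k_range:
        if not 2 <= k <= X.shape[0]:
            raise ValueError(f"k={k} outside [2, n_cells]")
        est = cluster_traces(X, k, seed=seed, n_restarts=n_restarts,
                             cell_ids=cell_ids)
        if degenerate or len(np.unique(est.labels_)) < 2:
            sil = float("nan")
        else:
            sil = float(silhouette_score(D, est.labels_, metric="precomputed"))
        out[int(k)] = {"inertia": est.inertia_, "silhouette": sil,
                       "degenerate": degenerate}
    return out


class SubtypeLabeling(dict):
    """cluster index -> region-qualified subtype name, with diagnostics."""

    def __init__(self, mapping: dict, diagnostics: pd.DataFrame):
        super().__init__(mapping)
        self.diagnostics = diagnostics


def label_clusters(centroids, protocol: LightProtocol, region: str,
                   on_tol: float = 1e-9, tie_tol: float = 1e-6,
                   phasic_peak_window: float = 5.0,
                   phasic_late_window: tuple = (10.0, 20.0)) -> SubtypeLabeling:
    """Name the three per-region centroids by stimulus-locked indices.

    ON-index = mean over light windows - mean over dark windows; the cluster
    with the largest (positive) ON-index is the ON-Tonic type.  Of the two
    remaining clusters, the phasic-index is the post-offset peak (within
    ``phasic_peak_window`` s of a light offset) divided by the late-dark mean
    (``phasic_late_window`` s after offset); the larger ratio is OFF-Phasic,
    the other OFF-Tonic.  Indices are computed on centroids shifted to
    minimum 0 so the ratio is well defined for z-scored traces.  Ties within
    tolerance raise :class:`AmbiguousLabelingError` rather than guessing.
    """
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    if C.shape[0] != 3:
        raise ValueError("expected exactly 3 centroids per region")
    if region not in ("dorsal", "ventral"):
        raise ValueError("region must be 'dorsal' or 'ventral'")
    prefix = "D-" if region == "dorsal" else "V-"
    t = protocol.time_axis
    if C.shape[1] != t.size:
        raise ValueError("centroid length does not match protocol time axis")
    light = protocol.light_mask()
    dark = ~light

    on_index = C[:, light].mean(axis=1) - C[:, dark].mean(axis=1)
    order = np.argsort(on_index)[::-1]
    if on_index[order[0]] <= on_tol:
        raise AmbiguousLabelingError(
            f"no centroid with positive ON-index (indices: {on_index.round(6).tolist()})")
    if abs(on_index[order[0]] - on_index[order[1]]) <= tie_tol:
        raise AmbiguousLabelingError(
            f"ON-index tie between clusters {order[0]} and {order[1]}")
    on_cluster = int(order[0])

    rest = [i for i in range(3) if i != on_cluster]
    ratios = {}
    for i in rest:
        c = C[i] - C[i].min()           # shift so the ratio is sign-safe
        scale = max(c.max(), 1e-12)
        peaks, lates = [], []
        for off in protocol.offsets:
            pk_sel = (t >= off) & (t <= off + phasic_peak_window)
            lt_sel = (t >= off + phasic_late_window[0]) & (t < off + phasic_late_window[1])
            if pk_sel.any() and lt_sel.any():
                peaks.append(c[pk_sel].max())
                lates.append(c[lt_sel].mean())
        peak = float(np.mean(peaks))
        late = float(np.mean(lates))
        ratios[i] = peak / max(late, 1e-3 * scale)
    a, b = rest
    if abs(ratios[a] - ratios[b]) <= tie_tol * max(abs(ratios[a]), abs(ratios[b]), 1.0):
        raise AmbiguousLabelingError(
            f"phasic-index tie between clusters {a} and {b} ({ratios})")
    phasic_cluster = a if ratios[a] > ratios[b] else b
    tonic_cluster = b if phasic_cluster == a else a

    mapping = {
        on_cluster: prefix + "ON-Tonic",
        tonic_cluster: prefix + "OFF-Tonic",
        phasic_cluster: prefix + "OFF-Phasic",
    }
    diag = pd.DataFrame({
        "cluster": range(3),
        "on_index": on_index,
        "phasic_index": [ratios.get(i, np.nan) for i in range(3)],
        "subtype": [mapping[i] for i in range(3)],
    })
    assert set(mapping.values()) <= set(SUBTYPES)
    return SubtypeLabeling(mapping, diag)
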