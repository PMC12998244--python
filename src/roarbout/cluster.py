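"""K-means call-type clustering on the standardized two-feature table.

Two variants mirror the analysis: k=4 with all call types, and k=3 after
moans are removed (moans overlap the roars in duration at low frequency,
so dropping them is what makes the two simple features sufficient).
Cluster indices are arbitrary, so a mapping step names them: against
reference labels, the optimal one-to-one (Hungarian) assignment; without
labels, a duration-rank heuristic that codifies "pick the long, high
cluster as the full-throated roars".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .audio import CallAnnotation
from .features import FeatureTable, build_features, standardize

__all__ = ["ClusterResult", "kmeans", "map_clusters", "predict_ftr"]

log = logging.getLogger(__name__)

#: duration-rank heuristic for k=3 (moans removed): longest to shortest.
_DURATION_RANK_LABELS = ("full_throated_roar", "intermediary_roar", "grunt")


@dataclass(frozen=True)
class ClusterResult:
    """Assignments + centroids of one k-means run on a standardized table."""

    table: FeatureTable
    assignments: np.ndarray
    centroids: np.ndarray  # (k, 2) in standardized feature space
    inertia: float
    label_map: dict[int, str] | None = None

    @property
    def k(self) -> int:
        return len(self.centroids)

    def predicted_labels(self) -> np.ndarray:
        if self.label_map is None:
            raise ValueError("no label_map; run map_clusters first")
        return np.array([self.label_map[int(c)] for c in self.assignments])

    def centroids_unstandardized(self) -> np.ndarray:
        """Centroids back in (seconds, Hz) units."""
        if self.table.scaler is None:
            return self.centroids
        out = self.centroids.copy()
        from .features import FEATURES

        for j, name in enumerate(FEATURES):
            mean, sd = self.table.scaler[name]
            out[:, j] = out[:, j] * sd + mean
        return out


def kmeans(table: FeatureTable, k: int, seed: int = 0, n_init: int = 10) -> ClusterResult:
    """Lloyd's k-means on the standardized table; best of ``n_init`` seeded
    starts by inertia, deterministic given ``seed``."""
    if not table.is_standardized:
        raise ValueError("table must be standardized before clustering")
    if k < 2:
        raise ValueError("k must be >= 2")
    x = table.values()
    if len(x) < k:
        raise ValueError(f"need at least k={k} rows, got {len(x)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    return ClusterResult(
        table=table,
        assignments=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def map_clusters(result: ClusterResult, reference_labels=None) -> ClusterResult:
    """Attach a cluster -> call-type map.

    With ``reference_labels``: the one-to-one assignment maximizing
    agreement (Hungarian on the cluster-by-label contingency table);
    requires k == number of distinct labels. Without labels (k=3 only):
    rank centroids by unstandardized duration, longest = full-throated
    roar, middle = intermediary roar, shortest = grunt.
    """
    if reference_labels is not None:
        reference_labels = np.asarray(reference_labels)
        if len(reference_labels) != len(result.assignments):
            raise ValueError("reference_labels length mismatch")
        classes = sorted(set(reference_labels.tolist()))
        if len(classes) != result.k:
            raise ValueError(
                f"k={result.k} but {len(classes)} distinct reference labels; "
                "cannot build a one-to-one mapping"
            )
        contingency = np.zeros((result.k, len(classes)))
        class_index = {c: j for j, c in enumerate(classes)}
        for cl, lab in zip(result.assignments, reference_labels):
            contingency[cl, class_index[lab]] += 1
        rows, cols = linear_sum_assignment(-contingency)
        label_map = {int(r): classes[c] for r, c in zip(rows, cols)}
        return replace(result, label_map=label_map)

    if result.k != len(_DURATION_RANK_LABELS):
        raise ValueError("heuristic mapping is defined for k=3 (moans removed)")
    durations = result.centroids_unstandardized()[:, 0]
    order = np.argsort(-durations)  # longest first; ties keep lower cluster index
    label_map = {int(cluster): _DURATION_RANK_LABELS[rank] for rank, cluster in enumerate(order)}
    return replace(result, label_map=label_map)


def predict_ftr(annotations: list[CallAnnotation], seed: int = 0,
                n_init: int = 10) -> list[CallAnnotation]:
    """Data-driven full-throated-roar selection.

    Moans must have been removed upstream. Clusters the remaining calls
    at k=3 on (duration, max frequency), names the clusters with the
    duration-rank heuristic and returns the calls in the
    full-throated-roar cluster.
    """
    if any(a.call_type == "moan" for a in annotations):
        raise ValueError("remove moans before predicting full-throated roars")
    if len(annotations) < 3:
        raise ValueError("need at least 3 calls to form 3 clusters")
    table = standardize(build_features(annotations))
    result = map_clusters(kmeans(table, k=3, seed=seed, n_init=n_init))
    labels = result.predicted_labels()
    kept = [ann for ann, lab in zip(annotations, labels) if lab == "full_throated_roar"]
    if not kept:
        log.warning("no calls fell in the full-throated-roar cluster")
    return kept
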