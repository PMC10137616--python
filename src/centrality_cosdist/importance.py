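"""Which centralities matter? Unsupervised labels + permutation importance.

Nodes are clustered in centrality space (DBSCAN or K-means on z-scored
features); a random forest is then trained to predict the cluster labels
from the centralities, and the importance of each centrality is the mean
drop in held-out accuracy when that column is shuffled. The seed-dependent
personalised-PageRank column and the duplicated eigenvector column are
excluded: the former is meaningless without a seed context and the latter
is redundant by construction.

The top-three importances can be renormalised to barycentric (ternary)
coordinates, the representation used to compare many networks at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_perm_importance
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .centrality import feature_subset

__all__ = [
    "ClusterLabels",
    "ImportanceReport",
    "cluster_nodes",
    "permutation_importance",
    "ternary_coordinates",
    "EXCLUDED_FOR_IMPORTANCE",
    "DEFAULT_TERNARY_MEASURES",
]

#: Columns dropped before the importance analysis.
EXCLUDED_FOR_IMPORTANCE: tuple[str, ...] = ("personalized_pagerank", "eigenvector_dup")

#: The trio shown on the ternary plot by default.
DEFAULT_TERNARY_MEASURES: tuple[str, str, str] = ("closeness", "eigenvector", "information")


class DegenerateLabelingError(RuntimeError):
    """Clustering produced labels unusable as a classification target."""


@dataclass
class ClusterLabels:
    """Integer cluster label per node; −1 marks density-clustering noise."""

    node_ids: list[str]
    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.node_ids, name="label")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels >= 0]))


@dataclass
class ImportanceReport:
    """Mean permutation-importance score per centrality for one labelling."""

    table: pd.DataFrame  # columns: measure, importance, importance_std
    method: str
    random_seed: int
    n_repeats: int
    test_accuracy: float

    def top(self, n: int = 3) -> list[str]:
        return (
            self.table.sort_values("importance", ascending=False)["measure"]
            .head(n)
            .tolist()
        )


def _knee_eps(X: np.ndarray, min_samples: int) -> float:
    """eps from the knee of the sorted k-NN distance curve.

    Takes the point of maximum distance to the chord joining the curve's
    endpoints (max-curvature heuristic).
    """
    k = min(min_samples, len(X) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dists = np.sort(nn.kneighbors(X)[0][:, -1])
    if dists[-1] == dists[0]:
        return float(dists[-1]) if dists[-1] > 0 else 0.5
    x = np.linspace(0.0, 1.0, len(dists))
    y = (dists - dists[0]) / (dists[-1] - dists[0])
    # distance from each point to the y = x chord
    knee = int(np.argmax(np.abs(y - x)))
    eps = float(dists[knee])
    return eps if eps > 0 else float(dists[dists > 0].min())


def cluster_nodes(
    matrix: pd.DataFrame,
    method: str = "kmeans",
    *,
    k: int = 4,
    eps: float | None = None,
    min_samples: int = 5,
    random_seed: int = 0,
    strict: bool = True,
) -> ClusterLabels:
    """Cluster nodes in centrality space (features z-scored internally).

    K-means uses ``k`` centroids (fixed seed for determinism); DBSCAN uses
    ``min_samples`` and either an explicit ``eps`` or one picked from the
    knee of the sorted ``min_samples``-NN distance curve. Raises
    :class:`DegenerateLabelingError` when the labels cannot serve as a
    classification target (all noise, or a single class); ``strict=False``
    returns such labels anyway for inspection.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 nodes to cluster")
    X = StandardScaler().fit_transform(matrix.to_numpy(dtype=float))
    params: dict = {}
    if method == "kmeans":
        k_eff = min(k, len(matrix))
        labels = KMeans(n_clusters=k_eff, random_state=random_seed, n_init=10).fit_predict(X)
        params = {"k": k_eff, "random_seed": random_seed}
    elif method == "dbscan":
        eps_eff = eps if eps is not None else _knee_eps(X, min_samples)
        labels = DBSCAN(eps=eps_eff, min_samples=min_samples).fit_predict(X)
        params = {"eps": eps_eff, "min_samples": min_samples}
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    result = ClusterLabels(
        node_ids=[str(i) for i in matrix.index], labels=labels, method=method, params=params
    )
    if strict:
        non_noise = labels[labels >= 0]
        if len(non_noise) == 0:
            raise DegenerateLabelingError(
                f"{method}: every point labelled noise; decrease min_samples or raise eps"
            )
        if len(set(labels)) < 2:
            raise DegenerateLabelingError(
                f"{method}: a single cluster; adjust parameters for usable labels"
            )
    return result


def permutation_importance(
    matrix: pd.DataFrame,
    labels: ClusterLabels,
    *,
    exclude: tuple[str, ...] | None = None,
    n_trees: int = 500,
    n_repeats: int = 10,
    random_seed: int = 0,
    test_fraction: float = 0.3,
) -> ImportanceReport:
    """Permutation importance of each centrality for predicting the labels.

    A random forest (``n_trees``, fixed seed) is fitted on a stratified
    70/30 split; each feature's importance is the mean accuracy drop over
    ``n_repeats`` independent shuffles of that column on the held-out
    split. Noise points (label −1) are excluded from both splits. Shuffling
    a constant column is a no-op, so its importance is exactly 0.
    """
    if exclude is None:
        exclude = tuple(m for m in EXCLUDED_FOR_IMPORTANCE if m in matrix.columns)
    feats = feature_subset(matrix, list(exclude)) if exclude else matrix
    y = labels.as_series().reindex(feats.index)
    if y.isna().any():
        raise ValueError("labels do not cover every node in the matrix")
    mask = y.to_numpy() >= 0
    X = feats.to_numpy(dtype=float)[mask]
    yv = y.to_numpy()[mask]
    classes, counts = np.unique(yv, return_counts=True)
    if len(classes) < 2:
        raise DegenerateLabelingError("single-class labels: importance undefined")
    stratify = yv if counts.min() >= 2 else None
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        yv,
        test_size=test_fraction,
        random_state=random_seed,
        stratify=stratify,
    )
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=random_seed)
    forest.fit(X_tr, y_tr)
    acc = float(forest.score(X_te, y_te))
    res = _sk_perm_importance(
        forest,
        X_te,
        y_te,
        n_repeats=n_repeats,
        random_state=random_seed,
        scoring="accuracy",
    )
    table = pd.DataFrame(
        {
            "measure": list(feats.columns),
            "importance": res.importances_mean,
            "importance_std": res.importances_std,
        }
    )
    return ImportanceReport(
        table=table,
        method=labels.method,
        random_seed=random_seed,
        n_repeats=n_repeats,
        test_accuracy=acc,
    )


def ternary_coordinates(
    reports: list[ImportanceReport] | ImportanceReport,
    measures: tuple[str, str, str] = DEFAULT_TERNARY_MEASURES,
) -> pd.DataFrame:
    """Barycentric coordinates of three measures' importances per report.

    Importances are clipped at 0 and renormalised to sum to 1, giving a
    point inside the simplex for each report. All three clipped
    importances being 0 leaves the point undefined and raises.
    """
    if isinstance(reports, ImportanceReport):
        reports = [reports]
    if len(measures) != 3:
        raise ValueError("exactly 3 measures required for ternary coordinates")
    rows = []
    for rep in reports:
        t = rep.table.set_index("measure")["importance"]
        missing = [m for m in measures if m not in t.index]
        if missing:
            raise KeyError(f"measures absent from report: {missing}")
        vals = np.clip(t.loc[list(measures)].to_numpy(dtype=float), 0.0, None)
        total = vals.sum()
        if total <= 0:
            raise ValueError(
                f"all three importances non-positive for report {rep.method!r}: "
                "ternary point undefined"
            )
        coords = vals / total
        rows.append({"method": rep.method, **dict(zip(measures, coords))})
    return pd.DataFrame(rows)
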