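"""Robust k-means over the expression space with CH-index model selection.

The number of clusters is not assumed: k-means is run for every k in a
range (2..50 by default), each with many k-means++ restarts, and the
optimum is the k maximizing the Calinski-Harabasz index — the ratio of
between-cluster to within-cluster dispersion, penalized for k.
Cluster/class agreement against annotated sample classes is summarized
by mapping each cluster to its modal class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class ClusteringResult:
    labels: pd.Series  # cluster label per sample
    k_opt: int
    ch_curve: pd.Series  # CH index per candidate k
    restarts: int
    seed: int

    def __post_init__(self):
        n_distinct = self.labels.nunique()
        if n_distinct != self.k_opt:
            raise ValueError(
                f"labels take {n_distinct} values but k_opt is {self.k_opt}"
            )


@dataclass
class AgreementSummary:
    per_class_percent: dict  # class -> percent of its samples correctly grouped
    overall_percent: float
    cluster_to_class: dict  # cluster label -> majority class


def ch_index(coords: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index ``[B/(k-1)] / [W/(n-k)]``.

    ``B`` is the between-cluster sum of squares (cluster sizes times
    squared centroid-to-grand-mean distances) and ``W`` the
    within-cluster sum of squares. Returns ``inf`` when ``W`` is 0
    (perfectly tight clusters).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    labels = np.asarray(labels)
    n = coords.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels and coordinates disagree in length")
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError(f"CH index requires k >= 2, got {k}")
    if n <= k:
        raise ValueError(f"CH index requires n > k (n={n}, k={k})")
    grand = coords.mean(axis=0)
    B = 0.0
    W = 0.0
    for lab in uniq:
        pts = coords[labels == lab]
        centroid = pts.mean(axis=0)
        B += len(pts) * float(np.sum((centroid - grand) ** 2))
        W += float(np.sum((pts - centroid) ** 2))
    if W == 0.0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def robust_kmeans(
    space,
    kmin: int = 2,
    kmax: int = 50,
    restarts: int = 50,
    seed: int = 0,
) -> ClusteringResult:
    """Best-of-restarts k-means over the retained axes for each k.

    ``space`` is an :class:`~pdxspace.mca.MCASpace` (its retained
    principal coordinates are clustered) or any DataFrame/array of
    sample coordinates. For each k in ``[kmin, min(kmax, n - 1)]`` the
    best of ``restarts`` k-means++ runs (Euclidean, tolerance 1e-8) is
    kept and scored by :func:`ch_index`; ``k_opt`` maximizes the CH
    curve (ties go to the smaller k). Deterministic given ``seed``.
    """
    if hasattr(space, "retained_coords"):
        frame = space.retained_coords()
    elif isinstance(space, pd.DataFrame):
        frame = space
    else:
        frame = pd.DataFrame(np.asarray(space, dtype=float))
    X = frame.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"clustering requires >= 3 samples, got {n}")
    if kmin < 2:
        raise ValueError(f"kmin must be >= 2, got {kmin}")
    kmax_eff = min(kmax, n - 1)
    if kmax_eff < kmin:
        raise ValueError(f"empty k range [{kmin}, {kmax_eff}]")

    rng = np.random.default_rng(seed)
    ch = {}
    best_labels = {}
    for k in range(kmin, kmax_eff + 1):
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=restarts,
            tol=1e-8,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X)
        lab = km.labels_
        if len(np.unique(lab)) < k or n <= k:
            continue  # degenerate solution at this k
        ch[k] = ch_index(X, lab)
        best_labels[k] = lab
    if not ch:
        raise RuntimeError("no valid clustering found in the requested k range")
    curve = pd.Series(ch).sort_index()
    k_opt = int(curve.idxmax())
    return ClusteringResult(
        labels=pd.Series(best_labels[k_opt], index=frame.index, name="cluster"),
        k_opt=k_opt,
        ch_curve=curve,
        restarts=restarts,
        seed=seed,
    )


def classification_agreement(labels, classes) -> AgreementSummary:
    """How well unsupervised clusters recover annotated classes.

    Each cluster is mapped to its modal class (ties broken by the
    lexicographically smaller class id); a sample counts as correctly
    grouped when its cluster maps to its own class. Percentages are
    reported per class and overall.
    """
    labels = pd.Series(np.asarray(labels))
    classes = pd.Series(np.asarray(classes))
    if len(labels) != len(classes):
        raise ValueError(
            f"labels ({len(labels)}) and classes ({len(classes)}) differ in length"
        )
    mapping = {}
    for cl in labels.unique():
        counts = classes[labels.to_numpy() == cl].value_counts()
        top = counts[counts == counts.max()].index
        mapping[cl] = sorted(top)[0]
    assigned = labels.map(mapping)
    correct = assigned.to_numpy() == classes.to_numpy()
    per_class = {}
    for cls in sorted(classes.unique()):
        mask = classes.to_numpy() == cls
        per_class[cls] = 100.0 * correct[mask].mean()
    return AgreementSummary(
        per_class_percent=per_class,
        overall_percent=100.0 * correct.mean(),
        cluster_to_class=mapping,
    )
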