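"""Multiple correspondence analysis of binary call matrices.

Each gene in a call matrix is a categorical variable with two levels
(expressed / silenced). Coding both levels as indicator columns and
running correspondence analysis on the resulting samples x indicator
table yields an "expression space": a Euclidean embedding in which
inter-sample distances approximate chi-square distances between call
profiles. This is the categorical analogue of PCA on intensities.

The informative (leading) dimensions of the space are selected by a
paired Wilcoxon signed-rank test between the absolute coordinates of
contiguous axes: an additional axis enters the space only while the
test keeps rejecting at the chosen significance level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: axes beyond this rank are not stored (inertias are kept for all axes)
MAX_STORED_AXES = 50

#: singular values below this are treated as numerically zero inertia
_SV_TOL = 1e-12


@dataclass
class MCASpace:
    """Sample embedding produced by :func:`mca`.

    Attributes
    ----------
    sample_coords : DataFrame
        Principal coordinates, samples x stored axes (columns "axis1"...).
    axis_inertia : ndarray
        Principal inertia (squared singular value) of every computed
        axis, non-increasing; may be longer than the stored coordinates.
    variance_fraction : ndarray
        ``axis_inertia`` divided by the total inertia.
    retained_dims : int
        Number of leading informative axes (1 until
        :func:`select_dimensions` is run).
    axis_pvalues : list of float
        Wilcoxon p-value for each tested contiguous axis pair
        (pair i compares axes i+1 and i+2).
    n_genes_used : int
        Non-constant genes that entered the analysis.
    """

    sample_coords: pd.DataFrame
    axis_inertia: np.ndarray
    variance_fraction: np.ndarray
    retained_dims: int = 1
    axis_pvalues: list = field(default_factory=list)
    n_genes_used: int = 0

    @property
    def n_axes(self) -> int:
        return self.sample_coords.shape[1]

    @property
    def total_inertia(self) -> float:
        return float(self.axis_inertia.sum())

    def retained_coords(self) -> pd.DataFrame:
        """Coordinates restricted to the informative axes."""
        return self.sample_coords.iloc[:, : self.retained_dims]

    def adjusted_variance_fraction(self) -> np.ndarray:
        """Benzecri-adjusted inertia fractions.

        Raw MCA inertias are known to understate the structure of the
        data because the indicator coding inflates the total inertia.
        The Benzecri correction rescales each principal inertia
        ``lam`` above the 1/Q threshold (Q = number of variables) to
        ``((Q / (Q - 1)) * (lam - 1 / Q)) ** 2`` and renormalizes over
        the surviving axes; axes at or below the threshold get 0.
        """
        Q = self.n_genes_used
        if Q < 2:
            raise ValueError("adjusted inertias require >= 2 genes")
        lam = self.axis_inertia
        adj = np.where(lam > 1.0 / Q, (Q / (Q - 1.0) * (lam - 1.0 / Q)) ** 2, 0.0)
        total = adj.sum()
        if total <= 0:
            return np.zeros_like(adj)
        return adj / total


def mca(C: pd.DataFrame, max_axes: int = MAX_STORED_AXES) -> MCASpace:
    """Correspondence analysis of the indicator-coded call matrix.

    Parameters
    ----------
    C : DataFrame
        Binary calls, genes x samples, values in {0, 1}; >= 3 samples
        and >= 2 non-constant genes.
    max_axes : int
        Cap on the number of axes whose coordinates are stored.

    Returns
    -------
    MCASpace
        Principal sample coordinates with axis signs fixed so that the
        largest-magnitude coordinate on every axis is positive.

    Notes
    -----
    Constant genes carry no inertia and are dropped (logged). The
    indicator table ``N`` has one "expressed" and one "silenced" column
    per gene; with ``P = N / N.sum()``, row masses ``r`` and column
    masses ``c``, the standardized residuals
    ``S = Dr^(-1/2) (P - r c^T) Dc^(-1/2)`` are decomposed by SVD and
    sample principal coordinates are ``Dr^(-1/2) U Sigma``.
    """
    vals = C.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("call matrix must be strictly binary")
    n_samples = C.shape[1]
    if n_samples < 3:
        raise ValueError(f"MCA requires >= 3 samples, got {n_samples}")

    nonconst = vals.std(axis=1) > 0
    n_dropped = int((~nonconst).sum())
    if n_dropped:
        logger.info("mca: dropped %d constant genes", n_dropped)
    vals = vals[nonconst]
    n_genes = vals.shape[0]
    if n_genes < 2:
        raise ValueError("MCA requires >= 2 non-constant genes")

    # samples x (2 * genes) indicator table: expressed, silenced per gene
    N = np.empty((n_samples, 2 * n_genes), dtype=float)
    N[:, 0::2] = vals.T
    N[:, 1::2] = 1.0 - vals.T

    total = N.sum()
    P = N / total
    r = P.sum(axis=1)  # = 1/n_samples for complete binary coding
    c = P.sum(axis=0)
    keep_cols = c > 0
    S = (P[:, keep_cols] - np.outer(r, c[keep_cols])) / np.sqrt(
        np.outer(r, c[keep_cols])
    )

    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    pos = sv > _SV_TOL
    U, sv = U[:, pos], sv[pos]

    inertia = sv**2
    total_inertia = float(inertia.sum())
    coords = (U * sv) / np.sqrt(r)[:, None]

    # deterministic sign convention: extreme sample points positive
    flip = coords[np.abs(coords).argmax(axis=0), np.arange(coords.shape[1])] < 0
    coords[:, flip] *= -1.0

    n_store = min(max_axes, coords.shape[1])
    frame = pd.DataFrame(
        coords[:, :n_store],
        index=C.columns,
        columns=[f"axis{i + 1}" for i in range(n_store)],
    )
    return MCASpace(
        sample_coords=frame,
        axis_inertia=inertia,
        variance_fraction=inertia / total_inertia,
        retained_dims=1,
        n_genes_used=n_genes,
    )


def _contiguous_axis_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired signed-rank p-value between |coords| of two axes.

    Exact null distribution for n <= 25, otherwise the normal
    approximation with continuity correction. All-zero differences
    (identical spread) give p = 1.
    """
    d = np.abs(a) - np.abs(b)
    if np.all(d == 0):
        return 1.0
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        alternative="two-sided",
        correction=True,
        method=method,
    )
    return float(res.pvalue)


def select_dimensions(space: MCASpace, alpha: float = 0.01) -> int:
    """Pick the number of informative axes of an MCA space.

    Axis 1 is always informative. Axis d+1 joins the space iff axis d
    is informative and the paired Wilcoxon signed-rank test between the
    absolute sample coordinates of axes d and d+1 rejects at ``alpha``
    (the spreads differ, i.e. axis d+1 still adds a distinct amount of
    structure). The walk stops at the first non-rejection; p-values for
    every tested pair are stored on the space.

    Returns the retained dimension count (also written to
    ``space.retained_dims``).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    coords = space.sample_coords.to_numpy()
    n_axes = coords.shape[1]
    if n_axes < 2:
        warnings.warn("space has a single axis; retaining 1 dimension", stacklevel=2)
        space.retained_dims = 1
        space.axis_pvalues = []
        return 1

    pvalues = []
    retained = 1
    for d in range(n_axes - 1):
        p = _contiguous_axis_pvalue(coords[:, d], coords[:, d + 1])
        pvalues.append(p)
        if retained == d + 1 and p < alpha:
            retained = d + 2
        elif retained <= d + 1:
            break
    space.axis_pvalues = pvalues
    space.retained_dims = retained
    return retained
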