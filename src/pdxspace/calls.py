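"""Binary expressed/silenced calls from normalized intensities.

Microarray barcoding declares a gene "expressed" in a sample when its
normalized intensity lies far above the silenced mode of that feature's
intensity distribution. The original barcode method z-scores each value
against frozen multi-array reference parameters; here the silenced-mode
location and spread are estimated from the dataset itself (lower-half
median / MAD), with the option to load an externally derived reference
table instead.

All matrices are pandas DataFrames with features (probes or genes) in
rows and samples in columns.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: floor applied to the silenced-mode scale so z-scores stay finite
SIGMA_EPSILON = 1e-6

#: default z-score cutoff separating expressed from silenced
DEFAULT_TAU = 5.0


def _check_matrix(X: pd.DataFrame) -> None:
    if X.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if X.index.has_duplicates:
        dupes = X.index[X.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated feature ids: {dupes[:5]}")
    if X.columns.has_duplicates:
        dupes = X.columns[X.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample ids: {dupes[:5]}")


def estimate_reference_null(X: pd.DataFrame, epsilon: float = SIGMA_EPSILON) -> pd.DataFrame:
    """Estimate per-feature silenced-mode parameters from the data.

    For each feature, the silenced mode is located by the median of the
    values at or below the feature's overall median (ties at the median
    are included), and its spread by 1.4826 x MAD of that same lower
    half, floored at ``epsilon``. For a feature silenced in at least
    half the samples this recovers the silenced-mode center and scale
    without being dragged by the expressed mode.

    Parameters
    ----------
    X : DataFrame
        Normalized intensities, features x samples; >= 4 samples.
    epsilon : float
        Lower bound on the returned scale.

    Returns
    -------
    DataFrame with columns ``mu`` and ``sigma`` indexed by feature.
    """
    _check_matrix(X)
    if X.shape[1] < 4:
        raise ValueError(f"need >= 4 samples to estimate a reference null, got {X.shape[1]}")
    V = X.to_numpy(dtype=float)
    med = np.median(V, axis=1, keepdims=True)
    lower = np.where(V <= med, V, np.nan)
    mu = np.nanmedian(lower, axis=1)
    mad = np.nanmedian(np.abs(lower - mu[:, None]), axis=1)
    sigma = np.maximum(1.4826 * mad, epsilon)
    return pd.DataFrame({"mu": mu, "sigma": sigma}, index=X.index)


def barcode_calls(X: pd.DataFrame, ref: pd.DataFrame, tau: float = DEFAULT_TAU) -> pd.DataFrame:
    """Convert intensities to binary calls by z-scoring against ``ref``.

    A feature is called expressed (1) in a sample iff
    ``(x - mu) / sigma > tau``; otherwise silenced (0).
    """
    _check_matrix(X)
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    missing = X.index.difference(ref.index)
    if len(missing) > 0:
        raise KeyError(
            f"{len(missing)} features missing from the reference null: "
            f"{missing[:10].tolist()}"
        )
    ref = ref.loc[X.index]
    if (ref["sigma"] <= 0).any():
        raise ValueError("reference null contains non-positive sigma")
    z = (X.to_numpy(dtype=float) - ref["mu"].to_numpy()[:, None]) / ref["sigma"].to_numpy()[:, None]
    calls = (z > tau).astype(np.int8)
    return pd.DataFrame(calls, index=X.index, columns=X.columns)


def collapse_probes(calls: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level call matrix to gene level.

    A gene is called expressed in a sample if any of its probes is
    expressed (logical OR). Probes absent from the map are dropped with
    a logged count.

    Parameters
    ----------
    calls : DataFrame
        Probe-level binary calls, probes x samples.
    probe_map : Series
        probe id -> gene symbol (many probes may map to one gene; each
        probe appears at most once).
    """
    if probe_map.index.has_duplicates:
        raise ValueError("probe map assigns some probes more than once")
    mapped = calls.index.intersection(probe_map.index)
    n_dropped = calls.shape[0] - len(mapped)
    if len(mapped) == 0:
        raise ValueError("no probe of the call matrix is present in the probe map")
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    sub = calls.loc[mapped]
    genes = probe_map.loc[mapped]
    collapsed = sub.groupby(genes.to_numpy()).max()
    collapsed.index.name = calls.index.name
    return collapsed.astype(np.int8)


def exclude_genes(C: pd.DataFrame, genes) -> pd.DataFrame:
    """Drop the rows of ``C`` named in ``genes``, preserving row order.

    ``genes`` may be any iterable of ids or a signature object with a
    ``genes`` attribute. Signature genes absent from the matrix are
    ignored (with a warning when none are present).
    """
    symbols = set(getattr(genes, "genes", genes))
    keep = ~C.index.isin(symbols)
    if keep.all() and symbols:
        warnings.warn("none of the excluded genes are present in the matrix", stacklevel=2)
        return C
    if not keep.any():
        raise ValueError("excluding these genes would remove every row")
    return C.loc[keep]
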