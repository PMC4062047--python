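"""Stromal/immune infiltration scoring and expression-space correction.

Bulk tumor samples are mixtures of tumoral cells and human non-tumoral
infiltrating (hNTI) cells — stroma and immune infiltrate. Xenografted
tumors lose this human compartment (murine stroma is invisible to a
human array), so infiltration differences masquerade as tumor-cell
expression differences between primaries and model systems.

Infiltration is quantified per sample by rank-based single-sample
enrichment of stromal and immune gene signatures on the continuous
intensities (the scoring statistic of the ESTIMATE family of methods);
the combined (stromal + immune) score is then used as the explanatory
variable in per-axis linear regressions, and the regression residuals
define an expression space corrected for the infiltration trend.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

#: ESTIMATE's published rank-weight exponent
DEFAULT_ALPHA = 0.25


@dataclass
class AxisFit:
    """Simple regression of one MCA axis on the combined score."""

    axis: str
    slope: float
    intercept: float
    r_squared: float
    pvalue: float


def ssgsea_score(
    X: pd.DataFrame, signature, alpha: float = DEFAULT_ALPHA
) -> pd.Series:
    """Single-sample rank-based enrichment score of a gene signature.

    For each sample, genes are ordered by decreasing expression (ties
    broken by gene id). Walking down this ranking, the in-signature
    cumulative weight ``P_G`` (rank weights ``(N - position)`` raised
    to ``alpha``, normalized by the in-signature total) is compared
    with the out-of-signature cumulative count ``P_NG``; the score is
    the sum of ``P_G - P_NG`` over all positions. Positive scores mean
    the signature concentrates at the top of the sample's ranking.

    The statistic is rank-based, hence invariant to any strictly
    monotone transform of a sample's expression values.
    """
    sig_genes = set(getattr(signature, "genes", signature))
    present = X.index.intersection(sig_genes)
    if len(present) < 2:
        missing = sorted(sig_genes - set(X.index))
        raise ValueError(
            f"need >= 2 signature genes in the matrix, found {len(present)} "
            f"(missing e.g. {missing[:10]})"
        )
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")

    vals = X.to_numpy(dtype=float)
    n_genes, n_samples = vals.shape
    in_set = X.index.isin(present).astype(bool)
    # precomputed tiebreak: alphabetical rank of each gene id
    id_order = np.argsort(np.argsort(X.index.to_numpy()))
    n_out = n_genes - len(present)
    if n_out == 0:
        raise ValueError("signature covers the whole matrix; score undefined")

    scores = np.empty(n_samples)
    for s in range(n_samples):
        # descending by value, ascending by gene id on ties
        order = np.lexsort((id_order, -vals[:, s]))
        hits = in_set[order]
        w = (n_genes - np.arange(n_genes)).astype(float) ** alpha
        w_hit = np.where(hits, w, 0.0)
        p_g = np.cumsum(w_hit) / w_hit.sum()
        p_ng = np.cumsum(~hits) / n_out
        scores[s] = np.sum(p_g - p_ng)
    return pd.Series(scores, index=X.columns, name=getattr(signature, "name", "score"))


def infiltration_scores(
    X: pd.DataFrame, stromal, immune, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Per-sample stromal, immune and combined infiltration scores.

    Returns a DataFrame with columns ``stromal``, ``immune`` and
    ``combined`` (= stromal + immune), one row per sample. Higher
    combined scores indicate a larger non-tumoral cell fraction.
    """
    s = ssgsea_score(X, stromal, alpha=alpha)
    i = ssgsea_score(X, immune, alpha=alpha)
    return pd.DataFrame({"stromal": s, "immune": i, "combined": s + i})


def correct_space(space, scores: pd.DataFrame):
    """Regress the infiltration trend out of each retained axis.

    Every retained axis is regressed (ordinary least squares) on the
    combined infiltration score; the corrected coordinate is the
    regression residual. Axes beyond ``retained_dims`` are left
    untouched, as are the stored inertias (the corrected space keeps
    the original axis scaling).

    Returns ``(corrected_space, fits)`` where ``fits`` is a list of
    :class:`AxisFit`. Correcting an already-corrected space is a
    no-op (residuals are orthogonal to the score).
    """
    combined = scores["combined"] if isinstance(scores, pd.DataFrame) else pd.Series(scores)
    coords = space.sample_coords
    missing = coords.index.difference(combined.index)
    if len(missing) > 0:
        raise ValueError(f"no infiltration score for samples: {missing[:5].tolist()}")
    x = combined.loc[coords.index].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("combined score is constant; cannot fit the infiltration trend")

    corrected = coords.copy()
    fits = []
    for axis in coords.columns[: space.retained_dims]:
        y = coords[axis].to_numpy(dtype=float)
        res = stats.linregress(x, y)
        corrected[axis] = y - (res.intercept + res.slope * x)
        fits.append(
            AxisFit(
                axis=axis,
                slope=float(res.slope),
                intercept=float(res.intercept),
                r_squared=float(res.rvalue**2),
                pvalue=float(res.pvalue),
            )
        )
    new_space = replace(space, sample_coords=corrected)
    return new_space, fits
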