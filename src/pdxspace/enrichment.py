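"""Expression frequencies, preranked GSEA, and overlap enrichment.

Groups of samples are compared on the fraction of samples in which each
gene is called expressed (its *expression frequency*); the per-gene
difference of frequencies between two groups (e.g. primary tumors minus
xenografts) ranks the genome for a preranked gene-set enrichment
analysis. The GSEA engine is the classic weighted Kolmogorov-Smirnov
running sum with a gene-label permutation null, normalized enrichment
scores, and a sign-stratified pooled-null false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: published GSEA defaults for testable set sizes
DEFAULT_MIN_SIZE = 15
DEFAULT_MAX_SIZE = 500

#: per-gene variance floor used by the t-statistic ranking
_VAR_FLOOR = 1e-8


@dataclass
class RankedList:
    """Gene ids ordered by a real metric, descending (ties by gene id)."""

    genes: np.ndarray
    metric: np.ndarray

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        frame = s.rename("metric").rename_axis("gene").reset_index()
        frame = frame.sort_values(["metric", "gene"], ascending=[False, True])
        return cls(
            genes=frame["gene"].to_numpy(),
            metric=frame["metric"].to_numpy(dtype=float),
        )

    def __len__(self):
        return len(self.genes)

    def to_series(self) -> pd.Series:
        return pd.Series(self.metric, index=self.genes, name="metric")


@dataclass
class EnrichmentResult:
    """Per-set preranked GSEA statistics."""

    table: pd.DataFrame  # index: set name; columns es, nes, pval, fdr, size, direction
    leading_edge: dict  # set name -> list of core genes
    n_perm: int
    seed: int

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] < fdr]


def expression_frequency(C: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-gene expression frequency within each sample group.

    ``groups`` maps every sample (column of ``C``) to a group label;
    the result is genes x groups with values in [0, 1]. Stores group
    sizes in ``result.attrs['group_sizes']``.
    """
    groups = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    missing = C.columns.difference(groups.index)
    if len(missing) > 0:
        raise ValueError(f"samples without a group assignment: {missing[:5].tolist()}")
    g = groups.loc[C.columns]
    if g.isna().any():
        raise ValueError("missing group labels")
    freq = C.T.groupby(g.to_numpy()).mean().T
    sizes = g.value_counts().to_dict()
    if any(v == 0 for v in sizes.values()):
        raise ValueError("empty group")
    freq.attrs["group_sizes"] = sizes
    return freq


def frequency_difference(freq: pd.DataFrame, group_a: str, group_b: str) -> RankedList:
    """Rank genes by frequency(group_a) - frequency(group_b), descending.

    With ``group_a`` the primary tumors and ``group_b`` the xenografts
    this is the contrast used to ask which genes are preferentially
    silenced or activated upon engraftment.
    """
    for grp in (group_a, group_b):
        if grp not in freq.columns:
            raise KeyError(f"unknown group {grp!r}; have {list(freq.columns)}")
    return RankedList.from_series(freq[group_a] - freq[group_b])


def _running_es(metric_sorted: np.ndarray, hit_mask: np.ndarray):
    """ES and extremum position of one weighted running sum (weight p=1)."""
    n = len(metric_sorted)
    n_hit = int(hit_mask.sum())
    w = np.abs(metric_sorted) * hit_mask
    total = w.sum()
    if total == 0:  # degenerate all-zero metric over hits: fall back to equal weights
        w = hit_mask.astype(float)
        total = w.sum()
    delta = w / total - (~hit_mask) / (n - n_hit)
    running = np.cumsum(delta)
    pos = int(np.argmax(np.abs(running)))
    return float(running[pos]), pos


def _null_es(metric_sorted: np.ndarray, n_hit: int, n_perm: int, rng) -> np.ndarray:
    """Null ES from random hit-position draws (gene-label permutation)."""
    n = len(metric_sorted)
    absm = np.abs(metric_sorted)
    # random n_hit positions per permutation
    idx = np.argpartition(rng.random((n_perm, n)), n_hit, axis=1)[:, :n_hit]
    hit_w = absm[idx]
    totals = hit_w.sum(axis=1)
    zero = totals == 0
    if zero.any():
        hit_w[zero] = 1.0
        totals[zero] = n_hit
    delta = np.full((n_perm, n), -1.0 / (n - n_hit))
    rows = np.repeat(np.arange(n_perm), n_hit)
    delta[rows, idx.ravel()] = (hit_w / totals[:, None]).ravel()
    running = np.cumsum(delta, axis=1)
    pos = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), pos]


def gsea_preranked(
    ranked: RankedList,
    sets: dict,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked GSEA over a collection of gene sets.

    Parameters
    ----------
    ranked : RankedList
        Genome ranked by a signed metric, descending.
    sets : dict
        set name -> iterable of gene ids (GMT semantics). Sets are
        intersected with the ranked universe and then filtered to
        ``[min_size, max_size]`` members.
    n_perm : int
        Gene-label permutations for the null; >= 100.
    seed : int
        Makes the permutation null reproducible.

    Notes
    -----
    ES is the maximum deviation of the running sum whose hit increments
    are proportional to |metric| (weight exponent 1) and whose miss
    decrements are ``1/(N - N_hits)``. NES divides ES by the mean
    |null ES| of the same sign. The nominal p-value is estimated on the
    same-sign null tail (with add-one smoothing); the FDR q-value is
    the canonical sign-stratified pooled-null ratio, clipped to [0, 1].
    """
    if len(ranked) == 0:
        raise ValueError("empty ranked list")
    if n_perm < 100:
        raise ValueError(f"need n_perm >= 100, got {n_perm}")
    universe = set(ranked.genes)
    kept = {}
    for name, members in sets.items():
        inter = universe.intersection(members)
        if min_size <= len(inter) <= max_size:
            kept[name] = inter
    if not kept:
        raise ValueError(
            f"no gene set with between {min_size} and {max_size} members "
            "after intersecting with the ranked universe"
        )

    rng = np.random.default_rng(seed)
    metric = ranked.metric
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}

    rows = []
    leading = {}
    null_nes_pos, null_nes_neg = [], []
    for name in sorted(kept):
        members = kept[name]
        hit_mask = np.zeros(len(metric), dtype=bool)
        hit_mask[[gene_pos[g] for g in members]] = True
        es, pos = _running_es(metric, hit_mask)

        n_hit = int(hit_mask.sum())
        null = _null_es(metric, n_hit, n_perm, rng)

        pos_null = null[null > 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if len(pos_null) else np.nan
        mean_neg = np.abs(neg_null).mean() if len(neg_null) else np.nan
        if es >= 0:
            same = pos_null
            nes = es / mean_pos if np.isfinite(mean_pos) else 0.0
            pval = (1 + (same >= es).sum()) / (1 + len(same)) if len(same) else 1.0
        else:
            same = neg_null
            nes = es / mean_neg if np.isfinite(mean_neg) else 0.0
            pval = (1 + (same <= es).sum()) / (1 + len(same)) if len(same) else 1.0
        if len(pos_null):
            null_nes_pos.append(pos_null / mean_pos)
        if len(neg_null):
            null_nes_neg.append(neg_null / mean_neg)

        order_idx = np.flatnonzero(hit_mask)
        if es >= 0:
            core = ranked.genes[order_idx[order_idx <= pos]]
        else:
            core = ranked.genes[order_idx[order_idx >= pos]]
        leading[name] = core.tolist()
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": float(nes),
                "pval": float(pval),
                "size": n_hit,
                "direction": "up" if es >= 0 else "down",
            }
        )

    table = pd.DataFrame(rows).set_index("set")
    pooled_pos = np.concatenate(null_nes_pos) if null_nes_pos else np.array([])
    pooled_neg = np.concatenate(null_nes_neg) if null_nes_neg else np.array([])
    obs = table["nes"].to_numpy()
    fdr = np.ones(len(table))
    for i, nes in enumerate(obs):
        if nes >= 0:
            null_frac = (pooled_pos >= nes).mean() if len(pooled_pos) else 1.0
            obs_frac = (obs[obs >= 0] >= nes).mean()
        else:
            null_frac = (pooled_neg <= nes).mean() if len(pooled_neg) else 1.0
            obs_frac = (obs[obs < 0] <= nes).mean()
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    table["fdr"] = fdr
    return EnrichmentResult(table=table, leading_edge=leading, n_perm=n_perm, seed=seed)


def overlap_enrichment(pathway, signature, universe) -> float:
    """Hypergeometric upper-tail P of the pathway/signature overlap.

    ``P(X >= k)`` where ``X`` counts signature genes among
    ``len(pathway)`` draws without replacement from ``universe``.
    """
    pathway, signature, universe = set(pathway), set(signature), set(universe)
    if not pathway <= universe:
        raise ValueError("pathway is not a subset of the universe")
    if not signature <= universe:
        raise ValueError("signature is not a subset of the universe")
    k = len(pathway & signature)
    return float(
        stats.hypergeom.sf(k - 1, len(universe), len(signature), len(pathway))
    )


def rank_by_ttest(X: pd.DataFrame, samples_a, samples_b) -> RankedList:
    """Rank genes by the two-sample Welch t-statistic (a vs b), descending.

    Per-gene variances are floored at a small epsilon so that genes
    with (near-)constant expression in both groups get a large but
    finite statistic instead of dividing by zero.
    """
    A = X[list(samples_a)].to_numpy(dtype=float)
    B = X[list(samples_b)].to_numpy(dtype=float)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples for a t-statistic")
    va = np.maximum(A.var(axis=1, ddof=1), _VAR_FLOOR)
    vb = np.maximum(B.var(axis=1, ddof=1), _VAR_FLOOR)
    t = (A.mean(axis=1) - B.mean(axis=1)) / np.sqrt(va / A.shape[1] + vb / B.shape[1])
    return RankedList.from_series(pd.Series(t, index=X.index))
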