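"""Differential expression across serial xenograft passages.

The design pairs each patient's original tumor (F0) with the fifth
(F5) and tenth (F10) xenograft passage. Per gene, a fixed-effects
linear model with passage-level means and patient block effects is
fitted; passage contrasts (F0 vs F5, F5 vs F10, F0 vs F10) are tested
with both the ordinary t-statistic and an empirical-Bayes moderated t
(gene variances shrunk toward a common prior fitted by moments on the
log-variance distribution, the classical scaled-F model). Ranking
genes by the moderated t feeds the preranked GSEA engine to ask which
functional groups move at engraftment and whether they keep moving
over later passages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from pdxspace.enrichment import RankedList, gsea_preranked

PASSAGE_LEVELS = ("F0", "F5", "F10")
CONTRASTS = (("F0", "F5"), ("F5", "F10"), ("F0", "F10"))


@dataclass
class BlockedModel:
    """Per-gene fixed-effects fit of expression on passage + patient."""

    coef: pd.DataFrame  # genes x design columns
    xtx_inv: np.ndarray
    design_columns: list
    sigma2: np.ndarray  # residual variance per gene
    df_resid: int
    genes: pd.Index


@dataclass
class ContrastResult:
    name: str
    table: pd.DataFrame  # genes x (estimate, t, mod_t)
    df_resid: int
    df_prior: float
    s2_prior: float

    def ranked(self) -> RankedList:
        return RankedList.from_series(self.table["mod_t"])


def _validate_design(design: pd.DataFrame) -> pd.DataFrame:
    for col in ("patient", "passage"):
        if col not in design.columns:
            raise ValueError(f"design is missing the {col!r} column")
    bad = set(design["passage"]) - set(PASSAGE_LEVELS)
    if bad:
        raise ValueError(f"unknown passage levels {sorted(bad)}; expected {PASSAGE_LEVELS}")
    per_patient = design.groupby("patient")["passage"].nunique()
    if (per_patient < 2).any():
        single = per_patient[per_patient < 2].index.tolist()
        raise ValueError(f"patients with a single passage level: {single}")
    level_counts = design["passage"].value_counts()
    lonely = level_counts[level_counts < 2].index.tolist()
    if lonely:
        raise ValueError(f"passage levels present in only one sample: {lonely}")
    if design["patient"].nunique() < 2:
        raise ValueError("need >= 2 patients for a blocked design")
    return design


def blocked_fit(X: pd.DataFrame, design: pd.DataFrame) -> BlockedModel:
    """Fit expression ~ passage + patient (fixed effects) per gene.

    ``X`` is genes x samples; ``design`` indexes the same samples with
    ``patient`` and ``passage`` columns. The design matrix carries one
    mean per observed passage level (no intercept) plus patient
    dummies (first patient as reference), which on a complete design
    is the transparent fixed-effects equivalent of a paired analysis.
    """
    design = _validate_design(design)
    missing = X.columns.difference(design.index)
    if len(missing) > 0:
        raise ValueError(f"samples missing from the design: {missing[:5].tolist()}")
    design = design.loc[X.columns]

    levels = [lv for lv in PASSAGE_LEVELS if lv in set(design["passage"])]
    patients = sorted(design["patient"].unique())
    cols = [f"passage_{lv}" for lv in levels] + [f"patient_{p}" for p in patients[1:]]
    D = np.zeros((len(design), len(cols)))
    for i, lv in enumerate(levels):
        D[:, i] = (design["passage"] == lv).to_numpy(dtype=float)
    for j, p in enumerate(patients[1:], start=len(levels)):
        D[:, j] = (design["patient"] == p).to_numpy(dtype=float)

    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    df_resid = D.shape[0] - rank
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    Y = X.to_numpy(dtype=float).T  # samples x genes
    xtx_inv = np.linalg.inv(D.T @ D)
    coef = xtx_inv @ D.T @ Y  # columns x genes
    resid = Y - D @ coef
    sigma2 = (resid**2).sum(axis=0) / df_resid
    return BlockedModel(
        coef=pd.DataFrame(coef.T, index=X.index, columns=cols),
        xtx_inv=xtx_inv,
        design_columns=cols,
        sigma2=sigma2,
        df_resid=df_resid,
        genes=X.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(sigma2: np.ndarray, df: int):
    """Moment-fit a scaled-F prior to gene residual variances.

    The sampling model ``s^2 ~ s0^2 * F(df, d0)`` implies a known mean
    and variance for ``log s^2`` in terms of digamma/trigamma
    functions; matching those moments gives the prior degrees of
    freedom ``d0`` (infinite when the observed log-variances are no
    more dispersed than chi-square sampling alone explains) and the
    prior scale ``s0^2``.
    """
    s2 = np.maximum(np.asarray(sigma2, dtype=float), 0.0)
    m = np.median(s2)
    if m == 0:
        m = 1.0
    s2 = np.maximum(s2, 1e-5 * m)  # guard genes with zero residual variance
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0 = s2.mean()
    return float(d0), float(s0)


def contrast(model: BlockedModel, pair) -> ContrastResult:
    """Estimate and test the difference between two passage levels.

    Returns per-gene estimate (first minus second level), ordinary t,
    and the moderated t computed with the posterior variance
    ``(d0*s0^2 + df*s^2) / (d0 + df)``. With fewer than 10 genes the
    prior cannot be estimated and the moderated t equals the ordinary
    t.
    """
    a, b = pair
    if a == b:
        raise ValueError(f"degenerate contrast {a} vs {b}")
    for lv in (a, b):
        if f"passage_{lv}" not in model.design_columns:
            raise KeyError(f"passage level {lv!r} not in the fitted model")
    c = np.zeros(len(model.design_columns))
    c[model.design_columns.index(f"passage_{a}")] = 1.0
    c[model.design_columns.index(f"passage_{b}")] = -1.0

    est = model.coef.to_numpy() @ c
    var_unit = float(c @ model.xtx_inv @ c)
    se = np.sqrt(var_unit * model.sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = np.where(se > 0, est / se, 0.0)

    if len(model.genes) >= 10:
        d0, s0 = fit_variance_prior(model.sigma2, model.df_resid)
    else:
        d0, s0 = np.inf, float(np.mean(model.sigma2))
    if np.isinf(d0):
        s2_post = np.full_like(model.sigma2, s0)
    else:
        s2_post = (d0 * s0 + model.df_resid * model.sigma2) / (d0 + model.df_resid)
    se_mod = np.sqrt(var_unit * s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se_mod > 0, est / se_mod, 0.0)

    table = pd.DataFrame(
        {"estimate": est, "t": t_ord, "mod_t": t_mod}, index=model.genes
    )
    return ContrastResult(
        name=f"{a}vs{b}",
        table=table,
        df_resid=model.df_resid,
        df_prior=d0,
        s2_prior=s0,
    )


def passage_stability(
    contrasts,
    groups: dict,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """Functional-group enrichment per passage contrast.

    ``contrasts`` is an iterable of :class:`ContrastResult` (the three
    passage pairs); each is ranked by moderated t and run through
    preranked GSEA restricted to the functional-group sets. Returns a
    tidy table (group x contrast rows) with ES/NES/p/FDR: groups that
    moved at engraftment show up in F0-anchored contrasts and, if the
    profile is stable afterwards, nowhere else.
    """
    contrasts = list(contrasts)
    if not contrasts:
        raise ValueError("no contrasts supplied")
    frames = []
    for cr in contrasts:
        res = gsea_preranked(
            cr.ranked(),
            groups,
            min_size=min_size,
            max_size=max_size,
            n_perm=n_perm,
            seed=seed,
        )
        sub = res.table.copy()
        sub.insert(0, "contrast", cr.name)
        frames.append(sub)
    out = pd.concat(frames)
    out.index.name = "group"
    return out.reset_index().set_index(["group", "contrast"])
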