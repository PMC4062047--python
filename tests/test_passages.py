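"""Blocked passage model, moderated t, and stability enrichment."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from pdxspace import (
    CONTRASTS,
    blocked_fit,
    contrast,
    generate_passage_cohort,
    passage_stability,
)


def paired_toy():
    """Four patients, F0/F5 only, single gene with per-patient
    F0-F5 differences (1, 2, 3, 2)."""
    f0 = np.array([5.0, 6.0, 7.0, 6.0])
    f5 = f0 - np.array([1.0, 2.0, 3.0, 2.0])
    samples = [f"p{i + 1}_{lv}" for i in range(4) for lv in ("F0", "F5")]
    design = pd.DataFrame(
        {
            "patient": [s.split("_")[0] for s in samples],
            "passage": [s.split("_")[1] for s in samples],
        },
        index=samples,
    )
    values = [v for pair in zip(f0, f5) for v in pair]
    X = pd.DataFrame([values], index=["g1"], columns=samples)
    return X, design


class TestBlockedFit:
    def test_paired_design_reduces_to_paired_t(self):
        X, design = paired_toy()
        cr = contrast(blocked_fit(X, design), ("F0", "F5"))
        row = cr.table.loc["g1"]
        assert row["estimate"] == pytest.approx(2.0)
        assert row["t"] == pytest.approx(4.898979, abs=1e-5)  # se = 0.408
        assert cr.df_resid == 3

    def test_identical_profiles_give_zero_effects(self):
        X, design = paired_toy()
        X.loc["g1"] = 4.2
        cr = contrast(blocked_fit(X, design), ("F0", "F5"))
        assert cr.table.loc["g1", "estimate"] == pytest.approx(0.0)

    def test_sample_order_irrelevant(self):
        coh = generate_passage_cohort(n_genes=200, genes_per_group=20, seed=2)
        perm = np.random.default_rng(0).permutation(coh.X.shape[1])
        a = contrast(blocked_fit(coh.X, coh.design), ("F0", "F10"))
        b = contrast(
            blocked_fit(coh.X.iloc[:, perm], coh.design.iloc[perm]), ("F0", "F10")
        )
        np.testing.assert_allclose(
            a.table["estimate"], b.table["estimate"], atol=1e-10
        )

    @pytest.mark.parametrize(
        "mutate, message",
        [
            (lambda d: d.assign(passage=["F0"] * len(d)), "single passage level"),
            (lambda d: d.assign(passage=d["passage"].str.replace("F10", "F99")),
             "unknown passage levels"),
        ],
    )
    def test_invalid_designs(self, mutate, message):
        coh = generate_passage_cohort(n_genes=200, genes_per_group=20, seed=0)
        with pytest.raises(ValueError, match=message):
            blocked_fit(coh.X, mutate(coh.design))

    def test_lonely_level_rejected(self):
        X, design = paired_toy()
        design.loc["p1_F0", "passage"] = "F10"
        with pytest.raises(ValueError, match="only one sample"):
            blocked_fit(X, design)


class TestContrast:
    def test_degenerate_pair_rejected(self):
        X, design = paired_toy()
        model = blocked_fit(X, design)
        with pytest.raises(ValueError, match="degenerate"):
            contrast(model, ("F0", "F0"))
        with pytest.raises(KeyError, match="F10"):
            contrast(model, ("F0", "F10"))

    def test_equal_gene_variances_leave_t_unmoderated(self):
        # clones of one profile (plus constants) share the residual
        # variance exactly: shrinkage has nothing to do
        coh = generate_passage_cohort(n_genes=200, genes_per_group=20, seed=1)
        base = coh.X.iloc[0]
        X = pd.DataFrame(
            {f"clone{i}": base + i for i in range(30)}, index=base.index
        ).T
        cr = contrast(blocked_fit(X, coh.design), ("F0", "F5"))
        assert np.isinf(cr.df_prior)
        np.testing.assert_allclose(cr.table["mod_t"], cr.table["t"], atol=1e-9)

    def test_estimates_are_transitive(self):
        coh = generate_passage_cohort(n_genes=300, genes_per_group=30, seed=3)
        model = blocked_fit(coh.X, coh.design)
        crs = {pair: contrast(model, pair) for pair in CONTRASTS}
        np.testing.assert_allclose(
            crs[("F0", "F10")].table["estimate"],
            crs[("F0", "F5")].table["estimate"]
            + crs[("F5", "F10")].table["estimate"],
            atol=1e-9,
        )

    def test_shrinkage_direction_depends_on_gene_variance(self):
        rng = np.random.default_rng(4)
        coh = generate_passage_cohort(n_genes=400, genes_per_group=30, seed=4)
        X = coh.X.mul(rng.uniform(0.2, 4.0, coh.X.shape[0]), axis=0)
        model = blocked_fit(X, coh.design)
        cr = contrast(model, ("F0", "F5"))
        assert np.isfinite(cr.df_prior)
        below = model.sigma2 < cr.s2_prior
        nonzero = cr.table["t"].abs() > 1e-9
        t, mt = cr.table["t"].abs(), cr.table["mod_t"].abs()
        assert (mt[below & nonzero.to_numpy()] <= t[below & nonzero.to_numpy()] + 1e-12).all()
        assert (mt[~below & nonzero.to_numpy()] >= t[~below & nonzero.to_numpy()] - 1e-12).all()

    def test_moderated_t_matches_limma_ebayes(self, tmp_path):
        # independent oracle: limma's lmFit + contrasts.fit + eBayes on
        # the same fixed-effects design, heteroskedastic gene variances
        rng = np.random.default_rng(7)
        coh = generate_passage_cohort(n_genes=200, genes_per_group=20, seed=7)
        X = coh.X.mul(rng.uniform(0.3, 3.0, coh.X.shape[0]), axis=0)
        model = blocked_fit(X, coh.design)
        cr = contrast(model, ("F5", "F10"))

        X.to_csv(tmp_path / "x.tsv", sep="\t")
        coh.design.to_csv(tmp_path / "d.tsv", sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{tmp_path}/x.tsv", row.names=1, check.names=FALSE))
            d <- read.delim("{tmp_path}/d.tsv", row.names=1)
            design <- model.matrix(~0 + factor(d$passage, levels=c("F0","F5","F10"))
                                      + factor(d$patient))
            colnames(design) <- c("F0","F5","F10","p2","p3","p4")
            fit <- eBayes(contrasts.fit(lmFit(x, design),
                                        makeContrasts(F5 - F10, levels=design)))
            write.table(data.frame(gene=rownames(x), t=fit$t[,1],
                                   d0=fit$df.prior, s0=fit$s2.prior),
                        "{tmp_path}/limma.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
            """
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        lim = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        assert cr.df_prior == pytest.approx(lim["d0"].iloc[0], abs=1e-6)
        assert cr.s2_prior == pytest.approx(lim["s0"].iloc[0], abs=1e-9)
        diff = (cr.table["mod_t"] - lim["t"].loc[cr.table.index]).abs().max()
        assert diff <= 1e-6


class TestPassageStability:
    def test_engraftment_only_shift_pattern(self):
        coh = generate_passage_cohort(seed=0)
        model = blocked_fit(coh.X, coh.design)
        crs = [contrast(model, pair) for pair in CONTRASTS]
        table = passage_stability(crs, coh.gene_sets, n_perm=500, seed=0)
        sig = table["fdr"] < 0.05
        assert sig.xs("F0vsF5", level="contrast").all()
        assert sig.xs("F0vsF10", level="contrast").all()
        assert not sig.xs("F5vsF10", level="contrast").any()
        # contrast estimates are F0 minus F5: groups up-shifted after
        # engraftment concentrate at the negative end of that ranking
        up = table.xs("F0vsF5", level="contrast").loc[coh.shifted_up, "nes"]
        down = table.xs("F0vsF5", level="contrast").loc[coh.shifted_down, "nes"]
        assert (up < 0).all() and (down > 0).all()

    def test_null_cohorts_stay_clean(self):
        clean = 0
        for seed in (101, 102, 103, 104):
            coh = generate_passage_cohort(engraftment_shift=False, seed=seed)
            model = blocked_fit(coh.X, coh.design)
            crs = [contrast(model, pair) for pair in CONTRASTS]
            table = passage_stability(crs, coh.gene_sets, n_perm=500, seed=seed)
            clean += not (table["fdr"] < 0.005).any()
        assert clean >= 3  # one marginal pooled-null event tolerated

    def test_same_seed_identical_tables(self):
        coh = generate_passage_cohort(seed=5)
        model = blocked_fit(coh.X, coh.design)
        crs = [contrast(model, pair) for pair in CONTRASTS]
        a = passage_stability(crs, coh.gene_sets, n_perm=200, seed=8)
        b = passage_stability(crs, coh.gene_sets, n_perm=200, seed=8)
        pd.testing.assert_frame_equal(a, b)
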