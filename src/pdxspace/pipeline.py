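"""End-to-end pipeline: calls -> space -> clusters -> correction -> enrichment.

Chains the analysis stages over one expression matrix and annotation
table, writing every intermediate artifact plus a machine-readable JSON
report. Each stochastic stage draws a named sub-seed from the master
seed so stage-level reruns are independent yet reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import pdxspace.calls as calls_mod
import pdxspace.clustering as clustering
import pdxspace.enrichment as enrich_mod
import pdxspace.infiltration as infiltration
import pdxspace.io as pio
import pdxspace.synthdata as synthdata
from pdxspace.mca import mca as run_mca
from pdxspace.mca import select_dimensions

logger = logging.getLogger(__name__)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the master seed."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Inputs and stage parameters of one pipeline run."""

    matrix: str | None = None
    annotation: str | None = None
    probe_map: str | None = None
    signature_gmt: str | None = None
    gene_sets_gmt: str | None = None
    out_dir: str = "pdxspace_out"
    # stage parameters (documented defaults of the protocol)
    tau: float = 5.0
    alpha_dims: float = 0.01
    kmin: int = 2
    kmax: int = 50
    restarts: int = 50
    ssgsea_alpha: float = 0.25
    min_size: int = 15
    max_size: int = 500
    n_perm: int = 1000
    fdr_threshold: float = 0.05
    exclude_signature_genes: bool = False
    correct_infiltration: bool = False
    group_column: str = "group"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SynthConfig overrides

    def validate(self) -> None:
        if self.kmax < self.kmin or self.kmin < 2:
            raise ValueError(f"invalid k range [{self.kmin}, {self.kmax}]")
        if not 0 < self.alpha_dims < 1:
            raise ValueError(f"alpha_dims must be in (0,1), got {self.alpha_dims}")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError(f"fdr_threshold must be in (0,1), got {self.fdr_threshold}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.n_perm < 100:
            raise ValueError(f"n_perm must be >= 100, got {self.n_perm}")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not 0 <= self.ssgsea_alpha:
            raise ValueError("ssgsea_alpha must be >= 0")
        if self.min_size < 1 or self.max_size < self.min_size:
            raise ValueError(
                f"invalid set-size window [{self.min_size}, {self.max_size}]"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full protocol; returns (and writes) the run report.

    Stages: load or simulate inputs -> binary calls -> (optional probe
    collapse, optional signature-gene exclusion) -> MCA + dimension
    selection -> CH-optimal k-means + class agreement -> (optional)
    infiltration scoring and residual correction -> expression
    frequency GSEA between primary and PDX groups. Each stage failure
    aborts with the stage name; artifacts written so far are kept.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    def _stage(name):
        report["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        _stage("load")
        stromal = immune = None
        truth = None
        if config.matrix is None:
            scfg = synthdata.SynthConfig(
                **{**config.simulate, "seed": stage_seed(config.seed, "simulate")}
            )
            X, C0, annotation, truth = synthdata.generate_cohort(scfg)
            stromal, immune = synthdata.planted_signatures(scfg)
            pio.write_matrix(X, out / "expression.tsv")
            pio.write_matrix(C0, out / "calls_true.tsv")
            annotation.to_csv(out / "annotation.tsv", sep="\t")
            pio.write_gmt(
                {"stromal": stromal.genes, "immune": immune.genes},
                out / "signatures.gmt",
            )
            truth.gene_role.to_csv(out / "gene_roles.tsv", sep="\t")
        else:
            X = pio.read_matrix(config.matrix)
            annotation = pio.read_annotation(config.annotation)
            if config.signature_gmt:
                stromal, immune = pio.read_signatures(config.signature_gmt)

        _stage("calls")
        ref = calls_mod.estimate_reference_null(X)
        C = calls_mod.barcode_calls(X, ref, tau=config.tau)
        if config.probe_map:
            C = calls_mod.collapse_probes(C, pio.read_probe_map(config.probe_map))
        pio.write_matrix(C, out / "calls.tsv")

        C_space = C
        if config.exclude_signature_genes and stromal is not None:
            excluded = set(stromal.genes) | set(immune.genes)
            C_space = calls_mod.exclude_genes(C, excluded)

        _stage("space")
        space = run_mca(C_space)
        dims = select_dimensions(space, alpha=config.alpha_dims)
        space.sample_coords.to_csv(out / "coords.tsv", sep="\t")
        report["retained_dims"] = dims
        report["axis_pvalues"] = [float(p) for p in space.axis_pvalues]
        report["variance_fraction"] = [
            float(v) for v in space.variance_fraction[: space.n_axes]
        ]

        _stage("cluster")
        result = clustering.robust_kmeans(
            space,
            kmin=config.kmin,
            kmax=config.kmax,
            restarts=config.restarts,
            seed=stage_seed(config.seed, "cluster"),
        )
        result.labels.to_csv(out / "clusters.tsv", sep="\t")
        result.ch_curve.rename("ch_index").to_csv(out / "ch_curve.tsv", sep="\t")
        report["k_opt"] = result.k_opt
        report["ch_index"] = float(result.ch_curve.loc[result.k_opt])
        group_col = annotation[config.group_column]
        agreement = clustering.classification_agreement(
            result.labels.to_numpy(), group_col.loc[result.labels.index].to_numpy()
        )
        report["agreement"] = {
            "overall_percent": agreement.overall_percent,
            "per_class_percent": agreement.per_class_percent,
        }

        if stromal is not None:
            _stage("infiltration")
            scores = infiltration.infiltration_scores(
                X, stromal, immune, alpha=config.ssgsea_alpha
            )
            scores.to_csv(out / "infiltration_scores.tsv", sep="\t")
            report["mean_combined_score_by_class"] = (
                scores["combined"].groupby(annotation["class"]).mean().to_dict()
            )
            if config.correct_infiltration:
                corrected, fits = infiltration.correct_space(space, scores)
                corrected.sample_coords.to_csv(out / "coords_corrected.tsv", sep="\t")
                report["axis_fits"] = [
                    {
                        "axis": f.axis,
                        "slope": f.slope,
                        "r_squared": f.r_squared,
                        "pvalue": f.pvalue,
                    }
                    for f in fits
                ]

        _stage("enrichment")
        classes = annotation["class"].loc[C.columns]
        if {"primary", "pdx"} <= set(classes):
            freq = enrich_mod.expression_frequency(C, classes)
            freq.to_csv(out / "expression_frequency.tsv", sep="\t")
            ranked = enrich_mod.frequency_difference(freq, "primary", "pdx")
            pio.write_rnk(ranked, out / "primary_minus_pdx.rnk")
            gene_sets = None
            if config.gene_sets_gmt:
                gene_sets = pio.read_gmt(config.gene_sets_gmt)
            elif truth is not None:
                gene_sets = {
                    k: v
                    for k, v in truth.planted_gene_sets().items()
                    if len(v) >= config.min_size
                }
            if gene_sets:
                res = enrich_mod.gsea_preranked(
                    ranked,
                    gene_sets,
                    min_size=config.min_size,
                    max_size=config.max_size,
                    n_perm=config.n_perm,
                    seed=stage_seed(config.seed, "gsea"),
                )
                res.table.to_csv(out / "gsea.tsv", sep="\t")
                report["n_sets_tested"] = int(len(res.table))
                report["n_sets_significant"] = int(
                    (res.table["fdr"] < config.fdr_threshold).sum()
                )

        if truth is not None:
            from sklearn.metrics import adjusted_rand_score

            report["ari_vs_truth"] = float(
                adjusted_rand_score(
                    truth.group_label().loc[result.labels.index], result.labels
                )
            )
    except Exception as exc:
        stage = report["stages"][-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    pio.write_json(report, out / "report.json")
    return report
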