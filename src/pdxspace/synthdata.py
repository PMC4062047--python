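"""Synthetic cohorts with the statistical structure of tumor/PDX panels.

The generator emulates the design of a two-tissue tumor-model
compendium: samples from two tissues of origin, each observed in
several environments (primary tumor in the patient, xenograft in the
mouse, cell line in culture), with

* a *tissue memory* pattern — genes whose expression probability
  differs by tissue of origin in every environment,
* an *environment* pattern — genes responding to the host environment
  regardless of tissue,
* a *non-tumoral infiltration* gradient — stromal and immune signature
  genes whose expression probability in a primary tumor rises with the
  sample's infiltrating-cell fraction; xenografts and cell lines carry
  no human infiltrate, so their fraction is 0,
* background genes with a fixed per-gene baseline expression
  probability, and
* Bernoulli flip noise on every call.

Continuous intensities are generated alongside the binary calls as a
two-mode Gaussian mixture per gene (silenced baseline + effect-size
shift when called expressed), so the barcoding stage can be tested
against known truth. Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("pancreas", "liver")
ENV_CLASSES = ("primary", "pdx", "cell_line")


@dataclass(frozen=True)
class GeneSignature:
    """A named set of gene symbols."""

    name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")

    def __len__(self):
        return len(self.genes)


@dataclass
class SynthConfig:
    """Cohort design and effect sizes for :func:`generate_cohort`.

    ``p_on`` / ``p_off`` are the expression probabilities of a signal
    gene in its on / off group; the tissue-to-environment effect
    ordering (tissue axis above environment axis, as in real tumor
    compendia) comes from the default gene counts.
    """

    n_samples_per_group: int = 64
    n_genes: int = 2000
    n_tissue_genes: int = 300
    n_env_genes: int = 150
    n_signature_genes: int = 100
    p_on: float = 0.9
    p_off: float = 0.1
    infiltration_range: tuple = (0.2, 0.8)
    noise_flip: float = 0.02
    intensity_scale: float = 8.0
    intensity_sd: float = 1.0
    tissue_strength_range: tuple = (0.55, 0.95)
    env_strength_range: tuple = (0.55, 0.95)
    tissues: tuple = TISSUES
    env_classes: tuple = ("primary", "pdx")
    seed: int = 0

    def validate(self) -> None:
        n_signal = self.n_tissue_genes + self.n_env_genes + self.n_signature_genes
        if n_signal > self.n_genes:
            raise ValueError(
                "n_tissue_genes + n_env_genes + n_signature_genes "
                f"({n_signal}) exceeds n_genes ({self.n_genes})"
            )
        if not 0 <= self.p_off < self.p_on <= 1:
            raise ValueError(f"need 0 <= p_off < p_on <= 1, got p_off={self.p_off}, p_on={self.p_on}")
        if not 0 <= self.noise_flip <= 0.5:
            raise ValueError(f"noise_flip must be in [0, 0.5], got {self.noise_flip}")
        lo, hi = self.infiltration_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError(f"infiltration_range must be within [0, 1], got {self.infiltration_range}")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")
        for rng_name in ("tissue_strength_range", "env_strength_range"):
            lo, hi = getattr(self, rng_name)
            if not 0 <= lo <= hi <= 1:
                raise ValueError(f"{rng_name} must be within [0, 1], got {(lo, hi)}")
        unknown = set(self.env_classes) - set(ENV_CLASSES)
        if unknown:
            raise ValueError(f"unknown environment classes: {sorted(unknown)}")
        if len(self.tissues) < 1 or len(self.env_classes) < 1:
            raise ValueError("need at least one tissue and one environment class")
        if self.intensity_scale <= 0 or self.intensity_sd <= 0:
            raise ValueError("intensity_scale and intensity_sd must be positive")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    tissue_label: pd.Series  # per sample
    env_label: pd.Series  # per sample
    infiltration_fraction: pd.Series  # per sample, in [0, 1]
    gene_role: pd.Series  # per gene: tissue | environment | stromal | immune | background
    on_group: pd.Series  # per signal gene: the group the gene marks
    tissue_strength: pd.Series | None = None  # per sample, pattern intensity in [0, 1]
    env_strength: pd.Series | None = None
    n_groups: int = 0

    def group_label(self) -> pd.Series:
        """tissue x environment group of every sample."""
        return self.tissue_label.str.cat(self.env_label, sep="/")

    def genes_with_role(self, role: str) -> list:
        return self.gene_role.index[self.gene_role == role].tolist()

    def planted_gene_sets(self) -> dict:
        """Signal genes grouped by the tissue or environment they mark.

        Keys like ``tissue:pancreas`` or ``env:primary``; useful as
        positive-control gene sets for enrichment analyses.
        """
        sets = {}
        for grp, sub in self.on_group.dropna().groupby(self.on_group.dropna()):
            sets[grp] = sub.index.tolist()
        return sets


def _gene_roles(config: SynthConfig) -> pd.Series:
    roles = np.array(["background"] * config.n_genes, dtype=object)
    i = 0
    roles[i : i + config.n_tissue_genes] = "tissue"
    i += config.n_tissue_genes
    roles[i : i + config.n_env_genes] = "environment"
    i += config.n_env_genes
    n_str = config.n_signature_genes // 2
    roles[i : i + n_str] = "stromal"
    roles[i + n_str : i + config.n_signature_genes] = "immune"
    genes = [f"g{j + 1:05d}" for j in range(config.n_genes)]
    return pd.Series(roles, index=pd.Index(genes, name="gene"), name="role")


def generate_cohort(config: SynthConfig):
    """Draw one synthetic cohort.

    Returns
    -------
    (X, C, annotation, truth)
        ``X`` continuous log-scale intensities (genes x samples),
        ``C`` binary calls (genes x samples) — the realized truth the
        intensities encode, ``annotation`` a DataFrame with columns
        ``tissue``, ``class``, ``group``, and ``truth`` a
        :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = [(t, e) for t in config.tissues for e in config.env_classes]
    n_per = config.n_samples_per_group
    sample_ids, tissue_lab, env_lab = [], [], []
    for t, e in groups:
        for j in range(n_per):
            sample_ids.append(f"{t}_{e}_{j + 1:03d}")
            tissue_lab.append(t)
            env_lab.append(e)
    sample_index = pd.Index(sample_ids, name="sample")
    tissue_lab = pd.Series(tissue_lab, index=sample_index, name="tissue")
    env_lab = pd.Series(env_lab, index=sample_index, name="class")
    n_samples = len(sample_ids)

    roles = _gene_roles(config)
    genes = roles.index

    # infiltration: a human non-tumoral cell fraction only primaries carry
    lo, hi = config.infiltration_range
    infil = pd.Series(0.0, index=sample_index, name="infiltration")
    is_primary = (env_lab == "primary").to_numpy()
    infil.iloc[np.flatnonzero(is_primary)] = rng.uniform(lo, hi, is_primary.sum())

    # per-sample pattern strengths: tumors differ in purity and in how
    # strongly they express their tissue / environment program, which
    # spreads samples along the signal axes instead of collapsing each
    # group onto a single point
    t_lo, t_hi = config.tissue_strength_range
    e_lo, e_hi = config.env_strength_range
    t_strength = pd.Series(rng.uniform(t_lo, t_hi, n_samples), index=sample_index, name="tissue_strength")
    e_strength = pd.Series(rng.uniform(e_lo, e_hi, n_samples), index=sample_index, name="env_strength")
    # in primary tumors the in-patient environment program is carried to a
    # large degree by the infiltrating stromal/immune compartment, so its
    # strength tracks the infiltration fraction (rescaled into the strength
    # band) rather than varying freely
    ilo, ihi = config.infiltration_range
    if ihi > ilo:
        rescaled = e_lo + (e_hi - e_lo) * (infil[is_primary] - ilo) / (ihi - ilo)
        e_strength[is_primary] = rescaled

    # per-gene on-groups: tissue genes alternate across tissues, environment
    # genes across environment classes
    on_group = pd.Series(np.nan, index=genes, dtype=object, name="on_group")
    t_genes = roles.index[roles == "tissue"]
    for j, g in enumerate(t_genes):
        on_group[g] = f"tissue:{config.tissues[j % len(config.tissues)]}"
    e_genes = roles.index[roles == "environment"]
    for j, g in enumerate(e_genes):
        on_group[g] = f"env:{config.env_classes[j % len(config.env_classes)]}"

    # call probability matrix
    prob = np.empty((config.n_genes, n_samples))
    background = roles.to_numpy() == "background"
    # fixed per-gene baseline probability for background genes, kept below
    # 0.5 so the silenced mode of every gene is identifiable from the
    # cohort itself (no frozen reference distributions)
    bg_p = rng.uniform(0.02, 0.5, background.sum())
    prob[background, :] = bg_p[:, None]

    tissue_of_sample = tissue_lab.to_numpy()
    env_of_sample = env_lab.to_numpy()
    dp = config.p_on - config.p_off
    ts = t_strength.to_numpy()
    es = e_strength.to_numpy()
    for j, g in enumerate(genes):
        role = roles.iloc[j]
        if role == "tissue":
            on = tissue_of_sample == on_group[g].split(":", 1)[1]
            prob[j] = np.where(on, config.p_off + ts * dp, config.p_off)
        elif role == "environment":
            on = env_of_sample == on_group[g].split(":", 1)[1]
            prob[j] = np.where(on, config.p_off + es * dp, config.p_off)
        elif role in ("stromal", "immune"):
            # probability rises linearly with the infiltrating fraction
            prob[j] = config.p_off + infil.to_numpy() * dp

    calls = rng.random((config.n_genes, n_samples)) < prob
    if config.noise_flip > 0:
        flips = rng.random((config.n_genes, n_samples)) < config.noise_flip
        calls = calls ^ flips
    calls = calls.astype(np.int8)

    baseline = rng.uniform(4.0, 8.0, config.n_genes)
    X = (
        baseline[:, None]
        + config.intensity_scale * calls
        + rng.normal(0.0, config.intensity_sd, (config.n_genes, n_samples))
    )

    C = pd.DataFrame(calls, index=genes, columns=sample_index)
    Xf = pd.DataFrame(X, index=genes, columns=sample_index)
    annotation = pd.DataFrame(
        {"tissue": tissue_lab, "class": env_lab, "group": tissue_lab.str.cat(env_lab, sep="/")}
    )
    truth = GroundTruth(
        tissue_label=tissue_lab,
        env_label=env_lab,
        infiltration_fraction=infil,
        gene_role=roles,
        on_group=on_group,
        tissue_strength=t_strength,
        env_strength=e_strength,
        n_groups=len(groups),
    )
    return Xf, C, annotation, truth


def weak_environment_config(seed: int = 0) -> SynthConfig:
    """Cohort whose expression space has exactly two informative axes.

    The tissue-memory pattern is kept at full strength while the
    environment pattern is thinned (35 genes, near-minimal signature)
    and fully graded (per-sample strength spanning almost the whole
    unit interval), so the environment axis sits just above the noise
    floor of the space. This is the regime in which contiguous-axis
    testing stops after the second axis: axis 1 towers over axis 2,
    axis 2 blends into axis 3.
    """
    return SynthConfig(
        n_samples_per_group=24,
        n_env_genes=35,
        n_signature_genes=10,
        env_strength_range=(0.05, 1.0),
        seed=seed,
    )


def planted_signatures(config: SynthConfig):
    """Stromal and immune gene signatures of a synthetic cohort.

    Deterministic given the config (signature membership does not
    depend on the draw); the two sets are disjoint and together cover
    exactly the genes with stromal or immune roles.
    """
    if config.n_signature_genes < 2:
        raise ValueError(
            f"need n_signature_genes >= 2 to split a stromal and an immune set, "
            f"got {config.n_signature_genes}"
        )
    config.validate()
    roles = _gene_roles(config)
    stromal = GeneSignature("stromal", frozenset(roles.index[roles == "stromal"]))
    immune = GeneSignature("immune", frozenset(roles.index[roles == "immune"]))
    return stromal, immune


@dataclass
class PassageCohort:
    """Synthetic serial-passage experiment (original tumor, 5th and 10th passage)."""

    X: pd.DataFrame  # genes x samples, log-scale intensities
    design: pd.DataFrame  # columns: patient, passage
    gene_sets: dict  # functional group name -> gene list
    shifted_up: list = field(default_factory=list)  # groups planted up after engraftment
    shifted_down: list = field(default_factory=list)


def generate_passage_cohort(
    n_patients: int = 4,
    n_genes: int = 1000,
    genes_per_group: int = 30,
    shift: float = 1.5,
    noise_sd: float = 0.5,
    patient_sd: float = 1.0,
    engraftment_shift: bool = True,
    seed: int = 0,
) -> PassageCohort:
    """Paired passage series with an engraftment-only expression shift.

    Each patient contributes one sample at F0 (original tumor), F5 and
    F10. Five planted functional groups mimic the processes that move
    at engraftment: two shift up and three shift down, by ``shift``
    log-units, at F5 and persist unchanged at F10 — the step happens at
    engraftment and the profile is stable over later passages. With
    ``engraftment_shift=False`` nothing is planted (null cohort).
    Patient baselines are random block effects shared across passages.
    """
    if n_patients < 2:
        raise ValueError("need >= 2 patients for a blocked design")
    if 5 * genes_per_group > n_genes:
        raise ValueError("not enough genes for five planted groups")
    rng = np.random.default_rng(seed)
    passages = ("F0", "F5", "F10")
    samples = [f"p{i + 1}_{lv}" for i in range(n_patients) for lv in passages]
    design = pd.DataFrame(
        {
            "patient": [s.split("_")[0] for s in samples],
            "passage": [s.split("_")[1] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    genes = pd.Index([f"g{j + 1:05d}" for j in range(n_genes)], name="gene")

    group_names = ["cell_cycle", "dna_replication", "ecm_organization", "hemostasis", "signal_transduction"]
    directions = {"cell_cycle": +1, "dna_replication": +1,
                  "ecm_organization": -1, "hemostasis": -1, "signal_transduction": -1}
    gene_sets = {}
    for i, name in enumerate(group_names):
        gene_sets[name] = genes[i * genes_per_group : (i + 1) * genes_per_group].tolist()

    base = rng.uniform(4.0, 10.0, n_genes)
    patient_eff = rng.normal(0.0, patient_sd, (n_genes, n_patients))
    X = np.empty((n_genes, len(samples)))
    for s_idx, s in enumerate(samples):
        p_idx = int(design.iloc[s_idx]["patient"][1:]) - 1
        engrafted = design.iloc[s_idx]["passage"] != "F0"
        mu = base + patient_eff[:, p_idx]
        X[:, s_idx] = mu + rng.normal(0.0, noise_sd, n_genes)
        if engrafted and engraftment_shift:
            for name in group_names:
                rows = genes.get_indexer(gene_sets[name])
                X[rows, s_idx] += directions[name] * shift

    return PassageCohort(
        X=pd.DataFrame(X, index=genes, columns=design.index),
        design=design,
        gene_sets=gene_sets,
        shifted_up=[n for n in group_names if directions[n] > 0] if engraftment_shift else [],
        shifted_down=[n for n in group_names if directions[n] < 0] if engraftment_shift else [],
    )
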