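"""Synthetic multi-omic AML-like cohort generator.

The generator reproduces the confounding structure the pipeline is built
for: the dominant expression axis tracks a two-level myeloid lineage label
(M1/M2 vs M4/M5, the FAB bins) while a hidden three-level biology group
drives a weaker secondary axis, group-linked survival hazards, group-
enriched binary mutations and group-shifted protein panels.  Counts are
negative binomial with a common dispersion; planted gene blocks give every
downstream stage a known truth.

Default shape parameters follow the cohort the pipeline targets: 81
samples, a 36/45 lineage split, latent groups in proportion 31:29:21, and
survival on the weeks scale with a baseline median near 25 weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationMatrix,
    ProteinMatrix,
    Scale,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "draw_sample_labels",
    "simulate_expression",
    "simulate_clinical_survival",
    "simulate_mutations_proteins",
    "generate_gene_set_collection",
    "simulate_cohort",
]

#: Biology-gene blocks: (block name, group pattern).  A gene in a block is
#: shifted up (by biology_effect_size on the log2 scale) in the listed
#: groups; the "hox_like" block is up in groups 1 and 3, i.e. down in the
#: favourable group 2, mimicking HOX-cluster suppression.
BIOLOGY_BLOCKS = (
    ("up_g1", (1,)),
    ("inflammatory_up_g2", (2,)),
    ("metabolic_up_g3", (3,)),
    ("hox_like_down_g2", (1, 3)),
)

MUTATION_PASSENGERS = (
    "TET2", "NPM1", "NRAS", "DNMT3A", "IDH1", "IDH2", "RUNX1", "TP53",
    "KRAS", "WT1", "CEBPA", "KIT", "SF3B1", "SRSF2", "U2AF1", "EZH2",
    "STAG2",
)
#: driver gene -> latent group it is enriched in
MUTATION_DRIVERS = {"ASXL1": 1, "GATA2": 2, "FLT3": 3}

#: proteins shifted up in group 3 (two correlated pairs, mTOR-axis-like)
SHIFTED_PROTEINS = ("MTOR.pS2448", "MCL1", "MTOR", "S6.pS235S236")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Effect sizes are log2-scale shifts.  ``latent_group_probs`` defaults to
    the 31:29:21 proportions; ``lineage_frac_m45`` to 45/81.  Survival uses
    exponential event times (weeks): per-endpoint baseline hazards with
    per-group multipliers and independent exponential censoring.
    """

    n_samples: int = 81
    n_genes: int = 15000
    lineage_frac_m45: float = 45 / 81
    latent_group_probs: tuple[float, float, float] = (31 / 81, 29 / 81, 21 / 81)
    n_lineage_genes: int = 600
    n_biology_genes_per_block: int = 15
    lineage_effect_size: float = 6.0
    biology_effect_size: float = 6.0
    nb_dispersion: float = 0.2
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    # survival (weeks): baseline hazards give medians near 25.4/22.4/42.4
    baseline_hazards: dict = field(
        default_factory=lambda: {"os": np.log(2) / 25.4,
                                 "efs": np.log(2) / 22.4,
                                 "remdur": np.log(2) / 42.4}
    )
    group_hazard_multipliers: tuple[float, float, float] = (1.0, 0.5, 1.1)
    censoring_rate: float = 0.004
    age_log_hr: float = 0.0  # per-year log hazard ratio (confounder when > 0)
    # mutations
    mutation_baseline_rate: float = 0.15
    driver_rate_in_group: float = 0.6
    # proteins
    n_proteins: int = 50
    protein_group3_shift: float = 1.2
    protein_pair_correlation: float = 0.5
    # gene sets
    n_decoy_sets: int = 10
    decoy_set_size: int = 15
    missing_treatment_frac: float = 11 / 81
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.latent_group_probs, dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("latent_group_probs must sum to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.lineage_effect_size < 0 or self.biology_effect_size < 0:
            raise ValueError("effect sizes must be >= 0")
        n_bio = self.n_biology_genes_per_block * len(BIOLOGY_BLOCKS)
        if self.n_lineage_genes + n_bio > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        if any(h <= 0 for h in self.baseline_hazards.values()):
            raise ValueError("baseline hazards must be positive")
        if any(m <= 0 for m in self.group_hazard_multipliers):
            raise ValueError("hazard multipliers must be positive")
        for rate in (self.mutation_baseline_rate, self.driver_rate_in_group):
            if not 0 <= rate <= 1:
                raise ValueError("mutation rates must lie in [0, 1]")


def draw_sample_labels(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample ids with lineage, a 4-level FAB refinement, and the latent
    group (1/2/3).  Lineage and group are drawn independently."""
    n = config.n_samples
    samples = [f"S{i + 1:03d}" for i in range(n)]
    m45 = rng.random(n) < config.lineage_frac_m45
    lineage = np.where(m45, "M4/M5", "M1/M2")
    refine = rng.random(n) < 0.5
    fab = np.where(m45, np.where(refine, "M4", "M5"), np.where(refine, "M1", "M2"))
    group = rng.choice([1, 2, 3], size=n, p=list(config.latent_group_probs))
    return pd.DataFrame({"lineage": lineage, "fab": fab, "group": group},
                        index=pd.Index(samples, name="sample_id"))


def _gene_truth(config: SimulationConfig) -> pd.DataFrame:
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    role = np.array(["null"] * config.n_genes, dtype=object)
    block = np.array([""] * config.n_genes, dtype=object)
    role[: config.n_lineage_genes] = "lineage"
    pos = config.n_lineage_genes
    for name, _ in BIOLOGY_BLOCKS:
        role[pos: pos + config.n_biology_genes_per_block] = "biology"
        block[pos: pos + config.n_biology_genes_per_block] = name
        pos += config.n_biology_genes_per_block
    return pd.DataFrame({"role": role, "block": block},
                        index=pd.Index(genes, name="gene"))


def simulate_expression(
    config: SimulationConfig,
    labels: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial count matrix with planted lineage and biology genes.

    log2 mean = baseline_g + lineage_effect * s_g * 1[M4/M5]  (lineage genes,
    random sign s_g) + biology_effect * 1[sample group in the gene block's
    pattern] (biology genes).  Returns the raw counts and the per-gene truth
    table (role: lineage / biology / null, biology block name).
    """
    truth = _gene_truth(config)
    n_genes, n = config.n_genes, config.n_samples
    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    base = np.clip(base, 0.5, 12.0)
    signs = rng.choice([-1.0, 1.0], size=config.n_lineage_genes)

    log2_mean = np.tile(base[:, None], (1, n))
    is_m45 = (labels["lineage"] == "M4/M5").to_numpy()
    lineage_rows = np.flatnonzero((truth["role"] == "lineage").to_numpy())
    log2_mean[np.ix_(lineage_rows, np.flatnonzero(is_m45))] += (
        config.lineage_effect_size * signs[:, None]
    )
    group = labels["group"].to_numpy()
    for name, pattern in BIOLOGY_BLOCKS:
        rows = np.flatnonzero((truth["block"] == name).to_numpy())
        cols = np.flatnonzero(np.isin(group, pattern))
        log2_mean[np.ix_(rows, cols)] += config.biology_effect_size

    mu = np.exp2(log2_mean)
    alpha = config.nb_dispersion
    counts = rng.negative_binomial(n=1.0 / alpha, p=1.0 / (1.0 + alpha * mu))
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=truth.index, columns=labels.index),
        Scale.raw_counts,
    )
    return expr, truth


def simulate_clinical_survival(
    config: SimulationConfig,
    labels: pd.DataFrame,
    rng: np.random.Generator,
) -> ClinicalTable:
    """Clinical covariates plus exponential survival endpoints.

    Event hazards are baseline * group multiplier * exp(age_log_hr *
    (age - 65)); censoring is an independent exponential clock shared per
    sample draw.  Covariates other than the optional age effect are drawn
    independently of the group, so outcome differences are group-driven.
    """
    n = config.n_samples
    group = labels["group"].to_numpy()
    age = np.clip(rng.normal(64.3, 14.1, n), 18, 86)
    sex = rng.choice(["male", "female"], size=n, p=[47 / 81, 34 / 81])
    ahd = (rng.random(n) < 33 / 81).astype(int)
    eln = rng.choice(["favorable", "intermediate", "unfavorable"], size=n,
                     p=[5 / 81, 46 / 81, 30 / 81])
    treatment = rng.choice(["arac", "hma", "investigational"], size=n,
                           p=[56 / 70, 9 / 70, 5 / 70]).astype(object)
    treatment[rng.random(n) < config.missing_treatment_frac] = None
    blast = np.clip(rng.normal(60.0, 23.1, n), 1, 100)

    mult = np.asarray(config.group_hazard_multipliers)[group - 1]
    frailty = np.exp(config.age_log_hr * (age - 65.0))
    data = {
        "fab": labels["fab"], "eln": eln, "age": age, "sex": sex,
        "ahd": ahd, "treatment": treatment, "blast_pct": blast,
    }
    for endpoint, h0 in config.baseline_hazards.items():
        hazard = h0 * mult * frailty
        t_event = rng.exponential(1.0 / hazard)
        if config.censoring_rate > 0:
            t_cens = rng.exponential(1.0 / config.censoring_rate, n)
        else:
            t_cens = np.full(n, np.inf)
        data[f"{endpoint}_time"] = np.minimum(t_event, t_cens)
        data[f"{endpoint}_event"] = (t_event <= t_cens).astype(int)
    return ClinicalTable(pd.DataFrame(data, index=labels.index))


def simulate_mutations_proteins(
    config: SimulationConfig,
    labels: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[MutationMatrix, ProteinMatrix]:
    """Binary mutation calls with three group-enriched drivers and a
    protein panel with correlated group-3 shifts on the mTOR-axis pair."""
    n = config.n_samples
    group = labels["group"].to_numpy()
    genes = list(MUTATION_DRIVERS) + list(MUTATION_PASSENGERS)
    rates = np.full((len(genes), n), config.mutation_baseline_rate)
    for i, (gene, g) in enumerate(MUTATION_DRIVERS.items()):
        rates[i, group == g] = config.driver_rate_in_group
    calls = (rng.random((len(genes), n)) < rates).astype(int)
    mutations = MutationMatrix(
        pd.DataFrame(calls, index=pd.Index(genes, name="gene"), columns=labels.index)
    )

    proteins = list(SHIFTED_PROTEINS) + [
        f"PROT_{i + 1:03d}" for i in range(config.n_proteins - len(SHIFTED_PROTEINS))
    ]
    values = rng.normal(0.0, 1.0, (len(proteins), n))
    rho = config.protein_pair_correlation
    shared = rng.normal(0.0, 1.0, n)
    for pair in ((0, 1), (2, 3)):  # correlated pairs among the shifted four
        for idx in pair:
            values[idx] = np.sqrt(1 - rho) * values[idx] + np.sqrt(rho) * shared
    in_g3 = group == 3
    values[: len(SHIFTED_PROTEINS), in_g3] += config.protein_group3_shift
    protein_matrix = ProteinMatrix(
        pd.DataFrame(values, index=pd.Index(proteins, name="protein"),
                     columns=labels.index)
    )
    return mutations, protein_matrix


def generate_gene_set_collection(
    config: SimulationConfig,
    gene_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> GeneSetCollection:
    """Planted gene sets (inflammatory up-in-group-2, metabolic
    up-in-group-3, HOX-like down-in-group-2 split into A/B halves) plus
    size-matched random decoy sets drawn from the null genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    block_sets = {
        "INFLAMMATORY_RESPONSE": "inflammatory_up_g2",
        "METABOLIC_OXPHOS": "metabolic_up_g3",
    }
    for set_name, block in block_sets.items():
        sets[set_name] = gene_truth.index[gene_truth["block"] == block].tolist()
        descriptions[set_name] = f"planted block {block}"
    hox = gene_truth.index[gene_truth["block"] == "hox_like_down_g2"].tolist()
    half = len(hox) // 2
    sets["HOXA_LIKE"], sets["HOXB_LIKE"] = hox[:half], hox[half:]
    descriptions["HOXA_LIKE"] = descriptions["HOXB_LIKE"] = (
        "planted block hox_like_down_g2"
    )
    nulls = gene_truth.index[gene_truth["role"] == "null"].to_numpy()
    if config.decoy_set_size > nulls.size:
        raise ValueError("decoy set size exceeds the null-gene universe")
    for i in range(config.n_decoy_sets):
        pick = rng.choice(nulls, size=config.decoy_set_size, replace=False)
        sets[f"DECOY_{i + 1:02d}"] = list(pick)
        descriptions[f"DECOY_{i + 1:02d}"] = "random null genes"
    return GeneSetCollection(sets, descriptions)


@dataclass
class SyntheticCohort:
    """A full simulated multi-omic cohort with its ground truth."""

    config: SimulationConfig
    expression: ExpressionMatrix  # raw counts
    clinical: ClinicalTable
    mutations: MutationMatrix
    proteins: ProteinMatrix
    gene_sets: GeneSetCollection
    sample_truth: pd.DataFrame  # lineage, fab, group per sample
    gene_truth: pd.DataFrame  # role, block per gene

    @property
    def latent_groups(self) -> pd.Series:
        return self.sample_truth["group"]

    def write(self, out_dir: str | Path) -> None:
        from . import io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_expression_matrix(self.expression, out / "counts.tsv")
        io.write_clinical_table(self.clinical, out / "clinical.csv")
        io.write_mutation_matrix(self.mutations, out / "mutations.tsv")
        io.write_protein_matrix(self.proteins, out / "proteins.tsv")
        io.write_gene_sets_gmt(self.gene_sets, out / "gene_sets.gmt")
        self.sample_truth.to_csv(out / "truth_samples.tsv", sep="\t")
        self.gene_truth.to_csv(out / "truth_genes.tsv", sep="\t")


def simulate_cohort(config: SimulationConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a complete cohort; fixed (config, seed) gives a
    byte-identical cohort.  ``seed`` overrides ``config.seed``."""
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    rng = np.random.default_rng(config.seed)
    labels = draw_sample_labels(config, rng)
    expression, gene_truth = simulate_expression(config, labels, rng)
    clinical = simulate_clinical_survival(config, labels, rng)
    mutations, proteins = simulate_mutations_proteins(config, labels, rng)
    gene_sets = generate_gene_set_collection(config, gene_truth, rng)
    return SyntheticCohort(config, expression, clinical, mutations, proteins,
                           gene_sets, labels, gene_truth)
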