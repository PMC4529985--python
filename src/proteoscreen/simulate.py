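"""Synthetic inputs with the statistical structure the screen assumes.

The generators emulate a three-condition (untreated control, nutrient-
overload treatment, comparator treatment) by three-replicate intensity
design.  Intensities are log-normal — positive and right-skewed, as
microarray and label-free LC-MS abundances are — with planted gene classes:

* *specific* genes up-regulated by the treatment only (default 2.2-fold),
* *shared* genes up-regulated by both treatment and comparator (2.3-fold),
* *null* genes unchanged everywhere.

Protein tables reuse each gene's planted effect with independent noise
(conservative coupling: shared effect size, uncorrelated measurement
error).  The interaction network wires each specific gene to a set of
high-confidence partners (score >= 900 on the 0-1000 scale), plus decoy
edges below the confidence cutoff; annotations cover a candidate's partner
neighbourhood with random terms plus one genuinely enriched term.  Every
generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import InteractionNetwork
import networkx as nx

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "generate_expression",
    "generate_proteomics",
    "generate_network",
    "generate_annotations",
    "write_expression",
    "write_protein_table",
    "write_network",
    "write_annotations",
]

#: Condition roles, in order: untreated control, treatment, comparator.
DEFAULT_CONDITIONS = ("control", "LPON", "OLE")


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated experiment.

    noise_sd is the standard deviation of log-intensities (natural-log
    scale); 0.1 corresponds to a ~10 % coefficient of variation between
    biological replicates.  base_log_mean only sets the intensity scale and
    cancels from every ratio-based statistic.
    """

    n_genes: int = 500
    n_replicates: int = 3
    conditions: tuple[str, str, str] = DEFAULT_CONDITIONS
    n_specific: int = 10
    n_shared: int = 10
    specific_fc: float = 2.2
    shared_fc: float = 2.3
    base_log_mean: float = 6.0
    noise_sd: float = 0.1
    proteome_coverage: float = 1.0
    peptide_count_range: tuple[int, int] = (1, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive count")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive count")
        if len(self.conditions) != 3 or len(set(self.conditions)) != 3:
            raise ValueError("conditions must be three distinct labels")
        if self.n_specific < 0:
            raise ValueError("n_specific must be >= 0")
        if self.n_shared < 0:
            raise ValueError("n_shared must be >= 0")
        if self.n_specific + self.n_shared > self.n_genes:
            raise ValueError("n_specific + n_shared must not exceed n_genes")
        if self.specific_fc < 1:
            raise ValueError("specific_fc must be >= 1")
        if self.shared_fc < 1:
            raise ValueError("shared_fc must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.proteome_coverage <= 1.0):
            raise ValueError("proteome_coverage must lie in [0, 1]")
        lo, hi = self.peptide_count_range
        if lo < 1 or hi < lo:
            raise ValueError("peptide_count_range must be a valid interval with lower bound >= 1")

    @property
    def control(self) -> str:
        return self.conditions[0]

    @property
    def treatment(self) -> str:
        return self.conditions[1]

    @property
    def comparator(self) -> str:
        return self.conditions[2]


@dataclass
class PlantedTruth:
    """Ground truth of one simulated experiment.

    ``specific_genes``, ``shared_genes`` and ``null_genes`` partition the
    gene universe; ``true_fc`` holds each gene's planted fold change per
    condition (1.0 for the control column by construction).
    """

    specific_genes: list[str]
    shared_genes: list[str]
    null_genes: list[str]
    true_fc: pd.DataFrame = field(repr=False)

    @property
    def all_genes(self) -> list[str]:
        return list(self.true_fc.index)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _truth_for(config: SimulationConfig) -> PlantedTruth:
    genes = _gene_ids(config.n_genes)
    specific = genes[: config.n_specific]
    shared = genes[config.n_specific : config.n_specific + config.n_shared]
    null = genes[config.n_specific + config.n_shared :]
    fc = pd.DataFrame(1.0, index=genes, columns=list(config.conditions))
    fc.loc[specific, config.treatment] = config.specific_fc
    fc.loc[shared, config.treatment] = config.shared_fc
    fc.loc[shared, config.comparator] = config.shared_fc
    return PlantedTruth(specific, shared, null, fc)


def _sample_ids(config: SimulationConfig) -> tuple[list[str], pd.Series]:
    samples, conds = [], []
    for cond in config.conditions:
        for r in range(1, config.n_replicates + 1):
            samples.append(f"{cond}_{r}")
            conds.append(cond)
    return samples, pd.Series(conds, index=samples, name="condition")


def generate_expression(config: SimulationConfig):
    """Simulate a genes x samples intensity matrix with planted effects.

    Each intensity is ``exp(Normal(base_log_mean, noise_sd))`` multiplied
    by the gene's planted fold change under the sample's condition.
    Returns ``(ExpressionMatrix, PlantedTruth)``.
    """
    from .transcriptomics import ExpressionMatrix

    truth = _truth_for(config)
    samples, conditions = _sample_ids(config)
    rng = np.random.default_rng(config.seed)
    log_noise = rng.normal(config.base_log_mean, config.noise_sd, (config.n_genes, len(samples)))
    effects = truth.true_fc[conditions.to_numpy()].to_numpy()
    values = pd.DataFrame(np.exp(log_noise) * effects, index=truth.all_genes, columns=samples)
    values.index.name = "gene_id"
    return ExpressionMatrix(values=values, conditions=conditions), truth


def generate_proteomics(config: SimulationConfig, truth: PlantedTruth) -> pd.DataFrame:
    """Simulate a label-free protein table coupled to the planted effects.

    A ``proteome_coverage`` fraction of genes (chosen at random) gets one
    protein row whose intensities carry the same planted fold change as the
    transcript, with independent log-normal noise.  Unique-peptide counts
    are uniform over ``peptide_count_range``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    genes = truth.all_genes
    n_cover = int(round(config.proteome_coverage * len(genes)))
    covered = sorted(rng.choice(genes, size=n_cover, replace=False))
    samples, conditions = _sample_ids(config)
    lo, hi = config.peptide_count_range
    if not covered:
        return pd.DataFrame(columns=["protein_id", "gene_symbol", "unique_peptides", *samples])
    log_noise = rng.normal(config.base_log_mean, config.noise_sd, (len(covered), len(samples)))
    effects = truth.true_fc.loc[covered, conditions.to_numpy()].to_numpy()
    intensities = np.exp(log_noise) * effects
    table = pd.DataFrame(intensities, columns=samples)
    table.insert(0, "unique_peptides", rng.integers(lo, hi + 1, size=len(covered)))
    table.insert(0, "gene_symbol", covered)
    table.insert(0, "protein_id", [f"P_{g}" for g in covered])
    return table


def generate_network(
    truth: PlantedTruth,
    partners_per_candidate: int = 32,
    decoy_edges: int = 100,
    seed: int = 0,
) -> InteractionNetwork:
    """Wire each planted specific gene to high-confidence partners.

    Partners are drawn from the null genes and connected at combined
    scores uniform on [900, 999] (the 0-1000 integer scale); ``decoy_edges``
    random additional edges get sub-threshold scores on [150, 899] so that
    the 0.900-confidence partner query is unaffected by them.
    """
    if partners_per_candidate < 0:
        raise ValueError("partners_per_candidate must be >= 0")
    if decoy_edges < 0:
        raise ValueError("decoy_edges must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    graph = nx.Graph()
    graph.add_nodes_from(truth.all_genes)
    pool = list(truth.null_genes)
    for cand in truth.specific_genes:
        if partners_per_candidate > len(pool):
            raise ValueError("not enough null genes to supply partners_per_candidate")
        chosen = rng.choice(pool, size=partners_per_candidate, replace=False)
        for partner in chosen:
            score = int(rng.integers(900, 1000))
            if graph.has_edge(cand, partner):
                score = max(score, graph.edges[cand, partner]["score"])
            graph.add_edge(cand, partner, score=score)
    genes = truth.all_genes
    added = 0
    while added < decoy_edges:
        u, v = rng.choice(genes, size=2, replace=False)
        if graph.has_edge(u, v):
            continue
        graph.add_edge(u, v, score=int(rng.integers(150, 900)))
        added += 1
    return InteractionNetwork(graph=graph, scale="integer")


def generate_annotations(
    genes,
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (3, 12),
    seed: int = 0,
    enriched_genes=None,
) -> dict[str, set[str]]:
    """Random term memberships over a gene universe, plus one planted term.

    ``enriched_genes`` (when given) become the membership of term
    ``TERM_ENRICHED``, so downstream ranked enrichment has a known positive
    control.  Random terms draw their sizes uniformly from
    ``term_size_range`` (clipped to the universe size).
    """
    genes = list(genes)
    if n_terms < 0:
        raise ValueError("n_terms must be >= 0")
    lo, hi = term_size_range
    if lo < 1 or hi < lo:
        raise ValueError("term_size_range must be a valid interval with lower bound >= 1")
    if lo > len(genes):
        raise ValueError("term sizes exceed the universe size")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    annotations: dict[str, set[str]] = {}
    for i in range(1, n_terms + 1):
        size = int(rng.integers(lo, min(hi, len(genes)) + 1))
        annotations[f"TERM_{i:03d}"] = set(rng.choice(genes, size=size, replace=False))
    if enriched_genes is not None:
        annotations["TERM_ENRICHED"] = set(enriched_genes)
    return annotations


# ---------------------------------------------------------------------------
# Plain-text writers (TSV / STRING protein.links dialect)

def write_expression(expr, matrix_path, condition_map_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t")
    expr.conditions.rename("condition").to_csv(condition_map_path, sep="\t", index_label="sample_id")


def write_protein_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_network(network: InteractionNetwork, path) -> None:
    """Write edges in the STRING protein.links dialect (space-separated)."""
    with open(path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for u, v, data in sorted(network.graph.edges(data=True)):
            score = data["score"]
            score_txt = f"{score:g}" if network.scale == "fractional" else str(int(score))
            fh.write(f"{u} {v} {score_txt}\n")


def write_annotations(annotations: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotations):
            for gene in sorted(annotations[term]):
                fh.write(f"{term}\t{gene}\n")
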