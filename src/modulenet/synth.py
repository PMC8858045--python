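"""Synthetic data with planted ground truth.

Generates the four substrates the pipeline consumes:

* expression matrices with planted correlated gene modules driven by latent
  factors, a subset of which shift their factor mean in case samples;
* scale-free interactomes via preferential attachment;
* disease-gene sets planted with tunable network locality;
* drug-target sets either proximal to the disease genes or uniform.

Every generator is deterministic given its seed, and the returned
:class:`SyntheticTruth` carries enough labels to score module recovery
(ARI), key-gene recall, and drug-class separation downstream.

Under the latent-factor model a member gene is ``loading * factor + noise``,
so the expected within-module correlation is
``loading**2 / (loading**2 + noise_sd**2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import CASE, CONTROL, DrugTarget, ExpressionMatrix

logger = logging.getLogger(__name__)

BACKGROUND = "background"

__all__ = [
    "SyntheticTruth",
    "simulate_expression",
    "simulate_scale_free_network",
    "plant_disease_genes",
    "plant_key_genes",
    "simulate_drugs",
    "sample_disease_gene_set",
]


@dataclass
class SyntheticTruth:
    """Ground-truth labels recorded by the generators."""

    module_of_gene: dict[str, str] = field(default_factory=dict)
    disease_modules: list[str] = field(default_factory=list)
    disease_genes: set = field(default_factory=set)
    key_genes: set = field(default_factory=set)
    drug_class: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        planted = set(self.module_of_gene.values()) - {BACKGROUND}
        if not set(self.disease_modules) <= planted:
            raise ValueError("disease_modules must be planted module labels")
        if any(c not in {"proximal", "random"} for c in self.drug_class.values()):
            raise ValueError("drug classes must be 'proximal' or 'random'")


def simulate_expression(
    n_genes: int = 400,
    n_samples_per_condition: int = 8,
    module_sizes=(50, 50, 50, 50),
    effect: float = 2.0,
    loading: float = 0.8,
    noise_sd: float = 0.6,
    n_disease_modules: int = 2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Latent-factor expression with planted modules and case shifts.

    Each planted module m draws a per-sample factor ``f_m ~ N(0, 1)``; for
    the first ``n_disease_modules`` modules the case-sample factor mean is
    shifted by ``effect``. A member gene is ``loading * f_m + N(0,
    noise_sd)``; the remaining genes are pure ``N(0, 1)`` background noise.
    """
    module_sizes = list(module_sizes)
    if any(s <= 0 for s in module_sizes) or n_genes <= 0:
        raise ValueError("sizes must be positive")
    if n_samples_per_condition < 2:
        raise ValueError("need at least 2 samples per condition")
    if sum(module_sizes) > n_genes:
        raise ValueError("sum(module_sizes) exceeds n_genes")
    if n_disease_modules > len(module_sizes):
        raise ValueError("n_disease_modules exceeds number of modules")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if not (0 < loading <= 1):
        raise ValueError("loading must be in (0, 1]")

    rng = np.random.default_rng(seed)
    n_samples = 2 * n_samples_per_condition
    case_mask = np.array([True] * n_samples_per_condition + [False] * n_samples_per_condition)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    sample_ids = [f"S{i:02d}" for i in range(n_samples)]
    condition = [CASE if c else CONTROL for c in case_mask]

    values = np.empty((n_genes, n_samples))
    truth = SyntheticTruth()
    row = 0
    for m, size in enumerate(module_sizes):
        label = f"planted{m + 1}"
        factor = rng.standard_normal(n_samples)
        if m < n_disease_modules:
            factor = factor + effect * case_mask
            truth.disease_modules.append(label)
        noise = rng.normal(scale=noise_sd, size=(size, n_samples))
        values[row : row + size] = loading * factor + noise
        for g in gene_ids[row : row + size]:
            truth.module_of_gene[g] = label
        row += size
    n_bg = n_genes - row
    values[row:] = rng.standard_normal((n_bg, n_samples))
    for g in gene_ids[row:]:
        truth.module_of_gene[g] = BACKGROUND

    expr = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        condition=condition,
    )
    truth.validate()
    return expr, truth


def simulate_scale_free_network(
    n_nodes: int, edges_per_new_node: int, seed: int = 0, node_labels=None
) -> nx.Graph:
    """Preferential-attachment graph: connected, heavy-tailed degrees.

    Edge count is exactly ``edges_per_new_node * (n_nodes -
    edges_per_new_node)``. ``node_labels`` (length n_nodes) replaces the
    integer node ids, in attachment order.
    """
    if edges_per_new_node < 1 or n_nodes <= edges_per_new_node:
        raise ValueError("need n_nodes > edges_per_new_node >= 1")
    g = nx.barabasi_albert_graph(n_nodes, edges_per_new_node, seed=int(seed))
    if node_labels is not None:
        if len(node_labels) != n_nodes:
            raise ValueError("node_labels length must equal n_nodes")
        g = nx.relabel_nodes(g, dict(enumerate(node_labels)))
    return g


def plant_disease_genes(
    network: nx.Graph, n_disease: int, locality: float = 0.8, seed: int = 0
) -> set:
    """Choose a disease-gene node set clustered in the network.

    The first gene is uniform; each subsequent gene is, with probability
    ``locality``, drawn uniformly from the unchosen neighbours of the
    current disease set, otherwise uniformly from all unchosen nodes. When
    the neighbourhood is exhausted the draw falls back to uniform (logged).
    """
    if not 0 <= locality <= 1:
        raise ValueError("locality must be in [0, 1]")
    nodes = sorted(network.nodes())
    if n_disease >= len(nodes):
        raise ValueError("n_disease must be below the node count")
    rng = np.random.default_rng(seed)
    chosen: list = [nodes[rng.integers(len(nodes))]]
    frontier = set(network.neighbors(chosen[0]))
    remaining = set(nodes) - set(chosen)
    while len(chosen) < n_disease:
        pool = sorted(frontier & remaining)
        if rng.random() < locality and pool:
            pick = pool[rng.integers(len(pool))]
        else:
            if rng.random() < locality and not pool:
                logger.info("disease-gene neighbourhood exhausted; uniform draw")
            rem = sorted(remaining)
            pick = rem[rng.integers(len(rem))]
        chosen.append(pick)
        remaining.discard(pick)
        frontier |= set(network.neighbors(pick))
    return set(chosen)


def plant_key_genes(
    network: nx.Graph,
    disease_genes,
    n_key: int = 3,
    links_per_key: int = 18,
    seed: int = 0,
) -> set:
    """Wire a few non-disease nodes into disease-neighbour hubs (in place).

    Each planted key gene gains edges to ``links_per_key`` distinct disease
    genes, making it a high-degree node whose neighbourhood is dominated by
    the disease class — the signature the disease-network statistics are
    designed to detect.
    """
    disease_genes = set(disease_genes)
    if links_per_key > len(disease_genes):
        raise ValueError("links_per_key exceeds disease gene count")
    rng = np.random.default_rng(seed)
    candidates = sorted(set(network.nodes()) - disease_genes)
    if n_key > len(candidates):
        raise ValueError("not enough non-disease nodes to plant key genes")
    keys = [candidates[i] for i in rng.choice(len(candidates), size=n_key, replace=False)]
    dis_sorted = sorted(disease_genes)
    for k in keys:
        picks = rng.choice(len(dis_sorted), size=links_per_key, replace=False)
        # shed pre-existing non-disease edges so the disease fraction is high
        for nbr in list(network.neighbors(k)):
            if nbr not in disease_genes and network.degree[nbr] > 1:
                network.remove_edge(k, nbr)
        for i in picks:
            network.add_edge(k, dis_sorted[i])
    return set(keys)


def simulate_drugs(
    network: nx.Graph,
    disease_genes,
    n_proximal: int = 20,
    n_random: int = 80,
    targets_per_drug: int = 4,
    seed: int = 0,
    in_disease_frac: float = 0.5,
) -> tuple[list[DrugTarget], SyntheticTruth]:
    """Drug-target sets at controlled proximity to the disease genes.

    Proximal drugs draw targets from the disease genes and their immediate
    neighbours — each target lands inside the disease set itself with
    probability ``in_disease_frac`` (a drug directly hitting disease
    proteins), otherwise on a first neighbour. Random drugs draw uniformly
    from all nodes.
    """
    if targets_per_drug < 1:
        raise ValueError("targets_per_drug must be >= 1")
    disease_genes = set(disease_genes) & set(network.nodes())
    rng = np.random.default_rng(seed)
    neighbourhood = set(disease_genes)
    for d in disease_genes:
        neighbourhood |= set(network.neighbors(d))
    dis_pool = sorted(disease_genes)
    nbr_pool = sorted(neighbourhood - disease_genes)
    all_pool = sorted(network.nodes())
    if targets_per_drug > len(neighbourhood) and n_proximal > 0:
        raise ValueError("targets_per_drug exceeds proximal candidate pool")
    if targets_per_drug > len(all_pool):
        raise ValueError("targets_per_drug exceeds node count")

    drugs: list[DrugTarget] = []
    truth = SyntheticTruth()
    for i in range(n_proximal + n_random):
        proximal = i < n_proximal
        if proximal:
            n_in = int(rng.binomial(targets_per_drug, in_disease_frac))
            n_in = min(n_in, len(dis_pool))
            n_out = min(targets_per_drug - n_in, len(nbr_pool))
            n_in = targets_per_drug - n_out
            targets = {
                dis_pool[j] for j in rng.choice(len(dis_pool), size=n_in, replace=False)
            }
            if n_out:
                targets |= {
                    nbr_pool[j]
                    for j in rng.choice(len(nbr_pool), size=n_out, replace=False)
                }
            targets = frozenset(targets)
        else:
            targets = frozenset(
                all_pool[j]
                for j in rng.choice(len(all_pool), size=targets_per_drug, replace=False)
            )
        drug_id = f"DRUG{i:03d}"
        drugs.append(
            DrugTarget(drug_id=drug_id, drug_name=f"drug-{i:03d}", targets=targets)
        )
        truth.drug_class[drug_id] = "proximal" if proximal else "random"
    truth.validate()
    return drugs, truth


def sample_disease_gene_set(
    truth: SyntheticTruth,
    n_from_disease_modules: int = 30,
    n_background: int = 10,
    seed: int = 0,
) -> set:
    """Draw a disease-gene catalogue aligned with the planted modules.

    Emulates a curated disease-gene database: mostly members of the
    disease-associated modules, plus a few unrelated genes.
    """
    rng = np.random.default_rng(seed)
    dm = set(truth.disease_modules)
    in_mod = sorted(g for g, m in truth.module_of_gene.items() if m in dm)
    outside = sorted(g for g, m in truth.module_of_gene.items() if m not in dm)
    if n_from_disease_modules > len(in_mod) or n_background > len(outside):
        raise ValueError("requested more genes than available")
    chosen = {in_mod[i] for i in rng.choice(len(in_mod), n_from_disease_modules, replace=False)}
    chosen |= {outside[i] for i in rng.choice(len(outside), n_background, replace=False)}
    return chosen
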