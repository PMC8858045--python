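"""Disease-specific interaction-network statistics.

Nodes of the combined disease network carry one of three classes:
``disease`` (catalogued disease genes), ``candidate`` (core genes entering
the network from the co-expression analysis), or ``other``. For every
candidate the module computes degree, disease-neighbour count and ratio,
mean shortest-path distances to the disease and candidate classes and
their ratio, an analytic hypergeometric p for the neighbour count, and
permutation p-values referenced to class-shuffled (degree-preserving)
null networks. Candidates that look like disease hubs — significantly
disease-enriched neighbourhoods, significantly short paths to the disease
class, and top-tail degree — are selected as key genes.

Also provides induced subnetworks, degree ranking, and pre-ranked GSEA on
any node score.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .io import GeneSetCollection
from .stats import bh_fdr, hypergeom_upper

DISEASE, CANDIDATE, OTHER = "disease", "candidate", "other"

__all__ = [
    "set_node_classes",
    "induce_subnetwork",
    "degree_rank",
    "preranked_gsea",
    "node_disease_stats",
    "select_key_genes",
]


def set_node_classes(network: nx.Graph, disease_genes, candidate_genes) -> nx.Graph:
    """Attach disjoint node classes; disease wins on overlap."""
    disease_genes = set(disease_genes)
    candidate_genes = set(candidate_genes) - disease_genes
    for n in network.nodes():
        if n in disease_genes:
            cls = DISEASE
        elif n in candidate_genes:
            cls = CANDIDATE
        else:
            cls = OTHER
        network.nodes[n]["node_class"] = cls
    return network


def induce_subnetwork(network: nx.Graph, genes) -> tuple[nx.Graph, int]:
    """Subgraph on ``genes``, isolated nodes dropped (returned as a count)."""
    present = set(genes) & set(network.nodes())
    if not present:
        raise ValueError("no requested genes present in the network")
    sub = network.subgraph(present).copy()
    isolates = [n for n, d in sub.degree() if d == 0]
    sub.remove_nodes_from(isolates)
    if sub.number_of_nodes() == 0:
        raise ValueError("no edges among the requested genes")
    return sub, len(isolates)


def degree_rank(network: nx.Graph) -> pd.Series:
    """Node degrees as a total order: degree descending, id ascending."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = pd.Series(dict(network.degree()), dtype=float)
    return deg.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort"
    )


def _running_es(is_hit: np.ndarray, weights: np.ndarray) -> float:
    n = is_hit.size
    nh = int(is_hit.sum())
    if nh == 0 or nh == n:
        return 0.0
    w = np.where(is_hit, weights, 0.0)
    nr = w.sum()
    steps = np.where(is_hit, w / nr if nr > 0 else 1.0 / nh, -1.0 / (n - nh))
    run = np.cumsum(steps)
    return float(run[np.argmax(np.abs(run))])


def preranked_gsea(
    ranks: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA with a gene-label permutation null.

    ``ranks`` must already follow the canonical order (score descending,
    id ascending). The running sum increments ``|score|**weight_p``
    (normalised over in-set genes) at hits and decrements ``1/(N - set
    size)`` at misses; ES is the extreme deviation. The null permutes which
    genes belong to the set; p is one-tailed among same-sign null ES, and
    NES divides ES by the mean |null ES| of matching sign. BH FDR across
    sets.
    """
    genes = np.array(ranks.index)
    scores = ranks.to_numpy(float)
    weights = np.abs(scores) ** weight_p
    n = genes.size
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in collection.sets.items():
        is_hit = np.isin(genes, sorted(members))
        nh = int(is_hit.sum())
        if nh == 0:
            warnings.warn(f"set {name!r} has no members in the ranked universe; skipped")
            continue
        es = _running_es(is_hit, weights)
        null = np.empty(n_perm)
        for b in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=nh, replace=False)] = True
            null[b] = _running_es(mask, weights)
        same = null * np.sign(es) > 0 if es != 0 else np.ones(n_perm, dtype=bool)
        n_same = int(same.sum())
        p = (1 + int((np.abs(null[same]) >= abs(es)).sum())) / (1 + n_same)
        denom = np.abs(null[same]).mean() if n_same else np.nan
        nes = es / denom if denom and denom > 0 else np.nan
        rows.append({"set": name, "size": nh, "es": es, "nes": nes, "p_perm": p})
    table = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p_perm"])
    table["fdr"] = bh_fdr(table["p_perm"])
    return table.sort_values(["p_perm", "set"], kind="mergesort").reset_index(drop=True)


def _class_masks(network: nx.Graph, nodes):
    cls = np.array([network.nodes[n].get("node_class", OTHER) for n in nodes])
    return cls == DISEASE, cls == CANDIDATE


def _sp_means(dfin, fin_counts, mask, self_mask):
    """Mean finite shortest path from every node to the masked class."""
    sums = dfin @ mask
    counts = fin_counts @ mask - (mask & self_mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def node_disease_stats(
    network: nx.Graph,
    n_perm: int = 1000,
    seed: int = 0,
    null_model: str = "class_shuffle",
) -> pd.DataFrame:
    """Per-candidate disease-connectivity statistics with permutation nulls.

    Analytic column: ``p_count_hyper`` is the upper-tail hypergeometric p of
    the disease-neighbour count when drawing ``degree`` neighbours from the
    other ``N - 1`` nodes containing ``K`` disease nodes. The permutation
    null shuffles node-class labels with class counts fixed (keeping every
    degree intact) and recomputes, for each focal candidate, the
    disease-neighbour ratio (upper tail) and the shortest-path ratio (lower
    tail); the focal node is excluded from the permuted class sets.
    Empirical p-values use the plus-one rule. ``null_model="rewire"``
    instead performs degree-preserving double-edge swaps with classes fixed.

    Unreachable targets are excluded from shortest-path means and counted
    in ``n_unreachable_disease``. Isolated candidates are flagged with NaN
    statistics.
    """
    nodes = sorted(network.nodes())
    n = len(nodes)
    dis_mask, cand_mask = _class_masks(network, nodes)
    if dis_mask.sum() < 1 or cand_mask.sum() < 2:
        raise ValueError("need >= 1 disease and >= 2 candidate nodes")
    if null_model not in {"class_shuffle", "rewire"}:
        raise ValueError(f"unknown null_model {null_model!r}")

    a = nx.to_numpy_array(network, nodelist=nodes, dtype=float)
    d = shortest_path(a != 0, method="D", unweighted=True)
    finite = np.isfinite(d)
    np.fill_diagonal(finite, True)
    dfin = np.where(finite, d, 0.0)
    fin_counts = finite.astype(float)
    self_mask = np.ones(n, dtype=bool)

    degrees = a.sum(axis=1)
    dnc = a @ dis_mask
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(degrees > 0, dnc / np.maximum(degrees, 1), np.nan)
    msd = _sp_means(dfin, fin_counts, dis_mask, self_mask)
    # candidates measure distance to *other* candidates (self excluded)
    msc_sums = dfin @ cand_mask
    msc_counts = fin_counts @ cand_mask - cand_mask.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        msc = np.where(msc_counts > 0, msc_sums / np.maximum(msc_counts, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp_ratio = msd / msc
    unreachable_dis = int(dis_mask.sum()) - (fin_counts @ dis_mask)
    degree_percentile = np.array(
        [float((degrees <= g).mean()) for g in degrees]
    )

    rng = np.random.default_rng(seed)
    cls_vector = np.where(dis_mask, 0, np.where(cand_mask, 1, 2))
    cand_idx = np.where(cand_mask)[0]
    ge_ratio = np.zeros(n, dtype=int)
    le_sp = np.zeros(n, dtype=int)

    g_perm = network.copy() if null_model == "rewire" else None
    for _ in range(n_perm):
        if null_model == "class_shuffle":
            perm = rng.permutation(cls_vector)
            p_dis = perm == 0
            p_cand = perm == 1
            a_p, dfin_p, fin_p = a, dfin, fin_counts
        else:
            nx.double_edge_swap(
                g_perm,
                nswap=2 * g_perm.number_of_edges(),
                max_tries=40 * g_perm.number_of_edges(),
                seed=int(rng.integers(2**31 - 1)),
            )
            a_p = nx.to_numpy_array(g_perm, nodelist=nodes, dtype=float)
            d_p = shortest_path(a_p != 0, method="D", unweighted=True)
            fin_bool = np.isfinite(d_p)
            np.fill_diagonal(fin_bool, True)
            dfin_p = np.where(fin_bool, d_p, 0.0)
            fin_p = fin_bool.astype(float)
            p_dis, p_cand = dis_mask, cand_mask

        # focal nodes are excluded from the permuted class sets; a node is
        # never its own neighbour, so the neighbour count needs no fixup
        deg_p = a_p.sum(axis=1)
        dnc_p = a_p @ p_dis
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio_p = np.where(deg_p > 0, dnc_p / np.maximum(deg_p, 1), np.nan)
        msd_sums = dfin_p @ p_dis
        msd_counts = fin_p @ p_dis - p_dis.astype(float)
        msc2_counts = fin_p @ p_cand - p_cand.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            msd_p = np.where(msd_counts > 0, msd_sums / np.maximum(msd_counts, 1), np.nan)
            msc_p = np.where(
                msc2_counts > 0, (dfin_p @ p_cand) / np.maximum(msc2_counts, 1), np.nan
            )
            sp_ratio_p = msd_p / msc_p
        with np.errstate(invalid="ignore"):
            ge_ratio += np.where(np.isnan(ratio_p) | np.isnan(ratio), False, ratio_p >= ratio)
            le_sp += np.where(
                np.isnan(sp_ratio_p) | np.isnan(sp_ratio), False, sp_ratio_p <= sp_ratio
            )

    k_dis = int(dis_mask.sum())
    rows = []
    for i in cand_idx:
        node = nodes[i]
        deg = int(degrees[i])
        if deg == 0:
            rows.append(
                {
                    "gene": node,
                    "degree": 0,
                    "disease_neighbor_count": 0,
                    "interaction_ratio": np.nan,
                    "p_count_hyper": np.nan,
                    "p_ratio_perm": np.nan,
                    "mean_sp_disease": np.nan,
                    "mean_sp_candidate": np.nan,
                    "shortest_ratio": np.nan,
                    "p_shortest_perm": np.nan,
                    "degree_percentile": degree_percentile[i],
                    "n_unreachable_disease": k_dis,
                    "note": "isolated",
                }
            )
            continue
        rows.append(
            {
                "gene": node,
                "degree": deg,
                "disease_neighbor_count": int(dnc[i]),
                "interaction_ratio": float(ratio[i]),
                "p_count_hyper": hypergeom_upper(int(dnc[i]), n - 1, k_dis, deg),
                "p_ratio_perm": (1 + int(ge_ratio[i])) / (1 + n_perm),
                "mean_sp_disease": float(msd[i]),
                "mean_sp_candidate": float(msc[i]),
                "shortest_ratio": float(sp_ratio[i]) if np.isfinite(sp_ratio[i]) else np.nan,
                "p_shortest_perm": (1 + int(le_sp[i])) / (1 + n_perm)
                if np.isfinite(sp_ratio[i])
                else np.nan,
                "degree_percentile": degree_percentile[i],
                "n_unreachable_disease": int(unreachable_dis[i]),
                "note": "",
            }
        )
    return pd.DataFrame(rows).sort_values("gene", kind="mergesort").reset_index(drop=True)


def select_key_genes(stats: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Candidates significant on all four axes.

    Requires permutation-significant disease-neighbour ratio, permutation-
    significant (low) shortest-path ratio, analytically significant
    disease-neighbour count, and degree in the top ``alpha`` tail.
    """
    if alpha <= 0:
        return []
    sel = stats[
        (stats.p_ratio_perm <= alpha)
        & (stats.p_shortest_perm <= alpha)
        & (stats.p_count_hyper <= alpha)
        & (stats.degree_percentile >= 1 - alpha)
    ]
    return sorted(sel.gene)
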