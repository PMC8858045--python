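"""Weighted gene co-expression network construction and module detection.

The classic weighted-correlation workflow: soft-threshold the gene-gene
Pearson correlation matrix into a power adjacency ``A = |C|**beta`` chosen
for approximate scale-free topology, transform it into a topological
overlap matrix (TOM), cluster genes by average linkage on ``1 - TOM``,
summarise each module by its eigengene (first principal component), merge
modules with correlated eigengenes, and relate modules to the case/control
trait and to a disease-gene catalogue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix
from .stats import bh_fdr, hypergeom_upper, pearson_corr_pvalue

UNASSIGNED = "unassigned"

__all__ = [
    "SoftThresholdReport",
    "CoexpressionMatrices",
    "ModulePartition",
    "EigengeneSet",
    "pick_soft_threshold",
    "build_matrices",
    "detect_modules",
    "module_trait_stats",
]


@dataclass
class SoftThresholdReport:
    """Per-power scale-free fit statistics and the selected power.

    ``chosen_power`` is the smallest candidate whose signed scale-free fit
    R^2 reaches ``r2_cutoff``; if none qualifies it is the argmax of the
    signed R^2 with ``warning`` set.
    """

    table: pd.DataFrame  # columns: power, signed_r2, mean_connectivity
    chosen_power: int
    r2_cutoff: float
    warning: bool = False


@dataclass
class CoexpressionMatrices:
    """Correlation, power adjacency, TOM, and 1-TOM dissimilarity."""

    gene_ids: list[str]
    correlation: np.ndarray
    adjacency: np.ndarray  # |C|**power, diagonal zeroed for connectivity sums
    tom: np.ndarray
    power: int

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.tom


@dataclass
class ModulePartition:
    """Gene-to-module labels; modules are size-ranked M1, M2, ...

    Genes in clusters smaller than ``min_size`` carry the reserved
    ``"unassigned"`` label.
    """

    module_of_gene: dict[str, str]
    min_size: int = 30
    merge_cut: float = 0.25

    def members(self, label: str) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == label]

    @property
    def module_labels(self) -> list[str]:
        labels = {m for m in self.module_of_gene.values() if m != UNASSIGNED}
        return sorted(labels, key=lambda m: (-len(self.members(m)), m))


@dataclass
class EigengeneSet:
    """Per-module eigengene sample scores and variance explained.

    Each eigengene has unit norm, with its sign fixed so that its
    correlation with the module's mean expression profile is >= 0 —
    making downstream statistics invariant to the sign convention of the
    underlying SVD.
    """

    sample_ids: list[str]
    eigengenes: dict[str, np.ndarray]
    variance_explained: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.eigengenes, index=self.sample_ids)


# ---------------------------------------------------------------------------


def _correlation(values: np.ndarray, gene_ids) -> np.ndarray:
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(gene_ids, sd) if s == 0]
        raise ValueError(f"constant gene rows (correlation undefined): {bad[:5]}")
    c = np.corrcoef(values)
    return np.clip(c, -1.0, 1.0)


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = 10):
    """Signed R^2 of log10(freq) vs log10(mean k) over 10 connectivity bins.

    Bins are equal-width intervals of k (the convention of the scale-free
    fit index used with weighted co-expression networks); empty bins are
    dropped.
    """
    k = connectivity[connectivity > 0]
    if np.unique(k).size < n_bins:
        n_bins = max(2, np.unique(k).size)
        warnings.warn(f"few distinct connectivities; using {n_bins} bins")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[which == b].mean() for b in range(n_bins) if (which == b).any()])
    freq = np.array([(which == b).mean() for b in range(n_bins) if (which == b).any()])
    keep = (mean_k > 0) & (freq > 0)
    x, y = np.log10(mean_k[keep]), np.log10(freq[keep])
    if x.size < 2 or np.allclose(x, x[0]):
        return 0.0
    slope, _, r, _, _ = sps.linregress(x, y)
    return float(r * r * np.sign(-slope))


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers=tuple(range(1, 13)),
    r2_cutoff: float = 0.85,
) -> SoftThresholdReport:
    """Scan candidate powers for approximate scale-free topology.

    For each power the whole-network connectivity ``k_i = sum_j |C_ij|**b``
    (j != i) is binned into 10 equal-count bins and log10(frequency) is
    regressed on log10(mean k); the fit R^2 is signed by ``-slope`` so only
    decreasing degree distributions can qualify.
    """
    powers = list(powers)
    if not powers:
        raise ValueError("powers must be non-empty")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    absC = np.abs(_correlation(expr.values, expr.gene_ids))
    np.fill_diagonal(absC, 0.0)
    rows = []
    for b in powers:
        a = absC**b
        k = a.sum(axis=1)
        rows.append(
            {"power": b, "signed_r2": _scale_free_fit(k), "mean_connectivity": float(k.mean())}
        )
    table = pd.DataFrame(rows)
    qualifying = table[table.signed_r2 >= r2_cutoff]
    if len(qualifying):
        chosen = int(qualifying.power.iloc[0])
        warning = False
    else:
        chosen = int(table.power.iloc[table.signed_r2.idxmax()])
        warning = True
        warnings.warn(
            f"no power reached signed R^2 >= {r2_cutoff}; using argmax power {chosen}"
        )
    return SoftThresholdReport(
        table=table, chosen_power=chosen, r2_cutoff=r2_cutoff, warning=warning
    )


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap of a symmetric adjacency in [0, 1].

    TOM_ij = (sum_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij) for
    i != j (the shared-neighbour sum excludes u in {i, j}); TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # diagonal of A is 0, so u = i, j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def build_matrices(expr: ExpressionMatrix, power: int) -> CoexpressionMatrices:
    """Correlation, adjacency ``|C|**power`` and unsigned TOM."""
    if power < 1:
        raise ValueError("power must be >= 1")
    C = _correlation(expr.values, expr.gene_ids)
    A = np.abs(C) ** power
    np.fill_diagonal(A, 0.0)
    tom = tom_from_adjacency(A)
    return CoexpressionMatrices(
        gene_ids=list(expr.gene_ids), correlation=C, adjacency=A, tom=tom, power=power
    )


def _eigengene(block: np.ndarray) -> tuple[np.ndarray, float]:
    """First-PC sample scores (unit norm) of a standardized gene block."""
    sd = block.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (block - block.mean(axis=1, keepdims=True)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = z.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    return me, var_explained


def compute_eigengenes(
    expr: ExpressionMatrix, partition: ModulePartition
) -> EigengeneSet:
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    es = EigengeneSet(sample_ids=list(expr.sample_ids), eigengenes={})
    for label in partition.module_labels:
        rows = [idx[g] for g in partition.members(label) if g in idx]
        me, ve = _eigengene(expr.values[rows])
        es.eigengenes[label] = me
        es.variance_explained[label] = ve
    return es


def _relabel_by_size(assignment: dict[str, str]) -> dict[str, str]:
    """Canonical size-ranked labels M1 >= M2 >= ...; ties by first gene id."""
    groups: dict[str, list[str]] = {}
    for g, m in assignment.items():
        groups.setdefault(m, []).append(g)
    named = [m for m in groups if m != UNASSIGNED]
    named.sort(key=lambda m: (-len(groups[m]), min(groups[m])))
    mapping = {m: f"M{i + 1}" for i, m in enumerate(named)}
    mapping[UNASSIGNED] = UNASSIGNED
    return {g: mapping[m] for g, m in assignment.items()}


def _adaptive_cut(Z: np.ndarray, min_size: int, ceiling: float) -> np.ndarray:
    """Cut height maximizing the number of clusters of size >= min_size.

    Candidate heights are the dendrogram's own merge heights up to
    ``ceiling``; among heights achieving the maximal count the lowest is
    taken, keeping clusters as tight as possible. A deterministic stand-in
    for dynamic tree cut: a single fixed fraction of the root height is
    brittle because module branches complete at data-dependent heights.
    """
    heights = np.unique(Z[:, 2])
    heights = heights[heights <= ceiling]
    best_count, best_clusters = -1, None
    for h in heights:
        clusters = fcluster(Z, t=h * (1 + 1e-9), criterion="distance")
        count = int((np.bincount(clusters) >= min_size).sum())
        if count > best_count:
            best_count, best_clusters = count, clusters
    return best_clusters


def detect_modules(
    matrices: CoexpressionMatrices,
    expr: ExpressionMatrix,
    min_size: int = 30,
    cut_height_fraction: float = 0.99,
    merge_cut: float = 0.25,
    kme_clean: float = 0.7,
) -> tuple[ModulePartition, EigengeneSet]:
    """Average-linkage clustering of 1-TOM into gene modules.

    The dendrogram is cut adaptively: among merge heights up to
    ``cut_height_fraction`` of the maximum, the lowest height yielding the
    most clusters of size >= ``min_size`` is used; smaller clusters become
    "unassigned". Each surviving module is then cleaned by module
    membership — genes whose |kME| against their own module eigengene
    falls below ``kme_clean`` are unassigned (set 0 to disable) — and
    module pairs whose eigengene dissimilarity (1 - Pearson r) falls below
    ``merge_cut`` are merged iteratively (closest pair first), recomputing
    eigengenes after every merge.
    """
    genes = matrices.gene_ids
    d = matrices.dissimilarity.copy()
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    clusters = _adaptive_cut(Z, min_size, cut_height_fraction * Z[:, 2].max())

    assignment: dict[str, str] = {}
    sizes = pd.Series(clusters).value_counts()
    for g, c in zip(genes, clusters):
        assignment[g] = f"c{c}" if sizes[c] >= min_size else UNASSIGNED
    if all(m == UNASSIGNED for m in assignment.values()):
        raise ValueError(
            "all genes unassigned; lower min_size or raise cut_height_fraction"
        )

    if kme_clean > 0:
        idx = {g: i for i, g in enumerate(expr.gene_ids)}
        for label in {m for m in assignment.values() if m != UNASSIGNED}:
            members = [g for g, m in assignment.items() if m == label]
            me, _ = _eigengene(expr.values[[idx[g] for g in members]])
            for g in members:
                v = expr.values[idx[g]]
                if np.std(v) == 0 or abs(np.corrcoef(v, me)[0, 1]) < kme_clean:
                    assignment[g] = UNASSIGNED
        sizes2 = pd.Series(list(assignment.values())).value_counts()
        assignment = {
            g: m if m == UNASSIGNED or sizes2[m] >= min_size else UNASSIGNED
            for g, m in assignment.items()
        }
        if all(m == UNASSIGNED for m in assignment.values()):
            raise ValueError("all genes unassigned after kME cleanup")

    assignment = _relabel_by_size(assignment)
    partition = ModulePartition(assignment, min_size=min_size, merge_cut=merge_cut)
    eigengenes = compute_eigengenes(expr, partition)

    # iterative eigengene merge: closest correlated pair first
    while True:
        labels = partition.module_labels
        if len(labels) < 2:
            break
        me = np.array([eigengenes.eigengenes[m] for m in labels])
        diss = 1.0 - np.corrcoef(me)
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut:
            break
        keep, drop = labels[i], labels[j]
        assignment = {
            g: keep if m == drop else m for g, m in partition.module_of_gene.items()
        }
        assignment = _relabel_by_size(assignment)
        partition = ModulePartition(assignment, min_size=min_size, merge_cut=merge_cut)
        eigengenes = compute_eigengenes(expr, partition)
    return partition, eigengenes


def module_trait_stats(
    eigengenes: EigengeneSet,
    condition,
    disease_genes,
    partition: ModulePartition,
    universe_size: int,
) -> pd.DataFrame:
    """Module-trait correlation, case/control shift, and catalogue overlap.

    Per module: Pearson r of the eigengene against the 0/1 condition with
    its t-transform p-value; a two-sided Wilcoxon rank-sum comparing case
    vs control eigengene values (BH-corrected across modules); and the
    upper-tail hypergeometric p of the module's overlap with the
    disease-gene catalogue given the expression universe.
    """
    y = np.array([1.0 if c == "case" else 0.0 for c in condition])
    if y.sum() in (0, len(y)):
        raise ValueError("need both case and control samples")
    disease_genes = set(disease_genes)
    rows = []
    for label in partition.module_labels:
        me = eigengenes.eigengenes[label]
        members = set(partition.members(label))
        overlap = len(members & disease_genes)
        p_overlap = hypergeom_upper(
            overlap, universe_size, len(disease_genes), len(members)
        )
        if np.std(me) == 0:
            rows.append(
                {
                    "module": label,
                    "n_genes": len(members),
                    "pearson_r": np.nan,
                    "p_corr": np.nan,
                    "diff_stat": np.nan,
                    "p_diff": np.nan,
                    "overlap_count": overlap,
                    "p_overlap": p_overlap,
                    "note": "constant eigengene",
                }
            )
            continue
        r = float(np.corrcoef(me, y)[0, 1])
        p_corr = pearson_corr_pvalue(r, len(y))
        stat, p_diff = sps.ranksums(me[y == 1], me[y == 0])
        rows.append(
            {
                "module": label,
                "n_genes": len(members),
                "pearson_r": r,
                "p_corr": p_corr,
                "diff_stat": float(stat),
                "p_diff": float(p_diff),
                "overlap_count": overlap,
                "p_overlap": p_overlap,
                "note": "",
            }
        )
    table = pd.DataFrame(rows)
    table["fdr_diff"] = bh_fdr(table["p_diff"])
    return table


def select_disease_modules(
    trait_table: pd.DataFrame, alpha: float = 0.05, fdr: float = 0.05
) -> list[str]:
    """Modules passing the triple criterion: trait correlation p < alpha,
    case/control shift FDR < fdr, and catalogue-overlap p < alpha."""
    sel = trait_table[
        (trait_table.p_corr < alpha)
        & (trait_table.fdr_diff < fdr)
        & (trait_table.p_overlap < alpha)
    ]
    return list(sel.module)
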