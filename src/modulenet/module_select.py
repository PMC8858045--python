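"""Over-representation analysis and core-gene selection.

After disease-associated modules are identified, the module's working gene
set is refined to a "core" set: genes tightly coupled to the module
eigengene (module membership kME above a cutoff) that also individually
discriminate cases from controls (ranking AUC above a cutoff). Enrichment
of arbitrary gene-set collections (GMT) is assessed with an upper-tail
hypergeometric test and BH FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .coexpr import EigengeneSet, ModulePartition
from .io import ExpressionMatrix, GeneSetCollection
from .stats import bh_fdr, hypergeom_upper

__all__ = ["ora", "gene_auc", "select_core_genes"]


def ora(query, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    Query members outside the universe are dropped (count reported in the
    ``n_query_dropped`` attribute of the returned frame). Per set the
    upper-tail p of ``|query & set|`` given ``(|universe|, |set & universe|,
    |query|)`` is computed, with BH FDR across the collection. Rows sorted
    by p, ties by set name.
    """
    universe = set(universe)
    query = set(query)
    dropped = len(query - universe)
    query &= universe
    if not query:
        raise ValueError("query is empty after restricting to the universe")
    rows = []
    for name, members in collection.sets.items():
        members_u = set(members) & universe
        overlap = query & members_u
        k = len(overlap)
        expected = len(query) * len(members_u) / len(universe)
        p = hypergeom_upper(k, len(universe), len(members_u), len(query))
        rows.append(
            {
                "set": name,
                "set_size": len(members_u),
                "overlap": k,
                "expected": expected,
                "p": p,
                "genes": ",".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"])
    table = table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    table.attrs["n_query_dropped"] = dropped
    return table


def gene_auc(values, case_mask) -> float:
    """Two-class ranking AUC of one expression row, oriented to >= 0.5.

    The Mann-Whitney probability P(case value > control value) with ties
    counted 1/2, then ``max(auc, 1 - auc)`` so under-expressed markers
    score symmetrically. Invariant under strictly monotone transforms.
    """
    values = np.asarray(values, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    n1 = int(case_mask.sum())
    n0 = int((~case_mask).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(values)
    u = ranks[case_mask].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    return float(max(auc, 1.0 - auc))


def select_core_genes(
    expr: ExpressionMatrix,
    partition: ModulePartition,
    eigengenes: EigengeneSet,
    disease_modules,
    kme_cutoff: float = 0.7,
    auc_cutoff: float = 0.8,
) -> pd.DataFrame:
    """Flag core genes of the disease modules.

    For each gene of each disease module: kME = |Pearson r| between the
    gene's profile and its own module eigengene, and the oriented per-gene
    AUC; ``selected`` iff kME > kme_cutoff and AUC > auc_cutoff. Rows
    ordered by module then gene id.
    """
    case_mask = expr.case_mask
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = []
    for label in disease_modules:
        me = eigengenes.eigengenes[label]
        for g in sorted(partition.members(label)):
            if g not in idx:
                continue
            v = expr.values[idx[g]]
            kme = abs(float(np.corrcoef(v, me)[0, 1])) if np.std(v) > 0 else np.nan
            auc = gene_auc(v, case_mask)
            rows.append(
                {
                    "gene": g,
                    "module": label,
                    "kme": kme,
                    "auc": auc,
                    "selected": bool(kme > kme_cutoff and auc > auc_cutoff)
                    if not np.isnan(kme)
                    else False,
                }
            )
    table = pd.DataFrame(rows, columns=["gene", "module", "kme", "auc", "selected"])
    table["selected"] = table["selected"].astype(bool)
    return table.sort_values(["module", "gene"], kind="mergesort").reset_index(drop=True)
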