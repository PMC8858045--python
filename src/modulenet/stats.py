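"""Shared statistical utilities.

Small wrappers used across the pipeline: Benjamini-Hochberg FDR and
upper-tail hypergeometric enrichment p-values. Centralised so every module
applies multiple-test correction and enrichment identically.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "hypergeom_upper", "pearson_corr_pvalue"]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR), preserving input order.

    NaN entries are propagated (left uncorrected and excluded from the
    family size).
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def hypergeom_upper(overlap: int, universe: int, successes: int, draws: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, successes, draws)."""
    if overlap <= 0:
        return 1.0
    return float(sps.hypergeom.sf(overlap - 1, universe, successes, draws))


def pearson_corr_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the t transform.

    t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of freedom.
    """
    if n < 3:
        return float("nan")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))
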