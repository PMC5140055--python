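"""Differential expression by the two-sample Kolmogorov–Smirnov test.

Per gene the two-sample KS statistic D (the supremum distance between the
two empirical CDFs) is computed across groups, p-values are corrected with
Benjamini–Hochberg, and a fold-change gate (ratio of pseudocounted group
medians, four-fold by default) decides the final call. A Spearman screen
links expression to copy-number segment means, and the Jaccard index
summarizes overlap between gene sets.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import RunConfig

#: Pseudocount (FPKM) added to group medians before forming the ratio.
FOLD_CHANGE_EPS = 0.01


def ks_two_sample(x: Sequence[float], y: Sequence[float], exact: bool = False) -> tuple[float, float]:
    """Two-sample KS statistic D and two-sided p-value.

    D = sup_t |ECDF_x(t) − ECDF_y(t)|. The p-value is asymptotic (effective
    n = |x||y|/(|x|+|y|)) by default; ``exact=True`` switches to the exact
    null distribution, useful only for very small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires non-empty samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("KS test requires finite values")
    res = stats.ks_2samp(x, y, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j ≥ i} (m·p_(j)/j), clipped to 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0,1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fold_change(x: Sequence[float], y: Sequence[float], eps: float = FOLD_CHANGE_EPS) -> float:
    """Ratio of pseudocounted group medians, (median(x)+ε)/(median(y)+ε).

    The pseudocount keeps the ratio finite when a group median is zero.
    Values > 1 mean "up in x".
    """
    return (float(np.median(x)) + eps) / (float(np.median(y)) + eps)


def jaccard(set_a: set, set_b: set) -> float:
    """|A∩B| / |A∪B|; two empty sets give 0 by convention."""
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


def differential_expression(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    fc_min: float = 4.0,
    eps: float = FOLD_CHANGE_EPS,
    config: "RunConfig | None" = None,
) -> pd.DataFrame:
    """Call differentially expressed genes between two sample groups.

    Per gene: KS test of group A vs group B, BH correction over all tested
    genes, and a fold-change gate on the ratio of group medians. A gene is
    ``significant`` when q < alpha and the fold change is at least ``fc_min``
    in either direction. ``direction`` is "up"/"down" in group A.

    Returns a frame indexed by gene with columns D, p, q, fc, log2fc,
    direction, significant.
    """
    if config is not None:
        alpha, fc_min = config.fdr_alpha, config.fc_min
    group_a = list(group_a)
    group_b = list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    stats_d = np.empty(matrix.shape[0])
    pvals = np.empty(matrix.shape[0])
    for i in range(matrix.shape[0]):
        stats_d[i], pvals[i] = ks_two_sample(a[i], b[i])
    q = bh_fdr(pvals)
    med_a = np.median(a, axis=1)
    med_b = np.median(b, axis=1)
    fc = (med_a + eps) / (med_b + eps)
    log2fc = np.log2(fc)
    direction = np.where(fc > 1.0, "up", np.where(fc < 1.0, "down", "flat"))
    significant = (q < alpha) & ((fc >= fc_min) | (fc <= 1.0 / fc_min))
    return pd.DataFrame(
        {
            "D": stats_d,
            "p": pvals,
            "q": q,
            "fc": fc,
            "log2fc": log2fc,
            "direction": direction,
            "significant": significant,
        },
        index=matrix.index,
    )


def cnv_expression_correlation(
    matrix: pd.DataFrame,
    cnv: pd.DataFrame,
    rho_min: float = 0.2,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Spearman correlation between expression and CNV segment mean per gene.

    Ranks are averaged over ties; a gene is ``correlated`` when rho ≥
    ``rho_min`` (one-sided by default, |rho| ≥ rho_min with
    ``two_sided=True``). Genes need ≥3 samples shared between the matrices.
    """
    shared_samples = matrix.columns.intersection(cnv.columns)
    genes = matrix.index.intersection(cnv.index)
    if len(shared_samples) < 3:
        raise ValueError("need at least 3 shared samples")
    expr = matrix.loc[genes, shared_samples].to_numpy(dtype=float)
    seg = cnv.loc[genes, shared_samples].to_numpy(dtype=float)
    rho = np.empty(len(genes))
    for i in range(len(genes)):
        rho[i] = stats.spearmanr(expr[i], seg[i]).statistic
    rho = np.nan_to_num(rho)  # constant rows have undefined rho; treat as 0
    correlated = (np.abs(rho) >= rho_min) if two_sided else (rho >= rho_min)
    return pd.DataFrame({"rho": rho, "correlated": correlated}, index=genes)
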