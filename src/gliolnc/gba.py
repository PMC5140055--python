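"""Guilt-by-association pathway inference for lncRNAs.

A lncRNA's pathways are inferred from its co-expression neighborhood: the
top fraction of protein-coding genes by Spearman correlation with the
lncRNA. Each pathway is tested for over-representation in the neighborhood
with the hypergeometric upper tail, BH-corrected across pathways per
lncRNA. Per prognosis group, pathways are ranked by how many lncRNAs they
are associated with.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Fraction of coding genes (by correlation, positive tail) in a neighborhood.
DEFAULT_TOP_FRAC = 0.05


def _rank_rows(values: np.ndarray) -> np.ndarray:
    out = np.empty_like(values, dtype=float)
    for i in range(values.shape[0]):
        out[i] = stats.rankdata(values[i], method="average")
    return out


def coexpression_neighborhood(
    lnc_values: pd.Series,
    coding_matrix: pd.DataFrame,
    top_frac: float = DEFAULT_TOP_FRAC,
) -> list[str]:
    """Top coding genes by Spearman correlation with one lncRNA.

    Only the positive tail is taken: the neighborhood is the
    ``top_frac`` × (number of coding genes) genes with the highest
    correlation. Requires ≥20 shared samples; a constant lncRNA has no
    correlation structure and is an error.
    """
    shared = coding_matrix.columns.intersection(lnc_values.index)
    if len(shared) < 20:
        raise ValueError("need at least 20 shared samples")
    x = lnc_values.loc[shared].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError("constant lncRNA expression")
    rx = stats.rankdata(x, method="average")
    rx = (rx - rx.mean()) / rx.std()
    coding = coding_matrix[shared].to_numpy(dtype=float)
    ranks = _rank_rows(coding)
    sd = ranks.std(axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centered @ rx) / (len(shared) * sd)
    rho = np.nan_to_num(rho, nan=-np.inf)  # constant coding genes sort last
    k = max(1, int(np.floor(top_frac * coding_matrix.shape[0])))
    top = np.argsort(-rho, kind="stable")[:k]
    return [coding_matrix.index[i] for i in top]


def pathway_enrichment(
    neighborhood: Iterable[str],
    pathways: Mapping[str, set[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each pathway in a neighborhood.

    For a universe of N genes, a pathway of K genes (restricted to the
    universe) and a neighborhood of n genes with k in the pathway, the
    p-value is the hypergeometric upper tail P(X ≥ k); BH correction runs
    across pathways. ``associated`` means q < alpha.
    """
    universe = set(universe)
    neighborhood = set(neighborhood) & universe
    n_univ = len(universe)
    n_neigh = len(neighborhood)
    rows = []
    for name in sorted(pathways):
        members = pathways[name] & universe
        k = len(neighborhood & members)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_neigh)) if members else 1.0
        rows.append({"pathway": name, "overlap": k, "pathway_size": len(members), "neighborhood_size": n_neigh, "p": p})
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = np.minimum(1.0, _bh(result["p"].to_numpy()))
        result["associated"] = result["q"] < alpha
    return result


def _bh(p: np.ndarray) -> np.ndarray:
    from .diffexp import bh_fdr

    return bh_fdr(p)


def pathway_lncrna_counts(
    lnc_ids: Sequence[str],
    lnc_matrix: pd.DataFrame,
    coding_matrix: pd.DataFrame,
    pathways: Mapping[str, set[str]],
    universe: Iterable[str] | None = None,
    top_frac: float = DEFAULT_TOP_FRAC,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank pathways by the number of lncRNAs associated with them.

    Runs the neighborhood + enrichment procedure for each lncRNA in a
    prognosis group and counts, per pathway, how many lncRNAs carry the
    ``associated`` flag. Sorted by count descending, pathway name as the
    tie-break, so the ranking is invariant to pathway input order.
    """
    if universe is None:
        universe = set(coding_matrix.index)
    counts: dict[str, int] = {name: 0 for name in pathways}
    for lnc in lnc_ids:
        neigh = coexpression_neighborhood(lnc_matrix.loc[lnc], coding_matrix, top_frac=top_frac)
        enr = pathway_enrichment(neigh, pathways, universe, alpha=alpha)
        for _, row in enr[enr["associated"]].iterrows():
            counts[row["pathway"]] += 1
    table = pd.DataFrame(
        {"pathway": list(counts), "n_lncrnas": list(counts.values())}
    ).sort_values(["n_lncrnas", "pathway"], ascending=[False, True], kind="stable")
    return table.reset_index(drop=True)
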