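"""Mutation- and subtype-associated lncRNA calling, and overlap permutation tests.

Mutation-associated calls split a cohort by the mutation status of one
protein-coding gene and run the KS/BH machinery with a |log2 fold change| >
0.5 gate. Subtype-specific calls require a lncRNA to differ (FDR < 0.05)
from *every* other subtype in pairwise comparisons, with a consistent
direction. The permutation test assesses whether two gene sets (e.g.
subtype-specific lncRNAs from two cohorts) overlap more than random draws
of the same sizes from their respective universes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr, ks_two_sample

logger = logging.getLogger(__name__)


@dataclass
class MutationAssociation:
    """lncRNAs called differentially expressed between mutant and wild-type tumors."""

    gene: str
    up: set[str]
    down: set[str]
    table: pd.DataFrame
    n_mutant: int
    n_wildtype: int


def mutation_associated(
    matrix: pd.DataFrame,
    mutation_table: pd.DataFrame,
    gene: str,
    alpha: float = 0.05,
    log2fc_min: float = 0.5,
    min_group: int = 5,
    eps: float = 0.01,
) -> MutationAssociation | None:
    """lncRNAs associated with the mutation status of one coding gene.

    Samples are split by the boolean mutation call for ``gene``; per lncRNA
    a KS test is run, BH-corrected over all tested lncRNAs, and a lncRNA is
    called when q < ``alpha`` and |log2 fold change| is strictly greater
    than ``log2fc_min``. When either group has fewer than ``min_group``
    samples the contrast is skipped (returns None) with a log message.
    ``up`` means higher in mutant tumors.
    """
    if gene not in mutation_table.index:
        raise KeyError(f"gene {gene!r} absent from mutation table")
    shared = matrix.columns.intersection(mutation_table.columns)
    status = mutation_table.loc[gene, shared].astype(bool)
    mut = shared[status].tolist()
    wt = shared[~status].tolist()
    if len(mut) < min_group or len(wt) < min_group:
        logger.info("skipping %s: groups too small (%d mutant / %d wild-type)", gene, len(mut), len(wt))
        return None
    a = matrix[mut].to_numpy(dtype=float)
    b = matrix[wt].to_numpy(dtype=float)
    pvals = np.empty(matrix.shape[0])
    d = np.empty(matrix.shape[0])
    for i in range(matrix.shape[0]):
        d[i], pvals[i] = ks_two_sample(a[i], b[i])
    q = bh_fdr(pvals)
    log2fc = np.log2((np.median(a, axis=1) + eps) / (np.median(b, axis=1) + eps))
    called = (q < alpha) & (np.abs(log2fc) > log2fc_min)
    table = pd.DataFrame({"D": d, "p": pvals, "q": q, "log2fc": log2fc, "called": called}, index=matrix.index)
    up = set(table.index[called & (log2fc > 0)])
    down = set(table.index[called & (log2fc < 0)])
    return MutationAssociation(gene=gene, up=up, down=down, table=table, n_mutant=len(mut), n_wildtype=len(wt))


def subtype_specific(
    matrix: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    min_group: int = 5,
    require_direction: bool = True,
) -> pd.DataFrame:
    """Subtype-specific lncRNAs by all-pairwise KS tests.

    For every gene and unordered subtype pair a KS test is run; BH
    correction is applied jointly across all gene×pair tests. A gene is
    specific to subtype s when every pairwise comparison of s against
    another subtype has q < ``alpha`` and (unless ``require_direction`` is
    off) the median in s sits on the same side in every comparison.
    Subtypes with fewer than ``min_group`` samples are excluded. Returns a
    gene×subtype boolean frame of ``specific`` flags.
    """
    labels = labels.dropna()
    samples = matrix.columns.intersection(labels.index)
    labels = labels.loc[samples]
    subtypes = sorted(s for s in labels.unique() if (labels == s).sum() >= min_group)
    if len(subtypes) < 2:
        raise ValueError("need at least 2 subtypes with enough samples")
    groups = {s: matrix[samples[labels == s]].to_numpy(dtype=float) for s in subtypes}
    medians = {s: np.median(groups[s], axis=1) for s in subtypes}
    pairs = list(combinations(subtypes, 2))
    n_genes = matrix.shape[0]
    pvals = np.empty((len(pairs), n_genes))
    for k, (s, t) in enumerate(pairs):
        for i in range(n_genes):
            _, pvals[k, i] = ks_two_sample(groups[s][i], groups[t][i])
    q = bh_fdr(pvals.ravel()).reshape(pvals.shape)
    specific = pd.DataFrame(False, index=matrix.index, columns=subtypes)
    for s in subtypes:
        others = [t for t in subtypes if t != s]
        ok = np.ones(n_genes, dtype=bool)
        sign = None
        for t in others:
            k = pairs.index((s, t)) if (s, t) in pairs else pairs.index((t, s))
            ok &= q[k] < alpha
            if require_direction:
                diff_sign = np.sign(medians[s] - medians[t])
                ok &= diff_sign != 0
                if sign is None:
                    sign = diff_sign
                else:
                    ok &= diff_sign == sign
        specific[s] = ok
    return specific


@dataclass
class OverlapTestResult:
    """Permutation test of the overlap between two gene sets.

    ``p_enrichment``/``p_depletion`` use the add-one estimator
    (1 + #{permutations at least/at most as extreme}) / (1 + n) and
    therefore never reach 0; the normal-approximation p-values resolve
    beyond the 1/(n+1) floor.
    """

    observed: int
    perm_mean: float
    perm_sd: float
    fold: float
    p_enrichment: float
    p_depletion: float
    p_enrichment_normal: float
    p_depletion_normal: float
    n_iterations: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def overlap_permutation_test(
    set_a: set,
    set_b: set,
    universe_a: Sequence,
    universe_b: Sequence,
    n_iterations: int = 1000,
    seed: int = 0,
) -> OverlapTestResult:
    """Is |A∩B| larger (or smaller) than random same-sized draws would give?

    Each iteration draws |A| elements from ``universe_a`` and |B| from
    ``universe_b`` without replacement and counts the intersection (which
    can only occur among identifiers shared by both universes). The draw is
    realized by its exact equivalent chain of hypergeometric variables, so
    large universes cost nothing.
    """
    universe_a = set(universe_a)
    universe_b = set(universe_b)
    if not set(set_a) <= universe_a:
        raise ValueError("set A not contained in universe A")
    if not set(set_b) <= universe_b:
        raise ValueError("set B not contained in universe B")
    n_a, n_b = len(set_a), len(set_b)
    if n_a > len(universe_a) or n_b > len(universe_b):
        raise ValueError("set larger than its universe")
    shared = universe_a & universe_b
    m = len(shared)
    observed = len(set(set_a) & set(set_b))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0x6F76,)))
    # a = |draw_A ∩ shared|, b = |draw_B ∩ shared|, overlap | a,b ~ Hypergeom(m, a, b)
    a = rng.hypergeometric(m, len(universe_a) - m, n_a, size=n_iterations) if n_a else np.zeros(n_iterations, int)
    b = rng.hypergeometric(m, len(universe_b) - m, n_b, size=n_iterations) if n_b else np.zeros(n_iterations, int)
    perm = np.zeros(n_iterations, dtype=int)
    both = (a > 0) & (b > 0)
    if m > 0 and both.any():
        perm[both] = rng.hypergeometric(a[both], m - a[both], b[both])
    mean = float(perm.mean())
    sd = float(perm.std(ddof=1))
    fold = observed / mean if mean > 0 else np.inf if observed > 0 else 1.0
    p_enr = (1 + int((perm >= observed).sum())) / (1 + n_iterations)
    p_dep = (1 + int((perm <= observed).sum())) / (1 + n_iterations)
    if sd > 0:
        z = (observed - mean) / sd
        p_enr_n = float(stats.norm.sf(z))
        p_dep_n = float(stats.norm.cdf(z))
    else:
        p_enr_n = p_dep_n = 1.0
    return OverlapTestResult(
        observed=observed,
        perm_mean=mean,
        perm_sd=sd,
        fold=float(fold),
        p_enrichment=p_enr,
        p_depletion=p_dep,
        p_enrichment_normal=p_enr_n,
        p_depletion_normal=p_dep_n,
        n_iterations=n_iterations,
        seed=seed,
    )
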