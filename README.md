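# gliolnc

Long noncoding RNAs (lncRNAs) are dysregulated in gliomas — both in lower
grade gliomas (LGG, WHO grades II–III) and glioblastoma multiforme (GBM) —
and a panel of them carries prognostic information beyond IDH1/2 mutation
status, age, sex, and grade. `gliolnc` implements the full in-silico
analysis as a tested, reusable Python library with a thin CLI:

- **Novel-lncRNA catalog filtering** — candidate transcripts from a de-novo
  assembly are kept only if they do not intersect annotated transcripts,
  are ≥ 200 bp, are spliced (≥ 2 exons), have a coding-potential score
  below 0.5242, and have at most one mass-spectrometry peptide mapping to
  their translated ORFs.
- **Differential expression** — per-gene two-sample Kolmogorov–Smirnov
  tests with Benjamini–Hochberg FDR (q < 0.05) and a four-fold median
  fold-change gate; Spearman screens against copy-number segment means
  (ρ ≥ 0.2); Jaccard overlap of call sets.
- **Mutation- and subtype-associated calls** — the same KS/BH machinery
  split by mutation status (|log2 FC| > 0.5 gate) or by all-pairwise
  subtype contrasts, plus a permutation test (1,000 same-size random
  draws) for the overlap of subtype-specific lncRNA sets across cohorts.
- **The survival algorithm** — per-lncRNA expression is rank-based inverse
  normal transformed; on a 60% test split, 100 random subsamples of 66% of
  patients are each fit with a multivariate Cox model (age, grade, sex,
  IDH status + one lncRNA); lncRNAs significant (Wald p < 0.05) in ≥ 80%
  of subsamples form the prognostic panel. Each patient's risk score sums
  the panel's median Cox coefficients over lncRNAs whose expression
  Z-score against the frozen test-set reference satisfies |Z| ≥ 1; a
  positive summed coefficient means poor prognosis. Groups are compared by
  Kaplan–Meier curves, the log-rank test, and the hazard ratio
  HR = exp(β) of a Cox fit on the group indicator, on the test set and on
  the held-out 40% validation set.
- **Guilt-by-association** — each prognostic lncRNA's pathways are
  inferred from hypergeometric enrichment of its co-expression
  neighborhood (top 5% of coding genes by Spearman correlation).
- **Synthetic cohorts with exported ground truth** — log-normal FPKM
  expression with planted log2 effects, Weibull proportional-hazards
  survival with planted lncRNA coefficients, rank-copula CNV, and a toy
  genome of candidate transcripts each planted to fail exactly one filter,
  so every stage is testable end to end without controlled-access data.

Cox models maximize the Efron-tie-corrected partial likelihood by Newton's
method with step-halving (monotone log-likelihood, observed-information
standard errors) and are cross-checked against lifelines and a brute-force
likelihood oracle in the test suite.

## Worked example

Train and evaluate the survival algorithm on a synthetic LGG-like cohort
(450 patients, 200 lncRNAs, 10 planted prognostic lncRNAs with |β| = 0.8):

```python
from gliolnc import synthdata, survival

cohort = synthdata.simulate_lgg_cohort(seed=1)
expr_test = survival.transform_matrix(cohort.expression[cohort.test_samples])
panel = survival.train_panel(expr_test, cohort.clinical.loc[cohort.test_samples], seed=1)
print(len(panel), sorted(set(panel.members.index) & set(cohort.truth.prognostic)))

result = survival.stratify_and_evaluate(
    panel,
    cohort.expression[cohort.validation_samples],
    cohort.clinical.loc[cohort.validation_samples],
    mode="signed",
)
print(result.group_sizes, round(result.hazard_ratio, 3), result.logrank_p)
```

prints

```
12 ['lnc0005', 'lnc0009', 'lnc0065', 'lnc0068', 'lnc0081', 'lnc0091', 'lnc0109', 'lnc0116', 'lnc0124', 'lnc0168']
{'poor': 88, 'good': 92} 6.167 1.207032126334816e-22
```

— the panel recovers all 10 planted prognostic lncRNAs (plus 2 of 190
nulls), and on the held-out 180-patient validation split the summed-
coefficient score separates patients into groups whose hazards differ
six-fold (log-rank p ≈ 1e-22). The same pipeline is available from the
shell via `gliolnc simulate`, `gliolnc survive-train`, and
`gliolnc survive-apply`; every subcommand takes `--seed`/`--config` and
writes its effective configuration next to its outputs.

See `docs/methods.md` for the model details, parameter conventions, and
known limitations.

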