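# Methods

## Scope and data model

The package analyzes gene×sample FPKM expression matrices (pandas frames,
genes as rows), per-sample clinical tables with right-censored survival
(`time_days`, `event`) and covariates (age, sex, grade, IDH1/2 status,
1p19q codeletion, subtype), transcript models parsed from GTF, copy-number
segment means and binary mutation calls as TSV matrices, GMT pathway
collections, and plain-text peptide lists. GTF coordinates are 1-based
inclusive on disk and 0-based half-open in memory; every reader validates
structure and raises on malformed input rather than coercing. Missing
clinical values are encoded "NA"; each analysis drops the samples it
cannot use and logs the count.

## Novel-lncRNA catalog filter

Candidates are screened in a fixed order, and the first failing rule is
attributed: (1) *annotation overlap* — the candidate's genomic span shares
at least one base with any annotated transcript span, strand-agnostic (a
conservative reading that also discards antisense overlaps); (2) *too
short* — summed exon length < 200 bp; (3) *no splice junction* —
mono-exonic; (4) *coding potential* — the supplied coding-potential score
(a logistic probability, e.g. from CPAT) is ≥ 0.5242; the boundary case
fails, since the cutoff marks the start of the possibly-coding regime;
(5) *peptide evidence* — two or more peptides (from the set of
mass-spectrometry peptides unmatched to known proteins) occur as exact
substrings of the candidate's translated ORFs; one mapped peptide is
tolerated. ORFs are enumerated on the sense strand only (assembled
transcripts are stranded): every ATG opens its own frame-wise ORF,
translated with the standard code to the first stop or the last complete
codon, ORFs containing N excluded, minimum length 25 aa (configurable;
chosen to bracket typical mass-spectrometry peptide lengths). Peptide
matching is exact substring matching — no I/L equivalence and no
missed-cleavage modeling. The keep set is order-independent because the
rules are independent predicates; the cascade order only determines
failure attribution.

Cohort-level screens: genes enter the statistics only when their cohort
median FPKM strictly exceeds 0.5 (the median is used; a mean option
exists). Samples are removed when, on the log2(FPKM+1) scale (chosen to
tame the FPKM tail), more than 15% of their genes lie over three standard
deviations from the per-gene cohort mean; the 15% boundary itself is
retained (strict >).

## Differential expression

Per gene, the two-sample Kolmogorov–Smirnov statistic
D = sup_t |ECDF_A(t) − ECDF_B(t)| is computed via `scipy.stats.ks_2samp`
with the asymptotic p-value (effective n = n_A·n_B/(n_A+n_B)); an exact
option exists for tiny groups. Benjamini–Hochberg correction
(q_(i) = min_{j≥i} m·p_(j)/j) runs within each contrast. Fold change is
the ratio of group medians with a 0.01 FPKM pseudocount (keeps the ratio
finite at zero medians); a gene is called at q < 0.05 with fold change
≥ 4 in either direction. Medians, not means, keep the fold change
consistent with the median-based expression floor. CNV linkage is the
Spearman correlation (average ranks) between expression and segment mean,
one-sided: ρ ≥ 0.2 flags a gene as copy-number-associated (a two-sided
flag is available but off by default).

Mutation-associated calls split samples by the boolean mutation status of
one coding gene (both groups ≥ 5 samples, else the contrast is skipped
with a log message) and require q < 0.05 and |log2 FC| strictly > 0.5.
Subtype-specific calls test each gene in every unordered subtype pair; BH
runs jointly across all gene×pair tests (the conservative scope), and a
gene is specific to subtype s only if every pairwise q < 0.05 *and* the
median in s lies on the same side in every comparison (the
direction-consistency requirement can be disabled for sensitivity
analysis). With exactly two groups this reduces to the mutation-associated
caller without the fold gate, which is tested.

## Overlap permutation test

To ask whether two call sets overlap more than chance, each of n
iterations (default 1,000) draws |A| identifiers from universe A and |B|
from universe B without replacement and counts the intersection; the
universes are the expression-floored lncRNA sets of each cohort and
intersection is counted on shared identifiers. The draw is realized by its
exact distributional equivalent — the number of A-draws landing in the
shared universe, the number of B-draws landing there, then a
hypergeometric intersection of those two — so cost is independent of
universe size. Empirical p-values use the add-one estimator
(1 + #extreme)/(1 + n) and never reach 0; because resolving very small
p-values needs more iterations than the add-one floor 1/(n+1) allows,
normal-approximation p-values (from the permutation mean and SD) are
reported alongside.

## Survival algorithm

**Inverse normal transform.** Per lncRNA within a cohort, value_i ↦
Φ⁻¹((r_i − 0.5)/n) with average ranks for ties. This is strictly monotone,
depends only on ranks, and maps all-identical input to zeros. It tames the
extreme outliers typical of RNA-seq before regression.

**Cox fitting.** `cox_fit` maximizes the Efron-tie-corrected partial
likelihood by Newton's method with step-halving, so the accepted
log-likelihood history is non-decreasing; convergence is |Δloglik| < 1e-9
or 100 iterations; standard errors come from the observed information.
Breslow tie handling is available and equals Efron exactly on tie-free
data. A linear-predictor spread over 50 on the log-hazard scale is treated
as monotone likelihood (separation): the fit is flagged non-converged with
a warning. Constant covariate columns are rejected. The implementation is
cross-checked in the test suite against lifelines and against direct
numerical maximization of an independently written likelihood on small
datasets.

**Panel training.** On the test cohort (complete clinical data only;
covariate coding: age in years, sex = indicator(male), grade =
indicator(III/IV), IDH = indicator(mutant)), 100 subsamples of
floor(0.66·n) patients are drawn without replacement; a subsample without
events is redrawn and logged. Each lncRNA is fit per subsample in its own
Cox model together with the clinical covariates — one model per lncRNA
rather than a joint model over all lncRNAs, since p ≫ n forbids the joint
fit. lncRNAs with Wald p < 0.05 in at least 80% of subsamples are
selected; the panel weight is the median coefficient over all subsamples,
and the reference mean/SD per lncRNA are frozen from the full test cohort
on the transformed scale. Each subsample draws from an RNG stream spawned
from (seed, subsample index), so increasing the subsample count never
reshuffles earlier draws and training is bit-reproducible under a fixed
seed.

**Scoring and stratification.** A new cohort is transformed within itself;
each panel lncRNA's Z-score uses the frozen training reference. Two
scoring modes exist. In `paper_literal` (the default of
`summed_cox_score`), the median coefficient is added whenever |Z| ≥ 1,
regardless of the deviation's direction. In `signed`, the contribution is
sign(Z)·coefficient. On the inverse-normal scale the transformed values
are symmetric around zero, so the literal rule treats over- and
under-expression identically and carries no directional information there
— on our synthetic cohorts it produces hazard ratios near 1 by
construction, which we verified empirically. The end-to-end evaluation in
the acceptance suite and the acceptance script therefore uses `signed`
mode; the literal rule remains available and default for single scores.
(On a raw, right-skewed FPKM scale, where |Z| ≥ 1 is predominantly the
upper tail, the literal rule approximates "is this lncRNA highly
expressed", which is likely how it behaves on real data; raw-scale scoring
is available via `transform=False`.)

Patients with a positive summed coefficient form the poor-prognosis group;
a score of exactly 0 is good (only a positive sum signals hazard). The
split is evaluated by Kaplan–Meier curves with at-risk tables and median
survival, the log-rank test, and the hazard ratio with Wald 95% CI from a
univariate Cox fit on the group indicator (both via lifelines). An empty
group yields an undefined HR, reported as None with a warning.

**Per-lncRNA prognosis (GBM-style).** One Cox model per lncRNA with age
and sex; β > 0 and p < 0.05 labels a poor predictor, β < 0 a good one,
with no multiplicity correction (calls are exploratory, calibrated at
~5% under the null by a test). `tertile_km` compares the top and bottom
floor(n/3) expressers of one lncRNA by KM, log-rank, and a univariate Cox
HR; ties are broken by sample order and constant expression is an error.

## Guilt-by-association

A lncRNA's co-expression neighborhood is the top 5% of coding genes by
Spearman correlation (positive tail only; the fraction and the one-sided
choice are conventions, configurable). Each pathway, restricted to the
universe of expression-floored coding genes, is tested by the
hypergeometric upper tail P(X ≥ k), BH-corrected across pathways per
lncRNA; q < 0.05 calls an association. Per prognosis group, pathways are
ranked by the number of associated lncRNAs, with the pathway name as a
deterministic tie-break.

## Synthetic data generator

The generator defines the conditions under which the pipeline is
validated. Expression is log-normal per gene (FPKM-like heavy right tail):
baseline log2 mean uniform on [0.5, 5], per-gene log2 SD uniform on
[0.2, 0.8] by default (a convention — public FPKM dispersion figures for
these cohorts are not available; planted-effect checks use σ = 0.3), and
planted effects are additive log2 shifts per group, recorded once each in
the exported truth. Survival is Weibull proportional hazards,
T = λ(−ln U)^{1/k}·e^{−η/k}, with independent exponential censoring whose
rate is solved numerically to hit the requested censored fraction. CNV
segment means are generated through a Gaussian rank copula calibrated so
the population Spearman correlation equals the target (Pearson r of normal
scores = 2·sin(πρ/6)).

The LGG-like cohort defaults mirror the real cohort's shape at desk
scale: 450 patients (60/40 split ⇒ 270 test / 180 validation), 200
lncRNAs of which 10 carry alternating ±0.8 coefficients on the
transformed-expression scale, clinical hazard effects age 0.03/yr, grade
III +0.4, male +0.1, IDH-mutant −1.0, Weibull shape 1.3 and scale 3,000 d
(median survival ≈ 2,300 d for an average patient), and 30% censoring.
Catalog fixtures plant five candidates per failure mode (including a
coding-potential score exactly at 0.5242 and a minus-strand candidate
carrying exactly one mapped peptide, which is kept) over a toy genome with
designed ORFs encoding listed peptides.

All generators draw from named substreams spawned from one master seed
(`SeedSequence(seed, spawn_key=crc32(name))`), so modules are mutually
independent and every output is bit-reproducible.

What the generator does *not* emulate: gene–gene correlation beyond
explicitly planted co-expression blocks, batch structure between cohorts
(none is modeled, and no batch correction is implemented), library-size or
GC biases, subtype-dependent censoring, or non-proportional hazards.
Passing tests therefore demonstrate correctness of the statistical
machinery under the assumed model, not robustness to those real-data
complications.

## Numerical choices and degenerate inputs

- Fold changes use a 0.01 FPKM pseudocount; Jaccard of two empty sets is 0.
- KS p-values are asymptotic by default (cohort sizes here are large).
- BH q-values are clipped to 1 and preserve input order.
- Spearman of a constant series is undefined and treated as 0 in the CNV
  screen; a constant lncRNA is an error in the GBA neighborhood.
- All-identical values transform to zeros under the inverse normal
  transform; panels require strictly positive reference SDs.
- Subsample draws with zero events are redrawn; lncRNAs constant within a
  subsample contribute a non-significant result for that subsample.
- Permutation p-values are bounded below by 1/(n+1) by construction.

## Problem sizes used in the checks

The acceptance suite and script run the cascade on 31 fixture candidates,
differential expression on 1,000-gene cohorts with 20 vs 20 samples, Cox
recovery at n = 1,000 over up to 100 seeds, one full panel run at
270 patients × 200 lncRNAs × 100 subsamples, 20 scaled train/evaluate
replicates at 50 lncRNAs each, 50 null stratification replicates at 180
patients, 200 permutation-test calibration replicates at 1,000 iterations
each, and guilt-by-association over a 300-gene coding matrix. These sizes
were chosen to make each statistical property measurable with comfortable
margins on a single CPU.

## Known limitations

- The literal |Z| ≥ 1 scoring rule is kept for fidelity but is
  direction-blind on symmetric scales (see above); cross-cohort claims
  should use the signed variant or raw-scale Z-scores deliberately.
- Coding-potential scores are inputs; the package does not recompute them,
  and does not align peptides to known proteins (the unmatched-peptide
  list is an input).
- No proportional-hazards diagnostics are provided; the Weibull generator
  satisfies the assumption by construction.
- FPKM reconciliation across sequencing batches is out of scope; matrices
  are assumed comparable as given.
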