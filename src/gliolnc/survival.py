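"""Cox proportional-hazards machinery and the lncRNA survival algorithm.

The survival algorithm proceeds in four steps:

1. Per-lncRNA expression is rank-based inverse normal transformed within a
   cohort, which tames RNA-seq outliers before regression.
2. On the test cohort, 100 random subsamples of 66% of patients are each
   fit with a multivariate Cox model per lncRNA (clinical covariates plus
   that lncRNA). lncRNAs whose coefficient is significant (Wald p < 0.05)
   in at least 80% of subsamples enter the prognostic panel, with the
   median coefficient across subsamples as the panel weight.
3. A patient's risk score sums panel coefficients over lncRNAs whose
   expression Z-score (against the frozen test-cohort mean/SD) has
   magnitude ≥ 1. Positive summed coefficient ⇒ poor prognosis.
4. Stratified groups are compared by Kaplan–Meier curves, the log-rank
   test, and the hazard ratio of a univariate Cox fit on the group
   indicator — on the test cohort and on a held-out validation cohort.

Cox models maximize the Efron-tie-corrected partial likelihood by Newton's
method with step-halving, so the log-likelihood is non-decreasing across
iterations; standard errors come from the observed information.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.special import ndtri

logger = logging.getLogger(__name__)

#: Default clinical covariates for the LGG panel training model.
PANEL_COVARIATES = ("age", "grade", "sex", "idh_mut")

#: Default clinical covariates for per-lncRNA GBM prognosis models.
GBM_COVARIATES = ("age", "sex")


def inverse_normal_transform(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse normal transform, Φ⁻¹((r − 0.5)/n).

    Ranks are averaged over ties, so the transform is strictly monotone in
    the input and invariant to any monotone rescaling of it. All-identical
    input maps to all zeros (every value sits at the median rank).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D array of at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    ranks = stats.rankdata(x, method="average")
    return ndtri((ranks - 0.5) / x.size)


def transform_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply the inverse normal transform to each gene (row) of a matrix."""
    out = np.empty(matrix.shape)
    values = matrix.to_numpy(dtype=float)
    for i in range(matrix.shape[0]):
        out[i] = inverse_normal_transform(values[i])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``params`` holds per-covariate coefficients β (exp(β) is the hazard
    ratio per unit covariate); ``loglik_history`` records the accepted
    partial log-likelihood after each Newton step and is non-decreasing.
    """

    names: list[str]
    params: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_history: list[float]
    n_iter: int
    converged: bool
    n: int
    n_events: int

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.se, "z": self.z, "p": self.p, "hr": self.hazard_ratios},
            index=self.names,
        )


class _CoxWorkspace:
    """Pre-sorted risk-set structure shared by fits on the same (times, events).

    Fitting many models over the same cohort (one per lncRNA) reuses the
    sort order, tie groups, and Efron within-tie weights.
    """

    def __init__(self, times: np.ndarray, events: np.ndarray, ties: str = "efron"):
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown tie handling {ties!r}")
        times = np.asarray(times, dtype=float)
        events = np.asarray(events).astype(bool)
        if times.ndim != 1 or times.shape != events.shape:
            raise ValueError("times and events must be 1-D and the same length")
        if not np.isfinite(times).all():
            raise ValueError("times must be finite")
        if events.sum() == 0:
            raise ValueError("at least one observed event is required")
        self.order = np.argsort(times, kind="stable")
        t = times[self.order]
        d = events[self.order]
        uniq, first_idx, inv = np.unique(t, return_index=True, return_inverse=True)
        self.ev_pos = np.nonzero(d)[0]
        self.g_ev = inv[self.ev_pos]
        self.n_groups = len(uniq)
        d_per_group = np.bincount(self.g_ev, minlength=self.n_groups)
        offsets = np.concatenate(([0], np.cumsum(d_per_group)))
        tie_rank = np.arange(self.ev_pos.size) - offsets[self.g_ev]
        # Breslow ignores the within-tie correction (all fractions zero)
        self.frac = tie_rank / d_per_group[self.g_ev] if ties == "efron" else np.zeros(self.ev_pos.size)
        self.risk_start = first_idx[self.g_ev]
        self.n = times.size
        self.n_events = int(self.ev_pos.size)

    def _loglik(self, Xs: np.ndarray, beta: np.ndarray) -> float:
        eta = Xs @ beta
        c = eta.max()
        w = np.exp(eta - c)
        s0 = np.cumsum(w[::-1])[::-1]
        s0_tie = np.bincount(self.g_ev, weights=w[self.ev_pos], minlength=self.n_groups)
        denom = s0[self.risk_start] - self.frac * s0_tie[self.g_ev]
        if (denom <= 0).any():
            return -np.inf
        return float((eta[self.ev_pos] - c).sum() - np.log(denom).sum())

    def _derivatives(self, Xs: np.ndarray, beta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        p = Xs.shape[1]
        eta = Xs @ beta
        c = eta.max()
        w = np.exp(eta - c)
        s0 = np.cumsum(w[::-1])[::-1]
        s0_tie = np.bincount(self.g_ev, weights=w[self.ev_pos], minlength=self.n_groups)
        denom = s0[self.risk_start] - self.frac * s0_tie[self.g_ev]
        loglik = float((eta[self.ev_pos] - c).sum() - np.log(denom).sum())
        xw = Xs * w[:, None]
        s1 = np.cumsum(xw[::-1], axis=0)[::-1]
        s1_tie = np.zeros((self.n_groups, p))
        np.add.at(s1_tie, self.g_ev, xw[self.ev_pos])
        m1 = (s1[self.risk_start] - self.frac[:, None] * s1_tie[self.g_ev]) / denom[:, None]
        grad = Xs[self.ev_pos].sum(axis=0) - m1.sum(axis=0)
        xxw = xw[:, :, None] * Xs[:, None, :]
        s2 = np.cumsum(xxw[::-1], axis=0)[::-1]
        s2_tie = np.zeros((self.n_groups, p, p))
        np.add.at(s2_tie, self.g_ev, xxw[self.ev_pos])
        num2 = s2[self.risk_start] - self.frac[:, None, None] * s2_tie[self.g_ev]
        info = (num2 / denom[:, None, None]).sum(axis=0) - m1.T @ m1
        return loglik, grad, info

    def fit(
        self,
        Xs: np.ndarray,
        beta0: np.ndarray | None = None,
        max_iter: int = 100,
        tol: float = 1e-9,
    ) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
        """Newton maximization on pre-sorted covariates ``Xs``."""
        p = Xs.shape[1]
        beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
        loglik, grad, info = self._derivatives(Xs, beta)
        history = [loglik]
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            new_beta = beta + step
            new_loglik = self._loglik(Xs, new_beta)
            halvings = 0
            while (not np.isfinite(new_loglik) or new_loglik < loglik) and halvings < 40:
                step = step / 2.0
                new_beta = beta + step
                new_loglik = self._loglik(Xs, new_beta)
                halvings += 1
            if not np.isfinite(new_loglik) or new_loglik < loglik:
                break  # no ascent direction left
            beta = new_beta
            delta = new_loglik - loglik
            loglik, grad, info = self._derivatives(Xs, beta)
            history.append(loglik)
            if abs(delta) < tol:
                converged = True
                break
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
            converged = False
        eta = Xs @ beta
        if eta.max() - eta.min() > 50:  # risk scores spread over e^50: monotone likelihood
            warnings.warn("possible monotone likelihood (separation); coefficients unreliable")
            converged = False
        return beta, se, history, n_iter, converged


def cox_fit(
    covariates: pd.DataFrame | np.ndarray,
    times: Sequence[float],
    events: Sequence[int],
    names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
    beta0: np.ndarray | None = None,
    ties: str = "efron",
) -> CoxFit:
    """Fit a Cox proportional-hazards model (Efron ties, Newton ascent).

    Convergence is declared when the partial log-likelihood improves by
    less than ``tol`` (default 1e-9) or after ``max_iter`` iterations.
    Perfect separation is reported via ``converged=False`` with a warning;
    a constant covariate column is an error.
    """
    if isinstance(covariates, pd.DataFrame):
        if names is None:
            names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    if (X.std(axis=0) == 0).any():
        bad = [names[i] for i in np.nonzero(X.std(axis=0) == 0)[0]]
        raise ValueError(f"constant covariate column(s): {bad}")
    ws = _CoxWorkspace(np.asarray(times, dtype=float), np.asarray(events), ties=ties)
    beta, se, history, n_iter, converged = ws.fit(X[ws.order], beta0=beta0, max_iter=max_iter, tol=tol)
    return CoxFit(
        names=list(names),
        params=beta,
        se=se,
        loglik=history[-1],
        loglik_history=history,
        n_iter=n_iter,
        converged=converged,
        n=ws.n,
        n_events=ws.n_events,
    )


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit estimate.

    ``median`` is the first time where S(t) ≤ 0.5, or None if the curve
    never crosses it.
    """

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Product-limit survival estimate with at-risk counts."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events))
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy(dtype=float)
    median = kmf.median_survival_time_
    return KMCurve(
        timeline=timeline,
        survival=survival,
        at_risk=at_risk,
        median=None if np.isinf(median) else float(median),
    )


def logrank_test(times: Sequence[float], events: Sequence[int], groups: Sequence) -> tuple[float, float]:
    """Log-rank test across groups; returns (chi-square, p)."""
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), np.asarray(groups), np.asarray(events)
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class PrognosticPanel:
    """Trained lncRNA panel: weights plus frozen training reference stats.

    ``members`` is indexed by lncRNA with columns ``median_coef`` (median
    Cox coefficient across subsamples), ``selection_freq`` (fraction of
    subsamples with a significant coefficient), ``ref_mean`` and ``ref_sd``
    (training-cohort mean/SD of the transformed expression used for
    Z-scoring new patients).
    """

    members: pd.DataFrame
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        required = {"median_coef", "selection_freq", "ref_mean", "ref_sd"}
        missing = required - set(self.members.columns)
        if missing:
            raise ValueError(f"panel members missing columns {sorted(missing)}")
        if (self.members["ref_sd"] <= 0).any():
            raise ValueError("panel reference SD must be positive")

    def __len__(self) -> int:
        return len(self.members)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "members": self.members.reset_index().rename(columns={"index": "lncRNA"}).to_dict(orient="records"),
            "config": self.config,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PrognosticPanel":
        payload = json.loads(Path(path).read_text())
        members = pd.DataFrame(payload["members"])
        if len(members):
            members = members.set_index("lncRNA")
        else:
            members = pd.DataFrame(columns=["median_coef", "selection_freq", "ref_mean", "ref_sd"])
        return cls(members=members, config=payload.get("config", {}), seed=payload.get("seed"))


def clinical_design(clinical: pd.DataFrame, covariates: Sequence[str] = PANEL_COVARIATES) -> pd.DataFrame:
    """Numeric design matrix from a clinical table.

    Coding: age in years untransformed; ``sex`` → indicator(male);
    ``grade`` → indicator(grade III or IV); ``idh_mut`` → indicator(mutant).
    Samples with a missing value in any requested covariate (or in
    time/event) are dropped with a logged count.
    """
    cols: dict[str, pd.Series] = {}
    for cov in covariates:
        if cov == "sex":
            cols["sex"] = (clinical["sex"] == "male").astype(float).where(clinical["sex"].notna())
        elif cov == "grade":
            cols["grade"] = clinical["grade"].isin(["III", "IV"]).astype(float).where(clinical["grade"].notna())
        else:
            cols[cov] = pd.to_numeric(clinical[cov], errors="coerce")
    design = pd.DataFrame(cols, index=clinical.index)
    keep = design.notna().all(axis=1) & clinical["time_days"].notna() & clinical["event"].notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d samples with incomplete clinical data", dropped)
    return design.loc[keep]


def train_panel(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: Sequence[str] = PANEL_COVARIATES,
    n_subsamples: int = 100,
    subsample_frac: float = 0.66,
    alpha: float = 0.05,
    selection_freq: float = 0.80,
    seed: int = 0,
) -> PrognosticPanel:
    """Train the resampling-based prognostic lncRNA panel on a test cohort.

    ``expression`` is lncRNA×sample, already inverse normal transformed per
    lncRNA over this cohort (see :func:`transform_matrix`). For each of
    ``n_subsamples`` random draws of ``floor(subsample_frac·n)`` patients
    (without replacement; a draw with zero events is redrawn), every lncRNA
    is fit in a Cox model together with the clinical covariates. lncRNAs
    with Wald p < ``alpha`` in at least ``selection_freq`` of subsamples are
    selected; each panel weight is the median coefficient over all
    subsamples, and reference mean/SD are frozen from the full cohort.

    Subsample s draws from its own RNG stream spawned from (seed, s), so
    changing ``n_subsamples`` does not reshuffle earlier draws.
    """
    design = clinical_design(clinical, covariates)
    samples = expression.columns.intersection(design.index)
    if len(samples) < 10:
        raise ValueError("too few samples with complete clinical data")
    design = design.loc[samples]
    times = clinical.loc[samples, "time_days"].to_numpy(dtype=float)
    events = clinical.loc[samples, "event"].to_numpy(dtype=float).astype(int)
    Z = design.to_numpy(dtype=float)
    expr = expression[samples].to_numpy(dtype=float)
    genes = list(expression.index)
    n = len(samples)
    m = int(np.floor(subsample_frac * n))
    n_genes = len(genes)
    betas = np.full((n_genes, n_subsamples), np.nan)
    pvals = np.full((n_genes, n_subsamples), np.nan)

    for s in range(n_subsamples):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(s,)))
        for attempt in range(100):
            idx = rng.choice(n, size=m, replace=False)
            if events[idx].sum() > 0:
                break
            logger.info("subsample %d had no events; redrawn", s)
        else:  # pragma: no cover - requires pathological censoring
            raise RuntimeError("could not draw a subsample containing an event")
        ws = _CoxWorkspace(times[idx], events[idx])
        Z_sub = Z[idx]
        Zs = Z_sub[ws.order]
        try:
            beta_clin, _, _, _, _ = ws.fit(Zs)
        except np.linalg.LinAlgError:  # pragma: no cover
            beta_clin = np.zeros(Z.shape[1])
        beta0 = np.append(beta_clin, 0.0)
        expr_sub = expr[:, idx][:, ws.order]
        for g in range(n_genes):
            col = expr_sub[g]
            if col.std() == 0:
                continue
            Xs = np.column_stack([Zs, col])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    beta, se, _, _, _ = ws.fit(Xs, beta0=beta0)
            except (np.linalg.LinAlgError, FloatingPointError):  # pragma: no cover
                continue
            b, e = beta[-1], se[-1]
            if np.isfinite(b) and np.isfinite(e) and e > 0:
                betas[g, s] = b
                pvals[g, s] = 2.0 * stats.norm.sf(abs(b / e))

    significant = np.nan_to_num(pvals, nan=1.0) < alpha
    freq = significant.mean(axis=1)
    selected = freq >= selection_freq
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median_coef = np.nanmedian(betas, axis=1)
    sel_genes = [genes[i] for i in np.nonzero(selected)[0]]
    ref = expression[samples]
    members = pd.DataFrame(
        {
            "median_coef": median_coef[selected],
            "selection_freq": freq[selected],
            "ref_mean": ref.loc[sel_genes].mean(axis=1).to_numpy() if sel_genes else [],
            "ref_sd": ref.loc[sel_genes].std(axis=1, ddof=1).to_numpy() if sel_genes else [],
        },
        index=pd.Index(sel_genes, name="lncRNA"),
    )
    config = {
        "covariates": list(covariates),
        "n_subsamples": n_subsamples,
        "subsample_frac": subsample_frac,
        "alpha": alpha,
        "selection_freq": selection_freq,
        "n_samples": int(n),
        "n_lncrnas": int(n_genes),
    }
    return PrognosticPanel(members=members, config=config, seed=seed)


def summed_cox_score(
    panel: PrognosticPanel,
    expression: pd.DataFrame,
    mode: str = "paper_literal",
    z_cutoff: float = 1.0,
) -> pd.Series:
    """Per-patient summed Cox coefficient risk score.

    Z-scores each panel lncRNA against the frozen training reference
    mean/SD. In ``paper_literal`` mode the median coefficient is added
    whenever |Z| ≥ ``z_cutoff`` regardless of the direction of deviation;
    in ``signed`` mode the contribution is sign(Z)·coefficient, so
    deviating *below* the reference flips the coefficient's sign.
    """
    if mode not in ("paper_literal", "signed"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    missing = panel.members.index.difference(expression.index)
    if len(missing):
        raise KeyError(f"expression missing panel lncRNAs: {list(missing)[:5]}")
    expr = expression.loc[panel.members.index]
    z = expr.sub(panel.members["ref_mean"], axis=0).div(panel.members["ref_sd"], axis=0)
    active = (z.abs() >= z_cutoff).astype(float)
    if mode == "signed":
        active = active * np.sign(z)
    return active.mul(panel.members["median_coef"], axis=0).sum(axis=0)


@dataclass
class StratificationResult:
    """Risk stratification of a cohort plus its survival evaluation."""

    scores: pd.Series
    groups: pd.Series  # 'poor' or 'good' per patient
    group_sizes: dict[str, int]
    hazard_ratio: float | None
    hr_ci: tuple[float, float] | None
    logrank_chi2: float | None
    logrank_p: float | None
    km: dict[str, KMCurve]
    median_survival: dict[str, float | None]


def stratify_and_evaluate(
    panel: PrognosticPanel,
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    mode: str = "paper_literal",
    z_cutoff: float = 1.0,
    transform: bool = True,
) -> StratificationResult:
    """Score a cohort with a trained panel and evaluate the split.

    ``expression`` is raw lncRNA×sample FPKM by default and is inverse
    normal transformed within this cohort (``transform=False`` if already
    transformed). Patients with positive summed coefficient form the poor
    group (score 0 counts as good: only a positive sum signals hazard). The
    hazard ratio is exp(β) of a univariate Cox fit on the poor indicator
    with a Wald 95% CI; group survival is summarized by Kaplan–Meier curves
    and the log-rank test. With an empty group the HR and log-rank are
    undefined and reported as None with a warning.
    """
    if transform:
        expression = transform_matrix(expression)
    samples = expression.columns.intersection(clinical.index)
    scores = summed_cox_score(panel, expression[samples], mode=mode, z_cutoff=z_cutoff)
    groups = pd.Series(np.where(scores > 0, "poor", "good"), index=scores.index, name="group")
    times = clinical.loc[samples, "time_days"].to_numpy(dtype=float)
    events = clinical.loc[samples, "event"].to_numpy(dtype=float).astype(int)
    group_sizes = {g: int((groups == g).sum()) for g in ("poor", "good")}
    km: dict[str, KMCurve] = {}
    medians: dict[str, float | None] = {}
    for g in ("poor", "good"):
        mask = (groups == g).to_numpy()
        if mask.any():
            km[g] = kaplan_meier(times[mask], events[mask])
            medians[g] = km[g].median
    hr = hr_ci = chi2 = p = None
    if group_sizes["poor"] > 0 and group_sizes["good"] > 0:
        indicator = (groups == "poor").to_numpy(dtype=float)
        fit = cox_fit(indicator[:, None], times, events, names=["poor_group"])
        hr = float(np.exp(fit.params[0]))
        lo, hi = fit.params[0] - 1.96 * fit.se[0], fit.params[0] + 1.96 * fit.se[0]
        hr_ci = (float(np.exp(lo)), float(np.exp(hi)))
        chi2, p = logrank_test(times, events, groups.to_numpy())
    else:
        warnings.warn("one risk group is empty; hazard ratio undefined")
    return StratificationResult(
        scores=scores,
        groups=groups,
        group_sizes=group_sizes,
        hazard_ratio=hr,
        hr_ci=hr_ci,
        logrank_chi2=chi2,
        logrank_p=p,
        km=km,
        median_survival=medians,
    )


def per_lncrna_prognosis(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: Sequence[str] = GBM_COVARIATES,
    alpha: float = 0.05,
    transform: bool = True,
) -> pd.DataFrame:
    """Per-lncRNA Cox prognosis calls with clinical covariates.

    Fits one model per lncRNA (covariates + transformed lncRNA expression)
    and labels each lncRNA ``poor`` (β > 0, p < alpha), ``good`` (β < 0,
    p < alpha) or ``ns``. No multiplicity correction is applied to these
    per-lncRNA p-values.
    """
    if transform:
        expression = transform_matrix(expression)
    design = clinical_design(clinical, covariates)
    samples = expression.columns.intersection(design.index)
    Z = design.loc[samples].to_numpy(dtype=float)
    times = clinical.loc[samples, "time_days"].to_numpy(dtype=float)
    events = clinical.loc[samples, "event"].to_numpy(dtype=float).astype(int)
    expr = expression[samples].to_numpy(dtype=float)
    ws = _CoxWorkspace(times, events)
    Zs = Z[ws.order]
    beta_clin, _, _, _, _ = ws.fit(Zs)
    beta0 = np.append(beta_clin, 0.0)
    rows = []
    for g, gene in enumerate(expression.index):
        col = expr[g][ws.order]
        if col.std() == 0:
            rows.append({"beta": np.nan, "se": np.nan, "z": np.nan, "p": np.nan, "group": "ns"})
            continue
        Xs = np.column_stack([Zs, col])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, se, _, _, _ = ws.fit(Xs, beta0=beta0)
        b, e = beta[-1], se[-1]
        z = b / e if e > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        group = "ns"
        if np.isfinite(p) and p < alpha:
            group = "poor" if b > 0 else "good"
        rows.append({"beta": b, "se": e, "z": z, "p": p, "group": group})
    return pd.DataFrame(rows, index=expression.index)


def tertile_km(expression: pd.Series, clinical: pd.DataFrame) -> dict:
    """Compare top-third vs bottom-third expressers of one lncRNA.

    Patients are ranked by expression; the top and bottom floor(n/3) form
    the high/low groups (ties broken by sample order), compared by
    Kaplan–Meier, log-rank, and a univariate Cox fit on the high-group
    indicator. Constant expression is an error (no ordering exists).
    """
    samples = expression.index.intersection(clinical.index)
    values = expression.loc[samples]
    if values.nunique() <= 1:
        raise ValueError("constant expression: tertiles undefined")
    n = len(samples)
    k = n // 3
    if k < 2:
        raise ValueError("too few patients for tertile comparison")
    order = np.argsort(values.to_numpy(), kind="stable")
    low_ids = samples[order[:k]]
    high_ids = samples[order[-k:]]
    sel = low_ids.append(high_ids)
    times = clinical.loc[sel, "time_days"].to_numpy(dtype=float)
    events = clinical.loc[sel, "event"].to_numpy(dtype=float).astype(int)
    indicator = np.concatenate([np.zeros(k), np.ones(k)])
    fit = cox_fit(indicator[:, None], times, events, names=["high_expression"])
    hr = float(np.exp(fit.params[0]))
    lo, hi = np.exp(fit.params[0] - 1.96 * fit.se[0]), np.exp(fit.params[0] + 1.96 * fit.se[0])
    chi2, p = logrank_test(times, events, indicator)
    return {
        "hr": hr,
        "hr_ci": (float(lo), float(hi)),
        "logrank_chi2": chi2,
        "logrank_p": p,
        "km_high": kaplan_meier(times[k:], events[k:]),
        "km_low": kaplan_meier(times[:k], events[:k]),
        "n_per_group": k,
    }
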