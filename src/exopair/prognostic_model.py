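"""Pair-based Cox risk model: screening, selection, fitting, evaluation.

Pipeline: univariate Cox screen over all valid pairs (Wald p < 0.001) ->
repeated cross-validated LASSO-Cox selection (selection-frequency vote) ->
backward AIC-minimal multivariate Cox fit.  The resulting risk score
``sum_i beta_i * S_i`` is evaluated with time-dependent (IPCW
cumulative/dynamic) ROC curves, Youden cutoffs, Kaplan-Meier / log-rank
group contrasts, clinical association tests, independence Cox models, and
decision-curve analysis.

Cox conventions: Breslow tie handling in the hand-rolled partial likelihood
(simulated times are continuous, so ties are measure-zero); multivariate
fits delegate to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from exopair.data_io import PairMatrix, RiskModel, SurvivalTable
from exopair.stats import censoring_km, chi_square_test, km_by_group, logrank_test, rank_sum_test

log = logging.getLogger(__name__)

__all__ = [
    "cox_partial_loglik",
    "univariate_cox_screen",
    "lasso_cox_select",
    "LassoSelection",
    "stepwise_aic_cox",
    "risk_score",
    "time_dependent_roc",
    "RocCurve",
    "dichotomize_and_test",
    "clinical_association",
    "independence_cox",
    "decision_curve",
]


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow)
# ---------------------------------------------------------------------------


def _riskset_index(time_desc: np.ndarray) -> np.ndarray:
    """For times sorted descending, index of the last member of each tie
    group — cumulative sums at that index give risk-set totals."""
    return np.searchsorted(-time_desc, -time_desc, side="right") - 1


def cox_partial_loglik(eta, time, event) -> float:
    """Breslow partial log-likelihood of linear predictors ``eta``."""
    eta = np.asarray(eta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="stable")
    eta_s, time_s, ev_s = eta[order], time[order], event[order]
    shift = eta_s.max()  # overflow guard; cancels in the ratio
    w = np.exp(eta_s - shift)
    s0 = np.cumsum(w)[_riskset_index(time_s)]
    mask = ev_s == 1
    return float(np.sum(eta_s[mask] - shift - np.log(s0[mask])))


def _univariate_cox(x, time, event, max_iter: int = 30, tol: float = 1e-9):
    """Newton fit of a single-covariate Cox model (Breslow ties).

    Returns ``(beta, se, converged)``; diverging fits (|beta| > 20, e.g.
    complete separation) are flagged unconverged.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="stable")
    xs, ts, es = x[order], time[order], event[order]
    idx = _riskset_index(ts)
    mask = es == 1
    beta = 0.0
    info = np.nan
    for _ in range(max_iter):
        w = np.exp(beta * (xs - xs.mean()))  # centering for stability
        s0 = np.cumsum(w)[idx]
        s1 = np.cumsum(w * xs)[idx]
        s2 = np.cumsum(w * xs * xs)[idx]
        mu = s1 / s0
        score = float(np.sum(xs[mask] - mu[mask]))
        info = float(np.sum(s2[mask] / s0[mask] - mu[mask] ** 2))
        if info <= 0:
            return beta, np.inf, False
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(beta) > 20.0:
            return beta, np.inf, False
        if abs(step) < tol:
            return beta, 1.0 / np.sqrt(info), True
    return beta, 1.0 / np.sqrt(info), False


def _align_pm_surv(pm: PairMatrix, surv: SurvivalTable):
    common = [s for s in pm.sample_ids if s in set(surv.sample_ids)]
    if not common:
        raise ValueError("pair matrix and survival table share no samples")
    sub = surv.subset(common)
    return pm.subset_samples(common), sub.time.to_numpy(), sub.event.to_numpy()


def univariate_cox_screen(
    pm: PairMatrix, surv: SurvivalTable, p_threshold: float = 0.001
) -> pd.DataFrame:
    """One single-covariate Cox fit per pair; Wald test against HR = 1.

    Returns a DataFrame (pair_id index) with beta, hr, ci_low, ci_high,
    pvalue and a ``selected`` flag (p < p_threshold, strict).  Unconverged
    pairs (e.g. complete separation) are dropped with a warning.
    """
    pm, time, event = _align_pm_surv(pm, surv)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("univariate Cox screen needs at least one event")
    if n_events < 10:
        log.warning("univariate Cox screen: only %d events; estimates unstable", n_events)
    rows = []
    dropped = []
    values = pm.values.to_numpy(dtype=float)
    for pid, x in zip(pm.pair_ids, values):
        beta, se, ok = _univariate_cox(x, time, event)
        if not ok or not np.isfinite(se):
            dropped.append(pid)
            continue
        z = beta / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "pair_id": pid,
                "beta": beta,
                "hr": np.exp(beta),
                "ci_low": np.exp(beta - 1.959963984540054 * se),
                "ci_high": np.exp(beta + 1.959963984540054 * se),
                "pvalue": p,
                "selected": p < p_threshold,
            }
        )
    if dropped:
        log.warning("univariate Cox screen: dropped %d unconverged pairs (e.g. %s)",
                    len(dropped), dropped[:3])
    columns = ["pair_id", "beta", "hr", "ci_low", "ci_high", "pvalue", "selected"]
    return pd.DataFrame(rows, columns=columns).set_index("pair_id")


# ---------------------------------------------------------------------------
# repeated cross-validated LASSO-Cox selection
# ---------------------------------------------------------------------------


@dataclass
class LassoSelection:
    """Selection frequencies across CV-LASSO cycles and the surviving set."""

    frequencies: pd.Series
    selected: list[str]
    chosen_alphas: list[float]
    n_cycles: int
    threshold: float


def _coxnet_path(X, y, alphas=None, n_alphas: int = 50):
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        alphas=alphas,
        n_alphas=n_alphas,
        alpha_min_ratio=0.01,
        max_iter=100000,
        tol=1e-7,
    )
    model.fit(X, y)
    return np.asarray(model.alphas_), np.asarray(model.coef_)


def lasso_cox_select(
    candidates: PairMatrix,
    surv: SurvivalTable,
    n_cycles: int = 50,
    folds: int = 10,
    selection_threshold: float = 0.5,
    seed: int = 0,
    lambda_rule: str = "1se",
) -> LassoSelection:
    """Repeated 10-fold CV LASSO-Cox with a selection-frequency vote.

    Each cycle draws a fresh fold assignment, fits the L1 path, scores each
    penalty by the cross-validated partial-likelihood deviance (Verweij &
    van Houwelingen: ``-2 * (ll(all; beta) - ll(train; beta))`` summed over
    folds), picks the penalty per ``lambda_rule``, and records which pairs
    have nonzero coefficients there (from the full-data path).  Pairs
    selected in more than ``selection_threshold`` of cycles survive.

    ``lambda_rule='1se'`` (default) takes the sparsest penalty whose mean
    CV deviance is within one standard error of the minimum — the usual
    choice for sparse prognostic signatures, which keeps redundant
    correlated pairs out of the vote; ``'min'`` takes the exact minimizer.
    """
    if lambda_rule not in ("min", "1se"):
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
    if len(candidates.pair_ids) < 2:
        raise ValueError("LASSO selection needs >= 2 candidate pairs")
    pm, time, event = _align_pm_surv(candidates, surv)
    n_events = int(event.sum())
    if folds > n_events:
        raise ValueError(f"folds ({folds}) cannot exceed the event count ({n_events})")
    X = pm.values.to_numpy(dtype=float).T
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    alphas, coefs_full = _coxnet_path(X, y)

    counts = np.zeros(len(pm.pair_ids))
    chosen_alphas = []
    rng = np.random.default_rng(seed)
    for _ in range(n_cycles):
        cycle_seed = int(rng.integers(0, 2**31 - 1))
        kf = KFold(n_splits=folds, shuffle=True, random_state=cycle_seed)
        devs = np.full((folds, len(alphas)), np.nan)
        for fold_i, (train_idx, _test_idx) in enumerate(kf.split(X)):
            if event[train_idx].sum() == 0:
                continue
            try:
                fold_alphas, fold_coefs = _coxnet_path(X[train_idx], y[train_idx], alphas=alphas)
            except (ArithmeticError, ValueError):
                continue
            pos = {round(float(a), 12): j for j, a in enumerate(fold_alphas)}
            for i, a in enumerate(alphas):
                j = pos.get(round(float(a), 12))
                if j is None:
                    continue
                beta = fold_coefs[:, j]
                ll_all = cox_partial_loglik(X @ beta, time, event)
                ll_train = cox_partial_loglik(
                    X[train_idx] @ beta, time[train_idx], event[train_idx]
                )
                devs[fold_i, i] = -2.0 * (ll_all - ll_train)
        n_ok = np.sum(~np.isnan(devs), axis=0)
        complete = n_ok == n_ok.max()
        if n_ok.max() == 0:
            continue
        mean_dev = np.where(complete, np.nanmean(devs, axis=0), np.inf)
        best = int(np.argmin(mean_dev))
        if lambda_rule == "1se":
            se_best = float(
                np.nanstd(devs[:, best], ddof=1) / np.sqrt(n_ok[best])
            ) if n_ok[best] > 1 else 0.0
            within = np.where(complete & (mean_dev <= mean_dev[best] + se_best))[0]
            best = int(within[0])  # alphas descend: first = sparsest
        chosen_alphas.append(float(alphas[best]))
        counts += coefs_full[:, best] != 0.0

    freqs = pd.Series(counts / n_cycles, index=pm.pair_ids, name="selection_frequency")
    if freqs.max() == 0:
        raise ValueError(
            "LASSO never selected any pair; consider relaxing the selection threshold "
            "or the upstream univariate p threshold"
        )
    selected = list(freqs.index[freqs > selection_threshold])
    if not selected:
        raise ValueError(
            f"no pair exceeded the selection-frequency threshold {selection_threshold}; "
            "consider relaxing it"
        )
    return LassoSelection(freqs, selected, chosen_alphas, n_cycles, selection_threshold)


# ---------------------------------------------------------------------------
# backward AIC-minimal multivariate Cox
# ---------------------------------------------------------------------------


def _fit_cox_df(df: pd.DataFrame, penalizer: float = 0.0) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df, duration_col="time", event_col="event")
    return cph


def _cox_fit_aic(X: pd.DataFrame, time, event, cols) -> tuple[float, CoxPHFitter | None]:
    if not cols:
        ll0 = cox_partial_loglik(np.zeros(len(time)), time, event)
        return -2.0 * ll0, None
    df = X[list(cols)].copy()
    df["time"] = time
    df["event"] = event
    try:
        cph = _fit_cox_df(df)
    except ConvergenceError:
        log.warning("multivariate Cox fit failed to converge; retrying with ridge "
                    "stabilization (penalizer=0.01)")
        cph = _fit_cox_df(df, penalizer=0.01)
    return float(cph.AIC_partial_), cph


def stepwise_aic_cox(selected: PairMatrix, surv: SurvivalTable) -> RiskModel:
    """Backward elimination from the full multivariate Cox fit by AIC.

    Iteratively removes the covariate whose removal most decreases
    ``AIC = -2 logPL + 2p``; stops when no removal helps.  The surviving
    coefficients define the risk model.
    """
    if len(selected.pair_ids) < 1:
        raise ValueError("stepwise fit needs >= 1 pair")
    pm, time, event = _align_pm_surv(selected, surv)
    X = pd.DataFrame(
        pm.values.to_numpy(dtype=float).T, columns=pm.pair_ids,
        index=pm.sample_ids,
    )
    current = list(pm.pair_ids)
    aic_current, fit_current = _cox_fit_aic(X, time, event, current)
    aic_start = aic_current
    while current:
        best_drop, best_aic, best_fit = None, aic_current, fit_current
        for col in current:
            trial = [c for c in current if c != col]
            aic_trial, fit_trial = _cox_fit_aic(X, time, event, trial)
            if aic_trial < best_aic - 1e-10:
                best_drop, best_aic, best_fit = col, aic_trial, fit_trial
        if best_drop is None:
            break
        current = [c for c in current if c != best_drop]
        aic_current, fit_current = best_aic, best_fit
    if not current:
        log.warning("backward AIC eliminated every pair; returning an empty model")
        return RiskModel([], [], training_meta={"aic": aic_current, "aic_full": aic_start})
    betas = [float(fit_current.params_[c]) for c in current]
    return RiskModel(
        pairs=current,
        beta=betas,
        training_meta={
            "aic": aic_current,
            "aic_full": aic_start,
            "n_samples": len(time),
            "n_events": int(np.sum(event)),
        },
    )


def risk_score(model: RiskModel, pm: PairMatrix) -> pd.Series:
    """Per-sample risk score ``sum_i beta_i * S_i`` over the model pairs."""
    missing = [p for p in model.pairs if p not in pm.values.index]
    if missing:
        raise KeyError(f"pairs absent from matrix: {missing}")
    if not model.pairs:
        return pd.Series(np.zeros(len(pm.sample_ids)), index=pm.sample_ids, name="risk_score")
    s = pm.values.loc[model.pairs].to_numpy(dtype=float)
    scores = np.asarray(model.beta, dtype=float) @ s
    return pd.Series(scores, index=pm.sample_ids, name="risk_score")


# ---------------------------------------------------------------------------
# time-dependent ROC (IPCW cumulative/dynamic)
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    """Time-dependent ROC at one horizon, with the Youden-optimal cutoff."""

    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    youden: float


def time_dependent_roc(scores: pd.Series, surv: SurvivalTable, horizon: float) -> RocCurve:
    """Cumulative-case / dynamic-control ROC at ``horizon`` with IPCW.

    Cases are samples with an observed event at or before the horizon,
    weighted by ``1 / G(T-)`` where G is the Kaplan-Meier estimate of the
    censoring survival function; controls are samples still at risk past
    the horizon (constant weight ``1 / G(horizon)``, which cancels).  A
    sample is called high-risk at threshold c iff its score strictly
    exceeds c.  The cutoff maximizes Youden's J with ties broken toward the
    lower score.
    """
    common = [s for s in scores.index if s in set(surv.sample_ids)]
    if not common:
        raise ValueError("scores and survival table share no samples")
    sub = surv.subset(common)
    sc = scores.loc[common].to_numpy(dtype=float)
    time = sub.time.to_numpy()
    event = sub.event.to_numpy()
    if horizon > time.max():
        raise ValueError(f"horizon {horizon} beyond the observed follow-up range")
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    if case.sum() == 0:
        raise ValueError("no events observed before the horizon")
    if control.sum() == 0:
        raise ValueError("no samples at risk past the horizon")
    G = censoring_km(time, event)
    w = np.zeros(len(sc))
    for i in np.where(case)[0]:
        g = G.at_left(time[i])
        if g <= 0:
            log.warning("case with zero censoring-survival weight excluded")
            case[i] = False
            continue
        w[i] = 1.0 / g
    w_ctrl = 1.0
    thr = np.unique(sc)
    sens = np.empty(len(thr))
    spec = np.empty(len(thr))
    w_case_total = w[case].sum()
    n_ctrl = control.sum() * w_ctrl
    for i, c in enumerate(thr):
        pos = sc > c
        sens[i] = w[case & pos].sum() / w_case_total
        spec[i] = (control & ~pos).sum() * w_ctrl / n_ctrl
    # integrate the staircase including the (1,1) endpoint; lexicographic
    # ordering keeps vertical risers (equal FPR, rising TPR) area-free
    fpr = np.concatenate([[1.0], 1.0 - spec])
    tpr = np.concatenate([[1.0], sens])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # thresholds ascending: first max = lowest score
    return RocCurve(
        horizon=float(horizon),
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        cutoff=float(thr[best]),
        youden=float(j[best]),
    )


def dichotomize_and_test(scores: pd.Series, cutoff: float, surv: SurvivalTable):
    """Split into high (score > cutoff) and low risk groups; KM + log-rank.

    Returns ``(labels, curves, statistic, p)``.  Raises if every sample
    lands in one group.
    """
    labels = pd.Series(
        np.where(scores.to_numpy(dtype=float) > cutoff, "high", "low"),
        index=scores.index,
        name="risk_group",
    )
    if labels.nunique() < 2:
        raise ValueError(f"cutoff {cutoff} puts every sample in one group")
    common = [s for s in labels.index if s in set(surv.sample_ids)]
    sub = surv.subset(common)
    grp = labels.loc[common].to_numpy()
    curves = km_by_group(sub.time.to_numpy(), sub.event.to_numpy(), grp)
    stat, _df, p = logrank_test(sub.time.to_numpy(), sub.event.to_numpy(), grp)
    return labels, curves, stat, p


# ---------------------------------------------------------------------------
# clinical association / independence
# ---------------------------------------------------------------------------


def clinical_association(
    scores: pd.Series, labels: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Associate the risk model with clinical covariates.

    Categorical covariates are cross-tabulated against the risk group
    (Pearson chi-square); binary covariates additionally compare the
    continuous risk score between their two levels (two-sided Wilcoxon
    rank-sum, exact for small tie-free groups).  Covariates with a single
    level are skipped with a warning.
    """
    common = [s for s in labels.index if s in set(covariates.index)]
    cov = covariates.loc[common]
    rows = []
    for name in cov.columns:
        col = cov[name].dropna()
        levels = col.unique()
        if len(levels) < 2:
            log.warning("covariate %r has a single level; skipped", name)
            continue
        if pd.api.types.is_numeric_dtype(col) and len(levels) > 6:
            log.warning("covariate %r looks continuous; association tests here are "
                        "categorical — skipped", name)
            continue
        table = pd.crosstab(labels.loc[col.index], col)
        stat, dof, p, _exp = chi_square_test(table.to_numpy())
        rows.append({"covariate": name, "test": "chi_square", "statistic": stat,
                     "df": dof, "pvalue": p})
        if len(levels) == 2:
            lv = sorted(levels)
            a = scores.loc[col.index[col == lv[0]]].to_numpy()
            b = scores.loc[col.index[col == lv[1]]].to_numpy()
            u, p2 = rank_sum_test(a, b)
            rows.append({"covariate": name, "test": "wilcoxon_rank_sum",
                         "statistic": u, "df": np.nan, "pvalue": p2})
    return pd.DataFrame(rows)


def _encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Ordinal-encode categorical covariates (sorted level order) for Cox fits."""
    out = {}
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            out[name] = col.astype(float)
        else:
            levels = sorted(col.dropna().unique())
            mapping = {lv: i for i, lv in enumerate(levels)}
            out[name] = col.map(mapping).astype(float)
    return pd.DataFrame(out, index=covariates.index)


def independence_cox(
    scores: pd.Series, covariates: pd.DataFrame, surv: SurvivalTable
) -> dict[str, pd.DataFrame]:
    """Univariate and multivariate Cox models testing the score's independence.

    Complete cases only (dropped rows logged).  Categorical covariates are
    ordinal-encoded.  Collinear designs are refit with a small ridge
    penalty (warning logged).  Returns ``{"univariate": ..., "multivariate":
    ...}`` tables with hr, ci_low, ci_high, pvalue per term.
    """
    common = [s for s in scores.index if s in set(surv.sample_ids)]
    sub = surv.subset(common)
    design = _encode_covariates(covariates.loc[common])
    design.insert(0, "risk_score", scores.loc[common].astype(float))
    full = design.copy()
    full["time"] = sub.time
    full["event"] = sub.event
    n_before = len(full)
    full = full.dropna()
    if len(full) < n_before:
        log.info("independence_cox: dropped %d incomplete cases", n_before - len(full))

    def summarize(cph: CoxPHFitter, terms) -> pd.DataFrame:
        s = cph.summary.loc[terms]
        return pd.DataFrame(
            {
                "hr": np.exp(s["coef"]),
                "ci_low": np.exp(s["coef lower 95%"]),
                "ci_high": np.exp(s["coef upper 95%"]),
                "pvalue": s["p"],
            }
        )

    uni_rows = []
    for term in design.columns:
        df = full[[term, "time", "event"]]
        try:
            cph = _fit_cox_df(df)
        except ConvergenceError:
            log.warning("univariate Cox for %r did not converge; ridge refit", term)
            cph = _fit_cox_df(df, penalizer=0.1)
        uni_rows.append(summarize(cph, [term]))
    univariate = pd.concat(uni_rows)

    X = full[list(design.columns)].to_numpy()
    penalizer = 0.0
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        log.warning("collinear covariates detected; multivariate Cox uses ridge "
                    "stabilization (penalizer=0.1)")
        penalizer = 0.1
    try:
        cph = _fit_cox_df(full, penalizer=penalizer)
    except ConvergenceError:
        log.warning("multivariate Cox did not converge; ridge refit (penalizer=0.1)")
        cph = _fit_cox_df(full, penalizer=0.1)
    multivariate = summarize(cph, list(design.columns))
    return {"univariate": univariate, "multivariate": multivariate}


# ---------------------------------------------------------------------------
# decision-curve analysis
# ---------------------------------------------------------------------------


def decision_curve(
    scores: pd.Series,
    surv: SurvivalTable,
    horizon: float,
    thresholds=None,
) -> pd.DataFrame:
    """Net benefit of score-guided treatment over threshold probabilities.

    The binary outcome is "event by the horizon" (samples censored before
    the horizon are excluded, logged).  The continuous score is mapped to a
    risk probability by a logistic fit of the outcome on the score; at each
    threshold probability p_t the net benefit is
    ``TP/n - FP/n * p_t / (1 - p_t)`` for the rule "treat iff predicted
    risk > p_t", alongside treat-all and treat-none reference curves.
    """
    if thresholds is None:
        thresholds = np.arange(0.01, 1.00, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold grid")
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    common = [s for s in scores.index if s in set(surv.sample_ids)]
    sub = surv.subset(common)
    time = sub.time.to_numpy()
    event = sub.event.to_numpy()
    sc = scores.loc[common].to_numpy(dtype=float)
    usable = (time > horizon) | ((time <= horizon) & (event == 1))
    n_excl = int((~usable).sum())
    if n_excl:
        log.info("decision_curve: excluded %d samples censored before the horizon", n_excl)
    y = ((time[usable] <= horizon) & (event[usable] == 1)).astype(int)
    x = sc[usable]
    n = len(y)
    prevalence = y.mean()
    if prevalence == 0:
        raise ValueError("no events by the horizon; decision curve undefined")
    if len(np.unique(y)) == 2 and len(np.unique(x)) > 1:
        lr = LogisticRegression(C=np.inf, max_iter=5000)  # unpenalized calibration
        lr.fit(x.reshape(-1, 1), y)
        prob = lr.predict_proba(x.reshape(-1, 1))[:, 1]
    else:
        prob = np.full(n, prevalence)
    rows = []
    for pt in thresholds:
        odds = pt / (1.0 - pt)
        treat = prob > pt
        tp = int((treat & (y == 1)).sum())
        fp = int((treat & (y == 0)).sum())
        nb_model = tp / n - fp / n * odds
        nb_all = prevalence - (1.0 - prevalence) * odds
        rows.append({"threshold": pt, "nb_model": nb_model, "nb_all": nb_all, "nb_none": 0.0})
    return pd.DataFrame(rows)
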