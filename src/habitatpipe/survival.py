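"""Habitat risk score and survival risk models.

The habitat risk score (HRS) of patient *i* is the relative hazard at
time zero under an L1-penalised Cox proportional-hazards model:

    HRS_i = h0(0) * exp( sum_j beta_j * x_ij )

where the x_ij are z-scored habitat-heterogeneity features, the beta_j
are the non-zero Cox-LASSO coefficients, and h0(0) is the Breslow
baseline-hazard increment at the earliest development event time — a
patient-independent positive constant, so every ranking-based statistic
downstream is invariant to it.

The penalised fit is a glmnet-style coordinate descent on the Breslow
partial likelihood, with the penalty chosen by 10-fold cross-validated
partial-likelihood deviance (Verweij & van Houwelingen), folds
stratified by event status, and a final refit on all development data.
Patients are stratified at the development-median score (score >= cutoff
is high risk), groups are compared with a single-covariate Cox fit, and
models are compared by Harrell's concordance over bootstrap replicates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats as sps

__all__ = [
    "CoxLassoModel",
    "cox_partial_loglik",
    "fit_cox_lasso",
    "compute_risk_score",
    "stratify",
    "group_hazard_ratio",
    "harrell_c_index",
    "compare_models",
    "build_all_risk_models",
]


def _order_by_time(time: np.ndarray, event: np.ndarray):
    order = np.argsort(time, kind="stable")
    return order, time[order], event[order]


def cox_partial_loglik(
    eta: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow partial log-likelihood at linear predictor ``eta``."""
    order, t, d = _order_by_time(np.asarray(time, float), np.asarray(event, int))
    e = np.asarray(eta, float)[order]
    e = e - e.max()  # partial likelihood is shift-invariant; avoid overflow
    # risk-set sums S0(t) via reverse cumulative sums of exp(eta)
    rev = np.cumsum(np.exp(e)[::-1])[::-1]
    ll = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dm = d[i:j].sum()
        if dm > 0:
            ll += e[i:j][d[i:j] == 1].sum() - dm * np.log(rev[i])
        i = j
    return float(ll)


def _grad_hess_diag(eta, time, event):
    """Per-subject gradient and diagonal Hessian of the Breslow loglik."""
    n = len(time)
    order, t, d = _order_by_time(np.asarray(time, float), np.asarray(event, int))
    eta_s = np.asarray(eta, float)[order]
    e = np.exp(eta_s - eta_s.max())  # shift-invariant; avoid overflow
    rev = np.cumsum(e[::-1])[::-1]
    # cumulative hazard terms A_i = sum_{t_m <= t_i} d_m / S0(t_m),
    # B_i likewise with S0^2; subjects tied in time share one risk set
    _, first, inv, counts = np.unique(
        t, return_index=True, return_inverse=True, return_counts=True
    )
    dm = np.bincount(inv, weights=d.astype(float))
    s0 = rev[first]
    a = np.cumsum(dm / s0)[inv]
    b = np.cumsum(dm / s0**2)[inv]
    grad_s = d - e * a
    w_s = e * a - e**2 * b
    grad = np.empty(n)
    w = np.empty(n)
    grad[order] = grad_s
    w[order] = np.clip(w_s, 1e-9, None)
    return grad, w


def _cd_quadratic(x, w, z, beta, lam, penalize, tol=1e-9, max_iter=1000):
    """Cyclic coordinate descent for penalised weighted least squares.

    Uses the usual active-set strategy: after a full sweep, iterate on
    the non-zero coordinates until convergence, then confirm with
    another full sweep (which may activate new coordinates).
    """
    n, p = x.shape
    wx = w[:, None] * x
    gram = wx.T @ x / n  # covariance updates: O(p) per coordinate
    c = wx.T @ z / n
    nu = np.diag(gram).copy()
    s = gram @ beta  # running gram . beta

    def sweep(idx):
        nonlocal s
        delta = 0.0
        for j in idx:
            if nu[j] == 0:
                continue
            rho = c[j] - s[j] + nu[j] * beta[j]
            if penalize[j]:
                bj = np.sign(rho) * max(abs(rho) - lam, 0.0) / nu[j]
            else:
                bj = rho / nu[j]
            step = bj - beta[j]
            if step != 0.0:
                s += gram[:, j] * step
                delta = max(delta, abs(step))
                beta[j] = bj
        return delta

    every = np.arange(p)
    iters = 0
    while iters < max_iter:
        if sweep(every) < tol:
            break
        iters += 1
        active = np.flatnonzero(beta != 0)
        while iters < max_iter and len(active):
            if sweep(active) < tol:
                break
            iters += 1
    return beta


def _fit_at_lambda(
    x, time, event, lam, beta0=None, penalize=None, max_outer=100, tol=1e-8
):
    """L1-penalised Cox fit at a single penalty via IRLS + coordinate descent."""
    n, p = x.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    if penalize is None:
        penalize = np.ones(p, dtype=bool)
    cd_tol = tol / 10
    for _ in range(max_outer):
        eta = x @ beta
        grad, w = _grad_hess_diag(eta, time, event)
        z = eta + grad / w
        new = _cd_quadratic(x, w, z, beta.copy(), lam, penalize, tol=cd_tol)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
        if np.max(np.abs(beta)) > 50.0:
            # monotone-likelihood divergence (saturated design at a tiny
            # penalty); stop rather than chase an infinite optimum
            warnings.warn("Cox fit diverging; stopping at the current iterate")
            break
    return beta


def _lambda_grid(x, time, event, n_lambda=50, ratio=None):
    grad, _ = _grad_hess_diag(np.zeros(len(time)), time, event)
    lam_max = np.max(np.abs(x.T @ grad)) / len(time)
    lam_max = max(lam_max, 1e-10)
    if ratio is None:
        # saturated designs (p >= n) need a higher penalty floor or the
        # path tail chases unbounded optima (glmnet uses the same split)
        ratio = 1e-3 if x.shape[0] > x.shape[1] else 1e-2
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _stratified_folds(event: np.ndarray, n_folds: int, seed: int):
    rng = np.random.default_rng(seed)
    folds = np.empty(len(event), dtype=int)
    for flag in (0, 1):
        idx = np.flatnonzero(event == flag)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


@dataclass
class CoxLassoModel:
    """Frozen Cox-LASSO risk model (selected panel + scoring constants)."""

    feature_names: list[str]  # selected (non-zero) features
    coefficients: np.ndarray  # matching betas
    lambda_: float
    h0: float  # Breslow baseline-hazard increment at the first event time
    cutoff: float  # development median risk score
    zscore_stats: pd.DataFrame | None = None  # development mean/sd per raw feature

    def to_json(self, path: str | Path) -> None:
        d = {
            "feature_names": list(self.feature_names),
            "coefficients": np.asarray(self.coefficients).tolist(),
            "lambda": self.lambda_,
            "h0": self.h0,
            "cutoff": self.cutoff,
        }
        if self.zscore_stats is not None:
            d["zscore_stats"] = self.zscore_stats.to_dict(orient="index")
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CoxLassoModel":
        d = json.loads(Path(path).read_text())
        stats_d = d.get("zscore_stats")
        return cls(
            feature_names=d["feature_names"],
            coefficients=np.asarray(d["coefficients"]),
            lambda_=float(d["lambda"]),
            h0=float(d["h0"]),
            cutoff=float(d["cutoff"]),
            zscore_stats=(
                pd.DataFrame.from_dict(stats_d, orient="index")
                if stats_d is not None
                else None
            ),
        )


def fit_cox_lasso(
    features: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    zscore_stats: pd.DataFrame | None = None,
) -> CoxLassoModel:
    """Fit the Cox-LASSO with cross-validated penalty selection.

    ``features`` must already be z-scored with development statistics.
    The penalty path runs from the smallest all-zero penalty downward
    over a 50-point log grid with warm starts; the cross-validation
    criterion is the Verweij-van Houwelingen partial-likelihood
    deviance; the final model is refit at the selected penalty on all
    supplied data.
    """
    x = features.to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least two events to fit a Cox model")
    n, p = x.shape
    if lambdas is None:
        lambdas = _lambda_grid(x, time, event)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]

    n_folds = min(n_folds, int(event.sum()))
    folds = _stratified_folds(event, n_folds, seed)
    cv_ll = np.zeros(len(lambdas))
    for f in range(n_folds):
        train = folds != f
        d_train = int(event[train].sum())
        if d_train == 0:
            continue
        # past ~0.9 events' worth of active features the fit is saturated
        # and smaller penalties cannot win the CV; freeze the path there
        df_max = max(1, int(0.9 * d_train))
        beta = np.zeros(p)
        for li, lam in enumerate(lambdas):
            # the cross-validated deviance curve is smooth in lambda, so a
            # looser tolerance and iteration cap suffice inside CV; the
            # final refit is tight
            beta = _fit_at_lambda(
                x[train], time[train], event[train], lam,
                beta0=beta, tol=1e-5, max_outer=30,
            )
            ll_all = cox_partial_loglik(x @ beta, time, event)
            ll_train = cox_partial_loglik(
                x[train] @ beta, time[train], event[train]
            )
            cv_ll[li] += ll_all - ll_train
            if int((beta != 0).sum()) >= df_max:
                # remaining (smaller) penalties inherit this fold's last
                # contribution: the frozen path approximates beta(lam)
                cv_ll[li + 1:] += ll_all - ll_train
                break
    best = int(np.argmax(cv_ll))
    lam_star = float(lambdas[best])

    # warm-started path refit on all data down to lam_star
    df_max = max(1, int(0.9 * event.sum()))
    beta = np.zeros(p)
    for lam in lambdas[: best + 1]:
        beta = _fit_at_lambda(x, time, event, lam, beta0=beta)
        if int((beta != 0).sum()) >= df_max:
            break

    eta = x @ beta
    h0 = breslow_h0(eta, time, event)
    selected = np.flatnonzero(np.abs(beta) > 1e-10)
    if selected.size == 0:
        warnings.warn("Cox-LASSO selected no features; risk score is constant")
    model = CoxLassoModel(
        feature_names=[features.columns[j] for j in selected],
        coefficients=beta[selected],
        lambda_=lam_star,
        h0=h0,
        cutoff=0.0,
        zscore_stats=zscore_stats,
    )
    scores = compute_risk_score(model, features)
    model.cutoff = float(np.median(scores))
    return model


def breslow_h0(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow baseline-hazard increment at the earliest event time."""
    event = np.asarray(event, int)
    time = np.asarray(time, float)
    if event.sum() == 0:
        raise ValueError("no events; baseline hazard undefined")
    t1 = time[event == 1].min()
    d1 = int(((time == t1) & (event == 1)).sum())
    at_risk = time >= t1
    return float(d1 / np.exp(np.asarray(eta, float)[at_risk]).sum())


def compute_risk_score(model: CoxLassoModel, features: pd.DataFrame) -> np.ndarray:
    """Risk score ``h0(0) * exp(beta . x)`` per patient."""
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise KeyError(f"features missing from table: {missing}")
    if len(model.feature_names) == 0:
        return np.full(len(features), model.h0)
    x = features[model.feature_names].to_numpy(dtype=float)
    return model.h0 * np.exp(x @ np.asarray(model.coefficients))


def stratify(scores: np.ndarray, cutoff: float) -> np.ndarray:
    """Boolean high-risk labels; score equal to the cutoff counts as high."""
    return np.asarray(scores, float) >= cutoff


def group_hazard_ratio(
    high: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, tuple[float, float], float]:
    """High- vs low-risk hazard ratio from a single-covariate Cox fit.

    Returns (HR, (lo, hi), p) with a Wald 95% confidence interval.
    Monotone-likelihood situations (a group with no events) are flagged
    with a warning and yield wide intervals rather than an error.
    """
    high = np.asarray(high, bool)
    event = np.asarray(event, int)
    if high.all() or (~high).all():
        raise ValueError("both risk groups must be non-empty")
    if event.sum() == 0:
        raise ValueError("no events in either group")
    for grp, name in ((high, "high"), (~high, "low")):
        if event[grp].sum() == 0:
            warnings.warn(f"no events in the {name}-risk group; HR estimate unstable")
    df = pd.DataFrame(
        {"time": np.asarray(time, float), "event": event, "high": high.astype(int)}
    )
    fitter = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitter.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(fitter.params_["high"]))
    ci = fitter.confidence_intervals_
    lo, hi = float(np.exp(ci.iloc[0, 0])), float(np.exp(ci.iloc[0, 1]))
    p = float(fitter.summary.loc["high", "p"])
    return hr, (lo, hi), p


def harrell_c_index(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, float]:
    """Harrell's concordance index with a pairs-based standard error.

    Usable pairs are those where the ordering of failure is known: the
    earlier patient had an event, or both failed at different times.
    Score ties count 0.5.  The SE is the binomial approximation
    sqrt(C(1-C)/N_pairs) over usable pairs.
    """
    s = np.asarray(scores, float)
    t = np.asarray(time, float)
    d = np.asarray(event, int)
    conc = disc = ties = 0
    n = len(s)
    for i in range(n):
        if d[i] != 1:
            continue
        later = t > t[i]
        conc += int((s[i] > s[later]).sum())
        disc += int((s[i] < s[later]).sum())
        ties += int((s[i] == s[later]).sum())
    total = conc + disc + ties
    if total == 0:
        raise ValueError("no comparable pairs")
    c = (conc + 0.5 * ties) / total
    se = float(np.sqrt(max(c * (1 - c), 1e-12) / total))
    return float(c), se


def compare_models(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Paired comparison of two models' C-indices over bootstrap replicates.

    Patients are resampled with replacement; both models' concordances
    are computed on each replicate and a two-sided paired t-test is
    applied to the per-replicate differences.  Identical score vectors
    return p = 1.
    """
    if n_boot < 20:
        raise ValueError("need at least 20 bootstrap replicates")
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    if len(scores_a) != len(scores_b):
        raise ValueError("score vectors must cover the same patients")
    if np.array_equal(scores_a, scores_b):
        return 1.0
    rng = np.random.default_rng(seed)
    n = len(scores_a)
    diffs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ca, _ = harrell_c_index(scores_a[idx], time[idx], event[idx])
            cb, _ = harrell_c_index(scores_b[idx], time[idx], event[idx])
        except ValueError:
            continue
        diffs.append(ca - cb)
    diffs = np.asarray(diffs)
    if len(diffs) < 20:
        raise ValueError("too few usable bootstrap replicates")
    if np.allclose(diffs, 0):
        return 1.0
    _, p = sps.ttest_1samp(diffs, 0.0)
    return float(p)


# ---------------------------------------------------------------------------
# the five risk models

MODEL_NAMES = (
    "radiomics_DCE_MR",
    "radiomics_perfusion",
    "HRS_only",
    "clinical",
    "combined_habitat",
)


def _fit_scoring_model(dev_feats, val_feats, dev_time, dev_event, seed):
    from habitatpipe.features import z_score_normalize

    dev_z, stats = z_score_normalize(dev_feats)
    val_z, _ = z_score_normalize(val_feats, stats)
    model = fit_cox_lasso(
        dev_z, dev_time, dev_event, seed=seed, zscore_stats=stats
    )
    return model, compute_risk_score(model, dev_z), compute_risk_score(model, val_z)


def build_all_risk_models(
    dev: Mapping[str, pd.DataFrame | np.ndarray],
    val: Mapping[str, pd.DataFrame | np.ndarray],
    seed: int = 0,
    n_boot: int = 200,
) -> tuple[pd.DataFrame, dict[str, CoxLassoModel]]:
    """Fit and evaluate the five survival risk models on both cohorts.

    ``dev``/``val`` map ``habitat_features``, ``dce_features``,
    ``perfusion_features`` and ``clinical`` to wide per-patient feature
    tables, and ``time``/``event`` to outcome arrays.  All models are
    fit on the development cohort only; coefficients, z-score statistics
    and median cutoffs are frozen and applied to the validation cohort.
    Each model row reports the high- vs low-risk hazard ratio, Harrell's
    C, and the bootstrap comparison p-value against the combined model.
    """
    dev_t, dev_e = np.asarray(dev["time"], float), np.asarray(dev["event"], int)
    val_t, val_e = np.asarray(val["time"], float), np.asarray(val["event"], int)

    models: dict[str, CoxLassoModel] = {}
    scores: dict[str, dict[str, np.ndarray]] = {}

    panels = {
        "radiomics_DCE_MR": "dce_features",
        "radiomics_perfusion": "perfusion_features",
        "HRS_only": "habitat_features",
        "clinical": "clinical",
    }
    for name, key in panels.items():
        model, sc_dev, sc_val = _fit_scoring_model(
            dev[key], val[key], dev_t, dev_e, seed
        )
        models[name] = model
        scores[name] = {"development": sc_dev, "validation": sc_val}

    # combined model: clinical covariates plus the HRS itself
    dev_comb = pd.DataFrame(dev["clinical"]).copy()
    val_comb = pd.DataFrame(val["clinical"]).copy()
    dev_comb["habitat_risk_score"] = scores["HRS_only"]["development"]
    val_comb["habitat_risk_score"] = scores["HRS_only"]["validation"]
    model, sc_dev, sc_val = _fit_scoring_model(
        dev_comb, val_comb, dev_t, dev_e, seed
    )
    models["combined_habitat"] = model
    scores["combined_habitat"] = {"development": sc_dev, "validation": sc_val}

    outcomes = {"development": (dev_t, dev_e), "validation": (val_t, val_e)}
    rows = []
    for name in MODEL_NAMES:
        cutoff = models[name].cutoff
        for cohort, (t, e) in outcomes.items():
            sc = scores[name][cohort]
            high = stratify(sc, cutoff)
            if high.all() or (~high).all():
                hr, (lo, hi), p = np.nan, (np.nan, np.nan), np.nan
            else:
                hr, (lo, hi), p = group_hazard_ratio(high, t, e)
            c, c_se = harrell_c_index(sc, t, e)
            if name == "combined_habitat":
                cmp_p = np.nan
            else:
                cmp_p = compare_models(
                    sc, scores["combined_habitat"][cohort], t, e,
                    n_boot=n_boot, seed=seed,
                )
            rows.append(
                {
                    "model": name,
                    "cohort": cohort,
                    "cutoff": cutoff,
                    "hazard_ratio": hr,
                    "hr_ci_low": lo,
                    "hr_ci_high": hi,
                    "hr_p": p,
                    "c_index": c,
                    "c_index_se": c_se,
                    "comparison_p": cmp_p,
                }
            )
    return pd.DataFrame(rows), models
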