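"""Mixed-effects analyses of the memory experiment.

All predictors are z-scored before fitting (the cohort pipeline does
this), so coefficients are per-SD effect sizes.  Logistic mixed models
follow a simplification ladder: the requested random-slope structure is
tried first (statsmodels' Laplace/MAP mixed GLM) and, when it fails to
converge, the model is refit with subject random intercepts only via the
exact Gauss–Hermite ML engine in :mod:`schemagaze.glmm`.  Linear mixed
models use statsmodels ``MixedLM`` (REML, Wald tests with a normal
approximation for the reference distribution, recorded per fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glmm import ConvergenceError, GlmmFit, fit_glm_logit, fit_glmm_logit


@dataclass
class FitResult:
    """Coefficient table plus provenance of a (possibly mixed) model fit."""

    model: str
    method: str
    ladder_level: str
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    pvalues: np.ndarray
    df: np.ndarray | None
    converged: bool
    extra: dict = field(default_factory=dict)

    def __getitem__(self, term: str) -> dict:
        i = self.names.index(term)
        out = {
            "coef": float(self.coef[i]),
            "se": float(self.se[i]),
            "stat": float(self.stat[i]),
            "p": float(self.pvalues[i]),
        }
        if self.df is not None:
            out["df"] = float(self.df[i])
        return out

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "method": self.method,
            "ladder_level": self.ladder_level,
            "converged": self.converged,
            "terms": {name: self[name] for name in self.names},
            **{k: v for k, v in self.extra.items() if np.isscalar(v)},
        }


@dataclass
class MediationResult:
    indirect: float
    ci_low: float
    ci_high: float
    reps: int
    a_path: float
    b_path: float
    scale: str

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)


def _design(df: pd.DataFrame, predictors, include_interaction: bool):
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for p in predictors:
        cols.append(df[p].to_numpy(dtype=float))
        names.append(p)
    if include_interaction and len(predictors) == 2:
        cols.append(cols[1] * cols[2])
        names.append(f"{predictors[0]}:{predictors[1]}")
    return np.column_stack(cols), names


def _from_glmm(fit: GlmmFit, model: str, method: str, level: str) -> FitResult:
    return FitResult(
        model=model,
        method=method,
        ladder_level=level,
        names=fit.names,
        coef=fit.coef,
        se=fit.se,
        stat=fit.zvalues,
        pvalues=fit.pvalues,
        df=None,
        converged=fit.converged,
        extra={"sigma_u": fit.sigma_u, "loglik": fit.loglik, "bic": fit.bic},
    )


def _try_slopes_logit(df, outcome, predictors, include_interaction, slopes):
    """Random-slopes logistic via statsmodels MAP Laplace; None on failure."""
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    rhs = " + ".join(predictors)
    if include_interaction and len(predictors) == 2:
        rhs += f" + {predictors[0]}:{predictors[1]}"
    vc = {"icept": "0 + C(subject)"}
    for j, s in enumerate(slopes):
        vc[f"slope{j}"] = f"0 + C(subject):{s}"
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            m = BinomialBayesMixedGLM.from_formula(f"{outcome} ~ {rhs}", vc, df)
            r = m.fit_map()
        except Exception:
            return None
    bad = any("did not converge" in str(w.message) for w in caught)
    if bad or not getattr(r.optim_retvals, "success", False):
        return None
    names = list(m.exog_names)
    return FitResult(
        model=f"{outcome} ~ {rhs}",
        method="laplace-map",
        ladder_level="slopes:" + ",".join(slopes),
        names=names,
        coef=np.asarray(r.fe_mean),
        se=np.asarray(r.fe_sd),
        stat=np.asarray(r.fe_mean) / np.asarray(r.fe_sd),
        pvalues=2 * sps.norm.sf(np.abs(np.asarray(r.fe_mean) / np.asarray(r.fe_sd))),
        df=None,
        converged=True,
    )


def fit_memory_model(
    df: pd.DataFrame,
    predictors: tuple[str, ...] = ("move_logprob_z", "pred_acc_z"),
    include_interaction: bool = True,
    outcome: str = "correct",
    random_slopes: tuple[str, ...] | None = None,
    drop_flagged: str | None = None,
) -> FitResult:
    """Mixed-effects logistic regression of memory accuracy.

    ``random_slopes`` names the predictors given subject-specific slopes
    at the top of the simplification ladder (defaults to all of
    ``predictors``); the ladder then falls back to random intercepts
    only, and the level actually fit is recorded on the result.
    """
    if drop_flagged is not None:
        df = df.loc[~df[drop_flagged].astype(bool)]
    df = df.dropna(subset=[outcome, *predictors])
    slopes = predictors if random_slopes is None else random_slopes
    if slopes:
        res = _try_slopes_logit(df, outcome, predictors, include_interaction, slopes)
        if res is not None:
            return res
    X, names = _design(df, predictors, include_interaction)
    fit = fit_glmm_logit(df[outcome].to_numpy(), X, df["subject"].to_numpy(), names)
    if not fit.converged:
        raise ConvergenceError("no ladder level converged")
    rhs = " + ".join(names[1:])
    return _from_glmm(fit, f"{outcome} ~ {rhs}", "gauss-hermite-ml", "intercept")


def fit_quadratic_model(
    df: pd.DataFrame,
    predictors: tuple[str, ...] = ("move_logprob_z", "pred_acc_z"),
    outcome: str = "correct",
) -> FitResult:
    """Memory model with linear and quadratic terms, random intercept only."""
    work = df.dropna(subset=[outcome, *predictors]).copy()
    quad = []
    for p in predictors:
        q = f"{p}_sq"
        work[q] = work[p] ** 2
        quad.append(q)
    X, names = _design(work, tuple(predictors) + tuple(quad), False)
    fit = fit_glmm_logit(work[outcome].to_numpy(), X, work["subject"].to_numpy(), names)
    if not fit.converged:
        raise ConvergenceError("quadratic model did not converge")
    return _from_glmm(fit, f"{outcome} ~ linear + quadratic", "gauss-hermite-ml",
                      "intercept")


def fit_linear_outcome(
    df: pd.DataFrame,
    outcome: str,
    predictors: tuple[str, ...],
    include_interaction: bool = False,
    random_slope: str | None = None,
    drop_flagged: str | None = None,
) -> FitResult:
    """Linear mixed model (random subject intercept, optional one slope)."""
    import statsmodels.api as sm

    if drop_flagged is not None:
        df = df.loc[~df[drop_flagged].astype(bool)]
    df = df.dropna(subset=[outcome, *predictors])
    X, names = _design(df, predictors, include_interaction)
    re_formula = f"~{random_slope}" if random_slope else "~1"
    exog_re = None
    if random_slope is not None:
        exog_re = np.column_stack([np.ones(len(df)), df[random_slope].to_numpy()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            df[outcome].to_numpy(), X,
            groups=df["subject"].to_numpy(), exog_re=exog_re,
        )
        res = model.fit(reml=True)
    k = len(names)
    coef = np.asarray(res.params[:k])
    se = np.asarray(res.bse[:k])
    tval = coef / se
    # residual-df normal approximation (Satterthwaite is unavailable here)
    dof = float(len(df) - k)
    pvals = 2 * sps.t.sf(np.abs(tval), dof)
    level = "intercept" if random_slope is None else f"slope:{random_slope}"
    return FitResult(
        model=f"{outcome} ~ " + " + ".join(names[1:]),
        method="mixedlm-reml (normal-approx df)",
        ladder_level=level,
        names=names,
        coef=coef,
        se=se,
        stat=tval,
        pvalues=pvals,
        df=np.full(k, dof),
        converged=bool(res.converged),
        extra={"loglik": float(res.llf)},
    )


def analyze_selected_move(
    df: pd.DataFrame,
    w_col: str = "w_moveProb_z",
    outcome: str = "selected_logprob_z",
    min_trials: int = 50,
) -> tuple[FitResult, FitResult]:
    """Selected-move probability ~ schema index, split by correctness.

    Returns (correct-trials fit, incorrect-trials fit); a positive slope
    on incorrect trials marks schema-guided guessing.
    """
    out = []
    for flag in (1, 0):
        sub = df.loc[df["correct"] == flag].dropna(subset=[w_col, outcome])
        if len(sub) < min_trials:
            raise ValueError(
                f"only {len(sub)} {'correct' if flag else 'incorrect'} trials"
            )
        out.append(fit_linear_outcome(sub, outcome, (w_col,)))
    return out[0], out[1]


def mediate(
    df: pd.DataFrame,
    treatment: str = "pred_acc_z",
    mediator: str = "w_moveProb_z",
    outcome: str = "correct",
    reps: int = 500,
    seed: int | np.random.Generator = 0,
    scale: str = "logit",
    outcome_family: str = "logit",
    max_fail: float = 0.1,
) -> MediationResult:
    """Product-of-paths mediation with a cluster (by-subject) bootstrap.

    a: OLS of mediator on treatment; b: logistic (or OLS, for a
    continuous outcome with ``outcome_family="linear"``) of outcome on
    treatment + mediator.  The indirect effect a*b is reported on the
    outcome model's linear-predictor (logit) scale by default;
    ``scale="probability"`` instead averages the implied change in
    P(outcome) over the sample.  Bootstrap replicates resample subjects
    with replacement and pool their trials; the CI is the 2.5th/97.5th
    percentile.
    """
    if reps < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    work = df.dropna(subset=[treatment, mediator]).reset_index(drop=True)
    subjects = work["subject"].unique()
    by_subj = {s: g.index.to_numpy() for s, g in work.groupby("subject")}

    t_all = work[treatment].to_numpy()
    m_all = work[mediator].to_numpy()
    y_all = work[outcome].to_numpy(dtype=float)

    def paths(idx):
        t, m, y = t_all[idx], m_all[idx], y_all[idx]
        Xa = np.column_stack([np.ones(len(t)), t])
        a = np.linalg.lstsq(Xa, m, rcond=None)[0][1]
        Xb = np.column_stack([np.ones(len(t)), t, m])
        if outcome_family == "linear":
            bcoef = np.linalg.lstsq(Xb, y, rcond=None)[0]
            return float(a * bcoef[2]), float(a), float(bcoef[2])
        fit = fit_glm_logit(y, Xb, ["Intercept", treatment, mediator])
        if not fit.converged:
            raise ConvergenceError("outcome model failed")
        b = fit.coef[2]
        if scale == "probability":
            from scipy.special import expit

            eta = Xb @ fit.coef
            ind = float(np.mean(expit(eta + a * b) - expit(eta)))
        else:
            ind = float(a * b)
        return ind, float(a), float(b)

    full_idx = np.arange(len(work))
    point, a0, b0 = paths(full_idx)
    draws, failures = [], 0
    for _ in range(reps):
        pick = rng.choice(subjects, size=len(subjects), replace=True)
        idx = np.concatenate([by_subj[s] for s in pick])
        try:
            draws.append(paths(idx)[0])
        except (ConvergenceError, np.linalg.LinAlgError):
            failures += 1
    if failures > max_fail * reps:
        raise ConvergenceError(f"{failures}/{reps} bootstrap replicates failed")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return MediationResult(point, float(lo), float(hi), len(draws), a0, b0, scale)


def bayes_factor_fixation(
    df: pd.DataFrame,
    duration_col: str = "fix_move_ms_z",
    outcome: str = "correct",
) -> tuple[float, FitResult]:
    """BF10 for post-move fixation duration predicting memory.

    Compares the random-intercept logistic model with the duration
    regressor against the intercept-only null via the BIC approximation
    BF10 = exp((BIC0 - BIC1) / 2).  Values below 1/3 favor the null.
    """
    work = df.dropna(subset=[duration_col])
    y = work[outcome].to_numpy()
    g = work["subject"].to_numpy()
    X1 = np.column_stack([np.ones(len(work)), work[duration_col].to_numpy()])
    f1 = fit_glmm_logit(y, X1, g, ["Intercept", duration_col])
    f0 = fit_glmm_logit(y, np.ones((len(work), 1)), g, ["Intercept"])
    if not (f1.converged and f0.converged):
        raise ConvergenceError("fixation-duration comparison did not converge")
    bf10 = float(np.exp((f0.bic - f1.bic) / 2.0))
    return bf10, _from_glmm(f1, f"{outcome} ~ {duration_col}", "gauss-hermite-ml",
                            "intercept")


def manipulation_check(
    square_df: pd.DataFrame,
    fix_col: str = "fix_share",
    prob_col: str = "model_prob",
    per_trial: bool = False,
) -> dict:
    """Coupling between predictive fixations and move probability.

    ``square_df`` has one row per (trial, empty square) with the trial's
    normalized fixation share and model move probability.  Per subject,
    a Pearson correlation is computed pooled over that subject's trials
    and squares (or per trial then averaged with ``per_trial=True``);
    a one-sample t-test asks whether the subject-level correlations
    exceed zero.  Subjects with degenerate variance are excluded+flagged.
    """
    rs, excluded = [], []
    for subj, g in square_df.groupby("subject"):
        if per_trial:
            trial_rs = []
            for _, tg in g.groupby(["block", "trial"]):
                x, y = tg[fix_col].to_numpy(), tg[prob_col].to_numpy()
                if x.std() > 0 and y.std() > 0:
                    trial_rs.append(sps.pearsonr(x, y)[0])
            r = float(np.mean(trial_rs)) if trial_rs else np.nan
        else:
            x, y = g[fix_col].to_numpy(), g[prob_col].to_numpy()
            r = sps.pearsonr(x, y)[0] if x.std() > 0 and y.std() > 0 else np.nan
        if np.isnan(r):
            excluded.append(subj)
        else:
            rs.append(r)
    rs = np.array(rs)
    if len(rs) < 2:
        raise ValueError("need at least 2 subjects with usable variance")
    t, p = sps.ttest_1samp(rs, 0.0)
    return {
        "mean_r": float(rs.mean()),
        "sd_r": float(rs.std(ddof=1)),
        "t": float(t),
        "p": float(p),
        "df": len(rs) - 1,
        "cohens_d": float(rs.mean() / rs.std(ddof=1)),
        "n_subjects": len(rs),
        "excluded_subjects": excluded,
        "per_subject_r": rs,
    }


def chance_baselines(trials: pd.DataFrame) -> dict:
    """Guessing baselines for memory accuracy.

    random_guess_acc: expected accuracy of a uniform guess over the empty
    squares, averaged over trials.  model_guess_acc: expected accuracy of
    probability-matched guessing from the gameplay model, i.e. the mean
    model probability of the correct move.
    """
    return {
        "random_guess_acc": float((1.0 / trials["n_empty"]).mean()),
        "model_guess_acc": float(trials["model_prob_correct"].mean()),
    }
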