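"""Group-level inference on fitted parameters.

Two arms, mirroring how hierarchical effects are usually reported for this
task:

* :func:`peb_fit` — a precision-weighted Bayesian GLM ("PEB-lite"): each
  subject-session contributes its posterior mean with its posterior
  variance as known observation noise, a between-subject variance and a
  subject random-intercept variance are estimated by marginal maximum
  likelihood (EM-style), and Bayesian model reduction scores every on/off
  combination of the effects of interest (group, session, their
  interaction) in closed form, giving inclusion probabilities and
  model-averaged effect posteriors.  Covariates (age, sex, premorbid IQ)
  are always included.
* :func:`lme_fit` — the frequentist check: a linear mixed model with a
  subject random intercept and the same predictors, reporting F, p, and
  partial eta squared per effect.

All parameter values are analysed in estimation space (log/logit).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import f as f_dist

logger = logging.getLogger(__name__)

__all__ = ["GroupDesign", "GroupResult", "build_group_design", "peb_fit", "lme_fit"]

EFFECTS_OF_INTEREST = ("group", "session", "group_x_session")
COVARIATE_COLUMNS = ("age", "sex_male", "wrat")


@dataclass
class GroupDesign:
    """Stacked subject-session design for one parameter.

    ``y`` holds estimation-space posterior means, ``var_y`` the matching
    subject-level posterior variances, ``X`` the predictor matrix with
    ``columns`` naming its columns (intercept, group SUD=1, session
    followup=1, group x session, then mean-centred covariates), and
    ``subject`` integer codes for the within-subject structure.
    """

    y: np.ndarray
    var_y: np.ndarray
    X: np.ndarray
    columns: tuple
    subject: np.ndarray
    parameter: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (len(self.var_y) == n and self.X.shape[0] == n and len(self.subject) == n):
            raise ValueError("design arrays must share their first dimension")
        counts = np.bincount(self.subject)
        if counts.max() > 2:
            raise ValueError("at most two rows (sessions) per subject")


@dataclass
class GroupResult:
    """Per-effect summaries from a group-level fit."""

    parameter: str
    method: str
    effects: dict  # name -> {"b", "ci_low", "ci_high", ...}
    meta: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"effect": k, **v} for k, v in self.effects.items()])


def build_group_design(
    posteriors: pd.DataFrame, clinical: pd.DataFrame, parameter: str
) -> GroupDesign:
    """Assemble a GroupDesign from a tidy posteriors frame and a clinical
    table (columns group, age, sex_male, wrat).

    Rows with missing covariates are excluded with a logged count, never
    silently dropped.
    """
    need = [f"mean_{parameter}", f"cov_{parameter}_{parameter}"]
    for c in need:
        if c not in posteriors.columns:
            raise ValueError(f"posteriors frame lacks {c}")
    merged = posteriors.merge(clinical, on="subject_id", how="inner", validate="many_to_one")
    complete = merged[list(COVARIATE_COLUMNS) + ["group"]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("build_group_design: dropped %d row(s) with missing covariates", n_dropped)
    merged = merged.loc[complete].reset_index(drop=True)

    group = (merged["group"] == "sud").astype(float).to_numpy()
    session = (merged["session"] == "followup").astype(float).to_numpy()
    age = merged["age"].to_numpy(dtype=float)
    wrat = merged["wrat"].to_numpy(dtype=float)
    sex = merged["sex_male"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(merged)),
            group,
            session,
            group * session,
            age - age.mean(),
            sex,
            wrat - wrat.mean(),
        ]
    )
    columns = ("intercept", "group", "session", "group_x_session", "age", "sex_male", "wrat")
    subject = pd.factorize(merged["subject_id"])[0]
    return GroupDesign(
        y=merged[f"mean_{parameter}"].to_numpy(dtype=float),
        var_y=merged[f"cov_{parameter}_{parameter}"].to_numpy(dtype=float),
        X=X,
        columns=columns,
        subject=subject,
        parameter=parameter,
        n_dropped=n_dropped,
    )


def _check_rank(X: np.ndarray, columns) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(columns[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _marginal_cov(design: GroupDesign, sigma2_e: float, sigma2_b: float) -> np.ndarray:
    n = len(design.y)
    Z = np.zeros((n, design.subject.max() + 1))
    Z[np.arange(n), design.subject] = 1.0
    return np.diag(design.var_y + sigma2_e) + sigma2_b * (Z @ Z.T)


def _gaussian_logpdf(y: np.ndarray, cov: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return -np.inf
    alpha = np.linalg.solve(cov, y)
    return float(-0.5 * (len(y) * np.log(2 * np.pi) + logdet + y @ alpha))


def peb_fit(
    design: GroupDesign,
    effects_of_interest: tuple = EFFECTS_OF_INTEREST,
    prior_var_effect: float = 1.0,
    prior_var_intercept: float = 10.0,
    ci_level: float = 0.90,
    min_subjects: int = 10,
    fix_variances: tuple | None = None,
) -> GroupResult:
    """Precision-weighted Bayesian GLM with Bayesian model reduction.

    The observation covariance is ``diag(var_y + sigma2_e) + sigma2_b ZZ'``
    with both variance components estimated by marginal maximum likelihood
    (betas integrated out under their Gaussian prior).  Every on/off
    combination of the effects of interest is scored by its exact Gaussian
    log evidence (an excluded effect's prior variance collapses to ~0);
    effect posteriors are model-averaged and summarised with credible
    intervals, and each effect's inclusion probability is the total
    posterior mass of models containing it.
    """
    if design.subject.max() + 1 < min_subjects:
        raise ValueError(f"peb_fit requires >= {min_subjects} subjects")
    _check_rank(design.X, design.columns)
    X, y = design.X, design.y
    p = X.shape[1]
    interest_idx = [design.columns.index(e) for e in effects_of_interest]

    prior_var_full = np.full(p, prior_var_effect)
    prior_var_full[design.columns.index("intercept")] = prior_var_intercept

    if fix_variances is not None:
        sigma2_e, sigma2_b = fix_variances
    else:

        def neg_marginal_ll(log_s):
            s_e, s_b = np.exp(log_s)
            cov = _marginal_cov(design, s_e, s_b) + X @ np.diag(prior_var_full) @ X.T
            return -_gaussian_logpdf(y, cov)

        opt = minimize(neg_marginal_ll, np.log([0.05, 0.05]), method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
        sigma2_e, sigma2_b = np.exp(opt.x)
    Sigma = _marginal_cov(design, sigma2_e, sigma2_b)
    Sigma_inv = np.linalg.inv(Sigma)

    # Bayesian model reduction over on/off combinations of the effects
    models = []
    for mask in itertools.product([True, False], repeat=len(interest_idx)):
        pv = prior_var_full.copy()
        for on, j in zip(mask, interest_idx):
            if not on:
                pv[j] = 1e-8
        ev = _gaussian_logpdf(y, Sigma + X @ np.diag(pv) @ X.T)
        V0_inv = np.diag(1.0 / pv)
        S = np.linalg.inv(X.T @ Sigma_inv @ X + V0_inv)
        m = S @ (X.T @ Sigma_inv @ y)
        models.append({"mask": mask, "evidence": ev, "mean": m, "cov": S})

    evidences = np.array([m["evidence"] for m in models])
    post = np.exp(evidences - evidences.max())
    post /= post.sum()
    winner = models[int(np.argmax(post))]
    full = models[0]  # first mask is all-True by construction

    bma_mean = sum(w * m["mean"] for w, m in zip(post, models))
    bma_second = sum(w * (np.diag(m["cov"]) + m["mean"] ** 2) for w, m in zip(post, models))
    bma_var = np.maximum(bma_second - bma_mean**2, 0.0)
    from scipy.stats import norm

    zcrit = norm.ppf(0.5 + ci_level / 2.0)

    effects = {}
    for j, name in enumerate(design.columns):
        row = {
            "b": float(bma_mean[j]),
            "ci_low": float(bma_mean[j] - zcrit * np.sqrt(bma_var[j])),
            "ci_high": float(bma_mean[j] + zcrit * np.sqrt(bma_var[j])),
        }
        if name in effects_of_interest:
            k = effects_of_interest.index(name)
            row["inclusion_prob"] = float(
                sum(w for w, m in zip(post, models) if m["mask"][k])
            )
            row["in_winning_model"] = bool(winner["mask"][k])
            # effect posterior conditional on inclusion (unshrunk by the
            # posterior mass of models that exclude it)
            w_in = np.array([w if m["mask"][k] else 0.0 for w, m in zip(post, models)])
            if w_in.sum() > 0:
                w_in = w_in / w_in.sum()
                m1 = float(sum(w * m["mean"][j] for w, m in zip(w_in, models)))
                m2 = float(sum(w * (m["cov"][j, j] + m["mean"][j] ** 2) for w, m in zip(w_in, models)))
                sd_c = np.sqrt(max(m2 - m1**2, 0.0))
                row["b_conditional"] = m1
                row["ci_low_conditional"] = float(m1 - zcrit * sd_c)
                row["ci_high_conditional"] = float(m1 + zcrit * sd_c)
        effects[name] = row

    return GroupResult(
        parameter=design.parameter,
        method="PEB-lite",
        effects=effects,
        meta={
            "sigma2_between_subject": float(sigma2_b),
            "sigma2_residual": float(sigma2_e),
            "winning_model": tuple(
                e for e, on in zip(effects_of_interest, winner["mask"]) if on
            ),
            "model_posteriors": post.tolist(),
            "full_model_mean": full["mean"].tolist(),
            "full_model_sd": np.sqrt(np.diag(full["cov"])).tolist(),
            "prior_var_effect": prior_var_effect,
            "n_dropped_missing": design.n_dropped,
        },
    )


def lme_fit(design: GroupDesign, min_subjects: int = 10) -> GroupResult:
    """Frequentist arm: linear mixed model with a subject random intercept.

    Reports per effect the Wald F (1 numerator df), p-value, and partial
    eta squared with denominator df approximated as rows minus fixed
    effects.  A singular random-effects fit falls back to OLS with a flag.
    """
    if design.subject.max() + 1 < min_subjects:
        raise ValueError(f"lme_fit requires >= {min_subjects} subjects")
    _check_rank(design.X, design.columns)
    import statsmodels.api as sm
    import warnings

    singular = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.MixedLM(design.y, design.X, groups=design.subject)
            res = mod.fit(reml=True, method="lbfgs")
        params = res.fe_params
        bse = res.bse_fe
        if not np.all(np.isfinite(bse)):
            raise np.linalg.LinAlgError("non-finite standard errors")
    except Exception:
        singular = True
        ols = sm.OLS(design.y, design.X).fit()
        params, bse = ols.params, ols.bse

    df2 = len(design.y) - design.X.shape[1]
    effects = {}
    for j, name in enumerate(design.columns):
        fval = float((params[j] / bse[j]) ** 2)
        pval = float(f_dist.sf(fval, 1, df2))
        effects[name] = {
            "b": float(params[j]),
            "F": fval,
            "p": pval,
            "eta2": float(fval / (fval + df2)),
        }
    return GroupResult(
        parameter=design.parameter,
        method="LME" + (" (OLS fallback)" if singular else ""),
        effects=effects,
        meta={"singular": singular, "df2": df2, "n_dropped_missing": design.n_dropped},
    )
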