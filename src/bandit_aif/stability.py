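"""Longitudinal stability and prediction statistics.

Covers the model-free and reliability side of the analysis: ICC(3,1)
test-retest consistency, Jeffreys-Zellner-Siow Bayes factors for
correlations, iterative Grubbs reaction-time trimming, win/lose stay/shift
counts with an early/late trial split, covariate-adjusted predictive
correlations, and pre-post change-score correlations with the
baseline-floor exclusion rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import betaln, gammaln, hyp2f1

from .task import N_TRIALS

logger = logging.getLogger(__name__)

__all__ = [
    "icc31",
    "jzs_bf_correlation",
    "grubbs_trim",
    "stay_shift_counts",
    "StayShiftSummary",
    "predictive_correlation",
    "change_score_analysis",
    "reliability_report",
    "BONFERRONI_THRESHOLDS",
]

#: The two multiple-comparison cutoffs used for prediction analyses:
#: .05/6 (one test per subsample) and .05/30 (five parameters x six samples).
BONFERRONI_THRESHOLDS = (0.05 / 6.0, 0.05 / 30.0)


# ---------------------------------------------------------------------------
# ICC(3, 1)


def icc31(baseline: np.ndarray, followup: np.ndarray) -> tuple:
    """Two-way mixed, consistency, single-measures intraclass correlation.

    ``ICC(3,1) = (MS_rows - MS_error) / (MS_rows + (k-1) * MS_error)`` with
    ``k = 2`` sessions; the p-value is from the one-sided F test
    ``F = MS_rows / MS_error`` with ``(n-1, n-1)`` degrees of freedom.
    Consistency ICCs ignore a fixed session shift by design.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(followup, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("baseline and followup must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("ICC requires at least 3 paired observations")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows + (k - 1) * ms_err <= 0 or ss_rows == 0:
        raise ValueError("ICC undefined: no between-subject variance")
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    if ms_err == 0:
        return float(icc), 0.0
    f = ms_rows / ms_err
    p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def reliability_report(
    table: pd.DataFrame,
    measures: list,
    group_col: str = "group",
    subject_col: str = "subject_id",
    session_col: str = "session",
) -> pd.DataFrame:
    """ICC(3,1) per measure, per group and pooled.

    ``table`` is long-form with one row per subject-session; only subjects
    present in both sessions enter.  Returns rows (measure, group, icc31,
    p, n) with group 'all' for the pooled estimate.
    """
    wide = table.pivot_table(
        index=[subject_col, group_col], columns=session_col, values=measures, aggfunc="first"
    )
    rows = []
    groups = ["all"] + sorted(table[group_col].unique().tolist())
    for measure in measures:
        sub = wide[measure].dropna()
        for g in groups:
            block = sub if g == "all" else sub.loc[sub.index.get_level_values(group_col) == g]
            icc, p = icc31(block["baseline"].to_numpy(), block["followup"].to_numpy())
            rows.append({"measure": measure, "group": g, "icc31": icc, "p": p, "n": len(block)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# JZS Bayes factor for a correlation


def _log_r_density(r: float, rho: float, n: int) -> float:
    """Log sampling density of the Pearson correlation ``r`` given the
    population correlation ``rho`` at sample size ``n``."""
    return (
        np.log(n - 2)
        + gammaln(n - 1)
        - 0.5 * np.log(2 * np.pi)
        - gammaln(n - 0.5)
        + 0.5 * (n - 1) * np.log1p(-(rho**2))
        + 0.5 * (n - 4) * np.log1p(-(r**2))
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(hyp2f1(0.5, 0.5, n - 0.5, 0.5 * (rho * r + 1.0)))
    )


def jzs_bf_correlation(x: np.ndarray, y: np.ndarray, rscale: float = 1.0 / 3.0) -> float:
    """Bayes factor BF10 for a nonzero correlation under the default
    stretched-beta prior.

    The population correlation has prior ``(rho + 1) / 2 ~
    Beta(1/rscale, 1/rscale)``; the marginal likelihood ratio is computed by
    adaptive numerical integration of the sampling density of the observed
    correlation over rho in (-1, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise ValueError("JZS correlation BF requires n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return bf10_from_r(r, n, rscale=rscale)


def bf10_from_r(r: float, n: int, rscale: float = 1.0 / 3.0) -> float:
    """BF10 from a precomputed Pearson ``r`` and sample size ``n``."""
    a = 1.0 / rscale
    log_null = _log_r_density(r, 0.0, n)

    def integrand(rho):
        log_prior = (
            (a - 1) * (np.log1p(rho) + np.log1p(-rho)) - betaln(a, a) - (2 * a - 1) * np.log(2.0)
        )
        return np.exp(_log_r_density(r, rho, n) + log_prior - log_null)

    val, _ = integrate.quad(integrand, -1.0, 1.0, limit=200)
    return float(val)


# ---------------------------------------------------------------------------
# Grubbs trimming


def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value at significance ``alpha``."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_trim(rts: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """Iterative two-sided Grubbs outlier removal.

    Repeatedly tests the single most extreme value at significance
    ``alpha`` and removes it until the remaining distribution contains no
    outlier; the order of the surviving values is preserved.
    """
    x = np.asarray(rts, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("grubbs_trim requires a vector of length >= 3")
    keep = np.ones(len(x), dtype=bool)
    while keep.sum() >= 3:
        vals = x[keep]
        s = vals.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(vals - vals.mean())
        g = dev.max() / s
        if g <= _grubbs_critical(len(vals), alpha):
            break
        worst_local = int(np.argmax(dev))
        keep[np.flatnonzero(keep)[worst_local]] = False
    return x[keep]


# ---------------------------------------------------------------------------
# Stay/shift counts


@dataclass
class StayShiftSummary:
    """Win/lose x stay/shift transition counts for one subject-session.

    A transition at trial t (t >= 2 within a game) is a *stay* when the
    choice repeats trial t-1, classified by the outcome at t-1.  The early
    phase covers transitions at trials 2-8 (7 per game), the late phase
    trials 9-16 (8 per game), so every transition is classified.
    """

    subject_id: str
    session: str
    win_stay: int
    win_shift: int
    lose_stay: int
    lose_shift: int
    early: dict
    late: dict
    n_complete_games: int
    trimmed_mean_rt: float

    @property
    def total(self) -> int:
        return self.win_stay + self.win_shift + self.lose_stay + self.lose_shift


def stay_shift_counts(behavior: pd.DataFrame, rt_alpha: float = 0.01) -> list:
    """Stay/shift summaries for every subject-session in a behavior table.

    Incomplete games (fewer than 16 trials) are excluded with a logged
    count.  The trimmed mean RT applies iterative Grubbs trimming to the
    session's RT distribution before averaging.
    """
    out = []
    n_dropped = 0
    for (sid, ses), block in behavior.groupby(["subject_id", "session"], sort=False):
        counts = {"win_stay": 0, "win_shift": 0, "lose_stay": 0, "lose_shift": 0}
        early = dict(counts)
        late = dict(counts)
        n_games = 0
        for _, game in block.groupby("game", sort=True):
            if len(game) != N_TRIALS:
                n_dropped += 1
                continue
            n_games += 1
            game = game.sort_values("trial")
            choice = game["choice"].to_numpy()
            outcome = game["outcome"].to_numpy()
            trial = game["trial"].to_numpy()
            for t in range(1, N_TRIALS):
                stay = choice[t] == choice[t - 1]
                won = outcome[t - 1] == "win"
                key = ("win_" if won else "lose_") + ("stay" if stay else "shift")
                counts[key] += 1
                phase = early if trial[t] <= 8 else late
                phase[key] += 1
        rts = block["rt"].dropna().to_numpy()
        trimmed = grubbs_trim(rts, alpha=rt_alpha) if len(rts) >= 3 else rts
        out.append(
            StayShiftSummary(
                subject_id=str(sid),
                session=str(ses),
                **counts,
                early=early,
                late=late,
                n_complete_games=n_games,
                trimmed_mean_rt=float(np.mean(trimmed)) if len(trimmed) else np.nan,
            )
        )
    if n_dropped:
        logger.warning("stay_shift_counts: excluded %d incomplete game(s)", n_dropped)
    return out


def stay_shift_frame(summaries: list) -> pd.DataFrame:
    """Tidy DataFrame over StayShiftSummary records (one row per session)."""
    rows = []
    for s in summaries:
        row = {
            "subject_id": s.subject_id,
            "session": s.session,
            "win_stay": s.win_stay,
            "win_shift": s.win_shift,
            "lose_stay": s.lose_stay,
            "lose_shift": s.lose_shift,
            "trimmed_mean_rt": s.trimmed_mean_rt,
        }
        for phase_name, phase in (("early", s.early), ("late", s.late)):
            for k, v in phase.items():
                row[f"{phase_name}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Predictive and change-score correlations


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of y regressed on covariates (with intercept)."""
    X = np.column_stack([np.ones(len(y)), covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _report_row(x, y, raw_r=None, rscale=1.0 / 3.0):
    r, p = stats.pearsonr(x, y)
    bf = bf10_from_r(float(r), len(x), rscale=rscale)
    row = {
        "r": float(r),
        "p": float(p),
        "bf10": float(bf),
        "n": len(x),
        "sig_bonferroni_6": bool(p < BONFERRONI_THRESHOLDS[0]),
        "sig_bonferroni_30": bool(p < BONFERRONI_THRESHOLDS[1]),
    }
    if raw_r is not None:
        row["raw_r"] = float(raw_r)
    return row


def predictive_correlation(
    baseline_param: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    rscale: float = 1.0 / 3.0,
    partial_both: bool = False,
) -> dict:
    """Correlation between a baseline parameter and a follow-up outcome.

    With covariates, the outcome is residualized on them first (the
    canonical "after accounting for" adjustment); ``partial_both=True``
    residualizes both sides instead, giving the classical partial
    correlation.  Attaches p, JZS BF10, and Bonferroni flags at the two
    printed thresholds.
    """
    x = np.asarray(baseline_param, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors required")
    if len(x) < 5:
        raise ValueError("predictive correlation requires n >= 5")
    if np.std(y) == 0 or np.std(x) == 0:
        raise ValueError("constant input: correlation undefined")
    raw_r = float(stats.pearsonr(x, y)[0])
    if covariates is None:
        return _report_row(x, y, raw_r=raw_r, rscale=rscale)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != len(x):
        C = C.T
    y_adj = _residualize(y, C)
    x_adj = _residualize(x, C) if partial_both else x
    if np.std(y_adj) == 0:
        raise ValueError("outcome fully explained by covariates")
    return _report_row(x_adj, y_adj, raw_r=raw_r, rscale=rscale)


def change_score_analysis(
    params_pre: np.ndarray,
    params_post: np.ndarray,
    dast_pre: np.ndarray,
    dast_post: np.ndarray,
    covariates: np.ndarray | None = None,
    rscale: float = 1.0 / 3.0,
) -> dict:
    """Correlation between pre-post parameter change and pre-post DAST change.

    Subjects at the symptom floor at baseline (DAST = 0) cannot show a
    measurable decrease and are excluded before analysis, with the excluded
    count logged and returned (``n_floor_excluded``).
    """
    arrays = [np.asarray(a, dtype=float) for a in (params_pre, params_post, dast_pre, dast_post)]
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("all vectors must be the same length")
    keep = arrays[2] > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("change_score_analysis: excluded %d floor-DAST subject(s)", n_excluded)
    pre, post, d_pre, d_post = (a[keep] for a in arrays)
    d_param = post - pre
    d_dast = d_post - d_pre
    if len(d_param) < 5:
        raise ValueError("too few subjects after floor exclusion")
    if np.std(d_dast) == 0:
        raise ValueError("DAST change is constant: correlation undefined")
    cov = None
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(keep):
            C = C.T
        cov = C[keep]
    row = predictive_correlation(d_param, d_dast, covariates=cov, rscale=rscale)
    row["n_floor_excluded"] = n_excluded
    return row
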