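"""Per-subject parameter estimation: MAP + Laplace (variational-Laplace style).

Parameters are estimated in an unconstrained space (log for action
precision, reward sensitivity and the initial concentration ``a_0``; logit
for learning rates) under Gaussian priors, by quasi-Newton maximisation of
the log joint from multiple starts.  The posterior is the Laplace Gaussian
at the optimum and the model evidence is the Laplace free-energy bound

    F = log p(y, theta_MAP) + 0.5 * log det(2 * pi * Sigma).

The trial likelihood exploits the structure of the learning rule: because
beliefs reset each game and each observed (win/loss, arm) event adds exactly
one learning-rate increment, the whole 320-trial concentration trajectory is
an affine function of (a_0, eta_win, eta_loss) given the data, so the
likelihood is evaluated with batched array operations rather than a trial
loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .model import AgentParams, build_preferences
from .task import N_GAMES, N_TRIALS

logger = logging.getLogger(__name__)

__all__ = [
    "PARAM_NAMES",
    "ModelSpec",
    "SubjectPosterior",
    "to_estimation_space",
    "to_native_space",
    "log_likelihood",
    "fit_subject",
    "accuracy_metrics",
    "prepare_session",
]

#: Canonical parameter order for the full model.
PARAM_NAMES = ("alpha", "c_r", "eta_win", "eta_loss", "a_0")

#: Native-space prior means used during estimation.
PRIOR_MEANS_NATIVE = {"alpha": 4.0, "c_r": 4.0, "eta": 0.5, "eta_win": 0.5, "eta_loss": 0.5, "a_0": 0.25}
#: Defaults for parameters not estimated by a given nested model.  A model
#: without a learning-rate parameter reverts to the standard Bayesian count
#: update (increment 1 per observation) rather than freezing beliefs, which
#: would collapse it onto the chance model.
DEFAULTS_NATIVE = {"alpha": 4.0, "a_0": 0.25, "eta": 1.0}
#: Prior variance (estimation space), deliberately precise to deter over-fitting.
PRIOR_VARIANCE = 2.0 ** -2

_LOG_PARAMS = {"alpha", "c_r", "a_0"}
_LOGIT_PARAMS = {"eta", "eta_win", "eta_loss"}


def to_estimation_space(name: str, value):
    """Map a native parameter value to its unconstrained estimation space."""
    if name in _LOG_PARAMS:
        return np.log(value)
    if name in _LOGIT_PARAMS:
        return logit(value)
    raise KeyError(name)


def to_native_space(name: str, value):
    """Inverse of :func:`to_estimation_space`."""
    if name in _LOG_PARAMS:
        return np.exp(value)
    if name in _LOGIT_PARAMS:
        return expit(value)
    raise KeyError(name)


@dataclass(frozen=True)
class ModelSpec:
    """One nested model: which parameters are free, and shared defaults.

    ``estimated`` lists free parameters by name; ``"eta"`` denotes a single
    learning rate shared by wins and losses, while ``"eta_win"``/``"eta_loss"``
    appear together in the split-rate models.  A model with no learning-rate
    entry updates beliefs with the standard unit count increment (eta = 1).
    """

    model_id: int
    estimated: tuple

    def __post_init__(self) -> None:
        if "eta" in self.estimated and ("eta_win" in self.estimated or "eta_loss" in self.estimated):
            raise ValueError("shared and split learning rates are mutually exclusive")
        if "c_r" not in self.estimated:
            raise ValueError("reward sensitivity is always estimated")

    @property
    def n_free(self) -> int:
        return len(self.estimated)

    @property
    def estimates_learning_rate(self) -> bool:
        return any(e in self.estimated for e in ("eta", "eta_win", "eta_loss"))

    def prior_mean(self) -> np.ndarray:
        """Prior mean vector in estimation space."""
        return np.array(
            [to_estimation_space(n, PRIOR_MEANS_NATIVE[n]) for n in self.estimated]
        )

    def prior_cov(self) -> np.ndarray:
        return np.eye(self.n_free) * PRIOR_VARIANCE

    def to_native(self, z: np.ndarray) -> dict:
        """Full native parameter dict from an estimation-space free vector."""
        free = {n: to_native_space(n, v) for n, v in zip(self.estimated, z)}
        if "eta" in free:
            eta_w = eta_l = free["eta"]
        else:
            eta_w = free.get("eta_win", DEFAULTS_NATIVE["eta"])
            eta_l = free.get("eta_loss", DEFAULTS_NATIVE["eta"])
        return {
            "alpha": free.get("alpha", DEFAULTS_NATIVE["alpha"]),
            "c_r": free["c_r"],
            "eta_win": eta_w,
            "eta_loss": eta_l,
            "a_0": free.get("a_0", DEFAULTS_NATIVE["a_0"]),
        }

    def from_params(self, params: AgentParams) -> np.ndarray:
        """Estimation-space free vector for a full parameter set."""
        native = {
            "alpha": params.action_precision,
            "c_r": params.reward_sensitivity,
            "eta": params.learning_rate_win,
            "eta_win": params.learning_rate_win,
            "eta_loss": params.learning_rate_loss,
            "a_0": params.info_insensitivity,
        }
        return np.array([to_estimation_space(n, native[n]) for n in self.estimated])


@dataclass
class SubjectPosterior:
    """Laplace posterior for one subject-session under one nested model."""

    subject_id: str
    session: str
    model_id: int
    param_names: tuple
    posterior_mean: np.ndarray  # estimation space
    posterior_cov: np.ndarray
    free_energy: float
    accuracy_pct: float
    avg_action_prob: float
    converged: bool = True

    def native_means(self) -> dict:
        """Posterior means mapped through the point transforms to native space."""
        return {
            n: float(to_native_space(n, v))
            for n, v in zip(self.param_names, self.posterior_mean)
        }


class _PreparedSession:
    """Cached per-session arrays for fast likelihood evaluation."""

    __slots__ = ("choices", "wins_before", "losses_before", "n_trials")

    def __init__(self, choices, wins_before, losses_before):
        self.choices = choices          # (T,) 0-based arm indices
        self.wins_before = wins_before  # (T, 3) win events on each arm earlier in the game
        self.losses_before = losses_before
        self.n_trials = len(choices)


def prepare_session(behavior: pd.DataFrame, allow_partial: bool = False) -> _PreparedSession:
    """Precompute within-game cumulative outcome counts for one session.

    Requires a complete single session (20 games x 16 trials, trials 1..16
    in order inside each game) unless ``allow_partial`` admits a subset of
    complete games; raises ``ValueError`` otherwise.
    """
    if behavior[["subject_id", "session"]].drop_duplicates().shape[0] != 1:
        raise ValueError("prepare_session expects exactly one subject-session")
    if not allow_partial and len(behavior) != N_GAMES * N_TRIALS:
        raise ValueError(
            f"incomplete session: {len(behavior)} rows, expected {N_GAMES * N_TRIALS}"
        )
    choices = np.empty(len(behavior), dtype=np.int64)
    wins_before = np.zeros((len(behavior), 3))
    losses_before = np.zeros((len(behavior), 3))
    pos = 0
    for game, block in behavior.groupby("game", sort=True):
        trials = block["trial"].to_numpy()
        if not np.array_equal(trials, np.arange(1, N_TRIALS + 1)):
            raise ValueError(f"game {game}: trials not ordered 1..{N_TRIALS}")
        arm = block["choice"].to_numpy(dtype=np.int64) - 1
        win = (block["outcome"].to_numpy() == "win").astype(float)
        onehot = np.zeros((N_TRIALS, 3))
        onehot[np.arange(N_TRIALS), arm] = 1.0
        w_ev = onehot * win[:, None]
        l_ev = onehot * (1.0 - win)[:, None]
        sl = slice(pos, pos + N_TRIALS)
        choices[sl] = arm
        wins_before[sl] = np.cumsum(w_ev, axis=0) - w_ev
        losses_before[sl] = np.cumsum(l_ev, axis=0) - l_ev
        pos += N_TRIALS
    return _PreparedSession(choices, wins_before, losses_before)


def _action_log_probs(native: dict, prep: _PreparedSession) -> np.ndarray:
    """(T, 3) log action probabilities under native parameters."""
    a0 = native["a_0"]
    win_counts = a0 + native["eta_win"] * prep.wins_before
    loss_counts = a0 + native["eta_loss"] * prep.losses_before
    counts = np.stack([win_counts, loss_counts], axis=1)  # (T, 2, 3)
    total = counts.sum(axis=1, keepdims=True)
    abar = counts / total
    gain = np.sum(abar * 0.5 * (1.0 / counts - 1.0 / total), axis=1)
    log_prefs = build_preferences(native["c_r"]).log_prefs
    pragmatic = abar[:, 0, :] * log_prefs[1] + abar[:, 1, :] * log_prefs[2]
    efe = -gain - pragmatic
    x = -native["alpha"] * efe
    x -= x.max(axis=1, keepdims=True)
    return x - np.log(np.exp(x).sum(axis=1, keepdims=True))


def log_likelihood(
    params: AgentParams | dict, behavior: pd.DataFrame, spec: ModelSpec
) -> float:
    """Sum of log action probabilities of the observed choices.

    Beliefs are advanced along the subject's *observed* choices and outcomes
    (not the model's own); models without a learning-rate parameter use the
    standard unit count increment.
    """
    prep = behavior if isinstance(behavior, _PreparedSession) else prepare_session(behavior)
    if isinstance(params, AgentParams):
        native = {
            "alpha": params.action_precision,
            "c_r": params.reward_sensitivity,
            "eta_win": params.learning_rate_win,
            "eta_loss": params.learning_rate_loss,
            "a_0": params.info_insensitivity,
        }
    else:
        native = params
    logp = _action_log_probs(native, prep)
    return float(logp[np.arange(prep.n_trials), prep.choices].sum())


def _finite_difference_hessian(fun, x: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    d = len(x)
    hess = np.empty((d, d))
    hs = step * np.maximum(1.0, np.abs(x))
    f0 = fun(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = hs[i]
        hess[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / hs[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = hs[j]
            hess[i, j] = hess[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * hs[i] * hs[j])
    return hess


def _nearest_psd(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    return (vecs * np.maximum(vals, floor)) @ vecs.T


def fit_subject(
    behavior: pd.DataFrame,
    spec: ModelSpec,
    n_starts: int = 5,
    seed: int = 0,
    jitter_sd: float = 1.0,
) -> SubjectPosterior:
    """MAP + Laplace fit of one nested model to one subject-session.

    Maximises log-likelihood + log Gaussian prior in estimation space from
    the prior mean plus ``n_starts - 1`` seeded jittered starts; the
    posterior covariance is the inverse of the finite-difference Hessian of
    the negative log joint at the optimum (projected to the nearest
    positive-definite matrix if needed, with a logged warning).
    """
    prep = behavior if isinstance(behavior, _PreparedSession) else prepare_session(behavior)
    if isinstance(behavior, pd.DataFrame):
        subject_id = str(behavior["subject_id"].iloc[0])
        session = str(behavior["session"].iloc[0])
    else:
        subject_id, session = "unknown", "unknown"

    mu0 = spec.prior_mean()
    prior_prec = 1.0 / PRIOR_VARIANCE

    def neg_log_joint(z: np.ndarray) -> float:
        native = spec.to_native(z)
        ll = log_likelihood(native, prep, spec)
        lp = -0.5 * prior_prec * float(np.sum((z - mu0) ** 2))
        return -(ll + lp)

    rng = np.random.default_rng(seed)
    starts = [mu0] + [mu0 + jitter_sd * rng.standard_normal(spec.n_free) for _ in range(n_starts - 1)]
    best = None
    converged = False
    for x0 in starts:
        res = minimize(
            neg_log_joint, x0, method="L-BFGS-B",
            options={"maxiter": 500, "gtol": 1e-5, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    z_map = best.x
    hess = _finite_difference_hessian(neg_log_joint, z_map)
    try:
        np.linalg.cholesky(hess)
        hess_pd = hess
    except np.linalg.LinAlgError:
        logger.warning(
            "subject %s session %s model %d: non-PD Hessian, projecting", subject_id, session, spec.model_id
        )
        hess_pd = _nearest_psd(hess)
        converged = False
    cov = np.linalg.inv(hess_pd)
    cov = 0.5 * (cov + cov.T)
    d = spec.n_free
    sign, logdet_cov = np.linalg.slogdet(cov)
    free_energy = -best.fun + 0.5 * (d * np.log(2.0 * np.pi) + logdet_cov)

    acc, avg_p = _accuracy_from_native(spec.to_native(z_map), prep)
    return SubjectPosterior(
        subject_id=subject_id,
        session=session,
        model_id=spec.model_id,
        param_names=spec.estimated,
        posterior_mean=z_map,
        posterior_cov=cov,
        free_energy=float(free_energy),
        accuracy_pct=acc,
        avg_action_prob=avg_p,
        converged=converged,
    )


def _accuracy_from_native(native: dict, prep: _PreparedSession):
    logp = _action_log_probs(native, prep)
    chosen = logp[np.arange(prep.n_trials), prep.choices]
    # a trial counts as matched when the observed action attains the maximum
    # probability; ties (e.g. the symmetric first trial of a game) therefore
    # count for any tied action, keeping the metric invariant under
    # consistent arm relabelling
    acc = 100.0 * float(np.mean(chosen >= logp.max(axis=1) - 1e-12))
    return acc, float(np.exp(chosen).mean())


def accuracy_metrics(
    posterior: SubjectPosterior, behavior: pd.DataFrame, spec: ModelSpec
):
    """(accuracy %, mean assigned action probability) at posterior-mean
    parameters over all trials of the session."""
    if spec.model_id != posterior.model_id:
        raise ValueError("posterior/spec model_id mismatch")
    if isinstance(behavior, pd.DataFrame):
        sid = str(behavior["subject_id"].iloc[0])
        ses = str(behavior["session"].iloc[0])
        if (sid, ses) != (posterior.subject_id, posterior.session):
            raise ValueError(
                f"posterior is for {(posterior.subject_id, posterior.session)}, behavior is {(sid, ses)}"
            )
    prep = behavior if isinstance(behavior, _PreparedSession) else prepare_session(behavior)
    return _accuracy_from_native(spec.to_native(posterior.posterior_mean), prep)


def posteriors_to_frame(posteriors) -> pd.DataFrame:
    """Flatten SubjectPosterior records into one tidy DataFrame."""
    rows = []
    for p in posteriors:
        row = {
            "subject_id": p.subject_id,
            "session": p.session,
            "model_id": p.model_id,
            "free_energy": p.free_energy,
            "accuracy_pct": p.accuracy_pct,
            "avg_action_prob": p.avg_action_prob,
            "converged": p.converged,
        }
        for i, n in enumerate(p.param_names):
            row[f"mean_{n}"] = p.posterior_mean[i]
            for j, m in enumerate(p.param_names):
                row[f"cov_{n}_{m}"] = p.posterior_cov[i, j]
        rows.append(row)
    return pd.DataFrame(rows)
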