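"""The ten nested models and random-effects Bayesian model selection.

Model selection treats the model identity as a random effect in the
population: subject-level log evidences feed a variational Dirichlet update
over model frequencies, exceedance probabilities come from Monte-Carlo
draws of that Dirichlet, and protected exceedance probabilities discount
them by the Bayes omnibus risk (BOR) — the posterior probability that all
models are equally frequent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

from .fitting import ModelSpec, fit_subject

__all__ = [
    "nested_model_table",
    "ModelComparisonResult",
    "rfx_bms",
    "identifiability_check",
]


def nested_model_table() -> list:
    """The ten nested models, from action-precision-and-reward only up to the
    full split-learning-rate model (model 9, the winning model)."""
    patterns = {
        1: ("alpha", "c_r"),
        2: ("alpha", "c_r", "eta"),
        3: ("alpha", "c_r", "eta", "a_0"),
        4: ("c_r", "eta", "a_0"),
        5: ("c_r", "eta"),
        6: ("c_r",),
        7: ("c_r", "a_0"),
        8: ("alpha", "c_r", "a_0"),
        9: ("alpha", "c_r", "eta_win", "eta_loss", "a_0"),
        10: ("alpha", "c_r", "eta_win", "eta_loss"),
    }
    return [ModelSpec(model_id=k, estimated=v) for k, v in patterns.items()]


@dataclass
class ModelComparisonResult:
    """Random-effects model comparison summary over M models."""

    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance_prob: np.ndarray
    bor: float
    pxp: np.ndarray
    n_subjects: int
    n_draws: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "exceedance_prob": self.exceedance_prob.tolist(),
            "bor": self.bor,
            "pxp": self.pxp.tolist(),
            "n_subjects": self.n_subjects,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL[Dir(alpha) || Dir(alpha0)]."""
    a_s, a0_s = alpha.sum(), alpha0.sum()
    return float(
        gammaln(a_s)
        - gammaln(a0_s)
        - np.sum(gammaln(alpha) - gammaln(alpha0))
        + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(a_s)))
    )


def rfx_bms(
    free_energies: np.ndarray,
    n_draws: int = 100_000,
    seed: int = 0,
    prior_alpha: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ModelComparisonResult:
    """Random-effects BMS over an N-subjects x M-models evidence matrix.

    Runs the variational update on a Dirichlet over model frequencies with a
    uniform prior concentration, estimates exceedance probabilities by
    seeded Dirichlet Monte Carlo, and computes the protected exceedance
    probabilities ``pxp = (1 - bor) * ep + bor / M``, where BOR compares the
    free energy of the random-effects model against the equal-frequency
    null.
    """
    lme = np.asarray(free_energies, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 2 or lme.shape[1] < 2:
        raise ValueError("free_energies must be N x M with N >= 2 and M >= 2")
    bad = ~np.all(np.isfinite(lme), axis=1)
    if bad.any():
        raise ValueError(
            f"non-finite free energies for subjects {np.flatnonzero(bad).tolist()}"
        )
    n, m = lme.shape
    alpha0 = np.full(m, float(prior_alpha))
    alpha = alpha0.copy()
    g = np.full((n, m), 1.0 / m)
    for _ in range(max_iter):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        log_u -= log_u.max(axis=1, keepdims=True)
        g = np.exp(log_u)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    expected_freq = alpha / alpha.sum()

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    winners = np.argmax(draws, axis=1)
    ep = np.bincount(winners, minlength=m) / n_draws

    # free energy of the RFX model
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    f1 = float(np.sum(g * (lme + e_log_r - np.log(np.maximum(g, 1e-300)))))
    f1 -= _dirichlet_kl(alpha, alpha0)
    # null: frequencies fixed and equal
    shift = lme.max(axis=1, keepdims=True)
    f0 = float(np.sum(np.log(np.mean(np.exp(lme - shift), axis=1)) + shift[:, 0]))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * ep + bor / m
    return ModelComparisonResult(
        dirichlet_alpha=alpha,
        expected_freq=expected_freq,
        exceedance_prob=ep,
        bor=bor,
        pxp=pxp,
        n_subjects=n,
        n_draws=n_draws,
        seed=seed,
    )


def _project_to_model(p, spec: ModelSpec):
    """Restrict a full parameter draw to one nested model: non-free
    parameters revert to their defaults (including the unit learning rate
    for models without a learning-rate parameter)."""
    from .fitting import DEFAULTS_NATIVE
    from .model import AgentParams

    alpha = p.action_precision if "alpha" in spec.estimated else DEFAULTS_NATIVE["alpha"]
    a0 = p.info_insensitivity if "a_0" in spec.estimated else DEFAULTS_NATIVE["a_0"]
    if "eta" in spec.estimated:
        ew = el = p.learning_rate_win
    elif "eta_win" in spec.estimated:
        ew, el = p.learning_rate_win, p.learning_rate_loss
    else:
        ew = el = DEFAULTS_NATIVE["eta"]
    return AgentParams(alpha, p.reward_sensitivity, ew, el, a0)


def identifiability_check(
    generating_model: ModelSpec,
    cohort_size: int = 122,
    seed: int = 0,
    models: list | None = None,
    n_starts: int = 3,
    progress: bool = False,
) -> dict:
    """Simulate a cohort from one model, fit all models, and compare.

    Parameters are drawn per agent from the empirically plausible
    estimation-space distribution (full-sample follow-up moments), each
    agent plays a fresh seeded Beta(2, 2) schedule shared across the cohort,
    and every nested model is fit to every agent.  Returns the winning model
    id, the full pxp vector, and per-subject fit failures (summarised, not
    fatal).
    """
    from .cohort import draw_parameter_vectors, pooled_reference_moments
    from .task import sample_schedule, simulate_agent

    if models is None:
        models = nested_model_table()
    rng = np.random.default_rng(seed)
    schedule = sample_schedule(int(rng.integers(2**31 - 1)))
    means, sds = pooled_reference_moments(session="followup")
    params = [
        _project_to_model(p, generating_model)
        for p in draw_parameter_vectors(cohort_size, means, sds, rng)
    ]

    failures = []
    fe = np.zeros((cohort_size, len(models)))
    for i, p in enumerate(params):
        behav = simulate_agent(p, schedule, seed=int(rng.integers(2**31 - 1)))
        for j, spec in enumerate(models):
            try:
                post = fit_subject(behav, spec, n_starts=n_starts, seed=seed + 17 * i + j)
                fe[i, j] = post.free_energy
            except Exception as exc:  # pragma: no cover - defensive
                failures.append((i, spec.model_id, repr(exc)))
                fe[i, j] = -np.inf
    ok = np.all(np.isfinite(fe), axis=1)
    result = rfx_bms(fe[ok], seed=seed)
    winner_idx = int(np.argmax(result.pxp))
    return {
        "generating_model": generating_model.model_id,
        "winner": models[winner_idx].model_id,
        "pxp": result.pxp,
        "bor": result.bor,
        "result": result,
        "free_energies": fe,
        "failures": failures,
    }
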