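"""Built-in model diagnostics: parameter recovery and self-consistency.

Recovery follows the two-stage procedure used to validate the original
analyses: first a cohort of agents is drawn at empirically plausible
parameter values (estimation-space Gaussians moment-matched to the
published follow-up moments) and fit with the winning model; the
*inferred* posterior parameter combinations then serve as generative
values for a second round of simulation and refitting, and generative vs
re-estimated values are correlated per parameter in estimation space
(learning rates in logit space, the others in log space).

Using inferred combinations matters: the model has a soft scale ridge —
multiplying ``a_0`` and both learning rates by a common factor leaves the
expected reward probabilities untouched and only rescales the novelty
term — so independently drawn parameter combinations can sit off the
identifiable manifold and are projected back onto it by estimation.
Inferred combinations already live on that manifold, which is exactly the
regime the recovery claim speaks to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .cohort import draw_parameter_vectors, pooled_reference_moments
from .fitting import ModelSpec, fit_subject
from .model import AgentParams
from .model_space import nested_model_table
from .task import sample_schedule, simulate_agent

__all__ = ["RecoveryResult", "parameter_recovery"]


@dataclass
class RecoveryResult:
    """Generative vs re-estimated summary for one recovery cohort."""

    n_agents: int
    correlations: dict  # parameter -> Pearson r (estimation space)
    p_values: dict
    true_est: np.ndarray  # (n, k) generative values, estimation space
    fitted_est: np.ndarray  # (n, k) posterior means, estimation space
    accuracy_pct: float  # mean over agents of % argmax-correct trials
    avg_action_prob: float  # mean assigned probability of taken actions


def _fit_cohort(agents, spec, schedule, rng, seed_base, n_starts):
    est = np.empty((len(agents), spec.n_free))
    accs, probs = [], []
    for i, p in enumerate(agents):
        behav = simulate_agent(
            p, schedule, seed=int(rng.integers(2**31 - 1)), subject_id=f"R{i:04d}"
        )
        post = fit_subject(behav, spec, n_starts=n_starts, seed=seed_base + i)
        est[i] = post.posterior_mean
        accs.append(post.accuracy_pct)
        probs.append(post.avg_action_prob)
    return est, float(np.mean(accs)), float(np.mean(probs))


def parameter_recovery(
    n_agents: int = 122,
    seed: int = 0,
    spec: ModelSpec | None = None,
    session: str = "followup",
    n_starts: int = 5,
) -> RecoveryResult:
    """Two-stage simulate-and-refit recovery of the winning model.

    Stage 1 draws ``n_agents`` independent parameter vectors matched to the
    published follow-up moments, simulates a session each on a shared
    Beta(2, 2) schedule, and fits ``spec``.  Stage 2 treats the stage-1
    posterior means as generative values, simulates fresh sessions, refits,
    and correlates generative against re-estimated values.  The reported
    accuracy metrics are the stage-2 refit metrics on self-generated data.
    """
    if spec is None:
        spec = nested_model_table()[8]  # split learning-rate model
    rng = np.random.default_rng(seed)
    schedule = sample_schedule(int(rng.integers(2**31 - 1)))
    means, sds = pooled_reference_moments(session=session)
    stage1_agents = draw_parameter_vectors(n_agents, means, sds, rng)

    inferred, _, _ = _fit_cohort(stage1_agents, spec, schedule, rng, seed, n_starts)

    gen_agents = []
    for z in inferred:
        nat = spec.to_native(z)
        gen_agents.append(
            AgentParams(nat["alpha"], nat["c_r"], nat["eta_win"], nat["eta_loss"], nat["a_0"])
        )
    fitted, acc, avg_p = _fit_cohort(gen_agents, spec, schedule, rng, seed + n_agents, n_starts)

    correlations, p_values = {}, {}
    for j, name in enumerate(spec.estimated):
        r, pv = pearsonr(inferred[:, j], fitted[:, j])
        correlations[name] = float(r)
        p_values[name] = float(pv)
    return RecoveryResult(
        n_agents=n_agents,
        correlations=correlations,
        p_values=p_values,
        true_est=inferred,
        fitted_est=fitted,
        accuracy_pct=acc,
        avg_action_prob=avg_p,
    )
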