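"""Generative active-inference model of a single three-armed bandit trial.

The agent holds Dirichlet beliefs over the win/loss probability of each arm,
scores each arm by its expected free energy ``G`` (an epistemic,
information-gain term plus a pragmatic, preference-weighted term; lower is
better), and samples actions from a softmax over ``-G`` sharpened by an
action-precision parameter.  Learning increments the Dirichlet
concentration count of the observed (outcome, arm) cell by a learning rate.

Outcome modality coding is ``(start/neutral, win, loss)``; only the win and
loss rows of the concentration matrix are learnable.  Choice states are fully
observed (identity mapping), so there is no state-estimation uncertainty and
policies are single-step arm choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

__all__ = [
    "WIN",
    "LOSS",
    "N_ARMS",
    "AgentParams",
    "DirichletBeliefs",
    "PreferenceVector",
    "PolicyEval",
    "build_preferences",
    "expected_free_energy",
    "information_gain",
    "action_distribution",
    "update_beliefs",
    "evaluate_policies",
]

#: Row indices of the learnable concentration matrix.
WIN, LOSS = 0, 1
N_ARMS = 3

#: Lower clip applied to concentration counts for numerical safety.
COUNT_FLOOR = 1e-8


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class InvalidBeliefsError(ValueError):
    """A Dirichlet belief state violates its invariants."""


@dataclass(frozen=True)
class AgentParams:
    """The five free parameters of the full (split learning rate) model.

    Parameters
    ----------
    action_precision : float
        Inverse temperature on negative expected free energy; higher values
        make action selection more deterministic.  Must be >= 0 (0 is the
        uniform-choice limiting case, admitted for diagnostics).
    reward_sensitivity : float
        Utility of a win in the preference vector, on the log-probability
        scale after softmax normalisation.
    learning_rate_win, learning_rate_loss : float
        Increment applied to the observed concentration cell after a win
        (respectively a loss); both in (0, 1).
    info_insensitivity : float
        Initial uniform concentration magnitude ``a_0``.  Larger values
        down-weight the information-gain term and make beliefs less
        malleable.
    """

    action_precision: float
    reward_sensitivity: float
    learning_rate_win: float
    learning_rate_loss: float
    info_insensitivity: float

    def __post_init__(self) -> None:
        vals = [
            self.action_precision,
            self.reward_sensitivity,
            self.learning_rate_win,
            self.learning_rate_loss,
            self.info_insensitivity,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite parameter in {vals}")
        if self.action_precision < 0:
            raise InvalidParameterError("action_precision must be >= 0")
        if self.reward_sensitivity <= 0:
            raise InvalidParameterError("reward_sensitivity must be > 0")
        for name in ("learning_rate_win", "learning_rate_loss"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.info_insensitivity <= 0:
            raise InvalidParameterError("info_insensitivity must be > 0")


@dataclass(frozen=True)
class DirichletBeliefs:
    """Concentration counts over (win, loss) outcomes for each of 3 arms."""

    counts: np.ndarray  # shape (2, 3)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (2, N_ARMS):
            raise InvalidBeliefsError(f"counts must be 2x{N_ARMS}, got {counts.shape}")
        if not np.all(np.isfinite(counts)) or np.any(counts <= 0):
            raise InvalidBeliefsError("all concentration counts must be positive")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def fresh(cls, a_0: float) -> "DirichletBeliefs":
        """Uninformative beliefs: every cell set to the magnitude ``a_0``."""
        if not np.isfinite(a_0) or a_0 <= 0:
            raise InvalidParameterError("a_0 must be a positive real")
        return cls(np.full((2, N_ARMS), float(a_0)))

    @property
    def win_probability(self) -> np.ndarray:
        """Expected win probability per arm under the current counts."""
        return self.counts[WIN] / self.counts.sum(axis=0)


@dataclass(frozen=True)
class PreferenceVector:
    """Log prior outcome probabilities over (neutral, win, loss)."""

    log_prefs: np.ndarray  # shape (3,)

    def __post_init__(self) -> None:
        lp = np.asarray(self.log_prefs, dtype=float)
        if lp.shape != (3,):
            raise InvalidParameterError("log_prefs must be a 3-vector")
        object.__setattr__(self, "log_prefs", lp)


@dataclass(frozen=True)
class PolicyEval:
    """Expected free energies and the induced policy/action distributions."""

    efe: np.ndarray
    policy_dist: np.ndarray
    action_dist: np.ndarray


def _log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    m = np.max(x, axis=axis, keepdims=True)
    z = x - m
    return z - np.log(np.sum(np.exp(z), axis=axis, keepdims=True))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    return np.exp(_log_softmax(x, axis=axis))


def build_preferences(reward_sensitivity: float) -> PreferenceVector:
    """Preference (C) vector from the raw utility triple ``(0, c_r, 0)``.

    Raw utilities over (neutral, win, loss) are passed through a softmax and
    converted to log probabilities, so ``log_prefs[win] - log_prefs[loss]``
    equals ``c_r`` exactly.
    """
    if not np.isfinite(reward_sensitivity):
        raise InvalidParameterError("reward_sensitivity must be finite")
    utilities = np.array([0.0, float(reward_sensitivity), 0.0])
    return PreferenceVector(_log_softmax(utilities))


def _as_count_array(beliefs: DirichletBeliefs | np.ndarray) -> np.ndarray:
    counts = beliefs.counts if isinstance(beliefs, DirichletBeliefs) else np.asarray(beliefs, dtype=float)
    if counts.shape[-2:] != (2, N_ARMS):
        raise InvalidBeliefsError("counts must have trailing shape (2, 3)")
    if np.any(counts <= 0):
        raise InvalidBeliefsError("all concentration counts must be positive")
    return np.maximum(counts, COUNT_FLOOR)


def information_gain(
    beliefs: DirichletBeliefs | np.ndarray, exact: bool = False
) -> np.ndarray:
    """Expected information gain about each arm's reward probability.

    The default is the standard Dirichlet novelty bound

    ``sum_o Abar[o,k] * (1/counts[o,k] - 1/sum_o' counts[o',k]) / 2``

    where ``Abar`` is the column-normalised count matrix.  With
    ``exact=True`` the expected Kullback-Leibler divergence
    ``E_{o~Abar[:,k]} KL[Dir(counts[:,k] + e_o) || Dir(counts[:,k])]`` is
    evaluated instead, which serves as a cross-check of the bound.

    Accepts a batch of count matrices with trailing shape (2, 3); returns the
    gain with trailing shape (3,).
    """
    counts = _as_count_array(beliefs)
    total = counts.sum(axis=-2, keepdims=True)
    abar = counts / total
    if not exact:
        novelty = 0.5 * (1.0 / counts - 1.0 / total)
        return np.sum(abar * novelty, axis=-2)
    # KL[Dir(a') || Dir(a)] with a' = a + e_o, evaluated per outcome o.
    tot = total[..., 0, :]
    kl = np.empty_like(abar)
    for o in range(2):
        a_new = counts.copy()
        a_new[..., o, :] += 1.0
        kl[..., o, :] = (
            gammaln(tot + 1.0)
            - gammaln(tot)
            - (gammaln(counts[..., o, :] + 1.0) - gammaln(counts[..., o, :]))
            + (digamma(counts[..., o, :] + 1.0) - digamma(tot + 1.0))
        )
    return np.sum(abar * kl, axis=-2)


def expected_free_energy(
    beliefs: DirichletBeliefs | np.ndarray,
    prefs: PreferenceVector,
    exact_info_gain: bool = False,
) -> np.ndarray:
    """Expected free energy ``G`` per arm; lower values mark better arms.

    ``G_k = -(expected information gain_k) - sum_o Abar[o,k] * log_prefs[o]``
    with the outcome sum running over win and loss (the neutral outcome
    cannot occur once an arm is chosen).  Supports batched count arrays with
    trailing shape (2, 3).
    """
    counts = _as_count_array(beliefs)
    abar = counts / counts.sum(axis=-2, keepdims=True)
    gain = information_gain(counts, exact=exact_info_gain)
    log_c = prefs.log_prefs[1:]  # (win, loss)
    pragmatic = np.einsum("...ok,o->...k", abar, log_c)
    return -gain - pragmatic


def action_distribution(efe: np.ndarray, action_precision: float) -> np.ndarray:
    """Softmax of ``action_precision * (-efe)`` over arms (last axis)."""
    efe = np.asarray(efe, dtype=float)
    if np.any(np.isnan(efe)):
        raise InvalidParameterError("efe contains NaN")
    if not np.isfinite(action_precision) or action_precision < 0:
        raise InvalidParameterError("action_precision must be a nonnegative real")
    return softmax(-float(action_precision) * efe, axis=-1)


def evaluate_policies(
    beliefs: DirichletBeliefs, prefs: PreferenceVector, action_precision: float
) -> PolicyEval:
    """EFE plus the policy distribution sigma(-G) and the precision-weighted
    action distribution sigma(-alpha * G) for one belief state."""
    efe = expected_free_energy(beliefs, prefs)
    return PolicyEval(
        efe=efe,
        policy_dist=softmax(-efe),
        action_dist=action_distribution(efe, action_precision),
    )


def update_beliefs(
    beliefs: DirichletBeliefs,
    arm: int,
    outcome: str,
    learning_rate_win: float,
    learning_rate_loss: float,
) -> DirichletBeliefs:
    """Return new beliefs after observing ``outcome`` on ``arm`` (1-based).

    The (outcome, arm) concentration cell is incremented by the matching
    learning rate; every other cell — including the unmodelled neutral row —
    is untouched, and the input beliefs are never mutated.
    """
    if arm not in (1, 2, 3):
        raise ValueError(f"arm must be 1, 2 or 3, got {arm!r}")
    if outcome not in ("win", "loss"):
        raise ValueError(f"outcome must be 'win' or 'loss', got {outcome!r}")
    counts = beliefs.counts.copy()
    row = WIN if outcome == "win" else LOSS
    eta = learning_rate_win if outcome == "win" else learning_rate_loss
    counts[row, arm - 1] += eta
    return DirichletBeliefs(counts)
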