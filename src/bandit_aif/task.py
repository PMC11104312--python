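"""Task design, reward schedules, and session simulation.

The task is a three-armed bandit played over 20 games of 16 trials each
(320 choices per session).  Each game has fixed, hidden win probabilities
per arm drawn from Beta(2, 2); probabilities change between games, and the
agent's beliefs reset to the uninformative ``a_0`` state at the start of
every game.  The same schedule is used for every subject in a study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    AgentParams,
    DirichletBeliefs,
    action_distribution,
    build_preferences,
    expected_free_energy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "N_GAMES",
    "N_TRIALS",
    "TaskSchedule",
    "sample_schedule",
    "simulate_agent",
    "read_behavior",
    "write_behavior",
    "read_schedule",
    "write_schedule",
    "validate_behavior",
]

N_GAMES = 20
N_TRIALS = 16

BEHAVIOR_COLUMNS = ["subject_id", "session", "game", "trial", "choice", "outcome", "rt"]
SESSIONS = ("baseline", "followup")


@dataclass(frozen=True)
class TaskSchedule:
    """Per-game, per-arm win probabilities plus a presentation order.

    The structural model (deterministic choice transitions, fixed start
    state, identity choice observation) carries no free parameters and is
    implicit in the simulator: the chosen arm is always reached and always
    observed.
    """

    win_prob: np.ndarray  # shape (N_GAMES, 3)
    game_order: np.ndarray = field(default=None)  # permutation of 1..N_GAMES
    n_trials_per_game: int = N_TRIALS

    def __post_init__(self) -> None:
        wp = np.asarray(self.win_prob, dtype=float)
        if wp.shape != (N_GAMES, 3):
            raise ValueError(f"win_prob must be ({N_GAMES}, 3), got {wp.shape}")
        if np.any(wp <= 0) or np.any(wp >= 1):
            raise ValueError("win probabilities must lie strictly in (0, 1)")
        order = self.game_order
        if order is None:
            order = np.arange(1, N_GAMES + 1)
        order = np.asarray(order, dtype=int)
        if sorted(order.tolist()) != list(range(1, N_GAMES + 1)):
            raise ValueError("game_order must be a permutation of 1..20")
        object.__setattr__(self, "win_prob", wp)
        object.__setattr__(self, "game_order", order)


def sample_schedule(seed: int) -> TaskSchedule:
    """Draw a schedule: 20x3 Beta(2, 2) win probabilities, seeded game order.

    Block pseudorandomisation is realised as a plain seeded permutation of
    the game order.
    """
    rng = np.random.default_rng(seed)
    win_prob = rng.beta(2.0, 2.0, size=(N_GAMES, 3))
    win_prob = np.clip(win_prob, 1e-6, 1 - 1e-6)
    game_order = rng.permutation(N_GAMES) + 1
    return TaskSchedule(win_prob=win_prob, game_order=game_order)


def simulate_agent(
    params: AgentParams,
    schedule: TaskSchedule,
    seed: int,
    subject_id: str = "sim",
    session: str = "baseline",
    rt_mean_log: float = np.log(0.55),
    rt_sd_log: float = 0.35,
) -> pd.DataFrame:
    """Simulate one full session (320 rows) of agent play.

    Per trial the agent computes expected free energy from its current
    Dirichlet beliefs, samples an arm from the precision-weighted action
    distribution, receives a Bernoulli(win_prob) outcome, and updates the
    chosen cell by the matching learning rate.  Beliefs reset to the fresh
    ``a_0`` state at every game boundary.  Reaction times are lognormal
    placeholders (the synthetic cohort layer plants RT structure).
    """
    if not isinstance(params, AgentParams):
        params = AgentParams(*params)
    rng = np.random.default_rng(seed)
    prefs = build_preferences(params.reward_sensitivity)
    eta = np.array([params.learning_rate_win, params.learning_rate_loss])

    rows = []
    for game in schedule.game_order:
        p_win = schedule.win_prob[game - 1]
        counts = np.full((2, 3), params.info_insensitivity)
        for trial in range(1, schedule.n_trials_per_game + 1):
            efe = expected_free_energy(counts, prefs)
            probs = action_distribution(efe, params.action_precision)
            arm = rng.choice(3, p=probs)  # 0-based
            win = rng.random() < p_win[arm]
            counts[0 if win else 1, arm] += eta[0 if win else 1]
            rt = float(np.exp(rng.normal(rt_mean_log, rt_sd_log)))
            rows.append(
                (subject_id, session, int(game), trial, arm + 1, "win" if win else "loss", rt)
            )
    return pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)


def validate_behavior(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a behavior table; returns the table with flags attached.

    Raises ``ValueError`` naming the first offending row for out-of-range
    values or duplicate (subject, session, game, trial) keys.  Sessions with
    fewer than 320 rows are flagged (``table.attrs['incomplete_sessions']``),
    not rejected.
    """
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavior table missing columns: {missing}")
    table = table.copy()
    for col, lo, hi in (("game", 1, N_GAMES), ("trial", 1, N_TRIALS), ("choice", 1, 3)):
        bad = ~table[col].between(lo, hi)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"row {row}: {col}={table[col].iloc[row]!r} outside [{lo}, {hi}]"
            )
    bad = ~table["outcome"].isin(["win", "loss"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"row {row}: outcome={table['outcome'].iloc[row]!r}")
    keys = ["subject_id", "session", "game", "trial"]
    dup = table.duplicated(subset=keys)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"row {row}: duplicate (subject, session, game, trial) key")
    sizes = table.groupby(["subject_id", "session"], sort=False).size()
    incomplete = sizes[sizes != N_GAMES * N_TRIALS]
    table.attrs["incomplete_sessions"] = [tuple(k) for k in incomplete.index]
    if len(incomplete):
        logger.warning("%d incomplete session(s): %s", len(incomplete), list(incomplete.index))
    return table


def write_behavior(table: pd.DataFrame, path) -> None:
    """Write a behavior table as UTF-8 CSV with a header row."""
    table.loc[:, BEHAVIOR_COLUMNS].to_csv(path, index=False)


def read_behavior(path) -> pd.DataFrame:
    """Read and validate a behavior CSV (see ``validate_behavior``)."""
    table = pd.read_csv(path)
    return validate_behavior(table)


def write_schedule(schedule: TaskSchedule, path) -> None:
    """Serialise a schedule as long-form CSV: game, arm, win_prob, order."""
    games = np.repeat(np.arange(1, N_GAMES + 1), 3)
    arms = np.tile([1, 2, 3], N_GAMES)
    order = np.repeat(np.argsort(schedule.game_order) + 1, 3)
    pd.DataFrame(
        {
            "game": games,
            "arm": arms,
            "win_prob": schedule.win_prob.ravel(),
            "presentation_order": order,
        }
    ).to_csv(path, index=False)


def read_schedule(path) -> TaskSchedule:
    """Read a schedule CSV written by ``write_schedule``."""
    df = pd.read_csv(path).sort_values(["game", "arm"])
    win_prob = df["win_prob"].to_numpy().reshape(N_GAMES, 3)
    if "presentation_order" in df.columns:
        pos = df.groupby("game")["presentation_order"].first()
        game_order = pos.sort_values().index.to_numpy()
    else:
        game_order = None
    return TaskSchedule(win_prob=win_prob, game_order=game_order)
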