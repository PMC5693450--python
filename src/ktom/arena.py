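"""Simulation of the experimental protocol.

A subject agent (the seeker) plays repeated 60-trial hide-and-seek sessions
against three opponent algorithms:

* ``RB`` — a pre-determined pseudo-random hiding sequence with a 65% bias
  for one hand (favoured side counterbalanced across sessions);
* ``OTOM`` — an online competitive 0-ToM hider that tracks the subject's
  seek frequency and hides where it predicts the subject will not seek;
* ``ITOM`` — an online competitive 1-ToM hider that models the subject as a
  0-ToM learner and tries to outwit it.

The full protocol is 4 sessions per condition (12 sessions), condition
order counterbalanced across individuals by a Latin-square rotation, with
sessions shorter than a minimum trial count flagged as excluded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import Agent, AgentSpec

__all__ = [
    "CONDITIONS",
    "RB_BIAS",
    "OPPONENT_SIGMA",
    "OPPONENT_BETA",
    "SessionRecord",
    "ProtocolDesign",
    "generate_rb_sequence",
    "make_opponent",
    "play_session",
    "run_protocol",
    "score_performance",
    "session_scores",
    "sessions_to_frame",
    "frame_to_sessions",
]

CONDITIONS = ("RB", "OTOM", "ITOM")

#: Bias of the pre-determined random opponent for its favoured hand.
RB_BIAS = 0.65

#: Parameters of the online opponent algorithms (volatility, temperature).
OPPONENT_SIGMA = 0.5
OPPONENT_BETA = 1.0


@dataclass
class SessionRecord:
    """Aligned per-trial sequences of one session (seeker convention:
    ``reward = 1`` iff ``a_self == a_op``)."""

    a_self: np.ndarray
    a_op: np.ndarray
    reward: np.ndarray
    condition: str
    session_index: int = 0
    day_gap: float = 1.0
    included: bool = True

    def __post_init__(self):
        self.a_self = np.asarray(self.a_self, dtype=int)
        self.a_op = np.asarray(self.a_op, dtype=int)
        self.reward = np.asarray(self.reward, dtype=int)
        if not (len(self.a_self) == len(self.a_op) == len(self.reward)):
            raise ValueError("misaligned session sequences")
        if not np.array_equal(self.reward, (self.a_self == self.a_op).astype(int)):
            raise ValueError("reward must equal the match indicator")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    def __len__(self):
        return len(self.a_self)

    @property
    def trial(self):
        """1-based trial indices."""
        return np.arange(1, len(self) + 1)

    @property
    def win_rate(self) -> float:
        return float(np.mean(self.reward))


@dataclass
class ProtocolDesign:
    """Study design: sessions per condition, trials per session, minimum
    session length for inclusion, and an optional truncation model for
    interrupted sessions (``truncation_rate`` = per-session probability of
    an interruption at a uniformly drawn trial)."""

    n_sessions_per_condition: int = 4
    trials_per_session: int = 60
    min_trials_keep: int = 20
    truncation_rate: float = 0.0
    condition_order: tuple | None = None

    @property
    def n_sessions(self) -> int:
        return 3 * self.n_sessions_per_condition


def generate_rb_sequence(n: int, favoured: int, seed) -> np.ndarray:
    """I.i.d. hiding sequence with P(favoured hand) = RB_BIAS."""
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    rng = np.random.default_rng(seed)
    pick_favoured = rng.random(n) < RB_BIAS
    seq = np.where(pick_favoured, favoured, 1 - favoured)
    return seq.astype(int)


def make_opponent(condition: str) -> Agent | None:
    """Fresh online opponent machine for a condition (None for RB)."""
    if condition == "RB":
        return None
    if condition == "OTOM":
        spec = AgentSpec(
            "0ToM", {"sigma": OPPONENT_SIGMA, "beta": OPPONENT_BETA}, role="hider"
        )
    elif condition == "ITOM":
        spec = AgentSpec(
            "1ToM-comp", {"sigma": OPPONENT_SIGMA, "beta": OPPONENT_BETA}, role="hider"
        )
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return Agent(spec)


def play_session(
    subject: AgentSpec,
    condition: str,
    design: ProtocolDesign | None = None,
    seed=None,
    session_index: int = 0,
    day_gap: float = 1.0,
    favoured: int = 1,
    n_trials: int | None = None,
) -> SessionRecord:
    """Simulate one session; fully reproducible given ``seed``."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    design = design or ProtocolDesign()
    n = n_trials if n_trials is not None else design.trials_per_session
    rng = np.random.default_rng(seed)
    player = Agent(subject)
    opponent = make_opponent(condition)
    rb_seq = generate_rb_sequence(n, favoured, rng) if condition == "RB" else None

    a_self = np.empty(n, dtype=int)
    a_op = np.empty(n, dtype=int)
    for t in range(n):
        act_s = player.act(rng.random())
        if condition == "RB":
            act_o = int(rb_seq[t])
        else:
            act_o = opponent.act(rng.random())
        a_self[t] = act_s
        a_op[t] = act_o
        player.observe(act_s, act_o)
        if opponent is not None:
            opponent.observe(act_o, act_s)
    reward = (a_self == a_op).astype(int)
    rec = SessionRecord(
        a_self,
        a_op,
        reward,
        condition,
        session_index=session_index,
        day_gap=day_gap,
        included=n >= design.min_trials_keep,
    )
    return rec


def _latin_square_order(design: ProtocolDesign, individual_index: int) -> tuple:
    """Counterbalanced condition order: block-wise rotation by individual."""
    order = []
    for block in range(design.n_sessions_per_condition):
        rot = (individual_index + block) % 3
        order.extend(CONDITIONS[rot:] + CONDITIONS[:rot])
    return tuple(order)


def run_protocol(
    subject: AgentSpec,
    design: ProtocolDesign | None = None,
    seed=None,
    individual_index: int = 0,
) -> list[SessionRecord]:
    """Simulate the full 12-session protocol for one individual."""
    design = design or ProtocolDesign()
    rng = np.random.default_rng(seed)
    order = design.condition_order or _latin_square_order(design, individual_index)
    if len(order) != design.n_sessions:
        raise ValueError("condition order length does not match the design")
    sessions = []
    rb_count = 0
    for s_idx, cond in enumerate(order):
        n = design.trials_per_session
        if design.truncation_rate > 0 and rng.random() < design.truncation_rate:
            n = int(rng.integers(5, design.trials_per_session))
        favoured = rb_count % 2
        if cond == "RB":
            rb_count += 1
        rec = play_session(
            subject,
            cond,
            design,
            seed=rng.integers(2**31),
            session_index=s_idx,
            day_gap=float(rng.choice([1.0, 2.0, 3.0])),
            favoured=favoured,
            n_trials=n,
        )
        sessions.append(rec)
    return sessions


def session_scores(sessions: list[SessionRecord]) -> pd.DataFrame:
    """Tidy per-session summary (one row per session)."""
    rows = [
        {
            "session_index": s.session_index,
            "condition": s.condition,
            "n_trials": len(s),
            "score": s.win_rate,
            "day_gap": s.day_gap,
            "included": s.included,
        }
        for s in sessions
    ]
    return pd.DataFrame(rows)


def score_performance(sessions: list[SessionRecord]) -> dict:
    """Per-condition win rates over included trials, raw and net of chance.

    'Net' is raw minus the 0.5 chance level (both are always reported)."""
    out = {}
    for cond in CONDITIONS:
        trials = [s.reward for s in sessions if s.condition == cond and s.included]
        if not trials:
            out[cond] = {"raw": np.nan, "net": np.nan, "n_trials": 0, "missing": True}
            continue
        rewards = np.concatenate(trials)
        raw = float(np.mean(rewards))
        out[cond] = {
            "raw": raw,
            "net": raw - 0.5,
            "n_trials": int(rewards.size),
            "missing": False,
        }
    return out


def sessions_to_frame(
    sessions: list[SessionRecord], individual_id: str = "ind0", species: str = "NA"
) -> pd.DataFrame:
    """Tidy trial-level log (one row per trial)."""
    frames = []
    for s in sessions:
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": individual_id,
                    "species": species,
                    "session_index": s.session_index,
                    "condition": s.condition,
                    "trial": s.trial,
                    "a_self": s.a_self,
                    "a_op": s.a_op,
                    "reward": s.reward,
                    "day_gap": s.day_gap,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_sessions(df: pd.DataFrame, min_trials_keep: int = 20) -> dict:
    """Rebuild ``{individual_id: [SessionRecord, ...]}`` from a trial log."""
    out: dict = {}
    for (ind, s_idx), grp in df.groupby(["individual_id", "session_index"]):
        grp = grp.sort_values("trial")
        rec = SessionRecord(
            grp["a_self"].to_numpy(),
            grp["a_op"].to_numpy(),
            grp["reward"].to_numpy(),
            grp["condition"].iloc[0],
            session_index=int(s_idx),
            day_gap=float(grp["day_gap"].iloc[0]),
            included=len(grp) >= min_trials_keep,
        )
        out.setdefault(str(ind), []).append(rec)
    for ind in out:
        out[ind].sort(key=lambda r: r.session_index)
    return out
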