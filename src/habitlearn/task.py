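"""Generative environment for the two-step devaluation task.

Two experiment variants are supported:

* **exp1** -- two structurally identical two-step games ("gold" and
  "silver", one coin type each) interleaved over 200 training trials, then
  4 no-feedback trials, devaluation of one coin type, 20 respond/withhold
  test trials (10 per game, random order) and a consumption display.
  Responding costs 1 cent; a coin is worth 25 cents.
* **exp2** -- a single game whose two second-stage states produce the two
  coin types.  150 trials with drifting reward probabilities are followed
  by 50 trials with probabilities pinned at .9 (the to-be-devalued state)
  and .1 (the to-remain-valued state), 4 no-feedback trials, devaluation,
  and a 10-trial forced-choice habit test (no withhold option, no cost).

Reward probabilities follow independent Gaussian random walks (SD 0.025)
reflected at .25/.75; first-stage actions reach their majority destination
with probability .70.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

PHASES = ("training", "nofeedback", "test", "consumption")
ACTIONS = ("left", "right")
MAX_RUN = 4  # longest permitted run of one game in the exp1 interleave


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TaskConfig:
    """Full specification of one experiment variant.

    ``devalued_target`` names the game (exp1) or the second-stage state
    (exp2) whose coin is devalued after training; in exp2 that state also
    carries the .9 stabilized reward probability.
    """

    experiment: str
    n_games: int
    n_training: int
    n_stabilized: int
    n_nofeedback: int
    n_test: int
    devalued_target: str
    p_common: float = 0.70
    walk_sd: float = 0.025
    walk_bounds: tuple[float, float] = (0.25, 0.75)
    stabilized_probs: tuple[float, float] = (0.9, 0.1)
    reward_value: float = 0.25
    response_cost: float = 0.01
    response_window: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if not 0.0 < self.p_common < 1.0:
            raise ValueError("p_common must lie strictly inside (0, 1)")
        lo, hi = self.walk_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("walk_bounds must satisfy 0 < lower < upper < 1")
        for name in ("n_games", "n_training", "n_nofeedback", "n_test"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_stabilized < 0 or self.n_stabilized >= self.n_training:
            raise ValueError("n_stabilized must be in [0, n_training)")
        if self.walk_sd <= 0:
            raise ValueError("walk_sd must be positive")
        if self.experiment == "exp1":
            if self.n_test % (2 * self.n_games):
                raise ValueError("exp1 n_test must balance across games")
            if self.n_training % self.n_games:
                raise ValueError("exp1 n_training must split evenly by game")
            if self.devalued_target not in self.games:
                raise ValueError("exp1 devalued_target must name a game")
        else:
            if self.n_games != 1:
                raise ValueError("exp2 uses a single game")
            if self.devalued_target not in self.state_names:
                raise ValueError("exp2 devalued_target must name a state")

    # -- structure -----------------------------------------------------
    @property
    def games(self) -> tuple[str, ...]:
        return ("gold", "silver") if self.experiment == "exp1" else ("single",)

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(f"{g}_{s}" for g in self.games for s in ("A", "B"))

    @property
    def n_states(self) -> int:
        return 2 * self.n_games

    @property
    def trials_per_game(self) -> int:
        return self.n_training // self.n_games

    @property
    def n_walk_steps(self) -> int:
        """Trials per game driven by the random walks (drifting portion)."""
        return self.trials_per_game - self.n_stabilized

    def game_index(self, game: str) -> int:
        return self.games.index(game)

    def state_index(self, state: str) -> int:
        return self.state_names.index(state)

    def common_destination(self, game: str, action: str) -> str:
        """Majority (70%) destination of ``action`` in ``game``."""
        return f"{game}_A" if action == "left" else f"{game}_B"

    def devalued_states(self) -> tuple[str, ...]:
        """Second-stage states whose coin is worthless after devaluation."""
        if self.experiment == "exp1":
            g = self.devalued_target
            return (f"{g}_A", f"{g}_B")
        return (self.devalued_target,)

    def stabilized_prob(self, state: str) -> float:
        """Reward probability of ``state`` during the exp2 stabilized block."""
        hi, lo = self.stabilized_probs
        return hi if state == self.devalued_target else lo

    # -- constructors --------------------------------------------------
    @classmethod
    def exp1(cls, seed: int = 0, devalued: str = "gold", **overrides) -> "TaskConfig":
        kw = dict(experiment="exp1", n_games=2, n_training=200, n_stabilized=0,
                  n_nofeedback=4, n_test=20, devalued_target=devalued, seed=seed)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def exp2(cls, seed: int = 0, devalued: str = "single_A", **overrides) -> "TaskConfig":
        kw = dict(experiment="exp2", n_games=1, n_training=200, n_stabilized=50,
                  n_nofeedback=4, n_test=10, devalued_target=devalued,
                  response_cost=0.0, seed=seed)
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **changes) -> "TaskConfig":
        return dataclasses.replace(self, **changes)

    # -- JSON round trip -----------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["walk_bounds"] = list(d["walk_bounds"])
        d["stabilized_probs"] = list(d["stabilized_probs"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TaskConfig":
        data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError("config JSON must be an object")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        missing = sorted(known - set(data))
        if missing:
            raise ValueError(f"missing config keys: {', '.join(missing)}")
        data["walk_bounds"] = tuple(data["walk_bounds"])
        data["stabilized_probs"] = tuple(data["stabilized_probs"])
        return cls(**data)


def reflect(value: float, lower: float, upper: float) -> float:
    """Mirror ``value`` back inside [lower, upper].

    A proposed step beyond a bound is reflected about that bound
    (p -> 2*bound - p), repeatedly if the overshoot spans the interval.
    """
    if lower >= upper:
        raise ValueError("lower bound must be below upper bound")
    width = upper - lower
    while value < lower or value > upper:
        if value < lower:
            value = 2.0 * lower - value
        else:
            value = 2.0 * upper - value
        # guard against pathological overshoot many widths away
        if value < lower - 2 * width or value > upper + 2 * width:
            value = lower + (value - lower) % (2 * width)
    return value


def make_reward_walks(config: TaskConfig, rng_seed=None,
                      n_steps: int | None = None) -> dict[str, np.ndarray]:
    """Independent reflected Gaussian reward-probability walks, one per state.

    Each walk starts uniformly inside ``walk_bounds`` and adds a zero-mean
    Gaussian increment (scale ``walk_sd``) per trial, reflecting at the
    bounds.  Length defaults to the number of drifting trials on which the
    state can be visited.
    """
    rng = _as_rng(config.seed if rng_seed is None else rng_seed)
    lo, hi = config.walk_bounds
    length = config.n_walk_steps if n_steps is None else int(n_steps)
    walks: dict[str, np.ndarray] = {}
    for state in config.state_names:
        p = np.empty(length)
        x = rng.uniform(lo, hi)
        steps = rng.normal(0.0, config.walk_sd, size=length)
        for t in range(length):
            p[t] = x
            x = reflect(x + steps[t], lo, hi)
        walks[state] = p
    return walks


def sample_transition(action: str, game: str, config: TaskConfig,
                      rng) -> tuple[str, str]:
    """Sample the second-stage state reached by ``action``.

    Returns ``(second_state, label)`` where label is "common" when the
    majority (p_common) destination was reached, else "rare".
    """
    if action not in ACTIONS:
        raise ValueError(f"cannot sample a transition for action {action!r}")
    rng = _as_rng(rng)
    dest = config.common_destination(game, action)
    alt = config.common_destination(game, "right" if action == "left" else "left")
    if rng.random() < config.p_common:
        return dest, "common"
    return alt, "rare"


class ScheduledTrial(NamedTuple):
    trial: int          # 0-based position in the whole session
    phase: str          # training | nofeedback | test
    game: str
    game_trial: int     # 0-based visit count of this game (walk index)
    stabilized: bool    # exp2: reward probabilities pinned, not drifting


def _constrained_interleave(counts: dict[str, int], max_run: int,
                            rng: np.random.Generator) -> list[str]:
    """Random interleave of game labels with no run longer than ``max_run``.

    Sequential sampling weighted by remaining counts; a label is only
    admissible if choosing it leaves a completable sequence (the majority
    label must fit into max_run-sized blocks separated by minority labels).
    """
    games = list(counts)
    remaining = dict(counts)
    seq: list[str] = []
    last, run = None, 0
    for _ in range(sum(counts.values())):
        admissible = []
        for g in games:
            if remaining[g] == 0:
                continue
            if g == last and run >= max_run:
                continue
            new_run = run + 1 if g == last else 1
            rem = dict(remaining)
            rem[g] -= 1
            ok = True
            for h in games:
                others = sum(v for k, v in rem.items() if k != h)
                cap = max_run * (others + 1)
                if h == g:
                    cap -= new_run
                if rem[h] > cap:
                    ok = False
                    break
            if ok:
                admissible.append(g)
        if not admissible:  # pragma: no cover - feasibility is maintained
            raise RuntimeError("interleave constraint became unsatisfiable")
        weights = np.array([remaining[g] for g in admissible], dtype=float)
        g = admissible[rng.choice(len(admissible), p=weights / weights.sum())]
        seq.append(g)
        remaining[g] -= 1
        run = run + 1 if g == last else 1
        last = g
    return seq


def build_phase_schedule(config: TaskConfig, rng) -> list[ScheduledTrial]:
    """Ordered trial plan: training, no-feedback, then test trials.

    The devaluation event sits between the no-feedback and test blocks (it
    is an event, not a trial, so it does not appear here).  Exp 1 training
    interleaves the two games (half the trials each, no run longer than
    four); its no-feedback block is split evenly and its test block is
    balanced 10/10 across games in random order.  Exp 2 appends the
    stabilized block to the drifting trials.
    """
    rng = _as_rng(rng)
    schedule: list[ScheduledTrial] = []
    visits = {g: 0 for g in config.games}
    t = 0

    if config.experiment == "exp1":
        order = _constrained_interleave(
            {g: config.trials_per_game for g in config.games}, MAX_RUN, rng)
    else:
        order = ["single"] * config.n_training
    for g in order:
        stab = visits[g] >= config.n_walk_steps
        schedule.append(ScheduledTrial(t, "training", g, visits[g], stab))
        visits[g] += 1
        t += 1

    if config.experiment == "exp1":
        nf = [g for g in config.games for _ in range(config.n_nofeedback // config.n_games)]
        rng.shuffle(nf)
    else:
        nf = ["single"] * config.n_nofeedback
    for g in nf:
        schedule.append(ScheduledTrial(t, "nofeedback", g, visits[g], False))
        visits[g] += 1
        t += 1

    if config.experiment == "exp1":
        test = [g for g in config.games for _ in range(config.n_test // config.n_games)]
        rng.shuffle(test)
    else:
        test = ["single"] * config.n_test
    for g in test:
        schedule.append(ScheduledTrial(t, "test", g, visits[g], False))
        visits[g] += 1
        t += 1
    return schedule
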