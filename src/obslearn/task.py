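"""Synthetic two-armed-bandit observational-learning experiments.

One *visit* (one stimulation session: vertex or dmpfc) comprises several
sub-sessions; each sub-session presents every condition once, with a fresh
stimulus pair and a fresh demonstrator per block.  The five conditions cross
two kinds of observable information (Action-Outcome: the demonstrator's
outcome is shown; Action-Only: it is scrambled) with two demonstrator
qualities (superb / bad), plus an individual-learning condition in which the
observer learns from their own outcomes instead.

Defaults follow the study design: 2 sites x 3 sub-sessions x 5 conditions x
2 blocks x 11 trials (330 trials per visit), reward probabilities 70%/30%
constant within a block, the first trial of each block without an
observation phase.  The superb demonstrator is a Q-learner (learning rate
0.3) accepted only if it picks the better option on 70-90% of the block's
trials (8 or 9 of 11); the bad demonstrator chooses uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import ModelRunner, ParameterSet, get_model

__all__ = [
    "CONDITIONS",
    "SITES",
    "RewardSchedule",
    "ExperimentDesign",
    "DemonstratorTrace",
    "DesignError",
    "GenerationFailure",
    "build_design",
    "draw_outcome",
    "simulate_demonstrator",
    "simulate_observer",
]

SITES = ("vertex", "dmpfc")
CONDITIONS = (
    "action_outcome_superb",
    "action_outcome_bad",
    "action_only_superb",
    "action_only_bad",
    "individual",
)


class DesignError(ValueError):
    """Invalid experiment-design configuration."""


class GenerationFailure(RuntimeError):
    """Rejection sampling for a demonstrator block exceeded its attempt cap."""


def condition_quality(condition: str) -> str | None:
    if condition.endswith("_superb"):
        return "superb"
    if condition.endswith("_bad"):
        return "bad"
    return None


def condition_outcome_visible(condition: str) -> bool:
    return condition.startswith("action_outcome")


@dataclass(frozen=True)
class RewardSchedule:
    """Constant Bernoulli reward rates for the (better, worse) option."""

    p_better: float = 0.7
    p_worse: float = 0.3

    def __post_init__(self) -> None:
        for p in (self.p_better, self.p_worse):
            if not 0.0 <= p <= 1.0:
                raise DesignError(f"reward probability {p} outside [0, 1]")

    def rate(self, action: int) -> float:
        return self.p_better if action == 1 else self.p_worse


@dataclass(frozen=True)
class ExperimentDesign:
    sessions: tuple[str, ...] = SITES
    conditions: tuple[str, ...] = CONDITIONS
    subsessions_per_visit: int = 3
    blocks_per_condition_per_subsession: int = 2
    trials_per_block: int = 11
    schedule: RewardSchedule = field(default_factory=RewardSchedule)
    # generation settings for the demonstrators
    demonstrator_alpha: float = 0.3
    demonstrator_beta: float = 9.0
    superb_band: tuple[float, float] = (0.70, 0.90)
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        for name in (
            "subsessions_per_visit",
            "blocks_per_condition_per_subsession",
            "trials_per_block",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise DesignError(f"{name} must be a positive integer, got {v!r}")
        if not self.conditions:
            raise DesignError("at least one condition required")
        if not 0.0 < self.schedule.p_better < 1.0 or not 0.0 < self.schedule.p_worse < 1.0:
            raise DesignError("reward probabilities must lie strictly inside (0, 1)")

    @property
    def blocks_per_visit(self) -> int:
        return (
            self.subsessions_per_visit
            * len(self.conditions)
            * self.blocks_per_condition_per_subsession
        )

    @property
    def trials_per_visit(self) -> int:
        return self.blocks_per_visit * self.trials_per_block


def build_design(config: dict | None = None, **overrides) -> ExperimentDesign:
    """Construct an :class:`ExperimentDesign` from a flat config mapping.

    Unknown keys raise; invalid counts raise :class:`DesignError`.  With no
    arguments this returns the default study design (330 trials per visit).
    """
    cfg = dict(config or {})
    cfg.update(overrides)
    if "p_better" in cfg or "p_worse" in cfg:
        cfg["schedule"] = RewardSchedule(
            p_better=cfg.pop("p_better", 0.7), p_worse=cfg.pop("p_worse", 0.3)
        )
    if "conditions" in cfg:
        cfg["conditions"] = tuple(cfg["conditions"])
    if "sessions" in cfg:
        cfg["sessions"] = tuple(cfg["sessions"])
    valid = set(ExperimentDesign.__dataclass_fields__)
    unknown = set(cfg) - valid
    if unknown:
        raise DesignError(f"unknown design keys: {sorted(unknown)}")
    return ExperimentDesign(**cfg)


def draw_outcome(action: int, schedule: RewardSchedule, rng: np.random.Generator) -> int:
    """Bernoulli reward for acting on ``action`` (1 = better option)."""
    if action not in (0, 1):
        raise ValueError(f"action must be 0 or 1, got {action!r}")
    p = schedule.rate(action)
    if not 0.0 <= p <= 1.0:
        raise DesignError(f"reward rate {p} outside [0, 1]")
    return int(rng.random() < p)


@dataclass(frozen=True)
class DemonstratorTrace:
    """One block of demonstrator behavior (actions: 1 = better option)."""

    actions: np.ndarray
    rewards: np.ndarray
    quality: str

    @property
    def prop_better(self) -> float:
        return float(np.mean(self.actions))


def _qlearner_block(
    n_trials: int,
    schedule: RewardSchedule,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    q = [0.5, 0.5]
    actions = np.empty(n_trials, dtype=np.int8)
    rewards = np.empty(n_trials, dtype=np.int8)
    for t in range(n_trials):
        x = beta * (q[1] - q[0])
        p1 = 1.0 / (1.0 + np.exp(-x)) if x >= 0 else np.exp(x) / (1.0 + np.exp(x))
        a = int(rng.random() < p1)
        r = draw_outcome(a, schedule, rng)
        q[a] += alpha * (r - q[a])
        actions[t] = a
        rewards[t] = r
    return actions, rewards


def simulate_demonstrator(
    quality: str,
    design: ExperimentDesign,
    rng: np.random.Generator,
    *,
    block_label: str = "",
) -> DemonstratorTrace:
    """Generate one block of demonstrator behavior.

    ``superb`` runs a Q-learner (learning rate ``design.demonstrator_alpha``,
    softmax temperature ``design.demonstrator_beta``) on the block's reward
    schedule and rejection-samples whole blocks until the proportion of
    better-option choices falls inside ``design.superb_band`` (for 11 trials:
    exactly 8 or 9).  ``bad`` chooses uniformly at random.  Rewards are always
    drawn from the schedule given the action.
    """
    n = design.trials_per_block
    if quality == "bad":
        actions = (rng.random(n) < 0.5).astype(np.int8)
        rewards = np.array(
            [draw_outcome(int(a), design.schedule, rng) for a in actions], dtype=np.int8
        )
        return DemonstratorTrace(actions, rewards, "bad")
    if quality != "superb":
        raise ValueError(f"quality must be 'superb' or 'bad', got {quality!r}")
    lo, hi = design.superb_band
    for _ in range(design.max_attempts):
        actions, rewards = _qlearner_block(
            n, design.schedule, design.demonstrator_alpha, design.demonstrator_beta, rng
        )
        prop = actions.mean()
        if lo <= prop <= hi:
            return DemonstratorTrace(actions, rewards, "superb")
    raise GenerationFailure(
        f"no superb block within {design.max_attempts} attempts"
        + (f" (block {block_label})" if block_label else "")
    )


def _visit_block_order(design: ExperimentDesign, rng: np.random.Generator):
    """Ordered (condition, block_id) pairs for one visit.

    Condition order is randomized independently within each sub-session;
    every block gets a distinct stimulus-pair identifier.
    """
    blocks = []
    pair = 0
    for ss in range(1, design.subsessions_per_visit + 1):
        conds = list(design.conditions)
        rng.shuffle(conds)
        for cond in conds:
            for b in range(1, design.blocks_per_condition_per_subsession + 1):
                pair += 1
                blocks.append((cond, f"ss{ss}-{cond}-b{b}", f"pair{pair:02d}"))
    return blocks


def simulate_observer(
    model: int | str,
    params: ParameterSet,
    design: ExperimentDesign,
    rng: np.random.Generator,
    *,
    subject: str = "s01",
    sites: tuple[str, ...] | None = None,
    traces: dict[tuple[str, str], DemonstratorTrace] | None = None,
    individual_alpha: float = 0.3,
    sticky: bool = True,
) -> pd.DataFrame:
    """Simulate one subject's full experiment from a learning model.

    Predictions and choices are sampled trial-by-trial from the model's
    probabilities (the same :class:`~obslearn.models.ModelRunner` machinery
    the likelihood uses); the stimulation divisor ``tau`` inside the model
    applies in dmpfc-labelled sessions.  Individual-condition choices come
    from a standard Q-learner on the observer's own outcomes and are not
    meant to be fitted.

    ``traces`` optionally supplies pre-generated demonstrator blocks keyed by
    ``(site, block_id)``; by default each block gets a fresh demonstrator.
    """
    spec = get_model(model)
    sites = tuple(sites) if sites is not None else design.sessions
    rows = []
    for site in sites:
        for cond, block_id, pair_id in _visit_block_order(design, rng):
            quality = condition_quality(cond)
            visible = condition_outcome_visible(cond)
            if quality is not None:
                key = (site, block_id)
                if traces is not None:
                    if key not in traces:
                        raise ValueError(f"missing demonstrator trace for block {key}")
                    trace = traces[key]
                else:
                    trace = simulate_demonstrator(quality, design, rng, block_label=block_id)
                runner = ModelRunner(spec, params, site, cond.startswith("action_only"),
                                     sticky=sticky)
                q_ind = None
            else:
                trace = None
                runner = None
                q_ind = [0.5, 0.5]
            for t in range(1, design.trials_per_block + 1):
                obs_absent = t == 1
                rec = {
                    "subject": subject,
                    "site": site,
                    "condition": cond,
                    "block": block_id,
                    "stimulus_pair": pair_id,
                    "trial": t,
                    "observation_absent": obs_absent,
                    "outcome_visible": visible and not obs_absent,
                    "dem_action": pd.NA,
                    "dem_reward": pd.NA,
                    "prediction": pd.NA,
                }
                if trace is not None and not obs_absent:
                    a = int(trace.actions[t - 1])
                    r = int(trace.rewards[t - 1])
                    p_pred = runner.prediction_probability()
                    pred = int(rng.random() < p_pred)
                    runner.record_prediction(pred)
                    runner.observe(a, float(r) if visible else None)
                    rec["dem_action"] = a
                    # the demonstrator's reward is logged even when it was
                    # shown scrambled; outcome_visible gates what models use
                    rec["dem_reward"] = r
                    rec["prediction"] = pred
                if runner is not None:
                    p_choice = runner.choice_probability()
                    choice = int(rng.random() < p_choice)
                    runner.record_choice(choice)
                    reward = draw_outcome(choice, design.schedule, rng)
                else:
                    # individual learning: own outcomes are visible
                    from .models import response_probability

                    prev = rows[-1]["choice"] if (t > 1 and rows) else -1
                    p_choice = response_probability(
                        q_ind[1], q_ind[0], params.beta, params.rho,
                        ca=1 if prev == 1 else 0, cb=1 if prev == 0 else 0,
                        sticky=sticky,
                    )
                    choice = int(rng.random() < p_choice)
                    reward = draw_outcome(choice, design.schedule, rng)
                    q_ind[choice] += individual_alpha * (reward - q_ind[choice])
                rec["choice"] = choice
                rec["observer_reward"] = reward
                rows.append(rec)
    df = pd.DataFrame(rows)
    for col in ("dem_action", "dem_reward", "prediction", "choice", "observer_reward", "trial"):
        df[col] = df[col].astype("Int64")
    return df
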