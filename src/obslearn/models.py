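"""The six observational-learning models.

All models share a common skeleton.  On every observation the observer runs
an internal simulation of the demonstrator (:mod:`obslearn.belief`), and
learns along two channels:

* an **outcome channel** — the simulated value ``Q_outcome`` of the chosen
  option moves toward the demonstrator's received reward with learning rate
  ``alpha`` (only when the outcome is visible, i.e. Action-Outcome blocks);
* an **action channel** — the expected choice probability ``Q_action`` moves
  toward the observed action with learning rate ``kappa`` (on every observed
  trial; the chosen option moves toward 1, the unchosen toward 0, so the two
  values behave as complementary accumulated choice probabilities).

The channels are mixed into an option value ``V = w*Q_outcome +
(1-w)*Q_action`` (``w`` is forced to 0 in Action-Only blocks, where no
outcome is ever shown), and responses follow a softmax with temperature
``beta`` and a perseverance term ``rho`` coupling the response to the
previous one.

The six models differ in how downregulating stimulation (the ``dmpfc``
session label) is allowed to change learning:

=======  =====================  ==============================================
 model    name                   stimulation mechanism (dmpfc sessions)
=======  =====================  ==============================================
 1        outcome                outcome rate divided by ``tau``
 2        action                 action rate divided by ``tau``
 3        action-outcome         both rates divided by ``tau``
 4        predictability-outcome outcome rate replaced by learned
                                 predictability AcP; ``tau`` divides the
                                 predictability learning rate ``upsilon``
 5        predictability-action  action rate replaced by AcP; ``tau`` divides
                                 ``upsilon``
 6        predictability-both    both rates replaced by AcP; ``tau`` divides
                                 ``upsilon``
=======  =====================  ==============================================

Predictability is one minus the Shannon entropy (base 2) of the simulated
demonstrator choice distribution, accumulated across trials into ``AcP``
with learning rate ``upsilon`` — a running estimate of how predictable the
demonstrator is, which models 4-6 use as a dynamic learning rate.

``tau = 1`` makes every dmpfc computation identical to vertex in all six
models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .belief import FIXED_ALPHA_DEM, FIXED_BETA_DEM, DemonstratorBelief, step_belief

__all__ = [
    "ModelSpec",
    "MODELS",
    "get_model",
    "ParameterSet",
    "PARAM_NAMES",
    "PARAM_RANGES",
    "LatentState",
    "ModelRunner",
    "predictability_of",
    "update_acp",
    "observe_and_update",
    "response_probability",
    "negative_log_likelihood",
]

#: Canonical parameter order shared with the numba core and the sampler.
PARAM_NAMES = ("alpha", "kappa", "w", "beta", "rho", "tau", "upsilon")

#: Native ranges; all parameters live on [0, high] with a linear unit map.
PARAM_RANGES = {
    "alpha": (0.0, 1.0),
    "kappa": (0.0, 1.0),
    "w": (0.0, 1.0),
    "beta": (0.0, 30.0),
    "rho": (0.0, 3.0),
    "tau": (0.0, 10.0),
    "upsilon": (0.0, 1.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """Static description of one model variant.

    ``outcome_mod`` / ``action_mod`` name the stimulation mechanism on each
    learning channel: ``None`` (channel untouched), ``"tau"`` (rate divided
    by tau in dmpfc sessions) or ``"acp"`` (rate replaced by accumulated
    predictability; tau then divides the predictability learning rate).
    """

    id: int
    name: str
    outcome_mod: str | None
    action_mod: str | None

    @property
    def family(self) -> str:
        return "predictability" if self.uses_acp else "direct"

    @property
    def uses_acp(self) -> bool:
        return self.outcome_mod == "acp" or self.action_mod == "acp"

    @property
    def free_params(self) -> tuple[str, ...]:
        names = ["alpha", "kappa", "w", "beta", "rho", "tau"]
        if self.outcome_mod == "acp":
            names.remove("alpha")
        if self.action_mod == "acp":
            names.remove("kappa")
        if self.uses_acp:
            names.append("upsilon")
        return tuple(names)


MODELS: dict[int, ModelSpec] = {
    1: ModelSpec(1, "outcome", "tau", None),
    2: ModelSpec(2, "action", None, "tau"),
    3: ModelSpec(3, "action-outcome", "tau", "tau"),
    4: ModelSpec(4, "predictability-outcome", "acp", None),
    5: ModelSpec(5, "predictability-action", None, "acp"),
    6: ModelSpec(6, "predictability-both", "acp", "acp"),
}


def get_model(model: int | str | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    if isinstance(model, str):
        for spec in MODELS.values():
            if spec.name == model:
                return spec
        raise KeyError(f"unknown model name {model!r}")
    if model not in MODELS:
        raise KeyError(f"model id must be 1..6, got {model!r}")
    return MODELS[model]


@dataclass
class ParameterSet:
    """Native-scale parameters for one subject, one model, one stream.

    ``stream`` tags which behavior the softmax parameters belong to
    (choices for self vs predictions of demonstrator actions); ``tau`` is
    correspondingly tau_choice or tau_prediction.
    """

    alpha: float = 0.3
    kappa: float = 0.3
    w: float = 0.5
    beta: float = 6.0
    rho: float = 0.3
    tau: float = 1.0
    upsilon: float = 0.4
    stream: str = "choice"

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = PARAM_RANGES[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(
                    f"{name}={v} outside native range [{lo}, {hi}]"
                )

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def predictability_of(p: tuple[float, float] | np.ndarray, *, atol: float = 1e-8) -> float:
    """Predictability = 1 − H(p) with base-2 entropy over two options.

    With two options H is in [0, 1], so predictability is in [0, 1]:
    0 for a coin-flip demonstrator, 1 for a fully deterministic one.
    Uses the 0·log 0 := 0 convention.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > atol:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
    h = 0.0
    for pi in p:
        if pi > 0:
            h -= pi * math.log2(pi)
    return 1.0 - h


def update_acp(acp: float, predictability: float, upsilon: float, tau: float, site: str) -> float:
    """One delta-rule step of accumulated predictability.

    Vertex sessions learn at rate ``upsilon``; dmpfc sessions at
    ``upsilon / tau`` (tau = 1 reduces to the vertex update).
    """
    if site not in ("vertex", "dmpfc"):
        raise ValueError(f"site must be 'vertex' or 'dmpfc', got {site!r}")
    if not 0.0 <= upsilon <= 1.0:
        raise ValueError(f"upsilon={upsilon} outside [0, 1]")
    rate = upsilon
    if site == "dmpfc":
        if tau == 0:
            raise ZeroDivisionError("tau = 0 under dmpfc stimulation")
        rate = upsilon / tau
    return acp + rate * (predictability - acp)


def response_probability(
    va: float,
    vb: float,
    beta: float,
    rho: float,
    ca: int = 0,
    cb: int = 0,
    *,
    sticky: bool = True,
) -> float:
    """Softmax probability of option a with a perseverance term.

    ``p(a) = logistic(beta*(va - vb) + rho*(ca - cb))`` with the default
    (sticky) sign convention, under which positive rho attracts the response
    toward the previous one; ``sticky=False`` flips the sign so positive rho
    repels instead.  On a block's first trial both indicators are 0.
    """
    sign = 1.0 if sticky else -1.0
    x = beta * (va - vb) + sign * rho * (ca - cb)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# per-block latent state and trial stepping
# ---------------------------------------------------------------------------

@dataclass
class LatentState:
    """Observer learning state within one block (option 1 = better option)."""

    q_outcome: list = field(default_factory=lambda: [0.5, 0.5])
    q_action: list = field(default_factory=lambda: [0.5, 0.5])
    acp: float = 0.0
    prev_choice: int = -1
    prev_prediction: int = -1
    predictability: float = float("nan")
    entropy: float = float("nan")

    def values(self, w: float) -> tuple[float, float]:
        va = w * self.q_outcome[0] + (1.0 - w) * self.q_action[0]
        vb = w * self.q_outcome[1] + (1.0 - w) * self.q_action[1]
        return va, vb


def observe_and_update(
    spec: ModelSpec,
    state: LatentState,
    params: ParameterSet,
    action: int,
    reward: float | None,
    site: str,
) -> LatentState:
    """Apply one trial's value updates to the latent state (in place).

    The outcome channel updates only when a reward was visible; the action
    channel updates on every observed action.  Effective rates follow the
    model's stimulation mechanism; accumulated predictability must already
    have been updated for this trial (``ModelRunner`` guarantees the order).
    """
    dmpfc = site == "dmpfc"
    if reward is not None:
        rate = params.alpha
        if spec.outcome_mod == "tau" and dmpfc:
            rate = params.alpha / params.tau
        elif spec.outcome_mod == "acp":
            rate = state.acp
        state.q_outcome[action] += rate * (reward - state.q_outcome[action])
    rate = params.kappa
    if spec.action_mod == "tau" and dmpfc:
        rate = params.kappa / params.tau
    elif spec.action_mod == "acp":
        rate = state.acp
    state.q_action[action] += rate * (1.0 - state.q_action[action])
    other = 1 - action
    state.q_action[other] += rate * (0.0 - state.q_action[other])
    return state


class ModelRunner:
    """Step one block of one model trial-by-trial.

    Encapsulates the within-trial order of operations: prediction response
    (pre-observation values) → observe demonstrator action/outcome → belief
    step → predictability / AcP update → value update → own choice
    (post-update values).  Both the likelihood and the simulator drive this
    runner, so simulated data and fitted likelihoods share one code path.
    """

    def __init__(
        self,
        spec: ModelSpec,
        params: ParameterSet,
        site: str,
        action_only: bool,
        *,
        alpha_dem: float = FIXED_ALPHA_DEM,
        beta_dem: float = FIXED_BETA_DEM,
        sticky: bool = True,
    ) -> None:
        self.spec = get_model(spec)
        self.params = params
        self.site = site
        self.action_only = bool(action_only)
        self.sticky = sticky
        self.belief = DemonstratorBelief(alpha=alpha_dem, beta=beta_dem)
        self.state = LatentState()
        self.rate_overflow = False  # diagnostic: an effective rate exceeded 1

    @property
    def w(self) -> float:
        return 0.0 if self.action_only else self.params.w

    def prediction_probability(self) -> float:
        """P(predict better option), using pre-observation values."""
        va, vb = self.state.values(self.w)
        pa = self.state.prev_prediction
        return response_probability(
            vb, va, self.params.beta, self.params.rho,
            ca=1 if pa == 1 else 0, cb=1 if pa == 0 else 0,
            sticky=self.sticky,
        )

    def record_prediction(self, prediction: int) -> None:
        self.state.prev_prediction = int(prediction)

    def observe(self, action: int, reward: float | None) -> None:
        """Process the observation phase of one trial."""
        # belief step; hidden outcomes are replaced by a pseudo-reward of 1
        # for the chosen option so the simulation tracks choice tendencies
        r_sim = 1.0 if reward is None else float(reward)
        self.belief, _ = step_belief(self.belief, action, r_sim)
        if self.spec.uses_acp:
            p1 = self.belief.p_better
            pred = predictability_of((1.0 - p1, p1))
            self.state.predictability = pred
            self.state.entropy = 1.0 - pred
            rate = self.params.upsilon
            if self.site == "dmpfc":
                rate = self.params.upsilon / self.params.tau
            if rate > 1.0:
                self.rate_overflow = True
            self.state.acp = update_acp(
                self.state.acp, pred, self.params.upsilon, self.params.tau, self.site
            )
        if self.site == "dmpfc" and "tau" in (self.spec.outcome_mod, self.spec.action_mod):
            if self.params.tau > 0 and max(self.params.alpha, self.params.kappa) / self.params.tau > 1.0:
                self.rate_overflow = True
        observe_and_update(self.spec, self.state, self.params, action, reward, self.site)

    def choice_probability(self) -> float:
        """P(choose better option), using post-update values."""
        va, vb = self.state.values(self.w)
        pc = self.state.prev_choice
        return response_probability(
            vb, va, self.params.beta, self.params.rho,
            ca=1 if pc == 1 else 0, cb=1 if pc == 0 else 0,
            sticky=self.sticky,
        )

    def record_choice(self, choice: int) -> None:
        self.state.prev_choice = int(choice)


# ---------------------------------------------------------------------------
# likelihood over a trial table
# ---------------------------------------------------------------------------

def _is_action_only(condition: str) -> bool:
    return str(condition).startswith("action_only")


def negative_log_likelihood(
    model: int | str | ModelSpec,
    params: ParameterSet,
    trials: pd.DataFrame,
    stream: str = "choice",
    *,
    sticky: bool = True,
    return_trace: bool = False,
):
    """Total negative log-likelihood of one subject's responses.

    Iterates blocks in order (state resets at block boundaries), replays the
    within-trial machinery, and sums ``−log p(observed response)`` for the
    requested behavior stream.  Individual-learning trials are excluded
    automatically.

    Parameters
    ----------
    trials
        Trial table for a single subject (both sites allowed), in the schema
        of :mod:`obslearn.io`.
    stream
        ``"choice"`` scores choices for self on every trial; ``"prediction"``
        scores predictions of the demonstrator's action on observation trials.
    return_trace
        Also return a DataFrame with the per-trial response probabilities
        and latent quantities, for debugging and cross-checks.

    Raises
    ------
    ValueError
        If a scored response is missing, or the accumulation becomes
        non-finite (the offending row index is named).
    """
    spec = get_model(model)
    if stream not in ("choice", "prediction"):
        raise ValueError(f"stream must be 'choice' or 'prediction', got {stream!r}")
    obs = trials[trials["condition"] != "individual"]
    if obs.empty:
        raise ValueError("no observational-condition trials in table")

    nll = 0.0
    rows = []
    for (_, _, _), block in obs.groupby(["site", "condition", "block"], sort=True):
        block = block.sort_values("trial")
        site = str(block["site"].iloc[0])
        cond = str(block["condition"].iloc[0])
        runner = ModelRunner(spec, params, site, _is_action_only(cond), sticky=sticky)
        for idx, row in block.iterrows():
            obs_absent = bool(row["observation_absent"])
            p_pred = float("nan")
            if not obs_absent:
                p_pred = runner.prediction_probability()
                pred = row["prediction"]
                if pd.isna(pred):
                    if stream == "prediction":
                        raise ValueError(f"missing prediction at row {idx}")
                else:
                    if stream == "prediction":
                        p = p_pred if int(pred) == 1 else 1.0 - p_pred
                        nll -= math.log(p) if p > 0 else -math.inf
                    runner.record_prediction(int(pred))
                # the outcome drives learning only when it was actually shown
                reward = row["dem_reward"]
                visible = bool(row["outcome_visible"]) and not pd.isna(reward)
                runner.observe(
                    int(row["dem_action"]),
                    float(reward) if visible else None,
                )
            p_choice = runner.choice_probability()
            choice = row["choice"]
            if pd.isna(choice):
                raise ValueError(f"missing choice at row {idx}")
            if stream == "choice":
                p = p_choice if int(choice) == 1 else 1.0 - p_choice
                nll -= math.log(p) if p > 0 else -math.inf
            runner.record_choice(int(choice))
            if not math.isfinite(nll):
                raise ValueError(f"non-finite likelihood accumulation at row {idx}")
            rows.append(
                {
                    "row": idx,
                    "site": site,
                    "condition": cond,
                    "block": row["block"],
                    "trial": row["trial"],
                    "p_prediction": p_pred,
                    "p_choice": p_choice,
                    "acp": runner.state.acp,
                    "predictability": runner.state.predictability,
                }
            )
        if runner.rate_overflow:
            warnings.warn(
                f"effective learning rate exceeded 1 (tau < rate) in block "
                f"{block['block'].iloc[0]!r}",
                RuntimeWarning,
                stacklevel=2,
            )
    if return_trace:
        return nll, pd.DataFrame(rows)
    return nll
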